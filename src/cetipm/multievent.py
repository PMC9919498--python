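"""Multievent capture-recapture model: matrices and forward likelihood.

Encounter histories of marked individuals are modelled as a hidden Markov
chain over demographic states, observed through integer event codes that
may be ambiguous (a detected prebreeder or nonbreeder female may only be
recorded as "seen alone"; a detected adult male may only be recorded as
"seen as adult").  The likelihood of a history conditions on the first
detection and is computed with the forward algorithm.

Conventions
-----------
* Occasion = calendar year; transitions are applied before emissions, and
  "state" refers to the year of observation.
* Transition matrix for year ``t`` governs the ``t -> t+1`` step.
* The dead state is absorbing and emits "not seen" with certainty; dead
  individuals are never recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .params import DetectionParams, RateSeries
from .states import (
    EVENT_NOT_SEEN,
    F_BC1, F_BC2, F_BC3, F_BY, F_DEAD, F_JUV, F_NB, F_PB,
    M_AD, M_ADNT, M_DEAD, M_JUV, M_SUB,
    N_FEMALE_EVENTS, N_FEMALE_STATES, N_MALE_EVENTS, N_MALE_STATES,
)

__all__ = [
    "CaptureHistory",
    "female_transition_matrix",
    "male_transition_matrix",
    "female_event_matrix",
    "male_event_matrix",
    "detection_probability",
    "initial_state_distribution",
    "history_loglik",
    "dataset_loglik",
    "standardize_effort",
    "build_matrices",
]


@dataclass
class CaptureHistory:
    """One marked individual's event sequence from first detection onward.

    ``events[k]`` is the event code observed in year ``first_year + k``;
    the first entry is never 1 ("not seen").
    """

    individual_id: int
    sex: str  # "F" or "M"
    first_year: int
    events: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=int)
        if self.events.size == 0:
            raise ValueError("history must contain at least one event")
        if self.events[0] == EVENT_NOT_SEEN:
            raise ValueError("histories start at first detection; first event cannot be 1")
        if self.sex not in ("F", "M"):
            raise ValueError(f"unknown sex code {self.sex!r}")

    @property
    def n_years(self) -> int:
        return len(self.events)


def _validated(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


def female_transition_matrix(phiF, phiBy, F, gamma, psiJuvPb, psiPbBy) -> np.ndarray:
    """8x8 row-stochastic female transition matrix (rows: state at t).

    Breeders keep their calf only while both mother (phiF) and calf
    (phiBy, conditional on the mother) survive; a 2-year-old calf stays a
    further year with probability ``F``.  Mothers whose calf dies or
    weans move to the nonbreeder state, from which they re-breed at rate
    ``gamma``.  Remaining mass in each row goes to the absorbing dead
    state.
    """
    phiF = _validated("phiF", phiF)
    phiBy = _validated("phiBy", phiBy)
    F = _validated("F", F)
    gamma = _validated("gamma", gamma)
    psiJuvPb = _validated("psiJuvPb", psiJuvPb)
    psiPbBy = _validated("psiPbBy", psiPbBy)

    T = np.zeros((N_FEMALE_STATES, N_FEMALE_STATES))
    T[F_JUV, F_PB] = phiF * psiJuvPb
    T[F_JUV, F_JUV] = phiF * (1 - psiJuvPb)
    T[F_PB, F_BY] = phiF * psiPbBy
    T[F_PB, F_PB] = phiF * (1 - psiPbBy)
    T[F_BY, F_BC1] = phiF * phiBy
    T[F_BY, F_NB] = phiF * (1 - phiBy)
    T[F_BC1, F_BC2] = phiF * phiBy
    T[F_BC1, F_NB] = phiF * (1 - phiBy)
    T[F_BC2, F_BC3] = phiF * phiBy * F
    T[F_BC2, F_NB] = phiF * (1 - phiBy * F)
    T[F_BC3, F_NB] = phiF
    T[F_NB, F_BY] = phiF * gamma
    T[F_NB, F_NB] = phiF * (1 - gamma)
    T[:, F_DEAD] = 1.0 - T.sum(axis=1)
    T[F_DEAD, :] = 0.0
    T[F_DEAD, F_DEAD] = 1.0
    return T


def male_transition_matrix(phiJuvSub, phiAd, psiM) -> np.ndarray:
    """5x5 male transition matrix; one shared stage-advance rate ``psiM``."""
    phiJuvSub = _validated("phiJuvSub", phiJuvSub)
    phiAd = _validated("phiAd", phiAd)
    psiM = _validated("psiM", psiM)

    T = np.zeros((N_MALE_STATES, N_MALE_STATES))
    T[M_JUV, M_SUB] = phiJuvSub * psiM
    T[M_JUV, M_JUV] = phiJuvSub * (1 - psiM)
    T[M_SUB, M_ADNT] = phiJuvSub * psiM
    T[M_SUB, M_SUB] = phiJuvSub * (1 - psiM)
    T[M_ADNT, M_AD] = phiAd * psiM
    T[M_ADNT, M_ADNT] = phiAd * (1 - psiM)
    T[M_AD, M_AD] = phiAd
    T[:, M_DEAD] = 1.0 - T.sum(axis=1)
    T[M_DEAD, :] = 0.0
    T[M_DEAD, M_DEAD] = 1.0
    return T


def female_event_matrix(p, deltaPb, deltaNb) -> np.ndarray:
    """8x7 emission matrix (rows: states, columns: events 1..7).

    All breeding states are ascertained with certainty when detected;
    detected prebreeders/nonbreeders are classified with probability
    ``deltaPb``/``deltaNb`` and otherwise produce event 7 ("seen alone").
    """
    p = _validated("p", p)
    deltaPb = _validated("deltaPb", deltaPb)
    deltaNb = _validated("deltaNb", deltaNb)

    E = np.zeros((N_FEMALE_STATES, N_FEMALE_EVENTS))
    E[:F_DEAD, 0] = 1 - p          # event 1: not seen
    E[F_JUV, 1] = p                # event 2
    E[F_PB, 2] = p * deltaPb       # event 3
    E[F_PB, 6] = p * (1 - deltaPb)
    E[F_BY, 3] = p                 # event 4
    E[F_BC1, 4] = p                # event 5 (calf age is latent)
    E[F_BC2, 4] = p
    E[F_BC3, 4] = p
    E[F_NB, 5] = p * deltaNb       # event 6
    E[F_NB, 6] = p * (1 - deltaNb)
    E[F_DEAD, 0] = 1.0
    return E


def male_event_matrix(p_by_stage, deltaAdNt, deltaAd) -> np.ndarray:
    """5x6 emission matrix with stage-specific detection (Juv, Sub, AdNt, Ad)."""
    p = np.asarray(p_by_stage, dtype=float)
    if p.shape != (4,):
        raise ValueError("p_by_stage must have four entries (Juv, Sub, AdNt, Ad)")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p_by_stage entries must lie in [0, 1]")
    deltaAdNt = _validated("deltaAdNt", deltaAdNt)
    deltaAd = _validated("deltaAd", deltaAd)

    E = np.zeros((N_MALE_STATES, N_MALE_EVENTS))
    E[:M_DEAD, 0] = 1 - p
    E[M_JUV, 1] = p[M_JUV]
    E[M_SUB, 2] = p[M_SUB]
    E[M_ADNT, 3] = p[M_ADNT] * deltaAdNt
    E[M_ADNT, 5] = p[M_ADNT] * (1 - deltaAdNt)
    E[M_AD, 4] = p[M_AD] * deltaAd
    E[M_AD, 5] = p[M_AD] * (1 - deltaAd)
    E[M_DEAD, 0] = 1.0
    return E


def detection_probability(alpha, beta_effort, effort_z, epsilon_t=0.0):
    """Inverse-logit detection probability, strictly inside (0, 1)."""
    return expit(np.asarray(alpha) + np.asarray(beta_effort) * np.asarray(effort_z)
                 + np.asarray(epsilon_t))


def initial_state_distribution(first_event: int, event_matrix: np.ndarray) -> np.ndarray:
    """State distribution at first capture, given the first observed event.

    A uniform prior over living states is updated by the emission
    probability of the first event; the returned vector spans all states
    with zero mass on the dead state and sums to one.
    """
    if first_event == EVENT_NOT_SEEN:
        raise ValueError("histories start at first detection; first event cannot be 1")
    n_states, n_events = event_matrix.shape
    if not (1 <= first_event <= n_events):
        raise ValueError(f"event code {first_event} outside 1..{n_events}")
    weights = np.zeros(n_states)
    weights[: n_states - 1] = event_matrix[: n_states - 1, first_event - 1]
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"event {first_event} has zero emission probability from every living state")
    return weights / total


def history_loglik(history: CaptureHistory, transitions: np.ndarray,
                   emissions: np.ndarray) -> float:
    """Forward-algorithm log-likelihood of one history, conditional on first capture.

    Parameters
    ----------
    transitions : (n_years - 1, S, S)
        Year-indexed transition matrices for the individual's sex;
        ``transitions[t]`` governs the ``t -> t+1`` step.
    emissions : (n_years, S, E)
        Year-indexed emission matrices.

    Returns ``-inf`` (not an exception) for an event sequence with zero
    probability under the matrices.
    """
    t0 = history.first_year
    if t0 + history.n_years > emissions.shape[0]:
        raise ValueError("emission matrices do not cover the history's years")
    try:
        alpha = initial_state_distribution(history.events[0], emissions[t0])
    except ValueError as err:
        if "zero emission" in str(err):
            return -np.inf
        raise
    for k in range(1, history.n_years):
        year = t0 + k
        alpha = alpha @ transitions[year - 1]
        alpha = alpha * emissions[year][:, history.events[k] - 1]
    total = alpha.sum()
    if total <= 0.0:
        return -np.inf
    return float(np.log(total))


def standardize_effort(effort) -> np.ndarray:
    """Z-score the per-year survey counts (population SD; constant effort -> zeros)."""
    effort = np.asarray(effort, dtype=float)
    sd = effort.std()
    if sd == 0:
        return np.zeros_like(effort)
    return (effort - effort.mean()) / sd


def build_matrices(rates: RateSeries, detection: DetectionParams, effort,
                   eps_F=None, eps_M=None):
    """Year-indexed transition and emission matrices for both sexes.

    ``eps_F``/``eps_M`` are per-year logit-scale detection deviations
    (default zero).  Returns ``(Tf, Tm, Ef, Em)`` with shapes
    ``(T-1, 8, 8)``, ``(T-1, 5, 5)``, ``(T, 8, 7)``, ``(T, 5, 6)``.
    """
    effort = np.asarray(effort, dtype=float)
    n_years = len(effort)
    if rates.n_transitions != n_years - 1:
        raise ValueError(
            f"rate series covers {rates.n_transitions} transitions but effort implies {n_years - 1}"
        )
    eps_F = np.zeros(n_years) if eps_F is None else np.asarray(eps_F, dtype=float)
    eps_M = np.zeros(n_years) if eps_M is None else np.asarray(eps_M, dtype=float)
    if len(eps_F) != n_years or len(eps_M) != n_years:
        raise ValueError("detection year effects must have one entry per year")
    z = standardize_effort(effort)

    Tf = np.empty((n_years - 1, N_FEMALE_STATES, N_FEMALE_STATES))
    Tm = np.empty((n_years - 1, N_MALE_STATES, N_MALE_STATES))
    for t in range(n_years - 1):
        r = rates.at(t)
        Tf[t] = female_transition_matrix(r.phiF, r.phiBy, r.F, r.gamma,
                                         r.psiJuvPb, r.psiPbBy)
        Tm[t] = male_transition_matrix(r.phiJuvSub, r.phiAd, r.psiM)

    Ef = np.empty((n_years, N_FEMALE_STATES, N_FEMALE_EVENTS))
    Em = np.empty((n_years, N_MALE_STATES, N_MALE_EVENTS))
    for t in range(n_years):
        pF = float(detection_probability(detection.alpha_F, detection.beta_effort,
                                         z[t], eps_F[t]))
        pM = detection_probability(detection.alpha_M_by_stage, detection.beta_effort,
                                   z[t], eps_M[t])
        Ef[t] = female_event_matrix(pF, detection.deltaPb, detection.deltaNb)
        Em[t] = male_event_matrix(pM, detection.deltaAdNt, detection.deltaAd)
    return Tf, Tm, Ef, Em


def dataset_loglik(histories, rates: RateSeries, detection: DetectionParams,
                   effort, eps_F=None, eps_M=None) -> float:
    """Sum of history log-likelihoods; each sex uses its own matrices."""
    Tf, Tm, Ef, Em = build_matrices(rates, detection, effort, eps_F, eps_M)
    total = 0.0
    for h in histories:
        if h.sex == "F":
            total += history_loglik(h, Tf, Ef)
        elif h.sex == "M":
            total += history_loglik(h, Tm, Em)
        else:  # pragma: no cover - CaptureHistory already validates
            raise ValueError(f"unknown sex code {h.sex!r}")
    return total
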