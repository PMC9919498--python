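"""Individual-based synthetic data generator.

Simulates a small open population of long-lived, deep-diving whales over
a multi-year photo-identification study: latent individual fates under
the stage-structured demographic process (with correlated year random
effects and Poisson immigration into the juvenile stage), then the
observation layer -- effort-driven, year-varying detection, ambiguous
event codes, annual aggregate counts -- with known "true" parameters, so
every downstream estimator can be validated against the truth.

Calves ride along as attributes of their mother's state and join the
counted population only at weaning, entering the juvenile stage with an
even sex ratio; immigrants do the same.  A configurable fraction of
individuals is unmarked (contributing to counts but never to encounter
histories) and a further fraction has unknown sex until first seen in a
reproductive stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .multievent import CaptureHistory, detection_probability, standardize_effort
from .params import (
    FEMALE_EFFECT_NAMES, MALE_EFFECT_NAMES, RateSeries, TrueParameters,
)
from .population import CountSeries, LatentPopulation
from .states import (
    F_BC1, F_BC2, F_BC3, F_BY, F_DEAD, F_JUV, F_NB, F_PB,
    M_AD, M_ADNT, M_DEAD, M_JUV, M_SUB, N_COUNTED,
)

__all__ = [
    "IndividualFates",
    "SimulatedDataset",
    "draw_rate_series",
    "simulate_effort",
    "simulate_population",
    "generate_observations",
    "simulate_dataset",
]

NOT_PRESENT = -1

# female living stage -> event code emitted when detected and classified
_FEMALE_EVENT = {F_JUV: 2, F_PB: 3, F_BY: 4, F_BC1: 5, F_BC2: 5, F_BC3: 5, F_NB: 6}
_MALE_EVENT = {M_JUV: 2, M_SUB: 3, M_ADNT: 4, M_AD: 5}


@dataclass
class IndividualFates:
    """Latent trajectories of every individual ever present.

    ``stages[i, t]`` is the sex-specific stage index in year ``t``
    (``-1`` before entry, the sex's dead code afterwards).
    """

    sex: np.ndarray           # 0 = female, 1 = male
    marked: np.ndarray        # bool: permanent marks (distinctiveness 2)
    unknown_sex: np.ndarray   # bool: sex not assignable outside reproductive stages
    entry_year: np.ndarray
    immigrant: np.ndarray     # bool
    stages: np.ndarray        # (n_individuals, n_years) int

    @property
    def n_individuals(self) -> int:
        return len(self.sex)

    @property
    def n_years(self) -> int:
        return self.stages.shape[1]

    def alive(self) -> np.ndarray:
        """Boolean (n, T): present and alive."""
        dead = np.where(self.sex[:, None] == 0, F_DEAD, M_DEAD)
        return (self.stages != NOT_PRESENT) & (self.stages != dead)


@dataclass
class SimulatedDataset:
    """Everything one synthetic study produces, latent truth included."""

    fates: IndividualFates
    latent: LatentPopulation
    truth: TrueParameters
    rates: RateSeries          # realized year-specific rates
    seed: int
    histories: list = field(default_factory=list)
    counts: CountSeries | None = None
    effort: np.ndarray | None = None
    eps_F: np.ndarray | None = None
    eps_M: np.ndarray | None = None


def draw_rate_series(params: TrueParameters, rng) -> RateSeries:
    """Realized year-specific rates under the correlated random-effect model.

    Logit-scale deviations for the female block (phiF, phiBy, F, gamma)
    and male block (phiJuvSubM, phiAdM) are multivariate normal with the
    scenario's SDs and correlations; omega is mean-centred lognormal so
    that E[omega_t] = omega_mean.
    """
    T1 = params.n_years - 1
    sds = params.year_effect_sds
    sds_f = np.array([sds.get(k, 0.0) for k in FEMALE_EFFECT_NAMES])
    sds_m = np.array([sds.get(k, 0.0) for k in MALE_EFFECT_NAMES])
    cov_f = np.outer(sds_f, sds_f) * np.asarray(params.year_effect_corr_female)
    cov_m = np.outer(sds_m, sds_m) * np.asarray(params.year_effect_corr_male)
    dev_f = rng.multivariate_normal(np.zeros(4), cov_f, size=T1, method="cholesky") \
        if np.any(sds_f > 0) else np.zeros((T1, 4))
    dev_m = rng.multivariate_normal(np.zeros(2), cov_m, size=T1, method="cholesky") \
        if np.any(sds_m > 0) else np.zeros((T1, 2))

    def series(mean, dev):
        if mean in (0.0, 1.0):
            return np.full(T1, mean)
        return expit(logit(mean) + dev)

    sd_o = sds.get("omega", 0.0)
    omega = params.omega_mean * np.exp(sd_o * rng.standard_normal(T1) - 0.5 * sd_o ** 2) \
        if sd_o > 0 else np.full(T1, float(params.omega_mean))
    return RateSeries(
        phiF=series(params.phiF, dev_f[:, 0]),
        phiBy=series(params.phiBy, dev_f[:, 1]),
        F=series(params.F, dev_f[:, 2]),
        gamma=series(params.gamma, dev_f[:, 3]),
        psiJuvPb=np.full(T1, params.psiJuvPb),
        psiPbBy=np.full(T1, params.psiPbBy),
        phiJuvSub=series(params.phiJuvSubM, dev_m[:, 0]),
        phiAd=series(params.phiAdM, dev_m[:, 1]),
        psiM=np.full(T1, params.psiM),
        omega=omega,
    )


def simulate_effort(params: TrueParameters, rng) -> np.ndarray:
    lo, hi = params.effort_range
    return rng.integers(lo, hi + 1, size=params.n_years)


class _Roster:
    """Growable individual table used during forward simulation."""

    def __init__(self, n_years):
        self.n_years = n_years
        self.sex, self.marked, self.unknown, self.entry, self.imm = [], [], [], [], []
        self.stage_rows = []

    def add(self, sex, stage, year, marked, unknown, immigrant):
        row = np.full(self.n_years, NOT_PRESENT, dtype=np.int64)
        row[year] = stage
        self.sex.append(sex)
        self.marked.append(marked)
        self.unknown.append(unknown)
        self.entry.append(year)
        self.imm.append(immigrant)
        self.stage_rows.append(row)
        return len(self.stage_rows) - 1

    def fates(self) -> IndividualFates:
        return IndividualFates(
            sex=np.array(self.sex, dtype=np.int64),
            marked=np.array(self.marked, dtype=bool),
            unknown_sex=np.array(self.unknown, dtype=bool),
            entry_year=np.array(self.entry, dtype=np.int64),
            immigrant=np.array(self.imm, dtype=bool),
            stages=np.array(self.stage_rows, dtype=np.int64),
        )


def _new_entrant(roster, rng, params, year, immigrant):
    sex = int(rng.random() < 0.5)
    marked = bool(rng.random() < params.mark_fraction)
    unknown = bool(rng.random() < params.unknown_sex_fraction)
    stage = F_JUV if sex == 0 else M_JUV
    roster.add(sex, stage, year, marked, unknown, immigrant)


def simulate_population(params: TrueParameters, seed: int) -> SimulatedDataset:
    """Forward individual-based simulation of latent fates and abundances."""
    params.validate()
    rng = np.random.default_rng(seed)
    T = params.n_years
    rates = draw_rate_series(params, rng)

    roster = _Roster(T)
    # initial population, counted-stage order (7 female cells then 4 male)
    for cell in range(N_COUNTED):
        sex = 0 if cell < 7 else 1
        stage = cell if cell < 7 else cell - 7
        repro = (sex == 0 and stage in (F_BY, F_BC1, F_BC2, F_BC3)) or \
                (sex == 1 and stage == M_AD)
        for _ in range(int(params.initial_sizes[cell])):
            marked = bool(rng.random() < params.mark_fraction)
            unknown = False if repro else bool(rng.random() < params.unknown_sex_fraction)
            roster.add(sex, stage, 0, marked, unknown, False)

    for t in range(T - 1):
        r = rates.at(t)
        n_now = len(roster.stage_rows)
        for i in range(n_now):
            row = roster.stage_rows[i]
            stage = row[t]
            if stage == NOT_PRESENT:
                continue
            if roster.sex[i] == 0:
                if stage == F_DEAD:
                    row[t + 1] = F_DEAD
                    continue
                if rng.random() >= r.phiF:
                    row[t + 1] = F_DEAD
                    # a dependent calf dies with its mother, except a
                    # 3-year-old calf, which weans regardless
                    if stage == F_BC3:
                        _new_entrant(roster, rng, params, t + 1, False)
                    continue
                if stage == F_JUV:
                    row[t + 1] = F_PB if rng.random() < r.psiJuvPb else F_JUV
                elif stage == F_PB:
                    row[t + 1] = F_BY if rng.random() < r.psiPbBy else F_PB
                elif stage in (F_BY, F_BC1):
                    calf_survives = rng.random() < r.phiBy
                    row[t + 1] = (stage + 1) if calf_survives else F_NB
                elif stage == F_BC2:
                    if rng.random() < r.phiBy:          # calf survives
                        if rng.random() < r.F:          # stays a third year
                            row[t + 1] = F_BC3
                        else:                           # weans now
                            row[t + 1] = F_NB
                            _new_entrant(roster, rng, params, t + 1, False)
                    else:
                        row[t + 1] = F_NB
                elif stage == F_BC3:
                    row[t + 1] = F_NB
                    _new_entrant(roster, rng, params, t + 1, False)
                elif stage == F_NB:
                    row[t + 1] = F_BY if rng.random() < r.gamma else F_NB
            else:
                if stage == M_DEAD:
                    row[t + 1] = M_DEAD
                    continue
                surv = r.phiJuvSub if stage in (M_JUV, M_SUB) else r.phiAd
                if rng.random() >= surv:
                    row[t + 1] = M_DEAD
                    continue
                if stage == M_AD:
                    row[t + 1] = M_AD
                else:
                    row[t + 1] = (stage + 1) if rng.random() < r.psiM else stage
        for _ in range(rng.poisson(r.omega)):
            _new_entrant(roster, rng, params, t + 1, True)

    fates = roster.fates()
    latent = _latent_from_fates(fates)
    return SimulatedDataset(fates=fates, latent=latent, truth=params,
                            rates=rates, seed=seed)


def _latent_from_fates(fates: IndividualFates) -> LatentPopulation:
    T = fates.n_years
    N = np.zeros((N_COUNTED, T), dtype=np.int64)
    for t in range(T):
        for sex, offset, n_living in ((0, 0, 7), (1, 7, 4)):
            sel = fates.sex == sex
            stages = fates.stages[sel, t]
            for s in range(n_living):
                N[offset + s, t] = int(np.sum(stages == s))
    return LatentPopulation(N)


def generate_observations(fates: IndividualFates, params: TrueParameters,
                          effort, seed: int):
    """Observation layer: detections, event codes, histories and counts.

    Every living individual is detected each year with its sex/stage/year
    probability; counts are the numbers detected per aggregate (all
    individuals).  Histories cover marked, sex-assignable individuals
    from first detection onward.  Returns ``(histories, counts, eps_F,
    eps_M)``.
    """
    effort = np.asarray(effort)
    if len(effort) != fates.n_years:
        raise ValueError("effort must have one entry per study year")
    det = params.detection
    rng = np.random.default_rng(seed)
    T = fates.n_years
    z = standardize_effort(effort)
    eps_F = rng.normal(0.0, det.sd_year_F, size=T)
    eps_M = rng.normal(0.0, det.sd_year_M, size=T)
    pF = detection_probability(det.alpha_F, det.beta_effort, z, eps_F)
    pM = np.stack([
        detection_probability(det.alpha_M_by_stage, det.beta_effort, z[t], eps_M[t])
        for t in range(T)
    ])

    n = fates.n_individuals
    detected = np.zeros((n, T), dtype=bool)
    events = np.ones((n, T), dtype=np.int64)
    juv_count = np.zeros(T, dtype=np.int64)
    nonrep_count = np.zeros(T, dtype=np.int64)
    breed_count = np.zeros(T, dtype=np.int64)
    tooth_count = np.zeros(T, dtype=np.int64)

    for i in range(n):
        sex = fates.sex[i]
        for t in range(T):
            stage = fates.stages[i, t]
            if stage == NOT_PRESENT:
                continue
            if sex == 0:
                if stage == F_DEAD:
                    continue
                p = pF[t]
                if rng.random() >= p:
                    continue
                detected[i, t] = True
                ev = _FEMALE_EVENT[stage]
                if stage == F_PB and rng.random() >= det.deltaPb:
                    ev = 7
                elif stage == F_NB and rng.random() >= det.deltaNb:
                    ev = 7
                events[i, t] = ev
                if stage == F_JUV:
                    juv_count[t] += 1
                elif stage in (F_PB, F_NB):
                    nonrep_count[t] += 1
                else:
                    breed_count[t] += 1
            else:
                if stage == M_DEAD:
                    continue
                p = pM[t, stage]
                if rng.random() >= p:
                    continue
                detected[i, t] = True
                ev = _MALE_EVENT[stage]
                if stage == M_ADNT and rng.random() >= det.deltaAdNt:
                    ev = 6
                elif stage == M_AD and rng.random() >= det.deltaAd:
                    ev = 6
                events[i, t] = ev
                if stage == M_JUV:
                    juv_count[t] += 1
                elif stage in (M_SUB, M_ADNT):
                    nonrep_count[t] += 1
                else:
                    tooth_count[t] += 1

    # sex is assignable once the individual was ever in a reproductive stage
    repro_seen = np.zeros(n, dtype=bool)
    for i in range(n):
        st = fates.stages[i]
        if fates.sex[i] == 0:
            repro_seen[i] = np.any((st >= F_BY) & (st <= F_BC3))
        else:
            repro_seen[i] = np.any(st == M_AD)
    sex_known = ~fates.unknown_sex | repro_seen

    histories = []
    for i in range(n):
        if not (fates.marked[i] and sex_known[i]):
            continue
        det_years = np.nonzero(detected[i])[0]
        if det_years.size == 0:
            continue
        t0 = int(det_years[0])
        histories.append(CaptureHistory(
            individual_id=i,
            sex="F" if fates.sex[i] == 0 else "M",
            first_year=t0,
            events=events[i, t0:].copy(),
        ))

    counts = CountSeries(
        juveniles=juv_count, nonreproductive=nonrep_count,
        breeding_females=breed_count, toothed_males=tooth_count,
    )
    return histories, counts, eps_F, eps_M


def simulate_dataset(params: TrueParameters, seed: int) -> SimulatedDataset:
    """Full pipeline: latent simulation, effort, observations."""
    sim = simulate_population(params, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    effort = simulate_effort(params, rng)
    obs_seed = int(np.random.SeedSequence([seed, 2]).generate_state(1)[0] % (2 ** 31))
    histories, counts, eps_F, eps_M = generate_observations(
        sim.fates, params, effort, obs_seed)
    sim.histories = histories
    sim.counts = counts
    sim.effort = effort
    sim.eps_F = eps_F
    sim.eps_M = eps_M
    return sim
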