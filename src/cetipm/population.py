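"""Stage-structured stochastic population model and Leslie system.

The counted population has 11 cells: seven female stages (Juv, Pb, By,
Bc1, Bc2, Bc3, Nb) and four male stages (Juv, Sub, AdNt, Ad).  Dependent
young are attributes of the mother's state and are never counted; they
enter the counted population at weaning, recruiting into the juvenile
stage of either sex with probability 0.5.  Weaning happens from the Bc2
stage with probability ``phiF * phiBy * (1 - F)`` (calf survives and
leaves, conditional on mother survival) and from the Bc3 stage with
probability 1.  Immigrants arrive Poisson(omega) per year into the
juvenile stages with an even sex ratio.

Realized growth is ``lambda_t = ||A_t N_t|| / ||N_t|| + iota_t`` with
``iota_t = omega_t / ||N_t||`` the per-capita immigration rate; the
additive form makes the sensitivity of growth to the immigration rate
exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .params import VitalRateSet
from .states import (
    COUNTED_STAGES, F_BC1, F_BC2, F_BC3, F_BY, F_JUV, F_NB, F_PB,
    M_AD, M_ADNT, M_JUV, M_SUB, N_COUNTED,
)

__all__ = [
    "LatentPopulation",
    "CountSeries",
    "LeslieSystem",
    "COUNT_AGGREGATES",
    "aggregate_latent",
    "aggregate_detection",
    "sample_transition",
    "project_expected",
    "immigration_vector",
    "leslie_matrix",
    "realized_lambda",
    "count_loglik",
]

# male cells sit after the 7 female cells in the 11-vector
MJ, MS, MA, MT = 7 + M_JUV, 7 + M_SUB, 7 + M_ADNT, 7 + M_AD

#: the four count aggregates as lists of counted-stage indices
COUNT_AGGREGATES = {
    "juveniles": [F_JUV, MJ],
    "nonreproductive": [F_PB, F_NB, MS, MA],
    "breeding_females": [F_BY, F_BC1, F_BC2, F_BC3],
    "toothed_males": [MT],
}
AGGREGATE_ORDER = ("juveniles", "nonreproductive", "breeding_females", "toothed_males")


@dataclass
class LatentPopulation:
    """Integer abundance by counted stage cell and year; shape (11, n_years)."""

    N: np.ndarray

    def __post_init__(self):
        self.N = np.asarray(self.N)
        if self.N.ndim != 2 or self.N.shape[0] != N_COUNTED:
            raise ValueError(f"N must be ({N_COUNTED}, n_years); stage order {COUNTED_STAGES}")
        if np.any(self.N < 0):
            raise ValueError("latent abundances must be nonnegative")

    @property
    def n_years(self) -> int:
        return self.N.shape[1]

    def totals(self) -> np.ndarray:
        return self.N.sum(axis=0)


@dataclass
class CountSeries:
    """Observed annual counts for the four stage aggregates."""

    juveniles: np.ndarray
    nonreproductive: np.ndarray
    breeding_females: np.ndarray
    toothed_males: np.ndarray

    def __post_init__(self):
        for name in AGGREGATE_ORDER:
            arr = np.asarray(getattr(self, name), dtype=int)
            if np.any(arr < 0):
                raise ValueError(f"{name} counts must be nonnegative")
            setattr(self, name, arr)

    @property
    def n_years(self) -> int:
        return len(self.juveniles)

    def as_matrix(self) -> np.ndarray:
        """(4, n_years) matrix in the order juveniles, nonreproductive,
        breeding_females, toothed_males."""
        return np.stack([getattr(self, name) for name in AGGREGATE_ORDER])


@dataclass
class LeslieSystem:
    """Leslie matrix over the 11 counted stages, abundance vector, and
    per-capita immigration rate."""

    A: np.ndarray
    n: np.ndarray
    iota: float = 0.0


def aggregate_latent(N: np.ndarray) -> np.ndarray:
    """Collapse an 11-cell abundance array to the four count aggregates."""
    N = np.asarray(N)
    return np.stack([N[COUNT_AGGREGATES[name]].sum(axis=0) for name in AGGREGATE_ORDER])


def aggregate_detection(N_t: np.ndarray, p_F: float, p_M_by_stage: np.ndarray) -> np.ndarray:
    """Detection probability of each count aggregate.

    Females share ``p_F`` across stages; males are stage specific.  For
    the two mixed-sex aggregates the abundance-weighted mean of the
    constituent stage probabilities is used (an empty aggregate falls
    back to the unweighted mean).
    """
    p_stage = np.empty(N_COUNTED)
    p_stage[:7] = p_F
    p_stage[7:] = np.asarray(p_M_by_stage, dtype=float)
    out = np.empty(len(AGGREGATE_ORDER))
    for k, name in enumerate(AGGREGATE_ORDER):
        idx = COUNT_AGGREGATES[name]
        weights = np.asarray(N_t, dtype=float)[idx]
        total = weights.sum()
        if total > 0:
            out[k] = float(p_stage[idx] @ weights / total)
        else:
            out[k] = float(p_stage[idx].mean())
    return out


def _split_binomial(rng, n, p):
    return int(rng.binomial(int(n), p)) if n > 0 else 0


def sample_transition(N_t: np.ndarray, rates: VitalRateSet, seed=None,
                      rng=None, return_detail: bool = False):
    """One stochastic year step: binomial thinning/splitting plus Poisson
    immigration.  Returns the integer abundance vector at ``t + 1``.

    With ``return_detail=True`` also returns the latent branch counts
    (survivors, transitions, weaners, immigrants) that generated it.
    """
    rates.validate()
    N_t = np.asarray(N_t)
    if N_t.shape != (N_COUNTED,) or np.any(N_t < 0):
        raise ValueError("N_t must be 11 nonnegative integers")
    if rng is None:
        rng = np.random.default_rng(seed)

    r = rates
    # female branches
    S_JuvF = _split_binomial(rng, N_t[F_JUV], r.phiF)
    A_JuvF = _split_binomial(rng, S_JuvF, r.psiJuvPb)
    S_Pb = _split_binomial(rng, N_t[F_PB], r.phiF)
    A_Pb = _split_binomial(rng, S_Pb, r.psiPbBy)
    S_By = _split_binomial(rng, N_t[F_BY], r.phiF)
    C_By = _split_binomial(rng, S_By, r.phiBy)
    S_Bc1 = _split_binomial(rng, N_t[F_BC1], r.phiF)
    C_Bc1 = _split_binomial(rng, S_Bc1, r.phiBy)
    S_Bc2 = _split_binomial(rng, N_t[F_BC2], r.phiF)
    C_Bc2 = _split_binomial(rng, S_Bc2, r.phiBy)
    K_Bc2 = _split_binomial(rng, C_Bc2, r.F)
    S_Bc3 = _split_binomial(rng, N_t[F_BC3], r.phiF)
    S_Nb = _split_binomial(rng, N_t[F_NB], r.phiF)
    B_Nb = _split_binomial(rng, S_Nb, r.gamma)
    # male branches
    S_JuvM = _split_binomial(rng, N_t[MJ], r.phiJuvSub)
    A_JuvM = _split_binomial(rng, S_JuvM, r.psiM)
    S_Sub = _split_binomial(rng, N_t[MS], r.phiJuvSub)
    A_Sub = _split_binomial(rng, S_Sub, r.psiM)
    S_AdNt = _split_binomial(rng, N_t[MA], r.phiAd)
    A_AdNt = _split_binomial(rng, S_AdNt, r.psiM)
    S_Ad = _split_binomial(rng, N_t[MT], r.phiAd)
    # weaned calves recruit to the juvenile stages, sex ratio 0.5
    weaners = (C_Bc2 - K_Bc2) + int(N_t[F_BC3])
    WF = _split_binomial(rng, weaners, 0.5)
    # immigrants, even sex ratio
    I = int(rng.poisson(r.omega))
    IF = _split_binomial(rng, I, 0.5)

    N_next = np.zeros(N_COUNTED, dtype=np.int64)
    N_next[F_JUV] = (S_JuvF - A_JuvF) + WF + IF
    N_next[F_PB] = A_JuvF + (S_Pb - A_Pb)
    N_next[F_BY] = A_Pb + B_Nb
    N_next[F_BC1] = C_By
    N_next[F_BC2] = C_Bc1
    N_next[F_BC3] = K_Bc2
    N_next[F_NB] = (S_By - C_By) + (S_Bc1 - C_Bc1) + (S_Bc2 - K_Bc2) + S_Bc3 + (S_Nb - B_Nb)
    N_next[MJ] = (S_JuvM - A_JuvM) + (weaners - WF) + (I - IF)
    N_next[MS] = A_JuvM + (S_Sub - A_Sub)
    N_next[MA] = A_Sub + (S_AdNt - A_AdNt)
    N_next[MT] = A_AdNt + S_Ad

    if return_detail:
        detail = dict(
            S_JuvF=S_JuvF, A_JuvF=A_JuvF, S_Pb=S_Pb, A_Pb=A_Pb, S_By=S_By,
            C_By=C_By, S_Bc1=S_Bc1, C_Bc1=C_Bc1, S_Bc2=S_Bc2, C_Bc2=C_Bc2,
            K_Bc2=K_Bc2, S_Bc3=S_Bc3, S_Nb=S_Nb, B_Nb=B_Nb, S_JuvM=S_JuvM,
            A_JuvM=A_JuvM, S_Sub=S_Sub, A_Sub=A_Sub, S_AdNt=S_AdNt,
            A_AdNt=A_AdNt, S_Ad=S_Ad, weaners=weaners, WF=WF,
            immigrants=I, IF=IF,
        )
        return N_next, detail
    return N_next


def immigration_vector(omega: float) -> np.ndarray:
    """Expected immigration inflow: omega/2 into each juvenile stage."""
    vec = np.zeros(N_COUNTED)
    vec[F_JUV] = omega / 2.0
    vec[MJ] = omega / 2.0
    return vec


def project_expected(N_t: np.ndarray, rates: VitalRateSet) -> np.ndarray:
    """Deterministic expectation of :func:`sample_transition`; linear in N_t."""
    rates.validate()
    N_t = np.asarray(N_t, dtype=float)
    if N_t.shape != (N_COUNTED,):
        raise ValueError("N_t must have 11 entries")
    return leslie_matrix(rates).A @ N_t + immigration_vector(rates.omega)


def leslie_matrix(rates: VitalRateSet) -> LeslieSystem:
    """Yearly Leslie matrix over the 11 counted stages (immigration excluded).

    Survival/stage-advance blocks follow the two sexes' transition
    matrices; recruitment rows add weaned calves to both juvenile stages:
    ``0.5 * phiF * phiBy * (1 - F)`` from the Bc2 column and ``0.5`` from
    the Bc3 column.  The column sums are therefore ``phiF`` for the
    female stages except Bc2 (``phiF * (1 + phiBy * (1 - F))``) and Bc3
    (``phiF + 1``), ``phiJuvSub`` for juvenile/subadult males and
    ``phiAd`` for adult males; the breeding probability ``gamma`` moves
    females between counted states without changing any column sum.
    """
    rates.validate()
    r = rates
    A = np.zeros((N_COUNTED, N_COUNTED))
    # female block: A[dest, source]
    A[F_JUV, F_JUV] = r.phiF * (1 - r.psiJuvPb)
    A[F_PB, F_JUV] = r.phiF * r.psiJuvPb
    A[F_PB, F_PB] = r.phiF * (1 - r.psiPbBy)
    A[F_BY, F_PB] = r.phiF * r.psiPbBy
    A[F_BC1, F_BY] = r.phiF * r.phiBy
    A[F_NB, F_BY] = r.phiF * (1 - r.phiBy)
    A[F_BC2, F_BC1] = r.phiF * r.phiBy
    A[F_NB, F_BC1] = r.phiF * (1 - r.phiBy)
    A[F_BC3, F_BC2] = r.phiF * r.phiBy * r.F
    A[F_NB, F_BC2] = r.phiF * (1 - r.phiBy * r.F)
    A[F_NB, F_BC3] = r.phiF
    A[F_BY, F_NB] = r.phiF * r.gamma
    A[F_NB, F_NB] = r.phiF * (1 - r.gamma)
    # male block
    A[MJ, MJ] = r.phiJuvSub * (1 - r.psiM)
    A[MS, MJ] = r.phiJuvSub * r.psiM
    A[MS, MS] = r.phiJuvSub * (1 - r.psiM)
    A[MA, MS] = r.phiJuvSub * r.psiM
    A[MA, MA] = r.phiAd * (1 - r.psiM)
    A[MT, MA] = r.phiAd * r.psiM
    A[MT, MT] = r.phiAd
    # recruitment of weaned calves into both juvenile rows
    wean2 = 0.5 * r.phiF * r.phiBy * (1 - r.F)
    A[F_JUV, F_BC2] += wean2
    A[MJ, F_BC2] += wean2
    A[F_JUV, F_BC3] += 0.5
    A[MJ, F_BC3] += 0.5
    return LeslieSystem(A=A, n=np.zeros(N_COUNTED), iota=0.0)


def realized_lambda(A: np.ndarray, n_t: np.ndarray, iota_t: float = 0.0) -> float:
    """Realized growth ||A n|| / ||n|| + iota (1-norms); errors on a zero vector."""
    n_t = np.asarray(n_t, dtype=float)
    norm = np.abs(n_t).sum()
    if norm == 0:
        raise ValueError("population vector is zero; realized growth undefined")
    return float(np.abs(A @ n_t).sum() / norm + iota_t)


def _binom_logpmf(k, n, p):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    pc = np.clip(p, 1e-300, 1 - 1e-16)
    out = np.where(
        (k < 0) | (k > n),
        -np.inf,
        gammaln(n + 1) - gammaln(np.maximum(k, 0) + 1)
        - gammaln(np.maximum(n - k, 0) + 1)
        + k * np.log(pc) + (n - k) * np.log1p(-pc),
    )
    # degenerate detection probabilities are handled exactly
    out = np.where((p == 1.0) & (k == n) & (k >= 0), 0.0, out)
    out = np.where((p == 1.0) & (k != n), -np.inf, out)
    out = np.where((p == 0.0), np.where(k == 0, 0.0, -np.inf), out)
    return out


def count_loglik(counts_t, N_t, p_aggregate) -> float:
    """Binomial log-likelihood of the four aggregate counts for one year.

    ``counts_t`` and ``p_aggregate`` follow the order juveniles,
    nonreproductive, breeding_females, toothed_males.  Counts exceeding
    the latent aggregate return ``-inf``.
    """
    counts_t = np.asarray(counts_t)
    totals = aggregate_latent(np.asarray(N_t))
    if np.any(counts_t > totals) or np.any(counts_t < 0):
        return -np.inf
    return float(_binom_logpmf(counts_t, totals, p_aggregate).sum())
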