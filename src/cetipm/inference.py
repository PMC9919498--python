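"""Joint Bayesian inference for the integrated population model.

The joint posterior combines four blocks: the multievent likelihood of
the encounter histories, the binomial likelihood of the aggregate
counts, the log-probability of the latent demographic process, and the
prior/random-effect densities.  The latent process is parameterized by
its binomial *branch counts* (survivors, stage transitions, weaners and
immigrants per year); stage abundances are deterministic sums of branch
counts, so the process log-probability is an explicit sum of binomial
and Poisson terms and single-site integer Metropolis updates of the
branch counts are valid moves on the joint posterior.

Sampling is adaptive random-walk Metropolis on transformed parameters
(logit for probabilities, log for standard deviations and the
immigration mean, non-centered standard-normal year effects), with
proposal scales tuned during burn-in only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import expit, logit

from .multievent import standardize_effort
from .params import DetectionParams, RateSeries
from .population import (
    COUNT_AGGREGATES, AGGREGATE_ORDER, CountSeries, LatentPopulation,
    aggregate_detection, sample_transition,
)
from .states import N_COUNTED

__all__ = [
    "IPMData",
    "PriorConfig",
    "FitConfig",
    "ModelParams",
    "LatentState",
    "PosteriorDraws",
    "joint_log_posterior",
    "fit",
    "rhat",
    "rhat_array",
    "posterior_predictive_check",
    "sample_latent_state",
]

# ---------------------------------------------------------------------------
# data and configuration containers

@dataclass
class IPMData:
    """Joint dataset: encounter histories, aggregate counts, survey effort."""

    histories: list
    counts: CountSeries | None
    effort: np.ndarray

    def __post_init__(self):
        self.effort = np.asarray(self.effort)
        if self.counts is not None and self.counts.n_years != len(self.effort):
            raise ValueError("counts and effort must cover the same years")
        for h in self.histories:
            if h.sex not in ("F", "M"):
                raise ValueError(f"unknown sex code {h.sex!r}")
            if h.first_year + h.n_years > len(self.effort):
                raise ValueError("history extends past the study period")

    @property
    def n_years(self) -> int:
        return len(self.effort)


@dataclass
class PriorConfig:
    """Vague priors: U(0,1) on mean probabilities, U(0, sd_upper) on
    random-effect SDs, uniform over valid correlation matrices,
    N(0, coef_sd) on detection intercepts/slope, U(0, omega_upper) on the
    immigration hyper-mean, discrete-uniform 0..n0_upper on initial
    abundances."""

    sd_upper: float = 10.0
    coef_sd: float = 10.0
    omega_upper: float = 50.0
    n0_upper: int = 3000

    def validate(self) -> None:
        if not (self.sd_upper > 0 and self.coef_sd > 0 and self.omega_upper > 0
                and self.n0_upper > 0):
            raise ValueError("all prior bounds must be positive")


@dataclass
class FitConfig:
    """Desk-scale MCMC settings."""

    n_chains: int = 3
    n_iterations: int = 20_000
    n_burnin: int = 10_000
    thin: int = 10
    seed: int = 0
    target_accept_scalar: float = 0.44
    target_accept_vector: float = 0.234

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required")
        if not (0 < self.n_burnin < self.n_iterations):
            raise ValueError("burn-in must be positive and smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


# names of the probability-mean parameters, in storage order
_PROB_MEANS = (
    "phiF", "phiBy", "F", "gamma", "psiJuvPb", "psiPbBy",
    "phiJuvSub", "phiAd", "psiM", "deltaPb", "deltaNb", "deltaAdNt", "deltaAd",
)
_SD_NAMES = (
    "sd_phiF", "sd_phiBy", "sd_F", "sd_gamma", "sd_phiJuvSub", "sd_phiAd",
    "sd_eps_F", "sd_eps_M", "sd_omega",
)
# female year-effect block order
_FEM_BLOCK = ("phiF", "phiBy", "F", "gamma")
_MAL_BLOCK = ("phiJuvSub", "phiAd")


@dataclass
class ModelParams:
    """All continuous parameters of the IPM, on natural scales.

    Year effects are stored non-centered: ``z_*`` are standard-normal
    deviates that get scaled by the corresponding SDs (and correlated
    through the Cholesky factor of the block correlation matrix) when
    year-specific rates are formed.
    """

    means: dict                      # name -> probability, keys _PROB_MEANS
    alpha_F: float
    alpha_M: np.ndarray              # (4,)
    beta_effort: float
    sds: dict                        # name -> sd, keys _SD_NAMES
    corr_F: np.ndarray               # (4, 4)
    corr_M: np.ndarray               # (2, 2)
    omega_mean: float
    z_F: np.ndarray                  # (T-1, 4)
    z_M: np.ndarray                  # (T-1, 2)
    z_eps_F: np.ndarray              # (T,)
    z_eps_M: np.ndarray              # (T,)
    z_omega: np.ndarray              # (T-1,)

    def copy(self) -> "ModelParams":
        return ModelParams(
            means=dict(self.means), alpha_F=self.alpha_F,
            alpha_M=self.alpha_M.copy(), beta_effort=self.beta_effort,
            sds=dict(self.sds), corr_F=self.corr_F.copy(),
            corr_M=self.corr_M.copy(), omega_mean=self.omega_mean,
            z_F=self.z_F.copy(), z_M=self.z_M.copy(),
            z_eps_F=self.z_eps_F.copy(), z_eps_M=self.z_eps_M.copy(),
            z_omega=self.z_omega.copy(),
        )

    # -- derived year-specific quantities ---------------------------------
    def rate_arrays(self):
        """Year-specific rates on probability scale; dict of (T-1,) arrays."""
        try:
            Lf = np.linalg.cholesky(self.corr_F)
            Lm = np.linalg.cholesky(self.corr_M)
        except np.linalg.LinAlgError:
            return None
        sds_f = np.array([self.sds[f"sd_{k}"] for k in _FEM_BLOCK])
        sds_m = np.array([self.sds[f"sd_{k}"] for k in _MAL_BLOCK])
        dev_f = self.z_F @ Lf.T * sds_f      # (T-1, 4)
        dev_m = self.z_M @ Lm.T * sds_m      # (T-1, 2)
        out = {}
        for j, name in enumerate(_FEM_BLOCK):
            out[name] = expit(logit(self.means[name]) + dev_f[:, j])
        for j, name in enumerate(_MAL_BLOCK):
            out[name] = expit(logit(self.means[name]) + dev_m[:, j])
        sd_o = self.sds["sd_omega"]
        # mean-centred lognormal: E[omega_t] = omega_mean
        out["omega"] = self.omega_mean * np.exp(sd_o * self.z_omega - 0.5 * sd_o ** 2)
        n_trans = self.z_F.shape[0]
        for name in ("psiJuvPb", "psiPbBy", "psiM"):
            out[name] = np.full(n_trans, self.means[name])
        return out

    def detection_arrays(self, effort_z):
        """Per-year detection probabilities: (T,) for females, (T, 4) for males."""
        eps_f = self.sds["sd_eps_F"] * self.z_eps_F
        eps_m = self.sds["sd_eps_M"] * self.z_eps_M
        pF = expit(self.alpha_F + self.beta_effort * effort_z + eps_f)
        pM = expit(self.alpha_M[None, :] + (self.beta_effort * effort_z + eps_m)[:, None])
        return pF, pM

    def to_rate_series(self) -> RateSeries:
        arrs = self.rate_arrays()
        if arrs is None:
            raise ValueError("correlation matrix is not positive definite")
        return RateSeries(**{k: arrs[k] for k in RateSeries.FIELDS})

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            alpha_F=self.alpha_F, alpha_M_by_stage=self.alpha_M.copy(),
            beta_effort=self.beta_effort, sd_year_F=self.sds["sd_eps_F"],
            sd_year_M=self.sds["sd_eps_M"], deltaPb=self.means["deltaPb"],
            deltaNb=self.means["deltaNb"], deltaAdNt=self.means["deltaAdNt"],
            deltaAd=self.means["deltaAd"],
        )


#: latent branch-count column layout, per transition year
LATENT_COLS = (
    "S_JuvF", "A_JuvF", "S_Pb", "A_Pb", "S_By", "C_By", "S_Bc1", "C_Bc1",
    "S_Bc2", "C_Bc2", "K_Bc2", "S_Bc3", "S_Nb", "B_Nb",
    "S_JuvM", "A_JuvM", "S_Sub", "A_Sub", "S_AdNt", "A_AdNt", "S_Ad",
    "WF", "I", "IF",
)
N_LATENT_COLS = len(LATENT_COLS)


@dataclass
class LatentState:
    """Initial abundances plus per-year branch counts of the state process."""

    N0: np.ndarray                   # (11,) int
    branches: np.ndarray             # (T-1, 24) int

    def __post_init__(self):
        self.N0 = np.asarray(self.N0, dtype=np.int64)
        self.branches = np.asarray(self.branches, dtype=np.int64)
        if self.N0.shape != (N_COUNTED,):
            raise ValueError("N0 must have 11 entries")
        if self.branches.ndim != 2 or self.branches.shape[1] != N_LATENT_COLS:
            raise ValueError(f"branches must be (n_years - 1, {N_LATENT_COLS})")

    def copy(self) -> "LatentState":
        return LatentState(self.N0.copy(), self.branches.copy())

    @property
    def n_years(self) -> int:
        return self.branches.shape[0] + 1

    def abundances(self) -> LatentPopulation:
        N = _propagate(self.N0, self.branches)
        if np.any(N < 0):
            raise ValueError("branch counts imply negative abundances")
        return LatentPopulation(N)


def sample_latent_state(N0, rates: RateSeries, rng) -> LatentState:
    """Forward-sample a latent state from the demographic process prior."""
    N0 = np.asarray(N0, dtype=np.int64)
    T1 = rates.n_transitions
    branches = np.zeros((T1, N_LATENT_COLS), dtype=np.int64)
    N = N0
    for t in range(T1):
        N, detail = sample_transition(N, rates.at(t), rng=rng, return_detail=True)
        branches[t] = [
            detail["S_JuvF"], detail["A_JuvF"], detail["S_Pb"], detail["A_Pb"],
            detail["S_By"], detail["C_By"], detail["S_Bc1"], detail["C_Bc1"],
            detail["S_Bc2"], detail["C_Bc2"], detail["K_Bc2"], detail["S_Bc3"],
            detail["S_Nb"], detail["B_Nb"], detail["S_JuvM"], detail["A_JuvM"],
            detail["S_Sub"], detail["A_Sub"], detail["S_AdNt"], detail["A_AdNt"],
            detail["S_Ad"], detail["WF"], detail["immigrants"], detail["IF"],
        ]
    return LatentState(N0, branches)


# ---------------------------------------------------------------------------
# jitted likelihood kernels

@njit(cache=False)
def _binln(k, n, p):
    if k < 0 or k > n or n < 0:
        return -np.inf
    if p <= 0.0:
        return 0.0 if k == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
            + k * math.log(p) + (n - k) * math.log1p(-p))


@njit(cache=False)
def _poisln(k, lam):
    if k < 0:
        return -np.inf
    if lam <= 0.0:
        return 0.0 if k == 0 else -np.inf
    return -lam + k * math.log(lam) - math.lgamma(k + 1.0)


@njit(cache=False)
def _propagate_kernel(N0, L, N):
    """Fill N (11, T) from initial abundances and branch counts."""
    T1 = L.shape[0]
    for i in range(11):
        N[i, 0] = N0[i]
    for t in range(T1):
        weaners = (L[t, 9] - L[t, 10]) + N[5, t]
        N[0, t + 1] = (L[t, 0] - L[t, 1]) + L[t, 21] + L[t, 23]
        N[1, t + 1] = L[t, 1] + (L[t, 2] - L[t, 3])
        N[2, t + 1] = L[t, 3] + L[t, 13]
        N[3, t + 1] = L[t, 5]
        N[4, t + 1] = L[t, 7]
        N[5, t + 1] = L[t, 10]
        N[6, t + 1] = ((L[t, 4] - L[t, 5]) + (L[t, 6] - L[t, 7])
                       + (L[t, 8] - L[t, 10]) + L[t, 11] + (L[t, 12] - L[t, 13]))
        N[7, t + 1] = (L[t, 14] - L[t, 15]) + (weaners - L[t, 21]) + (L[t, 22] - L[t, 23])
        N[8, t + 1] = L[t, 15] + (L[t, 16] - L[t, 17])
        N[9, t + 1] = L[t, 17] + (L[t, 18] - L[t, 19])
        N[10, t + 1] = L[t, 19] + L[t, 20]


@njit(cache=False)
def _state_loglik_kernel(N0, L, phiF, phiBy, F, gamma, psiJuvPb, psiPbBy,
                         phiJuvSub, phiAd, psiM, omega, N):
    """Log-probability of the branch counts; fills N as a side effect."""
    _propagate_kernel(N0, L, N)
    T1 = L.shape[0]
    total = 0.0
    for t in range(T1):
        for i in range(11):
            if N[i, t + 1] < 0:
                return -np.inf
        weaners = (L[t, 9] - L[t, 10]) + N[5, t]
        total += _binln(L[t, 0], N[0, t], phiF[t])
        total += _binln(L[t, 1], L[t, 0], psiJuvPb[t])
        total += _binln(L[t, 2], N[1, t], phiF[t])
        total += _binln(L[t, 3], L[t, 2], psiPbBy[t])
        total += _binln(L[t, 4], N[2, t], phiF[t])
        total += _binln(L[t, 5], L[t, 4], phiBy[t])
        total += _binln(L[t, 6], N[3, t], phiF[t])
        total += _binln(L[t, 7], L[t, 6], phiBy[t])
        total += _binln(L[t, 8], N[4, t], phiF[t])
        total += _binln(L[t, 9], L[t, 8], phiBy[t])
        total += _binln(L[t, 10], L[t, 9], F[t])
        total += _binln(L[t, 11], N[5, t], phiF[t])
        total += _binln(L[t, 12], N[6, t], phiF[t])
        total += _binln(L[t, 13], L[t, 12], gamma[t])
        total += _binln(L[t, 14], N[7, t], phiJuvSub[t])
        total += _binln(L[t, 15], L[t, 14], psiM[t])
        total += _binln(L[t, 16], N[8, t], phiJuvSub[t])
        total += _binln(L[t, 17], L[t, 16], psiM[t])
        total += _binln(L[t, 18], N[9, t], phiAd[t])
        total += _binln(L[t, 19], L[t, 18], psiM[t])
        total += _binln(L[t, 20], N[10, t], phiAd[t])
        total += _binln(L[t, 21], weaners, 0.5)
        total += _poisln(L[t, 22], omega[t])
        total += _binln(L[t, 23], L[t, 22], 0.5)
        if total == -np.inf:
            return -np.inf
    return total


@njit(cache=False)
def _count_loglik_kernel(N, counts, pF, pM):
    """Binomial likelihood of the four aggregates; counts is (4, T)."""
    T = N.shape[1]
    total = 0.0
    for t in range(T):
        juv = N[0, t] + N[7, t]
        nonrep = N[1, t] + N[6, t] + N[8, t] + N[9, t]
        breed = N[2, t] + N[3, t] + N[4, t] + N[5, t]
        tooth = N[10, t]
        # abundance-weighted detection for the mixed aggregates
        if juv > 0:
            p_juv = (N[0, t] * pF[t] + N[7, t] * pM[t, 0]) / juv
        else:
            p_juv = 0.5 * (pF[t] + pM[t, 0])
        if nonrep > 0:
            p_non = ((N[1, t] + N[6, t]) * pF[t] + N[8, t] * pM[t, 1]
                     + N[9, t] * pM[t, 2]) / nonrep
        else:
            p_non = 0.25 * (2.0 * pF[t] + pM[t, 1] + pM[t, 2])
        total += _binln(counts[0, t], juv, p_juv)
        total += _binln(counts[1, t], nonrep, p_non)
        total += _binln(counts[2, t], breed, pF[t])
        total += _binln(counts[3, t], tooth, pM[t, 3])
        if total == -np.inf:
            return -np.inf
    return total


@njit(cache=False)
def _forward_kernel(events, first, trans, emit):
    """Batched forward algorithm over one sex's histories.

    events: (n, T) int, 0 before first capture, codes 1.. afterwards.
    trans: (T-1, S, S); emit: (T, S, E).  Returns the summed log-likelihood.
    """
    n, T = events.shape
    S = emit.shape[1]
    total = 0.0
    alpha = np.empty(S)
    new = np.empty(S)
    for i in range(n):
        t0 = first[i]
        ev = events[i, t0]
        norm = 0.0
        for s in range(S - 1):
            alpha[s] = emit[t0, s, ev - 1]
            norm += alpha[s]
        alpha[S - 1] = 0.0
        if norm <= 0.0:
            return -np.inf
        for s in range(S - 1):
            alpha[s] /= norm
        for t in range(t0 + 1, T):
            ev = events[i, t]
            for s2 in range(S):
                acc = 0.0
                for s1 in range(S):
                    acc += alpha[s1] * trans[t - 1, s1, s2]
                new[s2] = acc * emit[t, s2, ev - 1]
            for s2 in range(S):
                alpha[s2] = new[s2]
        tot = 0.0
        for s in range(S):
            tot += alpha[s]
        if tot <= 0.0:
            return -np.inf
        total += math.log(tot)
    return total


@njit(cache=False)
def _latent_sweep_kernel(N0, L, phiF, phiBy, F, gamma, psiJuvPb, psiPbBy,
                         phiJuvSub, phiAd, psiM, omega, counts, pF, pM,
                         n0_upper, deltas, urand, ll_state, ll_count, N, N_try):
    """One full single-site Metropolis sweep over N0 and all branch counts.

    ``deltas``/``urand`` are pre-drawn proposal increments and uniforms,
    one per site.  Mutates N0, L and N in place; returns the updated
    (ll_state, ll_count).
    """
    n_cols = L.shape[1]
    n_sites = 11 + L.shape[0] * n_cols
    for s in range(n_sites):
        if s < 11:
            old = N0[s]
            new = old + deltas[s]
            if new < 0 or new > n0_upper:
                continue
            N0[s] = new
            t = -1
            c = -1
        else:
            t = (s - 11) // n_cols
            c = (s - 11) % n_cols
            old = L[t, c]
            new = old + deltas[s]
            if new < 0:
                continue
            L[t, c] = new
        ll_state_new = _state_loglik_kernel(N0, L, phiF, phiBy, F, gamma,
                                            psiJuvPb, psiPbBy, phiJuvSub,
                                            phiAd, psiM, omega, N_try)
        accept = False
        if ll_state_new > -np.inf:
            ll_count_new = _count_loglik_kernel(N_try, counts, pF, pM)
            if ll_count_new > -np.inf:
                delta = (ll_state_new - ll_state) + (ll_count_new - ll_count)
                if delta >= 0.0 or math.log(urand[s]) < delta:
                    accept = True
        if accept:
            ll_state = ll_state_new
            ll_count = ll_count_new
            for i in range(11):
                for t2 in range(N.shape[1]):
                    N[i, t2] = N_try[i, t2]
        else:
            if s < 11:
                N0[s] = old
            else:
                L[t, c] = old
    return ll_state, ll_count


def _propagate(N0, branches):
    N = np.empty((N_COUNTED, branches.shape[0] + 1), dtype=np.int64)
    _propagate_kernel(np.asarray(N0, np.int64), np.asarray(branches, np.int64), N)
    return N


# ---------------------------------------------------------------------------
# vectorized matrix builders (year-batched versions of multievent builders)

def _female_transition_stack(phiF, phiBy, F, gamma, psiJuvPb, psiPbBy):
    T1 = len(phiF)
    Tm = np.zeros((T1, 8, 8))
    Tm[:, 0, 1] = phiF * psiJuvPb
    Tm[:, 0, 0] = phiF * (1 - psiJuvPb)
    Tm[:, 1, 2] = phiF * psiPbBy
    Tm[:, 1, 1] = phiF * (1 - psiPbBy)
    Tm[:, 2, 3] = phiF * phiBy
    Tm[:, 2, 6] = phiF * (1 - phiBy)
    Tm[:, 3, 4] = phiF * phiBy
    Tm[:, 3, 6] = phiF * (1 - phiBy)
    Tm[:, 4, 5] = phiF * phiBy * F
    Tm[:, 4, 6] = phiF * (1 - phiBy * F)
    Tm[:, 5, 6] = phiF
    Tm[:, 6, 2] = phiF * gamma
    Tm[:, 6, 6] = phiF * (1 - gamma)
    Tm[:, :7, 7] = 1.0 - Tm[:, :7, :7].sum(axis=2)
    Tm[:, 7, 7] = 1.0
    return Tm


def _male_transition_stack(phiJuvSub, phiAd, psiM):
    T1 = len(phiJuvSub)
    Tm = np.zeros((T1, 5, 5))
    Tm[:, 0, 1] = phiJuvSub * psiM
    Tm[:, 0, 0] = phiJuvSub * (1 - psiM)
    Tm[:, 1, 2] = phiJuvSub * psiM
    Tm[:, 1, 1] = phiJuvSub * (1 - psiM)
    Tm[:, 2, 3] = phiAd * psiM
    Tm[:, 2, 2] = phiAd * (1 - psiM)
    Tm[:, 3, 3] = phiAd
    Tm[:, :4, 4] = 1.0 - Tm[:, :4, :4].sum(axis=2)
    Tm[:, 4, 4] = 1.0
    return Tm


def _female_emission_stack(pF, deltaPb, deltaNb):
    T = len(pF)
    E = np.zeros((T, 8, 7))
    E[:, :7, 0] = (1 - pF)[:, None]
    E[:, 0, 1] = pF
    E[:, 1, 2] = pF * deltaPb
    E[:, 1, 6] = pF * (1 - deltaPb)
    E[:, 2, 3] = pF
    E[:, 3, 4] = pF
    E[:, 4, 4] = pF
    E[:, 5, 4] = pF
    E[:, 6, 5] = pF * deltaNb
    E[:, 6, 6] = pF * (1 - deltaNb)
    E[:, 7, 0] = 1.0
    return E


def _male_emission_stack(pM, deltaAdNt, deltaAd):
    T = pM.shape[0]
    E = np.zeros((T, 5, 6))
    E[:, :4, 0] = 1 - pM
    E[:, 0, 1] = pM[:, 0]
    E[:, 1, 2] = pM[:, 1]
    E[:, 2, 3] = pM[:, 2] * deltaAdNt
    E[:, 2, 5] = pM[:, 2] * (1 - deltaAdNt)
    E[:, 3, 4] = pM[:, 3] * deltaAd
    E[:, 3, 5] = pM[:, 3] * (1 - deltaAd)
    E[:, 4, 0] = 1.0
    return E


@njit(cache=False)
def _me_loglik_kernel(evF, fiF, evM, fiM, phiF, phiBy, F, gamma, psiJuvPb,
                      psiPbBy, phiJuvSub, phiAd, psiM, pF, pM,
                      dPb, dNb, dAdNt, dAd):
    """Fused multievent likelihood: builds the year-indexed transition and
    emission matrices in place and runs the batched forward pass."""
    T = pF.shape[0]
    total = 0.0
    if evF.shape[0] > 0:
        Tf = np.zeros((T - 1, 8, 8))
        for t in range(T - 1):
            Tf[t, 0, 1] = phiF[t] * psiJuvPb[t]
            Tf[t, 0, 0] = phiF[t] * (1 - psiJuvPb[t])
            Tf[t, 1, 2] = phiF[t] * psiPbBy[t]
            Tf[t, 1, 1] = phiF[t] * (1 - psiPbBy[t])
            Tf[t, 2, 3] = phiF[t] * phiBy[t]
            Tf[t, 2, 6] = phiF[t] * (1 - phiBy[t])
            Tf[t, 3, 4] = phiF[t] * phiBy[t]
            Tf[t, 3, 6] = phiF[t] * (1 - phiBy[t])
            Tf[t, 4, 5] = phiF[t] * phiBy[t] * F[t]
            Tf[t, 4, 6] = phiF[t] * (1 - phiBy[t] * F[t])
            Tf[t, 5, 6] = phiF[t]
            Tf[t, 6, 2] = phiF[t] * gamma[t]
            Tf[t, 6, 6] = phiF[t] * (1 - gamma[t])
            for s in range(7):
                acc = 0.0
                for s2 in range(7):
                    acc += Tf[t, s, s2]
                Tf[t, s, 7] = 1.0 - acc
            Tf[t, 7, 7] = 1.0
        Ef = np.zeros((T, 8, 7))
        for t in range(T):
            for s in range(7):
                Ef[t, s, 0] = 1 - pF[t]
            Ef[t, 0, 1] = pF[t]
            Ef[t, 1, 2] = pF[t] * dPb
            Ef[t, 1, 6] = pF[t] * (1 - dPb)
            Ef[t, 2, 3] = pF[t]
            Ef[t, 3, 4] = pF[t]
            Ef[t, 4, 4] = pF[t]
            Ef[t, 5, 4] = pF[t]
            Ef[t, 6, 5] = pF[t] * dNb
            Ef[t, 6, 6] = pF[t] * (1 - dNb)
            Ef[t, 7, 0] = 1.0
        total += _forward_kernel(evF, fiF, Tf, Ef)
        if total == -np.inf:
            return -np.inf
    if evM.shape[0] > 0:
        Tm = np.zeros((T - 1, 5, 5))
        for t in range(T - 1):
            Tm[t, 0, 1] = phiJuvSub[t] * psiM[t]
            Tm[t, 0, 0] = phiJuvSub[t] * (1 - psiM[t])
            Tm[t, 1, 2] = phiJuvSub[t] * psiM[t]
            Tm[t, 1, 1] = phiJuvSub[t] * (1 - psiM[t])
            Tm[t, 2, 3] = phiAd[t] * psiM[t]
            Tm[t, 2, 2] = phiAd[t] * (1 - psiM[t])
            Tm[t, 3, 3] = phiAd[t]
            for s in range(4):
                acc = 0.0
                for s2 in range(4):
                    acc += Tm[t, s, s2]
                Tm[t, s, 4] = 1.0 - acc
            Tm[t, 4, 4] = 1.0
        Em = np.zeros((T, 5, 6))
        for t in range(T):
            for s in range(4):
                Em[t, s, 0] = 1 - pM[t, s]
            Em[t, 0, 1] = pM[t, 0]
            Em[t, 1, 2] = pM[t, 1]
            Em[t, 2, 3] = pM[t, 2] * dAdNt
            Em[t, 2, 5] = pM[t, 2] * (1 - dAdNt)
            Em[t, 3, 4] = pM[t, 3] * dAd
            Em[t, 3, 5] = pM[t, 3] * (1 - dAd)
            Em[t, 4, 0] = 1.0
        total += _forward_kernel(evM, fiM, Tm, Em)
    return total


class _Prepared:
    """Histories packed into dense arrays, one block per sex."""

    def __init__(self, data: IPMData):
        T = data.n_years
        self.effort_z = standardize_effort(data.effort)
        self.n_years = T
        self.counts = data.counts.as_matrix().astype(np.int64) if data.counts is not None else None
        by_sex = {"F": [], "M": []}
        for h in data.histories:
            by_sex[h.sex].append(h)
        self.events = {}
        self.first = {}
        for sex, hs in by_sex.items():
            ev = np.zeros((len(hs), T), dtype=np.int64)
            fi = np.zeros(len(hs), dtype=np.int64)
            for i, h in enumerate(hs):
                fi[i] = h.first_year
                ev[i, h.first_year:h.first_year + h.n_years] = h.events
                ev[i, h.first_year + h.n_years:] = 1
            self.events[sex] = ev
            self.first[sex] = fi


def _me_loglik(params: ModelParams, prep: _Prepared, rates: dict) -> float:
    pF, pM = params.detection_arrays(prep.effort_z)
    return float(_me_loglik_kernel(
        prep.events["F"], prep.first["F"], prep.events["M"], prep.first["M"],
        rates["phiF"], rates["phiBy"], rates["F"], rates["gamma"],
        rates["psiJuvPb"], rates["psiPbBy"], rates["phiJuvSub"], rates["phiAd"],
        rates["psiM"], pF, pM, params.means["deltaPb"], params.means["deltaNb"],
        params.means["deltaAdNt"], params.means["deltaAd"]))


def _state_loglik(params: ModelParams, latents: LatentState, rates: dict,
                  N_buf: np.ndarray) -> float:
    return float(_state_loglik_kernel(
        latents.N0, latents.branches, rates["phiF"], rates["phiBy"], rates["F"],
        rates["gamma"], rates["psiJuvPb"], rates["psiPbBy"], rates["phiJuvSub"],
        rates["phiAd"], rates["psiM"], rates["omega"], N_buf,
    ))


def _count_loglik(params: ModelParams, prep: _Prepared, N: np.ndarray) -> float:
    if prep.counts is None:
        return 0.0
    pF, pM = params.detection_arrays(prep.effort_z)
    return float(_count_loglik_kernel(N.astype(np.float64), prep.counts, pF, pM))


def _log_prior(params: ModelParams, priors: PriorConfig, latents=None) -> float:
    lp = 0.0
    for name in _PROB_MEANS:
        p = params.means[name]
        if not (0.0 < p < 1.0):
            return -np.inf
        lp += math.log(p * (1.0 - p))       # Jacobian of the logit transform
    s2 = priors.coef_sd ** 2
    lp += -0.5 * (params.alpha_F ** 2 + params.beta_effort ** 2
                  + float(np.sum(params.alpha_M ** 2))) / s2
    for name in _SD_NAMES:
        sd = params.sds[name]
        if not (0.0 < sd < priors.sd_upper):
            return -np.inf
        lp += math.log(sd)                  # Jacobian of the log transform
    for corr in (params.corr_F, params.corr_M):
        off = corr[np.triu_indices_from(corr, k=1)]
        if np.any(np.abs(off) >= 1.0):
            return -np.inf
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            return -np.inf
    if not (0.0 < params.omega_mean < priors.omega_upper):
        return -np.inf
    lp += math.log(params.omega_mean)       # Jacobian of the log transform
    for z in (params.z_F, params.z_M, params.z_eps_F, params.z_eps_M, params.z_omega):
        lp += -0.5 * float(np.sum(z ** 2))
    if latents is not None:
        if np.any(latents.N0 < 0) or np.any(latents.N0 > priors.n0_upper):
            return -np.inf
    return lp


def joint_log_posterior(params: ModelParams, latents, data: IPMData,
                        priors: PriorConfig = None, return_components=False):
    """Unnormalized joint log posterior (on the sampler's transformed scale).

    Sum of four components: multievent likelihood, count likelihood,
    state-process log-probability of the latents, and prior/random-effect
    densities.  Returns ``-inf`` outside the support.  With
    ``return_components=True`` returns the 4-tuple
    ``(multievent, counts, state, prior)`` instead.
    """
    priors = priors or PriorConfig()
    prep = _Prepared(data)
    if (prep.counts is not None) != (latents is not None):
        raise ValueError("latents must be supplied exactly when count data are present")
    lp = _log_prior(params, priors, latents)
    if lp == -np.inf:
        out = (-np.inf, -np.inf, -np.inf, -np.inf)
        return out if return_components else -np.inf
    rates = params.rate_arrays()
    if rates is None:
        out = (-np.inf, -np.inf, -np.inf, -np.inf)
        return out if return_components else -np.inf
    if latents is not None and latents.n_years != data.n_years:
        raise ValueError("latent state and data cover different numbers of years")
    ll_me = _me_loglik(params, prep, rates)
    if latents is not None:
        N_buf = np.empty((N_COUNTED, data.n_years), dtype=np.int64)
        ll_state = _state_loglik(params, latents, rates, N_buf)
        ll_count = _count_loglik(params, prep, N_buf) if ll_state > -np.inf else -np.inf
    else:
        ll_state = 0.0
        ll_count = 0.0
    if return_components:
        return (ll_me, ll_count, ll_state, lp)
    return ll_me + ll_count + ll_state + lp


# ---------------------------------------------------------------------------
# posterior container and diagnostics

@dataclass
class PosteriorDraws:
    """Stored MCMC output.

    ``scalars`` maps hyperparameter names to ``(n_chains, n_kept)``
    arrays; ``rate_draws`` maps each year-varying rate (including
    ``omega``) to ``(n_draws, T-1)`` arrays pooled across chains;
    ``latent_draws`` holds the ``(n_draws, 11, T)`` latent abundances
    (``None`` when no count data were fitted).
    """

    scalars: dict
    rate_draws: dict
    detection_pF: np.ndarray
    detection_pM: np.ndarray
    latent_draws: np.ndarray | None
    chain: np.ndarray
    iteration: np.ndarray
    n_years: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.chain)

    def scalar_pooled(self, name: str) -> np.ndarray:
        return self.scalars[name].reshape(-1)

    def credible_interval(self, name: str, level: float = 0.95):
        x = self.scalar_pooled(name)
        a = 100 * (1 - level) / 2
        return float(np.percentile(x, a)), float(np.percentile(x, 100 - a))

    def summary(self) -> "pd.DataFrame":
        import pandas as pd
        rows = []
        rh = self.diagnostics.get("rhat", {})
        for name, arr in self.scalars.items():
            x = arr.reshape(-1)
            rows.append({
                "parameter": name, "mean": x.mean(), "median": np.median(x),
                "2.5%": np.percentile(x, 2.5), "97.5%": np.percentile(x, 97.5),
                "rhat": rh.get(name, np.nan),
            })
        return pd.DataFrame(rows).set_index("parameter")

    def to_dataframe(self) -> "pd.DataFrame":
        """Long format: chain, iteration, parameter, value."""
        import pandas as pd
        n_chains, n_kept = next(iter(self.scalars.values())).shape
        frames = []
        for name, arr in self.scalars.items():
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_chains), n_kept),
                "iteration": np.tile(np.arange(n_kept), n_chains),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)


def rhat_array(chains: np.ndarray) -> float:
    """Split potential scale reduction factor for one scalar parameter.

    ``chains`` is ``(n_chains, n_draws)``; each chain is split in half,
    giving 2m sequences whose within- and between-variance are compared
    (Gelman et al. split-R-hat).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat needs at least 2 chains of draws")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short for split-rhat")
    halves = np.concatenate([chains[:, :n], chains[:, n:2 * n]], axis=0)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def rhat(draws: PosteriorDraws) -> dict:
    """Split-R-hat per stored scalar parameter plus a convergence flag."""
    if next(iter(draws.scalars.values())).shape[0] < 2:
        raise ValueError("rhat needs at least 2 chains")
    out = {name: rhat_array(arr) for name, arr in draws.scalars.items()}
    out["converged"] = all(v < 1.02 for k, v in out.items() if k != "converged")
    return out


# ---------------------------------------------------------------------------
# the sampler

def _default_init(T: int, rng) -> ModelParams:
    """Overdispersed but sane starting point."""
    u = rng.uniform
    means = {
        "phiF": u(0.85, 0.98), "phiBy": u(0.55, 0.95), "F": u(0.2, 0.8),
        "gamma": u(0.2, 0.8), "psiJuvPb": u(0.15, 0.6), "psiPbBy": u(0.15, 0.6),
        "phiJuvSub": u(0.85, 0.98), "phiAd": u(0.85, 0.98), "psiM": u(0.15, 0.6),
        "deltaPb": u(0.3, 0.9), "deltaNb": u(0.3, 0.9),
        "deltaAdNt": u(0.3, 0.9), "deltaAd": u(0.3, 0.9),
    }
    sds = {name: u(0.05, 0.4) for name in _SD_NAMES}
    return ModelParams(
        means=means, alpha_F=rng.normal(0, 1), alpha_M=rng.normal(0, 1, 4),
        beta_effort=rng.normal(0, 0.5), sds=sds, corr_F=np.eye(4),
        corr_M=np.eye(2), omega_mean=u(2.0, 15.0),
        z_F=np.zeros((T - 1, 4)), z_M=np.zeros((T - 1, 2)),
        z_eps_F=np.zeros(T), z_eps_M=np.zeros(T), z_omega=np.zeros(T - 1),
    )


def _init_latents(params: ModelParams, data: IPMData, priors: PriorConfig) -> LatentState:
    """Deterministic rounding of expected branch counts, inflating the
    initial population until every observed count is supported."""
    counts = data.counts.as_matrix()
    T = data.n_years
    rates = params.rate_arrays()
    base = np.maximum(counts[:, 0], 1).astype(float)
    for factor in 1.6 * 1.25 ** np.arange(40):
        agg = base * factor
        N0 = np.zeros(N_COUNTED)
        N0[[0, 7]] = agg[0] / 2                       # juveniles
        N0[[1, 6, 8, 9]] = agg[1] / 4                 # nonreproductive
        N0[[2, 3, 4, 5]] = agg[2] / 4                 # breeding females
        N0[10] = agg[3]                               # toothed males
        N0 = np.ceil(N0).astype(np.int64)
        if N0.max() > priors.n0_upper:
            break
        L = np.zeros((T - 1, N_LATENT_COLS), dtype=np.int64)
        N = np.zeros((N_COUNTED, T), dtype=np.int64)
        N[:, 0] = N0
        for t in range(T - 1):
            r = {k: rates[k][t] for k in rates}

            def rnd(x):
                return np.int64(round(x))

            L[t, 0] = rnd(N[0, t] * r["phiF"]); L[t, 1] = rnd(L[t, 0] * r["psiJuvPb"])
            L[t, 2] = rnd(N[1, t] * r["phiF"]); L[t, 3] = rnd(L[t, 2] * r["psiPbBy"])
            L[t, 4] = rnd(N[2, t] * r["phiF"]); L[t, 5] = rnd(L[t, 4] * r["phiBy"])
            L[t, 6] = rnd(N[3, t] * r["phiF"]); L[t, 7] = rnd(L[t, 6] * r["phiBy"])
            L[t, 8] = rnd(N[4, t] * r["phiF"]); L[t, 9] = rnd(L[t, 8] * r["phiBy"])
            L[t, 10] = rnd(L[t, 9] * r["F"])
            L[t, 11] = rnd(N[5, t] * r["phiF"])
            L[t, 12] = rnd(N[6, t] * r["phiF"]); L[t, 13] = rnd(L[t, 12] * r["gamma"])
            L[t, 14] = rnd(N[7, t] * r["phiJuvSub"]); L[t, 15] = rnd(L[t, 14] * r["psiM"])
            L[t, 16] = rnd(N[8, t] * r["phiJuvSub"]); L[t, 17] = rnd(L[t, 16] * r["psiM"])
            L[t, 18] = rnd(N[9, t] * r["phiAd"]); L[t, 19] = rnd(L[t, 18] * r["psiM"])
            L[t, 20] = rnd(N[10, t] * r["phiAd"])
            weaners = (L[t, 9] - L[t, 10]) + N[5, t]
            L[t, 21] = weaners // 2
            L[t, 22] = max(rnd(r["omega"]), 0)
            L[t, 23] = L[t, 22] // 2
            _propagate_kernel(N0, L[: t + 1], N[:, : t + 2])
        _propagate_kernel(N0, L, N)
        # every count must be inside its aggregate's support
        juv = N[0] + N[7]
        nonrep = N[1] + N[6] + N[8] + N[9]
        breed = N[2] + N[3] + N[4] + N[5]
        tooth = N[10]
        if (np.all(counts[0] <= juv) and np.all(counts[1] <= nonrep)
                and np.all(counts[2] <= breed) and np.all(counts[3] <= tooth)):
            return LatentState(N0, L)
    raise RuntimeError("could not find an initial latent state supporting the counts")


class _ChainState:
    """One chain: parameters, latents, cached components, proposal scales."""

    def __init__(self, params, latents, prep, priors, rng, cfg):
        self.params = params
        self.latents = latents
        self.prep = prep
        self.priors = priors
        self.rng = rng
        self.cfg = cfg
        T = prep.n_years
        self.N = np.zeros((N_COUNTED, T), dtype=np.int64)
        self.scales = {}
        self.acc = {}
        self.tries = {}
        self.refresh_all()

    # full recomputation (start of chain, and safety)
    def refresh_all(self):
        p, prep = self.params, self.prep
        self.rates = p.rate_arrays()
        self.lp_prior = _log_prior(p, self.priors, self.latents)
        self.ll_me = _me_loglik(p, prep, self.rates)
        if self.latents is not None:
            self.ll_state = _state_loglik(p, self.latents, self.rates, self.N)
            self.ll_count = _count_loglik(p, prep, self.N)
        else:
            self.ll_state = 0.0
            self.ll_count = 0.0

    def set_blocks(self, blocks):
        """Cache per-block prior contributions so a block update only
        recomputes its own part."""
        self.blocks = blocks
        self.prior_parts = {key: prior_fn() for key, *_, prior_fn in blocks}
        self.lp_prior = sum(self.prior_parts.values())

    def logpost(self):
        return self.ll_me + self.ll_count + self.ll_state + self.lp_prior

    def _scale(self, key, default):
        if key not in self.scales:
            self.scales[key] = default
            self.acc[key] = 0
            self.tries[key] = 0
        return self.scales[key]

    def _adapt(self, key, accepted, iteration, target):
        self.tries[key] += 1
        self.acc[key] += accepted
        if iteration < self.cfg.n_burnin:
            step = min(0.25, 2.0 / self.tries[key] ** 0.7)
            self.scales[key] *= math.exp(step * ((1.0 if accepted else 0.0) - target))

    def param_step(self, key, mutate, undo, affects, iteration, vector=False,
                   default_scale=0.25, prior_fn=None):
        """Generic Metropolis step for a continuous block."""
        scale = self._scale(key, default_scale)
        mutate(scale)
        part_new = prior_fn()
        lp_new = self.lp_prior - self.prior_parts[key] + part_new
        accepted = False
        if part_new > -np.inf:
            rates_new = self.rates
            ll_me_new, ll_state_new, ll_count_new = self.ll_me, self.ll_state, self.ll_count
            ok = True
            if "me" in affects or "state" in affects:
                rates_new = self.params.rate_arrays()
                ok = rates_new is not None
            if ok and "me" in affects:
                ll_me_new = _me_loglik(self.params, self.prep, rates_new)
            if ok and "state" in affects and self.latents is not None:
                ll_state_new = _state_loglik(self.params, self.latents, rates_new, self.N)
            if ok and "count" in affects and self.latents is not None:
                ll_count_new = _count_loglik(self.params, self.prep, self.N)
            if ok:
                delta = (ll_me_new - self.ll_me) + (ll_state_new - self.ll_state) \
                    + (ll_count_new - self.ll_count) + (lp_new - self.lp_prior)
                if delta >= 0 or math.log(self.rng.random()) < delta:
                    self.ll_me, self.ll_state, self.ll_count = ll_me_new, ll_state_new, ll_count_new
                    self.lp_prior = lp_new
                    self.prior_parts[key] = part_new
                    self.rates = rates_new
                    accepted = True
        if not accepted:
            undo()
        target = self.cfg.target_accept_vector if vector else self.cfg.target_accept_scalar
        self._adapt(key, accepted, iteration, target)

    def latent_sweep(self):
        """Single-site integer random-walk over N0 and all branch counts."""
        if self.latents is None:
            return
        lat = self.latents
        rng = self.rng
        if not hasattr(self, "_N_try"):
            self._N_try = np.empty_like(self.N)
        n_sites = N_COUNTED + lat.branches.shape[0] * N_LATENT_COLS
        deltas = (rng.integers(1, 3, size=n_sites)
                  * rng.choice((-1, 1), size=n_sites)).astype(np.int64)
        u = rng.random(n_sites)
        pF, pM = self.params.detection_arrays(self.prep.effort_z)
        r = self.rates
        self.ll_state, self.ll_count = _latent_sweep_kernel(
            lat.N0, lat.branches, r["phiF"], r["phiBy"], r["F"], r["gamma"],
            r["psiJuvPb"], r["psiPbBy"], r["phiJuvSub"], r["phiAd"], r["psiM"],
            r["omega"], self.prep.counts, pF, pM, self.priors.n0_upper,
            deltas, u, self.ll_state, self.ll_count, self.N, self._N_try)


def _make_blocks(chain: _ChainState):
    """Closures for every continuous parameter block, each carrying its
    own prior-contribution function (Jacobians of the sampled scale
    included)."""
    p = chain.params
    rng = chain.rng
    priors = chain.priors
    blocks = []

    def mean_prior(name):
        def f():
            v = p.means[name]
            return math.log(v * (1.0 - v)) if 0.0 < v < 1.0 else -np.inf
        return f

    def mean_block(name, affects):
        def mutate(scale):
            chain._undo = p.means[name]
            p.means[name] = float(expit(logit(chain._undo) + scale * rng.normal()))

        def undo():
            p.means[name] = chain._undo
        return (f"mean_{name}", mutate, undo, affects, False, 0.3, mean_prior(name))

    rate_means = ("phiF", "phiBy", "F", "gamma", "psiJuvPb", "psiPbBy",
                  "phiJuvSub", "phiAd", "psiM")
    for name in rate_means:
        blocks.append(mean_block(name, {"me", "state"}))
    for name in ("deltaPb", "deltaNb", "deltaAdNt", "deltaAd"):
        blocks.append(mean_block(name, {"me"}))

    s2 = priors.coef_sd ** 2

    def scalar_block(key, get, set_, affects, scale0=0.3):
        def mutate(scale):
            chain._undo = get()
            set_(chain._undo + scale * rng.normal())

        def undo():
            set_(chain._undo)

        def prior():
            return -0.5 * get() ** 2 / s2
        return (key, mutate, undo, affects, False, scale0, prior)

    blocks.append(scalar_block("alpha_F", lambda: p.alpha_F,
                               lambda v: setattr(p, "alpha_F", v), {"me", "count"}))
    blocks.append(scalar_block("beta_effort", lambda: p.beta_effort,
                               lambda v: setattr(p, "beta_effort", v), {"me", "count"}))
    for i in range(4):
        def mk(i=i):
            def get():
                return float(p.alpha_M[i])

            def set_(v):
                p.alpha_M[i] = v
            return get, set_
        g, s = mk()
        blocks.append(scalar_block(f"alpha_M_{i}", g, s, {"me", "count"}))

    sd_affects = {
        "sd_phiF": {"me", "state"}, "sd_phiBy": {"me", "state"},
        "sd_F": {"me", "state"}, "sd_gamma": {"me", "state"},
        "sd_phiJuvSub": {"me", "state"}, "sd_phiAd": {"me", "state"},
        "sd_eps_F": {"me", "count"}, "sd_eps_M": {"me", "count"},
        "sd_omega": {"state"},
    }
    for name, affects in sd_affects.items():
        def mk(name=name):
            def mutate(scale):
                chain._undo = p.sds[name]
                p.sds[name] = float(chain._undo * math.exp(scale * rng.normal()))

            def undo():
                p.sds[name] = chain._undo

            def prior():
                sd = p.sds[name]
                return math.log(sd) if 0.0 < sd < priors.sd_upper else -np.inf
            return mutate, undo, prior
        m, u, pr = mk(name)
        blocks.append((name, m, u, affects, False, 0.3, pr))

    def corr_block(attr, dim, affects):
        iu = np.triu_indices(dim, k=1)

        def mutate(scale):
            corr = getattr(p, attr)
            chain._undo = corr
            new = corr.copy()
            new[iu] = corr[iu] + scale * rng.normal(size=len(iu[0]))
            new.T[iu] = new[iu]
            setattr(p, attr, new)

        def undo():
            setattr(p, attr, chain._undo)

        def prior():
            corr = getattr(p, attr)
            if np.any(np.abs(corr[iu]) >= 1.0):
                return -np.inf
            try:
                np.linalg.cholesky(corr)
            except np.linalg.LinAlgError:
                return -np.inf
            return 0.0
        return (f"corr_{attr}", mutate, undo, affects, True, 0.1, prior)

    blocks.append(corr_block("corr_F", 4, {"me", "state"}))
    blocks.append(corr_block("corr_M", 2, {"me", "state"}))

    def mutate_omega(scale):
        chain._undo = p.omega_mean
        p.omega_mean = float(chain._undo * math.exp(scale * rng.normal()))

    def omega_prior():
        w = p.omega_mean
        return math.log(w) if 0.0 < w < priors.omega_upper else -np.inf

    blocks.append(("omega_mean", mutate_omega,
                   lambda: setattr(p, "omega_mean", chain._undo), {"state"},
                   False, 0.3, omega_prior))

    def vec_block(attr, col, affects, key):
        def mutate(scale):
            arr = getattr(p, attr)
            if col is None:
                chain._undo = arr.copy()
                arr += scale * rng.normal(size=arr.shape)
            else:
                chain._undo = arr[:, col].copy()
                arr[:, col] += scale * rng.normal(size=arr.shape[0])

        def undo():
            arr = getattr(p, attr)
            if col is None:
                arr[:] = chain._undo
            else:
                arr[:, col] = chain._undo

        def prior():
            arr = getattr(p, attr)
            z = arr if col is None else arr[:, col]
            return -0.5 * float(z @ z)
        return (key, mutate, undo, affects, True, 0.15, prior)

    for j in range(4):
        blocks.append(vec_block("z_F", j, {"me", "state"}, f"z_F_{j}"))
    for j in range(2):
        blocks.append(vec_block("z_M", j, {"me", "state"}, f"z_M_{j}"))
    blocks.append(vec_block("z_eps_F", None, {"me", "count"}, "z_eps_F"))
    blocks.append(vec_block("z_eps_M", None, {"me", "count"}, "z_eps_M"))
    blocks.append(vec_block("z_omega", None, {"state"}, "z_omega"))
    return blocks


_SCALAR_STORE = tuple(f"mean_{n}" for n in _PROB_MEANS) + (
    "alpha_F", "beta_effort", "alpha_M_0", "alpha_M_1", "alpha_M_2", "alpha_M_3",
) + _SD_NAMES + ("omega_mean",)


def _scalar_value(params: ModelParams, key: str) -> float:
    if key.startswith("mean_"):
        return params.means[key[5:]]
    if key.startswith("alpha_M_"):
        return float(params.alpha_M[int(key[-1])])
    if key in params.sds:
        return params.sds[key]
    return float(getattr(params, key))


def fit(data: IPMData, priors: PriorConfig = None, config: FitConfig = None,
        init: ModelParams = None) -> PosteriorDraws:
    """Fit the IPM by adaptive random-walk Metropolis MCMC.

    Latent abundances are sampled (through their branch counts) whenever
    count data are present; with empty data the marginal posterior of
    every parameter is its prior.  Non-convergence is reported in
    ``diagnostics``, never raised.
    """
    priors = priors or PriorConfig()
    config = config or FitConfig()
    priors.validate()
    config.validate()
    prep = _Prepared(data)
    T = data.n_years

    n_kept = (config.n_iterations - config.n_burnin) // config.thin
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    scal = {k: np.empty((config.n_chains, n_kept)) for k in _SCALAR_STORE}
    rate_keep = {k: [] for k in ("phiF", "phiBy", "F", "gamma", "phiJuvSub", "phiAd", "omega")}
    pF_keep, pM_keep, latent_keep = [], [], []
    chain_lab, iter_lab, logpost_keep = [], [], []
    accept_rates = {}

    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        params = init.copy() if init is not None else _default_init(T, rng)
        latents = _init_latents(params, data, priors) if data.counts is not None else None
        chain = _ChainState(params, latents, prep, priors, rng, config)
        blocks = _make_blocks(chain)
        chain.set_blocks(blocks)
        k = 0
        for it in range(config.n_iterations):
            for key, mutate, undo, affects, vector, scale0, prior_fn in blocks:
                chain.param_step(key, mutate, undo, affects, it, vector, scale0,
                                 prior_fn)
            chain.latent_sweep()
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                for key in _SCALAR_STORE:
                    scal[key][c, k] = _scalar_value(params, key)
                rates = chain.rates
                for name in rate_keep:
                    rate_keep[name].append(rates[name].copy())
                pF, pM = params.detection_arrays(prep.effort_z)
                pF_keep.append(pF)
                pM_keep.append(pM)
                if latents is not None:
                    latent_keep.append(chain.N.copy())
                chain_lab.append(c)
                iter_lab.append(k)
                logpost_keep.append(chain.logpost())
                k += 1
        accept_rates[c] = {key: chain.acc[key] / max(chain.tries[key], 1)
                           for key in chain.scales}

    draws = PosteriorDraws(
        scalars=scal,
        rate_draws={k: np.array(v) for k, v in rate_keep.items()},
        detection_pF=np.array(pF_keep),
        detection_pM=np.array(pM_keep),
        latent_draws=np.array(latent_keep) if latent_keep else None,
        chain=np.array(chain_lab),
        iteration=np.array(iter_lab),
        n_years=T,
    )
    diagnostics = {"acceptance": accept_rates, "log_posterior": np.array(logpost_keep)}
    if config.n_chains >= 2 and n_kept >= 4:
        diagnostics["rhat"] = {k: rhat_array(v) for k, v in scal.items()}
        diagnostics["converged"] = all(v < 1.02 for v in diagnostics["rhat"].values())
    draws.diagnostics = diagnostics
    return draws


# ---------------------------------------------------------------------------
# posterior predictive checks

def _freeman_tukey(obs, exp):
    return float(np.sum((np.sqrt(obs) - np.sqrt(exp)) ** 2))


def posterior_predictive_check(draws: PosteriorDraws, data: IPMData, seed: int = 0,
                               max_draws: int = 200) -> dict:
    """Bayesian p-values from Freeman-Tukey discrepancies.

    For counts: observed vs replicated aggregate counts against their
    binomial expectations.  For histories: observed vs replicated yearly
    detection totals (years after first capture) against expectations
    from the forward-propagated state distributions.
    """
    if draws.n_draws == 0:
        raise ValueError("draws are empty")
    rng = np.random.default_rng(seed)
    idx = np.arange(draws.n_draws)
    if draws.n_draws > max_draws:
        idx = rng.choice(idx, size=max_draws, replace=False)
    prep = _Prepared(data)
    out = {}

    if data.counts is not None and draws.latent_draws is not None:
        counts = data.counts.as_matrix()
        hits = 0
        for d in idx:
            N = draws.latent_draws[d]
            pF = draws.detection_pF[d]
            pM = draws.detection_pM[d]
            T = N.shape[1]
            exp = np.empty((4, T))
            rep = np.empty((4, T))
            for t in range(T):
                p_agg = aggregate_detection(N[:, t], pF[t], pM[t])
                agg = np.array([N[ix, t].sum() for ix in
                                (COUNT_AGGREGATES[name] for name in AGGREGATE_ORDER)])
                exp[:, t] = agg * p_agg
                rep[:, t] = rng.binomial(agg, p_agg)
            if _freeman_tukey(rep, exp) >= _freeman_tukey(counts, exp):
                hits += 1
        out["counts"] = hits / len(idx)

    if data.histories:
        T = data.n_years
        obs_totals = np.zeros(T)
        for sex in ("F", "M"):
            ev, fi = prep.events[sex], prep.first[sex]
            for i in range(ev.shape[0]):
                for t in range(fi[i] + 1, T):
                    obs_totals[t] += ev[i, t] != 1
        hits = 0
        for d in idx:
            pF = draws.detection_pF[d]
            pM = draws.detection_pM[d]
            r = {k: draws.rate_draws[k][d] for k in draws.rate_draws}
            dd = {k: draws.scalar_pooled(f"mean_{k}")[d]
                  for k in ("psiJuvPb", "psiPbBy", "psiM",
                            "deltaPb", "deltaNb", "deltaAdNt", "deltaAd")}
            Tf = _female_transition_stack(r["phiF"], r["phiBy"], r["F"], r["gamma"],
                                          np.full(T - 1, dd["psiJuvPb"]),
                                          np.full(T - 1, dd["psiPbBy"]))
            Tm = _male_transition_stack(r["phiJuvSub"], r["phiAd"],
                                        np.full(T - 1, dd["psiM"]))
            Ef = _female_emission_stack(pF, dd["deltaPb"], dd["deltaNb"])
            Em = _male_emission_stack(pM, dd["deltaAdNt"], dd["deltaAd"])
            exp_totals = np.zeros(T)
            rep_totals = np.zeros(T)
            for sex, trans, emit, n_states in (("F", Tf, Ef, 8), ("M", Tm, Em, 5)):
                ev, fi = prep.events[sex], prep.first[sex]
                n = ev.shape[0]
                if n == 0:
                    continue
                p_living = pF[:, None] * np.ones((T, n_states - 1)) if sex == "F" else pM
                # state distribution at first capture, given the first event
                marg = np.zeros((n, n_states))
                first_ev = ev[np.arange(n), fi]
                for i in range(n):
                    w = emit[fi[i], : n_states - 1, first_ev[i] - 1]
                    if w.sum() == 0:
                        w = np.ones(n_states - 1)
                    marg[i, : n_states - 1] = w / w.sum()
                state = (rng.random(n)[:, None] >
                         np.cumsum(marg, axis=1)).sum(axis=1).clip(0, n_states - 1)
                for t in range(1, T):
                    active = fi < t
                    if not active.any():
                        continue
                    marg[active] = marg[active] @ trans[t - 1]
                    exp_totals[t] += float(
                        (marg[active][:, : n_states - 1] * p_living[t]).sum())
                    cum = np.cumsum(trans[t - 1], axis=1)
                    state_new = (rng.random(n)[:, None] >
                                 cum[state]).sum(axis=1).clip(0, n_states - 1)
                    state = np.where(active, state_new, state)
                    det = active & (state < n_states - 1) & (
                        rng.random(n) < p_living[t, state.clip(0, n_states - 2)])
                    rep_totals[t] += int(det.sum())
            if _freeman_tukey(rep_totals, exp_totals) >= _freeman_tukey(obs_totals, exp_totals):
                hits += 1
        out["histories"] = hits / len(idx)
    return out
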