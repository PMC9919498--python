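"""Transient life table response experiments (tLTRE).

Realized population growth is written as a function of an 18-component
demographic vector ``q_t``: six demographic rates (phiF, phiBy, gamma, F,
phiJuvSub, phiAd), the per-capita immigration rate ``iota``, and the 11
proportional stage abundances (which sum to one).  Because growth equals
the Leslie-column-sum weighted mean of the stage proportions plus
``iota``, two identities hold exactly: the sensitivity of growth to the
immigration rate is 1 and the sensitivity to the breeding probability
``gamma`` is 0 (``gamma`` moves females between counted states without
changing any column sum).

Two retrospective decompositions are provided: the contribution of each
component's temporal (co)variation to var(lambda_t), and the first-order
contribution of each component's year-to-year change to
``delta lambda_t``; both evaluate sensitivities at temporal means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import COUNTED_STAGES

__all__ = [
    "Q_COMPONENTS",
    "build_q",
    "validate_q",
    "lambda_of_q",
    "sensitivities",
    "elasticities",
    "variance_contributions",
    "sequential_contributions",
    "TLTREResult",
    "decompose_posterior",
]

RATE_COMPONENTS = ("phiF", "phiBy", "gamma", "F", "phiJuvSub", "phiAd", "iota")
Q_COMPONENTS = RATE_COMPONENTS + tuple(f"Ntilde_{s}" for s in COUNTED_STAGES)
N_Q = len(Q_COMPONENTS)  # 18

_IDX = {name: i for i, name in enumerate(Q_COMPONENTS)}
_NTILDE = slice(7, 18)


def build_q(phiF, phiBy, gamma, F, phiJuvSub, phiAd, iota, Ntilde) -> np.ndarray:
    """Assemble a demographic vector in the canonical component order."""
    Ntilde = np.asarray(Ntilde, dtype=float)
    if Ntilde.shape != (11,):
        raise ValueError("Ntilde must have 11 entries in counted-stage order")
    return np.concatenate([[phiF, phiBy, gamma, F, phiJuvSub, phiAd, iota], Ntilde])


def validate_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (N_Q,):
        raise ValueError(f"q must have {N_Q} components ordered as {Q_COMPONENTS}")
    if np.any(q[:6] < 0) or np.any(q[:6] > 1):
        raise ValueError("demographic rates in q must lie in [0, 1]")
    if q[_IDX["iota"]] < 0:
        raise ValueError("iota must be nonnegative")
    if abs(q[_NTILDE].sum() - 1.0) > 1e-10:
        raise ValueError("proportional abundances must sum to 1 within 1e-10")
    return q


def _column_sums(phiF, phiBy, F, phiJuvSub, phiAd) -> np.ndarray:
    """Leslie column sums c_j for the 11 counted stages."""
    c = np.empty(11)
    c[:7] = phiF
    c[4] = phiF * (1.0 + phiBy * (1.0 - F))   # Bc2: weaner recruitment
    c[5] = phiF + 1.0                          # Bc3: weaning certain
    c[7:9] = phiJuvSub
    c[9:11] = phiAd
    return c


def lambda_of_q(q: np.ndarray, compositional: bool = False) -> float:
    """Realized growth as a function of the demographic vector.

    ``lambda = sum_j c_j * Ntilde_j + iota`` with ``c_j`` the Leslie
    column sums.  In compositional mode the stage proportions are
    renormalized to sum to one before evaluation (used for constrained
    sensitivities); the default treats them as free coordinates.
    """
    q = np.asarray(q, dtype=float)
    c = _column_sums(q[0], q[1], q[3], q[4], q[5])
    ntilde = q[_NTILDE]
    if compositional:
        total = ntilde.sum()
        if total <= 0:
            raise ValueError("proportional abundances sum to zero")
        ntilde = ntilde / total
    return float(c @ ntilde + q[_IDX["iota"]])


def sensitivities(q_bar: np.ndarray, compositional: bool = False) -> np.ndarray:
    """Central finite-difference gradient of lambda at ``q_bar``.

    Step ``h_i = 1e-6 * max(|q_i|, 1)``; components are perturbed one at
    a time with no renormalization of the stage proportions unless
    ``compositional=True``.
    """
    q_bar = np.asarray(q_bar, dtype=float)
    if q_bar.shape != (N_Q,):
        raise ValueError(f"q_bar must have {N_Q} components")
    grad = np.empty(N_Q)
    for i in range(N_Q):
        h = 1e-6 * max(abs(q_bar[i]), 1.0)
        if q_bar[i] + h == q_bar[i]:
            raise FloatingPointError(f"finite-difference step underflow for {Q_COMPONENTS[i]}")
        up = q_bar.copy()
        dn = q_bar.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (lambda_of_q(up, compositional) - lambda_of_q(dn, compositional)) / (2 * h)
    return grad


def elasticities(sens: np.ndarray, q_bar: np.ndarray, lambda_bar: float) -> np.ndarray:
    """Proportional sensitivities ``s_i * q_i / lambda``."""
    if lambda_bar <= 0:
        raise ValueError("lambda_bar must be positive")
    return np.asarray(sens) * np.asarray(q_bar) / lambda_bar


def variance_contributions(q_series: np.ndarray, compositional: bool = False):
    """Decompose var(lambda_t) into per-component contributions.

    ``contribution_i = sum_j cov(theta_i, theta_j) * s_i * s_j`` with
    sensitivities evaluated at the temporal mean vector and population
    covariances (denominator T).  Returns ``(contributions, total,
    shares)``; the total is the variance of the first-order approximation
    of lambda_t.
    """
    q_series = np.asarray(q_series, dtype=float)
    if q_series.ndim != 2 or q_series.shape[1] != N_Q:
        raise ValueError(f"q_series must be (n_years, {N_Q})")
    if q_series.shape[0] < 3:
        raise ValueError("variance decomposition needs at least 3 years")
    q_bar = q_series.mean(axis=0)
    s = sensitivities(q_bar, compositional)
    C = np.cov(q_series.T, bias=True)
    contributions = (C * np.outer(s, s)).sum(axis=1)
    total = float(s @ C @ s)
    shares = contributions / total if total > 0 else np.zeros(N_Q)
    return contributions, total, shares


def sequential_contributions(q_series: np.ndarray, compositional: bool = False):
    """First-order contributions to the change in lambda between years.

    ``contribution_{i,t} = (theta_{i,t+1} - theta_{i,t}) * s_i`` with the
    sensitivity evaluated at the temporal mean.  Returns the
    ``(n_components, n_years - 1)`` table and the per-interval sums.
    """
    q_series = np.asarray(q_series, dtype=float)
    if q_series.ndim != 2 or q_series.shape[1] != N_Q:
        raise ValueError(f"q_series must be (n_years, {N_Q})")
    if q_series.shape[0] < 2:
        raise ValueError("sequential decomposition needs at least 2 years")
    s = sensitivities(q_series.mean(axis=0), compositional)
    diffs = np.diff(q_series, axis=0)          # (T-1, 18)
    table = (diffs * s).T                      # (18, T-1)
    return table, table.sum(axis=0)


@dataclass
class TLTREResult:
    """Posterior summaries (mean, 2.5%, 97.5%) of the tLTRE quantities."""

    components: tuple
    sensitivity: np.ndarray        # (3, 18)
    elasticity: np.ndarray         # (3, 18)
    var_contribution: np.ndarray   # (3, 18)
    var_share: np.ndarray          # (3, 18)
    seq_contribution: np.ndarray   # (3, 18, T-2) per-interval
    delta_lambda: np.ndarray       # (3, T-2) per-interval sums

    def to_dataframe(self) -> pd.DataFrame:
        """One row per component: sensitivity, elasticity and variance
        contribution, each with mean and 95% interval."""
        cols = {}
        for label, arr in (
            ("sensitivity", self.sensitivity),
            ("elasticity", self.elasticity),
            ("contribution", self.var_contribution),
            ("share", self.var_share),
        ):
            cols[f"{label}_mean"] = arr[0]
            cols[f"{label}_2.5%"] = arr[1]
            cols[f"{label}_97.5%"] = arr[2]
        return pd.DataFrame(cols, index=list(self.components))


def _summaries(values: np.ndarray) -> np.ndarray:
    return np.stack([
        values.mean(axis=0),
        np.percentile(values, 2.5, axis=0),
        np.percentile(values, 97.5, axis=0),
    ])


def q_series_from_draw(rates: dict, N: np.ndarray) -> np.ndarray:
    """Demographic-vector series for one posterior draw.

    ``rates`` maps each of phiF, phiBy, gamma, F, phiJuvSub, phiAd and
    omega to a length ``T-1`` array; ``N`` is the (11, T) latent
    abundance.  The vector for year ``t`` combines the rates governing
    the ``t -> t+1`` step with the stage structure in year ``t``.
    """
    missing = [k for k in ("phiF", "phiBy", "gamma", "F", "phiJuvSub", "phiAd", "omega")
               if k not in rates]
    if missing:
        raise ValueError(f"missing rate series: {missing}")
    N = np.asarray(N, dtype=float)
    T = N.shape[1]
    totals = N.sum(axis=0)
    if np.any(totals[:-1] <= 0):
        raise ValueError("total abundance must be positive")
    out = np.empty((T - 1, N_Q))
    for t in range(T - 1):
        out[t] = build_q(
            rates["phiF"][t], rates["phiBy"][t], rates["gamma"][t], rates["F"][t],
            rates["phiJuvSub"][t], rates["phiAd"][t],
            rates["omega"][t] / totals[t],
            N[:, t] / totals[t],
        )
    return out


def decompose_posterior(draws, compositional: bool = False) -> TLTREResult:
    """Run both tLTRE decompositions for every posterior draw and summarize.

    ``draws`` must expose ``rate_draws`` (mapping each rate name to an
    ``(n_draws, T-1)`` array, including ``omega``) and ``latent_draws``
    (``(n_draws, 11, T)`` abundances), as produced by the inference
    module.
    """
    rate_draws = draws.rate_draws
    latent = np.asarray(draws.latent_draws)
    needed = ("phiF", "phiBy", "gamma", "F", "phiJuvSub", "phiAd", "omega")
    missing = [k for k in needed if k not in rate_draws]
    if missing:
        raise ValueError(f"posterior draws lack rate series: {missing}")
    n_draws = latent.shape[0]
    T = latent.shape[2]

    sens = np.empty((n_draws, N_Q))
    elas = np.empty((n_draws, N_Q))
    contrib = np.empty((n_draws, N_Q))
    share = np.empty((n_draws, N_Q))
    seq = np.empty((n_draws, N_Q, T - 2))
    dlam = np.empty((n_draws, T - 2))
    for d in range(n_draws):
        rates = {k: np.asarray(rate_draws[k][d]) for k in needed}
        q_series = q_series_from_draw(rates, latent[d])
        q_bar = q_series.mean(axis=0)
        s = sensitivities(q_bar, compositional)
        sens[d] = s
        elas[d] = elasticities(s, q_bar, lambda_of_q(q_bar, compositional))
        contrib[d], _, share[d] = variance_contributions(q_series, compositional)
        seq[d], dlam[d] = sequential_contributions(q_series, compositional)

    return TLTREResult(
        components=Q_COMPONENTS,
        sensitivity=_summaries(sens),
        elasticity=_summaries(elas),
        var_contribution=_summaries(contrib),
        var_share=_summaries(share),
        seq_contribution=_summaries(seq),
        delta_lambda=_summaries(dlam),
    )
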