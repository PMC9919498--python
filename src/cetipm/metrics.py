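"""Derived fecundity and growth metrics.

All metrics are simple deterministic functions of demographic rates or
latent abundances; in a Bayesian workflow they are computed per posterior
draw and then summarized (mean and central 95% interval), never on
posterior means of their inputs.
"""

from __future__ import annotations

import numpy as np

from .population import LatentPopulation

__all__ = [
    "interbirth_interval",
    "weaning_probability",
    "calf_retention_from_survivals",
    "reproductive_rate",
    "weaning_rate",
    "realized_growth_series",
    "immigration_rate",
    "posterior_metric_series",
    "summarize_draws",
]


def interbirth_interval(gamma_hat: float) -> float:
    """Mean years between successive births, ``1 / gamma_hat + 1``.

    A nonbreeding female waits a geometric number of years (mean
    1/gamma) before re-breeding, after the birth year itself.
    """
    if not (0.0 < gamma_hat <= 1.0):
        raise ValueError("gamma_hat must lie in (0, 1]")
    return 1.0 / gamma_hat + 1.0


def weaning_probability(F_t: float) -> float:
    """Probability a 2-year-old calf weans rather than staying: ``1 - F_t``."""
    if not (0.0 <= F_t <= 1.0):
        raise ValueError("F_t must lie in [0, 1]")
    return 1.0 - F_t


def calf_retention_from_survivals(phiBc: float, phiBy: float) -> float:
    """Retention probability ``F = phiBc / phiBy``.

    ``phiBc`` is the identifiable survival-and-stay product for older
    calves; dividing by young-of-the-year survival recovers the pure
    retention probability.
    """
    if not (0.0 < phiBy <= 1.0):
        raise ValueError("phiBy must lie in (0, 1]")
    if not (0.0 <= phiBc <= phiBy):
        raise ValueError("phiBc must lie in [0, phiBy] so that F <= 1")
    return phiBc / phiBy


def reproductive_rate(N_By, N_Bc1, N_Bc2, N_Bc3, N_Nb) -> float:
    """Proportion of recruited females with a young-of-the-year.

    Denominator: all females that have bred at least once (breeders of
    any calf age plus nonbreeders).
    """
    denom = N_By + N_Bc1 + N_Bc2 + N_Bc3 + N_Nb
    if denom <= 0:
        raise ValueError("no recruited females; reproductive rate undefined")
    return N_By / denom


def weaning_rate(phiF: float, phiBy: float, F: float) -> float:
    """Per-female weaning rate.

    A newborn weans successfully if it survives two mother-attached years
    (probability ``(phiF * phiBy)**2``) and then either leaves at the
    2 -> 3 transition (``1 - F``) or stays a third year, surviving with
    the mother, and weans at 3 (``F * phiF * phiBy``).
    """
    for name, v in (("phiF", phiF), ("phiBy", phiBy), ("F", F)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    s = phiF * phiBy
    return s ** 2 * ((1.0 - F) + F * s)


def realized_growth_series(population: LatentPopulation):
    """Yearly realized growth ``lambda_t = N_{t+1} / N_t`` and its geometric mean."""
    totals = population.totals().astype(float)
    if np.any(totals <= 0):
        raise ValueError("total abundance must be positive in every year")
    lam = totals[1:] / totals[:-1]
    T = len(totals)
    geo_mean = float((totals[-1] / totals[0]) ** (1.0 / (T - 1)))
    return lam, geo_mean


def immigration_rate(omega_t: float, total_N_t: float) -> float:
    """Per-capita immigration rate ``iota_t = omega_t / N_t``."""
    if total_N_t <= 0:
        raise ValueError("total abundance must be positive")
    return omega_t / total_N_t


def posterior_metric_series(draws):
    """Fecundity and growth metrics per posterior draw, summarized.

    ``draws`` must expose ``rate_draws`` (per-rate ``(n_draws, T-1)``
    arrays including ``omega``), ``latent_draws`` (``(n_draws, 11, T)``)
    and the stored scalar hyperparameters.  Metrics are evaluated on
    each draw and then summarized, so the returned intervals propagate
    posterior uncertainty correctly.  Returns a long-format DataFrame
    with columns metric, year, mean, 2.5%, 97.5% (year is empty for
    study-level scalars).
    """
    import pandas as pd

    rd = draws.rate_draws
    N = np.asarray(draws.latent_draws, dtype=float)
    totals = N.sum(axis=1)                      # (n_draws, T)
    if np.any(totals <= 0):
        raise ValueError("total abundance must be positive in every draw/year")
    gamma = np.asarray(rd["gamma"])
    F = np.asarray(rd["F"])
    per_year = {
        "gamma": gamma,
        "weaning_probability": 1.0 - F,
        "WR": np.vectorize(weaning_rate)(rd["phiF"], rd["phiBy"], F),
        "iota": rd["omega"] / totals[:, :-1],
        "lambda": totals[:, 1:] / totals[:, :-1],
    }
    recruited = N[:, 2:7, :].sum(axis=1)        # By..Nb females
    per_year["RR"] = np.where(recruited > 0, N[:, 2, :] / recruited, np.nan)
    T = totals.shape[1]
    scalars = {
        "interbirth_interval": 1.0 / gamma.mean(axis=1) + 1.0,
        "psiPbBy": draws.scalar_pooled("mean_psiPbBy"),
        "geometric_mean_lambda": (totals[:, -1] / totals[:, 0]) ** (1.0 / (T - 1)),
    }
    rows = []
    for name, values in per_year.items():
        mean, lo, hi = summarize_draws(values)
        for year in range(values.shape[1]):
            rows.append((name, year, mean[year], lo[year], hi[year]))
    for name, values in scalars.items():
        mean, lo, hi = summarize_draws(values)
        rows.append((name, pd.NA, mean, lo, hi))
    return pd.DataFrame(rows, columns=["metric", "year", "mean", "2.5%", "97.5%"])


def summarize_draws(values: np.ndarray, axis: int = 0):
    """Posterior mean and central 95% interval along ``axis``."""
    values = np.asarray(values, dtype=float)
    return (
        values.mean(axis=axis),
        np.percentile(values, 2.5, axis=axis),
        np.percentile(values, 97.5, axis=axis),
    )
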