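"""Delimited-text readers and writers for the pipeline's artifacts.

All files are plain CSV (histories, counts, effort, posterior draws) or
YAML (scenario truth), so a simulated study can be written to disk,
inspected, and read back for recovery experiments.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .multievent import CaptureHistory
from .params import DetectionParams, TrueParameters
from .population import CountSeries

__all__ = [
    "write_histories", "read_histories",
    "write_counts", "read_counts",
    "write_effort", "read_effort",
    "write_truth", "read_truth",
]


def write_histories(histories, path) -> None:
    """One row per individual-year: id, sex, year, event (from first detection)."""
    rows = []
    for h in histories:
        for k, ev in enumerate(h.events):
            rows.append((h.individual_id, h.sex, h.first_year + k, int(ev)))
    pd.DataFrame(rows, columns=["id", "sex", "year", "event"]).to_csv(path, index=False)


def read_histories(path) -> list:
    df = pd.read_csv(path)
    histories = []
    for ind, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if np.any(np.diff(years) != 1):
            raise ValueError(f"history of individual {ind} has missing years")
        histories.append(CaptureHistory(
            individual_id=int(ind),
            sex=str(grp["sex"].iloc[0]),
            first_year=int(years[0]),
            events=grp["event"].to_numpy(dtype=int),
        ))
    return histories


def write_counts(counts: CountSeries, path) -> None:
    pd.DataFrame({
        "year": np.arange(counts.n_years),
        "juveniles": counts.juveniles,
        "nonreproductive": counts.nonreproductive,
        "breeding_females": counts.breeding_females,
        "toothed_males": counts.toothed_males,
    }).to_csv(path, index=False)


def read_counts(path) -> CountSeries:
    df = pd.read_csv(path).sort_values("year")
    return CountSeries(
        juveniles=df["juveniles"].to_numpy(dtype=int),
        nonreproductive=df["nonreproductive"].to_numpy(dtype=int),
        breeding_females=df["breeding_females"].to_numpy(dtype=int),
        toothed_males=df["toothed_males"].to_numpy(dtype=int),
    )


def write_effort(effort, path) -> None:
    effort = np.asarray(effort)
    pd.DataFrame({"year": np.arange(len(effort)), "n_surveys": effort}).to_csv(
        path, index=False)


def read_effort(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("year")
    return df["n_surveys"].to_numpy(dtype=int)


def write_truth(params: TrueParameters, path) -> None:
    """Scenario parameters as YAML, for parameter-recovery bookkeeping."""
    data = asdict(params)
    data["detection"]["alpha_M_by_stage"] = [
        float(x) for x in params.detection.alpha_M_by_stage]
    data["year_effect_corr_female"] = np.asarray(
        params.year_effect_corr_female).tolist()
    data["year_effect_corr_male"] = np.asarray(params.year_effect_corr_male).tolist()
    data["initial_sizes"] = [int(x) for x in params.initial_sizes]
    data["effort_range"] = list(params.effort_range)
    data["year_effect_sds"] = {k: float(v) for k, v in params.year_effect_sds.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_truth(path) -> TrueParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    det = data.pop("detection")
    det["alpha_M_by_stage"] = np.asarray(det["alpha_M_by_stage"], dtype=float)
    data["detection"] = DetectionParams(**det)
    data["year_effect_corr_female"] = np.asarray(data["year_effect_corr_female"])
    data["year_effect_corr_male"] = np.asarray(data["year_effect_corr_male"])
    data["initial_sizes"] = np.asarray(data["initial_sizes"], dtype=int)
    data["effort_range"] = tuple(data["effort_range"])
    params = TrueParameters(**data)
    params.validate()
    return params
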