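"""Preparation of derived white-matter tract metrics.

Per-hemisphere tract measures are screened for outliers beyond +/- 3 SD of
the group mean (single pass, strict inequality), a participant flagged in any
hemisphere or measure of a tract is excluded for that whole tract, and the
surviving left/right values are averaged into the analysis phenotype.
Input tables follow the ``<tract>_<measure>_<L|R>`` column convention.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

MEASURES = ("axonal_density", "orientation_dispersion")


def trim_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean flag per value: ``|v - mean| > k * SD`` (strict), with mean and
    SD computed once on all non-missing values. Zero variance flags nothing;
    missing values are never flagged. Requires >= 3 non-missing values."""
    values = np.asarray(values, dtype=float)
    obs = np.isfinite(values)
    if obs.sum() < 3:
        raise ValueError("need at least 3 non-missing values to trim")
    mu = values[obs].mean()
    sd = values[obs].std(ddof=1)
    if sd == 0:
        return np.zeros(len(values), dtype=bool)
    return obs & (np.abs(values - mu) > k * sd)


def bilateral_average(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Arithmetic mean of hemispheres; NaN wherever either side is missing."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    out = (left + right) / 2.0
    out[~(np.isfinite(left) & np.isfinite(right))] = np.nan
    return out


def prepare_phenotypes(
    raw: pd.DataFrame,
    tracts: tuple[str, ...],
    measures: tuple[str, ...] = MEASURES,
    k: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim and bilaterally average a raw per-hemisphere phenotype table.

    Returns ``(wide, tidy)``: ``wide`` has one ``<tract>_<measure>`` column of
    bilateral means (NaN where the participant is excluded for that tract);
    ``tidy`` has one row per (participant, tract, measure) with left/right,
    mean and the exclusion flag.
    """
    excluded: dict[str, np.ndarray] = {}
    for tract in tracts:
        flag = np.zeros(len(raw), dtype=bool)
        for measure in measures:
            for hemi in ("L", "R"):
                col = f"{tract}_{measure}_{hemi}"
                flag |= trim_outliers(raw[col].to_numpy(), k)
        excluded[tract] = flag

    wide = pd.DataFrame(index=raw.index)
    tidy_rows = []
    for tract in tracts:
        flag = excluded[tract]
        for measure in measures:
            left = raw[f"{tract}_{measure}_L"].to_numpy(dtype=float)
            right = raw[f"{tract}_{measure}_R"].to_numpy(dtype=float)
            mean = bilateral_average(left, right)
            mean[flag] = np.nan
            wide[f"{tract}_{measure}"] = mean
            tidy_rows.append(
                pd.DataFrame(
                    {
                        "IID": raw.index,
                        "tract": tract,
                        "measure": measure,
                        "left": left,
                        "right": right,
                        "mean": mean,
                        "excluded": flag,
                    }
                )
            )
    tidy = pd.concat(tidy_rows, ignore_index=True)
    return wide, tidy
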