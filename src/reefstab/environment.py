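"""Per-site abiotic predictors: SST trend and variability, chlorophyll
variability, human gravity and site depth.

Each site carries 14 annual values of sea surface temperature (SST) and
chlorophyll a.  The predictors entering the path model are the temporal mean
of SST, its least-squares linear trend (warming rate, degrees C per year),
the interannual coefficients of variation of SST and chlorophyll, the human
gravity index (population density over travel time, a fishing-pressure
proxy), mean site depth, and the number of surveyed years (a gap-filling
control).  Mean chlorophyll and its trend are computed but excluded from the
default predictor set because they track mean SST too closely to separate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["sst_trend", "cv_series", "abiotic_summary", "DEFAULT_PREDICTORS"]

DEFAULT_PREDICTORS = (
    "mean_sst",
    "sst_change",
    "cv_sst",
    "cv_chl",
    "gravity",
    "site_depth",
    "n_years",
)


def sst_trend(annual_sst, years=None) -> float:
    """OLS slope of annual SST on calendar year (degrees C per year)."""
    y = np.asarray(annual_sst, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 years to estimate a trend")
    x = np.arange(len(y)) if years is None else np.asarray(years, dtype=float)
    if len(x) != len(y):
        raise ValueError("years and series lengths differ")
    if np.all(y == y[0]):
        return 0.0
    return float(linregress(x, y).slope)


def cv_series(series) -> float:
    """Interannual coefficient of variation: sample sd / mean."""
    y = np.asarray(series, dtype=float)
    m = y.mean()
    if m <= 0:
        raise ValueError("coefficient of variation needs a positive mean")
    return float(y.std(ddof=1) / m)


def abiotic_summary(sites, include_chl_mean: bool = False) -> pd.DataFrame:
    """Summarize a list of site profiles into the path-model predictor table.

    ``sites`` is an iterable of objects (or dicts) with fields site_id,
    sst_series, chl_series, gravity, site_depth and surveyed_years.
    """
    rows = []
    for s in sites:
        get = s.get if isinstance(s, dict) else lambda k, _s=s: getattr(_s, k)
        sst = np.asarray(get("sst_series"), dtype=float)
        chl = np.asarray(get("chl_series"), dtype=float)
        row = {
            "site_id": get("site_id"),
            "mean_sst": float(sst.mean()),
            "sst_change": sst_trend(sst),
            "cv_sst": cv_series(sst),
            "cv_chl": cv_series(chl),
            "gravity": float(get("gravity")),
            "site_depth": float(get("site_depth")),
            "n_years": len(get("surveyed_years")),
        }
        if include_chl_mean:
            row["mean_chl"] = float(chl.mean())
            row["chl_change"] = sst_trend(chl)
        rows.append(row)
    return pd.DataFrame(rows)
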