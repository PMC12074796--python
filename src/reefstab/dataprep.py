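"""From survey-style counts to per-site species x year biomass matrices.

The processing chain mirrors standard reef-transect practice:

1. sum counts over the two blocks (sides) of each transect;
2. convert counts to weight with species length-weight relationships
   (w = a * L^b at the size-class midpoint) and average species biomass
   across the transects surveyed in each site-year;
3. replace zero records of locally present species with half the minimum
   positive value for that species at the site (detection-limit rule);
4. fill unsurveyed years by linear interpolation inside the surveyed span
   and by nearest-value extrapolation at the edges;
5. keep only sites surveyed in at least ``min_years`` of the window.

Every cell of the resulting matrix carries a provenance flag so downstream
sensitivity analyses can distinguish observed from reconstructed biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "WINDOW",
    "CommunityMatrix",
    "aggregate_blocks",
    "biomass_from_counts",
    "build_matrices",
    "impute_zero_records",
    "interpolate_missing_years",
    "filter_sites",
    "prepare_communities",
    "degrade_and_correlate",
]

#: the study window: 14 calendar years, inclusive
WINDOW = tuple(range(2008, 2022))

SURVEY_KEYS = ["site_id", "year", "transect_id", "block_id", "species_id", "size_class"]

OBSERVED = "observed"
ZERO_IMPUTED = "zero_imputed"
INTERPOLATED = "interpolated"
EDGE = "edge_extrapolated"


@dataclass
class CommunityMatrix:
    """Species x year biomass for one site, with per-cell provenance flags."""

    site_id: str
    biomass: pd.DataFrame  # rows = species, columns = years (int)
    flags: pd.DataFrame  # same shape, values in {observed, zero_imputed, ...}
    surveyed_years: tuple

    def __post_init__(self):
        if self.biomass.shape != self.flags.shape:
            raise ValueError("biomass and flag matrices must have equal shape")
        if (self.biomass.to_numpy() < 0).any():
            raise ValueError("biomass must be non-negative")
        self.surveyed_years = tuple(sorted(int(y) for y in self.surveyed_years))

    @property
    def years(self) -> list[int]:
        return [int(c) for c in self.biomass.columns]

    @property
    def species(self) -> list:
        return list(self.biomass.index)


def aggregate_blocks(surveys: pd.DataFrame) -> pd.DataFrame:
    """Sum abundance over the two blocks of each transect.

    Input columns: site_id, year, transect_id, block_id, species_id,
    size_class, abundance.  Duplicate survey keys are malformed input.
    """
    required = set(SURVEY_KEYS) | {"abundance"}
    missing = required - set(surveys.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    if surveys.duplicated(SURVEY_KEYS).any():
        raise ValueError("duplicate (site, year, transect, block, species, size) keys")
    keys = [k for k in SURVEY_KEYS if k != "block_id"]
    if len(surveys) == 0:
        return surveys.loc[:, keys + ["abundance"]]
    return surveys.groupby(keys, as_index=False, sort=True)["abundance"].sum()


def biomass_from_counts(aggregated: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Transect-averaged annual biomass (g) per (site, year, species).

    Per size class, weight = lw_a * size_class^lw_b * abundance; size-class
    weights are summed within each transect and the species total is averaged
    over all transects surveyed in that site-year (a transect where the
    species was not recorded contributes zero).
    """
    t = traits.set_index("species_id") if "species_id" in traits.columns else traits
    species = aggregated["species_id"].unique()
    missing = [s for s in species if s not in t.index or
               pd.isna(t.loc[s, "lw_a"]) or pd.isna(t.loc[s, "lw_b"])]
    if missing:
        raise ValueError(f"species missing length-weight coefficients: {sorted(missing)}")
    if len(aggregated) == 0:
        return pd.DataFrame(columns=["site_id", "year", "species_id", "biomass"])

    df = aggregated.copy()
    df["weight"] = (
        t.loc[df["species_id"], "lw_a"].to_numpy()
        * df["size_class"].to_numpy() ** t.loc[df["species_id"], "lw_b"].to_numpy()
        * df["abundance"].to_numpy()
    )
    # number of transects actually surveyed in each site-year
    n_tr = (
        df.groupby(["site_id", "year"])["transect_id"].nunique().rename("n_transects")
    )
    per_sp = (
        df.groupby(["site_id", "year", "species_id"], as_index=False)["weight"].sum()
    )
    per_sp = per_sp.merge(n_tr, on=["site_id", "year"])
    per_sp["biomass"] = per_sp["weight"] / per_sp["n_transects"]
    return per_sp.loc[:, ["site_id", "year", "species_id", "biomass"]]


def build_matrices(biomass: pd.DataFrame, surveyed_years: dict | None = None) -> dict:
    """Pivot per-(site, year, species) biomass into CommunityMatrix objects.

    Every species ever recorded at a site gets a value in every surveyed
    year; years with no record for a locally present species become explicit
    zeros (candidates for the detection-limit rule).  ``surveyed_years`` may
    supply the surveyed set per site; by default it is the set of years with
    any record.
    """
    out = {}
    for site_id, sub in biomass.groupby("site_id"):
        years = (
            sorted(surveyed_years[site_id])
            if surveyed_years is not None
            else sorted(sub["year"].unique())
        )
        mat = (
            sub.pivot_table(index="species_id", columns="year", values="biomass",
                            aggfunc="sum", fill_value=0.0)
            .reindex(columns=years, fill_value=0.0)
            .sort_index()
        )
        flags = pd.DataFrame(OBSERVED, index=mat.index, columns=mat.columns)
        out[site_id] = CommunityMatrix(str(site_id), mat.astype(float), flags, tuple(years))
    return out


def impute_zero_records(cm: CommunityMatrix) -> CommunityMatrix:
    """Replace zeros in each species' surveyed-year series by half the
    species' minimum positive biomass at the site (its detection limit).

    A species that was never positive at the site violates the "previously
    observed" premise and raises.
    """
    mat = cm.biomass.copy()
    flags = cm.flags.copy()
    arr = mat.to_numpy()
    for i, sp in enumerate(mat.index):
        row = arr[i]
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"species {sp!r} has an all-zero series at {cm.site_id}")
        if (row == 0).any():
            fill = pos.min() / 2.0
            zero = row == 0
            arr[i, zero] = fill
            flags.iloc[i, np.flatnonzero(zero)] = ZERO_IMPUTED
    mat.iloc[:, :] = arr
    return replace(cm, biomass=mat, flags=flags)


def interpolate_missing_years(cm: CommunityMatrix, window=WINDOW) -> CommunityMatrix:
    """Fill unsurveyed years over the full window.

    Interior gaps are filled by linear interpolation of each species' series
    against calendar year; years before the first (after the last) survey are
    held constant at the nearest surveyed value.  Observed cells are never
    altered.
    """
    window = [int(y) for y in window]
    surveyed = [y for y in cm.years if y in window]
    if not surveyed:
        raise ValueError(f"site {cm.site_id} has no surveyed years in the window")
    wide = cm.biomass.reindex(columns=window)
    filled = wide.T  # years as index so interpolate uses the year spacing
    filled.index = filled.index.astype(float)
    filled = filled.interpolate(method="index", limit_area="inside")
    filled = filled.ffill().bfill().T
    filled.columns = window

    first, last = min(surveyed), max(surveyed)
    flags = pd.DataFrame(index=cm.biomass.index, columns=window, dtype=object)
    for y in window:
        if y in surveyed:
            flags[y] = cm.flags[y].to_numpy()
        elif y < first or y > last:
            flags[y] = EDGE
        else:
            flags[y] = INTERPOLATED
    return replace(cm, biomass=filled.astype(float), flags=flags,
                   surveyed_years=tuple(surveyed))


def filter_sites(matrices: dict, min_years: int = 7, window=WINDOW) -> dict:
    """Keep sites surveyed in at least ``min_years`` years of the window."""
    window = set(int(y) for y in window)
    return {
        sid: cm
        for sid, cm in matrices.items()
        if len(set(cm.surveyed_years) & window) >= min_years
    }


def prepare_communities(
    surveys: pd.DataFrame,
    traits: pd.DataFrame,
    min_years: int = 7,
    window=WINDOW,
    surveyed_years: dict | None = None,
) -> dict:
    """Full chain: aggregate, weigh, impute zeros, interpolate, filter."""
    agg = aggregate_blocks(surveys)
    bio = biomass_from_counts(agg, traits)
    mats = build_matrices(bio, surveyed_years)
    mats = {sid: interpolate_missing_years(impute_zero_records(cm), window)
            for sid, cm in mats.items()}
    return filter_sites(mats, min_years=min_years, window=window)


def write_matrices(matrices: dict, out_dir) -> None:
    """Serialize CommunityMatrix objects: wide biomass CSV + parallel flag CSV."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for sid, cm in matrices.items():
        cm.biomass.to_csv(os.path.join(out_dir, f"{sid}_biomass.csv"))
        cm.flags.to_csv(os.path.join(out_dir, f"{sid}_flags.csv"))


def read_matrices(in_dir) -> dict:
    """Load matrices written by :func:`write_matrices`."""
    import glob
    import os

    out = {}
    for path in sorted(glob.glob(os.path.join(in_dir, "*_biomass.csv"))):
        sid = os.path.basename(path)[: -len("_biomass.csv")]
        bio = pd.read_csv(path, index_col=0)
        bio.columns = bio.columns.astype(int)
        flags = pd.read_csv(os.path.join(in_dir, f"{sid}_flags.csv"), index_col=0)
        flags.columns = flags.columns.astype(int)
        surveyed = [y for y in bio.columns if (flags[y].isin([OBSERVED, ZERO_IMPUTED])).any()]
        out[sid] = CommunityMatrix(sid, bio.astype(float), flags, tuple(surveyed))
    return out


def degrade_and_correlate(
    complete: dict,
    n_drop: int,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Sensitivity of community stability to gap filling.

    Each replicate drops ``n_drop`` random years independently per site from
    fully surveyed matrices, re-interpolates, recomputes community stability
    and correlates it (Pearson, across sites) with the raw-data stability.
    Returns one row per replicate with the correlation.
    """
    from .stability import community_stability

    sites = list(complete)
    if not sites:
        raise ValueError("no sites supplied")
    window = list(WINDOW)
    if n_drop >= len(window):
        raise ValueError("cannot drop all years of the window")
    for cm in complete.values():
        if list(cm.surveyed_years) != window or cm.years != window:
            raise ValueError("degradation requires fully surveyed sites")

    raw = np.array([community_stability(complete[s].biomass.to_numpy()) for s in sites])
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        degraded = []
        for s in sites:
            cm = complete[s]
            if n_drop == 0:
                degraded.append(raw[sites.index(s)])
                continue
            drop = rng.choice(len(window), size=n_drop, replace=False)
            keep = [y for k, y in enumerate(window) if k not in set(drop)]
            sub = replace(
                cm,
                biomass=cm.biomass.loc[:, keep],
                flags=cm.flags.loc[:, keep],
                surveyed_years=tuple(keep),
            )
            refilled = interpolate_missing_years(sub, window=window)
            degraded.append(community_stability(refilled.biomass.to_numpy()))
        degraded = np.asarray(degraded)
        r = 1.0 if n_drop == 0 else float(np.corrcoef(raw, degraded)[0, 1])
        rows.append({"replicate": rep, "n_drop": n_drop, "correlation": r})
    return pd.DataFrame(rows)
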