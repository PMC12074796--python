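"""Facets of functional diversity for reef-fish communities.

Four complementary facets of the community trait distribution:

* community-weighted means (CWM) of each trait — trait dominance;
* taxonomic Hill diversity of order 1, ``TD1 = exp(Shannon entropy)``;
* functional Hill diversity ``FD1``, the effective number of functionally
  distinct species given a trait-distance threshold ``tau`` (the
  attribute-diversity framework of Chao et al.);
* trait redundancy ``FR1 = 1 - FD1/TD1`` and per-species trait
  distinctiveness with richness-residualized counts of distinct species.

Distances are Euclidean on transformed traits: maximum length and maximum
depth are log-transformed, then all traits are z-scored over the species pool
so that no trait dominates through its measurement unit.  ``tau`` defaults to
the mean off-diagonal trait distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

TRAIT_COLUMNS = ("max_length", "growth_coeff", "trophic_level", "max_depth")
LOG_TRAITS = ("max_length", "max_depth")

__all__ = [
    "DistanceMatrix",
    "cwm",
    "trait_distances",
    "hill_taxonomic",
    "hill_functional",
    "trait_redundancy",
    "distinctiveness",
    "n_distinct_residual",
    "relative_biomass_weights",
    "facet_table",
]


@dataclass
class DistanceMatrix:
    """Species x species Euclidean trait distances with threshold tau."""

    species: list
    d: np.ndarray
    tau: float

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def subset(self, species) -> "DistanceMatrix":
        """Distance sub-matrix for a species subset (tau unchanged)."""
        idx = [self.species.index(s) for s in species]
        return DistanceMatrix(list(species), self.d[np.ix_(idx, idx)], self.tau)


def cwm(traits: pd.DataFrame, weights) -> dict[str, float]:
    """Community-weighted mean of each trait on the raw (untransformed) scale.

    ``weights`` are relative biomasses aligned with the rows of ``traits``
    and must sum to 1.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(traits):
        raise ValueError("weights and trait table lengths differ")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return {
        f"cwm_{col}": float(np.dot(w, traits[col].to_numpy(dtype=float)))
        for col in TRAIT_COLUMNS
        if col in traits.columns
    }


def trait_distances(
    traits: pd.DataFrame,
    standardize: bool = True,
    columns: tuple[str, ...] = TRAIT_COLUMNS,
) -> DistanceMatrix:
    """Euclidean trait distances over the species pool.

    max_length and max_depth are log-transformed first; all traits are then
    z-scored over the pool (disable with ``standardize=False``).  tau is set
    to the mean off-diagonal distance.
    """
    if len(traits) < 2:
        raise ValueError("need at least 2 species")
    X = traits.loc[:, list(columns)].to_numpy(dtype=float).copy()
    for j, col in enumerate(columns):
        if col in LOG_TRAITS:
            if np.any(X[:, j] <= 0):
                raise ValueError(f"{col} must be positive for log transform")
            X[:, j] = np.log(X[:, j])
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant trait carries no distance information
        X = (X - X.mean(axis=0)) / sd
    d = squareform(pdist(X, metric="euclidean"))
    n = d.shape[0]
    tau = float(d[np.triu_indices(n, k=1)].mean())
    species = list(traits["species_id"]) if "species_id" in traits else list(traits.index)
    return DistanceMatrix(species, d, tau)


def _clean_weights(weights) -> np.ndarray:
    p = np.asarray(weights, dtype=float)
    if np.any(p < 0):
        raise ValueError("weights must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return p


def hill_taxonomic(weights, q: float = 1.0) -> float:
    """Hill number of order q on relative biomasses (q=1: exp Shannon)."""
    p = _clean_weights(weights)
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_functional(weights, distances: DistanceMatrix, q: float = 1.0) -> float:
    """Functional Hill number FD_q under the distance threshold tau.

    Distances are truncated at tau and rescaled, f(d) = min(d, tau)/tau, so
    species at distance >= tau are fully distinct and identical species
    (d = 0) pool their abundances.  FD1 is the effective number of equally
    distinct species; FD1 = 1 when all species are functionally identical
    and FD1 = TD1 when all pairs are at least tau apart.
    """
    p = _clean_weights(weights)
    d = distances.d
    tau = distances.tau
    if tau <= 0:
        raise ValueError("tau must be positive")
    if d.shape[0] != len(p):
        raise ValueError("weights and distance matrix sizes differ")
    keep = p > 0
    p = p[keep]
    d = d[np.ix_(keep, keep)]
    sim = 1.0 - np.minimum(d, tau) / tau
    v = sim @ p  # effective abundance seen from each species
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(v))))
    return float(np.sum(p * v ** (q - 1)) ** (1.0 / (1.0 - q)))


def trait_redundancy(td1: float, fd1: float) -> float:
    """FR1 = 1 - FD1/TD1: the share of effective species that is redundant."""
    if fd1 > td1 * (1 + 1e-12):
        raise ValueError("FD1 cannot exceed TD1")
    return 1.0 - fd1 / td1


def distinctiveness(distances: DistanceMatrix, literal_sum: bool = False) -> np.ndarray:
    """Per-species trait distinctiveness D_i.

    By default the mean trait distance of species i to the other S-1 species
    (the rarity-framework convention, comparable across pools of different
    richness); ``literal_sum=True`` returns the plain row sum instead.
    Global distinctiveness uses the full-pool matrix; local distinctiveness
    is obtained by passing ``distances.subset(community_species)``.
    """
    n = distances.d.shape[0]
    if n < 2:
        raise ValueError("distinctiveness undefined for a single species")
    row = distances.d.sum(axis=1)
    return row if literal_sum else row / (n - 1)


def n_distinct_residual(
    communities: dict[str, list],
    global_d: pd.Series,
    quantile: float = 0.25,
) -> pd.Series:
    """Richness-residualized count of functionally distinct species per site.

    Species in the top ``quantile`` of global distinctiveness are flagged as
    functionally distinct (ties at the threshold all included).  Their count
    per site is regressed on site species richness; the residuals remove the
    mechanical richness effect and are the facet entering the path model.
    """
    if len(communities) < 3:
        raise ValueError("need at least 3 sites for the richness regression")
    cutoff = float(np.quantile(global_d.to_numpy(), 1.0 - quantile))
    distinct = set(global_d.index[global_d >= cutoff])
    sites = list(communities)
    richness = np.array([len(communities[s]) for s in sites], dtype=float)
    counts = np.array(
        [sum(sp in distinct for sp in communities[s]) for s in sites], dtype=float
    )
    if richness.std() == 0:
        raise ValueError("richness has zero variance; regression undefined")
    fit = linregress(richness, counts)
    resid = counts - (fit.intercept + fit.slope * richness)
    return pd.Series(resid, index=sites, name="n_distinct_residual")


def relative_biomass_weights(matrix: pd.DataFrame) -> pd.Series:
    """Mean relative biomass of each species over the full year window."""
    mean_b = matrix.mean(axis=1)
    total = mean_b.sum()
    if total <= 0:
        raise ValueError("community has no biomass")
    return mean_b / total


def facet_table(
    matrices: dict[str, pd.DataFrame],
    traits: pd.DataFrame,
    quantile: float = 0.25,
) -> pd.DataFrame:
    """Per-site functional-diversity facets from biomass matrices and traits.

    Returns one row per site with CWMs, TD1, FD1, FR1, richness and the
    richness-residualized count of functionally distinct species.  The trait
    distance matrix, tau and global distinctiveness are computed once over
    the full species pool.
    """
    traits = traits.set_index("species_id") if "species_id" in traits else traits
    pool = trait_distances(traits.reset_index().rename(columns={"index": "species_id"}))
    global_d = pd.Series(distinctiveness(pool), index=pool.species, name="global_d")

    rows = []
    communities: dict[str, list] = {}
    for site_id, mat in matrices.items():
        w = relative_biomass_weights(mat)
        present = w[w > 0]
        sp = list(present.index)
        communities[site_id] = sp
        sub = pool.subset(sp)
        p = present.to_numpy()
        td1 = hill_taxonomic(p)
        fd1 = hill_functional(p, sub)
        row = {"site_id": site_id, "richness": len(sp), "td1": td1, "fd1": fd1,
               "fr1": trait_redundancy(td1, fd1)}
        row.update(cwm(traits.loc[sp], p))
        rows.append(row)

    out = pd.DataFrame(rows).set_index("site_id")
    out["n_distinct_residual"] = n_distinct_residual(communities, global_d, quantile)
    return out.reset_index()
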