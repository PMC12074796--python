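"""Temporal stability of community biomass and its multiplicative partition.

Community stability ``S_c`` is the inverse coefficient of variation of annual
total biomass.  It factors exactly into the biomass-weighted average species
stability ``1/CV_sp`` and a synchrony term::

    log S_c = log(1/CV_sp) - 1/2 * log(phi)

where ``phi`` is the Loreau & de Mazancourt community-wide synchrony index,
the ratio of the variance of total biomass to the squared sum of species-level
standard deviations.  ``CV_sp`` here is the biomass-weighted mean of species
coefficients of variation, ``sum_i (m_i/m_c) * (sd_i/m_i) = sum_i sd_i / m_c``,
which is the form under which the partition is an identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StabilityComponents",
    "community_stability",
    "average_species_stability",
    "synchrony",
    "decompose",
    "stability_table",
]


def _as_matrix(matrix) -> np.ndarray:
    """Coerce a species x year table to a 2-D float array."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("expected a species x year matrix")
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 years to measure stability")
    if np.any(arr < 0):
        raise ValueError("biomass must be non-negative")
    return arr


@dataclass
class StabilityComponents:
    """All pieces of the stability partition for one community.

    Attributes
    ----------
    s_c : community stability, mean/sd of annual total biomass (inf if the
        totals are constant).
    inv_cv_sp : biomass-weighted average species stability.
    phi : community-wide synchrony in [0, 1] (nan if every species is
        constant through time).
    asynchrony : 1 - phi, the variable entering the path model.
    log_s_c, log_inv_cv_sp, log_asynchrony_term : natural-log partition,
        with log_asynchrony_term = -0.5 * log(phi) so that
        log_s_c = log_inv_cv_sp + log_asynchrony_term.
    m_c : mean annual total biomass (g).
    species_means, species_sds : per-species annual-biomass moments.
    cov : species x species sample variance-covariance matrix of annual
        biomass.
    """

    s_c: float
    inv_cv_sp: float
    phi: float
    asynchrony: float
    log_s_c: float
    log_inv_cv_sp: float
    log_asynchrony_term: float
    m_c: float
    species_means: np.ndarray = field(repr=False)
    species_sds: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)


def community_stability(matrix) -> float:
    """Inverse CV of annual total community biomass (sample sd, ddof=1).

    Returns ``inf`` when the annual totals are exactly constant: a community
    that never fluctuates is infinitely stable, not an error.
    """
    arr = _as_matrix(matrix)
    totals = arr.sum(axis=0)
    sd = totals.std(ddof=1)
    m = totals.mean()
    if m <= 0:
        raise ValueError("total biomass must be positive")
    if sd == 0:
        return np.inf
    return m / sd


def average_species_stability(matrix, literal: bool = False) -> float:
    """Biomass-weighted average species stability, 1/CV_sp.

    The default is the reciprocal of the weighted mean species CV,
    ``1 / (sum_i sd_i / m_c)``, the form under which the log partition with
    synchrony holds exactly.  ``literal=True`` instead returns the weighted
    sum of species-level mean/sd ratios, ``sum_i (m_i/m_c) * (m_i/sd_i)``,
    kept for comparison; it does not satisfy the partition in general.

    Species with zero mean biomass are excluded (with a warning); a species
    with zero variance makes the literal form infinite but is harmless in
    the default form.
    """
    arr = _as_matrix(matrix)
    means = arr.mean(axis=1)
    if np.any(means == 0):
        warnings.warn("excluding species with zero mean biomass", stacklevel=2)
        arr = arr[means > 0]
        means = means[means > 0]
    if arr.shape[0] == 0:
        raise ValueError("no species with positive mean biomass")
    sds = arr.std(axis=1, ddof=1)
    m_c = means.sum()
    if literal:
        with np.errstate(divide="ignore"):
            return float(np.sum((means / m_c) * (means / sds)))
    total_sd = sds.sum()
    if total_sd == 0:
        return np.inf
    return float(m_c / total_sd)


def synchrony(matrix) -> float:
    """Loreau & de Mazancourt community-wide synchrony phi in [0, 1].

    phi = sum of all elements of the species variance-covariance matrix
    divided by the squared sum of species standard deviations.  phi = 1 is
    perfect synchrony (the community fluctuates like one species); the
    complement 1 - phi measures asynchrony / compensatory dynamics.

    Returns nan when every species is constant (undefined synchrony).
    """
    arr = _as_matrix(matrix)
    sds = arr.std(axis=1, ddof=1)
    denom = sds.sum() ** 2
    if denom == 0:
        return np.nan
    cov = np.cov(arr, ddof=1)
    return float(np.sum(cov) / denom)


def decompose(matrix) -> StabilityComponents:
    """Compute all stability components and their exact log-linear partition.

    Raises if the numerical identity log S_c = log(1/CV_sp) - 1/2 log(phi)
    fails beyond floating-point tolerance, which would indicate an internal
    inconsistency.
    """
    arr = _as_matrix(matrix)
    means = arr.mean(axis=1)
    sds = arr.std(axis=1, ddof=1)
    cov = np.atleast_2d(np.cov(arr, ddof=1))
    m_c = float(means.sum())

    s_c = community_stability(arr)
    inv_cv_sp = average_species_stability(arr)
    phi = synchrony(arr)

    log_s_c = float(np.log(s_c)) if np.isfinite(s_c) else np.inf
    log_inv = float(np.log(inv_cv_sp)) if np.isfinite(inv_cv_sp) else np.inf
    log_asyn = -0.5 * float(np.log(phi)) if phi > 0 else np.inf

    if np.isfinite(log_s_c) and np.isfinite(log_inv) and np.isfinite(log_asyn):
        resid = log_s_c - (log_inv + log_asyn)
        if abs(resid) > 1e-8:
            raise AssertionError(
                f"stability partition violated: residual {resid:.3e}"
            )

    return StabilityComponents(
        s_c=s_c,
        inv_cv_sp=inv_cv_sp,
        phi=phi,
        asynchrony=1.0 - phi if not np.isnan(phi) else np.nan,
        log_s_c=log_s_c,
        log_inv_cv_sp=log_inv,
        log_asynchrony_term=log_asyn,
        m_c=m_c,
        species_means=means,
        species_sds=sds,
        cov=cov,
    )


def stability_table(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Decompose every community and return a per-site table.

    Parameters
    ----------
    matrices : mapping site_id -> species x year biomass DataFrame.
    """
    rows = []
    for site_id, mat in matrices.items():
        c = decompose(mat.to_numpy() if isinstance(mat, pd.DataFrame) else mat)
        rows.append(
            {
                "site_id": site_id,
                "s_c": c.s_c,
                "inv_cv_sp": c.inv_cv_sp,
                "phi": c.phi,
                "asynchrony": c.asynchrony,
                "log_s_c": c.log_s_c,
                "log_inv_cv_sp": c.log_inv_cv_sp,
                "log_asynchrony_term": c.log_asynchrony_term,
                "m_c": c.m_c,
            }
        )
    return pd.DataFrame(rows)
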