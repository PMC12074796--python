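"""End-to-end analysis: synthetic surveys -> site table -> path model.

This wires the individual stages together the way the full study runs:
generate (or load) surveys, build interpolated biomass matrices, partition
stability, compute functional-diversity facets, summarize abiotic series,
select covariates per response, fit the piecewise SEM and accumulate
direct/indirect effects of the abiotic drivers on the stability components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dataprep, diversity, environment, sem, stability, synthetic

__all__ = ["AnalysisResult", "build_site_table", "fit_stability_sem", "run_full_analysis"]

#: facets considered as mediators in the path model
FACETS = (
    "fd1",
    "fr1",
    "cwm_trophic_level",
    "cwm_max_length",
    "cwm_growth_coeff",
    "cwm_max_depth",
    "n_distinct_residual",
)
STABILITY_COMPONENTS = ("log_inv_cv_sp", "asynchrony")
SINK = ("log_s_c", STABILITY_COMPONENTS)


@dataclass
class AnalysisResult:
    site_table: pd.DataFrame
    stability: pd.DataFrame
    facets: pd.DataFrame
    abiotic: pd.DataFrame
    selection: dict
    fit: sem.PathFit
    effects: pd.DataFrame
    truth: synthetic.TruthLedger | None = None
    matrices: dict = field(default_factory=dict, repr=False)


def build_site_table(
    matrices: dict,
    traits: pd.DataFrame,
    sites: list,
    quantile: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assemble the per-site modelling table from prepared matrices."""
    biomass = {sid: cm.biomass for sid, cm in matrices.items()}
    stab = stability.stability_table(biomass)
    facets = diversity.facet_table(biomass, traits, quantile=quantile)
    abiotic = environment.abiotic_summary(
        [s for s in sites if s.site_id in matrices]
    )
    table = (
        stab.merge(facets, on="site_id").merge(abiotic, on="site_id")
    )
    return table, stab, facets, abiotic


def fit_stability_sem(
    table: pd.DataFrame,
    selection_delta: float | None = None,
    facets=FACETS,
    abiotic=environment.DEFAULT_PREDICTORS,
) -> tuple[sem.PathFit, dict, pd.DataFrame]:
    """Covariate selection, piecewise fit and effect accumulation.

    Per response, candidate predictors are ranked by all-subsets AICc:
    abiotic drivers for each diversity facet, abiotic drivers plus facets
    for the two stability components.  Facets selected for neither stability
    component cannot mediate anything and are dropped from the graph.
    """
    abiotic = [a for a in abiotic if a in table.columns]
    facets = [f for f in facets if f in table.columns]
    selection: dict = {}
    for comp in STABILITY_COMPONENTS:
        selection[comp] = sem.select_covariates(
            comp, abiotic + facets, table, delta=selection_delta
        )
    kept_facets = [
        f for f in facets
        if any(f in selection[comp] for comp in STABILITY_COMPONENTS)
    ]
    # re-select the stability components over abiotic + retained facets only
    for comp in STABILITY_COMPONENTS:
        selection[comp] = sem.select_covariates(
            comp, abiotic + kept_facets, table, delta=selection_delta
        )
    for f in kept_facets:
        selection[f] = sem.select_covariates(f, abiotic, table, delta=selection_delta)

    edges = {resp: parents for resp, parents in selection.items() if parents}
    for comp in STABILITY_COMPONENTS:
        edges.setdefault(comp, ())
    # facets are mathematically and compositionally intertwined (e.g. FR1 is
    # defined from FD1 and TD1, CWMs share the biomass weights): their pairwise
    # correlations are modelled as free, not as testable independence claims
    facet_pairs = [
        (a, b) for i, a in enumerate(kept_facets) for b in kept_facets[i + 1:]
    ]
    spec = sem.PathModelSpec(
        edges=edges,
        correlated_errors=[STABILITY_COMPONENTS] + facet_pairs,
        sink=SINK,
    )
    fit = sem.fit_piecewise(spec, table)
    effects = sem.accumulate_effects(
        fit, drivers=abiotic, outcomes=list(STABILITY_COMPONENTS) + [SINK[0]]
    )
    return fit, selection, effects


def run_full_analysis(
    n_sites: int = 215,
    n_species: int = 655,
    seed: int = 0,
    site_config: synthetic.SiteConfig | None = None,
    survey_params: synthetic.SurveyParams | None = None,
    min_years: int = 7,
    quantile: float = 0.25,
    selection_delta: float | None = None,
) -> AnalysisResult:
    """Run the whole synthetic study at the requested scale."""
    traits = synthetic.generate_species_pool(n_species, seed)
    sites = synthetic.generate_sites(n_sites, seed + 1, site_config)
    surveys, truth = synthetic.simulate_surveys(traits, sites, survey_params, seed + 2)
    surveyed = {s.site_id: s.surveyed_years for s in sites}
    matrices = dataprep.prepare_communities(
        surveys, traits, min_years=min_years,
        surveyed_years={k: v for k, v in surveyed.items()
                        if k in set(surveys["site_id"])},
    )
    table, stab, facets, abiotic = build_site_table(matrices, traits, sites, quantile)
    fit, selection, effects = fit_stability_sem(table, selection_delta)
    return AnalysisResult(
        site_table=table, stability=stab, facets=facets, abiotic=abiotic,
        selection=selection, fit=fit, effects=effects, truth=truth,
        matrices=matrices,
    )
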