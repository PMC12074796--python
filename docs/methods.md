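# Methods

This note documents the quantitative model implemented by `reefstab`: the
definitions each module computes, the generative model behind the synthetic
data, every tunable parameter with its default and rationale, the numerical
conventions, and the known limitations.

## 1. Stability partition

For a site with species-by-year biomass matrix `B` (rows = species, columns =
years), with annual totals `T_t = Σ_i B_it`:

- **Community stability** `S_c = mean(T) / sd(T)` — the inverse coefficient
  of variation of total biomass.
- **Average species stability** `1/CV_sp = mean(T) / Σ_i sd_i` — total mean
  biomass over the summed species standard deviations. This biomass-weighted
  form is used because it makes the partition below an exact identity; the
  alternative weighted sum of per-species `m_i/sd_i` ratios does not, and is
  available behind `average_species_stability(..., literal=True)` for
  comparison.
- **Synchrony** `φ = Σ_ij cov(B_i, B_j) / (Σ_i sd_i)²` — the variance ratio
  of Loreau & de Mazancourt, bounded in [0, 1]; **asynchrony** is `1 − φ`.

These satisfy, exactly and for every positive matrix,

```
log S_c = log(1/CV_sp) − ½ log φ
```

All standard deviations and covariances use the sample convention
(`ddof = 1`). `decompose` asserts the identity to 1e-8 internally; the test
suite verifies it to 1e-10 over 1000 random matrices, along with covariance
conservation (`Σ_ij cov_ij = var(T)`).

Degenerate inputs are reported, not silently patched: constant totals give
infinite `S_c`; an all-constant matrix gives undefined (`nan`) synchrony;
zero-mean species are excluded from the literal species-stability form with
a warning.

## 2. Functional diversity

Four traits describe each species: maximum length, growth coefficient,
trophic level and maximum depth. Maximum length and maximum depth are
log-transformed (they are right-skewed, ratio-scale quantities); all four
are then z-scored across the species pool, and pairwise species distances
are Euclidean in that standardized space.

With relative biomass weights `p_i` over a site's species:

- **TD₁** `= exp(−Σ p_i ln p_i)` — the exponential of Shannon entropy,
  the effective number of species.
- **FD₁** `= exp(−Σ_i p_i ln(Σ_j s_ij p_j))` with similarity
  `s_ij = 1 − min(d_ij, τ)/τ` and threshold `τ` set to the mean
  off-diagonal distance of the pool — the attribute-diversity Hill number
  of order 1: the effective number of functionally distinct groups.
- **Trait redundancy** `FR₁ = 1 − FD₁/TD₁`.

Boundary laws: identical species give `FD₁ = 1`; species all at distance
≥ τ give `FD₁ = TD₁`; always `1 ≤ FD₁ ≤ TD₁ ≤ S`. The tests verify these
and agreement with a literal-summation implementation to 1e-12.

**Distinctiveness** `D_i` is the mean trait distance of species `i` to the
other `S − 1` species (the mean convention removes the mechanical richness
dependence of a raw sum; the sum is available via `literal_sum=True`).
The site-level facet `n_distinct_residual` counts species in the global top
quartile of distinctiveness present at the site, then takes the residual of
that count regressed on site richness, so it measures distinct species
*beyond* what richness alone predicts.

Community-weighted mean (CWM) traits are biomass-weighted averages of the
raw (untransformed) trait values.

## 3. Data preparation

Raw survey rows are `(site, year, transect, block, species, size_class,
abundance)` counts. The chain:

1. **Block aggregation** — abundances are summed over the two blocks of each
   transect. Duplicate keys are malformed input and raise.
2. **Biomass conversion** — weight per record is `lw_a · L^lw_b · abundance`
   at the size-class midpoint `L`; size classes are summed within a transect
   and species totals are averaged over **all** transects surveyed in the
   site-year (a transect without the species contributes zero). Species
   lacking length-weight coefficients are named in the error.
3. **Zero replacement** — within each site, a recorded zero for a locally
   present species is treated as below detection and replaced by half that
   species' minimum positive biomass at the site. An all-zero series
   violates the "locally present" premise and raises.
4. **Gap filling** — unsurveyed years inside the 2008–2021 window are
   filled by linear interpolation against calendar year; years before the
   first (after the last) survey are held at the nearest surveyed value.
   Observed cells are never altered.
5. **Site filter** — sites surveyed in at least 7 of the 14 window years
   are retained (inclusive threshold).

Every cell carries a provenance flag (`observed`, `zero_imputed`,
`interpolated`, `edge_extrapolated`). `degrade_and_correlate` quantifies the
cost of gap filling: starting from fully surveyed matrices it drops `n`
random years per site, re-interpolates, and correlates the resulting
community stabilities with the raw ones across sites. The correlation is 1
at `n = 0` by construction and decays as `n` grows.

## 4. Environmental summaries

Per site: mean SST over the window; SST trend as the least-squares slope of
annual SST on year (requires ≥ 3 years); interannual variability of SST and
chlorophyll-a as coefficients of variation (`sd/mean`, `ddof = 1`, positive
mean required); human gravity (population pressure / travel-time measure,
log-scaled in the generator); site depth; and the number of surveyed years,
carried as a nuisance covariate for the path model.

## 5. Piecewise structural equation model

Each response in the causal graph is fit by its own OLS regression on
z-standardized variables, so coefficients are standardized effects.

- **Covariate selection** (`select_covariates`): all subsets of the
  candidate set are ranked by AICc with `k = (number of slopes) + 2`
  (slope count plus intercept and residual variance). Either the single
  best subset or the union of subsets within a ΔAICc threshold is
  returned. Perfect collinearity and `n ≤ candidates + 2` raise.
- **Goodness of fit**: Shipley's d-separation test. The basis set contains
  each pair of non-adjacent variables, conditioned on the union of both
  variables' parents; the independence claim is tested by the p-value of
  the "would-be" slope with the causally downstream variable as response.
  Excluded from the basis set: exogenous–exogenous pairs (their covariance
  is free), pairs declared as correlated errors, and any pair involving the
  deterministic community-stability sink. Fisher's
  `C = −2 Σ ln p_k` is referred to χ² with `2k` degrees of freedom.
- **Correlated errors**: the two stability components (species stability
  and asynchrony) and all pairs of retained diversity facets are declared
  correlated rather than causally ordered — the facets are mathematically
  linked (redundancy is a function of TD₁ and FD₁; CWMs share the same
  weights), so treating their residual associations as testable claims
  would reject any model.
- **Sink node**: `log S_c` is an exact linear function of its two
  components, so it is attached as a deterministic sink; its "effects"
  from any driver are the component effects combined through the identity.
- **Effect accumulation** (`accumulate_effects`): with `B` the matrix of
  direct standardized coefficients on a DAG, total effects are
  `Σ_{k≥1} B^k` (the series is finite because `B` is nilpotent);
  indirect = total − direct. The tests verify equality with brute-force
  enumeration of all simple paths to 1e-12.

## 6. Synthetic data generator

### Species pool (`generate_species_pool`)

Traits are driven by a latent body-size axis `z ~ N(0,1)`:
max length `= exp(log 30 + 0.7 z)` cm, trophic level
`= clip(3.2 + 0.45 z + 0.35 ε, 2, 4.6)`, growth coefficient
`= exp(log 0.35 − 0.4 z + 0.3 ε)` (larger fish grow slower), max depth
lognormal. Length-weight coefficients: `lw_a ≈ 0.01`, `lw_b ~ N(3, 0.08)`
— the standard allometric range for teleosts. The built-in trait
correlations matter because CWMs and FD must respond realistically to
compositional change.

### Sites (`generate_sites`, `SiteConfig`)

Defaults are chosen to emulate a temperate-to-tropical monitoring network:

| parameter | default | why |
|---|---|---|
| `window` | 2008–2021 | 14-year study window |
| `sst_span` | (13.9, 25.4) °C | temperate–tropical gradient of mean SST |
| `sst_trend_mean`, `sst_trend_sd` | 0.1, 0.05 °C/yr | modest warming with site scatter |
| `sst_noise_sd` | 0.35 °C | interannual SST variability |
| `chl_mean`, `chl_log_sd_range` | 0.4, (0.1, 0.5) | oligotrophic-to-mesotrophic chlorophyll with variable interannual CV |
| `gravity_log_mean/sd` | 0, 1.5 | human gravity spans orders of magnitude |
| `depth_mean`, `depth_log_sd` | 6.5 m, 0.4 | shallow transect depths |
| `gap_prob` | 0.33 | each year independently unsurveyed, giving ≈ 9 surveyed years of 14 on average |
| `min_years` | 7 | site inclusion threshold |

### Surveys (`simulate_surveys`, `SurveyParams`, `EffectSizes`)

Each species' latent annual abundance at a site is lognormal AR(1)
(`ar_rho = 0.5`, `base_sigma = 0.35`, mean log abundance 2.0 ± 0.8).
Site covariates act multiplicatively on the log-scale volatility via the
`EffectSizes` knobs (defaults in the 0.2–0.5 standardized band — large
enough to recover at realistic sample sizes, small enough not to be
trivial): gravity and SST trend raise species-level variability, trophic
level modulates both, gravity reduces high-trophic occupancy, mean SST
raises richness, and SST variability raises synchrony through a shared
environmental shock whose loading mixes two community-wide modes by trophic
level. Loadings are normalized so marginal species variance is unchanged —
synchrony is moved without mechanically moving species stability. Every
nonzero knob is written to the `TruthLedger`.

Observation: per site-year, 2–4 transects; species counts are Poisson
around the latent expectation, split binomially between two blocks and
multinomially over three adjacent size classes around the species'
characteristic size. With `observation_noise=False` counts are
deterministic roundings in the nearest size class, which makes the
data-preparation chain exactly invertible — the reconstruction test uses
this mode.

What the generator deliberately does **not** emulate: species interactions
(no competition or predation dynamics — covariance structure comes only
from shared environmental responses), immigration/colonization dynamics,
observer-specific bias, within-transect spatial structure, and trait
plasticity. It is a validation instrument for the estimation chain, not an
ecosystem model.

### Site-table generator (`simulate_site_table`)

For calibration studies that need *exact* standardized ground truth, a
linear-Gaussian SEM generator draws site-level variables directly from a
user-specified DAG of standardized coefficients. Residual variances are set
by covariance propagation so every variable has unit population variance
and the specified betas are the population standardized effects
(configurations implying ≥ 1 explained variance raise). This is the
generator used for parameter-recovery and Fisher's C type-I calibration
tests: the survey-level generator cannot place exact standardized betas on
derived quantities because finite-series estimation attenuates them.

## 7. Numerical conventions

- Sample moments everywhere: `ddof = 1`.
- All SEM variables are z-scored before fitting; coefficients are
  standardized effects.
- OLS is solved by `numpy.linalg.lstsq` with explicit rank checking;
  p-values from Student's t via `scipy.stats`. This keeps the all-subsets
  selection and 500-replicate calibration loops fast; `statsmodels` is used
  in the test suite as an independent oracle for coefficients, p-values
  and AIC.
- AICc uses `k = slopes + 2`.
- Hill numbers skip zero-weight species (the `p log p → 0` limit).
- Random streams are `numpy.random.default_rng` seeded explicitly; every
  public simulation function takes a `seed`.

## 8. Limitations

- The stability partition assumes positive biomass series; after the
  detection-limit rule this always holds, but the rule itself injects a
  floor value whose magnitude is site- and species-dependent.
- Linear interpolation of unsurveyed years smooths real interannual
  variability, biasing stability upward for heavily gap-filled sites;
  `degrade_and_correlate` measures exactly this distortion and should be
  reported alongside any analysis with many filled years.
- The d-separation test treats each submodel as independently estimated;
  with deterministic or near-deterministic derived facets the basis set
  must exclude (or declare correlated) their pairs, as done by the
  pipeline, otherwise Fisher's C diverges for structural rather than
  causal reasons.
- AICc best-subset selection retains spurious covariates with
  non-negligible probability at moderate n (roughly one-in-seven per
  candidate); the ΔAICc-union option is more conservative about dropping
  true effects but keeps more noise.
- Effect accumulation assumes linearity throughout; standardized total
  effects are only interpretable on the z-scale of the fitted sample.
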