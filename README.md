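# reefstab

Temporal stability of reef-fish community biomass: how much of it comes from
the stability of individual populations versus their asynchrony, and how do
environmental variability, warming and human pressure shape each part?

`reefstab` implements the full analysis chain for long-term reef transect
monitoring data, together with a synthetic survey generator with known ground
truth so every step can be validated end to end:

1. **Synthetic data** (`reefstab.synthetic`) — species pools with correlated
   life-history traits, sites on a temperature/pressure gradient, and raw
   transect survey tables generated from a latent lognormal AR(1) community
   model. Every causal effect wired into the generator is recorded in a
   `TruthLedger`, so estimated effects can be compared against what was
   actually simulated.
2. **Data preparation** (`reefstab.dataprep`) — block aggregation,
   length-weight biomass conversion, transect averaging, detection-limit
   zero replacement (half the species' minimum positive biomass at the
   site), linear interpolation of unsurveyed years, and a ≥ 7-year site
   filter over the 2008–2021 window. Every cell carries a provenance flag.
3. **Stability partition** (`reefstab.stability`) — community stability
   `S_c = mu/sigma` of annual total biomass decomposed exactly into average
   species stability and community-wide synchrony:
   `log S_c = log(1/CV_sp) − ½ log φ`.
4. **Functional diversity** (`reefstab.diversity`) — order-1 taxonomic and
   functional Hill numbers, trait redundancy `FR₁ = 1 − FD₁/TD₁`,
   community-weighted mean traits, and richness-adjusted counts of
   functionally distinct species.
5. **Environment** (`reefstab.environment`) — site-level abiotic summaries:
   mean SST, SST trend, interannual SST/chlorophyll variability, human
   gravity, depth.
6. **Path model** (`reefstab.sem`) — piecewise structural equation models:
   per-response OLS on standardized data, AICc covariate selection,
   Shipley's d-separation test (Fisher's C), and exact accumulation of
   direct/indirect/total effects along the causal graph.

`reefstab.pipeline.run_full_analysis` strings all of this together from
generator to effect table.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite checks exact mathematical identities (the stability partition to
1e-10, Hill numbers against literal-summation oracles to 1e-12), hand-worked
micro-examples, data-preparation rule fixtures, parameter recovery and
Fisher's C calibration on synthetic data with known ground truth, and the
equivalence of matrix effect accumulation with brute-force path enumeration.

## Worked example

```python
import numpy as np
from reefstab import decompose
from reefstab.pipeline import run_full_analysis

# Two species observed over three years.
m = np.array([[1.0, 2.0, 3.0],
              [3.0, 1.0, 2.0]])
c = decompose(m)
print(f"community stability  S_c      = {c.s_c:.3f}")
print(f"species stability    1/CV_sp  = {c.inv_cv_sp:.3f}")
print(f"synchrony            phi      = {c.phi:.3f}")

# Full pipeline on a small synthetic archipelago.
result = run_full_analysis(n_sites=60, n_species=120, seed=4)
print(f"sites retained: {len(result.site_table)}")
print(f"Fisher's C = {result.fit.fisher_c:.2f} "
      f"(df = {result.fit.df}, p = {result.fit.p_value:.3f})")
print(result.effects.query("outcome == 'log_s_c'").round(3).to_string(index=False))
```

Output:

```
community stability  S_c      = 4.000
species stability    1/CV_sp  = 2.000
synchrony            phi      = 0.250
sites retained: 60
Fisher's C = 14.84 (df = 24, p = 0.925)
    driver outcome  direct  indirect  total
  mean_sst log_s_c     0.0    -0.248 -0.248
sst_change log_s_c     0.0     0.502  0.502
    cv_sst log_s_c     0.0    -0.796 -0.796
    cv_chl log_s_c     0.0     0.000  0.000
   gravity log_s_c     0.0    -0.581 -0.581
site_depth log_s_c     0.0     0.000  0.000
   n_years log_s_c     0.0    -0.258 -0.258
```

The two annual totals are (4, 3, 5): community stability is 4/1 = 4. Each
species has mean 2 and standard deviation 1, so 1/CV_sp = 4/2 = 2; since
S_c = (1/CV_sp) · φ^(−1/2), synchrony is φ = (2/4)² = ¼ and the partition
identity holds exactly. Community stability itself is a deterministic function of its
two components, so its `direct` effects are zero by construction and all
driver influence flows through species stability and asynchrony.

A command-line interface mirrors the library:

```bash
reefstab simulate --n-sites 60 --n-species 120 --seed 4 --out-dir runs/sim
reefstab prep --surveys runs/sim/surveys.csv --traits runs/sim/traits.csv \
    --sites runs/sim/sites.csv --out-dir runs/prep
reefstab stability --matrices runs/prep --out runs/stability.csv
reefstab full --n-sites 60 --n-species 120 --seed 4 --out-dir runs/full
```

## Documentation

See `docs/methods.md` for the generative model, parameter defaults and their
rationale, numerical conventions (ddof, standardization, AICc), and known
limitations.
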