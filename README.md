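# airdfc

Short-term air-pollution exposure and dynamic functional brain
connectivity: a simulation-backed, fully tested re-implementation of a
repeated-measures epidemiological analysis pipeline.

## Who this is for

Environmental-epidemiology and neuroimaging-statistics researchers who want
to study — or stress-test — the analysis chain that links weekly
traffic-related air-pollution exposure at the home or school address to
*dynamic* resting-state brain connectivity in a longitudinal cohort. Cohort
data of this kind are access-restricted, so the package ships a first-class
synthetic-data generator that emulates the statistical structure of such a
study end to end, with planted, recoverable parameters.

## What it computes

1. **Connectivity states and dwell times.** Per-session component time
   series (from group ICA, taken as given) are screened for motion
   (exclude if mean FD > 0.25 mm or > 20 % of volumes have FD > 0.2 mm),
   cut into tapered sliding windows (width 25 TR, taper = rectangle ⊛
   Gaussian(σ = 3 TR)), and each window is summarized by the Fisher-z
   vector of its weighted Pearson correlations. Pooled window vectors
   across all sessions and visits are clustered by multi-restart k-means
   into k = 5 reoccurring "states"; the per-session outcome is the **mean
   dwell time** per state — the average length (in windows) of maximal
   runs — Box-Cox transformed and standardized.

2. **Ratio-method exposure extrapolation.** Annual land-use-regression
   (LUR) means at each address are carried to single days by the ratio
   method: r(d) = mean over monitoring sites of (daily concentration /
   reference-period annual mean), and daily(address) = annual(address) ×
   r(d). Weekly pre-scan averages use the 7 days before each MRI visit,
   with surrogate substitution on days without monitoring data (NOx for
   PM2.5 absorbance, PM10 for PM2.5) and residence-time-weighted long-term
   childhood averages.

3. **Repeated-measures inference.** For each pollutant × state, a linear
   mixed model with a participant random intercept:

   `transformed dwell_ij = β·exposure_ij + γ'·covariates_ij + b_i + e_ij`

   fitted by REML over both visits, with nested covariate-adjustment sets,
   stochastic-regression multiple imputation pooled by Rubin's rules,
   stabilized inverse-probability-of-inclusion weights, VIF collinearity
   checks, and coefficients reported per fixed increments (10 μg/m³ NO₂,
   20 μg/m³ NOx, 5 μg/m³ PM2.5, 10 μg/m³ PM10, 5 μg/m³ PMcoarse, 10⁻⁵ m⁻¹
   PM2.5 absorbance). Multiplicity over the five dwell outcomes uses the
   eigenvalue-based effective number of tests
   m_eff = (Σ√λ)² / Σλ and the adjusted threshold 0.05 / m_eff ≈ 0.01.

## Worked example

```bash
python examples/05_association_grid.py
```

prints, for an 80-participant simulated cohort with a planted effect on
state-4 dwell time:

```
sessions kept after motion QC: 134 / 160
m_eff-adjusted significance threshold: 0.010 (0.05 before correction)
beta per reporting increment (rows: pollutant, columns: state):
state         1      2      3      4      5
exposure
NO2       0.163  0.020 -0.161  0.031  0.052
NOX       0.091  0.024 -0.321  0.119  0.013
...
```

Each cell is the change in Box-Cox-standardized mean dwell time per
reporting increment of weekly exposure; the adjusted threshold 0.010 is
what a five-outcome analysis must clear after accounting for the
correlation between dwell outcomes. The other examples
(`examples/01…04_*.py`) walk the generator, the windowing, the state
clustering and the ratio method individually.

A thin CLI mirrors the library for file-based runs:

```bash
airdfc run-all --config my_run.yaml --outdir out/
```

writing documented CSVs (`sessions.csv`, `exposure_records.csv`,
`dwell.csv`, `results.csv`, `multiplicity.json`) plus a JSON manifest per
stage.

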