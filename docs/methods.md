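# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of the `airdfc` package. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The measurement model

### Windowed connectivity and states

Component time series (rows = repetition times, columns = ICA components
grouped into named networks) are assumed already preprocessed; the package
starts at session QC. A session is excluded when mean framewise
displacement exceeds 0.25 mm or when more than 20 % of volumes exceed
0.2 mm; both thresholds are configurable (`QCSpec`) and both reasons are
logged when both fire.

Sliding windows are half-open `[start, start+width)` ranges of width 25 TR
(default) advanced by `step` TR. The taper is a width-25 rectangle
convolved with a Gaussian of sd 3 TR, truncated to the window and
normalized to sum 1 — the field-standard construction for tapered
sliding-window correlation. Within each window the package computes the
taper-weighted Pearson correlation of every component pair (weighted means
and covariances), clips to |r| ≤ 1 − 10⁻⁶, and stores z = atanh(r) for the
C(C−1)/2 upper-triangle edges. Clipping bounds the Fisher transform on
degenerate windows; with σ = 0 the weighted estimator reduces exactly to
the plain Pearson correlation of the slice (tested to 10⁻¹⁰).

States are identified by k-means (Euclidean distance on the z-vectors,
k = 5, best of `n_restarts` seeds by inertia) over windows pooled across
all sessions and visits. Centroids are canonically ordered by descending
occupancy, and replicate runs are aligned to a reference by an exact
Hungarian assignment maximizing summed centroid correlation. The
lineage of this method sometimes uses L1 distance and a two-stage exemplar
pass; plain multi-restart k-means with Euclidean distance is sufficient at
the scales this package targets, and the distance is the simplest
defensible default.

Mean dwell time per state is the average length, in windows, of maximal
runs of that state within a session. A state never visited in a session
has *missing* dwell (not zero): a mean run length over zero runs is
undefined, and observation-wise exclusion downstream is the cleaner
default (configurable to zero-fill). Dwell outcomes are right-skewed, so
each state's dwell is Box-Cox transformed (λ by profile maximum
likelihood, pooled across participants and visits — one transform per
outcome) and standardized. An additive shift is applied automatically only
if nonpositive values occur (dwell is ≥ 1 where defined, so normally no
shift).

### Ratio-method exposure

The monitoring panel provides daily concentrations at routine sites. For
each site and pollutant, the *annual* reference value is the arithmetic
mean over the reference measurement period (first panel year), requiring
75 % coverage. The daily ratio r(d) is the cross-site mean of
daily/annual; days on which the target pollutant has no data at any site
fall back to the surrogate's ratio (NOx for PM2.5 absorbance, PM10 for
PM2.5) and are flagged. Substitution happens at the *ratio* level because
ratios are the extrapolation currency. Daily address concentration is
annual(address) × r(d); the weekly exposure is the mean over the 7
calendar days strictly before the scan (configurable to include the scan
day, i.e. an 8-day window — the source description is ambiguous between
the two readings and strictly-before is the conservative one), requiring
5/7 resolvable days. Long-term childhood exposure time-weights annual
means over the residence history (90 % coverage required, overlap
rejected). The coverage thresholds (75 %, 5/7, 90 %) are package
decisions; they are exposed in the configuration.

### Mixed-model inference

For one pollutant, setting, state, and adjustment set, the model is a
Gaussian random-intercept LMM fitted by REML, CIs are Wald ±1.96·SE.
Unweighted fits use statsmodels MixedLM; when MixedLM fails (it raises on
boundary fits with singular random-effect covariance, which genuinely
occur for low-ICC dwell outcomes) or when observation weights are
supplied, an internal profiled-REML solver takes over. That solver
profiles β and σ² out of the restricted likelihood and optimizes the
single ratio θ = σ_b²/σ² with Sherman–Morrison group inverses, checking
the θ = 0 boundary explicitly; a boundary fit is reported as σ_b² = 0 with
a `singular` flag, and reduces exactly (10⁻⁶) to weighted OLS. Weights
enter as residual-precision observation weights (a pseudo-likelihood
treatment); at unit weights the solver matches MixedLM.

Imputation of missing covariates is stochastic regression (fitted
conditional mean + resampled Gaussian residual; logistic + Bernoulli for
binary), M completions pooled by Rubin's rules with Barnard–Rubin
small-sample degrees of freedom. Variables ≥ 35 % missing are rejected,
mirroring the covariate-selection rule of the emulated design. This is a
deliberately simple stand-in for chained equations that preserves the
interface and the pooling arithmetic. Attrition weighting is a stabilized
inverse-probability-of-inclusion weight from a logistic model, truncated
at the 1st/99th percentiles, with separation handled by probability
capping — again a simplified, clearly-labeled stand-in for
covariate-balancing propensity scores.

Multiplicity over the five dwell outcomes: eigenvalues λ of the pairwise
complete Pearson correlation matrix of the (transformed) outcomes,
negatives clipped at 0, m_eff = (Σ√λ)²/Σλ, adjusted α = 0.05/m_eff. This
interpolates between m (independent outcomes) and 1 (rank one). The
correlation matrix is computed on outcomes pooled across visits, matching
the single per-outcome transform. VIF uses 1/(1−R²) per covariate with a
strict < 10 pass rule and reports ∞ under exact collinearity.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed and recorded in every bundle manifest.

**Latent dynamics.** The connectivity process is a first-order Markov
chain over window-length epochs — one state label per epoch of
`epoch_len` = 25 TR — with symmetric default transitions (self-transition
0.9, so geometric dwell with mean 10 windows). This makes planted dwell
directly comparable to windowed estimates when windows align with epochs.
Exposure (and a shared socioeconomic factor, the confounding path) shifts
the log-odds of the target state's self-transition: a monotone, bounded,
single-parameter effect. Default effect size: 0.15 logit per 10 μg/m³ NOx
(centered at 40 μg/m³), acting on state 4, the non-modularized state.

**Templates.** Five archetypes on a component/network layout (test scale:
12 components in 4 networks; demo scale: 51 in 7): a drowsy
subcortical–sensorimotor state, two modularized states (sensorimotor +
default-mode; default-mode), a non-modularized state, and a partially
modularized state with sub-network sign splits. Block values (within
+0.65, between −0.28, archetype-specific cross-couplings, background sd
0.04) are projected to the nearest correlation matrix, so every template
is symmetric, unit-diagonal and PSD. The archetype-specific sign
structure keeps pairwise template z-vector correlations below 0.3 at test
scale — the separation regime in which five states are identifiable from
25-TR windows, and a deliberate idealization relative to real data.

**Monitoring world.** Daily site series = site offset × seasonal sinusoid
× exponentiated AR(1) noise (positivity by construction, as the ratio
method requires). Traffic pollutants (NOx, NO₂, PM2.5 absorbance) share
one latent daily factor and particulate-mass pollutants another, giving
within-group temporal correlations above 0.75. Annual address surfaces are
log-normal around field-realistic means (NOx 40, PM2.5 11.5 μg/m³ — the
range reported for Dutch urban cohorts) with a shared spatial factor and a
socioeconomic tilt (−8 % per SD of SES by default), the planted
exposure–confounder link. The address's daily concentration is *defined*
as annual × cross-site ratio, i.e. the extrapolation model is exactly true
in the synthetic world; the pipeline's weekly exposures therefore
reproduce the generator's to 10⁻¹⁰, isolating downstream error sources.

**Cohort.** 300 participants × 2 visits by default (the validation scale),
SES-linked covariate proxies (maternal IQ, income, age, BMI), seasonal
weather at scan dates, MCAR missingness on stable covariates (8–15 %),
log-normal FD traces under which the default QC rule excludes roughly
10 % of sessions, a
logistic inclusion model on SES for attrition, 30 % movers with two-address
residence histories, and school addresses sharing the exposure machinery
(PM2.5 absorbance at home only). One seed drives everything through
spawned substreams; regenerating from the manifest is byte-identical.

**What the generator does not emulate:** voxel-level fMRI, scanner
artifacts, spatial ICA mixing, real LUR estimation, autocorrelated
within-epoch BOLD dynamics, non-Markovian state processes, informative
(MNAR) missingness, and measurement error in covariates. Passing tests
therefore demonstrate that the *analysis chain* is correct and calibrated
under a faithful statistical emulation — not that the substantive findings
of any particular cohort generalize.

## Validation design and problem sizes

The planted effect is a logistic shift, so the *implied* linear slope of
transformed dwell on exposure is not a free parameter. The estimand for
coverage checks is defined by a sequence-level oracle: a 50 000-participant
cohort simulated without imaging, pushed through the same dwell /
transform / adjusted-regression path. The Box-Cox transform is frozen from
an auxiliary cohort so all replicates and the oracle share one transform
(a per-replicate refit would change the estimand per replicate).

Recovery replicates (100 with the effect, 100 null) use 300 participants ×
2 visits, 12 components, 60 windows of 25 TR per session with
non-overlapping windows aligned to epochs, complete covariates, and no
IPW; imputation and weighting are validated by their own dedicated tests.
Remaining calibration error in this design is dominated by per-window
assignment error (~0.2–0.5 %), which splits dwell runs and attenuates the
slope by a few percent of its standard error — visible as coverage a
shade below nominal but inside the acceptance band.

Monte-Carlo tolerances elsewhere follow the usual
3-standard-error convention at the stated replication counts.

## Known limitations

- The weighted-LMM treatment is pseudo-likelihood, not exact likelihood
  weighting; for strongly informative weights the SEs are approximate.
- Wald CIs can be slightly anti-conservative for small participant counts;
  the validation scale (≥ 300 participants) is where they are trusted.
- Imputation and IPW are simplified stand-ins (documented above), suitable
  for interface and calibration work, not for production missing-data
  analysis with categorical predictors.
- The dwell estimator inherits the known sensitivity of run-length
  statistics to label noise; with poorly separated states its attenuation
  grows quickly.
- `m_eff` uses pairwise-complete correlations, which can be slightly
  inconsistent under heavy missingness.
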