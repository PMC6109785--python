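# Methods

This note documents the models, estimators and design choices behind
`fcmech`, and what the synthetic cohorts do and do not emulate.

## Synthetic cohorts

Each subject's 4D series is a sum of network signals plus Gaussian noise:

```
y(v, t) = Σ_k c_k(subject, v) · w_k(v) · s_k(t) + ε(v, t),  ε ~ N(0, σ²)
```

* **Templates** `w_k`: isotropic Gaussian blobs (σ = max(1.2, min(grid)/7)
  voxels), peak weight exactly 1, centers placed by seeded rejection
  sampling so the >0.5 level sets of distinct networks are disjoint.
* **Time courses** `s_k`: white noise band-passed to 0.01–0.1 Hz (the
  resting-state band), zero mean, unit sd, drawn independently per subject
  and network.
* **Couplings**: `c_k = 1 + N(0, 0.05²)` per subject and network. Inside a
  planted scenario region (sphere of radius 2 voxels at the template peak,
  clipped to the template's half-max extent), MS subjects additionally get

  ```
  fc_effect + t2ll_slope·(T2LL − mean) + msss_slope·(MSSS − mean) + N(0, 0.1²)
  ```

  The covariate terms are **centered at the configured population means** so
  the planted group-mean shift equals `fc_effect` regardless of the slope
  signs; without centering, a positive-slope scenario (e.g. reduced FC with
  positive FC–MSSS association) would partially cancel its own group effect.
* **Defaults** (units: coupling is dimensionless signal amplitude):
  grid 20×20×12 voxels of 3.75×3.75×4 mm, T = 120 at TR = 2.5 s, 29 HC and
  62 MS (36 short / 26 long disease duration), noise σ = 0.4,
  `fc_effect` = ±0.6, `t2ll_slope` = ±0.025 per mL,
  `msss_slope` = ±0.25 per MSSS unit. With the cohort's covariate spreads
  these put the group, lesion-load and severity contributions on a common
  scale (each ~0.4 coupling units sd). σ = 0.4 corresponds to a core-voxel
  amplitude SNR of 2.5 before smoothing — a level typical of denoised,
  5-mm-smoothed resting data — and is the operating point at which dual
  regression resolves individual subject maps (spatial correlation ≳ 0.95
  with the planted templates). An `fc_effect` of ±0.6 changes coupling by
  60% without inverting the network signal; inverting effects are
  unphysiological for "reduced FC" and would also remove the affected
  voxels from the network's own spatial extent.
* **Covariates**: age, education and GM ratio are normal (clipped to sane
  ranges) with group means following the emulated cohort table; gender is
  Bernoulli at the observed proportions. T2LL is lognormal moment-matched to
  mean 16.63 / sd 22.23 mL and resampled above 80 mL (≈2% tail) — an
  uncapped heavy tail occasionally dominates desk-scale cohorts. MSSS is
  uniform on 0–6; disease duration uniform on (0.5, 5] / (5, 15] for the
  short/long subgroups. HC rows carry missing T2LL/MSSS/duration and are
  never imputed; only MS subjects enter the covariate stages.
* The default planted mechanism set is {1, 2, 3b, 4b}, one region per
  network; `all_scenario_effects` plants all six (needs ≥ 6 networks).

**What the generator does not emulate**: hemodynamic response shapes, head
motion, scanner drift, physiological noise, registration error, structured
artifacts, lesion geometry. Passing the closed-loop tests therefore shows
the *analysis chain* is correct and calibrated under its statistical
assumptions — not that it is robust to the artifact structure of real
scanner data.

## Preprocessing

The high-pass filter removes the discrete-cosine components with frequency
below 1/cutoff (including the mean), i.e. drifts are regressed out rather
than attenuated by a recursive filter; this is deterministic, phase-free and
idempotent. Smoothing converts FWHM (mm) to per-axis sigmas via the affine
(sheared affines are rejected) and uses reflective boundaries, which
preserve the spatial sum. Variance normalization (unit sample variance per
voxel) conditions only the ICA input; dual regression runs on the
filtered+smoothed data so PE maps retain amplitude information — normalizing
first would saturate high-SNR voxels and erase the covariate signal the
cascade measures.

## Group ICA and model order

Order selection maximizes Minka's Laplace approximation to the pPCA
evidence over the eigen-spectrum of the temporal covariance, voxels acting
as observations. Two practical points:

* Exactly low-rank input (zero residual variance) makes the evidence
  unbounded at the numerical rank, which is returned directly with a logged
  warning.
* The evidence assumes exchangeable observations; spatially smoothed voxels
  are not. The pipeline therefore estimates the order on a decimated voxel
  lattice (~one FWHM spacing) and a temporal subsample (≤150 rows), which
  restores the nominal behaviour (without decimation the estimator
  saturates at the candidate cap). The cap is 40 candidates by default.

Decomposition: randomized SVD whitens the concatenated data to the chosen
order; FastICA (fixed-point negentropy, symmetric decorrelation, tol 1e-6,
≤500 iterations, up to 5 seed-perturbed restarts) extracts spatially
independent maps, which are Z-scaled (zero mean, unit variance over the
mask), sign-fixed to positive skew, and deterministically ordered by peak
location. Components are labeled with a template's name when their best
absolute spatial correlation is ≥ 0.4 *and* ≥ 50% of their time-course
power lies in 0.01–0.1 Hz; each template is assigned at most once, greedily
by correlation (ties to the lower component index). The thresholds separate
the planted blobs from white-spectrum artifacts with a wide margin and are
configurable.

## Dual regression

Stage-1 time courses are scaled to unit sample variance before stage 2 (the
common convention), so stage-2 PE maps carry amplitude and shape; Z maps
divide each PE by its standard error and map the resulting t (T − q df) to
a standard normal deviate. Group statistics consume PE maps; the cascade's
per-subject summaries use Z maps.

## Permutation inference

The GLM engine precomputes the hat pieces once per design; each permutation
costs one matrix product. Nuisance handling follows Freedman–Lane:
residualize the data against the nuisance regressors, permute the residual
rows, add back the nuisance fit, refit the full model. When the regressor
of interest is a two-level indicator and the nuisance block is constant,
the distinct relabelings (`C(n, n1)`) are enumerated exhaustively whenever
they fit in `n_perm`, and p = (#maxima ≥ observed)/#relabelings with the
identity included — the exact-test convention. Sampled permutations use
p = (1 + #exceedances)/(1 + n_perm), so p ≥ 1/(n_perm+1).

TFCE uses E = 0.5, H = 2, 26-connectivity and dh = max/100 per map (the
standard parameterization). The implementation processes thresholds from
high to low with a union-find over voxels, accumulating each cluster's
`size^E · h^H · dh` contributions lazily through prefix sums — identical
to the brute-force threshold sweep (verified to machine precision in the
tests) but O(V α) instead of O(V · n_steps). Negative values are enhanced
on the negated map. One permutation pass records separate positive- and
negative-side maximum distributions, giving both one-sided contrasts
(MS<HC / MS>HC; covariate +/−) at once. The group contrasts are run as two
one-sided families (the conventional pair of contrasts); the covariate
stages of the cascade instead correct both signs as a single family (null =
image-wide max over either direction), so the union of positive and
negative discoveries is FWE-controlled at the nominal level. Voxelwise
`se = 0` (noiseless data) is guarded by a floor rather than an error so
degenerate unit-test inputs produce ±large t.

Per-component group inference is restricted to the component's own spatial
extent (|Z| ≥ 3 of the group map, also the ranking atlas): the analysis
asks how FC changes *within each network*, and whole-brain per-component
testing lets one network's regions bleed into another component's scenario
labels.

## gFC and ranking

`gFC = Σ |t|` over FWE-significant voxels inside the network extent — the
sum couples cluster extent (voxel count) and magnitude (|t|). The exact
functional form of the original index is not published with the method;
this definition satisfies the stated extent-and-magnitude property and is
exposed as a pluggable scoring hook. Ranking is by descending gFC within
contrast, ties alphabetical.

## Cascade and scenarios

Stage masks are strictly nested by construction: the T2LL analysis runs
only inside the FC-significant mask, the MSSS analysis only inside the
T2LL-significant mask. Covariate stages use MS subjects only (controls
carry no T2LL/MSSS), keep the demographic nuisance covariates by default
(switchable), and test both covariate signs. Per-subject mean Z over each
stage mask feeds Pearson correlations; Bonferroni's m is the number of
Pearson tests actually run, recorded in the output table.

Scenario semantics: "FC increases with the covariate" is the sign of the
voxel's covariate t statistic. Scenarios 1/2 are decided at the T2LL stage
(negative association); 3a/3b/4a/4b additionally require MSSS-stage
significance — a voxel with positive T2LL association but no MSSS decision
stays unlabeled. The 4a/4b naming has two circulating readings; the default
takes 4b = pre-symptomatic (reduced FC, positive FC–T2LL and FC–MSSS
associations, i.e. low FC co-occurring with low lesion load and low
severity), and `methods_convention=True` swaps the two labels. Per-network
label maps are merged first-come; with per-network analysis masks the
supports are disjoint in practice.

## Pipeline

A single master seed is fanned out to per-stage seeds through
`default_rng([seed, counter])`, so each stage is independently
reproducible. The file runner writes per-stage artifacts (NIfTI triplets
with JSON sidecars recording stage, contrast, n_perm and seed; TSV tables;
a structured log) and skips stages whose config hash matches an existing
completion marker; identical config + seed reproduces byte-identical
outputs.

## Problem sizes in the test suite

Tests run the generator's default study conditions (20×20×12 grid, T = 120,
91 subjects) with 500 permutations (the analysis default is 5000), 10 seeds
for scenario recovery, 20 for ranking, 50 for order selection, and 200
null cohorts of 12 subjects × 1000 voxels for the FWE calibration; exact
permutation checks use ≤ 9-subject instances where all relabelings are
enumerable. `scripts/acceptance.py` uses the same conditions with 60 null
cohorts and 20 order-selection seeds.

## Known limitations

* The mechanism classifier inherits all caveats of mass-univariate
  inference: labels are assigned per voxel at fixed FWE thresholds, so
  scenario support reflects power as much as biology; boundary voxels of a
  true region often carry the label just outside the planted mask (the
  smoothing halo).
* gFC values are comparable across networks within one analysis, not
  across analyses with different masks or permutation counts.
* The order estimator assumes near-isotropic residuals after decimation;
  strongly autocorrelated noise (not generated here) would bias it upward.
* RSN labeling is template matching; with real data the templates would be
  published atlas maps and the labels only as good as those templates.
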