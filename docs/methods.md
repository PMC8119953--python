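# Methods

This note documents the models implemented in cdomkit, the defaults and
why they were chosen, what the synthetic campaign generator does and does
not emulate, and the numerical decisions that affect results.

## CDOM absorption and spectral slopes

Decadal absorbance `A(λ)` measured over 220–750 nm in a cuvette of
pathlength `l` (meters; default 0.05 m) is converted to Napierian
absorption coefficients `a_CDOM(λ) = 2.303·A(λ)/l` (m⁻¹).  Replicate
scans are averaged after a robust screen: a scan is discarded when its
mean absolute deviation from the pointwise median spectrum over
250–500 nm exceeds five times the median of those deviations.  The rule
is scale-free, needs no instrument error model, and never discards
anything when scans agree.

Spectral slopes are obtained by unweighted nonlinear least squares on
absorption values,

    a_CDOM(λ) = a_CDOM(λ₀) · exp(−S(λ−λ₀)),

with λ₀ fixed at the window midpoint (285 nm for S275:295, 375 nm for
S350:400).  Fitting absorption directly — rather than regressing
log-absorption — weights the fit toward the larger short-wavelength
values, which is the conventional behavior of nonlinear slope-fitting
routines; a log-linear estimator is provided as a cross-check and agrees
exactly on pure exponentials.  No additive offset term is included: the
model assumes a fully exponential spectrum over the window, and values
≤ 0 inside a window abort the fit rather than being silently masked,
because masked negative tails bias slopes low exactly where CDOM is
scarce (high-salinity samples).  SUVA254 is `(A(254)/l)/DOC` in
L mg-C⁻¹ m⁻¹.

## EEM correction chain

Corrections apply in a fixed order — blank subtraction, inner-filter
correction, Raman normalization, scatter masking — enforced by an
append-only state tuple; any other order raises.  Rationale: the
inner-filter multiplier and the Raman area are both defined on
blank-subtracted signals, and masking last keeps the mask geometry
independent of intensity.

* **Inner-filter effect**: absorbance-based correction
  `F_corr(ex,em) = F_obs·10^{(A(ex)+A(em))/2}` with `A` per cm of the
  1-cm fluorescence cuvette.  Total absorbance above 1.5 flags the
  correction unreliable (the approximation degrades in optically thick
  samples) but still applies it.
* **Raman normalization**: the sample is divided by the trapezoidal
  integral of the blank emission scan at 350 nm excitation over
  371–428 nm — the community-standard Raman-unit calibration window.
  Because sample and blank share the instrument gain, normalization
  cancels gain exactly (tested with a simulated gain factor).
* **Scatter masking**: first/second-order Rayleigh (em = ex, 2·ex) and
  Raman bands (water OH-stretch shift of 3400 cm⁻¹) are set to missing
  within configurable half-widths (defaults ±10/±5/±10/±10 nm).  Masked
  cells stay missing — interpolation would fabricate data that the
  decomposition then treats as observed.  The physically meaningless
  region em ≤ ex + 5 nm is masked as missing by default: it cannot be
  reproduced by any trilinear component (outer products of nonnegative
  spectra are positive there), so leaving it observed — as zeros or as
  raw scatter — injects structured residual into every fit.  "zero" and
  "keep" remain available for comparison with toolchains that zero the
  wedge.

Negative intensities after blank subtraction are retained; clipping
before the decomposition would bias the noise distribution upward, and
the non-negativity constraint belongs to the model loadings, not the
data.

## Non-negative PARAFAC

The dataset tensor `X` (sample × emission × excitation) is modeled as

    X_ijk ≈ Σ_f a_if · b_jf · c_kf,   a, b, c ≥ 0.

Fitting is alternating least squares.  Each mode update solves exact
per-row non-negative least squares on the F×F normal equations (Cholesky
reduction to a small NNLS problem), so one sweep is three exact block
updates.  Missing cells are handled by expectation-maximization: they
are imputed from the running model at every sweep and the reported
residual sum of squares runs over observed cells only, which makes
masked cells provably inert (poisoning them changes nothing — this is a
test).  Convergence is declared when the relative change of the observed
RSS falls below `tol` (default 1e-8) or after `max_iter` (default 2500)
sweeps.

Multi-start strategy: `n_starts` (default 10) random nonnegative starts
plus one SVD-based start (absolute values of the leading singular
vectors of each unfolding) are each run with the full tolerance but a
capped sweep budget (400); the best final RSS is then refined to the
full budget.  This spends iterations on the basin that wins rather than
polishing every start, and is deterministic given the seed.

Indeterminacies are fixed by convention: spectral loadings are unit
Euclidean norm with all magnitude in the scores, and components are
ordered by descending emission-peak wavelength (ties by descending
excitation peak).  Two independent fits of the same data then agree
component-by-component without explicit alignment (tested at congruence
≥ 0.999).

**Validation** is split-half: samples are assigned round-robin to four
quarters (robust to manifests ordered by station or time), the three
quarter-pair combinations are refit independently, components are
matched across halves by maximal Tucker congruence (Hungarian
assignment on the product of emission and excitation congruences), and
the model validates only when every pair reproduces every component at
congruence ≥ 0.95 in both spectral modes.  Requiring all three pairs is
deliberately strict; it is what makes over-factored models fail.  Core
consistency is computed (least-squares Tucker core against the
superidentity) as an auxiliary diagnostic only — the validation gate is
split-half.

**Outlier screening** uses sample-mode leverages, the hat-matrix
diagonal of the score matrix; their sum equals the number of components.
The default flag threshold (0.2) is a conventional screening value, and
flagged samples are reported for refitting rather than silently dropped.

`select_n_components` fits each candidate F, split-half validates it,
and returns the largest validated F — or an explicit "no validated
model" result, which is the correct answer on noise.

## Component metrics

Fmax of component f in sample i is `score_if · max(b_f) · max(c_f)` —
with unit-norm loadings, the modeled peak intensity in Raman units.
Percent contribution divides a sample's Fmax vector by its sum
(rows sum to 100 by construction); percent change is
`100·(C_t − C_0)/C_0` against the day-0 baseline of the same bottle, so
replicate bottles produce independent change records that are averaged
only in the summary tables.

Change populations are screened per component × treatment with an
iterative two-sided Grubbs test at α = 0.05 (one removal per iteration,
recomputing the statistic after each), with a zero-variance guard and a
pass-through below n = 3.  The critical value uses the standard
t-distribution form.

## Decay kinetics

Photobleaching series (absorption at a wavelength, or component Fmax,
normalized to day 0) are fit with

    single: y = a·e^{−kt}
    double: y = a·(f₁e^{−k₁t} + (1−f₁)e^{−k₂t}),  k₁ ≥ k₂ ≥ 0, f₁ ∈ [0,1]

by bounded least squares; the double fit multi-starts over rate decades
and canonicalizes to fast-pool-first.  A double fit is *degenerate* when
the rates are separated less than threefold or either pool fraction is
below 0.1 — then the two pools are not physically distinguishable and
the fit is reported as reduced to the single model.

Model selection prefers the double model only when it is non-degenerate
and improves AIC by more than 4.  The small-sample AICc correction is
deliberately not used: with the six-timepoint photobleaching schedule
(days 0/1/3/7/14/24) the correction term for the four-parameter model is
degenerate (n−K−1 ≤ 0 counting the variance parameter), which would
forbid the double model at exactly the sample size where biexponential
photobleaching is observed.  Plain AIC with the Δ>4 threshold plus the
physical degeneracy guard discriminates mono- from bi-exponential truth
with ≥ 95% accuracy at 1% noise in the seeded simulation study that the
test suite runs.  Selection depends only on the RSS ratio, so it is
invariant to rescaling of y.  Time is measured in days by default;
cumulative UV exposure can be used as the abscissa by supplying it as
`t` — the fits are agnostic to the unit.

The wavelength of peak absolute absorption loss is the argmax of
`a_t0 − a_t` over a search window (default 250–450 nm), ties resolving
to the shortest wavelength, with an explicit "no loss" result when the
difference is nowhere positive.

## Synthetic campaign generator

The generator is the package's test bed: it produces campaigns whose
statistical structure matches what the analysis assumes, with full
ground truth.

* **Design**: ten stations spanning salinities 0.1–31.2 psu (three
  river-like, six plume, one ocean), treatments PB (UV photobleaching;
  days 0/1/3/7/14/24, duplicate bottles), dark microbial treatments
  MD0.2/MD0.7/MD3.0 (days 0/3/10/24) and a dark treatment of previously
  photoexposed water (PB3.0).
* **Fluorophores**: six components with Gaussian excitation and emission
  bells at canonical humic/protein peak positions (e.g., UV humic
  ex≈250/em≈432 nm; tyrosine-like ex≈270/em≈306 nm).  Peak positions
  are configuration, not literature assertions; the build fails with an
  identifiability error if any pair's combined spectral congruence
  reaches 0.9.
* **Kinetics**: under UV, humic scores decay (losing ~45–85% by day 24),
  the terrestrial-derivative component rises then falls
  (photoproduction then photooxidation), and the protein-like component
  rises ~+170% toward a saturating maximum.  Dark changes are a few
  percent — an order of magnitude smaller than UV changes — except for
  modest microbial production of the protein-like component.  The
  generator enforces this sign structure and fails loudly if a
  configured law violates it.
* **Absorbance**: exact single-exponential spectra (so slope recovery is
  analytic), with baseline slopes drawn from 0.0140–0.0251 nm⁻¹.  Under
  UV the amplitude decays biexponentially to ~38% by day 24 and the
  slope steepens by +0.0090 nm⁻¹, which places the peak absolute
  absorption loss in the 290–305 nm band for river-like baselines — the
  closed-form peak position is used as a test oracle.
* **Noise**: multiplicative relative error (default 0.5%, mimicking
  source/detector fluctuations) plus an additive floor (default
  1e-4 R.U., baseline noise), clipped at zero because fluorescence is
  physically nonnegative.  Station baseline scores are log-uniform over
  0.5–5 R.U., which creates the leverage spread that exercises outlier
  screening.  Absolute Fmax scales are free parameters of the generator.
* **DOC**: day-24 losses are drawn per treatment (means −12% to −20%,
  sd 5%) — concentrations are sampled, not mechanistically produced.

What the generator does **not** emulate: radiative transfer of the lamp
setup, microbial population dynamics, wavelength-dependent apparent
quantum yields, non-trilinear EEM structure (true fluorophores shift
with environment; ours are exactly trilinear), correlated instrument
drift, and inner-filter/scatter artifacts beyond what
`apply_instrument_effects` reintroduces for preprocessing tests.
Consequently, passing recovery tests demonstrate the correctness of the
algorithms under the stated noise model — not that six components or
these kinetics are identifiable in any particular field dataset.

## Problem sizes and determinism

The shipped test suite and the acceptance script run campaigns of 60
samples on the default grids (83 excitation × 151 emission points);
unit tests use coarser grids (~42 × 61) chosen so the full spectral
structure is retained while fits complete in seconds.  Every stochastic
step (generation, ALS starts, simulation studies) derives its stream
from one seed via hierarchical seed sequences, so campaigns, fits and
whole pipeline runs are bit-reproducible; the pipeline writes per-file
checksums into `run_manifest.json` to make that verifiable.

## Known limitations

* EM imputation of masked cells converges more slowly than direct
  weighted least squares when the masked fraction is very large; for
  EEM-typical masks (≤ ~55% of the grid) this is immaterial.
* The ALS objective is non-convex; multi-start with an SVD start makes
  the best-RSS solution stable in practice (tested), but global
  optimality is not guaranteed for any single start.
* Leverage screening flags influential samples but does not iterate
  removal-and-refit automatically; that loop is left to the analyst.
* The summary tables implement no between-treatment hypothesis tests;
  group cells are means ± sd only.
* Station classes use configurable salinity bounds (river < 1 psu,
  ocean ≥ 30 psu); datasets with brackish river endmembers need those
  bounds adjusted.
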