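# Methods

This note documents the models, the simulation that exercises them, the
numerical choices, and the limits of what the tests demonstrate.

## ALFF

For a voxel time series of length N sampled at TR = 2 s, the one-sided
power spectrum is `|X_k|^2 / N` with doubling of all bins except DC and
(even N) Nyquist, so that the one-sided power sums to `sum(ts^2)`
(Parseval). ALFF is the mean of the square root of power over the bins
with `low <= f <= high` (band edges inclusive), default 0.01–0.08 Hz; no
windowing is applied. Any fixed spectral convention would do — the
per-subject division by the global mean ALFF cancels it — but the
convention changes *unstandardized* values, so it is fixed and asserted by
a Parseval test. The global mean is taken over the brain mask only;
including out-of-brain zeros would deflate it.

A 170-point series at TR = 2 s has 24 usable bins in the band; series
shorter than ~1/(high·TR) points have none, and the computation refuses
them with the minimum length in the message.

## Preprocessing

Fixed stage order: discard first 10 volumes (motion trace truncated
synchronously) → 8 mm FWHM isotropic Gaussian smoothing (zero padding at
the grid edge; masked renormalization available but off) → voxelwise
linear detrend → nuisance regression (intercept + Friston-24 motion
expansion [R, R², R(t−1), R(t−1)²; lag row zero-filled] + mean WM and CSF
signals; rank-deficient designs drop dependent columns with a warning so
degenerate traces cannot crash a run) → ideal frequency-domain band-pass.
All temporal stages are linear, and the ideal filter makes
"band-pass then ALFF = ALFF of the unfiltered series over the same band"
an exact cross-module identity (tested at 1e−10).

Motion QC: subjects whose trace exceeds 3 mm translation or 3° rotation on
any axis are excluded. Framewise displacement is the sum of absolute
parameter differences with rotations scaled by a 50 mm sphere radius;
FD₁ = 0 and the mean runs over all retained frames. Mean FD enters the
group model as a covariate; no frame censoring is performed.

## Group inference

The design is intercept + diagnosis (ASD = +1, TC = −1) + two sum-to-zero
age columns + their products + mean-centered gender/FIQ/meanFD: 9 columns,
df_error = 119 at n = 128. Each effect is tested by the partial
(Type-III-style) F comparing the full model to the model without that
effect's columns; partial η² = SS_effect/(SS_effect + SSE). In balanced
designs without covariates this coincides with sequential SS (tested).
F maps are converted to one-tailed Z equivalents through the log-space
survival function (`ndtri_exp`), so arbitrarily large F stays finite.

**Smoothness.** Residual vectors are normalized to unit length per voxel
and the pooled variance of their spatial first differences measures
roughness. The raw formula `FWHM = sqrt(4 ln 2 / var)` treats a first
difference as an exact derivative and overestimates FWHM by 4–9 % for
discretely sampled smooth fields; by default the lag-one autocorrelation
implied by a Gaussian ACF is inverted instead
(`var = 2(1 − exp(−1/(4σ²)))`), the estimator used by the classic
smoothness tools, which recovers known kernels without bias (tested at
±15 %). Fields rougher than white noise fall back to the raw formula.

**Cluster correction.** With resel counts R₀..R₃ from Worsley's lattice
counting on the actual mask and the Euler-characteristic densities of a
unit Gaussian field, the expected cluster count is E[m] = Σ R_d ρ_d(u),
the expected suprathreshold volume E[N] = V·Φ̄(u), and the cluster-size
tail P(n ≥ k) = exp(−β k^{2/3}) with β = (Γ(5/2)·E[m]/E[N])^{2/3}. The
extent threshold k is the smallest integer with
1 − exp(−E[m]·P(n ≥ k)) ≤ α. Cluster-level corrected p values for
reported clusters use the same model. Connectivity is 6-neighbour faces by
default (18/26 available).

*Validity domain.* Monte-Carlo calibration on stationary smooth null
fields gives a family-wise cluster false-positive rate of ≈ 0.049 at
FWHM 4 voxels, ≈ 0.03 at 3–3.5 voxels and ≈ 0.026 at 2.5 voxels: below
roughly 3 voxels FWHM the lattice approximation degrades and the threshold
becomes conservative (never anti-conservative in our measurements). The
shipped calibration therefore runs at 4 voxels FWHM (~12 mm at 3 mm
voxels, the composite smoothness typical after 8 mm applied smoothing),
and analyses on rougher fields should read cluster p values as
conservative.

Post-hoc ROI comparisons are equal-variance two-sample t-tests per age
cohort, Bonferroni-gated at 0.05/3 (reported as 0.017), plus a pooled
ASD-vs-TC comparison at 0.05.

## Age trajectories

ROI value per subject is the mean standardized ALFF over the cluster's
voxels (mean rather than peak; peak is noisier and the choice is
documented rather than fitted). Ages are mean-centered before the
quadratic term is built (condition number), and coefficients are reported
in the raw-age basis. Significance is the overall model F on (2, n−3) df
against the intercept-only model — the stated question is whether the
model explains ALFF, not whether the quadratic coefficient alone does.

## Symptom prediction

Features are the standardized ALFF values at every voxel of the pooled
diagnosis-main-effect and interaction clusters, columns ordered by
(cluster label, lexicographic voxel coordinate). Only ASD subjects with
the target score enter. The regressor is ε-insensitive linear SVR with
C = 1, ε = 0.1 (library defaults of the era, fixed and configurable);
features are z-scored with training-fold statistics only (leakage-free; a
constructed counterexample test shows fold scaling and global scaling
disagree). The permutation p uses the strict inequality
`#(R_perm > R)/n_perm` exactly as defined; the `+1/(n+1)` variant is a
one-line change but not the default. Because the folds do not depend on
the target, per-fold standardized Grams are precomputed once and reused
across permutations; the hot loop calls the vendored libsvm solver
directly, which a test pins to the public `sklearn.svm.SVR` results at
1e−10.

Caveat carried over from the study design: the clusters that define the
features are selected on the same subjects the prediction is evaluated on,
so R measures in-study association strength, not out-of-sample accuracy.

## The synthetic cohort

Defaults are the study conditions: cells 18/20, 28/26, 18/18 (128
subjects), TR 2 s, 180 volumes, band 0.01–0.08 Hz, 24 × 28 × 24 grid at
3 mm (a desk-scale stand-in for a brain grid — voxelwise model cost is
linear in voxels, so grid size changes nothing inferential). Nominal age
distributions per cohort: child 9.4 ± 1.3 y, adolescent 14 ± 1.9 y, adult
25.4 ± 5 y, truncated to the cohort windows and to ±3 SD; FIQ ~ N(108,
14²); 90 % male.

Per subject, in-brain signal =
`baseline + g(v)·[bg(v,t) + Σ_r 1_r(v)·a₀·m_r·s_r(t)] + tissue confounds
+ drift + white noise`, where

* `bg` is spatially smooth (6 mm FWHM), temporally band-limited background
  activity with RMS 0.5 — the "resting-state" floor that keeps regional
  effects from being infinitely salient after smoothing;
* `g(v)` is a smooth (9 mm) subject-specific modulation field,
  SD 3 % — amplitude heterogeneity that survives spatial smoothing but is
  *uncoupled* to symptoms; it is deliberately kept below the coupled
  jitter so the planted brain–behaviour relation stays identifiable;
* `s_r` is a unit-RMS sum of 5 random in-band sinusoids, coherent across
  region r (closed-form relation between planted amplitude and ALFF, used
  by the oracle tests); a₀ = 0.8;
* `m_r = model_r(diagnosis, age)·(1 + jitter)`, jitter SD 15 %. Planted
  models: precuneus and MOG multiply TC 1.0 vs ASD 0.85 (a 15 % reduction,
  one jitter SD → diagnosis main effect at interior F ≈ 20 at n = 128,
  comparable to the Z ≈ 3–4 peaks and partial η² ≈ 0.1 such studies
  report); mPFC follows a TC quadratic
  `1 + 0.0035 (age − 22)²` (high in childhood, minimum in the twenties)
  against a flat ASD 1.3 — the cohort-weighted TC mean, so the region
  carries a diagnosis × age interaction (ASD lower than TC in childhood,
  higher in adolescence/adulthood) with no spurious diagnosis main
  effect, plus the TC-significant / ASD-flat trajectory pattern. The TC
  quadratic coefficients are free parameters of the simulation (the real
  ones are not published as numbers); they are sized so the interaction
  contrast clears the cluster-extent threshold with a ~2-standard-error
  margin over cohort-sampling variability.
* ADOS_SOCIAL = round(clip(−14.5 + 7.5·Σ_r m_r + N(0, 0.8²))) into 0–14,
  giving mean ≈ 8, SD ≈ 2 — magnitudes typical of the social subscale;
  communication and stereotyped scores are independent draws (no planted
  coupling), so prediction specificity is testable.
* Motion is a 6-parameter random walk (translation step 0.03 mm, rotation
  3×10⁻⁴ rad) giving mean FD ≈ 0.11 mm, in the range such cohorts report;
  WM/CSF confound series (temporally smoothed noise, RMS 1.5) leak at 0.3
  into gray matter and exist to give the nuisance regression real work.

A recruitment simulator wraps this core: 184 recruits = 128 matched + 49
age outliers (young children / older adults beyond ±3 SD of their cohort's
nominal mean) + 7 high-motion subjects (an injected 4–6 mm excursion).
Applying motion QC then the 3-SD matching rule reproduces the
184 − 7 − 49 = 128 bookkeeping deterministically.

**What the generator does not emulate:** hemodynamic response shapes,
cardiac/respiratory physiology, motion-correlated image artifacts,
multi-site effects, anatomical geometry. Passing tests therefore
demonstrate that the *statistical machinery* is correct and calibrated
under its assumptions — not that the pipeline is robust to every artifact
of real fMRI.

## Calibration and recovery (what the test suite measures)

* Null pipeline F values match F(df₁, df₂) by KS test on an i.i.d.-null
  configuration (no regions, no background field, no modulation, no tissue
  leak, 0 mm smoothing — KS requires independent voxels, which smoothed
  maps are not).
* The GRF extent threshold controls the family-wise cluster
  false-positive rate at 0.05 ± 0.02 over ≥ 500 simulated null fields
  (see validity domain above).
* Under default planted effects, across 10 seeds: the interaction cluster
  overlaps the planted mPFC mask (Dice > 0.5), diagnosis clusters cover
  the planted precuneus/MOG, the TC quadratic fit is significant while the
  ASD fit is not, and the social-subscale permutation p clears the
  Bonferroni gate while the uncoupled subscales do not — each in ≥ 8/10
  seeds (200 permutations per test in CI-scale runs; 1000 is the
  analysis-scale default).

## Known limitations

* Cluster p values are conservative for fields smoother-estimated below
  ~3 voxels FWHM (lattice limit of the analytic cluster-size tail).
* Global-mean standardization couples regions: strong regional effects
  shift the global mean by ~1–2 % and induce tiny opposite-signed
  pseudo-effects elsewhere (well below threshold here, but a real
  phenomenon in ALFF studies).
* The permutation test permutes scores i.i.d.; it does not preserve any
  age structure in the null (matching the stated procedure).
* `estimate_smoothness` assumes approximate stationarity; masks thinner
  than ~2 voxels in any axis are refused.
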