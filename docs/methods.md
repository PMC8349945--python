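# Methods

## Signal model and estimators

Each voxel follows the biexponential IVIM signal equation
S(b) = S0[(1−f)·exp(−bD) + f·exp(−b(D+D\*))] with S0 > 0, D ≥ 0,
0 ≤ f < 1 and D\* ≥ D. The simplified estimators use only b = 0, 50,
800 s/mm²:

* D′ is the log-slope between b = 50 and 800;
* f′ is the relative b-0 signal excess over the diffusion decay
  extrapolated back from b = 50 with rate D′;
* ADC is the log-slope between b = 0 and 800.

All three are exact algebra on the same three signals, which yields the
identity ADC = D′ − ln(1−f′)/800 on every voxel (used as a test
invariant at 10⁻¹² mm²/s on noiseless data). Internally everything is
kept in mm²/s and unitless fractions; the conventional 10⁻⁶/10⁻³
display scalings are applied only at I/O boundaries.

### Estimator bias under incomplete dephasing

If the perfusion compartment were fully dephased at b ≥ 50
(D\* → ∞), D′ = D and f′ = f exactly; the generator exposes this as the
`fully_dephased` forward mode, which is what makes exact-recovery and
distribution-matching tests possible. At finite D\* the residue
ε = exp(−50·D\*) raises S(50), and (neglecting the ≤ 3×10⁻⁴ remnant at
b = 800) one gets, with x = f·ε/(1−f):

    D′ = D + ln(1 + x)/750        (biased up)
    f′ = 1 − (1−f)(1+x)^(16/15)   (biased down)

So the perfusion residue inflates the apparent diffusion coefficient
but *deflates* the apparent perfusion fraction — both monotonically in
ε, vanishing as D\* grows. The test suite asserts exactly these
directions on noiseless biexponential phantoms.

### Validity policy

Voxels with a non-positive signal inside a logarithm are marked invalid
rather than floored: clamping would fabricate diffusion values. f′ is
deliberately not clipped to [0, 1] — raw estimates may be negative
under noise, and clipping would bias ROI means. Invalid-voxel counts
per map are logged as warnings. How noise-corrupted voxels should be
handled is genuinely open; the validity-mask policy is this package's
choice.

## Index maps and ROI scoring

Binarisation is strict: parameter < cutoff → 100 (red), otherwise
(including exact ties) → 0 (green). I_Df is the voxel-wise AND of the
red states of I_D and I_f, i.e. their minimum. Invalid voxels render
as plain grayscale in overlays, never as green — absence of an estimate
is not evidence of benignity. Overlays blend red/green at alpha = 0.4
over the b-800 slice windowed to its 1st–99th percentile; these display
conventions are package choices.

The ROI mean of an index map is the percent-red score (100 × red
fraction). Lesion calls:

* `Df_means`: malignant iff mean D′ < c_D AND mean f′ < c_f;
* `adc_mean`: malignant iff mean ADC < c_ADC;
* `index_pct` / `iadc_pct`: malignant iff percent-red exceeds the
  percentage cutoff (reference values 50.2 for I_Df, 53.4 for I_ADC);
  ties are benign, mirroring the strict voxel rule.

The human four-point visual judgment is replaced by a quantitative
red-dominance surrogate with default band edges 25/50/75; only the 50%
majority split is anchored in the source study, the outer edges are a
convention. The reference f′ cutoff is shipped as 114.5×10⁻³ (the
study's results table); its abstract once prints 114.4×10⁻³ — the
discrepancy is recorded here rather than silently resolved.

Masking replaces the study's visual criteria by mask arithmetic with
k = 2 SD thresholds by default: b-800 hyperintensity is signal above
mean + k·SD of a normal-liver reference region; the necrosis/cyst/scar
exclusion inside a ROI takes voxels above the ROI median + k·SD on b-0
or below the median − k·SD on b-800 (a median/MAD variant is
available). The k values are declared conventions, not published
numbers.

## Statistics

* ROC: empirical; AUC = normalised Mann–Whitney U (ties ½); 95% CI from
  the DeLong structural-components variance (Wald, clipped to [0, 1]).
* Youden cutoff: candidates are midpoints between consecutive sorted
  unique marker values plus ±∞, so cutoffs are independent of sample
  order. The maximisation runs on integer TP/TN counts (J·n₁·n₂), which
  avoids float ties at 1/n resolution. Ties on J break towards higher
  sensitivity, then towards the smaller cutoff — a deterministic rule
  chosen so that a separable sample and the worked examples give a
  unique answer. Reported accuracy uses the sample's class prevalences.
* DeLong comparisons: paired uses the placement covariance,
  var(AUC_a−AUC_b) = var_a + var_b − 2·cov; unpaired sums the
  single-marker variances; two-sided normal p. A marker compared with
  itself returns z = 0, p = 1.
* Group differences: Shapiro–Wilk gate at α = 0.05 per group; both
  normal → Welch t (unequal variances throughout); otherwise
  Mann–Whitney U, by full enumeration (midranks, two-sided
  p = min(1, 2·min(P≤, P≥))) when n₁+n₂ ≤ 12, else the normal
  approximation with tie and continuity correction. The choice of
  Shapiro–Wilk as the gate is a convention.
* ICC: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) by default (one-way ICC(1,1) and consistency ICC(3,1)
  available). Absolute agreement is the appropriate default when
  sessions/readers are interchangeable and systematic shifts should
  count as disagreement. The published per-lesion ratings are not
  available, so the printed reliability coefficients cannot be
  recomputed; the implementation is validated against an independent
  ANOVA mean-squares computation instead.

## Phantom generator

The generator reproduces the *statistics* of a liver-lesion DWI cohort,
not its anatomy: an abstract 64×64×16 grid (3 mm isotropic) of liver
parenchyma (D = 1.0×10⁻³ mm²/s, f = 0.10) holds non-overlapping
spherical/ellipsoidal lesions of radius ≥ 1.5 voxels (mirroring the
≥ 1 cm inclusion rule at 3 mm voxels). Lesion classes follow the study
cohort (HCC, CCC, colorectal and breast metastases, haemangioma, FNH,
at the 109-patient frequencies when drawn automatically). Per lesion,
one (D, f) pair is drawn from class distributions targeting the
published group statistics: all non-haemangioma classes
D = 1,076 ± 184×10⁻⁶ mm²/s, haemangioma 1,784 ± 314; all non-FNH
classes f = 63 ± 35×10⁻³, FNH 164 ± 58. Sampling uses truncated
normals at the physical bounds whose *truncated* mean is solved to
equal the target (a plain truncation would inflate the non-FNH f mean
by ≈ 3×10⁻³, i.e. many standard errors at n = 10⁴). D\* is uniform on
10–100×10⁻³ mm²/s (typical liver magnitudes; it is simulated but never
estimated), S0 = 1000 ± 100. Lesions are homogeneous apart from an
optional central necrosis/cyst/scar core (D = 3.0×10⁻³ mm²/s, f = 0,
S0 × 1.8 — bright on b-0, dark on b-800) used to exercise the exclusion
mask. Rician noise is applied per b-value volume as |S + g₁ + i·g₂|
with independent N(0, σ) channels; σ is a free parameter, since no
acquisition noise level is published.

What passing phantom tests shows — and what it does not: the pipeline
correctly inverts its own forward model, reproduces the published group
statistics by construction, and recovers cutoffs from finite cohorts.
It does not show robustness to motion, misalignment, partial-volume
effects, EPI distortion, or anatomy-dependent ROI placement, none of
which are simulated by default.

## Problem sizes and determinism

Tests use small grids (48³-ish scenes, 64³ for the identity check);
the cutoff-recovery experiment uses 21 independent 500-lesion cohorts
(one point estimate + 20 repetitions for the sampling SD) in the
fully-dephased noiseless regime, where ROI means equal the sampled
class values and the recovery target — the population Youden optimum of
the generating distributions (≈ 1,380×10⁻⁶ for D′, ≈ 109×10⁻³ for f′,
computed from the truncated-normal CDFs) — is well defined. Every
random draw flows from a single integer seed through
`numpy.random.default_rng`; identical configs produce byte-identical
CSV outputs.

## Known limitations

* No biexponential/segmented/Bayesian fitting and no D\* estimation —
  the simplified estimators are the point.
* The b = 250 s/mm² volume can be simulated and carried through I/O but
  is ignored by the estimators.
* Geometry is abstract; no anatomical liver atlas, coil model, or
  artifact simulation.
* Reliability (ICC) of the visual surrogate can be computed on
  synthetic repeats, but published reader ratings are unavailable for
  comparison.
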