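# Methods

## Perfusion model and deconvolution

Bolus-tracking perfusion imaging observes, per voxel, the convolution
of the arterial input function with the flow-scaled tissue residue:

C(t) = ∫₀ᵗ AIF(τ) h(t−τ) dτ,  h(t) = F·R(t),  R(0) = 1, R non-increasing.

`signal_to_concentration` uses a linear signal model: the concentration
is the signal minus the per-voxel mean over the pre-contrast baseline
frames. No T1-based conversion is attempted; with a linear model the
absolute scale of PBF/PBV depends on the (unknown) AIF calibration, so
absolute values are comparable within a subject and session but are not
calibrated across scanners. Defect thresholding is scale-invariant
(quantile-based), which is why the defect analysis is insensitive to
this choice.

`build_convolution_operator` discretizes the Volterra equation of the
first kind with trapezoidal product quadrature on a uniform frame grid:
L[i,j] = Δt·w·AIF(t_i − t_j) for j ≤ i, with w = 1/2 at the band ends
(j = 0, j = i) and 1 in the interior. This is second order in Δt; the
test suite verifies the ≈4× error reduction per halving of Δt against a
dense adaptive-quadrature oracle. Frame-time jitter up to 5% of the
mean interval is tolerated; beyond that the series is linearly
resampled to a uniform grid first.

`deconvolve_voxel` / `map_perfusion` solve C = L·h by truncated SVD:
singular values below λ·σ_max are discarded. λ = 0.15 by default — the
standard conditioning for bolus-tracking deconvolution at clinical SNR;
λ = 0 falls back to a numerical-rank pseudoinverse and recovers
noiseless simulations essentially exactly. The recovered h is clipped
at 0 (residues are physically nonnegative) before the readouts:

- PBF = 60·max(h) in mL/100mL/min (flow is carried in 1/s internally).
  The max — rather than h(0) — absorbs small bolus delays. A delay of
  δ attenuates PBF by at most exp(−δ/MTT): the data simply do not
  contain R on (0, δ). At Δt = 1 s this is <10% for MTT ≳ 9.5 s and
  ~15% at MTT = 6 s; the tests assert the attenuation bound explicitly.
- PBV = trapezoidal ∫h dt in mL/100mL. For a 60-frame, 1 s acquisition
  the trapezoid bias is ≈ Δt²/(12·MTT²) (≈2% at MTT = 2 s, the edge of
  the tested range) and the truncation loss exp(−T/MTT) is <1%.
- MTT = PBV/PBF (s), flagged undefined where PBF = 0. The central
  volume identity PBV = PBF·MTT/60 holds exactly by construction.

Units: maps are labeled per 100 mL of lung; per-100 g conventions
differ only by the assumed unit tissue density and are treated as
synonymous in metadata.

## CT map preparation

CT iodine (blood-volume surrogate) maps are denoised with an isotropic
3D Gaussian of sd 2 voxels by default, with nearest-neighbour boundary
handling so lung edges are not artificially darkened into pseudo-defects.
The sd can alternatively be given in mm (`sigma_in_mm`), converted per
axis through the voxel spacing. The cohort studies shipped in
`ctephperf.studies` smooth with a 2 mm physical kernel: the clinical
filter scale belongs to thin-slice (≈1 mm) CT, and applying 2 voxels on
the coarse 3 mm phantom grid would smooth 6 mm — disproportionate blur
that inflates boundary misclassification around the Q75-based
threshold. `harmonize` only *verifies* grid identity (shape equal,
spacing within 1e−3 mm); registration is out of scope and inputs must
be co-registered.

## Defect maps and percentages

The defect threshold is 0.7 × the 75th in-lung percentile of the map,
computed per subject, modality, session and parameter — never shared
across maps. The quantile uses linear interpolation between order
statistics (numpy's default, type-7); this matters only for degenerate
value distributions. A voxel is defect iff value < threshold (strict
inequality; configurable). Voxels with missing values inside the lung
are dropped from both numerator and denominator, and the percentile is
computed on the final mask. Lobar QDP is reported against the lobe
volume and, separately, against whole-lung volume; the latter satisfies
the exact partition identity (lobar values sum to the whole-lung QDP),
which the tests assert on every fixture.

## Agreement statistics

Overlap = 100·(both-defect + both-healthy)/ROI voxels; Dice is computed
per label and reported as missing (not 1) when both label sets are
empty, to avoid inflating agreement in degenerate lobes. Overlap and
the two Dice coefficients are linked by an exact identity (overlap
fraction equals the Dice-weighted mean label size over the ROI), used
as an internal consistency oracle. Pearson r carries the two-sided
t-distribution p-value on n−2 df; the paired pre/post test is a
two-sided paired t-test on post−pre (zero-variance differences are
flagged: t = 0, p = NaN); Bland–Altman limits are bias ± 1.96·sd of the
paired differences. p-values are reported unadjusted at α = 0.05, and
whole-lung overlap summaries are means of per-subject overlaps, not
pooled-voxel statistics. Cross-sectional analyses include one session
per subject; subjects with both phases contribute a seeded random
choice to avoid double counting.

## Synthetic cohort

The generator emulates the *structure* of a paired-modality CTEPH
cohort, not lung anatomy:

- **Geometry**: two analytic ellipsoids on a 64³ grid at 3 mm
  (desk-scale default), the right lung cut into three lobes and the
  left into two by oblique planes; semi-axes and cut positions are
  jittered per seed (lobe volumes vary by roughly ±10–20% around their
  means). Only label topology and volumes matter downstream.
- **Defects**: one contiguous cap per lobe, grown by physical distance
  from a peripheral seed voxel until the requested fraction is hit
  exactly (within one voxel of rounding) — contiguity makes overlap and
  Dice behave as with real wedge-shaped vascular defects. Pre-op
  per-lobe fractions are drawn from N(0.5, 0.1) clipped to [0.4, 0.7],
  placing the whole-lung defect burden near half the lung with
  realistic between-subject spread.
- **Perfusion**: healthy PBF 60 mL/100mL/min, MTT 4 s, PBV = PBF·MTT/60;
  defect voxels carry contrast ratio 0.3 of the healthy value — well
  below the 0.7·Q75 threshold, so planted and detected defects coincide
  in the noiseless limit.
- **AIF**: gamma-variate A·(t−t0)^α·exp(−(t−t0)/β) with α = 3,
  β = 1.5 s, peak-normalized, onset after 3 baseline frames; optional
  delayed recirculation. Frame interval 1 s (clinical range
  0.8–1.1 s), 60 frames.
- **Residue**: mono-exponential. The deconvolution is model-free, so
  any smooth decreasing R with R(0) = 1 exercises it; the exponential
  gives closed forms for the oracles.
- **Modality maps**: CT = PBV truth + i.i.d. Gaussian noise; MRI either
  a forward-simulated DCE series (same trapezoidal operator the
  inverse stage uses, plus Gaussian signal noise) or direct noisy maps.
  Noise sd is healthy-level (or peak-signal) divided by the SNR,
  default SNR 10; the two modalities use independently derived seeds.
- **Post-op scenario**: lower-lobe fractions drop by 0.20 (sd 0.05)
  absolute, RUL/RML by 0.04 (sd 0.03), and the left upper lobe receives
  a zero-mean perturbation (sd 0.05). The LUL term is deliberate: with
  the lobe exactly frozen, the paired test degenerates — microscopic
  systematic threshold shifts (the Q75 cutoff moves when whole-lung
  burden drops) become "significant" against near-zero variance,
  whereas the clinical picture is a non-significant change against
  real between-subject variability.

What passing tests on this phantom do **not** show: robustness to
motion, registration error, beam hardening, basal artifact exclusions,
cardiac-output dependence of iodine concentration, or anatomically
realistic defect shapes. Cross-modality correlations on the phantom
(r ≈ 0.99) exceed clinical values because both modalities share exact
defect truth and are perfectly co-registered; the cohort-level checks
are therefore qualitative (r above 0.7, overlap above 60%), not
reproductions of patient-study values.

## Numerical and design choices

- TSVD cutoff λ is relative to σ_max; λ = 0 uses a 1e−12 numerical-rank
  floor. Clipping h at zero precedes integration.
- The AIF may be supplied as a CSV curve or taken from simulation
  truth; automatic AIF ROI detection is not implemented.
- All-zero concentration deconvolves to h = 0 (PBF = PBV = 0) — a valid
  result; an all-zero AIF is an error (singular operator).
- Empty ROIs yield missing rows, never zeros; absent modalities produce
  no table rather than failing the run.
- Determinism: every stochastic stage takes a seed; derived seeds are
  drawn below 2³¹. Identical configs re-run bit-identically (asserted
  on the CSV outputs).
- Problem sizes in the shipped studies (64³ grids, 60 frames,
  19- and 12-subject cohorts, 200-curve banks) are chosen so the whole
  validation runs on a single CPU in well under an hour while keeping
  every statistic comfortably inside its asymptotic regime.

## Known limitations

- The linear signal model leaves PBF/PBV uncalibrated in absolute
  terms; only within-map (threshold-based) analyses are
  scale-invariant. The corresponding patient-study observation — defect
  percentages agree across modalities while absolute PBV/PBF values do
  not — cannot be probed on this phantom, whose modalities are
  consistent by construction.
- A 1-frame bolus delay attenuates PBF by exp(−Δt/MTT); no delay
  correction is applied.
- The phantom plants one defect per lobe; multifocal or subsegmental
  patterns, and the ad-hoc exclusion of basal/pericardial artifact
  regions, are not emulated (consumers may pass reduced masks).
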