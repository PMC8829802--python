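# Methods

## Scope and models

`perfconc` implements a perfusion-concordance analysis between ¹⁵O-water
PET and pCASL MRI, plus the synthetic-data machinery needed to validate
it. Everything volumetric lives on one common `VoxelGrid` per run
(default 64 × 64 × 48 at 2 mm isotropic — small enough for minute-scale
runs while keeping the voxel volume that makes a 10 mm sphere equal 65
voxels). There is no registration or resampling: synthetic data are born
aligned.

### Digital phantom

The brain is a set of concentric ellipsoids: a grey-matter shell
(normalized radius 0.75–1.0), a white-matter interior, and a small central
CSF ellipsoid (zero perfusion, excluded from the brain mask). Defaults:
GM 60 and WM 20 ml/100 g/min; M0 of 1.0 (GM), 0.7 (WM), 1.4 (CSF)
arbitrary units. Lesions are spheres that reduce the underlying tissue CBF
by a stated fraction; M0 is assigned from the pre-lesion tissue, since a
perfusion deficit does not change water content. The arterial transit time
is a seeded Gaussian-smoothed random field rescaled into `att_range`
(default 800–1800 ms — an elderly/clinical range that deliberately
straddles typical post-labeling delays). The geometry is synthetic, not
anatomical; the 13-region atlas (`build_synthetic_atlas`) is a
deterministic parcellation (posterior fifth = reference region, remainder
3 × 2 × 2 sectors) that borrows the roster of regions assessed in
frontotemporal-dementia studies purely as names.

### Dynamic PET

Each voxel obeys the one-tissue model dC/dt = k₁·Ca(t) − k₂·C with
k₁ = f/6000 s⁻¹ (f in ml/100 g/min) and k₂ = k₁/λ, λ = 0.9 ml/g. The
solver is an exponential integrator that is exact for a piecewise-linear
input function, evaluated on a 0.05 s grid once per unique perfusion value
and then averaged over each frame. Radioactive decay is not modeled
(simulated data stand for decay-corrected reconstructions). Noise, when
requested, is Gaussian with standard deviation noise_sd/√(frame duration),
mimicking count statistics without Poisson reconstruction modeling — the
noiseless path stays exact.

The input function is a gamma variate
a(t) = A·(t/t_p)^κ·exp(κ(1 − t/t_p)) (defaults: peak 30 kBq/ml at 30 s,
κ = 3). Real arterial curves carry a recirculation tail; its absence was
checked not to matter for any conclusion drawn here (see "known
limitations").

### PET quantification

`pmrflow_cbf` implements the phase-contrast-calibrated integral formula
(README). Unit bookkeeping: with f in ml/100 g/min, λ in ml/g and time
converted to minutes, the double-integral terms carry 1/(100λ). All
integrals are trapezoidal on frame-midpoint samples with an implicit
(0, 0) anchor, truncated at T (default 300 s; when T exceeds the last
midpoint, integration stops at the last midpoint). Voxels with a
non-positive denominator are flagged invalid and excluded from all
downstream statistics rather than clipped, to avoid biasing control-group
SD maps. The blood-volume signal contribution is deliberately not modeled
— the method is reproduced as defined, including its known tendency to
overestimate.

**Heterogeneity bias.** The calibration treats the whole-brain curve as if
it came from a single one-tissue system with flow f_wb. For a homogeneous
brain this is exact, and the package recovers truth to ~1e−6 relative
(pure quadrature). For a GM/WM mixture it is not: the denominator is short
by cov_w(f, ∫₀ᵀ∫₀ᵗC)/(λ·f̄) — a strictly positive covariance between flow
and the accumulated activity integral — so CBF is overestimated in *both*
tissues and the GM/WM contrast is inflated. On the default phantom
(59% GM, GM 60 / WM 20) the recovered means are ≈ 75 and ≈ 22, contrast
≈ 3.4 versus a true 3.0. This was verified with exact fine-grid integrals,
so it is a property of the formula, not of the quadrature. The error
grows with the integration time (≈ +3% in GM at T = 60 s, ≈ +26% at
T = 300 s). It is systematic per tissue and common to patients and
controls processed identically, so the single-case t statistics and all
concordance results are essentially unaffected; absolute PET CBF values on
mixed tissue should be read with this bias in mind.

### ASL signal model and quantification

`buxton_signal` is the single-compartment pCASL difference signal: zero
before the label arrives, saturating inflow for ATT ≤ t < ATT + LD,
exponential decay afterwards, with amplitude
2·α·(M0/λ)·(f/6000)·T1app·exp(−ATT/T1b) times the background-suppression
factor. The M0 argument is the *tissue* equilibrium magnetization; the
labeled magnetization is arterial, hence the division by λ — this is what
makes the consensus closed form (which carries λ in its numerator) the
exact algebraic inverse of the model, and it is why the noiseless
single-delay recovery test can demand near-machine precision wherever
ATT ≤ PLD. Constants (α = 0.85, T1b = 1650 ms, λ = 0.9 ml/g,
background-suppression factor 0.83 for two inversion pulses at ≈ 0.91
each) follow the ASL consensus recommendations and are config-overridable.
The apparent tissue T1 defaults to the blood T1 (`t1_tissue=None`); a
distinct tissue T1 may be supplied.

Single-delay acquisitions interleave control (= M0-proportional static
signal) and label (= control − ΔM at readout time LD + PLD) volumes,
16 pairs by default with LD/PLD = 1800/2000 ms. Time-encoded acquisitions
use the Sylvester Hadamard construction with the all-ones column dropped;
entry +1 means "labeled", so the first encoded volume labels every
sub-bolus, and decoding is ΔM_k = −(2/N)·Σᵢ E[i,k]·Vᵢ. The default scheme
is N = 8 with a 2000 ms free-lunch first sub-bolus, six 250 ms sub-boli
and a 200 ms final delay, giving effective PLDs 1700…200 ms; the long
first sub-bolus is included in the fit (it carries most of the perfusion
information; excluding it is possible by passing a trimmed
`PerfusionWeightedSet`).

`fit_te_cbf_att` exploits that the model is linear in f at fixed ATT: for
each candidate ATT the optimal amplitude is closed-form, so only a 1-D
profiled objective over ATT needs searching. A 20 ms grid over the ATT
bounds (default 200–2000 ms) is followed by six rounds of 9-point grid
zooming (no derivative assumptions — the objective has kinks where ATT
crosses a sub-bolus readout time). Ties in the objective are broken toward
the smallest ATT: once ATT exceeds every informative readout time a
one-point fit becomes scale-invariant and the objective is exactly flat,
so the estimate anchors at the identifiable edge rather than drifting.
Noiseless recovery is better than (0.01%, 0.1 ms) for ATT in 700–1700 ms;
above the longest effective PLD (1700 ms) ATT is structurally
unidentifiable and estimates saturate there, with f errors of a few
percent. Voxels with no signal get f = 0, ATT at the lower bound, and an
invalid flag.

Maps are smoothed (mask-renormalized separable Gaussian,
σ = FWHM/(2√(2 ln 2)); 6 mm for PET and 8 mm for ASL by default, applied
before any group statistics) and intensity-normalized so the brain mean
equals the phase-contrast whole-brain CBF; relative maps divide by a
reference-region mean (whole brain by default; any mask, e.g. the
occipital atlas region, may be used).

### Single-case statistics

Control maps are reduced voxelwise to a sample mean and sample SD (n − 1);
validity is the intersection of the inputs' masks, and voxels invalid in
any contributing map are excluded rather than imputed. The
Crawford–Howell statistic divides the patient's deviation by
sd·√((n+1)/n) with df = n − 1; thresholding is one-sided (hypoperfusion
only) at the upper-α t quantile. Cluster extent uses
floor((π/6)d³/voxel volume), clamped to ≥ 1 (anisotropic voxels use the
volume product); clusters of size exactly equal to the threshold are
retained ("at least the sphere's volume"). Connectivity defaults to the
26-neighborhood and is configurable (6/18/26). `type1_error_sim`
demonstrates the calibration: the empirical null rejection rate matches α
within Monte-Carlo error for control groups of 5–20, where a naive normal
threshold visibly inflates it.

### Concordance

The overlap partition computes overlap = test ∩ reference, groups the
remaining test voxels into connected components, and calls a component
adjacent if it touches any overlap voxel under the same connectivity,
isolated otherwise; the three counts are reported as percentages of the
test mask and sum to 100 exactly. ROI classification restricts clusters to
within each ROI (a straddling cluster contributes only its in-ROI voxels);
sensitivity/specificity treat the PET-derived classification as the
reference, and undefined proportions (no reference positives/negatives)
are returned as NaN with the caller deciding how to aggregate. Group ROI
comparisons default to Welch's unequal-variance two-sample test —
patients and controls are independent groups — with a paired mode
available for matched designs. `summarize_columns` reproduces
"mean ± SD" summary rows with per-column rounding (percentages to 1
decimal, Jaccard to 2).

### Pipeline and the noiseless-limit configuration

`run_pipeline` simulates every subject (per-subject seeds and biology all
derived from one master seed), quantifies all three modalities, smooths,
normalizes, runs the case-control chain per modality × {absolute,
relative}, and assembles concordance and ROI tables. Between-subject
biology is modeled as independent per-subject draws of GM and WM CBF
(60 ± 6 and 20 ± 2 ml/100 g/min); the cohort defaults to 13 controls and
8 patients, two per disease subtype, with subtype-flavoured lesion
placements (spheres of 8–10 mm radius, 50% CBF reduction) specified as
fractions of the grid extent.

`matched_noiseless_config` defines the noiseless limit used for exact
end-to-end checks: zero measurement noise, zero smoothing for all
modalities (unequal smoothing would blur lesion edges differently per
modality and voxel-identical masks could not be expected), and patients
pinned at the population-mean baseline so they differ from controls only
by their lesions. Controls keep their biological variability — without it
the control SD would vanish and the t statistic would be undefined. In
this configuration every modality's hypoperfusion mask equals the true
lesion voxel set, so ROI sensitivity/specificity are 1 and the overlap
partition is (100, 0, 0); adding ASL noise degrades the Jaccard index
monotonically.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the measurement chain —
kinetic signal formation, frame integration, encoding/decoding, cohort
statistics — with exactly known ground truth, which is what validating
the analysis code requires. It does not emulate scanner physics (k-space,
GRASE readouts, Poisson/OSEM reconstruction, attenuation), motion,
registration error, partial-volume effects at acquisition resolution,
arterial delay/dispersion of the PET bolus, or anatomy. Passing tests
therefore certify the correctness and calibration of the analysis, not
the clinical performance of either modality on real patients.

## Numerical choices

- PET ODE: exponential integrator, exact for piecewise-linear forcing;
  0.05 s fine grid; per-unique-f evaluation.
- Quantification integrals: trapezoid with (0, 0) anchor on frame
  midpoints; frame averages treated as midpoint samples (second-order
  accurate; sub-percent for the default schedule).
- TE fit: separable least squares; 20 ms coarse ATT grid + 6 zoom rounds;
  smallest-ATT tie-breaking; f clamped to ≥ 0; no-signal tolerance
  1e−9 × M0.
- Degenerate inputs raise (`ValueError`) rather than silently propagate:
  empty masks, non-positive denominators, mixed absolute/relative scales,
  mismatched grids (reported with both shapes).
- Determinism: all stochastic steps take explicit integer seeds; the
  pipeline derives per-subject seeds from its master seed, so identical
  configs reproduce outputs bit-for-bit.

## Known limitations

- The PET calibration's heterogeneity bias (above) is reproduced, not
  corrected; absolute PET CBF on mixed tissue is overestimated by design
  fidelity to the method.
- ATT above the longest effective PLD is unidentifiable for the default
  time-encoded scheme; estimates saturate at 1700 ms.
- The whole-brain TAC uses the unweighted voxel mean over the brain mask
  (volume weighting is equivalent here because voxels are equal-sized).
- Problem sizes used by the test suite (32³-scale phantoms, reduced
  cohorts for some end-to-end checks) were chosen to keep full validation
  runs at desk scale; all conclusions were also spot-checked at the
  default 64 × 64 × 48 grid with the full 13 + 8 cohort.
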