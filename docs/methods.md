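# Methods

## Scope and model

The package quantifies a simultaneous dynamic [11C]PiB PET/MRI protocol:
70-minute list-mode PET reconstructed into 38 frames
(12×5 s, 6×10 s, 3×20 s, 4×30 s, 5×60 s, 4×5 min, 4×10 min), of which the
first 21 frames (exactly 0–180 s) feed the kinetic analysis and the
50–70 min window feeds amyloid quantification. All activity values are
decay-corrected to injection time by construction; no physical decay is
simulated or corrected.

### Input function

The arterial input is image-derived. The duration-weighted average of the
frames whose mid-times fall in [10, 40) s localizes the arterial first
pass; the 30 most intense voxels inside a user-supplied search region form
the IDIF mask (the original protocol localizes the mask on the cavernous
internal carotid with co-registered MR angiography; vessel segmentation is
out of scope here, so the search region comes from the parcellation's
artery label or an explicit ROI). Intensity ties at the cutoff are broken
by lexicographic voxel index, which makes the selection deterministic and
invariant to value-preserving reorderings.

The per-frame mask mean, sampled at frame mid-times and truncated to
0–180 s, is the whole-blood curve. Two corrections follow:

* **Plasma fraction.** The unmetabolized fraction is fixed at 0.95 during
  the early frames; the plasma channel is 0.95 × whole blood. The source
  protocol does not separate plasma-to-whole-blood partitioning from
  metabolite correction, so the package likewise applies a single
  multiplicative factor, rebuilt on every construction so the invariant
  cannot drift.
* **Dispersion.** Peripheral dispersion is modeled as convolution with
  (1/τ)e^(−t/τ), τ = 4 s. The correction applies the exact first-order
  inverse C_true(t) = C_d(t) + τ·dC_d/dt with central differences
  (one-sided at the ends) and a floor at zero. On a dense 1 s grid the
  forward–inverse round trip errs < 1 % of peak; on the coarser
  frame-mid-time grid (5 s early frames) the residual error is a few
  percent at the peak but propagates to < 0.3 % error in regional CBF,
  because the weighted integrals average over the whole window. No
  tracer-arrival delay correction is applied: the input is read at the
  skull base from the same dynamic data as the tissue.

### Kinetics

Tissue follows the one-tissue compartment model
dC/dt = K1·Cp − k2·C (K1, k2 in 1/min). The production estimator is a
three-weighted-integral method with weights w = {1, t, t²} on the 0–180 s
window — the classic polynomial choice; the specific weights of the
original implementation are not published, so this variant is a declared
stand-in, and the third integral is used only as a consistency diagnostic.
Because the model is linear in K1, the ratio I2/I1 of weighted frame sums
depends on k2 alone; it is strictly monotone over the default 200-point
log-spaced grid (0.001–1.0 1/min; asserted at lookup construction) and is
inverted with a monotone PCHIP interpolant. K1 then follows from I1
against the unit-K1 basis integral. Ratios outside the lookup are clamped
to the grid edge and flagged; negative K1 estimates are floored at zero
and flagged. Fitting is fully vectorized (two dot products and two
interpolant evaluations per voxel), so whole-brain fits take milliseconds.

The forward model — and the phantom — use an exact exponential-integrator
propagation of the linear ODE assuming piecewise-linear input on a 0.25 s
grid, which is unconditionally stable and exact for piecewise-linear
inputs. Frame values are exact trapezoid averages of the dense curve over
each frame interval, matching how the scanner averages activity within a
frame. An independent nonlinear least-squares fit of the same model
(`fit_nlls`, scipy `least_squares`, bounds k ≥ 0) serves as the reference
estimator: noise-free weighted-integral K1 agrees with it to < 1 % over
K1 ∈ [0.1, 0.5], k2 ∈ [0.05, 0.3] 1/min.

CBF conversion uses the fixed first-pass extraction fraction E = 0.65:
K1 = E × CBF/100, i.e. CBF [mL/min/100 g] = 100·K1/E, assuming tissue
density 1 g/mL. A flow-dependent (Renkin–Crone) extraction and the
two-tissue model of specific PiB binding are out of scope; the one-tissue
approximation means late-phase amyloid binding can bias K1 in high-uptake
regions of real data, a limitation the phantom does not emulate.

### Amyloid uptake

SUV = activity / (injected dose per gram body weight); with activity in
kBq/mL and density 1 g/mL, a voxel at the injected dose per gram maps to
SUV = 1. SUVr divides by the mean SUV over the cerebellar cortical
reference (both hemisphere labels by default), making it invariant to
global rescaling — dose and weight cancel. The "cortical SUVr mean" is the
unweighted mean over the four lobar regions per hemisphere, then averaged
across hemispheres; this averaging is not prescribed by the protocol and
is configurable. The cortical SUVr ratio divides that mean by the
white-matter SUVr, contrasting specific cortical binding against the
myelin-bound component, which is stable across groups. Visual scoring
(0–3) is a human rating; the package stores scores and computes Pearson
correlations (two-sided p) of MMSE against cortical SUVr, visual score and
SUVr ratio, dropping incomplete subjects pairwise and flagging
zero-variance pairs. Correlations are reported as signed r.

### fALFF

Preprocessing discards the first 10 volumes (201 → 191 at TR 2.3 s),
removes the per-voxel linear trend, and optionally residualizes against
user-supplied nuisance regressors by OLS (an intercept is always included;
rank-deficient designs are rejected). Slice timing, realignment, spatial
normalization, smoothing and motion-parameter regression belong to
scanner/SPM tooling and are not re-implemented; the regressor hook is the
integration point. The amplitude spectrum is the square root of the
windowless one-sided periodogram. ALFF sums amplitudes over
0.01 ≤ f ≤ 0.08 Hz (band edges inclusive, for determinism); fALFF divides
by the amplitude sum over all positive-frequency bins, so fALFF ∈ [0, 1]
and is invariant to series scaling. "Sum of amplitudes" (not mean) is
implemented as stated by the protocol; the choice affects ALFF's scale
only. Zero-variance voxels get fALFF = 0. Subject maps are standardized to
z within a mask (ddof = 1).

Finite windows leak: an off-bin sinusoid spreads amplitude outside the
band, so e.g. a 0.05 Hz sinusoid at TR 2.3 s over 191 volumes has fALFF
≈ 0.93, not 1. The pure-sinusoid ≈ 1 limit holds for window-periodic
(bin-aligned) frequencies, which the BOLD generator therefore uses by
default.

### Group statistics

Regional values are unweighted label means over the parcellation. Group
comparison per region uses Welch's t (the protocol names only a "t test";
unequal variances are the safer default given the patient group's larger
spread), flagged at p < 0.05, plus a mixed ANOVA (region within, group
between; pingouin) per quantity. The VSRAD-style atrophy score is
(control mean − individual)/(control SD) — positive for values below the
normative mean — referenced to an emulated external normal database, as
VSRAD references a normative cohort rather than the study controls.

Voxelwise inference stacks per-subject z-maps and computes a
pooled-variance two-sample t (df = n_A + n_B − 2). The height threshold is
the t-value whose upper-tail p equals 0.005, one-sided by default
(decreases only, matching the reported contrasts; two-sided optional).
Suprathreshold voxels are decomposed into 18-connectivity components
(the SPM convention) and components smaller than 50 voxels are discarded.
Cluster-level p-values come from permutation of group labels (default
1000 permutations) against the null distribution of the maximum cluster
size — the original analysis ran inside SPM with an ambiguous correction,
so permutation was chosen as the explicit, assumption-light alternative.
Under null simulation the suprathreshold voxel fraction is calibrated to
0.005 within binomial error.

## Phantom and cohort

The phantom is a deterministic block geometry (default 20³ voxels of
4 mm): a cerebellar slab (split by hemisphere) with a 3×3×4-voxel artery
blob at its base, and a supratentorial compartment with a central
white-matter core wrapped by a cortical shell divided into four lobes per
hemisphere. It is deliberately schematic — no realistic anatomy, scanner
PSF, attenuation, partial-volume effects or motion — so passing tests
demonstrate the correctness of the estimators, not robustness to those
real-data effects.

The arterial bolus is a gamma variate A·u^α·e^(α(1−u)),
u = (t − t₀)/(t_p − t₀), defaults α = 3, onset 5 s, peak 80 kBq/mL at
25 s — a plausible first-pass shape for a 700–750 MBq injection. The
*undispersed* plasma curve (0.95 × bolus) drives the tissue model; the
*dispersed* whole-blood curve fills the artery voxels, so the IDIF →
dispersion-correction → plasma chain must invert the generative process to
recover CBF. Regional CBF defaults are the study groups' printed regional
means (e.g. control right frontal 41.6, patient right parietal
37.8 mL/min/100 g); K1 = 0.65 × CBF/100 exactly, everywhere. Efflux rates
are not reported for the early phase; defaults are 0.10 1/min (cortex),
0.12 (cerebellum), 0.05 (white matter), within the plausible
0.05–0.20 1/min range. White-matter CBF (20 mL/min/100 g) is a standard
physiological value, not a study-reported one. Noise is additive Gaussian
with SD = noise_scale·√(C/Δt_f), the standard reconstruction-noise
approximation of count statistics (more counts per longer frame); the
protocol reports no noise model. Late statics encode the groups' SUVr
patterns times a reference cerebellar SUV of 1.2 and dose/weight scaling,
so the SUV→SUVr chain recovers the pattern exactly in the noise-free
case.

The cohort generator draws 27 patients and 16 controls. Regional CBF and
SUVr are Gaussian draws at the printed group means/SDs; white-matter SUVr
(1.25 ± 0.10) is drawn identically in both groups. Patients carry a latent
severity factor that jointly lowers MMSE (24 ± 3 vs 29 ± 1) and raises
cortical SUVr, so uptake–cognition correlations emerge at the cohort
level; visual scores are thresholded from the cortical SUVr mean at
1.2/1.5/1.9. The hippocampal volume index (patients 4.07 ± 0.60, controls
4.365 ± 0.50 against a normative 5.0 ± 0.5) yields database-referenced
atrophy z-means near 1.86 and 1.27. These couplings are generative
choices, not estimates: the cohort reproduces the *structure* of the
clinical findings (group separation in SUVr, overlap in CBF, correlation
signs), and exact correlation magnitudes are not calibration targets.

BOLD-like series are sums of in-band sinusoids (default 0.02/0.04/0.06 Hz,
snapped to DFT bins; random phases per voxel) plus white noise and an
optional linear trend; a per-voxel amplitude map can plant regional
deficits. The recorded target fALFF combines the exact deterministic
amplitude spectrum with the expected (Rayleigh-mean) flat noise spectrum;
it is exact in the pure-sinusoid and pure-noise limits and an
expectation-level approximation for mixtures, computed on the full
generated window (the 10-volume discard changes it only marginally).

## Pipeline and reproducibility

`run_study` executes phantom → IDIF → CBF → SUVr → fALFF → stats into an
output directory, then writes a manifest with the seed, a config snapshot
and SHA-256 checksums of every output; identical config + seed reproduces
all checksums. All randomness flows from the single study seed through
`numpy.random.SeedSequence` spawning (phantom noise, cohort, BOLD
series, permutations). The default study uses a 20³ dynamic phantom,
a 12×12×14 BOLD grid with 201 volumes per subject for all 43 subjects,
and 1000 permutations — sizes chosen so a full run takes seconds while
every region holds hundreds of voxels; the voxelwise deficit block
(5×5×4 = 100 voxels) comfortably exceeds the 50-voxel extent threshold.
The markdown report mirrors the study's table layout (four lobes × two
hemispheres for CBF and SUVr, correlation panel, cluster table) and
regenerates byte-identically from unchanged outputs.

## Numerical choices and edge cases

* Frame schedules must be contiguous with the first frame at 0 s; the
  printed "39 frames" of the source protocol is inconsistent with its own
  composition (which sums to 38 frames / 70 min with the first 21 spanning
  exactly 3 min); the composition is authoritative here.
* Grid mixing rejects on affine mismatch beyond 1e-4 mm.
* The early-average window is half-open [10, 40) s on frame mid-times.
* Input-function resampling is linear, zero before t = 0, constant beyond
  the last sample (only relevant past 170 s of the 180 s window).
* Degenerate inputs: all-zero TACs give K1 = 0 unflagged; zero-variance
  regional comparisons with equal means give t = 0, p = 1; empty
  parcellation labels yield NaN regional means with a zero count.

## Known limitations

* The weighted-integral weights are a stand-in for an unpublished
  implementation; any monotone-ratio triplet would serve, and the tests
  anchor correctness to the NLLS oracle rather than to specific weights.
* No partial-volume or spill-over correction of the IDIF; the phantom's
  artery is noise-corrupted but not blurred, so real-data IDIF bias modes
  are not exercised.
* The one-tissue model ignores specific binding; the phantom generates
  data from the same model it fits, so model-mismatch bias is untested by
  construction.
* Cluster inference assumes exchangeability under permutation and uses
  hard extent thresholds; random-field theory corrections are not
  implemented.
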