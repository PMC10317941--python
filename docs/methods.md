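# Methods

## Dose model

The dose engine implements voxel-level ⁹⁰Y dosimetry under four
assumptions: (1) microspheres are permanently trapped, so the
time-integrated activity per voxel is Ã_v = A_v·T½/ln 2 with physical
decay only; (2) no activity shunts outside the liver, so the whole liver
is the default self-calibration region; (3) no energy cross-talk between
voxels (local deposition): D_v = Ã_v·E̅·(J/MeV)/m_v; (4) constants
T½ = 64.1 h, E̅ = 0.93 MeV per decay, ρ = 1.05 g/cm³. These combine into
a single conversion factor (T½/ln 2)·E̅·(J/MeV)·10⁹ ≈ 49.61 Gy·kg/GBq,
which yields the closed-form identity used throughout the tests: the
mean dose over the calibration region equals factor·A_net/(region mass)
for *any* spatial distribution, because self-calibration fixes the
regional activity sum.

Both imaging arms run through the identical chain. The ⁹⁹ᵐTc-MAA count
map is treated purely as a spatial surrogate for the microsphere
distribution: it is calibrated to the ⁹⁰Y net activity and converted
with ⁹⁰Y constants. No ⁹⁹ᵐTc physics appears anywhere.

Choices left open by the problem and resolved here:

* **Calibration region** — whole liver (assumption 2); counts outside it
  are treated as extra-hepatic signal and assigned zero activity. A
  whole-field-of-view option exists (`calibration_region: fov`).
* **Net activity** — A_net = injected − residual; lung-shunt correction
  exists but is off by default, consistent with the no-shunt assumption.
  Normalized metrics are Gy per GBq of A_net, which makes them invariant
  to the activity record itself (only the spatial distribution matters).
* **Lobe contours** are intersected with the liver before deriving the
  non-tumoral targeted-lobe VOI, since lobe contours drawn on CT may
  exceed the liver surface; a config flag disables the clipping.
* **Registration is upstream.** Inputs are assumed rigidly co-registered;
  the package only resamples onto the reference grid (the simulation
  count map's grid), nearest-neighbour for masks and trilinear for
  continuous maps.

## DVH metrics

Dx and Vx are evaluated on the exact (unbinned) step DVH. With voxel
doses sorted descending, Dx = sup{d : F(d) ≥ x} is the ⌈x·N/100⌉-th
largest voxel dose; Vx = 100·#{d_v ≥ x}/N. No interpolation is used —
this matches the printed definitions literally and is exactly testable
against a brute-force sorted-voxel oracle; a linear-interpolation
variant exists behind a flag for plot parity only, and the 1-Gy binned
DVH export is only for plotting. Lesions under 4 ml (a ~2-cm sphere) are
excluded before the tumour VOI is formed; the threshold is strict (a
4.0-ml lesion is kept). Overlapping lesions are unioned, never double
counted. TNR is computed from the activity map and is invariant to any
global rescale, so the simulation TNR needs no ⁹⁰Y calibration at all.

## Agreement statistics

* The primary two-sample test is the **unpaired Mann–Whitney U**, applied
  to the two arms of each metric; a paired Wilcoxon signed-rank variant
  is available (`paired=True`) for users who prefer a matched-pairs test.
  Exact null enumeration is used for tie-free samples with m+n ≤ 12,
  otherwise the tie- and continuity-corrected normal approximation; both
  paths agree within ~0.02 in p for moderate samples.
* Pearson categories are half-open bands on |r|: [0,0.3) very weak,
  [0.3,0.5) weak, [0.5,0.7) moderate, [0.7,0.9) strong, [0.9,1] very
  strong.
* Relative differences are 100·(sim − ther)/ther per case, averaged over
  the cases where the denominator is nonzero; if any case is undefined
  the cohort cell is flagged and printed as "–".
* Bland–Altman differences are oriented therapy − simulation (negative
  bias ⇒ simulation overestimates); limits are bias ± 1.96·SD with the
  n−1 sample SD.
* Regression is reported in both orientations. The primary fit is
  therapy on simulation ("how well does the simulation predict the
  delivered dose"); the simulation-on-therapy slope is carried alongside
  because it is the orientation in which a tumour overestimation
  manifests as a slope above one, and because it is robust to noise in
  the therapy arm entering as regressor noise (OLS attenuation).
  Voxel-wise joint histograms use the same convention.
* Tumour-volume stratification cuts at 200 ml, inclusive on the small
  side. Two-sided tests, α = 0.05, no multiple-testing correction.
* Cohort statistics are computed on normalized (Gy/GBq) dose metrics and
  on % for Vx.

## Synthetic paired-phantom generator

The generator produces what the analysis consumes — paired count maps,
contours, and an activity record — with known ground truth.

**Geometry.** Ellipsoidal liver (default semi-axes 95×75×55 mm ≈ 1.6 l)
on a 64³ grid of 4-mm voxels; a half-space lobar split at 35% of the
liver x-extent (right lobe ≈ 65%); spherical lesions placed via the
Euclidean distance transform so they fit entirely inside the liver,
preferentially in the treated lobe.

**Uptake.** Latent specific uptake u(v) is 1 in normal liver and
TNR_true in tumour on average, with mean-corrected multiplicative
lognormal heterogeneity (μ = −σ²/2 so the expectation is unbiased and
TNR_true is the expected specific-uptake ratio); tumour tissue is more
heterogeneous (σ_t = 0.5) than normal tissue (σ_n = 0.3).

**Imaging.** Expected counts are count_scale·normalize(blur(u)), with an
isotropic Gaussian PSF (default FWHM 12 mm, typical of SPECT; the
therapy arm can be given a wider PSF to mimic bremsstrahlung imaging)
and Poisson sampling (default 2×10⁶ total counts). An expected-count
mode disables the Poisson step for noise-free analyses.

**Simulation-arm discordance.** The simulation latent is u times
voxelwise mean-corrected lognormal noise (τ_t = 0.35 in tumour,
τ_n = 0.15 elsewhere — tumour tissue is the less faithful surrogate).
The tumour-specific overestimation is then applied to the *expected
count map after the PSF* as a redistribution at fixed liver total:
tumour voxels ×bias, remaining liver voxels ×κ so the liver sum is
unchanged. Two reasons. First, self-calibration pins both arms to the
same A_net, so only redistributions are observable — a global rescaling
of the simulation map is invisible by construction. Second, applying the
bias after the blur makes `bias_tumor` equal to the *measured* expected
tumour dose ratio between arms, i.e. the parameter is directly
recoverable by the pipeline (bias 1.26 ⇒ ~26% mean tumour
overestimation) rather than being eroded by PSF spill at the tumour
boundary; with the PSF disabled the two definitions coincide. The
recovery tests depend on this property.

**Cohorts.** Per-case parameters are drawn once per case: injected
activity lognormal around 2.6 GBq (clipped to 0.7–6 GBq), residual
fraction 1–5%, LSF lognormal around 8%, waiting time ~21 ± 7 days,
right lobe treated with probability 0.76, 1–3 lesions (77/9/14%), total
tumour volume lognormal around 180 ml (clipped to 6–450 ml, which
populates both sides of the 200-ml stratification), TNR lognormal around
2.5, and a per-case mean-corrected lognormal spread (σ = 0.25) of the
tumour bias around 1.26 so that case-level tumour relative differences
scatter over roughly −30 to +90% rather than sitting at the mean, as a
real cohort's do. All draws flow from one seeded generator;
regeneration from the same seed is bit-identical.

**What the phantom does not emulate** — and therefore what passing
recovery tests do and do not show: no SPECT projection/reconstruction
physics (no OSEM, attenuation, scatter or partial-volume structure
beyond the Gaussian PSF), no anatomy beyond ellipsoids and spheres, no
necrotic cores, no registration error, no catheter-repositioning
mismatches (the discordance is purely the parametric bias + lognormal
noise). Recovery results validate the *pipeline arithmetic* under the
stated noise model, not the clinical fidelity of MAA simulation.

## Numerical choices and degenerate inputs

* Negative voxels (reconstruction ringing) are clamped to 0 at load;
  masks binarize at 0.5; non-finite inputs are rejected.
* Resampling outside the input extent yields 0/false; disjoint grids are
  an error; trilinear output is clamped at 0 against round-off.
* Zero total counts in the calibration region, empty masks, and
  residual ≥ injected activity are errors; a zero non-tumoral activity
  makes TNR undefined (reported missing, not raised).
* A metric that is constant across a cohort (e.g. V205 ≡ 0) yields
  undefined correlation/slope cells rather than failing the run.
* Case-level failures in a cohort run are logged and skipped; at least
  two successful cases are required for statistics.

## Problem sizes

Synthetic validation uses 64³ grids at 4-mm spacing. The acceptance
script averages 32 replicate 30-case cohorts (960 cases) for the
discordance-recovery quantities, eight noise-free cases for the
voxel-wise slope, 100 random maps of up to 10³ voxels for the DVH
oracle, every tie-free Mann–Whitney size with m+n ≤ 10 against full
enumeration, and 10⁴ Monte-Carlo draws for Bland–Altman coverage; the
test suite uses six replicate cohorts for the same recovery checks.

## Known limitations

Constant liver density (no CT-derived density maps); no dose-point-kernel
or Monte-Carlo transport (LDM only); no radiobiological conversions
(EQD2/BED); rank tests follow the unpaired convention described above;
the OLS voxel-wise slope is attenuated by counting noise in the
regressor, which is why noise-free mode is used when the slope itself is
the quantity of interest.
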