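# Methods

This note documents the models, algorithms and numerical choices behind
`centroquant`, what the synthetic-data generators do and do not emulate,
and the known limitations of each stage.

## 1. The measurement model

The package targets a common experimental design in locus-tagging
microscopy: a nucleus is imaged in 3D with a DNA stain plus one or more
marker channels; a handful of bright foci per nucleus mark a tagged
genomic locus; the question is how strongly a marker concentrates at those
foci, how large the tagged domains are at super-resolution, and whether a
perturbation of the locus changes the mis-segregation rate of its
chromosome.

### Normalized density

For one nucleus and one channel, all segmented foci are pooled and

    density = (Signal_foci / Volume_foci) / (Signal_nucleus / Volume_nucleus)

with `Signal_nucleus` the total nuclear signal *including* the foci.
Pooling before the ratio gives one density per nucleus; this is a
different (and more stable) statistic than the mean of per-focus
densities, and the pooled identity is asserted by tests. The inclusive
denominator is the default because "total nuclear signal" is the natural
normalizer; an exclusive variant would shift densities upward slightly but
identically in both groups, so group contrasts are insensitive to the
choice. Densities are invariant under global intensity rescaling (all
thresholds in the segmentation are relative), which tests assert, and a
uniform nucleus has density exactly 1.

Group comparisons use the two-sided Wilcoxon–Mann–Whitney test: exact by
enumeration of the U distribution when both samples have ≤ 8 tie-free
observations, otherwise the normal approximation with tie and continuity
corrections (delegated to `scipy.stats.mannwhitneyu`; an independent
enumeration oracle lives in the test suite).

### Spot-size-normalized intensity

For markers whose foci vary in size (e.g. a centromeric histone variant),
`spot_mean_intensity` reports `Signal_foci / Volume_foci` per focus so
that integrated-intensity comparisons are not confounded by spot volume.

### Overlap fraction

`overlap_fraction` reports `100 × |ref ∩ cand| / |ref|` for the candidate
object maximizing it, emulating the rule that when several partner foci
touch one reference focus only the largest-overlap partner is kept. Ties
are broken by larger absolute intersection, then lowest label — the tie
rule is arbitrary but deterministic.

## 2. 3D segmentation

### Nuclei

Pipeline: Gaussian smoothing (default 0.5 µm, all length scales in µm and
converted per axis to respect the ~2.3× axial anisotropy) → per-axis
gradient magnitude → Otsu threshold on the smoothed DNA channel for
foreground seeds (eroded) and a background seed ring → watershed on the
gradient map, so borders land on intensity-gradient maxima → half-height
border refinement → hole filling → minimum-volume filter (default 4 µm³).

The half-height refinement exists because the discrete watershed ridge
sits on the partial-volume edge voxels and systematically assigns them to
the background basin; on hard-edged test ellipsoids this shaves roughly a
one-voxel shell (~10% of the volume). Since the gradient maximum of a
symmetric edge profile coincides with the half-intensity level, each
object is re-bounded at the mean of its interior median and the background
median, computed on *raw* intensities (heavy smoothing depresses the
interior of small nuclei and would bias the level). Objects may only grow
into the background basin, never into a neighbour, so touching nuclei keep
their watershed separation. With this refinement, volumes of noise-free
analytic ellipsoids are recovered within ~3% and of noisy simulated nuclei
within a few percent (the acceptance tolerance is 10%).

Otsu seeding is parameter-free and scale-invariant; manual per-cell
quality control is replaced by automatic flags (border-touching nuclei are
marked `excluded`).

### Foci

Per nucleus: a Laplacian-of-Gaussian band-pass at the expected focus scale
(default σ = 0.22 µm) defines candidate voxels together with an adaptive
intensity gate `median + k·(1.4826·MAD)` of the intranuclear intensities
(default k = 4; at k = 3 the default noise model produces occasional
false-positive spots). The robust scale has a floor of 5% of the nucleus'
99th-percentile excess so a noise-free interior (MAD ≈ 0) still yields a
meaningful threshold. Seeds are local maxima of a denoised copy restricted
to candidate voxels — seeding on intensity rather than on the LoG response
because the LoG of two nearby spots can merge into a single maximum,
whereas intensity maxima split pairs down to ~2.5σ separation. A watershed
over the whole nucleus assigns each seed a cell; each focus is then
trimmed to the connected voxels whose excess over the nuclear median is at
least 30% of its own peak excess.

The relative (per-peak) trim is the load-bearing design choice: with a
purely absolute threshold the segmented extent grows with spot brightness,
making the pooled mean intensity sublinear in the underlying enrichment —
in recovery experiments a 20% encoded marker loss then measures as ~8%.
With the relative trim a dim and a bright focus of the same physical size
get the same mask, the density excess is linear in enrichment, and the
loss is recovered within the acceptance band.

### Effect estimation

Because the intranuclear baseline is part of the focus mask, enrichment
enters the density as an excess over 1. The marker-effect estimator is
therefore defined on excess densities:

    δ̂ = 1 − (mean(density_treated) − 1) / (mean(density_control) − 1)

which is exact in the noise-free additive model. A small residual negative
bias (~0.02 at the default settings) remains because the foci contribute
to the nuclear mean in the denominator, slightly more so in the control
group; this is inherent to the inclusive-denominator convention and well
inside the ±0.05 acceptance band.

## 3. SMLM pipeline

* **Fitting** (`fit_events`): per frame, difference-of-Gaussians
  band-pass, local maxima above 5 robust noise sigmas, least-squares
  symmetric 2D Gaussian fit (amplitude, x, y, σ_psf, offset) in a 9×9 px
  window. Photons are the fitted Gaussian integral; localization precision
  follows the Thompson photon-statistics formula
  σ² = (s² + a²/12)/N + 8π s⁴ b²/(a² N²). Monte-Carlo tests hold the
  per-axis RMS error within 2·σ_psf/√N at N = 1000 photons.
* **Drift correction** (`correct_drift`): fiducial beads (present in every
  frame) are tracked by incremental nearest neighbour; drift is the mean
  bead displacement per frame, interpolated over dark frames, smoothed
  with a local-linear (Savitzky–Golay order 1) filter — unbiased for
  steady drift including at the sequence ends, where a moving average
  flattens the trend and fails the 2 nm recovery budget — and re-anchored
  to zero at frame 0. Fiducial-based correction is used because beads are
  part of the sample preparation; a cross-correlation fallback is out of
  scope.
* **Merging** (`merge_consecutive`): greedy nearest-neighbour linking of
  detections in consecutive frames (≤ 1 dark frame, ≤ 50 nm by default;
  both exposed), collapsing each chain to an inverse-variance-weighted
  position with summed photons and combined uncertainty 1/√(Σ 1/σᵢ²).
* **Rendering** (`render`): canvas pixel = raw pixel / 10 (144 → 14.4 nm);
  each record adds a unit-amplitude Gaussian with σ = its uncertainty,
  truncated at 4σ (< 10⁻⁴ amplitude error). The canvas integral per
  localization is 2πσ² in pixel units, asserted to 1%.
* **Cluster area** (`cluster_area`): ROI (default 1 µm × 1 µm) around a
  cluster, normalized to its own maximum — removing emitter-density
  differences between clusters so only extent is compared — then area =
  pixels ≥ threshold × pixel area. The threshold (default 0.5) is
  deliberately a free parameter and is recorded in the output; areas are
  monotone non-increasing in it, which is property-tested. Absolute areas
  depend on this threshold and on σ_loc, so only *comparisons* between
  conditions measured with the same settings are meaningful.

Coordinates are nm with origin at the top-left corner of raw pixel (0,0);
pixel centres sit at (i + 0.5)·a. The optics helper maps a 16 µm camera
pixel through a 111× magnification to 144 nm in the object plane.

## 4. Instability scoring

Counts are tetraploid at baseline. `apply_exclusions` flags (never
deletes) nuclei with 8 copies of *either* probed chromosome (replicated
S/G2 cells — excluded, not aberrant) and, within each group among the
remaining nuclei, volumes above median + 2×(1.4826·MAD) (a robust stand-in
for "significantly enlarged"; the multiplier is exposed). The instability
rate is the percentage of usable nuclei deviating from 4 copies. The 2×2
aberrant/normal × induced/uninduced contrast uses Pearson χ² with 1 df
without continuity correction by default; the Yates-corrected variant is
available behind a flag since either convention is defensible at these
sample sizes. Within each tail of fixed margins the χ² statistic orders
tables exactly like the conditional hypergeometric probability, which the
tests verify against a combinatorial oracle.

## 5. Synthetic data: what it emulates, and what it does not

* **IF stacks**: axis-aligned ellipsoidal nuclei (closed-form truth
  volumes) with a low-frequency multiplicative texture; foci are isotropic
  3D Gaussians truncated at 3σ, with centres kept ≥ 1.4 µm apart
  (> 2×3σ, so truth blobs never overlap and per-focus truth is
  closed-form) and fully inside the nucleus; the marker channel carries a
  per-focus peak enrichment e (default 3×) over the intranuclear baseline,
  multiplied by (1 − δ) in the treated group; Gaussian PSF blur
  (anisotropic, 0.25/0.11 µm) then Poisson shot noise and Gaussian read
  noise. Default stacks are desk-scale (30×256×256 voxels at
  0.23 × 0.1 × 0.1 µm; recovery runs use 24×96×96 single-nucleus stacks);
  acquisition-scale geometry (60×1344×1024) is reachable via configuration
  only. Not emulated: realistic nuclear shapes and chromatin texture,
  inter-channel bleed-through, depth-dependent aberrations, mitotic cells.
  Passing recovery tests therefore demonstrates correctness of the
  *measurement chain*, not robustness to every property of real cells.
* **SMLM**: emitters uniform in disc-shaped clusters (default radius
  60 nm), one geometric on-streak per emitter (mean 3 frames), isotropic
  localization noise (default 20 nm), linear stage drift, bright fiducials
  in every frame with 1 nm noise. 2000 frames by default — a deliberate
  tenfold scale-down of a typical 20000-frame acquisition that preserves
  every pipeline property while keeping experiments fast. Not emulated:
  photophysics (re-blinking of the same emitter in distant frames),
  astigmatic 3D PSFs, non-linear drift.
* **Ploidy populations**: per-nucleus categories drawn i.i.d. —
  aberrant with probability π (counts mostly 3, rarer 5 and 6, weights
  0.76/0.20/0.04 mirroring the observed dominance of single losses),
  S/G2 with probability ρ (count 8 on both chromosomes, volume inflated
  1.6×), else euploid; log-normal volumes (median 700 µm³, σ_log 0.25) and
  a 1% volume-outlier contamination. Not emulated: correlation between
  chromosomes' aberrations within a nucleus, cell-cycle structure beyond
  the single S/G2 class.

Generator defaults where no external value existed (enrichment 3×,
baseline/background levels, noise magnitudes, cluster emitter counts,
volume distribution) were chosen once as plausible for antibody-stained
U2OS-like nuclei and are not tuned thereafter; they are configuration,
not calibration.

## 6. Validation experiments and problem sizes

`centroquant.validation` drives three end-to-end experiments, shared by
the heavy tests and the acceptance script:

* **Marker-effect recovery**: 200 single-nucleus stacks per group at
  δ = 0.20; the estimator must land within ±0.05. Runs in ~1 min on one
  CPU at the 24×96×96 stack size.
* **SMLM drift + equal-radius areas**: 2000 frames, drift 0.5 nm/frame;
  drift RMS must stay below 2 nm, and two conditions with equal true
  cluster radius must give statistically indistinguishable area
  distributions (rank-sum). Being a null-hypothesis check it
  false-positives at the test's α; the test suite therefore requires a
  non-significant majority of three independent replicates.
* **Instability recovery**: 200 replicates of 1200 nuclei per group at
  rates 3.9% vs 6.3% with ρ = 0.05. The mean recovered percent increase
  carries a small upward Jensen bias (~+5 points, from the reciprocal of
  the noisy baseline rate) around the encoded 61.5%; the χ² power at
  α = 0.01 under these conditions is ~0.53, so the rejection fraction is
  expected to clear 0.5 only narrowly — a property of the design, not of
  the implementation.

## 7. Known limitations

* Nucleus segmentation assumes blob-like, non-touching-to-moderately
  touching nuclei; heavily clumped tissue would need a different seeding
  strategy.
* Focus segmentation assumes roughly isotropic diffraction-limited spots
  at a single scale; elongated or multi-scale structures are out of scope.
* The SMLM fitter is single-emitter; overlapping events in dense frames
  are discarded or mis-fit, and no Fourier-ring-correlation resolution
  estimate is provided.
* Absolute cluster areas are threshold- and σ_loc-dependent by
  construction; report them only alongside the parameters used.
* The χ² test is asymptotic; for very small usable counts an exact test
  would be preferable (the test suite's hypergeometric oracle shows the
  orderings agree).
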