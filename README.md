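# centroquant

Quantitative 3D microscopy of centromeric foci: nucleus and focus
segmentation in calibrated Z-stacks, normalized focus-density statistics,
a single-molecule localization (PALM/STORM) pipeline with drift correction
and cluster-area measurement, and chromosome-instability scoring from FISH
focus counts — plus synthetic-data generators with ground truth so the
whole pipeline is testable without any raw microscope data.

## Who this is for

Groups that tag a specific genomic locus (e.g. centromeric α-satellite
repeats bound by a programmable TALE protein) and ask quantitative
questions with fluorescence microscopy:

* *How enriched is a chromatin mark or protein at the tagged foci,
  relative to the rest of the nucleus?*
* *How large are the tagged nanodomains in super-resolution images?*
* *Does perturbing the locus change the mis-segregation rate of that
  chromosome?*

## The statistics at the core

**Normalized focus density.** For each nucleus, all segmented foci of a
channel are pooled and the density is the ratio of mean intensities

```
density = (Signal_foci / Volume_foci) / (Signal_nucleus / Volume_nucleus)
```

where `Signal_nucleus` is the *total* nuclear signal (foci included) and
volumes come from voxel counts × voxel volume (default calibration
0.23 × 0.1 × 0.1 µm). A uniform nucleus has density 1; density > 1 means
the signal concentrates in the foci. Group differences are tested with a
two-sided Wilcoxon–Mann–Whitney test (exact for small tie-free samples).

**SMLM cluster area.** Localizations (Gaussian PSF fits of blinking
emitters) are drift-corrected against fiducial beads, consecutive
detections of one molecule are merged (inverse-variance position, combined
uncertainty `1/√(Σ 1/σᵢ²)`), and a super-resolved image is rendered on a
tenfold-upsampled canvas as a sum of unit-amplitude Gaussians with σ equal
to each localization's uncertainty. Cluster ROIs are normalized to their
maximum pixel and the area above a relative threshold (default 0.5) is
reported in µm².

**Chromosome instability.** Per-nucleus FISH focus counts around a
tetraploid baseline: nuclei with 8 copies of either probed chromosome
(S/G2 cells) and robust volume outliers are excluded, the instability rate
is the fraction of remaining nuclei deviating from 4 copies, and
induced/uninduced conditions are compared with a Pearson χ² test on the
2×2 aberrant/normal table.

## Worked example

```python
import pandas as pd
from centroquant.simulate import PloidySimConfig, simulate_ploidy_population
from centroquant.ploidy import instability_report

un  = simulate_ploidy_population(PloidySimConfig(
    n_nuclei=1200, instability=0.039, group="uninduced", seed=1))
ind = simulate_ploidy_population(PloidySimConfig(
    n_nuclei=1200, instability=0.063, group="induced", seed=2))
rep = instability_report(pd.concat([un, ind], ignore_index=True))
print(f"uninduced rate {rep['groups']['uninduced']['rate_pct']:.2f}%")
print(f"induced   rate {rep['groups']['induced']['rate_pct']:.2f}%")
print(f"chi2 {rep['chi2']:.2f}  p {rep['p_value']:.4f}  "
      f"increase {rep['percent_change']:.0f}%")
```

prints

```
uninduced rate 3.60%
induced   rate 6.32%
chi2 8.54  p 0.0035  increase 76%
```

i.e. the induced population shows a significantly higher fraction of
nuclei with an aberrant chromosome-7 count (one simulated draw; the
sampling spread of the percent increase at these rates is large, which is
why the validation experiment below averages 200 replicates).

The same style of driver exists for the imaging path
(`centroquant.validation.recover_marker_effect`: simulate stacks → segment
→ densities → effect estimate) and the SMLM path
(`smlm_drift_and_area_experiment`). A `centroquant` command-line tool
wraps the stages (`simulate`, `segment`, `quantify`, `smlm`, `ploidy`).

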