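# Methods

## Scope

`centroquant` re-implements, as a library, the quantification used to
compare centromeric fluorescence between experimental conditions in
egg-extract / sperm-chromatin experiments, plus the densitometry used for
in-vitro nucleosome-binding blots.  Wet-lab procedures, alignment of
homologues, and structure prediction are out of scope; the package starts
from images (real or simulated) and ends at fold changes and p-values.

## Image model of the synthetic generator

A simulated field contains `n_nuclei` non-overlapping circular nuclei
(soft-edged super-Gaussian blobs in the DNA channel) each carrying
`foci_per_nucleus` centromere foci.  A focus is an anisotropic 3-D Gaussian
(σ_xy, σ_z) centred at a subpixel position inside its nucleus footprint,
with a minimum lateral separation between foci so neighbouring
diffraction-limited spots stay resolvable.  Per channel the rendered signal
is

    image = clip( round( offset + N(0, read_sd²)
                         + Poisson( shading(x, y) · (background + Σ foci) ) ) )

quantized to `bit_depth` bits.  `shading(x, y) = 1 + a·cos-bump` is a smooth
multiplicative flat-field error (default a = 0.3) included specifically to
exercise the median-filter normalization.  Setting `shot_noise=False`,
`read_noise_sd=0`, `shading_amplitude=0` gives an analytic render used by
tests (a focus of amplitude A on background B projects to a peak of exactly
A + B up to quantization).

Amplitudes: each focus draws an independent unit-mean lognormal factor with
coefficient of variation `amplitude_cv` (default 0.3; centromere intensity
distributions are right-skewed).  The marker channel carries no condition
effect; the target channel amplitude is multiplied by the condition's fold
change (wild type ≡ 1).  Each biological replicate multiplies all
amplitudes by a shared unit-mean lognormal batch factor
(`replicate_batch_sd`, default 0.1), emulating day-to-day extract and
staining variation; this is what makes per-replicate reference
normalization matter.  One RNG stream is derived per (condition, replicate)
from the master seed, so adding a condition never changes another
condition's images; batch factors use a stream keyed only by replicate.

Default acquisition geometry matches the emulated experiments: 41
z-sections at 0.2 µm (an 8 µm span), 16-bit camera, and per condition and
replicate 13 nuclei × 8 foci = 104 centromeres — satisfying the sampling
rule of at least 100 centromeres among at least 10 nuclei.  Pixel size
(0.11 µm on a 60×/1.4 system) and unit camera gain are placeholders not
constrained by the emulated acquisition.  Defaults for the amplitudes
(marker and target 2000 counts over a background of 50 with offset 100)
put foci far above the noise floor, as real anti-CENP-A staining does.

What the generator does **not** emulate: realistic PSFs (no Airy rings, no
depth-dependent aberration), spectral bleed-through, photobleaching,
chromatin texture inside nuclei, clustered or touching nuclei, or
non-centromeric debris that manual curation removes in practice.  Passing
recovery tests therefore demonstrates the pipeline's arithmetic and its
robustness to shading, shot noise and batch effects — not performance on
every pathology of real microscopy.

## Segmentation

Measurements are taken on maximum-intensity projections, so segmentation
operates in the same projected space.  The marker projection is divided by
its own median-filtered copy (square window of side 2r+1, edge-replicated;
default radius 10 px, chosen to be much wider than a focus so a spot does
not inflate its own background estimate).  The normalized image is
thresholded (Otsu by default; an absolute threshold in normalized-contrast
units is available) behind a robust-contrast guard: if the 99th percentile
over the median is below 1.5 the field is considered blank and the mask is
empty rather than noise-thresholded.  Whether to threshold normalized or
raw intensities is exposed as a switch (`threshold_on_normalized`,
default on).

Connected components use 8-connectivity (configurable).  The size gate
keeps components of 5–25 px **inclusive** — regions *larger or smaller*
than the cut-offs are removed, so the bounds themselves survive.  Surviving
regions are renumbered in raster order of their first pixel.  The exact
median filter is implemented as a row-blocked sliding-window partition
(several-fold faster than the generic ndimage filter at these window sizes
and verified against it element-for-element in tests).

Nuclei are segmented from the DNA projection (Gaussian smooth, Otsu, hole
fill, minimum area); each focus receives the nucleus label under its
centroid, and foci outside every nucleus are flagged.  Border-touching
regions are kept but flagged.  Manual inspection is reified as a
`CurationList` file (label → reason); applying it removes the listed
regions without renumbering the survivors, so focus identity is stable and
a run is exactly reproducible from its inputs.  An automatic rule that
rejects foci outside nuclei exists and is off by default.

## Measurement and normalization

Per focus and channel the mean raw projection intensity under the label is
recorded, together with a local background estimate: the median intensity
in an annulus around the focus (between 2 and 5 binary dilations of the
region, all focus pixels excluded).  Fold-change estimation subtracts this
background by default.  The reason is arithmetic: a ratio of raw means is
biased toward 1 by any additive pedestal (camera offset plus diffuse
background), and with the generator's defaults that bias alone would be
several times larger than the recovery tolerance; the annulus-corrected
ratio is unbiased and also insensitive to smooth shading.  `background="none"`
restores plain raw-mean ratios for sensitivity analysis.

Normalization to the reference (wild-type) condition defaults to
**per-replicate** scope: each replicate's foci are divided by that
replicate's reference mean.  This cancels multiplicative batch effects
exactly and makes replicate means comparable across days; it also fixes the
reference replicate means at exactly 1.  A pooled scope (one global
reference mean) is provided for sensitivity analysis.  In both scopes the
reference's normalized values average to 1 by construction (asserted to
1e-12 in tests).

## Statistics

Replicate summaries follow the superplot convention: the replicate mean is
the mean normalized value over that replicate's foci; the condition grand
mean is the arithmetic mean of replicate means; the reported SEM is the
standard deviation of replicate means over √n_replicates.  Conditions with
fewer than two replicates are rejected.

Condition contrasts use Welch's unpaired two-tailed t-test **on the
replicate means** with Welch–Satterthwaite degrees of freedom.  Degenerate
conventions: both variances zero with equal means gives p = 1; with unequal
means, p = 0 with a warning.  When the reference was the normalization
scope its variance is exactly zero and the statistic reduces to a
one-sample t with n−1 degrees of freedom, which remains calibrated (the
type-I acceptance run verifies ~5% rejections under the null).  No
multiple-testing correction is applied; contrasts are reported pairwise
as-is, and the output metadata says so.

The fold change of a condition versus the reference is the ratio of grand
means.  Its confidence interval uses the first-order delta method for a
ratio of independent means,

    var(f) ≈ s_c²/(n_c·ḡ_r²) + ḡ_c²·s_r²/(n_r·ḡ_r⁴),

with a t quantile on Welch–Satterthwaite degrees of freedom over the two
variance terms; with a constant reference this is a one-sample t-interval.

Sampling QC checks ≥100 foci among ≥10 nuclei per condition and replicate.
Failures are warnings, not errors — the counts describe the strength of
evidence, not the validity of the arithmetic — unless `strict` mode is on.

## Densitometry

Every band (bound protein and loading control) is measured with one fixed
rectangle size; background is the mean of the same-size rectangle
translated straight down by one rectangle height (the distance is
configurable, since "directly below" does not fix a gap).  Net = raw −
background; negative nets are kept and flagged (clipping would bias
ratios).  Each lane's band/loading ratio is divided by the mean ratio of
the wild-type lanes, making the wild-type normalized mean exactly 1.  Film
response is treated as linear (uncalibrated X-ray film); an `invert` option
handles dark-bands-on-light scans and is recorded in the output.  Lane and
band detection are deliberately absent: ROIs are explicit inputs, matching
the manual workflow being reproduced.

## Problem sizes used in tests

The statistical validation (fold-change recovery over 20 seeds, power at
batch sd 0.05, type-I calibration over 400 null experiments) runs the full
image pipeline on a reduced geometry — 192 × 192 px fields with 5
z-sections — while keeping the study's sampling design intact: 3 biological
replicates and 13 nuclei × 8 foci ≥ 100 centromeres per condition per
replicate.  The quantities under test (ratios of replicate means and their
t-statistics) depend on the sampling design, not on the field of view, and
measured recovery at this size is unbiased to well under the ±0.05
tolerance.  The acceptance script uses the same geometry with 8 recovery
seeds and 200 null experiments.

## Known limitations

- Segmentation is 2-D on projections; axially overlapping foci merge.
- Foci closer than about twice the thresholded spot radius merge into one
  component and, if the union exceeds 25 px, are dropped by the size gate;
  the generator's minimum separation keeps this rare, real images may not.
- The Otsu default assumes some foci are present; the contrast guard
  returns an empty mask on blank fields but cannot rescue very low-contrast
  staining.
- Background annuli assume locally flat background; sharp background
  structure under a focus is not corrected.
- The delta-method CI for fold changes is first-order; at n = 3 replicates
  it is approximate and reported as such.
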