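# Methods

`lipidmsi` analyzes negative-ion GCIB-SIMS imaging data of lymphoid tissue:
it builds a centroided peak table from averaged spectra, normalizes and masks
the pixel images, segments a multi-sample composite by PCA and k-means, and
assigns lipid identities by accurate mass. A synthetic-scene generator with
ground truth makes every stage testable end to end without access to patient
data.

## Data model and geometry

Images are mosaics of square tiles (default 900 µm edge, 128-pixel raster,
i.e. 7.03125 µm ≈ 7 µm pixels). Pixel indices are 0-based, row-major, origin
top-left; physical coordinates refer to pixel centers. imzML (+ .ibd) is the
only on-disk spectral format and inputs are assumed mass-calibrated.
Composite canvases pack member images side by side in member order with a
bidirectional canvas↔member pixel map; the arrangement is bookkeeping, not
science.

## Peak picking and centroiding

The averaged spectrum of each image is the mean of per-pixel TIC-normalized
spectra, resampled to a uniform m/z grid (default 0.005 m/z, linear
interpolation); zero-TIC pixels are excluded and counted. The picker then

1. Gaussian-smooths the spectrum (`gaussian_sigma`, default 0.02 m/z),
2. takes a smoothed second derivative (Savitzky–Golay, window
   `deriv_window` = 7 samples, polyorder 2),
3. zeroes positive derivative values and negates the rest,
4. treats every contiguous positive feature of the result as one peak:
   centroid = derivative-weighted mean position, integration window = the
   feature's half-open m/z span `[lo, hi)`, apex = raw-intensity maximum,
5. keeps the `n_keep` (default 300) highest-apex centroids per mass range
   (defaults 590–800 and 800–1190), breaking apex ties toward lower m/z, and
   concatenates the ranges into one ascending table.

Because a Gaussian's second derivative is negative only within ±σ of its
apex, integration windows cover the peak core rather than the full line; the
per-pixel centroid intensity is therefore the spectrum summed over the
window, and conservation is asserted against direct integration. Peaks
closer than the resolving power share one derivative feature and collapse
into a single merged centroid — deliberately so: isobaric interferences
(e.g. the M+2 isotopologue of PI 38:4 under PI 38:3 at Δ ≈ 0.009) are kept,
not deisotoped, and flagged via `merged_flag` when a feature holds two or
more local maxima. The exact smoothing settings of the original ChiToolBox
processing are not public; the defaults above are this package's declared
choices and are configurable.

## Normalization and substrate masking

Each pixel's centroid vector is sum-normalized to 1 and square-rooted, a
variance-stabilizing transform for counting data; every nonzero pixel then
has unit sum of squares, which the tests assert to 1e-9. Substrate (bare ITO
slide) pixels are found with k-means (k = 2, k-means++ init, 10 restarts,
fixed seed) on the normalized profiles; the cluster with lower mean *raw*
TIC is the substrate, making the label invariant to cluster index
permutation. Masking zero-fills substrate rows rather than dropping them.
The order normalize → mask commutes for the retained pixels because both
operations are per-pixel. Whether to cluster on the full feature set or a
substrate-indicative subset is configurable; the full set is the default.

## Multivariate analysis

PCA is mean-centered with no variance scaling (the square root already
stabilized variance). By default it is fit on all canvas pixels including
the zero-filled substrate, so PC1 captures tissue versus substrate and later
components capture tissue chemistry; fitting on tissue pixels only
(`fit_on="tissue"`) is available. Loadings are orthonormal, components are
ordered by explained variance, and the sign convention makes the
largest-|loading| channel of each component positive — sign is otherwise
arbitrary and both directions are annotated. k-means (k-means++, 10
restarts, fixed seed) runs on the same matrix; with substrate included, one
cluster trivially captures it, so k = 3 on a two-condition composite targets
substrate/healthy/cancer, and a sweep over k = 3–10 probes finer tissue
structure. Cluster contrasts are reported as difference spectra (cluster
mean minus overall mean); size-weighted differences sum to zero by
construction, and any display inversion is a plotting flag only. Candidate
marker peaks can be validated with single-ion images (nearest centroid
within tolerance, ties to lower m/z).

Cluster-recovery quality against synthetic ground truth is scored with the
adjusted Rand index, which is invariant to label permutation.

## Accurate-mass annotation

Theoretical m/z values are computed from elemental formulas (monoisotopic
masses from the pyteomics NIST table) with the [M−H]⁻ convention
monoisotopic(M) − 1.007276 Da; the electron-mass subtlety is below the
2-decimal reporting precision. Fragment hypotheses subtract a neutral-loss
composition from the deprotonated ion: the PS serine head-group loss
(−C₃H₅NO₂, 87.0320 Da), the N-acetylhexosamine−H₂O loss (−C₈H₁₃NO₅) and the
monosaccharide loss (−C₆H₁₀O₅) seen for glycosphingolipids. Search matches a
measured m/z against all hypotheses within ±0.01 (configurable), ranked by
|ppm| with a per-species biological-plausibility prior as tie-break.

Because PS lipids fragment to PA-like ions in SIMS, a PA assignment at m/z p
is replaced by the PS-fragment hypothesis whenever a centroid at p + 87.0320
(± window) exceeds a significance threshold (default 1% of the base-peak
apex) and itself carries an intact PS assignment; the rule changes
hypotheses, never the number of annotated peaks. Assignments below m/z 900
get metabolomics reporting confidence level 2; at or above 900 (possible
fragments of larger gangliosides) level 2/3, with the boundary value
assigned upward. Accuracy is summarized as mean |ppm| and the percentage of
assignments under 5 ppm. Printed m/z comparisons use round-half-up to 2
decimals.

The bundled reference table (`data/lipids.csv`, 56 species) encodes the PI,
LPI, PS, PE, PE-O, PG, PA, PA-O, SM, SHexCer, SHex₂Cer and ganglioside-type
species discussed for DLBCL lymph nodes, with formulas derived from fixed
per-class composition rules. Two caveats are deliberate: SM species keep
their standard compositions although SIMS frequently detects them after
methyl loss (≈14.02 Da lower), and PI 38:3's theoretical 887.5655 sits on a
rounding boundary. Live database queries are out of scope.

## Synthetic scenes

The generator emulates the statistical structure of a lymph-node cohort, not
the physics of sputtering. Each member tile holds a tissue block on a
substrate margin; region types are substrate, healthy lymphoid, DLBCL, an
aggressive sulfatide-rich DLBCL sub-region, a histiocyte pocket and a
connective band. Default profiles: healthy and DLBCL swap the
healthy-marker/cancer-marker sets at a 3:1 abundance ratio; the aggressive
sub-region raises the sulfatide series ten-fold (well above the 5× floor
that guarantees detectability is a pipeline property, not a tautology);
histiocyte pockets modulate the healthy profile by the tabulated directions
with declared magnitudes (slight 1.2×, small 1.5×, moderate 2×, inverses for
decreases) and connective tissue applies the square root of those factors.
Tissue pixels average 2000 counts, substrate 20 (a 100× TIC contrast);
substrate carries a flat baseline across the axis.

Every species contributes a Gaussian line at its [M−H]⁻ m/z with flat FWHM
0.05 m/z — wide enough to merge Δ ≤ 0.01 pairs, narrow enough to separate
885.55 from 887.56 — plus an isotopologue envelope (aggregated binomial
convolution of natural abundances, peaks at +1.00336·j), normalized so the
species' total expected counts equal abundance × TIC. Counts are drawn
per-pixel from a Poisson model; a seed fixes all randomness and equal seeds
give bit-identical cubes. The spectral axis is a sparse union of ±4-FWHM
windows around all lines at 0.01 m/z steps, which keeps memory proportional
to the number of lines rather than the full 590–1190 range.

What the generator does *not* emulate — matrix effects, detector saturation,
mass-calibration drift, spatial intensity gradients, partial-volume mixtures
at region boundaries, and chemical noise — bounds what passing tests show:
they validate the algorithmic chain (picking, normalization, masking,
segmentation, annotation) under the stated noise model, not instrument-level
robustness on real tissue.

## Problem sizes and determinism

The default scene uses five members (two healthy, one of them with the
histiocyte pocket and connective band; two DLBCL; one aggressive) at a
32-pixel raster. The test suite and worked examples run the same scene at a
12–16-pixel raster, which preserves every regional structure while keeping
the full suite under a minute; segmentation recovery there is exact
(ARI = 1.0 for k = 3 against substrate/healthy/cancer, and k = 3–7 isolate
the sulfatide-rich sub-region on the aggressive sample). All stochastic
stages (scene simulation, masking, k-means) take explicit seeds recorded in
the run manifest; reruns with the same config are byte-identical for every
artifact the pipeline writes.

## Known limitations

- The picker assumes a uniform (or near-uniform) resampling grid and a flat
  resolving-power model; real ToF resolution varies with m/z.
- Integration windows derived from second-derivative features truncate peak
  tails; intensities are core areas, consistent across pixels but not total
  line areas.
- Annotation is accurate-mass only (level 2 / 2–3 confidence); no MS/MS,
  mobility or retention evidence, and no isotope-pattern scoring.
- The composite accepts any member count and arrangement; no spatial
  co-registration with histology is attempted.
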