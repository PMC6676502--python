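# Methods

## The measurement model

`nucquant` quantifies the amount of a nuclear antigen (the *query* signal,
e.g. phosphorylated Smad) in cells identified on an independent *marker*
channel (e.g. the pan-neuronal nuclear protein Elav), from multi-channel
RGB TIFF images of immunostained tissue. The model of one image is:

- a polygonal **selection** delimits the tissue of interest (e.g. the
  ventral ganglion of a larval CNS);
- within the selection, nuclei appear as bright, roughly circular blobs on
  the marker channel;
- the query channel carries signal of interest inside nuclei plus a diffuse
  background (autofluorescence, non-specific staining) assumed spatially
  uniform at the scale of the selection.

The pipeline per image is:

1. split the RGB stack into channels (multi-slice stacks are reduced to one
   plane by a per-channel maximum projection by default, or a single-slice
   index; the choice is recorded in the run log);
2. clear the marker channel outside the selection;
3. binarize with an inclusive intensity window `[min_level, max_level]`,
   computed automatically (iterative-intermeans "default", or Otsu) from
   the histogram of in-selection pixels only, or supplied manually;
4. optionally dilate (3×3 structuring element) and/or split touching blobs
   with a distance-transform watershed — in that order;
5. particle analysis: 8-connected components filtered by area and
   circularity `4πA/P²`; survivors are the ROIs;
6. optional headless ROI edits (include/exclude label lists) replacing
   interactive inspection;
7. superimpose the ROIs on the query channel; per-ROI mean intensity is
   `mean_raw`, the mean over all in-selection pixels belonging to no ROI is
   `mean_bg`, and `mean_corrected = mean_raw − mean_bg`.

The per-image summary statistic is the unweighted mean of `mean_corrected`
over ROIs (each nucleus is one biological observation, so a large nucleus
does not count more). Group-level analysis reports fold-change
(experimental group mean / control group mean of the per-image values),
with dispersion as the sample SD of per-image folds, plus the coefficient
of variation per group. Formal hypothesis tests are left to the user's
statistics tool; the CSVs carry everything needed.

### Why a single global background

Background is estimated once per image from the in-selection complement of
the ROI union, not from per-ROI annuli. This matches the assumption of a
spatially uniform background and makes `mean_corrected` exactly invariant
to any constant offset added to the query channel — the central property
the tests verify. Negative corrected means are reported (and flaggable),
never clipped, because clipping would bias fold-changes upward near zero.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `slice_policy` | — | `max` | or an integer slice index |
| threshold mode | — | auto (`default` method) | `otsu` selectable; manual `min:max` levels 0–255 |
| `min_area`, `max_area` | px² | 20, 10 000 | nucleus size window |
| `min_circ`, `max_circ` | — | 0.3, 1.0 | circularity `4πA/P²`, clamped ≤ 1 |
| `apply_dilate`, `dilate_iterations` | — | off, 1 | 3×3 dilation before watershed |
| `apply_watershed` | — | off | distance-transform split of touching blobs |
| `exclude_edge_particles` | — | off | border-touching ROIs kept by default |
| `background_statistic` | — | mean | `median` available |

Defaults are implementation starting values that work for the synthetic
nuclei this package ships and for similarly scaled fluorescence data; they
are expected to be tuned per experiment and are persisted between runs in
`.nucquant.json`.

## Numerical choices

- **8-bit contract.** RGB TIFF samples are uint8; 16-bit inputs are
  divided by 257 and rounded on load. All means are computed in double
  precision.
- **Polygon membership** uses the even-odd rule evaluated at pixel centers,
  with centers lying exactly on an edge counted inside — a deterministic,
  testable convention. Out-of-bounds vertices are clipped with a warning;
  zero-area polygons are rejected.
- **Auto-threshold conventions.** Both methods return `min_level =
  level + 1` (bright foreground on dark background) and `max_level = 255`.
  The iterative-intermeans method stops when the cut passes the mean of the
  two class means; Otsu takes the smallest cut among ties maximizing
  between-class variance. A constant in-selection histogram is an error
  directing the user to manual mode.
- **Connectivity and labels.** Foreground components are 8-connected;
  labels are assigned in raster-scan order of each component's first pixel,
  so output ordering is deterministic.
- **Perimeter and circularity.** Perimeter uses the 4-direction Crofton
  estimate, which tracks the true boundary length of digitized disks within
  about 1%, so disk circularity approaches 1 from above/below as radius
  grows; values are clamped at 1.0 because very small particles exceed 1
  numerically (a single pixel is assigned circularity 1).
- **Watershed.** Markers are the regional maxima of the Euclidean distance
  transform of the mask; the watershed runs on the negated distance map
  with a one-pixel background line between basins. Foreground never grows,
  and blobs with a single distance maximum pass through unchanged.
- **Dilate-then-watershed order** is fixed when both are requested (dilate
  can merge what watershed would then split; the order is recorded in the
  run log).
- **Degenerate inputs.** An empty mask yields an empty particle list; zero
  surviving ROIs yield a summary row with count 0 and NaN means; an ROI
  union tiling the whole selection makes the background undefined and is an
  error advising a larger selection.

## The synthetic-data generator

No real micrographs ship with the package, so `synthgen` renders
ground-truth images: hard disks (nuclei) of known radius at a fixed marker
level over a uniform background, with the same disks on the query channel
at known per-nucleus means, optional additive Gaussian noise (applied
before clipping to [0, 255] and uint8 quantization; the clip count is
reported), and a label image tying every rendered pixel to its nucleus.
Default conditions: 192×192 px images, 12 non-overlapping nuclei of radius
5–8 px, marker 200, background 20, noise SD 5, and experiments of 8 images
per group — the scale of a motor-neuron nucleus field and the group size
typical of the two-genotype comparisons this tool serves. Disks are
non-overlapping by default so particle counts have unambiguous truth; an
`allow_touching` mode produces merged blobs specifically to exercise the
watershed. Generation is fully deterministic per seed, and per-image seeds
are derived from a base seed and image index (kept below 2³¹).

What the generator does *not* emulate: neuropil texture, axons, optical
blur (PSF), Poisson photon statistics, intensity gradients, or non-disk
nuclear shapes. Passing tests therefore demonstrate correctness of the
measurement machinery under the stated model — exact recovery, invariances,
oracle equivalence — not segmentation robustness on difficult real tissue,
where threshold and filter parameters must still be tuned by eye.

## Design choices that were genuinely open

- Dispersion on the fold-change is the SD of per-image folds (each
  experimental image divided by the control mean); propagating the two
  group SDs through the ratio is the alternative. The choice is stated in
  the `fold.csv` column name and here.
- The per-ROI statistic is the mean; integrated density (mean × area) is
  exposed as a property but not a CSV column.
- Multi-slice reduction (projection vs single slice) is a user-visible
  parameter rather than a fixed behavior, since either is defensible.
- Whether border-touching particles should be excluded is left as an
  off-by-default flag.

## Problem sizes used by the test suite and acceptance script

Exact recovery runs one 256×256 noiseless image with 10 nuclei; oracle
equivalence uses 100 random 64×64 masks and 50 synthetic histograms;
fold-change recovery uses 50 replicate experiments of 2×8 images (ratio 4
and ratio 1), about 1 600 image quantifications in total. These sizes give
Monte-Carlo standard errors on the recovered fold of well under 2% while
keeping a full run to tens of seconds on one CPU.

## Known limitations

- Background uniformity is assumed; strong gradients bias `mean_corrected`.
- The watershed marker detection can over-split highly irregular blobs with
  multiple distance maxima; it is tuned for convex nuclei.
- Only polygon-type ImageJ `.roi` files are parsed.
- No 3-D voxel measurement: stacks are reduced to a single plane before
  analysis.
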