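# Methods

## Scope and model

The package quantifies multi-channel 3D immunofluorescence stacks of
midbrain-organoid sections. One section is an `ImageStack`: a non-negative
intensity volume indexed `(z, y, x, channel)` with channel roles drawn from
{HOECHST, TH, GFAP, S100B, TUJ1} and a physical voxel size carried as
metadata. A 2D image is a z-depth-1 stack, so every operation is written
once for 3D. All count-based features (nucleus sizes, pixel sums, the QC
gate) are computed in voxel units, not physical units, because the analysis
thresholds are defined in pixels; the voxel size is metadata only.

The per-section procedure is:

1. **Nuclei.** The Hoechst channel is smoothed with a Gaussian, binarised
   (Otsu by default), and split into nuclei by a watershed seeded from local
   maxima of the Euclidean distance transform of the foreground. Nuclei with
   more than 10,000 voxels (strictly greater) are removed as merged or
   artefactual; the removal count is recorded in provenance. Retained cells
   define `n_cells`.
2. **Marker masks.** Each marker channel (and Hoechst itself for the
   nuclear-pixel sum) is median-filtered and binarised with `filtered >=
   threshold`. The nuclear-pixel sum deliberately comes from this
   threshold-mask contract, not from the nucleus label map, so section QC is
   independent of watershed quality.
3. **Per-cell positivity.** A perinuclear zone per retained nucleus:
   Euclidean dilation of the nucleus by the ring width, minus all nucleus
   voxels; a voxel within reach of two nuclei goes to the nearer one, exact
   distance ties to the lower label. A cell is positive for a marker when at
   least 1% (inclusive) of its zone lies in the marker mask. Percentages are
   over the post-size-filter cell count.
4. **Fragmentation.** The TH score is surface/volume of the TH mask, with
   surface = mask minus its erosion by the 6-connected structuring element
   (26-connected optional); volume borders count as surface. For a solid
   a×b×c cuboid (a,b,c ≥ 3) this is exactly 1 − (a−2)(b−2)(c−2)/(abc);
   for fixed mask volume the score grows with the number of pieces, which is
   what makes it a degeneration readout.
5. **QC and statistics.** Sections whose Hoechst pixel sum is strictly below
   5000 are removed. Groups are compared per feature with the two-sided
   Mann–Whitney U test. The analysis unit is the section (one point per
   passed section); per-organoid means of passed sections are available as
   an alternative unit — both readings of "a section is a data point,
   averaged with the other sections" are implemented rather than resolved.
   No multiple-testing adjustment is applied by default (per-feature
   unadjusted tests); a Bonferroni option exists.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `nuclei.sigma_vox` | 2 in-plane, z scaled by anisotropy (≥ 0.5) | voxels | nucleus-scale smoothing; physically isotropic |
| `nuclei.threshold_method` | `otsu` | — | parameter-free on a bimodal Hoechst histogram; `fixed` available |
| `nuclei.min_seed_distance_vox` | 5 | voxels | minimum separation of watershed seeds; below a nucleus diameter |
| `nuclei.max_nucleus_size_vox` | 10000 | voxels | strict upper bound on a single nucleus; exactly 10000 is retained |
| `markers.window_vox` | (3, 3, 3) | voxels | smallest centred denoising window; per-marker overrides allowed — for strongly anisotropic stacks (e.g. 5 µm z-steps at 1 µm/px) an in-plane window (1, 3, 3) avoids mixing planes that are far apart physically |
| `markers.threshold_method` | `otsu` | — | Otsu assumes the channel contains signal; for channels that may be legitimately empty (a marker absent from a section), a fixed threshold calibrated to the acquisition is the appropriate choice, since Otsu on a signal-free channel splits noise |
| `ring_width_vox` | 2 | voxels | minimal reading of "perinuclear": a thin shell adjacent to the nucleus |
| `min_positive_fraction` | 0.01 | fraction | inclusive positivity bound |
| `min_hoechst_sum` | 5000 | voxels | strict QC gate for failed staining/imaging |
| `surface_connectivity` | 6 | — | face-connected erosion gives the conventional voxel surface |

Numerical notes. The positivity rule compares `count / zone_area >=
min_fraction` in division form: at the boundary the quotient rounds to the
same double as the fraction literal, keeping the inclusive rule exact,
whereas the product form `count >= min_fraction * zone_area` can fail by one
ulp. The watershed seed surface is the distance transform smoothed with a
fixed sigma of 1 voxel; without it, plateaus of the discrete distance
transform spawn several seeds inside one nucleus. Otsu on a constant volume
is treated as "no signal" (empty mask) rather than an error. An empty mask
makes the fragmentation score undefined (NaN), as does `n_cells = 0` for a
percentage; undefined values are dropped from aggregation with a warning.

Segmentation order: thresholding precedes watershed seeding (seeds are
maxima of the foreground distance transform). The alternative order is not
offered; the choice is recorded in each label map's provenance.

## The synthetic generator

`synthetic_organoid` renders sections with exact ground truth. Defaults
emulate one realistic desk-scale field: a 10×128×128 slab (a 50 µm section
sampled at ~5 µm z-steps, ~1 µm/px in-plane), 25 ellipsoidal nuclei with
semi-axes (2.5, 5.5, 5.5) voxels jittered by sd 0.4, GFAP/S100β-positive
fractions 0.4/0.25, a few tubular neurites per neuronal channel, background
100 / foreground 1000 intensities, and additive Gaussian noise of sd 20
(2.2% of contrast), with optional Poisson shot noise. With these defaults a
section carries ~6200–6900 Hoechst-positive voxels, comfortably above the
QC gate, as any analyzable real section must be.

Design choices that matter for interpretation:

- **Positivity is rendered as a perinuclear shell**, not a whole-cell fill,
  because the classifier reads the perinuclear area: ground truth is
  expressed in the classifier's own terms.
- **Nuclei are placed by rejection sampling with a bounded retry budget**
  and a minimum inter-nucleus gap of 4 voxels. "Well-separated" is only
  meaningful relative to the pipeline's smoothing scale: the gap must exceed
  the Gaussian support (2 × sigma = 4 voxels in-plane), otherwise adjacent
  nuclei merge after smoothing by construction. Watershed behaviour on
  touching objects is tested separately with purpose-built overlapping
  ellipsoid fixtures. Placement failure raises an error; it is never
  silent.
- **Neurites are axis-aligned integer tubes** (a Euclidean dilation of an
  integer centreline run along y or x). Axis alignment keeps fragment
  geometry voxel-exact, so a fragmentation series is not confounded by grid
  aliasing: `fragmentation_level = k` breaks a tube into k+1 identical
  pieces with the same total centreline length, separated by gaps wider
  than twice the tube radius so pieces never reconnect. The dilated volume
  grows slightly with k (each new piece adds two end caps) while the
  surface grows faster, so the surface-to-volume score is strictly
  non-decreasing in k.

What the generator does **not** emulate: optics (no PSF convolution,
photobleaching, or spectral bleed-through), irregular nucleus shapes and
chromatin texture, densely packed or overlapping nuclei, curved or
branching neurites, intensity gradients across the field, and autofluorescent
background structure. Passing tests therefore demonstrate the correctness of
the measurement chain — segmentation, classification, scoring, QC,
statistics — under controlled conditions, not the biological accuracy of
any particular threshold on real Operetta acquisitions, where thresholds
and windows must be calibrated to the instrument.

## Verification problem sizes

The test suite verifies filters against brute-force oracles on small
fixtures (9×9×5 convolution, 7×7×3 median, exhaustive zone/surface
checks), parameter recovery on 20-nucleus scenes over 20 seeds (exact in
the noise-free limit; count within 10% and percentages within 5 points at
noise = 10% of contrast), fragmentation monotonicity over 10 seeds ×
k ∈ {1, 2, 4, 8}, the exact Mann–Whitney null against full enumeration for
all group sizes ≤ 5, and a power handshake — GFAP fractions 0.40 vs 0.10,
10 sections per group, 100 cohort replicates on 12-nucleus scenes — that
requires p < 0.05 in at least 95 replicates. The acceptance script renders
10 sections per group at the generator's default field size. These sizes
were chosen so the whole verification runs in minutes on one CPU while
each check still has the power to fail.

## Known limitations

- The default Otsu thresholds presume each channel contains genuine signal;
  empty marker channels need fixed thresholds (see above).
- The watershed can merge nuclei whose separation is below the smoothing
  scale or split strongly non-convex nuclei; `min_seed_distance_vox` trades
  one failure mode against the other.
- The fragmentation score conflates thinning with fragmentation: any change
  that raises surface at fixed volume raises the score. On real data it
  should be read as a relative, within-study index, not an absolute count
  of fragments.
- Exact Mann–Whitney p-values are used only for tie-free samples with
  n_a × n_b ≤ 400; larger or tied samples use the tie-corrected normal
  approximation, and the method used is recorded in every comparison.
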