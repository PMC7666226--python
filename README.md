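# organoid-profiler

Quantitative immunofluorescence profiling of midbrain-organoid sections.

Midbrain organoids differentiated from patient-derived iPSCs are stained for
cell-type markers — Hoechst (nuclei), TH (dopaminergic neurons), GFAP and
S100β (astrocytes), Tuj1 (pan-neuronal) — sectioned at 50 µm, and imaged as
confocal z-stacks. This package turns those multi-channel 3D stacks into a
small per-section feature vector and compares experimental groups, for
researchers who need reproducible, scriptable quantification of astrocyte
abundance and dopaminergic neurite degeneration in organoid models of
Parkinson's disease.

## The analysis

Per section, the pipeline computes:

| feature | definition |
| --- | --- |
| `n_cells` | nuclei segmented from the Hoechst channel (Gaussian smoothing → threshold → distance-transform-seeded watershed), after removing nuclei larger than 10,000 voxels (strictly greater; a nucleus of exactly 10,000 is kept) |
| `nuclear_pixels` | sum of Hoechst-positive voxels (median filter + threshold) |
| `gfap_percentage`, `s100b_percentage` | % of cells positive for the marker: around each retained nucleus a perinuclear zone is built (Euclidean dilation by *w* voxels minus all nuclei, contested voxels to the nearer nucleus); a cell is positive when at least 1% of its zone (inclusive) lies in the marker mask |
| `tuj1_pixels` | sum of Tuj1-mask voxels |
| `th_fragmentation` | surface-to-volume ratio of the TH mask, S/V = \|M \ erode(M)\| / \|M\| with a 6-connected structuring element; a solid a×b×c cuboid scores 1 − (a−2)(b−2)(c−2)/(abc), and more fragmented neurites of the same volume score higher |

Sections with `nuclear_pixels` strictly below 5000 are removed by QC.
Groups are compared per feature with the two-sided Mann–Whitney U test
(exact permutation null for small tie-free samples, normal approximation
with tie correction otherwise), one data point per passed section by
default, or per-organoid means.

A synthetic-scene renderer (`synthetic_organoid`) generates organoid-like
sections — ellipsoidal nuclei, perinuclear marker shells, tubular neurites
with a controllable number of breaks, Gaussian/Poisson noise — with exact
ground truth, so every stage is verifiable without raw microscope data.

## Worked example

```python
import organoid_profiler as op

spec = op.SyntheticSceneSpec(seed=7, n_nuclei=20, noise_sd=0.0,
                             marker_positive_fraction={op.GFAP: 0.4},
                             n_neurites={op.TH: 1, op.TUJ1: 1})
stack, truth = op.render_scene(spec)
feat = op.extract_section_features(op.SectionRecord("org1", "H", 0, stack))
print(feat.n_cells, feat.gfap_percentage, round(feat.th_fragmentation, 3))
```

prints

```
20 65.0 0.802
```

— all 20 rendered nuclei are recovered, the GFAP-positive percentage matches
the seeded draw exactly (13 of 20 cells), and the single intact TH neurite
scores a fragmentation ratio of 0.802 (a thin tube is mostly surface; what matters is
that breaking the same tube into more pieces never lowers the score).

From the shell:

```sh
organoid-profiler simulate --spec cohort.yaml --out images/
organoid-profiler run --config config.yaml --images images/ --out results/
organoid-profiler stats --features results/features.csv --group-col line_id
```

`run` writes `features.csv` (one row per section), `qc_report.json`, and
`comparisons.csv` (pairwise Mann–Whitney results per feature).

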