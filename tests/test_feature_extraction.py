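"""Perinuclear classification, pixel sums, and the fragmentation score."""

import math

import numpy as np
import pytest

import organoid_profiler as op
from organoid_profiler.config import MarkerConfig
from organoid_profiler.feature_extraction import (
    PerinuclearZone,
    build_perinuclear_zones,
    classify_positive_cells,
    hoechst_pixel_sum,
    marker_pixel_sum,
    percent_positive,
    th_fragmentation,
)
from organoid_profiler.marker_segmentation import MarkerMask, make_marker_mask
from organoid_profiler.nuclei_segmentation import NucleiLabelMap


def _label_map(labels):
    labels = np.asarray(labels, dtype=np.int32)
    labs, counts = np.unique(labels, return_counts=True)
    sizes = {int(l): int(c) for l, c in zip(labs, counts) if l > 0}
    return NucleiLabelMap(labels=labels, sizes=sizes)


def _mask(mask, role=op.GFAP):
    mask = np.asarray(mask, dtype=bool)
    return MarkerMask(role=role, mask=mask, positive_voxels=int(mask.sum()))


def brute_force_zones(labels, ring_width):
    """Exhaustive perinuclear zones: per-voxel distance to every nucleus's
    voxel set, nearest nucleus wins, exact ties to the lower label."""
    lab = np.asarray(labels)
    nuclei = {l: np.argwhere(lab == l) for l in np.unique(lab) if l > 0}
    zones = {l: set() for l in nuclei}
    for idx in np.argwhere(lab == 0):
        best = (np.inf, None)
        for l in sorted(nuclei):
            d = np.sqrt(((nuclei[l] - idx) ** 2).sum(axis=1)).min()
            if d < best[0]:  # strict: ties keep the lower label
                best = (d, l)
        if best[1] is not None and best[0] <= ring_width:
            zones[best[1]].add(tuple(idx))
    return {l: v for l, v in zones.items() if v}


def brute_force_surface(mask, connectivity):
    """A mask voxel is surface iff any structuring-element neighbour is
    outside the mask (volume border counts as outside)."""
    m = np.asarray(mask, dtype=bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    surface = np.zeros_like(m)
    for idx in np.argwhere(m):
        for off in offsets:
            n = idx + off
            if np.any(n < 0) or np.any(n >= np.array(m.shape)) or not m[tuple(n)]:
                surface[tuple(idx)] = True
                break
    return surface


class TestPixelSums:
    def test_empty_mask_sums_to_zero(self):
        assert marker_pixel_sum(_mask(np.zeros((2, 4, 4)))) == 0

    def test_additive_over_disjoint_masks(self, rng):
        a = np.zeros((3, 6, 6), dtype=bool)
        b = np.zeros((3, 6, 6), dtype=bool)
        a[0] = rng.random((6, 6)) > 0.5
        b[2] = rng.random((6, 6)) > 0.5
        assert marker_pixel_sum(_mask(a | b)) == marker_pixel_sum(_mask(a)) + marker_pixel_sum(_mask(b))

    def test_matches_exhaustive_count(self, rng):
        m = rng.random((4, 7, 7)) > 0.6
        count = sum(1 for idx in np.ndindex(m.shape) if m[idx])
        assert marker_pixel_sum(_mask(m)) == count

    def test_hoechst_sum_requires_hoechst_mask(self, rng):
        stack = op.ImageStack(rng.random((2, 4, 4, 1)), (op.HOECHST,))
        with pytest.raises(ValueError, match="HOECHST"):
            hoechst_pixel_sum(stack, _mask(np.zeros((2, 4, 4)), role=op.TH))

    def test_hoechst_sum_on_clean_scene_equals_truth(self, clean_scene):
        stack, truth = clean_scene
        mask = make_marker_mask(
            stack, op.HOECHST, window_vox=(1, 1, 1),
            threshold_method="fixed", fixed_threshold=550.0,
        )
        assert hoechst_pixel_sum(stack, mask) == truth.nuclei_voxel_total


class TestPerinuclearZones:
    def test_single_voxel_nucleus_ring_one_has_six_faces(self):
        lab = np.zeros((5, 5, 5), dtype=np.int32)
        lab[2, 2, 2] = 1
        zones = build_perinuclear_zones(_label_map(lab), ring_width_vox=1)
        assert len(zones) == 1
        assert zones[0].zone_area == 6  # Euclidean distance 1: face neighbours only

    def test_matches_brute_force_on_random_blobs(self, rng):
        lab = np.zeros((4, 9, 9), dtype=np.int32)
        lab[1:3, 1:3, 1:3] = 1
        lab[1:3, 5:8, 5:8] = 2
        lab[0, 7, 1] = 3
        for ring in (1, 2):
            zones = build_perinuclear_zones(_label_map(lab), ring_width_vox=ring)
            oracle = brute_force_zones(lab, ring)
            got = {z.nucleus_label: set(zip(*z.zone_voxels)) for z in zones}
            assert got == oracle

    def test_distance_tie_goes_to_lower_label(self):
        lab = np.zeros((1, 1, 7), dtype=np.int32)
        lab[0, 0, 1] = 1
        lab[0, 0, 5] = 2
        zones = {z.nucleus_label: z for z in build_perinuclear_zones(_label_map(lab), 2)}
        # voxel x=3 is exactly 2 from both nuclei -> label 1
        assert (0, 0, 3) in set(zip(*zones[1].zone_voxels))
        assert (0, 0, 3) not in set(zip(*zones[2].zone_voxels))

    def test_far_nuclei_have_disjoint_zones_that_avoid_nuclei(self):
        lab = np.zeros((3, 12, 12), dtype=np.int32)
        lab[1, 2, 2] = 1
        lab[1, 9, 9] = 2
        zones = build_perinuclear_zones(_label_map(lab), ring_width_vox=2)
        sets = [set(zip(*z.zone_voxels)) for z in zones]
        assert sets[0].isdisjoint(sets[1])
        nuclei = {(1, 2, 2), (1, 9, 9)}
        assert nuclei.isdisjoint(sets[0] | sets[1])

    def test_empty_label_map_gives_no_zones(self):
        lm = NucleiLabelMap(labels=np.zeros((2, 3, 3), dtype=np.int32), sizes={})
        assert build_perinuclear_zones(lm, 2) == []


class TestClassification:
    def _zone(self, area, label=1):
        coords = np.unravel_index(np.arange(area), (1, 20, 20))
        return PerinuclearZone(nucleus_label=label, zone_voxels=coords, zone_area=area)

    def _mask_with_first_n(self, n):
        mask = np.zeros((1, 20, 20), dtype=bool)
        coords = np.unravel_index(np.arange(n), (1, 20, 20))
        mask[coords] = True
        return _mask(mask)

    def test_exactly_one_percent_is_positive(self):
        zone = self._zone(200)
        assert classify_positive_cells([zone], self._mask_with_first_n(2), 0.01) == {1}

    def test_below_one_percent_is_negative(self):
        zone = self._zone(200)
        assert classify_positive_cells([zone], self._mask_with_first_n(1), 0.01) == set()

    def test_empty_mask_no_positive_cells(self):
        zones = [self._zone(50, label=1), self._zone(80, label=2)]
        assert classify_positive_cells(zones, self._mask_with_first_n(0), 0.01) == set()


class TestPercentPositive:
    @pytest.mark.parametrize(
        "positive, n, expected", [({1, 2, 3, 4, 5, 6, 7, 8}, 20, 40.0), (set(), 20, 0.0)]
    )
    def test_simple_arithmetic(self, positive, n, expected):
        assert percent_positive(positive, n) == expected

    def test_zero_cells_is_undefined(self):
        assert math.isnan(percent_positive(set(), 0))

    def test_excess_positive_is_an_internal_error(self):
        with pytest.raises(ValueError, match="exceed"):
            percent_positive({1, 2, 3}, 2)


class TestFragmentation:
    def test_single_voxel_is_all_surface(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        assert th_fragmentation(_mask(m)) == 1.0

    @pytest.mark.parametrize("dims", [(3, 3, 3), (3, 4, 5), (10, 10, 10), (4, 7, 12)])
    def test_cuboid_closed_form_six_connectivity(self, dims):
        a, b, c = dims
        m = np.zeros((a + 2, b + 2, c + 2), dtype=bool)
        m[1 : 1 + a, 1 : 1 + b, 1 : 1 + c] = True
        expected = 1 - (a - 2) * (b - 2) * (c - 2) / (a * b * c)
        assert th_fragmentation(_mask(m), 6) == pytest.approx(expected, abs=1e-12)

    def test_ten_cube_gives_0_488(self):
        m = np.ones((10, 10, 10), dtype=bool)
        assert th_fragmentation(_mask(m), 6) == pytest.approx(0.488, abs=1e-12)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_surface(self, rng, connectivity):
        blob = rng.random((5, 8, 8)) > 0.55
        got = th_fragmentation(_mask(blob), connectivity)
        surface = brute_force_surface(blob, connectivity)
        assert got == pytest.approx(surface.sum() / blob.sum(), abs=1e-12)

    def test_empty_mask_is_undefined(self):
        assert math.isnan(th_fragmentation(_mask(np.zeros((2, 3, 3)))))

    def test_more_fragments_never_lower_score(self):
        for seed in range(10):
            scores = []
            for level in (0, 1, 3, 7):
                spec = op.SyntheticSceneSpec(
                    seed=seed, n_nuclei=0, noise_sd=0.0, n_neurites={op.TH: 1},
                    marker_positive_fraction={}, fragmentation_level=level,
                )
                _, truth = op.render_scene(spec)
                scores.append(th_fragmentation(_mask(truth.neurite_mask[op.TH], op.TH)))
            assert all(s1 <= s2 for s1, s2 in zip(scores, scores[1:]))


class TestExtractSectionFeatures:
    def test_clean_scene_ground_truth_recovery(self, clean_scene, fixed_threshold_config):
        stack, truth = clean_scene
        cfg = fixed_threshold_config
        cfg.marker_overrides[op.TUJ1] = MarkerConfig(
            window_vox=(1, 1, 1), threshold_method="fixed", fixed_threshold=550.0
        )
        rec = op.SectionRecord("o1", "H", 0, stack)
        feat = op.extract_section_features(rec, cfg)
        assert feat.n_cells == truth.n_nuclei
        true_pct = 100 * len(truth.positive_cells[op.GFAP]) / truth.n_nuclei
        assert feat.gfap_percentage == true_pct
        assert feat.tuj1_pixels == truth.neurite_mask[op.TUJ1].sum()
        assert math.isnan(feat.s100b_percentage)  # channel absent from the scene

    def test_all_background_stack(self):
        voxels = np.zeros((3, 16, 16, 1))
        stack = op.ImageStack(voxels, (op.HOECHST,))
        feat = op.extract_section_features(op.SectionRecord("o", "H", 0, stack))
        assert feat.nuclear_pixels == 0
        assert feat.n_cells == 0
        assert feat.qc_pass is None  # QC decided downstream

    def test_extraction_is_deterministic(self, clean_scene, fixed_threshold_config):
        stack, _ = clean_scene
        rec = op.SectionRecord("o1", "H", 0, stack)
        f1 = op.extract_section_features(rec, fixed_threshold_config)
        f2 = op.extract_section_features(rec, fixed_threshold_config)
        assert f1 == f2
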