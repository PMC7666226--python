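"""Per-section feature extraction: marker pixel sums, perinuclear
percent-positive classification, the TH fragmentation score, and the Hoechst
pixel sum.

The per-cell positivity rule: around every successfully segmented nucleus a
perinuclear zone is built (Euclidean dilation by ``ring_width_vox`` voxels
minus all nucleus voxels, contested voxels going to the nearer nucleus, ties
to the lower label).  A cell is positive for a marker when at least
``min_positive_fraction`` (default 1%, inclusive) of its zone lies inside the
marker mask.

The fragmentation score of a binary mask is its surface-to-volume ratio:
surface voxels are the mask minus its erosion by the chosen structuring
element (6-connected by default, 26-connected optional), and the score is
|surface| / |mask|, in (0, 1] for any non-empty mask.  More fragmented
structures of the same total volume expose more surface and score higher.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import PipelineConfig
from .image_io import (
    GFAP,
    HOECHST,
    S100B,
    TH,
    TUJ1,
    ImageIOError,
    ImageStack,
    SectionRecord,
)
from .marker_segmentation import MarkerMask, make_marker_mask
from .nuclei_segmentation import (
    NucleiLabelMap,
    filter_large_nuclei,
    preprocess_hoechst,
    segment_nuclei,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage, wrapping the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #


@dataclass
class PerinuclearZone:
    """Ring of voxels around one nucleus, disjoint from every nucleus."""

    nucleus_label: int
    #: Voxel coordinates as a (z_idx, y_idx, x_idx) index-array triple.
    zone_voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    zone_area: int

    def __post_init__(self) -> None:
        if self.zone_area != len(self.zone_voxels[0]):
            raise ValueError("zone_area inconsistent with zone_voxels")


@dataclass
class SectionFeatures:
    """The extracted feature vector for one organoid section.

    Percentages are in [0, 100]; a feature is ``nan`` when undefined (the
    corresponding channel is absent, the mask is empty for the fragmentation
    score, or no cells were segmented for a percentage).  ``qc_pass`` is
    ``None`` until the QC gate has been applied.
    """

    organoid_id: str
    line_id: str
    section_index: int
    n_cells: int
    nuclear_pixels: int
    gfap_percentage: float
    s100b_percentage: float
    tuj1_pixels: float
    th_fragmentation: float
    qc_pass: bool | None = None
    provenance: dict = field(default_factory=dict, repr=False)


# --------------------------------------------------------------------------- #
# Pixel sums
# --------------------------------------------------------------------------- #


def marker_pixel_sum(mask: MarkerMask) -> int:
    """Sum of positive voxels of a marker mask."""
    return int(mask.positive_voxels)


def hoechst_pixel_sum(stack: ImageStack, hoechst_mask: MarkerMask) -> int:
    """Sum of Hoechst-positive voxels (the QC and 'nuclear pixels' quantity).

    The mask must come from the Hoechst channel under the same
    median-filter-and-threshold contract as the marker masks, so QC is
    independent of watershed quality.
    """
    if hoechst_mask.role != HOECHST:
        raise ValueError(f"expected a HOECHST mask, got {hoechst_mask.role}")
    if hoechst_mask.mask.shape != stack.shape_zyx:
        raise ValueError("mask not aligned to stack")
    return int(hoechst_mask.positive_voxels)


# --------------------------------------------------------------------------- #
# Perinuclear zones and classification
# --------------------------------------------------------------------------- #


def build_perinuclear_zones(
    labels: NucleiLabelMap, ring_width_vox: int = 2
) -> list[PerinuclearZone]:
    """One perinuclear zone per retained nucleus.

    A zone is the Euclidean dilation of its nucleus by ``ring_width_vox``
    minus all nucleus voxels.  A voxel within reach of two nuclei goes to the
    nearer one; exact distance ties go to the lower label.  A nucleus whose
    zone would be empty (fully crowded out) is skipped and logged rather than
    classified with a zero denominator.
    """
    if ring_width_vox < 1:
        raise ValueError("ring_width_vox must be >= 1")
    lab = labels.labels
    if labels.n_labels == 0:
        return []
    nuclei_mask = lab > 0
    best_dist = np.full(lab.shape, np.inf)
    best_label = np.zeros(lab.shape, dtype=np.int32)

    pad = int(ring_width_vox) + 1
    objects = ndi.find_objects(lab)
    for idx, sl in enumerate(objects):
        if sl is None:
            continue
        label = idx + 1
        window = tuple(
            slice(max(0, s.start - pad), min(dim, s.stop + pad))
            for s, dim in zip(sl, lab.shape)
        )
        local = lab[window] == label
        d = ndi.distance_transform_edt(~local)
        # strict < keeps the earlier (lower) label on exact distance ties
        take = (d > 0) & (d <= ring_width_vox) & (d < best_dist[window])
        bd, bl = best_dist[window], best_label[window]
        bd[take] = d[take]
        bl[take] = label
        best_dist[window] = bd
        best_label[window] = bl

    best_label[nuclei_mask] = 0
    zones: list[PerinuclearZone] = []
    for label in sorted(labels.sizes):
        coords = np.nonzero(best_label == label)
        area = len(coords[0])
        if area == 0:
            logger.warning("nucleus %d has an empty perinuclear zone; excluded", label)
            continue
        zones.append(
            PerinuclearZone(nucleus_label=label, zone_voxels=coords, zone_area=area)
        )
    return zones


def classify_positive_cells(
    zones: list[PerinuclearZone], mask: MarkerMask, min_fraction: float = 0.01
) -> set[int]:
    """Labels of cells whose perinuclear zone is at least ``min_fraction``
    inside the marker mask (inclusive bound: exactly 1% of the area counts)."""
    positive: set[int] = set()
    for zone in zones:
        if zone.zone_area == 0:
            logger.warning(
                "nucleus %d has zone_area 0; excluded from classification",
                zone.nucleus_label,
            )
            continue
        count = int(np.count_nonzero(mask.mask[zone.zone_voxels]))
        # division form: count/area rounds to the same double as the literal
        # fraction at the boundary, keeping the inclusive rule exact
        if count / zone.zone_area >= min_fraction:
            positive.add(zone.nucleus_label)
    return positive


def percent_positive(positive: set[int], n_cells: int) -> float:
    """100 × |positive| / n_cells; ``nan`` when there are no cells."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if len(positive) > n_cells:
        raise ValueError(
            f"{len(positive)} positive cells exceed n_cells={n_cells}"
        )
    if n_cells == 0:
        return math.nan
    return 100.0 * len(positive) / n_cells


# --------------------------------------------------------------------------- #
# Fragmentation score
# --------------------------------------------------------------------------- #

def th_fragmentation(mask: MarkerMask, surface_connectivity: int = 6) -> float:
    """Surface-to-volume ratio of a binary mask.

    Surface voxels are ``mask & ~erosion(mask)`` with a 6-connected (face
    neighbours) or 26-connected (full cube) structuring element; voxels at the
    volume border count as surface.  Returns ``nan`` for an empty mask.  For a
    solid a×b×c cuboid under 6-connectivity the score is the closed form
    ``1 - (a-2)(b-2)(c-2)/(abc)`` (clamping negative factors at 0).
    """
    if surface_connectivity not in (6, 26):
        raise ValueError("surface_connectivity must be 6 or 26")
    m = np.asarray(mask.mask, dtype=bool)
    volume = int(np.count_nonzero(m))
    if volume == 0:
        return math.nan
    struct = ndi.generate_binary_structure(3, 1 if surface_connectivity == 6 else 3)
    eroded = ndi.binary_erosion(m, structure=struct, border_value=0)
    surface = int(np.count_nonzero(m & ~eroded))
    return surface / volume


# --------------------------------------------------------------------------- #
# Section-level composition
# --------------------------------------------------------------------------- #


def extract_section_features(
    record: SectionRecord, config: PipelineConfig | None = None
) -> SectionFeatures:
    """Run the full per-section pipeline and assemble the feature vector.

    Stages: Gaussian preprocess → threshold + watershed → size filter →
    marker masks → perinuclear zones → positivity classification → features.
    Deterministic for a fixed record and config.  Features whose channel is
    absent from the stack are ``nan``.
    """
    if config is None:
        config = PipelineConfig()
    stack = record.stack
    if not stack.has_role(HOECHST):
        raise ImageIOError("pipeline requires a HOECHST channel")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ImageIOError, ValueError) as exc:
            raise PipelineStageError(name, exc) from exc

    smoothed = stage("preprocess_hoechst", preprocess_hoechst, stack, config.nuclei.sigma_vox)
    label_map = stage(
        "segment_nuclei",
        segment_nuclei,
        smoothed,
        threshold_method=config.nuclei.threshold_method,
        fixed_threshold=config.nuclei.fixed_threshold,
        use_watershed=config.nuclei.watershed,
        min_seed_distance_vox=config.nuclei.min_seed_distance_vox,
    )
    label_map = stage(
        "filter_large_nuclei", filter_large_nuclei, label_map, config.nuclei.max_nucleus_size_vox
    )
    n_cells = label_map.n_labels

    def mask_for(role: str) -> MarkerMask:
        mc = config.marker_config(role)
        return stage(
            f"make_marker_mask[{role}]",
            make_marker_mask,
            stack,
            role,
            window_vox=mc.window_vox,
            threshold_method=mc.threshold_method,
            fixed_threshold=mc.fixed_threshold,
        )

    hoechst_mask = mask_for(HOECHST)
    nuclear_pixels = hoechst_pixel_sum(stack, hoechst_mask)

    zones = stage("build_perinuclear_zones", build_perinuclear_zones, label_map, config.ring_width_vox)

    def percent_for(role: str) -> float:
        if not stack.has_role(role):
            return math.nan
        positive = classify_positive_cells(
            zones, mask_for(role), config.min_positive_fraction
        )
        return percent_positive(positive, n_cells)

    gfap_pct = percent_for(GFAP)
    s100b_pct = percent_for(S100B)

    tuj1_pixels = (
        float(marker_pixel_sum(mask_for(TUJ1))) if stack.has_role(TUJ1) else math.nan
    )
    th_frag = (
        th_fragmentation(mask_for(TH), config.surface_connectivity)
        if stack.has_role(TH)
        else math.nan
    )

    provenance = {
        "nuclei": dict(label_map.provenance),
        "hoechst_mask": dict(hoechst_mask.provenance),
        "ring_width_vox": config.ring_width_vox,
        "min_positive_fraction": config.min_positive_fraction,
        "surface_connectivity": config.surface_connectivity,
    }
    return SectionFeatures(
        organoid_id=record.organoid_id,
        line_id=record.line_id,
        section_index=record.section_index,
        n_cells=n_cells,
        nuclear_pixels=nuclear_pixels,
        gfap_percentage=gfap_pct,
        s100b_percentage=s100b_pct,
        tuj1_pixels=tuj1_pixels,
        th_fragmentation=th_frag,
        provenance=provenance,
    )
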