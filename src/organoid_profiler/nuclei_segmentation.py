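"""Hoechst nuclei segmentation: Gaussian preprocessing, thresholding,
watershed splitting of touching nuclei, and the 10,000-voxel size filter.

The segmentation contract: smooth the raw Hoechst channel with a Gaussian,
binarise (Otsu by default, fixed threshold as an alternative), split the
connected foreground with a watershed seeded from local maxima of the
Euclidean distance transform, then remove nuclei strictly larger than
``max_nucleus_size_vox`` voxels.  The size bound uses a strict inequality:
a nucleus of exactly the bound is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .image_io import HOECHST, ImageIOError, ImageStack

logger = logging.getLogger(__name__)


@dataclass
class NucleiLabelMap:
    """Integer-labelled nuclei aligned to the source stack.

    ``labels`` uses 0 for background and positive consecutive integers for
    nuclei; ``sizes`` maps each label to its exact voxel count; ``provenance``
    records the parameters that produced the map.
    """

    labels: np.ndarray
    sizes: dict[int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")

    @property
    def n_labels(self) -> int:
        return len(self.sizes)

    def recompute_sizes(self) -> dict[int, int]:
        """Exact voxel counts from the label volume (consistency oracle)."""
        labs, counts = np.unique(self.labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts) if l > 0}


def default_sigma(stack: ImageStack, sigma_inplane: float = 2.0) -> tuple[float, float, float]:
    """Nucleus-scale smoothing: ``sigma_inplane`` voxels in y/x, with the z
    component scaled by voxel anisotropy so the physical smoothing length is
    isotropic (capped below at 0.5 voxel so thin stacks keep z detail)."""
    vz, vy, vx = stack.voxel_size_um
    inplane_um = sigma_inplane * (vy + vx) / 2.0
    return (max(0.5, inplane_um / vz), sigma_inplane, sigma_inplane)


def preprocess_hoechst(
    stack: ImageStack, sigma_vox: tuple[float, float, float] | None = None
) -> np.ndarray:
    """Gaussian-smooth the raw Hoechst channel.

    Linear, shape-preserving, and non-negative; a constant volume is returned
    unchanged because the kernel is normalised.
    """
    if not stack.has_role(HOECHST):
        raise ImageIOError("stack has no HOECHST channel")
    if sigma_vox is None:
        sigma_vox = default_sigma(stack)
    if any(s <= 0 for s in sigma_vox):
        raise ValueError(f"sigma_vox must be > 0, got {sigma_vox}")
    channel = stack.channel(HOECHST).astype(np.float64)
    out = ndi.gaussian_filter(channel, sigma=sigma_vox, mode="reflect")
    return np.clip(out, 0.0, None)


def segment_nuclei(
    smoothed: np.ndarray,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    use_watershed: bool = True,
    min_seed_distance_vox: float = 5.0,
) -> NucleiLabelMap:
    """Binarise the smoothed Hoechst volume and label nuclei.

    With the watershed on, touching nuclei whose distance-transform maxima are
    at least ``min_seed_distance_vox`` apart receive distinct labels; with it
    off, each connected foreground component is one label.  An all-background
    volume yields an empty (valid) label map.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        lo, hi = float(smoothed.min()), float(smoothed.max())
        thr = np.inf if lo == hi else float(threshold_otsu(smoothed))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    fg = smoothed >= thr
    provenance = {
        "threshold_method": threshold_method,
        "threshold": None if np.isinf(thr) else thr,
        "watershed": bool(use_watershed),
        "min_seed_distance_vox": float(min_seed_distance_vox),
    }
    if not fg.any():
        return NucleiLabelMap(
            labels=np.zeros(smoothed.shape, dtype=np.int32),
            sizes={},
            provenance=provenance,
        )

    if use_watershed:
        dist = ndi.distance_transform_edt(fg)
        # smooth the seed surface so plateau voxels of the discrete EDT do
        # not each spawn a seed inside one nucleus
        dist = ndi.gaussian_filter(dist, sigma=1.0)
        peaks = peak_local_max(
            dist,
            min_distance=max(1, int(round(min_seed_distance_vox))),
            labels=fg,
            exclude_border=False,
        )
        markers = np.zeros(smoothed.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        if markers.max() == 0:  # degenerate: no peak found, fall back
            labels, _ = ndi.label(fg)
        else:
            labels = watershed(-dist, markers, mask=fg)
    else:
        labels, _ = ndi.label(fg)

    labels, sizes = _compact(labels)
    return NucleiLabelMap(labels=labels, sizes=sizes, provenance=provenance)


def filter_large_nuclei(
    label_map: NucleiLabelMap, max_nucleus_size_vox: int = 10000
) -> NucleiLabelMap:
    """Remove nuclei strictly larger than ``max_nucleus_size_vox`` voxels.

    A nucleus of exactly the bound is retained.  Remaining labels are
    compacted to consecutive integers; the removal count is recorded in the
    provenance.  Idempotent.
    """
    labels = label_map.labels
    removed = [lab for lab, size in label_map.sizes.items() if size > max_nucleus_size_vox]
    if removed:
        labels = labels.copy()
        labels[np.isin(labels, removed)] = 0
        logger.info(
            "size filter removed %d nuclei (> %d voxels)", len(removed), max_nucleus_size_vox
        )
    labels, sizes = _compact(labels)
    provenance = dict(label_map.provenance)
    provenance.update(
        {
            "max_nucleus_size_vox": int(max_nucleus_size_vox),
            "n_removed_by_size": len(removed),
        }
    )
    return NucleiLabelMap(labels=labels, sizes=sizes, provenance=provenance)


def _compact(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel to consecutive positive integers and tally exact sizes."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    compacted = lut[labels]
    labs, counts = np.unique(compacted, return_counts=True)
    sizes = {int(l): int(c) for l, c in zip(labs, counts) if l > 0}
    return compacted, sizes
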