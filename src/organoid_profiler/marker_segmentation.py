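"""Marker-channel segmentation: median filtering and thresholding.

The same operator serves all marker channels (TH, GFAP, S100β, Tuj1) and the
Hoechst channel when a nuclear-pixel mask is needed: median-filter the raw
channel with a small odd window, then binarise with ``>=`` against an Otsu or
fixed threshold.  Window and threshold are recorded in the mask provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .image_io import ImageIOError, ImageStack


@dataclass
class MarkerMask:
    """Boolean voxel mask for one channel role."""

    role: str
    mask: np.ndarray
    positive_voxels: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.positive_voxels != int(np.count_nonzero(self.mask)):
            raise ValueError("positive_voxels inconsistent with mask")


def median_filter(
    channel: np.ndarray, window_vox: tuple[int, int, int] = (3, 3, 3)
) -> np.ndarray:
    """Median filter with reflect boundary handling.

    Each output voxel is the median of its ``window_vox`` neighbourhood; all
    window dimensions must be odd so the window is centred.
    """
    window_vox = tuple(int(w) for w in window_vox)
    if any(w < 1 or w % 2 == 0 for w in window_vox):
        raise ValueError(f"window dimensions must be odd and >= 1, got {window_vox}")
    channel = np.asarray(channel)
    if channel.ndim != len(window_vox):
        raise ValueError(
            f"window has {len(window_vox)} dims for a {channel.ndim}-d volume"
        )
    return ndi.median_filter(channel, size=window_vox, mode="reflect")


def make_marker_mask(
    stack: ImageStack,
    role: str,
    window_vox: tuple[int, int, int] = (3, 3, 3),
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> MarkerMask:
    """Median-filter one channel and binarise it into a marker mask.

    The mask is ``filtered >= threshold``, so mask positivity is monotone
    non-increasing in the threshold.  A constant channel under Otsu yields an
    empty mask (no contrast means no signal).
    """
    if not stack.has_role(role):
        raise ImageIOError(f"channel role {role!r} not present in stack")
    filtered = median_filter(stack.channel(role), window_vox)
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_method == "otsu":
        arr = np.asarray(filtered, dtype=np.float64)
        lo, hi = float(arr.min()), float(arr.max())
        thr = np.inf if lo == hi else float(threshold_otsu(arr))
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = np.asarray(filtered, dtype=np.float64) >= thr
    return MarkerMask(
        role=role,
        mask=mask,
        positive_voxels=int(np.count_nonzero(mask)),
        provenance={
            "window_vox": window_vox,
            "threshold_method": threshold_method,
            "threshold": None if np.isinf(thr) else thr,
        },
    )
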