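"""Reading and writing of multi-channel 3D image stacks and tabular outputs.

All volumes in this package use a single axis convention: ``(z, y, x, channel)``
with 0-based indexing.  Physical sections cut at 50 µm and imaged as confocal
z-stacks are represented directly; a 2D image is a z-depth-1 stack, so every
downstream operation is written once for 3D.

Voxel anisotropy is carried as metadata (``voxel_size_um``) but all pixel-count
features downstream are computed in voxel units, because the thresholds of the
analysis (nucleus size bound, Hoechst-sum QC gate) are defined in pixels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

# --------------------------------------------------------------------------- #
# Channel roles
# --------------------------------------------------------------------------- #

HOECHST = "HOECHST"  #: DNA dye marking nuclei; required for any pipeline run
TH = "TH"            #: tyrosine hydroxylase, dopaminergic neurons
GFAP = "GFAP"        #: glial fibrillary acidic protein, astrocytes
S100B = "S100B"      #: S100 beta, astrocytes
TUJ1 = "TUJ1"        #: class III beta-tubulin, pan-neuronal

#: Canonical ordering of the recognised channel roles.
CHANNEL_ROLES: tuple[str, ...] = (HOECHST, TH, GFAP, S100B, TUJ1)

#: Column order of the per-section feature table (identifiers first, then the
#: extracted features, then the QC flag).
FEATURE_COLUMNS: tuple[str, ...] = (
    "organoid_id",
    "line_id",
    "section_index",
    "n_cells",
    "nuclear_pixels",
    "gfap_percentage",
    "s100b_percentage",
    "tuj1_pixels",
    "th_fragmentation",
    "qc_pass",
)


class ImageIOError(ValueError):
    """Raised for malformed stacks, bad channel maps, or unreadable files."""


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #


@dataclass
class ImageStack:
    """A 3D multi-channel voxel volume with channel-role labels.

    Parameters
    ----------
    voxels
        Non-negative intensity array indexed ``(z, y, x, channel)``.
    channel_roles
        One role per channel, drawn from :data:`CHANNEL_ROLES`; each role
        appears at most once.
    voxel_size_um
        ``(z, y, x)`` physical spacing in micrometres; strictly positive.
    """

    voxels: np.ndarray
    channel_roles: tuple[str, ...]
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ImageIOError(
                f"voxels must be (z, y, x, channel); got ndim={self.voxels.ndim}"
            )
        if not np.issubdtype(self.voxels.dtype, np.number):
            raise ImageIOError(f"non-numeric pixel data: dtype={self.voxels.dtype}")
        self.channel_roles = tuple(self.channel_roles)
        if len(self.channel_roles) != self.voxels.shape[3]:
            raise ImageIOError(
                f"{len(self.channel_roles)} roles for {self.voxels.shape[3]} channels"
            )
        for role in self.channel_roles:
            if role not in CHANNEL_ROLES:
                raise ImageIOError(f"unknown channel role {role!r}")
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ImageIOError("duplicate channel roles")
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.all(np.isfinite(self.voxels)):
                raise ImageIOError("intensities must be finite")
            if np.any(self.voxels < 0):
                raise ImageIOError("intensities must be >= 0")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ImageIOError(f"voxel_size_um must be 3 positive values, got {self.voxel_size_um}")

    # -- accessors ---------------------------------------------------------- #

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` volume for one channel role."""
        if role not in self.channel_roles:
            raise ImageIOError(f"channel role {role!r} not present in stack")
        return self.voxels[..., self.channel_roles.index(role)]


@dataclass
class SectionRecord:
    """One imaged organoid section: identifiers plus its image stack."""

    organoid_id: str
    line_id: str
    section_index: int
    stack: ImageStack

    def __post_init__(self) -> None:
        if int(self.section_index) < 0:
            raise ImageIOError("section_index must be >= 0")
        self.section_index = int(self.section_index)


# --------------------------------------------------------------------------- #
# Axis normalisation
# --------------------------------------------------------------------------- #

_AXIS_ALIASES = {"S": "C"}  # tifffile sometimes reports samples as 'S'


def normalize_axes(array: np.ndarray, axes: str) -> np.ndarray:
    """Reorder ``array`` with axis labels ``axes`` into ``(z, y, x, channel)``.

    Missing Z or C axes are inserted with length 1.  Applying this to an
    already-normalised ``(z, y, x, c)`` array with ``axes="ZYXC"`` is the
    identity, so normalisation is involutive.
    """
    axes = "".join(_AXIS_ALIASES.get(a, a) for a in axes.upper())
    if len(axes) != array.ndim:
        raise ImageIOError(f"axes {axes!r} does not match ndim {array.ndim}")
    if "Y" not in axes or "X" not in axes:
        raise ImageIOError(f"axes {axes!r} must contain Y and X")
    for a in axes:
        if a not in "ZYXC":
            raise ImageIOError(f"unsupported axis {a!r} in {axes!r}")
    if "Z" not in axes:
        array = array[np.newaxis]
        axes = "Z" + axes
    if "C" not in axes:
        array = array[..., np.newaxis]
        axes = axes + "C"
    order = [axes.index(a) for a in "ZYXC"]
    return np.transpose(array, order)


# --------------------------------------------------------------------------- #
# Stack I/O
# --------------------------------------------------------------------------- #


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a TIFF, embedding roles and voxel size.

    The voxel array is stored bit-exactly in ``(z, y, x, channel)`` order with
    a JSON description carrying ``channel_roles`` and ``voxel_size_um``, so
    :func:`read_stack` round-trips losslessly without an explicit channel map.
    """
    meta = {
        "axes": "ZYXC",
        "channel_roles": list(stack.channel_roles),
        "voxel_size_um": list(stack.voxel_size_um),
    }
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    *,
    axes: str | None = None,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack and attach channel roles.

    Parameters
    ----------
    path
        TIFF file whose page/axis layout resolves to ``(z, y, x, channel)``
        after normalisation.
    channel_map
        Mapping role -> channel index in the file.  Must cover ``HOECHST``.
        May be omitted only for files written by :func:`write_stack`, whose
        embedded metadata then supplies the roles.
    axes
        Override the axis-order string if the file metadata is missing or
        wrong (letters from ``ZYXC``).
    voxel_size_um
        Override the physical voxel size; defaults to embedded metadata or
        ``(1, 1, 1)``.

    Returns
    -------
    ImageStack
        Channels reordered to the canonical role order, dtype preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        file_axes = axes if axes is not None else series.axes
        description = tif.pages[0].description or ""

    meta: dict = {}
    if description.lstrip().startswith("{"):
        try:
            meta = json.loads(description)
        except json.JSONDecodeError:
            meta = {}

    if axes is None and isinstance(meta.get("axes"), str):
        file_axes = meta["axes"]
    if not isinstance(file_axes, str) or any(
        a not in "ZYXCSQ" for a in file_axes.upper()
    ):
        file_axes = _guess_axes(data.ndim)
    file_axes = file_axes.upper().replace("Q", _guess_axes(data.ndim)[0])
    data = normalize_axes(data, file_axes)

    if not np.issubdtype(data.dtype, np.number):
        raise ImageIOError(f"non-numeric pixel data in {path}")

    if voxel_size_um is None:
        voxel_size_um = tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))

    if channel_map is None:
        roles = meta.get("channel_roles")
        if roles is None:
            raise ImageIOError(
                f"{path} has no embedded channel roles; pass channel_map"
            )
        channel_map = {role: i for i, role in enumerate(roles)}

    if HOECHST not in channel_map:
        raise ImageIOError("channel_map must cover HOECHST")
    n_channels = data.shape[3]
    for role, idx in channel_map.items():
        if role not in CHANNEL_ROLES:
            raise ImageIOError(f"unknown channel role {role!r}")
        if not 0 <= idx < n_channels:
            raise ImageIOError(
                f"channel index {idx} for {role} out of range (file has {n_channels})"
            )

    ordered = [r for r in CHANNEL_ROLES if r in channel_map]
    voxels = data[..., [channel_map[r] for r in ordered]]
    return ImageStack(voxels=voxels, channel_roles=tuple(ordered), voxel_size_um=voxel_size_um)


def _guess_axes(ndim: int) -> str:
    if ndim == 2:
        return "YX"
    if ndim == 3:
        return "ZYX"
    if ndim == 4:
        return "ZYXC"
    raise ImageIOError(f"cannot interpret a {ndim}-dimensional TIFF as a stack")


# --------------------------------------------------------------------------- #
# Feature tables
# --------------------------------------------------------------------------- #


def features_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert SectionFeatures records (dataclasses) to a tidy DataFrame."""
    if len(records) == 0:
        raise ImageIOError("no feature records to tabulate")
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec)
        rows.append({col: d.get(col) for col in FEATURE_COLUMNS})
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def write_features_table(records: Sequence, path: str | Path) -> None:
    """Write one CSV row per section with the deterministic column order.

    Floats are written with ``%.17g`` so a re-parsed table reproduces every
    numeric field to full precision.
    """
    frame = features_to_frame(records)
    frame.to_csv(Path(path), index=False, float_format="%.17g")


def read_features_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV produced by :func:`write_features_table`."""
    return pd.read_csv(Path(path), float_precision="round_trip")
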