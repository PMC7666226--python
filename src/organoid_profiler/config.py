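"""Pipeline configuration: every tunable parameter, with YAML round-trip.

Defaults follow the analysis contract: Gaussian smoothing of the Hoechst
channel before nuclei segmentation, watershed splitting of touching nuclei,
removal of nuclei larger than 10,000 voxels, median-filter marker masks,
a 2-voxel perinuclear ring read out with an inclusive 1% positivity rule,
and a Hoechst-sum QC gate at 5000.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


@dataclass
class NucleiConfig:
    """Parameters of Hoechst preprocessing, segmentation and size filtering."""

    #: Gaussian sigma per axis (z, y, x) in voxels; ``None`` means 2 voxels
    #: in-plane with the z component scaled by voxel anisotropy.
    sigma_vox: tuple[float, float, float] | None = None
    threshold_method: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float | None = None
    watershed: bool = True
    min_seed_distance_vox: float = 5.0
    #: Nuclei strictly larger than this many voxels are removed.
    max_nucleus_size_vox: int = 10000


@dataclass
class MarkerConfig:
    """Median-filter window and binarisation rule for one marker channel."""

    window_vox: tuple[int, int, int] = (3, 3, 3)
    threshold_method: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float | None = None


@dataclass
class PipelineConfig:
    """Full parameter set for one pipeline run."""

    nuclei: NucleiConfig = field(default_factory=NucleiConfig)
    #: Default marker segmentation parameters, applied to every channel role.
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    #: Per-role overrides, keyed by channel role name (e.g. ``"TH"``).
    marker_overrides: dict[str, MarkerConfig] = field(default_factory=dict)
    #: Perinuclear ring width in voxels (Euclidean dilation distance).
    ring_width_vox: int = 2
    #: A cell is positive when >= this fraction of its perinuclear zone is
    #: inside the marker mask (inclusive bound).
    min_positive_fraction: float = 0.01
    #: Sections with a Hoechst pixel sum strictly below this are removed.
    min_hoechst_sum: int = 5000
    #: Surface structuring-element connectivity for the fragmentation score.
    surface_connectivity: int = 6

    def marker_config(self, role: str) -> MarkerConfig:
        return self.marker_overrides.get(role, self.markers)

    # -- YAML round-trip ---------------------------------------------------- #

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        nuclei = NucleiConfig(**_tupled(data.pop("nuclei", {}), "sigma_vox"))
        markers = MarkerConfig(**_tupled(data.pop("markers", {}), "window_vox"))
        overrides = {
            role: MarkerConfig(**_tupled(sub, "window_vox"))
            for role, sub in data.pop("marker_overrides", {}).items()
        }
        return cls(nuclei=nuclei, markers=markers, marker_overrides=overrides, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _tupled(sub: Mapping, key: str) -> dict:
    # YAML has no tuples; convert list-valued fields back.
    out = dict(sub)
    if out.get(key) is not None:
        out[key] = tuple(out[key])
    return out
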