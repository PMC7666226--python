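"""Quality control, aggregation, and two-group Mann–Whitney comparison.

Sections whose Hoechst pixel sum falls strictly below the QC threshold
(default 5000) indicate failed staining or imaging and are removed before
analysis.  Passed sections are grouped by cell line; the analysis unit is the
section by default (each imaged section is one data point), with a
per-organoid mean as the alternative unit.  Two groups are compared with the
two-sided Mann–Whitney U test: exact permutation null for small tie-free
samples, normal approximation with tie correction otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .feature_extraction import SectionFeatures

logger = logging.getLogger(__name__)

#: Feature columns eligible for group comparison.
COMPARABLE_FEATURES = (
    "nuclear_pixels",
    "gfap_percentage",
    "s100b_percentage",
    "tuj1_pixels",
    "th_fragmentation",
)


@dataclass
class QCReport:
    """Outcome of the Hoechst-sum QC gate over a set of sections."""

    n_input_sections: int
    n_passed: int
    removed: list[tuple[str, int, int]]  # (organoid_id, section_index, hoechst_sum)
    threshold: int

    def __post_init__(self) -> None:
        if self.n_passed + len(self.removed) != self.n_input_sections:
            raise ValueError("QC accounting does not balance")

    def to_dict(self) -> dict:
        return {
            "n_input_sections": self.n_input_sections,
            "n_passed": self.n_passed,
            "threshold": self.threshold,
            "removed": [
                {"organoid_id": o, "section_index": s, "hoechst_sum": h}
                for o, s, h in self.removed
            ],
        }


@dataclass
class GroupComparison:
    """Two-sided Mann–Whitney comparison of one feature between two groups."""

    feature_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    direction: int  # sign of median(a) - median(b)
    method: str = "exact"

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n_a * self.n_b:
            raise ValueError("U statistic outside [0, n_a * n_b]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


# --------------------------------------------------------------------------- #
# QC gate
# --------------------------------------------------------------------------- #


def qc_filter(
    features: Sequence[SectionFeatures], min_hoechst_sum: int = 5000
) -> tuple[list[SectionFeatures], QCReport]:
    """Remove sections with a Hoechst pixel sum strictly below the threshold.

    A sum of exactly the threshold passes.  Every record's ``qc_pass`` flag is
    set; the report lists each removed section with its sum.  Idempotent on
    already-filtered input.
    """
    passed: list[SectionFeatures] = []
    removed: list[tuple[str, int, int]] = []
    for feat in features:
        ok = feat.nuclear_pixels >= min_hoechst_sum
        feat.qc_pass = bool(ok)
        if ok:
            passed.append(feat)
        else:
            removed.append((feat.organoid_id, feat.section_index, int(feat.nuclear_pixels)))
    report = QCReport(
        n_input_sections=len(features),
        n_passed=len(passed),
        removed=removed,
        threshold=int(min_hoechst_sum),
    )
    return passed, report


# --------------------------------------------------------------------------- #
# Aggregation
# --------------------------------------------------------------------------- #


def aggregate(
    features: Sequence[SectionFeatures],
    feature_name: str,
    unit: str = "section",
) -> dict[str, list[float]]:
    """Data points per group (``line_id``) for one feature.

    ``unit="section"`` yields one point per passed section (the default
    analysis unit); ``unit="organoid"`` yields the per-organoid mean of its
    passed sections.  Undefined (nan) feature values are dropped with a
    warning, as are groups left with no points.
    """
    if unit not in ("section", "organoid"):
        raise ValueError(f"unknown aggregation unit {unit!r}")
    by_group: dict[str, list[SectionFeatures]] = {}
    for feat in features:
        if feat.qc_pass is False:
            continue
        by_group.setdefault(feat.line_id, []).append(feat)

    out: dict[str, list[float]] = {}
    for group, feats in by_group.items():
        values: list[float] = []
        if unit == "section":
            pairs = [(f, getattr(f, feature_name)) for f in feats]
            for f, v in pairs:
                if isinstance(v, float) and math.isnan(v):
                    logger.warning(
                        "dropping undefined %s for %s section %d",
                        feature_name, f.organoid_id, f.section_index,
                    )
                    continue
                values.append(float(v))
        else:
            by_organoid: dict[str, list[float]] = {}
            for f in feats:
                v = getattr(f, feature_name)
                if isinstance(v, float) and math.isnan(v):
                    continue
                by_organoid.setdefault(f.organoid_id, []).append(float(v))
            values = [float(np.mean(vs)) for _, vs in sorted(by_organoid.items())]
        if not values:
            logger.warning("group %s has no usable data points; excluded", group)
            continue
        out[group] = values
    return out


# --------------------------------------------------------------------------- #
# Mann–Whitney U
# --------------------------------------------------------------------------- #

#: Largest n_a * n_b for which the exact permutation null is used.
EXACT_LIMIT = 400


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    feature_name: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two samples.

    The exact permutation distribution is used when the samples are tie-free
    and ``n_a * n_b <= 400``; otherwise the normal approximation with tie
    correction (and continuity correction) is used.  ``u_statistic`` is the U
    of the first sample; ``direction`` is the sign of the difference of
    medians.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is offered")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (not has_ties) and a.size * b.size <= EXACT_LIMIT
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = float(np.median(a) - np.median(b))
    return GroupComparison(
        feature_name=feature_name,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        direction=int(np.sign(direction)),
        method=method,
    )


def compare_groups(
    features: Sequence[SectionFeatures],
    feature_names: Iterable[str] = COMPARABLE_FEATURES,
    unit: str = "section",
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """All pairwise two-group comparisons for each requested feature.

    No multiple-testing adjustment is applied by default (per-feature
    unadjusted tests); ``bonferroni=True`` multiplies each p-value by the
    number of comparisons, capped at 1.
    """
    comparisons: list[GroupComparison] = []
    for name in feature_names:
        groups = aggregate(features, name, unit=unit)
        keys = sorted(groups)
        for i, ga in enumerate(keys):
            for gb in keys[i + 1 :]:
                comparisons.append(
                    mann_whitney(
                        groups[ga], groups[gb],
                        feature_name=name, group_a=ga, group_b=gb,
                    )
                )
    if bonferroni and comparisons:
        m = len(comparisons)
        for c in comparisons:
            c.p_value = min(1.0, c.p_value * m)
    return comparisons
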