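"""Lesion localization by atlas overlap.

A lesion mask registered to atlas space is intersected with an integer label
volume; per-class voxel counts (hemisphere, vascular territory, cortical
shell) are aggregated over all labels sharing the class, and a class counts as
affected when at least ``min_voxels`` lesion voxels (default 100) overlap it.
A subject whose lesion reaches the threshold in no class of a category falls
back to the maximal-overlap class and is flagged, rather than dropped, so the
cohort size is preserved and flagged rows can be excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import AtlasVolume, LesionMask, require_same_grid

__all__ = ["LocationProfile", "overlap_counts", "classify_location"]

DEFAULT_MIN_OVERLAP_VOXELS = 100


@dataclass(frozen=True)
class LocationProfile:
    """Per-subject lesion location classification.

    ``below_threshold`` names the categories ("hemisphere", "territory") whose
    assignment fell back to the argmax class because no class reached the
    overlap threshold.
    """

    hemisphere: str            # left | right | both
    territory: str             # left ICA | right ICA | basilar | multiple
    cortical_involved: bool
    overlap_counts: dict = field(repr=False)
    below_threshold: frozenset = frozenset()

    def as_dict(self) -> dict:
        return {
            "hemisphere": self.hemisphere,
            "territory": self.territory,
            "cortical_involved": self.cortical_involved,
            "bilateral": self.hemisphere == "both",
            "multiple_territories": self.territory == "multiple",
            "location_below_threshold": bool(self.below_threshold),
        }


def overlap_counts(mask: LesionMask, atlas: AtlasVolume) -> dict[int, int]:
    """Lesion voxel count per atlas label (every declared label reported)."""
    require_same_grid(mask, atlas, "lesion mask and atlas")
    hit = atlas.labels[mask.data]
    counts = np.bincount(hit, minlength=int(atlas.label_table["label"].max()) + 1)
    return {int(lab): int(counts[lab]) for lab in atlas.label_table["label"]}


def _class_counts(counts: dict[int, int], table, column: str) -> dict[str, int]:
    agg: dict[str, int] = {}
    for _, row in table.iterrows():
        key = row[column]
        agg[key] = agg.get(key, 0) + counts.get(int(row["label"]), 0)
    agg.pop("none", None)
    return agg


def classify_location(
    counts: dict[int, int],
    atlas: AtlasVolume,
    min_voxels: int = DEFAULT_MIN_OVERLAP_VOXELS,
) -> LocationProfile:
    """Apply the minimum-overlap rule to hemisphere, territory and cortex.

    A hemisphere/territory/cortical class is affected iff its aggregated count
    is >= ``min_voxels``. Hemisphere is "both" when both sides are affected;
    territory is "multiple" when two or more territories are affected.
    """
    if sum(counts.values()) == 0:
        raise ValueError("lesion has no overlap with any atlas label")
    table = atlas.label_table

    flags = set()

    def pick(category: str, class_counts: dict[str, int], multi_value: str):
        affected = [c for c, v in class_counts.items() if v >= min_voxels]
        if len(affected) >= 2:
            return multi_value
        if len(affected) == 1:
            return affected[0]
        flags.add(category)
        return max(class_counts, key=lambda c: (class_counts[c], c))

    hemisphere = pick("hemisphere", _class_counts(counts, table, "hemisphere"), "both")
    territory = pick("territory", _class_counts(counts, table, "territory"), "multiple")
    cortical_count = sum(
        counts.get(int(row["label"]), 0) for _, row in table.iterrows() if row["cortical"]
    )
    return LocationProfile(
        hemisphere=hemisphere,
        territory=territory,
        cortical_involved=cortical_count >= min_voxels,
        overlap_counts=dict(counts),
        below_threshold=frozenset(flags),
    )
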