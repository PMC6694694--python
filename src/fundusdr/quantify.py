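"""Pixel-level lesion quantification and group summaries.

Six indices per image: total area, region count and maximum region area,
for the hemorrhage family (microaneurysms + hemorrhages by default) and
the exudate family (exudates + cotton-wool spots).  Areas are raw pixel
counts.  Group summaries report the per-group n, sample mean and sample SD
(n-1 denominator) of each index — the inputs the one-way ANOVA in
:mod:`fundusdr.evaluation` consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ._exceptions import ContractError
from .config import RunConfig
from .core import BRIGHT_FAMILY, GroundTruth
from .lesions import LesionSet

INDEX_NAMES = (
    "hemorrhage_total_area_px",
    "hemorrhage_count",
    "hemorrhage_max_area_px",
    "exudate_total_area_px",
    "exudate_count",
    "exudate_max_area_px",
)


@dataclass
class QuantReport:
    image_id: str
    hemorrhage_total_area_px: int = 0
    hemorrhage_count: int = 0
    hemorrhage_max_area_px: int = 0
    exudate_total_area_px: int = 0
    exudate_count: int = 0
    exudate_max_area_px: int = 0

    def __post_init__(self) -> None:
        for family in ("hemorrhage", "exudate"):
            total = getattr(self, f"{family}_total_area_px")
            count = getattr(self, f"{family}_count")
            mx = getattr(self, f"{family}_max_area_px")
            if min(total, count, mx) < 0:
                raise ContractError("indices must be non-negative")
            if mx > total:
                raise ContractError("max area cannot exceed total area")
            if (count == 0) != (total == 0) or (count == 0) != (mx == 0):
                raise ContractError("count, total and max must vanish together")

    def values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INDEX_NAMES], dtype=np.float64)


@dataclass
class GroupSummary:
    label: str
    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ContractError("group summaries need n >= 2")
        if any(sd < 0 for sd in self.sds.values()):
            raise ContractError("SDs must be non-negative")

    def triple(self, index: str) -> tuple[int, float, float]:
        """(n, mean, sd) for one index — ANOVA input form."""
        return self.n, self.means[index], self.sds[index]


def _family_indices(areas: list[int]) -> tuple[int, int, int]:
    if not areas:
        return 0, 0, 0
    return int(sum(areas)), len(areas), int(max(areas))


def quantify(
    lesions: LesionSet, image_id: str = "", config: RunConfig | None = None
) -> QuantReport:
    """Compute the six indices from a detected :class:`LesionSet`.

    The hemorrhage family includes microaneurysm regions unless
    ``config.count_ma_in_hemorrhage_family`` is off; cotton-wool spots
    always count in the exudate family.  Repeated calls on the same set
    are bit-identical (quantification is a pure function of the masks).
    """
    cfg = config or RunConfig()
    red_classes = (
        ("microaneurysm", "hemorrhage") if cfg.count_ma_in_hemorrhage_family else ("hemorrhage",)
    )
    hem = _family_indices([r.area_px for r in lesions.of_class(*red_classes)])
    exu = _family_indices([r.area_px for r in lesions.of_class(*BRIGHT_FAMILY)])
    return QuantReport(image_id, *hem, *exu)


def quantify_truth(
    truth: GroundTruth, image_id: str = "", config: RunConfig | None = None
) -> QuantReport:
    """Same six indices computed from planted ground-truth regions."""
    cfg = config or RunConfig()
    red_classes = (
        ("microaneurysm", "hemorrhage") if cfg.count_ma_in_hemorrhage_family else ("hemorrhage",)
    )
    hem = _family_indices([r.pixel_area for r in truth.regions_of(*red_classes)])
    exu = _family_indices([r.pixel_area for r in truth.regions_of(*BRIGHT_FAMILY)])
    return QuantReport(image_id, *hem, *exu)


def summarize_groups(
    reports: list[QuantReport], assignment: dict[str, str]
) -> list[GroupSummary]:
    """Per-group sample mean and SD (n-1) of each index.

    ``assignment`` maps image_id to group label; every report must be
    assigned and every group must contain at least two images.
    """
    groups: dict[str, list[QuantReport]] = {}
    for rep in reports:
        if rep.image_id not in assignment:
            raise ContractError(f"report {rep.image_id!r} has no group assignment")
        groups.setdefault(assignment[rep.image_id], []).append(rep)

    summaries = []
    for label in sorted(groups):
        members = groups[label]
        if len(members) < 2:
            raise ContractError(f"group {label!r} has n={len(members)} < 2")
        data = np.stack([m.values() for m in members])
        means = data.mean(axis=0)
        sds = data.std(axis=0, ddof=1)
        summaries.append(
            GroupSummary(
                label,
                len(members),
                dict(zip(INDEX_NAMES, map(float, means))),
                dict(zip(INDEX_NAMES, map(float, sds))),
            )
        )
    return summaries
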