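"""Image-quality gating and decision-rule DR staging.

Quality: a photograph is disqualified when any of five measurements trips
its threshold — blur (low high-frequency energy), a large dark area, an
eyelash intruding over the field, overexposure, or a decentered field.
Thresholds were calibrated once on the seeded synthetic degradation suite
(``scripts/calibrate_quality.py``) and are frozen in the default config.

Staging is a first-match rule cascade over the lesion evidence, an
operationalization of the international severity scale for what is visible
on single non-mydriatic photographs: photocoagulation scars dominate, a
4-quadrant hemorrhage load or a large total red area means severe disease,
any hemorrhage or bright lesion means moderate, microaneurysms alone mean
mild.  Venous beading and IRMA are not assessable on such photographs, so
an area fallback supplements the quadrant-count rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import convex_hull_image

from ._exceptions import ContractError
from .anatomy import OpticDisc, QuadrantMap
from .config import RunConfig
from .core import FundusImage, RoiMask, Stage
from .lesions import LesionSet

QUALITY_FLAGS = ("fuzzy", "dark_area", "eyelash", "overexposed", "decentered")


@dataclass
class QualityReport:
    fuzzy_score: float
    dark_fraction: float
    saturated_fraction: float
    eyelash_score: float
    decenter_px: float
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = set(self.flags) - set(QUALITY_FLAGS)
        if unknown:
            raise ContractError(f"unknown quality flags {unknown}")
        for frac in (self.dark_fraction, self.saturated_fraction):
            if not 0 <= frac <= 1:
                raise ContractError("fractions must lie in [0, 1]")

    @property
    def qualified(self) -> bool:
        return not self.flags


@dataclass
class GradingResult:
    stage: Stage
    rule_path: list[str]
    evidence: dict

    def __post_init__(self) -> None:
        if not self.rule_path:
            raise ContractError("rule_path must be non-empty")


def assess_quality(
    image: FundusImage,
    roi: RoiMask,
    disc: OpticDisc,
    config: RunConfig | None = None,
) -> QualityReport:
    """Measure the five disqualification features and set their flags."""
    cfg = config or RunConfig()
    h, w = image.shape
    lum = image.pixels.astype(np.float64).mean(axis=2)
    m = ndimage.binary_erosion(roi.mask, iterations=3)

    # blur: energy of the Laplacian over the field
    lap = ndimage.laplace(ndimage.gaussian_filter(lum, 1.0))
    fuzzy_score = float(lap[m].std()) if m.any() else 0.0

    # dark areas and eyelashes carve themselves OUT of the adaptive ROI, so
    # measure them over the convex hull of the field instead
    hull = convex_hull_image(roi.mask) if roi.area_px else roi.mask
    hull_area = int(hull.sum())
    dark_fraction = float((lum[hull] < cfg.dark_luminance).mean()) if hull_area else 0.0
    saturated = (image.pixels >= cfg.saturated_level).any(axis=2)
    saturated_fraction = float(saturated[roi.mask].mean()) if roi.area_px else 0.0

    # eyelash: elongated dark intrusions crossing the field boundary
    eyelash_score = 0.0
    if hull_area:
        dark = (lum < cfg.dark_luminance) & hull
        border_ring = hull & ~ndimage.binary_erosion(hull, iterations=6)
        labeled, n = ndimage.label(dark)
        for prop in measure.regionprops(labeled):
            comp = labeled == prop.label
            if not (comp & border_ring).any():
                continue
            elongation = prop.axis_major_length / max(prop.axis_minor_length, 1.0)
            if elongation >= 2.5:
                eyelash_score += prop.area / hull_area

    # decentering: deviation of the field center from the frame center
    if hull_area:
        rows, cols = np.nonzero(hull)
        r0, c0 = float(rows.mean()), float(cols.mean())
    else:
        r0, c0 = h / 2, w / 2
    decenter_px = float(np.hypot(r0 - h / 2, c0 - w / 2))

    flags = set()
    if fuzzy_score < cfg.scaled(cfg.fuzzy_min_score, w, power=0):
        flags.add("fuzzy")
    if dark_fraction > cfg.dark_max_fraction:
        flags.add("dark_area")
    if eyelash_score > cfg.eyelash_max_score:
        flags.add("eyelash")
    if saturated_fraction > cfg.saturated_max_fraction:
        flags.add("overexposed")
    if decenter_px > cfg.scaled(cfg.decenter_max_px, w):
        flags.add("decentered")
    return QualityReport(
        fuzzy_score, dark_fraction, saturated_fraction, eyelash_score, decenter_px, flags
    )


def _quadrant_hemorrhage_counts(lesions: LesionSet, quadrants: QuadrantMap) -> dict[int, int]:
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for region in lesions.of_class("hemorrhage"):
        q = quadrants.quadrant_of(*region.centroid)
        counts[q] += 1
    return counts


def grade_dr(
    lesions: LesionSet,
    quadrants: QuadrantMap,
    quality: QualityReport,
    config: RunConfig | None = None,
) -> GradingResult:
    """First-match staging cascade.

    Order: quality gate, PRP scar pattern, severe disease (hemorrhage count
    reaching the per-quadrant threshold in all four quadrants, or total
    red-lesion area at/above the severe-area fallback), moderate (any
    hemorrhage or bright lesion), mild (microaneurysms only), else no DR.
    The experimental PDR rule (large confluent red area) only runs when
    enabled in config.
    """
    cfg = config or RunConfig()
    if lesions.shape != quadrants.labels.shape:
        raise ContractError("lesions and quadrants come from different images")

    w = lesions.shape[1]
    red_regions = lesions.of_class("microaneurysm", "hemorrhage")
    hem_regions = lesions.of_class("hemorrhage")
    bright_regions = lesions.of_class("exudate", "cottonwool")
    qcounts = _quadrant_hemorrhage_counts(lesions, quadrants)
    total_red_area = sum(r.area_px for r in red_regions)
    evidence = {
        "n_microaneurysm": len(lesions.of_class("microaneurysm")),
        "n_hemorrhage": len(hem_regions),
        "n_bright": len(bright_regions),
        "n_prp_scar": len(lesions.of_class("prp_scar")),
        "prp_positive": lesions.prp_positive,
        "total_red_area_px": total_red_area,
        "quadrant_hemorrhages": qcounts,
    }

    path: list[str] = []
    if not quality.qualified:
        path.append("quality_gate")
        return GradingResult(Stage.UNGRADABLE, path, evidence)
    path.append("quality_ok")

    if lesions.prp_positive:
        path.append("prp_pattern")
        return GradingResult(Stage.PRP, path, evidence)

    if cfg.pdr_mode:
        pdr_area = cfg.scaled(cfg.pdr_area_px, w, power=2)
        if any(r.area_px >= pdr_area for r in hem_regions):
            path.append("pdr_confluent_red")
            return GradingResult(Stage.PDR, path, evidence)

    severe_area = cfg.scaled(cfg.severe_red_area_px, w, power=2)
    if all(qcounts[q] >= cfg.hq_per_quadrant for q in (1, 2, 3, 4)):
        path.append("severe_4quadrant_hemorrhages")
        return GradingResult(Stage.DR3, path, evidence)
    if total_red_area >= severe_area:
        path.append("severe_red_area")
        return GradingResult(Stage.DR3, path, evidence)

    if hem_regions or bright_regions:
        path.append("moderate_hemorrhage_or_bright")
        return GradingResult(Stage.DR2, path, evidence)
    if red_regions:
        path.append("mild_microaneurysms_only")
        return GradingResult(Stage.DR1, path, evidence)
    path.append("no_lesions")
    return GradingResult(Stage.DR0, path, evidence)
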