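"""End-to-end per-image pipeline: preprocess -> anatomy -> lesions ->
quality -> grade -> quantify."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from ._models import LinearModel
from .anatomy import (
    OpticDisc,
    QuadrantMap,
    VesselMap,
    locate_optic_disc,
    partition_quadrants,
    segment_vessels,
)
from .config import RunConfig
from .core import FundusImage, GradingRecord, RoiMask, Stage
from .grading import GradingResult, QualityReport, assess_quality, grade_dr
from .lesions import LesionSet, detect_bright_lesions, detect_prp_scars, detect_red_lesions
from .preprocess import denoise, establish_roi, normalize, standard_profile
from .quantify import QuantReport, quantify

logger = logging.getLogger(__name__)


@dataclass
class PreprocessedScene:
    roi: RoiMask
    normalized: FundusImage
    vessels: VesselMap
    disc: OpticDisc


@dataclass
class ImageAnalysis:
    """Everything the pipeline derives from one photograph."""

    image: FundusImage
    prep: PreprocessedScene
    quadrants: QuadrantMap
    lesions: LesionSet
    quality: QualityReport
    grading: GradingResult
    quant: QuantReport
    elapsed_s: float = 0.0

    @property
    def record(self) -> GradingRecord:
        return GradingRecord(self.image.image_id, self.grading.stage, self.quality, self.quant)


_PROFILE_CACHE: dict[int, object] = {}


def _profile(config: RunConfig):
    key = id(type(config))  # one standard profile per process
    if "std" not in _PROFILE_CACHE:
        _PROFILE_CACHE["std"] = standard_profile(config)
    return _PROFILE_CACHE["std"]


def preprocess_scene(image: FundusImage, config: RunConfig | None = None) -> PreprocessedScene:
    """ROI, denoise, normalize against the standard profile, vessels, disc."""
    cfg = config or RunConfig()
    roi = establish_roi(image, cfg)
    smooth = denoise(image, cfg.denoise_radius)
    norm = normalize(smooth, roi, _profile(cfg), cfg)
    vessels = segment_vessels(norm, roi, config=cfg)
    disc = locate_optic_disc(norm, vessels, roi, cfg)
    return PreprocessedScene(roi, norm, vessels, disc)


def analyze_image(
    image: FundusImage,
    config: RunConfig | None = None,
    laterality: str = "OD",
    red_model: LinearModel | None = None,
) -> ImageAnalysis:
    """Run the full pipeline on one photograph.

    The quality gate is always evaluated; lesion detection still runs on
    unqualified images (its output is reported but the stage is
    UNGRADABLE).
    """
    cfg = config or RunConfig()
    t0 = time.perf_counter()
    prep = preprocess_scene(image, cfg)
    quality = assess_quality(image, prep.roi, prep.disc, cfg)
    quadrants = partition_quadrants(prep.roi, prep.disc, laterality, cfg)
    red = detect_red_lesions(prep.normalized, prep.vessels, prep.disc, prep.roi, red_model, cfg)
    bright = detect_bright_lesions(prep.normalized, prep.disc, prep.roi, cfg)
    prp = detect_prp_scars(prep.normalized, prep.roi, prep.disc, cfg)
    lesions = red.merged_with(bright).merged_with(prp)
    grading = grade_dr(lesions, quadrants, quality, cfg)
    quant = quantify(lesions, image.image_id, cfg)
    elapsed = time.perf_counter() - t0
    logger.info(
        "image=%s stage=%s lesions=%d quality=%s %.2fs",
        image.image_id,
        grading.stage.value,
        len(lesions),
        "ok" if quality.qualified else ";".join(sorted(quality.flags)),
        elapsed,
    )
    return ImageAnalysis(image, prep, quadrants, lesions, quality, grading, quant, elapsed)


def expected_stage_from_truth(truth, quadrants: QuadrantMap, config: RunConfig | None = None) -> Stage:
    """Ground-truth stage label: the same rule cascade applied to the
    planted lesion evidence (perfect detection, qualified image)."""
    import numpy as np
    from scipy import ndimage as ndi

    from .grading import grade_dr as _grade
    from .lesions import LesionRegion, LesionSet

    cfg = config or RunConfig()
    lesion_regions = []
    # reconstruct each region's mask from the label raster (regions of one
    # class are disjoint connected components by construction)
    class_labels: dict[str, np.ndarray] = {}
    for i, reg in enumerate(truth.regions, start=1):
        if reg.lesion_class not in class_labels:
            lab, _ = ndi.label(truth.class_mask(reg.lesion_class))
            class_labels[reg.lesion_class] = lab
        lab = class_labels[reg.lesion_class]
        r, c = int(round(reg.centroid[0])), int(round(reg.centroid[1]))
        lbl = lab[r, c]
        if lbl == 0:  # centroid outside a concave region: nearest labeled px
            rows, cols = np.nonzero(lab > 0)
            k = int(np.argmin((rows - r) ** 2 + (cols - c) ** 2))
            lbl = lab[rows[k], cols[k]]
        mask = lab == lbl
        lesion_regions.append(
            LesionRegion(i, reg.lesion_class, mask, int(mask.sum()), reg.centroid)
        )
    lesions = LesionSet(truth.label_raster.shape, lesion_regions)
    n_scars = len(lesions.of_class("prp_scar"))
    lesions.prp_positive = n_scars >= cfg.prp_min_count
    quality = QualityReport(1e9, 0.0, 0.0, 0.0, 0.0, set())
    return _grade(lesions, quadrants, quality, cfg).stage
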