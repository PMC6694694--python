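"""Seeded benchmark suites: the fixed synthetic conditions under which the
pipeline's detection, localization and grading quality are measured.

Two suites are defined:

* the detection suite — 14 lesion-bearing scenes (hemorrhages 50-500 px,
  a few microaneurysms, exudate clusters) plus 6 clean scenes, used for
  per-lesion hemorrhage recall, false positives per clean scene, exudate
  area error, vessel Dice and disc localization;
* the default three-group cohort (39/29/23 scenes) from
  :func:`fundusdr.synthetic.default_cohort_spec`, used for stage accuracy
  and the group-trend statistics.

A planted lesion counts as detected when at least 30% of its pixels are
covered by the detected mask of its family (the usual region-overlap hit
criterion in lesion-detection evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import RunConfig
from .core import Stage
from .grading import grade_dr
from .pipeline import analyze_image, expected_stage_from_truth, preprocess_scene
from .quantify import quantify
from .synthetic import CohortSpec, LesionLoad, SceneSpec, default_cohort_spec, iter_cohort, render_scene

HIT_COVERAGE = 0.30
MIN_HEM_AREA = 50  # per-lesion recall is scored on hemorrhages >= this many px


def detection_suite_specs(seed: int = 0, n_lesion: int = 14, n_clean: int = 6) -> list[SceneSpec]:
    """The fixed 20-scene detection suite (lesion scenes first)."""
    ss = np.random.SeedSequence([seed, 404])
    seeds = ss.generate_state(n_lesion + n_clean) % (2**31 - 1)
    loads = {
        "microaneurysm": LesionLoad((1, 3), (6.0, 28.0), 0.85),
        "hemorrhage": LesionLoad((3, 8), (50.0, 500.0), 0.85),
        "exudate": LesionLoad((2, 6), (60.0, 400.0), 0.85),
    }
    specs = [SceneSpec(seed=int(s), lesion_loads=dict(loads)) for s in seeds[:n_lesion]]
    specs += [SceneSpec(seed=int(s)) for s in seeds[n_lesion:]]
    return specs


@dataclass
class DetectionSuiteResult:
    hemorrhage_recall: float
    n_hemorrhages: int
    false_positives_per_clean_scene: list[int]
    exudate_area_rel_errors: list[float]
    vessel_dice: list[float]
    disc_hits: list[bool]

    @property
    def max_false_positives(self) -> int:
        return max(self.false_positives_per_clean_scene)

    @property
    def mean_exudate_area_error(self) -> float:
        return float(np.mean(self.exudate_area_rel_errors))

    @property
    def mean_vessel_dice(self) -> float:
        return float(np.mean(self.vessel_dice))

    @property
    def disc_success_rate(self) -> float:
        return float(np.mean(self.disc_hits))


def run_detection_suite(seed: int = 0, config: RunConfig | None = None) -> DetectionSuiteResult:
    """Render and analyze the 20-scene suite, scoring every detector
    against the generator's ground truth."""
    cfg = config or RunConfig()
    hem_hits: list[bool] = []
    fps: list[int] = []
    ex_errs: list[float] = []
    dices: list[float] = []
    disc_hits: list[bool] = []
    for spec in detection_suite_specs(seed):
        image, truth = render_scene(spec)
        analysis = analyze_image(image, cfg)
        prep = analysis.prep

        disc_mask = truth.class_mask("disc")
        rows, cols = np.nonzero(disc_mask)
        true_center = (rows.mean(), cols.mean())
        true_radius = np.sqrt(disc_mask.sum() / np.pi)
        err = np.hypot(
            prep.disc.center[0] - true_center[0], prep.disc.center[1] - true_center[1]
        )
        disc_hits.append(bool(err < 0.5 * true_radius))

        vessel_truth = truth.class_mask("vessel")
        inter = (prep.vessels.mask & vessel_truth).sum()
        dices.append(float(2 * inter / max(prep.vessels.mask.sum() + vessel_truth.sum(), 1)))

        red_det = analysis.lesions.family_mask("red")
        if truth.regions_of("hemorrhage"):
            labeled, n = ndimage.label(truth.class_mask("hemorrhage"))
            for i in range(1, n + 1):
                region = labeled == i
                area = int(region.sum())
                if area >= MIN_HEM_AREA:
                    cov = (region & red_det).sum() / area
                    hem_hits.append(bool(cov >= HIT_COVERAGE))
            true_ex = int(truth.class_mask("exudate").sum())
            det_ex = sum(r.area_px for r in analysis.lesions.of_class("exudate", "cottonwool"))
            ex_errs.append(abs(det_ex - true_ex) / max(true_ex, 1))
        else:
            fps.append(len(analysis.lesions.of_class("microaneurysm", "hemorrhage")))
    return DetectionSuiteResult(
        hemorrhage_recall=float(np.mean(hem_hits)),
        n_hemorrhages=len(hem_hits),
        false_positives_per_clean_scene=fps,
        exudate_area_rel_errors=ex_errs,
        vessel_dice=dices,
        disc_hits=disc_hits,
    )


@dataclass
class CohortRunResult:
    image_ids: list[str]
    groups: list[str]
    true_stages: list[Stage]
    predicted_stages: list[Stage]
    estimated_total_hem_areas: list[int]
    truth_total_hem_areas: list[int]
    estimated_group_means: dict[str, float] = field(default_factory=dict)
    truth_group_means: dict[str, float] = field(default_factory=dict)

    @property
    def stage_accuracy(self) -> float:
        agree = [p == t for p, t in zip(self.predicted_stages, self.true_stages)]
        return float(np.mean(agree))

    @property
    def dr_sensitivity(self) -> float:
        """Among scenes whose truth stage is DR1+, the fraction graded DR1+."""
        flags = [
            p not in (Stage.DR0, Stage.UNGRADABLE)
            for p, t in zip(self.predicted_stages, self.true_stages)
            if t not in (Stage.DR0, Stage.UNGRADABLE)
        ]
        return float(np.mean(flags)) if flags else float("nan")


def run_cohort(
    spec: CohortSpec | None = None, seed: int = 0, config: RunConfig | None = None
) -> CohortRunResult:
    """Analyze the stage-structured cohort end to end.

    Truth stage labels come from the same rule cascade applied to the
    planted lesion evidence, so accuracy isolates detection fidelity from
    rule choice.
    """
    cfg = config or RunConfig()
    spec = spec or default_cohort_spec(seed, cfg.cohort_sizes)
    ids, groups, t_stages, p_stages, est_areas, tru_areas = [], [], [], [], [], []
    est_by_group: dict[str, list[float]] = {}
    tru_by_group: dict[str, list[float]] = {}
    for scene in iter_cohort(spec):
        analysis = analyze_image(scene.image, cfg)
        true_stage = expected_stage_from_truth(scene.truth, analysis.quadrants, cfg)
        ids.append(scene.image.image_id)
        groups.append(scene.group)
        t_stages.append(true_stage)
        p_stages.append(analysis.grading.stage)
        est = analysis.quant.hemorrhage_total_area_px
        tru = sum(r.pixel_area for r in scene.truth.regions_of("microaneurysm", "hemorrhage"))
        est_areas.append(est)
        tru_areas.append(tru)
        est_by_group.setdefault(scene.group, []).append(est)
        tru_by_group.setdefault(scene.group, []).append(tru)
    return CohortRunResult(
        ids,
        groups,
        t_stages,
        p_stages,
        est_areas,
        tru_areas,
        {g: float(np.mean(v)) for g, v in est_by_group.items()},
        {g: float(np.mean(v)) for g, v in tru_by_group.items()},
    )
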