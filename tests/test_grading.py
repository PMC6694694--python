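"""Quality gating and the DR staging cascade."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundusdr._exceptions import ContractError
from fundusdr.anatomy import OpticDisc, QuadrantMap, partition_quadrants
from fundusdr.config import RunConfig
from fundusdr.core import RoiMask, Stage, STAGE_SEVERITY
from fundusdr.grading import GradingResult, QualityReport, assess_quality, grade_dr
from fundusdr.lesions import LesionRegion, LesionSet
from fundusdr.pipeline import preprocess_scene
from fundusdr.synthetic import SceneSpec, degrade, render_scene

OK_QUALITY = QualityReport(5.0, 0.0, 0.0, 0.0, 0.0, set())
BAD_QUALITY = QualityReport(0.1, 0.0, 0.0, 0.0, 0.0, {"fuzzy"})


def _setup(config):
    rr, cc = np.mgrid[0:512, 0:512]
    roi = RoiMask((rr - 256) ** 2 + (cc - 256) ** 2 < 230**2)
    disc = OpticDisc(
        (256.0, 256.0 + config.macula_offset_frac * roi.equivalent_radius), 30.0, 0.9
    )
    return roi, partition_quadrants(roi, disc, "OD", config)


def _lesion(shape, row, col, cls, size=6, rid=1):
    m = np.zeros(shape, dtype=bool)
    m[row : row + size, col : col + size] = True
    return LesionRegion(rid, cls, m, int(m.sum()), (row + size / 2, col + size / 2))


def _lesion_set(shape, spec_list):
    regions = [
        _lesion(shape, r, c, cls, size, i + 1)
        for i, (r, c, cls, size) in enumerate(spec_list)
    ]
    return LesionSet(shape, regions)


class TestAssessQuality:
    def test_clean_scene_is_qualified(self, clean_scene, clean_prep, config):
        image, _ = clean_scene
        q = assess_quality(image, clean_prep.roi, clean_prep.disc, config)
        assert q.qualified
        assert q.flags == set()

    @pytest.mark.parametrize(
        "mode,flag",
        [
            ("blur", "fuzzy"),
            ("dark_patch", "dark_area"),
            ("eyelash", "eyelash"),
            ("overexpose", "overexposed"),
            ("decenter", "decentered"),
        ],
    )
    def test_each_degradation_trips_its_flag(self, clean_scene, config, mode, flag):
        image, _ = clean_scene
        bad = degrade(image, mode, 0.5, seed=3)
        prep = preprocess_scene(bad, config)
        q = assess_quality(bad, prep.roi, prep.disc, config)
        assert flag in q.flags
        assert not q.qualified

    def test_heavy_saturation_sets_overexposed(self, clean_scene, clean_prep, config):
        image, _ = clean_scene
        px = image.pixels.copy()
        rows, cols = np.nonzero(clean_prep.roi.mask)
        k = int(0.4 * rows.size)
        px[rows[:k], cols[:k]] = 255
        from fundusdr.core import FundusImage

        q = assess_quality(FundusImage(px), clean_prep.roi, clean_prep.disc, config)
        assert "overexposed" in q.flags

    def test_qualified_iff_no_flags(self):
        assert QualityReport(5, 0, 0, 0, 0, set()).qualified
        assert not QualityReport(5, 0, 0, 0, 0, {"dark_area"}).qualified


class TestGradeDr:
    def test_no_lesions_grades_dr0(self, config):
        roi, qm = _setup(config)
        res = grade_dr(LesionSet(roi.shape), qm, OK_QUALITY, config)
        assert res.stage == Stage.DR0
        assert res.rule_path[-1] == "no_lesions"

    def test_microaneurysms_only_grades_dr1(self, config):
        roi, qm = _setup(config)
        lesions = _lesion_set(
            roi.shape, [(150, 150, "microaneurysm", 3), (300, 300, "microaneurysm", 3), (200, 350, "microaneurysm", 3)]
        )
        res = grade_dr(lesions, qm, OK_QUALITY, config)
        assert res.stage == Stage.DR1

    def test_any_hemorrhage_or_bright_lesion_grades_dr2(self, config):
        roi, qm = _setup(config)
        res = grade_dr(
            _lesion_set(roi.shape, [(150, 150, "hemorrhage", 8)]), qm, OK_QUALITY, config
        )
        assert res.stage == Stage.DR2
        res = grade_dr(
            _lesion_set(roi.shape, [(150, 150, "exudate", 8)]), qm, OK_QUALITY, config
        )
        assert res.stage == Stage.DR2

    def test_hemorrhages_in_all_quadrants_grade_dr3(self, config):
        roi, qm = _setup(config)
        spec_list = []
        centers = {1: (150, 420), 2: (150, 120), 3: (380, 120), 4: (380, 420)}
        for q, (r, c) in centers.items():
            for i in range(25):
                spec_list.append((r + (i % 5) * 8, c + (i // 5) * 8, "hemorrhage", 4))
        lesions = _lesion_set(roi.shape, spec_list)
        res = grade_dr(lesions, qm, OK_QUALITY, config)
        assert res.stage == Stage.DR3
        assert "severe_4quadrant_hemorrhages" in res.rule_path

    def test_large_total_red_area_grades_dr3(self, config):
        roi, qm = _setup(config)
        lesions = _lesion_set(
            roi.shape, [(120, 120, "hemorrhage", 80), (300, 300, "hemorrhage", 80)]
        )
        assert sum(r.area_px for r in lesions.regions) >= config.severe_red_area_px
        res = grade_dr(lesions, qm, OK_QUALITY, config)
        assert res.stage == Stage.DR3

    def test_prp_pattern_dominates(self, config):
        roi, qm = _setup(config)
        lesions = _lesion_set(roi.shape, [(150, 150, "hemorrhage", 8)])
        lesions.prp_positive = True
        res = grade_dr(lesions, qm, OK_QUALITY, config)
        assert res.stage == Stage.PRP

    def test_ungradable_is_absorbing(self, config):
        roi, qm = _setup(config)
        lesions = _lesion_set(
            roi.shape, [(120, 120, "hemorrhage", 80), (300, 300, "hemorrhage", 80)]
        )
        lesions.prp_positive = True
        res = grade_dr(lesions, qm, BAD_QUALITY, config)
        assert res.stage == Stage.UNGRADABLE

    def test_pdr_only_in_experimental_mode(self, config):
        import dataclasses

        roi, qm = _setup(config)
        lesions = _lesion_set(roi.shape, [(100, 100, "hemorrhage", 170)])  # 28900 px
        res = grade_dr(lesions, qm, OK_QUALITY, config)
        assert res.stage == Stage.DR3  # not PDR by default
        cfg_pdr = dataclasses.replace(config, pdr_mode=True)
        res = grade_dr(lesions, qm, OK_QUALITY, cfg_pdr)
        assert res.stage == Stage.PDR

    def test_shape_mismatch_rejected(self, config):
        roi, qm = _setup(config)
        with pytest.raises(ContractError):
            grade_dr(LesionSet((128, 128)), qm, OK_QUALITY, config)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_stage_monotone_under_lesion_addition(self, data):
        """Removing lesions can never raise the stage (DR0<DR1<DR2<DR3)."""
        config = RunConfig()
        roi, qm = _setup(config)
        pool = []
        rng = np.random.default_rng(77)
        for i in range(30):
            cls = ["microaneurysm", "hemorrhage", "exudate"][i % 3]
            size = 3 if cls == "microaneurysm" else int(rng.integers(5, 40))
            r = int(rng.integers(80, 420))
            c = int(rng.integers(80, 420))
            pool.append((r, c, cls, size))
        chosen = data.draw(
            st.lists(st.sampled_from(range(30)), min_size=0, max_size=30, unique=True)
        )
        subset_idx = data.draw(
            st.lists(st.sampled_from(chosen), min_size=0, max_size=len(chosen), unique=True)
            if chosen
            else st.just([])
        )
        sup = _lesion_set(roi.shape, [pool[i] for i in chosen])
        sub = _lesion_set(roi.shape, [pool[i] for i in subset_idx])
        stage_sup = grade_dr(sup, qm, OK_QUALITY, config).stage
        stage_sub = grade_dr(sub, qm, OK_QUALITY, config).stage
        assert STAGE_SEVERITY[stage_sup] >= STAGE_SEVERITY[stage_sub]

    def test_rule_path_never_empty(self, config):
        roi, qm = _setup(config)
        for lesions in (LesionSet(roi.shape), _lesion_set(roi.shape, [(150, 150, "hemorrhage", 9)])):
            res = grade_dr(lesions, qm, OK_QUALITY, config)
            assert res.rule_path
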