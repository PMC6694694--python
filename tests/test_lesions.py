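"""Red/bright lesion and photocoagulation-scar detection."""

import numpy as np
import pytest
from scipy import ndimage

from fundusdr._exceptions import ContractError
from fundusdr._models import load_bundled
from fundusdr.config import RunConfig
from fundusdr.lesions import (
    FeatureVector,
    LesionSet,
    detect_bright_lesions,
    detect_prp_scars,
    detect_red_lesions,
    train_candidate_classifier,
)
from fundusdr.pipeline import preprocess_scene
from fundusdr.synthetic import LesionLoad, SceneSpec, render_scene


def _fv(**kw):
    base = dict(
        area_px=50,
        eccentricity=0.5,
        circularity=0.8,
        mean_hue=0.03,
        mean_saturation=0.7,
        green_contrast=40.0,
        boundary_gradient=8.0,
        dist_to_vessel_px=10.0,
    )
    base.update(kw)
    return FeatureVector(**base)


class TestDetectRedLesions:
    def test_single_small_microaneurysm_found(self, config):
        spec = SceneSpec(
            seed=99, lesion_loads={"microaneurysm": LesionLoad((1, 1), (9.0, 9.0), 0.85)}
        )
        image, truth = render_scene(spec)
        prep = preprocess_scene(image, config)
        lesions = detect_red_lesions(
            prep.normalized, prep.vessels, prep.disc, prep.roi, config=config
        )
        mas = lesions.of_class("microaneurysm")
        assert len(mas) >= 1
        true_centroid = truth.regions_of("microaneurysm")[0].centroid
        best = min(
            np.hypot(m.centroid[0] - true_centroid[0], m.centroid[1] - true_centroid[1])
            for m in mas
        )
        assert best <= 2.0

    def test_lesion_free_scene_yields_few_regions(self, clean_scene, clean_prep, config):
        lesions = detect_red_lesions(
            clean_prep.normalized, clean_prep.vessels, clean_prep.disc, clean_prep.roi,
            config=config,
        )
        assert len(lesions.of_class("microaneurysm", "hemorrhage")) <= 2

    def test_no_lesion_inside_disc_or_outside_roi(self, lesion_prep, config):
        lesions = detect_red_lesions(
            lesion_prep.normalized, lesion_prep.vessels, lesion_prep.disc, lesion_prep.roi,
            config=config,
        )
        disc = lesion_prep.disc
        rr, cc = np.mgrid[0 : lesion_prep.roi.shape[0], 0 : lesion_prep.roi.shape[1]]
        disc_zone = (rr - disc.center[0]) ** 2 + (cc - disc.center[1]) ** 2 <= disc.radius_px**2
        for reg in lesions.regions:
            assert not (reg.mask & disc_zone).any()
            assert not (reg.mask & ~lesion_prep.roi.mask).any()

    def test_vessel_buried_candidate_suppressed(self, lesion_prep, config):
        # a fake vessel map covering 90% of a planted candidate suppresses it
        lesions_before = detect_red_lesions(
            lesion_prep.normalized, lesion_prep.vessels, lesion_prep.disc, lesion_prep.roi,
            config=config,
        )
        hems = lesions_before.of_class("hemorrhage")
        assert hems, "fixture scene should contain detected hemorrhages"
        target = hems[0]
        boosted = lesion_prep.vessels.mask.copy()
        eroded = ndimage.binary_erosion(target.mask, iterations=1)
        boosted |= eroded if eroded.any() else target.mask
        from fundusdr.anatomy import VesselMap

        vm = VesselMap(boosted, float(boosted.sum() / lesion_prep.roi.area_px))
        lesions_after = detect_red_lesions(
            lesion_prep.normalized, vm, lesion_prep.disc, lesion_prep.roi, config=config
        )
        det_after = lesions_after.family_mask("red")
        cov = (target.mask & det_after).sum() / target.area_px
        assert cov < 0.5

    def test_monotone_visibility_in_contrast(self, config):
        # raising a hemorrhage's contrast never removes its detection
        detected = {}
        for contrast in (0.55, 0.75, 0.95):
            spec = SceneSpec(
                seed=321,
                lesion_loads={"hemorrhage": LesionLoad((1, 1), (220.0, 220.0), contrast)},
            )
            image, truth = render_scene(spec)
            prep = preprocess_scene(image, config)
            lesions = detect_red_lesions(
                prep.normalized, prep.vessels, prep.disc, prep.roi, config=config
            )
            reg = truth.regions_of("hemorrhage")[0]
            lab, _ = ndimage.label(truth.class_mask("hemorrhage"))
            region_mask = lab == lab[int(reg.centroid[0]), int(reg.centroid[1])]
            cov = (region_mask & lesions.family_mask("red")).sum() / region_mask.sum()
            detected[contrast] = cov >= 0.3
        assert detected[0.95] and detected[0.75]
        if detected[0.55]:  # monotone: visible at low contrast implies visible above
            assert detected[0.75] and detected[0.95]

    def test_identical_inputs_give_identical_output(self, lesion_prep, config):
        runs = [
            detect_red_lesions(
                lesion_prep.normalized, lesion_prep.vessels, lesion_prep.disc,
                lesion_prep.roi, config=config,
            )
            for _ in range(3)
        ]
        masks = [r.family_mask("red") for r in runs]
        assert np.array_equal(masks[0], masks[1])
        assert np.array_equal(masks[0], masks[2])


class TestDetectBrightLesions:
    def test_planted_exudate_area_within_20_percent(self, config):
        spec = SceneSpec(
            seed=77, lesion_loads={"exudate": LesionLoad((4, 4), (150.0, 400.0), 0.85)}
        )
        image, truth = render_scene(spec)
        prep = preprocess_scene(image, config)
        lesions = detect_bright_lesions(prep.normalized, prep.disc, prep.roi, config)
        det = sum(r.area_px for r in lesions.of_class("exudate", "cottonwool"))
        true_area = int(truth.class_mask("exudate").sum())
        assert abs(det - true_area) / true_area <= 0.20

    def test_disc_never_reported_as_exudate(self, lesion_prep, config):
        lesions = detect_bright_lesions(
            lesion_prep.normalized, lesion_prep.disc, lesion_prep.roi, config
        )
        disc = lesion_prep.disc
        rr, cc = np.mgrid[0 : lesion_prep.roi.shape[0], 0 : lesion_prep.roi.shape[1]]
        disc_zone = (rr - disc.center[0]) ** 2 + (cc - disc.center[1]) ** 2 <= disc.radius_px**2
        for reg in lesions.regions:
            assert not (reg.mask & disc_zone).any()

    def test_sharp_vs_fuzzy_blob_classified_exudate_vs_cottonwool(self, config):
        spec = SceneSpec(
            seed=88,
            lesion_loads={
                "exudate": LesionLoad((1, 1), (300.0, 300.0), 0.9),
                "cottonwool": LesionLoad((1, 1), (300.0, 300.0), 0.8),
            },
        )
        image, truth = render_scene(spec)
        prep = preprocess_scene(image, config)
        lesions = detect_bright_lesions(prep.normalized, prep.disc, prep.roi, config)
        ex_truth = truth.class_mask("exudate")
        cw_truth = truth.class_mask("cottonwool")
        got_ex = got_cw = False
        for reg in lesions.regions:
            if (reg.mask & ex_truth).sum() / reg.area_px > 0.5:
                got_ex = got_ex or reg.lesion_class == "exudate"
            if (reg.mask & cw_truth).sum() / reg.area_px > 0.5:
                got_cw = got_cw or reg.lesion_class == "cottonwool"
        assert got_ex and got_cw


class TestDetectPrpScars:
    def test_prp_scene_positive_with_most_scars_found(self, config):
        spec = SceneSpec(
            seed=55, lesion_loads={"prp_scar": LesionLoad((48, 48), (120.0, 160.0), 0.9)}
        )
        image, truth = render_scene(spec)
        prep = preprocess_scene(image, config)
        lesions = detect_prp_scars(prep.normalized, prep.roi, prep.disc, config)
        assert lesions.prp_positive
        assert len(lesions.of_class("prp_scar")) >= 0.8 * 48

    def test_clean_scene_has_no_scars(self, clean_prep, config):
        lesions = detect_prp_scars(
            clean_prep.normalized, clean_prep.roi, clean_prep.disc, config
        )
        assert not lesions.prp_positive
        assert len(lesions.of_class("prp_scar")) <= 3

    def test_three_scattered_spots_is_negative(self, config):
        spec = SceneSpec(
            seed=56, lesion_loads={"prp_scar": LesionLoad((3, 3), (120.0, 160.0), 0.9)}
        )
        image, _ = render_scene(spec)
        prep = preprocess_scene(image, config)
        lesions = detect_prp_scars(prep.normalized, prep.roi, prep.disc, config)
        assert not lesions.prp_positive


class TestExports:
    def test_masks_and_region_table_round_trip(self, lesion_prep, config, tmp_path):
        import json

        import imageio.v3 as iio

        from fundusdr.anatomy import export_anatomy
        from fundusdr.lesions import export_lesions

        lesions = detect_red_lesions(
            lesion_prep.normalized, lesion_prep.vessels, lesion_prep.disc,
            lesion_prep.roi, config=config,
        )
        export_lesions(lesions, tmp_path)
        table = json.loads((tmp_path / "regions.json").read_text())
        assert len(table) == len(lesions.regions)
        for cls in {r.lesion_class for r in lesions.regions}:
            mask = iio.imread(tmp_path / f"mask_{cls}.png")
            assert (mask > 0).sum() == int(lesions.class_raster(cls).sum())
        export_anatomy(lesion_prep.vessels, lesion_prep.disc, tmp_path)
        geom = json.loads((tmp_path / "anatomy.json").read_text())
        assert geom["disc"]["radius_px"] > 0
        vessels_png = iio.imread(tmp_path / "vessels.png")
        assert (vessels_png > 0).sum() == int(lesion_prep.vessels.mask.sum())


class TestCandidateClassifier:
    def test_separable_toy_set_fits_perfectly(self):
        pairs = []
        for i in range(20):
            pairs.append((_fv(green_contrast=45.0 + i % 5, area_px=60), "lesion"))
            pairs.append((_fv(green_contrast=2.0 + i % 5, area_px=8, boundary_gradient=1.0), "reject"))
        model = train_candidate_classifier(pairs, seed=0)
        X = np.stack([fv.to_array() for fv, _ in pairs])
        y = np.array([label for _, label in pairs])
        assert (model.predict(X) == y).all()

    def test_retraining_is_deterministic(self, rng):
        pairs = []
        for i in range(60):
            lesion = i % 3 != 0
            pairs.append(
                (
                    _fv(
                        green_contrast=float(rng.normal(40 if lesion else 10, 5)),
                        boundary_gradient=float(abs(rng.normal(8 if lesion else 2, 2))),
                    ),
                    "lesion" if lesion else "reject",
                )
            )
        m1 = train_candidate_classifier(pairs, seed=7)
        m2 = train_candidate_classifier(pairs, seed=7)
        probe = np.stack([_fv(green_contrast=float(g)).to_array() for g in range(0, 60, 5)])
        assert np.array_equal(m1.predict(probe), m2.predict(probe))
        assert np.allclose(m1.support_vectors, m2.support_vectors)
        assert np.allclose(m1.dual_coef, m2.dual_coef)

    def test_single_class_input_rejected(self):
        with pytest.raises(ContractError):
            train_candidate_classifier([(_fv(), "lesion")] * 5, seed=0)

    def test_bundled_model_held_out_accuracy(self, config):
        from fundusdr.lesions import build_candidate_corpus

        model = load_bundled("red_candidate")
        corpus = build_candidate_corpus(2, seed=91, config=config)  # unseen seeds
        X = np.stack([fv.to_array() for fv, _ in corpus])
        y = np.array([label for _, label in corpus])
        assert (model.predict(X) == y).mean() >= 0.85

    def test_json_round_trip_preserves_decisions(self, tmp_path):
        model = load_bundled("red_candidate")
        path = tmp_path / "m.json"
        model.to_json(path)
        from fundusdr._models import RbfSvmModel

        back = RbfSvmModel.from_json(path)
        probe = np.stack([_fv(green_contrast=float(g)).to_array() for g in range(0, 50, 5)])
        assert np.array_equal(model.predict(probe), back.predict(probe))
        assert np.allclose(
            model.decision_function(probe), back.decision_function(probe), atol=1e-12
        )
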