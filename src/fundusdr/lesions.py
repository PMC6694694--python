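"""Detection and classification of DR lesions.

Red lesions (microaneurysms, hemorrhages) are dark reddish blobs: small
ones are picked up by a dark top-hat (morphological closing minus image)
on the green channel at a fine scale, large ones by color discrimination
(darkness relative to the local background plus reddish hue).  Candidates
overlapping the vessel map or the optic disc are suppressed, the rest are
accepted or rejected by a margin classifier over shape/color/contrast
features, and the survivors are split microaneurysm vs hemorrhage at a
configurable pixel-area boundary.

Bright lesions (hard exudates, cotton-wool spots) come from a bright
top-hat on lightness at two scales; the two classes are separated by a
fixed two-feature rule: sharp boundary gradient with yellowish hue means
exudate, soft and pale means cotton-wool.

Photocoagulation scars are round, similar-sized pale spots in the
peripheral annulus; a scene is PRP-positive when enough regular spots are
found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.color import rgb2hsv
from skimage.morphology import convex_hull_image, disk

from ._exceptions import ConfigurationError, ContractError
from ._models import LinearModel, RbfSvmModel, fit_rbf_svm, load_bundled
from .anatomy import OpticDisc, VesselMap
from .config import RunConfig
from .core import BRIGHT_FAMILY, RED_FAMILY, FundusImage, RoiMask

LESION_CLASSES = ("microaneurysm", "hemorrhage", "exudate", "cottonwool", "prp_scar")

FEATURE_NAMES = [
    "area_px",
    "eccentricity",
    "circularity",
    "mean_hue",
    "mean_saturation",
    "green_contrast",
    "boundary_gradient",
    "dist_to_vessel_px",
]


@dataclass
class FeatureVector:
    """Shape, color and contrast descriptors of one candidate region."""

    area_px: int
    eccentricity: float
    circularity: float
    mean_hue: float
    mean_saturation: float
    green_contrast: float
    boundary_gradient: float
    dist_to_vessel_px: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ContractError("feature values must be finite")
        if not (0 < self.circularity <= 1):
            raise ContractError("circularity must lie in (0, 1]")
        if not (0 <= self.eccentricity < 1):
            raise ContractError("eccentricity must lie in [0, 1)")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)


@dataclass
class LesionRegion:
    region_id: int
    lesion_class: str
    mask: np.ndarray            # full-frame boolean raster of this region
    area_px: int
    centroid: tuple[float, float]
    features: FeatureVector | None = None

    def __post_init__(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ContractError(f"unknown lesion class {self.lesion_class!r}")
        if self.area_px != int(self.mask.sum()):
            raise ContractError("area_px must equal the mask pixel count")


@dataclass
class LesionSet:
    """All lesions detected on one image, with per-class rasters on demand."""

    shape: tuple[int, int]
    regions: list[LesionRegion] = field(default_factory=list)
    prp_positive: bool = False

    def class_raster(self, lesion_class: str) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for r in self.regions:
            if r.lesion_class == lesion_class:
                m |= r.mask
        return m

    def family_mask(self, family: str) -> np.ndarray:
        classes = RED_FAMILY if family == "red" else BRIGHT_FAMILY
        m = np.zeros(self.shape, dtype=bool)
        for r in self.regions:
            if r.lesion_class in classes:
                m |= r.mask
        return m

    def of_class(self, *classes: str) -> list[LesionRegion]:
        return [r for r in self.regions if r.lesion_class in classes]

    def merged_with(self, other: "LesionSet") -> "LesionSet":
        if other.shape != self.shape:
            raise ContractError("cannot merge lesion sets of different shapes")
        regions = list(self.regions)
        offset = max((r.region_id for r in regions), default=0)
        for r in other.regions:
            regions.append(
                LesionRegion(
                    offset + r.region_id, r.lesion_class, r.mask, r.area_px, r.centroid, r.features
                )
            )
        return LesionSet(self.shape, regions, self.prp_positive or other.prp_positive)

    def __len__(self) -> int:
        return len(self.regions)


def export_lesions(lesions: LesionSet, out_dir) -> None:
    """Write per-class binary masks as PNG plus a JSON region table
    (id, class, area_px, centroid)."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cls in LESION_CLASSES:
        raster = lesions.class_raster(cls)
        if raster.any():
            iio.imwrite(out / f"mask_{cls}.png", (raster * 255).astype(np.uint8))
    table = [
        {
            "region_id": r.region_id,
            "class": r.lesion_class,
            "area_px": r.area_px,
            "centroid": [round(r.centroid[0], 2), round(r.centroid[1], 2)],
        }
        for r in lesions.regions
    ]
    (out / "regions.json").write_text(json.dumps(table, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# shared candidate machinery


def masked_background(
    channel: np.ndarray, mask: np.ndarray, sigma: float
) -> np.ndarray:
    """Smooth background estimate restricted to the field (normalized
    convolution), immune to the black border dragging the estimate down."""
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(channel * m, sigma=sigma)
    den = ndimage.gaussian_filter(m, sigma=sigma)
    return np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)


def _disc_exclusion(shape, disc: OpticDisc, scale: float) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (rows - disc.center[0]) ** 2 + (cols - disc.center[1]) ** 2
    return d2 <= (disc.radius_px * scale) ** 2


def _extract_features(
    comp_mask: np.ndarray,
    prop,
    hsv: np.ndarray,
    green: np.ndarray,
    green_bg: np.ndarray,
    grad_mag: np.ndarray,
    vessel_dist: np.ndarray,
) -> FeatureVector:
    area = int(prop.area)
    perim = max(prop.perimeter, 1.0)
    circularity = float(np.clip(4 * np.pi * area / perim**2, 1e-6, 1.0))
    ecc = float(np.clip(prop.eccentricity, 0.0, 1 - 1e-9))
    boundary = comp_mask & ~ndimage.binary_erosion(comp_mask)
    # edge sharpness is a property of the natural lesion edge; boundary
    # pixels created by stripping vessel overlap are artificial cuts and
    # would dilute it, so exclude anything within 2 px of a vessel
    natural = boundary & (vessel_dist > 2)
    if natural.any():
        boundary = natural
    cr, cc = prop.centroid
    return FeatureVector(
        area_px=area,
        eccentricity=ecc,
        circularity=circularity,
        mean_hue=float(hsv[:, :, 0][comp_mask].mean()),
        mean_saturation=float(hsv[:, :, 1][comp_mask].mean()),
        green_contrast=float((green_bg - green)[comp_mask].mean()),
        boundary_gradient=float(grad_mag[boundary].mean()) if boundary.any() else 0.0,
        dist_to_vessel_px=float(vessel_dist[int(round(cr)), int(round(cc))]),
    )


def _candidate_regions(candidate_mask: np.ndarray, min_area: int):
    labeled, _ = ndimage.label(candidate_mask)
    for prop in measure.regionprops(labeled):
        if prop.area < min_area:
            continue
        yield labeled == prop.label, prop


# ---------------------------------------------------------------------------
# red lesions


def red_candidate_mask(
    image: FundusImage,
    disc: OpticDisc,
    roi: RoiMask,
    config: RunConfig,
    suppress_disc: bool = True,
) -> np.ndarray:
    """Raw red-lesion candidate pixels (before vessel/classifier filtering)."""
    green = image.pixels[:, :, 1].astype(np.float64)
    hsv = rgb2hsv(image.pixels)
    w = image.shape[1]

    # small scale: dark top-hat (closing minus image) at ~disc_radius/15
    se = max(2, int(round(disc.radius_px / config.red_small_tophat_div)))
    size = 2 * se + 1
    tophat = ndimage.grey_closing(green, size=(size, size)) - green
    small = tophat > config.red_tophat_threshold

    # large scale: color discrimination — dark vs local background + reddish
    background = masked_background(green, roi.mask, 1.5 * disc.radius_px)
    dark = (background - green) > 2.2 * config.red_tophat_threshold
    reddish = (hsv[:, :, 0] < 0.14) | (hsv[:, :, 0] > 0.92)
    lowval = hsv[:, :, 2] < config.red_color_value_max + 0.25
    large = dark & reddish & lowval

    mask = (small | large) & ndimage.binary_erosion(roi.mask, iterations=4)
    if suppress_disc:
        mask &= ~_disc_exclusion(image.shape, disc, config.disc_exclusion_scale)
    return mask


def detect_red_lesions(
    image: FundusImage,
    vessels: VesselMap,
    disc: OpticDisc,
    roi: RoiMask,
    model: RbfSvmModel | LinearModel | None = None,
    config: RunConfig | None = None,
) -> LesionSet:
    """Detect microaneurysms and hemorrhages on a normalized image.

    Candidates overlapping the vessel map by at least the configured
    fraction of their area, or lying inside the (dilated) disc region, are
    suppressed; the rest are scored by the margin classifier and the
    survivors split by the microaneurysm area boundary.
    """
    cfg = config or RunConfig()
    if model is None:
        try:
            model = load_bundled("red_candidate")
        except ConfigurationError as exc:
            raise ConfigurationError(f"red-lesion candidate classifier unavailable: {exc}")

    w = image.shape[1]
    ma_boundary = cfg.scaled(cfg.ma_max_area_px, w, power=2)
    accepted: list[tuple[np.ndarray, FeatureVector]] = []
    for comp, prop, feats in iter_red_candidates(image, vessels, disc, roi, cfg):
        if model.predict(feats.to_array()[None, :])[0] == "reject":
            continue
        accepted.append((comp, feats))
    if not accepted:
        return LesionSet(image.shape)

    # fuse fragments: vessels crossing a hemorrhage cut its candidate apart
    # and the stripped pixels are lost — bridge accepted parts across short
    # gaps, then complete each region's convex hull with candidate/vessel
    # pixels (lesions are convex-ish blobs; the annexed pixels are the
    # occluded interior), so region areas reflect the full lesion extent
    union = np.zeros(image.shape, dtype=bool)
    for comp, _ in accepted:
        union |= comp
    raw = red_candidate_mask(image, disc, roi, cfg, suppress_disc=False)
    annexable = raw | vessels.mask
    bridge = ndimage.binary_closing(union, structure=disk(4)) & annexable
    fused = union | bridge
    labeled, n = ndimage.label(fused)
    for i in range(1, n + 1):
        comp = labeled == i
        rows, cols = np.nonzero(comp)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        hull = convex_hull_image(comp[r0:r1, c0:c1])
        fused[r0:r1, c0:c1] |= hull & annexable[r0:r1, c0:c1]
    fused = ndimage.binary_fill_holes(fused)
    fused &= ndimage.binary_erosion(roi.mask, iterations=4)
    fused &= ~_disc_exclusion(image.shape, disc, cfg.disc_exclusion_scale)

    feats_by_seed = accepted
    regions: list[LesionRegion] = []
    rid = 0
    labeled, n = ndimage.label(fused)
    for prop in measure.regionprops(labeled):
        comp = labeled == prop.label
        # carry over the features of the largest accepted seed inside
        seed_feats = max(
            (f for c, f in feats_by_seed if (c & comp).any()),
            key=lambda f: f.area_px,
            default=None,
        )
        rid += 1
        cls = "microaneurysm" if prop.area <= ma_boundary else "hemorrhage"
        regions.append(
            LesionRegion(
                rid, cls, comp, int(prop.area), tuple(map(float, prop.centroid)), seed_feats
            )
        )
    return LesionSet(image.shape, regions)


class _VesselSpeckFilter:
    """Per-candidate view of the vessel map that ignores interior specks.

    A vessel component lying entirely within the 2-px dilation of one
    candidate region, and smaller than half of it, is pixel-classifier
    noise on the lesion rather than a crossing vessel (a real vessel
    extends beyond the lesion it crosses) and must not trigger overlap
    suppression or be stripped from the candidate."""

    def __init__(self, vessel_mask: np.ndarray):
        self.mask = vessel_mask
        self.labels, self.n = ndimage.label(vessel_mask)
        self.sizes = np.bincount(self.labels.ravel())

    def effective_in(self, comp: np.ndarray, comp_area: float) -> np.ndarray:
        """Vessel pixels inside ``comp`` that count as vessel for it."""
        inside = comp & self.mask
        if not inside.any() or self.n == 0:
            return inside
        rows, cols = np.nonzero(comp)
        r0, r1 = max(rows.min() - 3, 0), rows.max() + 4
        c0, c1 = max(cols.min() - 3, 0), cols.max() + 4
        halo = ndimage.binary_dilation(comp[r0:r1, c0:c1], iterations=2)
        ids = np.unique(self.labels[inside])
        ids = ids[ids > 0]
        keep = inside.copy()
        for i in ids:
            if self.sizes[i] >= 0.5 * comp_area:
                continue  # big enough to be real vessel structure
            local = self.labels[r0:r1, c0:c1] == i
            if local.sum() == self.sizes[i] and not (local & ~halo).any():
                keep &= self.labels != i  # fully contained speck: exempt
        return keep


def iter_red_candidates(
    image: FundusImage,
    vessels: VesselMap,
    disc: OpticDisc,
    roi: RoiMask,
    config: RunConfig,
):
    """Yield (mask, regionprops, features) for every red candidate that
    survives vessel/disc suppression — the exact stream the margin
    classifier scores, also used to assemble its training corpus.

    Candidates fused with the vessel map (overlap at or above the
    configured fraction) are not discarded outright: their vessel pixels
    are stripped and the off-vessel remainder re-examined, so a lesion
    merely touching the tree survives while pure vessel segments do not.
    Vessel-map specks wholly contained inside a candidate do not count as
    vessel for this purpose — a real vessel extends beyond the lesion it
    crosses, while interior specks are pixel-classifier noise on the
    lesion itself.
    """
    candidates = red_candidate_mask(image, disc, roi, config)
    speck_filter = _VesselSpeckFilter(vessels.mask)
    green = image.pixels[:, :, 1].astype(np.float64)
    # contrast is measured against the healthy field: candidate and vessel
    # pixels are excluded from the background so a dense lesion load cannot
    # drag the estimate down and mask its own contrast
    bg_support = (
        roi.mask
        & ~ndimage.binary_dilation(candidates, iterations=2)
        & ~vessels.mask
    )
    green_bg = masked_background(green, bg_support, 1.5 * disc.radius_px)
    hsv = rgb2hsv(image.pixels)
    grad = ndimage.gaussian_gradient_magnitude(image.pixels.mean(axis=2).astype(float), 1.5)
    vessel_dist = ndimage.distance_transform_edt(~vessels.mask)
    min_area = max(
        1, int(round(config.scaled(config.red_min_area_px, image.shape[1], power=2)))
    )
    # fragments produced by vessel stripping must be more substantial than a
    # fresh candidate, or thin slivers along the tree leak through
    min_fragment = max(
        min_area, int(round(config.scaled(config.ma_max_area_px, image.shape[1], power=2) / 2))
    )
    # dark blobs at vessel crossings mimic lesions but sit embedded in the
    # tree: a closing of the vessel map covers them almost completely while
    # barely covering a lesion that merely borders one vessel
    vessels_closed = ndimage.binary_closing(vessels.mask, structure=disk(4))
    embed_cap = config.scaled(700, image.shape[1], power=2)
    queue = [(comp, prop, False) for comp, prop in _candidate_regions(candidates, min_area)]
    while queue:
        comp, prop, is_fragment = queue.pop()
        vessel_in_comp = speck_filter.effective_in(comp, prop.area)
        overlap = vessel_in_comp.sum() / prop.area
        if overlap >= config.vessel_overlap_max:
            remainder = comp & ~vessel_in_comp
            if remainder.sum() >= min_fragment and remainder.sum() < prop.area:
                queue.extend(
                    (c, p, True) for c, p in _candidate_regions(remainder, min_fragment)
                )
            continue
        # junction-scale candidates embedded in the (closed) vessel network
        # are vessel structure; large regions crossed by several vessels are
        # legitimate lesions and exempt from this test
        if prop.area <= embed_cap:
            closed_cover = (comp & vessels_closed).sum() / prop.area
            if closed_cover >= (0.85 if is_fragment else 0.6):
                continue
        yield comp, prop, _extract_features(
            comp, prop, hsv, green, green_bg, grad, vessel_dist
        )


# ---------------------------------------------------------------------------
# bright lesions


def bright_response(
    lum: np.ndarray, roi_mask: np.ndarray, disc: OpticDisc, config: RunConfig
) -> np.ndarray:
    """Brightness above the shade-corrected field background, in gray
    levels.

    The background is a field-restricted smooth estimate at a scale
    comfortably above the largest lesion, so both small sharp exudate dots
    and large confluent patches stand out while the vignetted field and
    the black border do not."""
    bg = masked_background(lum, roi_mask, 1.5 * disc.radius_px)
    return lum - bg


def detect_bright_lesions(
    image: FundusImage,
    disc: OpticDisc,
    roi: RoiMask,
    config: RunConfig | None = None,
) -> LesionSet:
    """Detect exudates and cotton-wool spots on a normalized image.

    The disc region is excluded before classification.  The fixed
    two-feature rule: mean boundary gradient at or above the configured cut
    means exudate (sharp lipid edge); below it the region is a cotton-wool
    spot when large and pale, otherwise a soft small exudate.
    """
    cfg = config or RunConfig()
    lum = image.pixels.astype(np.float64).mean(axis=2)
    w = image.shape[1]
    resp = bright_response(lum, roi.mask, disc, cfg)
    mask = resp > cfg.bright_threshold
    mask &= ndimage.binary_erosion(roi.mask, iterations=4)
    mask &= ~_disc_exclusion(image.shape, disc, cfg.disc_exclusion_scale)

    hsv = rgb2hsv(image.pixels)
    green = image.pixels[:, :, 1].astype(np.float64)
    green_bg = masked_background(green, roi.mask, 1.5 * disc.radius_px)
    grad = ndimage.gaussian_gradient_magnitude(lum, 1.5)
    vessel_dist = np.full(image.shape, np.inf)
    vessel_dist[:] = max(image.shape)  # bright lesions don't use vessel distance

    min_area = max(1, int(round(cfg.scaled(cfg.bright_min_area_px, w, power=2))))
    cw_min = cfg.scaled(cfg.cottonwool_min_area_px, w, power=2)
    regions: list[LesionRegion] = []
    rid = 0
    for comp, prop in _candidate_regions(mask, min_area):
        feats = _extract_features(comp, prop, hsv, green, green_bg, grad, vessel_dist)
        rid += 1
        if feats.boundary_gradient >= cfg.exudate_gradient_cut:
            cls = "exudate"
        elif prop.area >= cw_min:
            cls = "cottonwool"
        else:
            cls = "exudate"
        regions.append(
            LesionRegion(rid, cls, comp, int(prop.area), tuple(map(float, prop.centroid)), feats)
        )
    return LesionSet(image.shape, regions)


# ---------------------------------------------------------------------------
# photocoagulation scars


def detect_prp_scars(
    image: FundusImage,
    roi: RoiMask,
    disc: OpticDisc,
    config: RunConfig | None = None,
) -> LesionSet:
    """Detect pan-retinal photocoagulation scars: round, similar-sized pale
    spots in the peripheral annulus.  The returned set's ``prp_positive``
    flag is true when at least ``prp_min_count`` spots of sufficiently
    regular size are found."""
    cfg = config or RunConfig()
    lum = image.pixels.astype(np.float64).mean(axis=2)
    w = image.shape[1]
    resp = bright_response(lum, roi.mask, disc, cfg)
    mask = resp > 0.7 * cfg.bright_threshold
    mask &= ndimage.binary_erosion(roi.mask, iterations=4)
    mask &= ~_disc_exclusion(image.shape, disc, cfg.disc_exclusion_scale)

    # peripheral annulus about the ROI center
    r0, c0 = roi.center
    rows, cols = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    dist = np.hypot(rows - r0, cols - c0)
    mask &= dist > cfg.prp_annulus_frac * roi.equivalent_radius

    lo = cfg.scaled(cfg.prp_min_area_px, w, power=2)
    hi = cfg.scaled(cfg.prp_max_area_px, w, power=2)
    regions: list[LesionRegion] = []
    rid = 0
    for comp, prop in _candidate_regions(mask, int(lo)):
        if prop.area > hi:
            continue
        perim = max(prop.perimeter, 1.0)
        circularity = 4 * np.pi * prop.area / perim**2
        if circularity < 0.55:
            continue
        rid += 1
        regions.append(
            LesionRegion(rid, "prp_scar", comp, int(prop.area), tuple(map(float, prop.centroid)))
        )
    areas = np.array([r.area_px for r in regions], dtype=float)
    positive = False
    if len(regions) >= cfg.prp_min_count:
        cv = areas.std() / areas.mean() if areas.mean() > 0 else np.inf
        positive = cv <= cfg.prp_area_cv_max
    return LesionSet(image.shape, regions, prp_positive=positive)


# ---------------------------------------------------------------------------
# candidate classifier training


def train_candidate_classifier(
    candidates: list[tuple[FeatureVector, str]], seed: int
) -> RbfSvmModel:
    """Train the red-lesion accept/reject classifier (an RBF support-vector
    machine over the candidate features).

    ``candidates`` pairs each :class:`FeatureVector` with its label
    (``"lesion"`` or ``"reject"``).  Deterministic given (data, seed); the
    result can be persisted as a versioned JSON fixture with
    :meth:`RbfSvmModel.to_json`.
    """
    if not candidates:
        raise ContractError("empty training set")
    X = np.stack([fv.to_array() for fv, _ in candidates])
    y = [label for _, label in candidates]
    if len(set(y)) < 2:
        raise ContractError("training data must contain both classes")
    return fit_rbf_svm(
        X, y, FEATURE_NAMES, seed, metadata={"task": "red_candidate_accept"}
    )


def build_candidate_corpus(
    n_scenes: int, seed: int, config: RunConfig | None = None
) -> list[tuple[FeatureVector, str]]:
    """Generator-labeled training corpus: the same candidate stream the
    detector scores (vessel/disc suppression and vessel stripping
    included), labeled 'lesion' when at least half a candidate's pixels
    fall on a planted red lesion, else 'reject'."""
    from .pipeline import preprocess_scene
    from .synthetic import LesionLoad, SceneSpec, render_scene

    cfg = config or RunConfig()
    corpus: list[tuple[FeatureVector, str]] = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    # rotate through mild, dense, large-lesion and lesion-free scenes
    # (mirroring the severity range the detector will see, large exudates
    # included: photometric normalization couples bright-lesion load to
    # red-lesion feature statistics)
    scene_loads = [
        {
            "microaneurysm": LesionLoad((2, 6), (6.0, 28.0), 0.85),
            "hemorrhage": LesionLoad((3, 10), (50.0, 500.0), 0.85),
            "exudate": LesionLoad((0, 5), (60.0, 400.0), 0.85),
        },
        {
            "microaneurysm": LesionLoad((3, 8), (6.0, 28.0), 0.85),
            "hemorrhage": LesionLoad((18, 26), (140.0, 700.0), 0.85),
            "exudate": LesionLoad((10, 18), (150.0, 650.0), 0.85),
        },
        {
            "microaneurysm": LesionLoad((0, 2), (6.0, 28.0), 0.85),
            "hemorrhage": LesionLoad((6, 10), (900.0, 2600.0), 0.85),
            "exudate": LesionLoad((4, 8), (1000.0, 3200.0), 0.85),
        },
        {},  # lesion-free scene: every candidate is a reject
    ]
    for i in range(n_scenes):
        loads = scene_loads[i % 4]
        spec = SceneSpec(seed=int(rng.integers(0, 2**31 - 1)), lesion_loads=loads)
        image, truth = render_scene(spec)
        prep = preprocess_scene(image, cfg)
        red_truth = truth.class_mask("microaneurysm") | truth.class_mask("hemorrhage")
        for comp, prop, feats in iter_red_candidates(
            prep.normalized, prep.vessels, prep.disc, prep.roi, cfg
        ):
            on_lesion = (comp & red_truth).sum() / prop.area
            corpus.append((feats, "lesion" if on_lesion >= 0.5 else "reject"))
    return corpus
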