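"""Retinal anatomy: vessel segmentation, optic-disc localization, quadrants.

Vessels are the darkest elongated structures on the green channel, so the
detector is a classic multi-orientation line operator: the response at a
pixel is the local background mean minus the mean along the best-aligned
short line segment, maximized over orientations and two lengths.  The
thresholded response is optionally refined by a per-pixel color classifier
(a shipped linear fixture trained on generator-labeled scenes) that
suppresses dark non-vessel structure such as hemorrhages.

The optic disc is the bright, circular blob that the vessel tree converges
on; candidates are scored by a weighted sum of brightness, circularity and
vessel convergence.  Low-confidence results are returned flagged (they feed
the quality gate), never raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError, ContractError
from ._models import LinearModel, load_bundled
from .config import RunConfig
from .core import FundusImage, RoiMask


@dataclass
class VesselMap:
    mask: np.ndarray
    vessel_fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class OpticDisc:
    center: tuple[float, float]
    radius_px: float
    confidence: float

    @property
    def low_confidence(self) -> bool:
        return self.confidence < 1e-9


@dataclass
class QuadrantMap:
    """Label raster assigning each ROI pixel to quadrant 1-4 about the
    posterior-pole reference center (0 outside the ROI)."""

    labels: np.ndarray
    center: tuple[float, float]

    def quadrant_of(self, row: float, col: float) -> int:
        r, c = self.center
        if row < r:
            return 1 if col >= c else 2
        return 4 if col >= c else 3


# ---------------------------------------------------------------------------
# vessels

VESSEL_FEATURES = ["red", "green", "blue", "lineness", "anisotropy", "green_minus_local"]


def _line_kernels(length: int, n_orientations: int) -> list[np.ndarray]:
    """Unit-sum line kernels at evenly spaced orientations."""
    kernels = []
    half = length // 2
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        kern = np.zeros((length, length))
        for t in range(-half, half + 1):
            r = int(round(half + t * np.sin(theta)))
            c = int(round(half + t * np.cos(theta)))
            kern[r, c] = 1.0
        kernels.append(kern / kern.sum())
    return kernels


def line_response(
    green: np.ndarray, config: RunConfig, width: int, return_anisotropy: bool = False
):
    """Multi-orientation dark-line response on the green channel
    (background mean minus best-aligned line mean), in gray levels.

    With ``return_anisotropy`` also returns response minus the
    worst-orientation response: high for true line structure, low for
    isotropically dark blobs whose every orientation responds alike.
    """
    response = np.zeros_like(green)
    worst = np.zeros_like(green)
    for length in config.vessel_line_lengths:
        length = max(3, int(round(config.scaled(length, width))) | 1)
        local = ndimage.uniform_filter(green, size=2 * length + 1)
        scale_min = None
        for kern in _line_kernels(length, config.vessel_n_orientations):
            r = local - ndimage.correlate(green, kern, mode="nearest")
            np.maximum(response, r, out=response)
            scale_min = r if scale_min is None else np.minimum(scale_min, r)
        np.maximum(worst, scale_min, out=worst)
    if return_anisotropy:
        return response, response - worst
    return response


def _vessel_feature_stack(
    image: FundusImage, lineness: np.ndarray, anisotropy: np.ndarray
) -> np.ndarray:
    px = image.pixels.astype(np.float64)
    green = px[:, :, 1]
    local = ndimage.uniform_filter(green, size=25)
    feats = np.stack(
        [px[:, :, 0], green, px[:, :, 2], lineness, anisotropy, green - local], axis=-1
    )
    return feats


def segment_vessels(
    image: FundusImage,
    roi: RoiMask,
    model: LinearModel | None = None,
    config: RunConfig | None = None,
) -> VesselMap:
    """Extract the vessel map from a normalized image.

    ``model=None`` with refinement enabled loads the shipped fixture;
    passing ``config.vessel_use_classifier=False`` skips refinement and
    keeps the raw thresholded line response.
    """
    cfg = config or RunConfig()
    if roi.area_px == 0:
        raise ContractError("empty ROI")
    h, w = image.shape
    green = image.pixels[:, :, 1].astype(np.float64)
    lineness, anisotropy = line_response(green, cfg, w, return_anisotropy=True)
    candidates = (lineness > cfg.vessel_threshold) & roi.mask
    # the field border is a dark edge: keep clear of it
    interior = ndimage.binary_erosion(roi.mask, iterations=3)
    candidates &= interior

    if cfg.vessel_use_classifier:
        if model is None:
            try:
                model = load_bundled("vessel_pixel")
            except ConfigurationError:
                raise ConfigurationError(
                    "vessel refinement enabled but no pixel classifier available"
                )
        feats = _vessel_feature_stack(image, lineness, anisotropy)
        idx = np.nonzero(candidates)
        if idx[0].size:
            # operating point biased toward vessel recall: missing a vessel
            # chunk costs a red-lesion false positive downstream, while
            # over-calling is recoverable by the candidate strip-and-requeue
            scores = model.decision_function(feats[idx])
            keep = scores > -cfg.vessel_decision_shift
            candidates = np.zeros_like(candidates)
            candidates[idx[0][keep], idx[1][keep]] = True
        # bridge 1-px gaps the per-pixel decision leaves along a vessel
        candidates = ndimage.binary_closing(candidates, structure=np.ones((3, 3)))
        candidates &= interior
        # reclaim rejected line-response components that reconnect the tree
        # (dark chunks at crossings/overlaps look isotropic pixel-wise but
        # touch the accepted network on two or more disjoint arcs)
        raw = (lineness > cfg.vessel_threshold) & interior
        rejected, n_rej = ndimage.label(raw & ~candidates)
        cap = cfg.scaled(400, w, power=2)
        for i in range(1, n_rej + 1):
            chunk = rejected == i
            area = chunk.sum()
            if area < 8 or area > cap:
                continue
            contacts = ndimage.label(ndimage.binary_dilation(chunk, iterations=2) & candidates)[1]
            if contacts >= 2:
                candidates |= chunk

    # drop small spurious components
    min_px = max(1, int(round(cfg.scaled(cfg.vessel_min_component_px, w, power=2))))
    labeled, n = ndimage.label(candidates)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(green), labeled, index=np.arange(1, n + 1))
        keep_ids = np.flatnonzero(sizes >= min_px) + 1
        candidates = np.isin(labeled, keep_ids)
    mask = candidates & roi.mask
    return VesselMap(mask, vessel_fraction=float(mask.sum() / roi.area_px))


def build_vessel_corpus(
    n_scenes: int = 4,
    seed: int = 0,
    samples_per_scene: int = 25000,
    config: RunConfig | None = None,
):
    """Generator-labeled pixel corpus for the vessel color classifier.

    Candidate pixels (line response above threshold) from synthetic scenes
    containing red and bright lesions, labeled 'vessel'/'not' by the
    ground-truth raster.  Returns (X, y, feature_names).
    """
    from .preprocess import denoise, establish_roi, normalize, standard_profile
    from .synthetic import LesionLoad, SceneSpec, render_scene

    cfg = config or RunConfig()
    prof = standard_profile(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    X, y = [], []
    # sparse, dense and large-lesion scenes: the classifier must reject
    # hemorrhage pixels across the whole lesion-density range
    hem_loads = [
        LesionLoad((4, 8), (50.0, 500.0), 0.85),
        LesionLoad((18, 26), (140.0, 700.0), 0.85),
        LesionLoad((6, 10), (900.0, 2600.0), 0.85),
    ]
    for i in range(n_scenes):
        spec = SceneSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            lesion_loads={
                "microaneurysm": LesionLoad((2, 5), (6.0, 28.0), 0.85),
                "hemorrhage": hem_loads[i % 3],
                "exudate": LesionLoad((2, 6), (60.0, 400.0), 0.85),
            },
        )
        image, truth = render_scene(spec)
        roi = establish_roi(image, cfg)
        norm = normalize(denoise(image, cfg.denoise_radius), roi, prof, cfg)
        green = norm.pixels[:, :, 1].astype(np.float64)
        lineness, anisotropy = line_response(green, cfg, image.shape[1], return_anisotropy=True)
        interior = ndimage.binary_erosion(roi.mask, iterations=3)
        cand = (lineness > min(cfg.vessel_threshold, 3.0)) & interior
        feats = _vessel_feature_stack(norm, lineness, anisotropy)
        vt = truth.class_mask("vessel")
        idx = np.nonzero(cand)
        sel = rng.choice(idx[0].size, size=min(samples_per_scene, idx[0].size), replace=False)
        X.append(feats[idx[0][sel], idx[1][sel]])
        y.append(np.where(vt[idx[0][sel], idx[1][sel]], "vessel", "not"))
    return np.vstack(X), np.concatenate(y), list(VESSEL_FEATURES)


# ---------------------------------------------------------------------------
# optic disc


def locate_optic_disc(
    image: FundusImage,
    vessels: VesselMap,
    roi: RoiMask,
    config: RunConfig | None = None,
) -> OpticDisc:
    """Score bright-blob candidates by brightness, circularity and vessel
    convergence; return the best with confidence = its normalized score."""
    cfg = config or RunConfig()
    h, w = image.shape
    lum = image.pixels.astype(np.float64).mean(axis=2)
    roi_radius = roi.equivalent_radius
    disc_r = cfg.disc_radius_frac * roi_radius

    smooth = ndimage.uniform_filter(lum, size=max(3, int(disc_r)))
    vals = smooth[roi.mask]
    cut = np.percentile(vals, 98.5)
    bright = (smooth >= cut) & roi.mask
    labeled, n = ndimage.label(bright)
    if n == 0:
        r0, c0 = roi.center
        return OpticDisc((r0, c0), disc_r, confidence=0.0)

    best_score, best = -np.inf, None
    brightness_terms = {}
    lum_lo, lum_hi = np.percentile(lum[roi.mask], [2, 99.8])
    for lbl in range(1, n + 1):
        comp = labeled == lbl
        area = comp.sum()
        if area < 0.05 * np.pi * disc_r**2:
            continue
        rows, cols = np.nonzero(comp)
        cr, cc = rows.mean(), cols.mean()
        eq_r = np.sqrt(area / np.pi)
        # circularity: IoU with the equivalent circle
        rr, wc = np.mgrid[0:h, 0:w]
        circ_mask = (rr - cr) ** 2 + (wc - cc) ** 2 <= eq_r**2
        circularity = (comp & circ_mask).sum() / max((comp | circ_mask).sum(), 1)
        # brightness percentile term
        brightness = np.clip((lum[comp].mean() - lum_lo) / max(lum_hi - lum_lo, 1e-9), 0, 1)
        # vessel convergence: vessel density in a ring around the candidate
        ring = ((rr - cr) ** 2 + (wc - cc) ** 2 <= (2.5 * disc_r) ** 2) & roi.mask
        conv = vessels.mask[ring].mean() if ring.any() else 0.0
        conv = np.clip(conv / 0.25, 0, 1)
        score = (
            cfg.disc_brightness_weight * brightness
            + cfg.disc_circularity_weight * circularity
            + cfg.disc_convergence_weight * conv
        )
        brightness_terms[lbl] = brightness
        # ties broken by the brightness term
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12
            and best is not None
            and brightness > brightness_terms.get(best[3], -1)
        ):
            best_score, best = score, ((cr, cc), eq_r, score, lbl)

    if best is None:
        r0, c0 = roi.center
        return OpticDisc((r0, c0), disc_r, confidence=0.0)
    (cr, cc), eq_r, score, _ = best
    radius = float(np.clip(eq_r, 0.05 * roi_radius, 0.25 * roi_radius))
    return OpticDisc((float(cr), float(cc)), radius, confidence=float(np.clip(score, 0, 1)))


def export_anatomy(vessels: VesselMap, disc: OpticDisc, out_dir) -> None:
    """Write the vessel mask as PNG and the disc geometry as JSON."""
    import json
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "vessels.png", (vessels.mask * 255).astype(np.uint8))
    record = {
        "vessel_fraction": round(vessels.vessel_fraction, 6),
        "disc": {
            "center_row": round(disc.center[0], 2),
            "center_col": round(disc.center[1], 2),
            "radius_px": round(disc.radius_px, 2),
            "confidence": round(disc.confidence, 4),
        },
    }
    (out / "anatomy.json").write_text(json.dumps(record, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# quadrants


def partition_quadrants(
    roi: RoiMask,
    disc: OpticDisc,
    laterality: str = "OD",
    config: RunConfig | None = None,
) -> QuadrantMap:
    """Split the ROI into four quadrants about the posterior-pole center
    (the disc center shifted toward the macula, i.e. temporally)."""
    cfg = config or RunConfig()
    if not roi.mask[int(round(disc.center[0])) % roi.shape[0], int(round(disc.center[1])) % roi.shape[1]]:
        raise ContractError("disc center lies outside the ROI")
    roi_radius = roi.equivalent_radius
    direction = -1.0 if laterality == "OD" else 1.0  # macula is temporal to the disc
    center = (
        disc.center[0],
        disc.center[1] + direction * cfg.macula_offset_frac * roi_radius,
    )
    h, w = roi.shape
    rows, cols = np.mgrid[0:h, 0:w]
    upper = rows < center[0]
    right = cols >= center[1]
    labels = np.where(upper, np.where(right, 1, 2), np.where(right, 4, 3))
    labels = np.where(roi.mask, labels, 0).astype(np.uint8)
    return QuadrantMap(labels, center)
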