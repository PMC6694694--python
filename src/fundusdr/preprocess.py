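"""Field-of-view extraction and photometric normalization.

Non-mydriatic photographs vary widely in brightness, color balance and
exposure between cameras and operators.  Before any structure or lesion is
extracted, the circular field of view (ROI) is isolated from the black
border, the raster is median-denoised, and its lightness/saturation
statistics are matched to those of a standard reference image so that
downstream gray-level thresholds mean the same thing on every photograph.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from ._exceptions import ContractError, NoFieldFound
from .config import RunConfig
from .core import FundusImage, RoiMask

logger = logging.getLogger(__name__)


def _luminance(pixels: np.ndarray) -> np.ndarray:
    # Rec.601 luma; coefficients are conventional, not critical
    return pixels @ np.array([0.299, 0.587, 0.114])


def establish_roi(image: FundusImage, config: RunConfig | None = None) -> RoiMask:
    """Locate the circular camera field on the black photograph border.

    Adaptive luminance thresholding (local mean minus an offset, window
    about 1/8 of the frame) combined with an absolute dark floor yields
    field candidates; the largest connected component is hole-filled and
    checked against a disc template (intersection-over-union with the
    equivalent-area circle about its centroid).  If the frame has no black
    border at all, the ROI falls back to the full frame minus a 1-px
    margin.  Raises :class:`NoFieldFound` when no candidate covers the
    configured minimum fraction of the frame.
    """
    cfg = config or RunConfig()
    lum = _luminance(image.pixels.astype(np.float64))
    h, w = lum.shape
    window = max(min(h, w) // 8, 3)
    local_mean = ndimage.uniform_filter(lum, size=window)
    candidates = (lum > local_mean - cfg.roi_adaptive_offset) & (lum > cfg.roi_dark_floor)

    if candidates.mean() > cfg.roi_full_frame_frac:
        # uniformly bright frame: no black border to remove
        mask = np.zeros_like(candidates)
        mask[1:-1, 1:-1] = True
        return RoiMask(mask)

    labeled, n = ndimage.label(candidates)
    if n == 0:
        raise NoFieldFound("no above-floor pixels in the frame")
    sizes = ndimage.sum_labels(np.ones_like(lum), labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.roi_min_frac * h * w:
        raise NoFieldFound(
            f"largest bright component covers {sizes[best - 1] / (h * w):.1%} "
            f"of the frame (< {cfg.roi_min_frac:.0%})"
        )
    mask = ndimage.binary_fill_holes(labeled == best)

    # disc-template check: the field should be close to a circle
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    radius = np.sqrt(mask.sum() / np.pi)
    rr, wc = np.mgrid[0:h, 0:w]
    template = (rr - cr) ** 2 + (wc - cc) ** 2 <= radius**2
    iou = (mask & template).sum() / max((mask | template).sum(), 1)
    if iou < 0.55:
        logger.warning("field component is weakly circular (IoU %.2f vs disc template)", iou)
    return RoiMask(mask)


def denoise(image: FundusImage, radius: int = 1) -> FundusImage:
    """Per-channel median smoothing; ``radius=0`` is the identity."""
    if radius < 0:
        raise ContractError("denoise radius must be >= 0")
    if radius == 0:
        return image.copy()
    size = 2 * radius + 1
    out = np.empty_like(image.pixels)
    for ch in range(3):
        out[:, :, ch] = ndimage.median_filter(image.pixels[:, :, ch], size=size)
    return FundusImage(out, image.image_id, image.source_path)


@dataclass
class NormalizationProfile:
    """Target photometric statistics taken from a standard reference image.

    Means/SDs are on the 0-255 scale: ``target_lightness_*`` from the HSV
    value channel, ``target_saturation_mean`` from the saturation channel,
    and ``target_gray_range`` the (1st, 99th) luminance percentiles of the
    reference field.
    """

    target_lightness_mean: float
    target_lightness_sd: float
    target_saturation_mean: float
    target_gray_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.target_gray_range
        if not (0 <= lo < hi <= 255):
            raise ContractError("gray range must satisfy 0 <= low < high <= 255")
        if not (0 <= self.target_lightness_mean <= 255):
            raise ContractError("lightness mean out of [0, 255]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationProfile":
        d = json.loads(Path(path).read_text())
        d["target_gray_range"] = tuple(d["target_gray_range"])
        return cls(**d)


def make_profile(
    reference: FundusImage, roi: RoiMask, config: RunConfig | None = None
) -> NormalizationProfile:
    """Measure the normalization targets over the reference image's ROI."""
    cfg = config or RunConfig()
    if roi.area_px == 0:
        raise ContractError("empty ROI")
    hsv = rgb2hsv(reference.pixels)
    m = roi.mask
    v = hsv[:, :, 2][m] * 255.0
    s = hsv[:, :, 1][m]
    lum = _luminance(reference.pixels.astype(np.float64))[m]
    lo, hi = np.percentile(lum, cfg.profile_percentiles)
    if hi - lo < 1.0:  # flat reference: keep the range valid
        lo, hi = max(lo - 0.5, 0.0), min(max(lo + 1.0, hi + 0.5), 255.0)
    return NormalizationProfile(
        target_lightness_mean=float(v.mean()),
        target_lightness_sd=float(v.std()),
        target_saturation_mean=float(s.mean()),
        target_gray_range=(float(lo), float(min(hi, 255.0))),
    )


def normalize(
    image: FundusImage,
    roi: RoiMask,
    profile: NormalizationProfile,
    config: RunConfig | None = None,
) -> FundusImage:
    """Match the image's ROI lightness mean/SD and saturation mean to the
    profile (linear rescale of HSV value; multiplicative on saturation),
    clip to the valid range, and black out everything outside the ROI."""
    if roi.area_px == 0:
        raise ContractError("empty ROI")
    if roi.shape != image.shape:
        raise ContractError("ROI shape does not match image")
    hsv = rgb2hsv(image.pixels)
    m = roi.mask
    v = hsv[:, :, 2] * 255.0
    mean_in, sd_in = float(v[m].mean()), float(v[m].std())
    if sd_in < 1e-6:
        logger.warning("zero lightness SD in ROI; applying mean shift only")
        v_new = v + (profile.target_lightness_mean - mean_in)
    else:
        gain = profile.target_lightness_sd / sd_in
        v_new = (v - mean_in) * gain + profile.target_lightness_mean
    hsv[:, :, 2] = np.clip(v_new / 255.0, 0.0, 1.0)

    s = hsv[:, :, 1]
    s_mean = float(s[m].mean())
    if s_mean > 1e-6:
        hsv[:, :, 1] = np.clip(s * (profile.target_saturation_mean / s_mean), 0.0, 1.0)

    out = np.round(hsv2rgb(hsv) * 255.0).astype(np.uint8)
    out[~m] = 0
    return FundusImage(out, image.image_id, image.source_path)


# ---------------------------------------------------------------------------
# standard reference


def standard_reference(config: RunConfig | None = None) -> tuple[FundusImage, RoiMask]:
    """The shipped 'standard image': a clean synthetic scene with fixed seed.

    Users normalizing real photographs should supply their own reference
    via :func:`make_profile`.
    """
    from .synthetic import SceneSpec, render_scene

    image, _ = render_scene(SceneSpec(seed=20_0913))
    roi = establish_roi(image, config)
    return image, roi


def standard_profile(config: RunConfig | None = None) -> NormalizationProfile:
    image, roi = standard_reference(config)
    return make_profile(image, roi, config)
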