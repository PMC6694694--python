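"""Core raster containers, grading records, image/report I/O and the lesion overlay.

Conventions used throughout the package:

* pixel rasters are numpy arrays indexed ``[row, col]``, row 0 at top;
* color images are ``H x W x 3`` uint8 in RGB channel order;
* lesion areas are raw pixel counts (no mm^2 calibration is attempted).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._exceptions import ContractError, ImageReadError, ImageSizeError

logger = logging.getLogger(__name__)

MIN_FRAME = 128

#: lesion classes whose pixels belong to the "red" (hemorrhage) family
RED_FAMILY = ("microaneurysm", "hemorrhage")
#: lesion classes whose pixels belong to the "bright" (exudate) family
BRIGHT_FAMILY = ("exudate", "cottonwool")

OVERLAY_GREEN = np.array([0, 255, 0], dtype=np.uint8)
OVERLAY_BLUE = np.array([0, 0, 255], dtype=np.uint8)


class Stage(str, Enum):
    """Retinopathy stage emitted by the grading cascade.

    DR0-DR3 follow the international severity scale (no DR, mild NPDR,
    moderate NPDR, severe NPDR).  PDR is kept distinct from DR3; a
    configurable collapse map can pool them for comparison against
    graders who report severe NPDR and PDR in one category.  PRP marks a
    photocoagulation scar pattern and UNGRADABLE a failed quality gate.
    """

    DR0 = "DR0"
    DR1 = "DR1"
    DR2 = "DR2"
    DR3 = "DR3"
    PDR = "PDR"
    PRP = "PRP"
    OTHER = "OTHER"
    UNGRADABLE = "UNGRADABLE"


#: ordering used by the staging-monotonicity property (severity rank)
STAGE_SEVERITY = {
    Stage.DR0: 0,
    Stage.DR1: 1,
    Stage.DR2: 2,
    Stage.DR3: 3,
    Stage.PDR: 4,
}


@dataclass
class FundusImage:
    """A color fundus photograph.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        RGB samples.
    image_id : str
        Stable identifier used in reports.
    source_path : str
        Originating file, or ``""`` for in-memory images.
    """

    pixels: np.ndarray
    image_id: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ContractError(f"expected HxWx3 raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ContractError("pixel samples must lie in [0, 255]")
            px = px.astype(np.uint8)
        if px.shape[0] < MIN_FRAME or px.shape[1] < MIN_FRAME:
            raise ImageSizeError(
                f"frame {px.shape[0]}x{px.shape[1]} below minimum {MIN_FRAME}x{MIN_FRAME}"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def copy(self) -> "FundusImage":
        return FundusImage(self.pixels.copy(), self.image_id, self.source_path)


@dataclass
class RoiMask:
    """Binary mask of the circular camera field of view."""

    mask: np.ndarray
    area_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ContractError("ROI mask must be 2-D")
        self.area_px = int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def center(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        if rows.size == 0:
            raise ContractError("empty ROI has no center")
        return float(rows.mean()), float(cols.mean())

    @property
    def equivalent_radius(self) -> float:
        """Radius of the circle with the same pixel area."""
        return float(np.sqrt(self.area_px / np.pi))


# label codes of the synthetic ground-truth raster, shared with the generator
GT_CLASSES = (
    "background",
    "field",
    "vessel",
    "disc",
    "macula",
    "microaneurysm",
    "hemorrhage",
    "exudate",
    "cottonwool",
    "prp_scar",
)
GT_CODE = {name: i for i, name in enumerate(GT_CLASSES)}


@dataclass
class GroundTruthRegion:
    region_id: int
    lesion_class: str
    pixel_area: int
    centroid: tuple[float, float]


@dataclass
class GroundTruth:
    """Exact per-pixel labels and region table for a synthetic scene."""

    label_raster: np.ndarray
    regions: list[GroundTruthRegion] = field(default_factory=list)

    def class_mask(self, name: str) -> np.ndarray:
        return self.label_raster == GT_CODE[name]

    def regions_of(self, *names: str) -> list[GroundTruthRegion]:
        return [r for r in self.regions if r.lesion_class in names]


@dataclass
class GradingRecord:
    """One image's end-to-end outcome: stage, quality gate and quantification."""

    image_id: str
    stage: Stage
    quality: "object" = None  # QualityReport; typed loosely to avoid cycles
    quant: "object" = None  # QuantReport

    def __post_init__(self) -> None:
        if self.quality is not None:
            ungradable = self.stage == Stage.UNGRADABLE
            if ungradable != (not self.quality.qualified):
                raise ContractError("stage is UNGRADABLE iff quality.qualified is false")


def read_image(path: str | Path) -> FundusImage:
    """Read a PNG/JPEG/TIFF photograph as an 8-bit RGB :class:`FundusImage`.

    Grayscale inputs are replicated to three channels (with a logged
    warning); an alpha channel is dropped.  Images smaller than 128 px on
    either side raise :class:`ImageSizeError`; undecodable files raise
    :class:`ImageReadError`.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such file: {path}")
    try:
        px = iio.imread(path)
    except Exception as exc:  # imageio raises various decoder errors
        raise ImageReadError(f"cannot decode {path}: {exc}") from exc
    px = np.asarray(px)
    if px.ndim == 2:
        logger.warning("grayscale input %s replicated to 3 channels", path)
        px = np.stack([px] * 3, axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    elif px.ndim != 3 or px.shape[2] != 3:
        raise ImageReadError(f"unsupported raster shape {px.shape} in {path}")
    if px.dtype != np.uint8:
        # 16-bit TIFFs: rescale to 8 bits
        px = (px.astype(np.float64) / px.max() * 255.0).round().astype(np.uint8)
    if px.shape[0] < MIN_FRAME or px.shape[1] < MIN_FRAME:
        raise ImageSizeError(
            f"{path}: frame {px.shape[0]}x{px.shape[1]} below minimum {MIN_FRAME}"
        )
    return FundusImage(px, image_id=path.stem, source_path=str(path))


def write_image(image: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an RGB raster losslessly (PNG recommended)."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    iio.imwrite(Path(path), px)


def write_overlay(
    image: FundusImage,
    lesions: "object",
    path: str | Path | None,
    green_over_blue: bool = True,
) -> FundusImage:
    """Render the lesion overlay: hemorrhage-family pixels saturated green,
    exudate-family pixels saturated blue.

    The fill is saturated rather than alpha-blended so that per-color pixel
    counts in the rendered file equal the quantified lesion areas exactly.
    Pixels claimed by both families follow the tie rule (default: green
    wins).  When ``path`` is None the overlay is returned without writing.
    """
    red_mask = lesions.family_mask("red")
    bright_mask = lesions.family_mask("bright")
    if red_mask.shape != image.shape or bright_mask.shape != image.shape:
        raise ContractError("lesion masks do not match image shape")
    out = image.pixels.copy()
    if green_over_blue:
        out[bright_mask] = OVERLAY_BLUE
        out[red_mask] = OVERLAY_GREEN
    else:
        out[red_mask] = OVERLAY_GREEN
        out[bright_mask] = OVERLAY_BLUE
    result = FundusImage(out, image_id=image.image_id + "_overlay")
    if path is not None:
        write_image(result, path)
    return result


REPORT_COLUMNS = [
    "image_id",
    "stage",
    "qualified",
    "quality_flags",
    "hemorrhage_total_area_px",
    "hemorrhage_count",
    "hemorrhage_max_area_px",
    "exudate_total_area_px",
    "exudate_count",
    "exudate_max_area_px",
]


def _record_row(rec: GradingRecord) -> dict:
    q = rec.quality
    quant = rec.quant
    return {
        "image_id": rec.image_id,
        "stage": rec.stage.value,
        "qualified": bool(q.qualified) if q is not None else True,
        "quality_flags": ";".join(sorted(q.flags)) if q is not None else "",
        "hemorrhage_total_area_px": quant.hemorrhage_total_area_px if quant else 0,
        "hemorrhage_count": quant.hemorrhage_count if quant else 0,
        "hemorrhage_max_area_px": quant.hemorrhage_max_area_px if quant else 0,
        "exudate_total_area_px": quant.exudate_total_area_px if quant else 0,
        "exudate_count": quant.exudate_count if quant else 0,
        "exudate_max_area_px": quant.exudate_max_area_px if quant else 0,
    }


def write_report(
    records: Sequence[GradingRecord], path: str | Path, format: str = "csv"
) -> None:
    """Write per-image grading/quantification rows as CSV (RFC 4180) or JSON.

    The CSV header is fixed to :data:`REPORT_COLUMNS`; the stage enum is
    serialized as its literal name (e.g. ``"DR2"``).
    """
    if not records:
        raise ContractError("record list must be non-empty")
    rows = [_record_row(r) for r in records]
    fmt = format.lower()
    path = Path(path)
    if fmt == "csv":
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=2), encoding="utf-8")
    else:
        raise ContractError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report` (either format)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
    return pd.read_csv(path, keep_default_na=False)
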