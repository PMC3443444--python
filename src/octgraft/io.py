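"""Image and segmentation I/O with explicit pixel-to-micron calibration.

B-scan orientation convention used throughout the package: the image is a
(rows, cols) array; the row index increases with axial depth (the anterior
corneal surface sits at small row indices), the column index increases
left-to-right laterally.  Curves are stored in (col, row) order so the
lateral position is the independent variable.

Calibration is never implicit: the scanner's export pixel pitch varies, so
every :class:`OCTImage` carries a :class:`Calibration` supplied by the
caller (CLI/config), and every metric output requires one.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from PIL import Image

from . import __version__
from .errors import ImageFormatError, SegmentationFormatError

__all__ = [
    "Calibration",
    "OCTImage",
    "SegmentationRecord",
    "load_image",
    "save_image",
    "save_segmentation",
    "load_segmentation",
]

#: default pixel pitch (µm/px), the axial resolution class of time-domain
#: anterior-segment scanners; always overridable.
DEFAULT_MICRONS_PER_PIXEL = 18.0


@dataclass(frozen=True)
class Calibration:
    """Pixel pitch in µm/px, lateral (columns) and axial (rows)."""

    microns_per_pixel_lateral: float = DEFAULT_MICRONS_PER_PIXEL
    microns_per_pixel_axial: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self):
        for name in ("microns_per_pixel_lateral", "microns_per_pixel_axial"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive number, got {v!r}")

    @property
    def um2_per_px2(self) -> float:
        return self.microns_per_pixel_lateral * self.microns_per_pixel_axial


@dataclass(frozen=True)
class OCTImage:
    """A calibrated 2-D grayscale B-scan with intensities in [0, 1]."""

    pixels: np.ndarray
    calibration: Calibration
    image_id: str = ""
    acquisition_meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImageFormatError(f"expected a 2-D grid, got {px.ndim} dimensions")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ImageFormatError(f"image too small: {px.shape}, need at least 32x32")
        if not np.isfinite(px).all():
            raise ImageFormatError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ImageFormatError(
                f"intensities must lie in [0, 1]; range is [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


_BIT_DEPTH_MAX = {np.uint8: 255.0, np.uint16: 65535.0}


def load_image(path: str | Path, calibration: Calibration,
               image_id: str | None = None) -> OCTImage:
    """Read a grayscale 8- or 16-bit PNG/TIFF and rescale to [0, 1].

    Intensities are divided by the bit-depth maximum (255 or 65535); the
    pixel grid shape is preserved.  Color images are rejected naming the
    channel count.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            bands = im.getbands()
            if len(bands) != 1:
                raise ImageFormatError(
                    f"{path.name}: expected a single-channel grayscale image, "
                    f"got {len(bands)} channels ({''.join(bands)})"
                )
            arr = np.asarray(im)
    except ImageFormatError:
        raise
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise ImageFormatError(f"unreadable image file {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL mode 'I' loads 16-bit PNG as int32
        scale = 65535.0
    else:
        raise ImageFormatError(
            f"{path.name}: unsupported pixel type {arr.dtype}; need 8- or 16-bit grayscale"
        )
    return OCTImage(arr.astype(float) / scale, calibration,
                    image_id=image_id if image_id is not None else path.stem)


def save_image(image: OCTImage, path: str | Path) -> None:
    """Write an :class:`OCTImage` as 16-bit grayscale PNG/TIFF.

    Intensities already quantised to the 16-bit grid (as phantom output is)
    round-trip pixel-identically through :func:`load_image`.
    """
    path = Path(path)
    arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)  # uint16 -> 16-bit grayscale


@dataclass(frozen=True)
class SegmentationRecord:
    """Serializable envelope for a graft segmentation.

    Bundles the segmentation with the source image id, the analysis mode
    tag and the software version; round-trips losslessly through JSON.
    """

    segmentation: Any  # GraftSegmentation; typed loosely to avoid an import cycle
    image_id: str
    mode: str
    calibration: Calibration | None = None
    software_version: str = __version__


def _curve_to_dict(curve) -> dict:
    return {
        "control_points": np.asarray(curve.control_points, dtype=float).tolist(),
        "smoothing": float(curve.smoothing),
    }


def save_segmentation(record: SegmentationRecord, path: str | Path) -> None:
    seg = record.segmentation
    doc = {
        "image_id": record.image_id,
        "mode": record.mode,
        "software_version": record.software_version,
        "corners": {name: list(map(float, pt))
                    for name, pt in seg.corners.as_dict().items()},
        "anterior": _curve_to_dict(seg.anterior),
        "posterior": _curve_to_dict(seg.posterior),
        "image_shape": list(seg.image_shape),
    }
    if record.calibration is not None:
        doc["calibration"] = {
            "microns_per_pixel_lateral": record.calibration.microns_per_pixel_lateral,
            "microns_per_pixel_axial": record.calibration.microns_per_pixel_axial,
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_segmentation(path: str | Path) -> SegmentationRecord:
    from .segmentation import CornerSet, GraftCurve, GraftSegmentation

    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SegmentationFormatError(
            f"{path.name}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    for key in ("corners", "anterior", "posterior", "mode", "image_id", "image_shape"):
        if key not in doc:
            raise SegmentationFormatError(f"{path.name}: missing required key {key!r}")
    try:
        corners = CornerSet(**{k: tuple(v) for k, v in doc["corners"].items()})
        curves = {
            side: GraftCurve(
                control_points=np.asarray(doc[side]["control_points"], dtype=float),
                smoothing=float(doc[side]["smoothing"]),
            )
            for side in ("anterior", "posterior")
        }
        seg = GraftSegmentation(
            anterior=curves["anterior"],
            posterior=curves["posterior"],
            corners=corners,
            mode=doc["mode"],
            image_shape=tuple(doc["image_shape"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SegmentationFormatError(f"{path.name}: invalid segmentation: {exc}") from exc
    cal = None
    if "calibration" in doc:
        cal = Calibration(**doc["calibration"])
    return SegmentationRecord(
        segmentation=seg,
        image_id=doc["image_id"],
        mode=doc["mode"],
        calibration=cal,
        software_version=doc.get("software_version", "unknown"),
    )
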