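"""Image and annotation I/O plus the package's coordinate conventions.

Conventions used throughout retmorph:

* pixel coordinates are 0-based ``(row, col)`` with row increasing downward;
* images are 8-bit rasters (2-D grayscale or H x W x 3 RGB);
* all geometry is expressed in pixel units unless a physical ``pixel_size``
  is supplied on the :class:`FundusImage` (fundus cameras rarely export a
  trustworthy calibration, so none is assumed).

The "red-free" working image — the representation on which vessels show the
strongest contrast — is the green channel of an RGB fundus photograph, the
standard ophthalmic convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import AnnotationError, FormatError

__all__ = [
    "FundusImage",
    "SegmentAnnotation",
    "load_image",
    "save_image",
    "to_red_free",
    "load_annotations",
    "save_annotations",
]

ChannelMode = Literal["rgb", "grayscale", "red_free"]

#: Smallest raster accepted as a fundus photograph (either dimension).
MIN_IMAGE_SIDE = 64

VESSEL_CLASSES = ("arteriole", "venule")


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit fundus photograph (or derived single-channel working image).

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, 3)`` array of dtype uint8.
    channel_mode
        ``"rgb"`` for colour photographs, ``"grayscale"`` for single-channel
        captures, ``"red_free"`` for the green-channel working image.
    pixel_size
        Optional physical scale (length per pixel). Purely informational;
        every computation in the package stays in pixel units.
    """

    pixels: np.ndarray
    channel_mode: ChannelMode = "grayscale"
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise FormatError(f"pixels must be uint8, got {px.dtype}")
        if px.ndim == 2:
            if self.channel_mode == "rgb":
                raise FormatError("2-D raster cannot be channel_mode='rgb'")
        elif px.ndim == 3 and px.shape[2] == 3:
            if self.channel_mode != "rgb":
                raise FormatError("3-channel raster must be channel_mode='rgb'")
        else:
            raise FormatError(f"unsupported raster shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise FormatError(
                f"image {px.shape[0]}x{px.shape[1]} below minimum "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class SegmentAnnotation:
    """Operator-selected vessel segment: endpoints between the optic-disc edge
    and the first vascular bifurcation, with the operator's artery/vein call."""

    vessel_id: str
    vessel_class: str
    start: tuple[int, int]
    end: tuple[int, int]

    def __post_init__(self) -> None:
        if self.vessel_class not in VESSEL_CLASSES:
            raise AnnotationError(
                f"vessel {self.vessel_id!r}: unknown vessel_class "
                f"{self.vessel_class!r} (expected one of {VESSEL_CLASSES})"
            )
        if tuple(self.start) == tuple(self.end):
            raise AnnotationError(
                f"vessel {self.vessel_id!r}: start and end coincide"
            )
        for name, pt in (("start", self.start), ("end", self.end)):
            if len(pt) != 2 or any(int(v) < 0 for v in pt):
                raise AnnotationError(
                    f"vessel {self.vessel_id!r}: {name} coordinate {pt} invalid"
                )


def load_image(path: str | Path) -> FundusImage:
    """Read a PNG/TIFF/JPEG raster into a :class:`FundusImage`.

    16-bit inputs are rescaled to 8-bit; RGBA alpha channels are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises many concrete types
        raise FormatError(f"cannot read raster {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    mode: ChannelMode = "rgb" if arr.ndim == 3 else "grayscale"
    return FundusImage(pixels=arr, channel_mode=mode)


def save_image(img: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an image (or bare array / boolean mask) as PNG/TIFF/JPEG."""
    arr = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    iio.imwrite(Path(path), arr.astype(np.uint8))


def to_red_free(img: FundusImage) -> FundusImage:
    """Return the red-free (green channel) working image.

    Grayscale and already red-free inputs pass through unchanged, which makes
    the operation idempotent.
    """
    if img.channel_mode in ("grayscale", "red_free"):
        if img.channel_mode == "red_free":
            return img
        return replace(img, channel_mode="red_free")
    green = np.ascontiguousarray(img.pixels[:, :, 1])
    return FundusImage(pixels=green, channel_mode="red_free",
                       pixel_size=img.pixel_size)


_ANNOT_COLUMNS = ["vessel_id", "vessel_class", "start_row", "start_col",
                  "end_row", "end_col"]


def load_annotations(
    path: str | Path,
    image_shape: tuple[int, int] | None = None,
) -> list[SegmentAnnotation]:
    """Parse the per-image segment-annotation CSV.

    Expected header: ``vessel_id,vessel_class,start_row,start_col,end_row,
    end_col``. When ``image_shape`` is given, coordinates are checked to lie
    inside the image. Validation of the 2-arteriole + 2-venule rule is
    deferred to AVR computation so partial annotation files remain loadable.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse annotation CSV {path}: {exc}") from exc
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation CSV missing column(s): {missing}")

    annotations: list[SegmentAnnotation] = []
    for i, row in df.iterrows():
        try:
            coords = [int(row[c]) for c in _ANNOT_COLUMNS[2:]]
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"row {i}: non-integer coordinate") from exc
        if any(c < 0 for c in coords):
            raise AnnotationError(
                f"row {i} (vessel {row['vessel_id']!r}): negative coordinate "
                f"{tuple(coords)}"
            )
        if image_shape is not None:
            h, w = image_shape[:2]
            for which, (r, c) in (("start", coords[:2]), ("end", coords[2:])):
                if r >= h or c >= w:
                    raise AnnotationError(
                        f"row {i} (vessel {row['vessel_id']!r}): {which} "
                        f"({r}, {c}) outside {h}x{w} image"
                    )
        try:
            ann = SegmentAnnotation(
                vessel_id=str(row["vessel_id"]),
                vessel_class=str(row["vessel_class"]),
                start=(coords[0], coords[1]),
                end=(coords[2], coords[3]),
            )
        except AnnotationError as exc:
            raise AnnotationError(f"row {i}: {exc}") from exc
        annotations.append(ann)
    return annotations


def save_annotations(annotations: list[SegmentAnnotation],
                     path: str | Path) -> None:
    rows = [
        {
            "vessel_id": a.vessel_id,
            "vessel_class": a.vessel_class,
            "start_row": a.start[0],
            "start_col": a.start[1],
            "end_row": a.end[0],
            "end_col": a.end[1],
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, index=False)
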