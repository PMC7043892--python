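"""Calibrated movie I/O and region-of-interest geometry.

Conventions used throughout the package:

* array axis order is ``(t, y, x)``; pixel coordinates are 0-based with the
  origin at the top-left pixel centre, and continuous coordinates refer to
  pixel centres;
* the image x-axis is the worm's anterior-posterior (AP) axis;
* physical quantities are micrometres and seconds; pixel→µm conversion
  happens exactly once, at measurement time, via the :class:`Movie`
  calibration.

Calibration travels in a JSON sidecar (``<movie>.json``) next to the TIFF;
ImageJ-style TIFF metadata is read when present but the sidecar wins on
conflict.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Movie",
    "RoiSpec",
    "load_movie",
    "save_movie",
    "roi_mask",
    "circle_from_area_um2",
]


class FormatError(ValueError):
    """Raised for unsupported image layouts (RGB, missing calibration...)."""


class GeometryError(ValueError):
    """Raised when an ROI does not fit inside the frame."""


@dataclass
class Movie:
    """A calibrated single-channel time-lapse stack.

    Parameters
    ----------
    frames:
        ``(T, H, W)`` array of non-negative intensities.
    pixel_size_um:
        Lateral calibration, µm per pixel (> 0).
    frame_interval_s:
        Time between consecutive frames, seconds (> 0).
    t0_wound:
        Frame index at which the wound was inflicted, or ``None`` for
        unwounded acquisitions.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    t0_wound: int | None = None
    #: residual images (e.g. unclamped background-subtracted movies) may
    #: legitimately contain negative values
    residual: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise FormatError(
                f"movie must be (T, H, W), got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape
        if t < 1 or h < 8 or w < 8:
            raise FormatError(f"movie too small: {self.frames.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not (self.frame_interval_s > 0):
            raise ValueError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        if np.issubdtype(self.frames.dtype, np.floating):
            if not np.all(np.isfinite(self.frames)):
                raise ValueError("movie intensities must be finite")
            if not self.residual and self.frames.min() < 0:
                raise ValueError("movie intensities must be >= 0")

    # -- derived geometry ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def times_s(self) -> np.ndarray:
        """Frame times in seconds; relative to wounding when t0 is known."""
        t = np.arange(self.n_frames, dtype=float) * self.frame_interval_s
        if self.t0_wound is not None:
            t -= self.t0_wound * self.frame_interval_s
        return t

    def with_frames(self, frames: np.ndarray, **overrides) -> "Movie":
        """Copy calibration onto a new frame array."""
        return replace(self, frames=frames, **overrides)


@dataclass
class RoiSpec:
    """Circle or rectangle region of interest in pixel coordinates.

    ``centre`` is ``(y, x)`` in continuous pixel coordinates.  Circles take
    ``radius_px``; rectangles take ``height_px``/``width_px`` (the rectangle
    spans ``centre ± size/2`` and is rasterised to whole pixels).
    """

    shape: str  # "circle" | "rectangle"
    centre: tuple[float, float]
    radius_px: float | None = None
    height_px: int | None = None
    width_px: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rectangle"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "circle" and not (self.radius_px and self.radius_px > 0):
            raise ValueError("circle ROI needs radius_px > 0")
        if self.shape == "rectangle" and not (
            self.height_px and self.width_px and self.height_px > 0 and self.width_px > 0
        ):
            raise ValueError("rectangle ROI needs height_px, width_px > 0")

    def analytic_area_px2(self) -> float:
        if self.shape == "circle":
            return math.pi * self.radius_px**2
        return float(self.height_px * self.width_px)

    def area_um2(self, pixel_size_um: float, frame_shape=None) -> float:
        """Physical area from the rasterised pixel count."""
        if frame_shape is None:
            n = self.analytic_area_px2()
        else:
            n = int(roi_mask(self, frame_shape).sum())
        return n * pixel_size_um**2

    def bounds(self) -> tuple[float, float, float, float]:
        cy, cx = self.centre
        if self.shape == "circle":
            r = self.radius_px
            return cy - r, cy + r, cx - r, cx + r
        return (
            cy - self.height_px / 2,
            cy + self.height_px / 2,
            cx - self.width_px / 2,
            cx + self.width_px / 2,
        )


def circle_from_area_um2(area_um2: float, centre, pixel_size_um: float) -> RoiSpec:
    """Circle ROI whose physical area is ``area_um2`` at the given calibration."""
    r_um = math.sqrt(area_um2 / math.pi)
    return RoiSpec("circle", tuple(centre), radius_px=r_um / pixel_size_um)


def roi_mask(roi: RoiSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an ROI to a boolean mask over an ``(H, W)`` frame.

    A pixel belongs to a circle when its centre lies within the radius.
    Raises :class:`GeometryError` when the ROI extends past the frame.
    """
    h, w = shape
    y0, y1, x0, x1 = roi.bounds()
    # pixels are selected by their centres, so bounds may overhang by half a pixel
    if y0 < -0.5 or x0 < -0.5 or y1 > h - 0.5 or x1 > w - 0.5:
        raise GeometryError(
            f"ROI bounds ({y0:.1f},{x0:.1f})-({y1:.1f},{x1:.1f}) exceed frame {shape}"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = roi.centre
    if roi.shape == "circle":
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= roi.radius_px**2
    # half-open integer span: exactly height_px × width_px pixels
    return (yy >= y0) & (yy < y0 + roi.height_px) & (xx >= x0) & (xx < x0 + roi.width_px)


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_movie(movie: Movie, path) -> Path:
    """Write a movie as a multi-page grayscale TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    meta = {
        "pixel_size_um": float(movie.pixel_size_um),
        "frame_interval_s": float(movie.frame_interval_s),
        "t0_wound": movie.t0_wound,
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))
    return path


def _calibration_from_tiff(tif: tifffile.TiffFile) -> dict:
    """Best-effort read of ImageJ-style calibration from TIFF metadata."""
    out: dict = {}
    ij = tif.imagej_metadata or {}
    if "finterval" in ij:
        out["frame_interval_s"] = float(ij["finterval"])
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        unit = ij.get("unit", "")
        if num and unit in ("um", "micron", "µm"):
            out["pixel_size_um"] = den / num
    return out


def load_movie(
    path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    t0_wound: int | None = None,
) -> Movie:
    """Load a grayscale multi-page TIFF as a calibrated :class:`Movie`.

    Calibration precedence: explicit arguments > JSON sidecar > TIFF
    metadata.  Missing calibration from all three sources is an error, as is
    RGB/multi-sample input.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = _calibration_from_tiff(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path.name}: expected grayscale T×H×W stack, got shape {arr.shape}"
        )
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if pixel_size_um is not None:
        meta["pixel_size_um"] = pixel_size_um
    if frame_interval_s is not None:
        meta["frame_interval_s"] = frame_interval_s
    if t0_wound is not None:
        meta["t0_wound"] = t0_wound
    if "pixel_size_um" not in meta or "frame_interval_s" not in meta:
        raise FormatError(
            f"{path.name}: no calibration in arguments, sidecar or TIFF metadata"
        )
    for key in ("pixel_size_um", "frame_interval_s"):
        if not (meta[key] and meta[key] > 0):
            raise ValueError(f"{key} must be > 0, got {meta[key]}")
    return Movie(
        frames=arr,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        t0_wound=meta.get("t0_wound"),
    )
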