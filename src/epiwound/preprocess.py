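"""Movie conditioning: drift correction, temporal-median background
subtraction, and standard crop/substack extraction.

The default pipeline order is register → median-subtract; registration
estimates pure translation (rotation/scaling are out of scope for
stage-drift correction), and the temporal median uses a centred window that
shrinks at the ends of the movie so early post-wound frames stay usable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .imgio import Movie, RoiSpec

__all__ = [
    "MedianFilterParams",
    "DriftTrace",
    "register_translation",
    "temporal_median_subtract",
    "crop_substack",
]


@dataclass
class MedianFilterParams:
    window_frames: int = 31
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.window_frames < 3 or self.window_frames % 2 == 0:
            raise ValueError("window_frames must be an odd integer >= 3")


@dataclass
class DriftTrace:
    """Per-frame (dy, dx) shifts relative to the reference frame."""

    shifts: np.ndarray  # (T, 2) continuous
    degenerate: bool = False  # all-constant input, shifts forced to zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.shifts)),
                "dy_px": self.shifts[:, 0],
                "dx_px": self.shifts[:, 1],
            }
        )


def register_translation(
    movie: Movie, reference: str = "first", upsample_factor: int = 20
) -> tuple[Movie, DriftTrace]:
    """Estimate and correct XY stage drift by subpixel phase correlation.

    ``reference`` selects the alignment target: the ``first`` frame, the
    ``previous`` frame (shifts accumulated), or the ``mean`` projection.
    Corrected frames are resampled with linear interpolation;
    out-of-field pixels are filled with the frame median.
    """
    if movie.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    if reference not in ("first", "previous", "mean"):
        raise ValueError(f"unknown reference {reference!r}")
    frames = movie.frames.astype(np.float64, copy=False)
    t_count = movie.n_frames

    degenerate = bool(np.ptp(frames) == 0)
    shifts = np.zeros((t_count, 2))
    if not degenerate:
        if reference == "mean":
            ref = frames.mean(axis=0)
            for t in range(t_count):
                shifts[t] = phase_cross_correlation(
                    ref, frames[t], upsample_factor=upsample_factor,
                    normalization=None,
                )[0]
            shifts -= shifts[0]  # reference frame convention: frame 0 at (0,0)
        else:
            for t in range(1, t_count):
                ref = frames[0] if reference == "first" else frames[t - 1]
                mov = frames[t]
                d = phase_cross_correlation(
                    ref, mov, upsample_factor=upsample_factor, normalization=None
                )[0]
                shifts[t] = d if reference == "first" else shifts[t - 1] + d

    corrected = np.empty_like(frames)
    corrected[0] = frames[0]
    for t in range(1, t_count):
        dy, dx = shifts[t]
        if dy == 0 and dx == 0:
            corrected[t] = frames[t]
        else:
            corrected[t] = ndi.shift(
                frames[t], (dy, dx), order=1, mode="constant",
                cval=float(np.median(frames[t])),
            )
    return movie.with_frames(corrected), DriftTrace(shifts, degenerate)


def temporal_median_subtract(
    movie: Movie, params: MedianFilterParams | None = None
) -> Movie:
    """Subtract the per-pixel temporal median from every frame.

    For each pixel the median is taken over a centred window of
    ``window_frames`` frames, truncated (shrinking) at the ends of the
    movie.  This removes the stable background while transient objects —
    comets, moving vesicles — survive with their amplitude intact.
    Negative residuals are clamped to zero by default.
    """
    if params is None:
        params = MedianFilterParams()
    t_count = movie.n_frames
    if params.window_frames > t_count:
        raise ValueError(
            f"window_frames={params.window_frames} exceeds movie length {t_count}"
        )
    frames = movie.frames.astype(np.float64, copy=False)
    half = params.window_frames // 2
    out = np.empty_like(frames)
    med = None
    prev_span = None
    for t in range(t_count):
        lo, hi = max(0, t - half), min(t_count, t + half + 1)
        if (lo, hi) != prev_span:
            med = np.median(frames[lo:hi], axis=0)
            prev_span = (lo, hi)
        out[t] = frames[t] - med
    if params.clamp_negative:
        np.clip(out, 0, None, out=out)
        return movie.with_frames(out)
    return movie.with_frames(out, residual=True)


def crop_substack(
    movie: Movie,
    roi: RoiSpec | None = None,
    frame_range: tuple[int, int] | None = None,
    frame_stride: int = 1,
) -> Movie:
    """Extract a rectangular spatial crop and/or temporal substack.

    The result is an exact sub-array copy; calibration is preserved except
    that ``frame_interval_s`` is multiplied by ``frame_stride`` (e.g. a
    stride of 100 on a 0.2 s movie yields the 20 s substack used for slow
    cluster tracking).
    """
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    t0, t1 = frame_range if frame_range is not None else (0, movie.n_frames)
    if not (0 <= t0 < t1 <= movie.n_frames):
        raise ValueError(f"empty or out-of-bounds frame range ({t0}, {t1})")
    frames = movie.frames[t0:t1:frame_stride]
    if frames.shape[0] == 0:
        raise ValueError("empty frame selection")
    if roi is not None:
        if roi.shape != "rectangle":
            raise ValueError("crop_substack needs a rectangular ROI")
        y0, y1, x0, x1 = roi.bounds()
        iy0, ix0 = int(np.ceil(y0)), int(np.ceil(x0))
        iy1, ix1 = iy0 + roi.height_px, ix0 + roi.width_px
        h, w = movie.frames.shape[1:]
        if iy0 < 0 or ix0 < 0 or iy1 > h or ix1 > w:
            raise ValueError("crop ROI outside frame bounds")
        frames = frames[:, iy0:iy1, ix0:ix1]
    t0_wound = movie.t0_wound
    if t0_wound is not None:
        t0_wound = max(0, (t0_wound - t0)) // frame_stride
    return Movie(
        frames.copy(),
        movie.pixel_size_um,
        movie.frame_interval_s * frame_stride,
        t0_wound,
    )
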