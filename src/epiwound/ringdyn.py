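"""Wound-centred ring dynamics: radial profiles, AP kymographs, two-phase
contraction velocimetry and Huang-threshold ring-area measurement.

The contracting wound ring is summarised per frame by the radius of maximum
intensity of its annular-mean radial profile; the radius-versus-time trace
is then fitted with a continuous two-segment piecewise-linear model whose
absolute slopes are the fast (P1) and slow (P2) closure velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label

from .imgio import Movie, RoiSpec, roi_mask

__all__ = [
    "RadialProfile",
    "Kymograph",
    "PhaseFit",
    "wound_centroid",
    "radial_profile",
    "build_kymograph",
    "two_phase_fit",
    "huang_threshold",
    "ring_area",
    "intensity_across_wound",
]


@dataclass
class RadialProfile:
    """Annular-mean intensity versus radius."""

    bin_centres_um: np.ndarray
    mean_intensity: np.ndarray
    pixel_counts: np.ndarray
    centre: tuple[float, float]
    bin_width_px: float
    r_max_um: float          # radius of maximum mean intensity
    r_max_is_plateau: bool   # True when the maximum is tied across bins


@dataclass
class Kymograph:
    """Time × AP-position matrix, each row max-normalised."""

    values: np.ndarray       # (T, W_stripe)
    centre: tuple[float, float]
    stripe_half_height_px: int
    pixel_size_um: float
    frame_interval_s: float


@dataclass
class PhaseFit:
    """Two-segment continuous piecewise-linear fit of r(t)."""

    v1_um_s: float
    v2_um_s: float
    t_break_s: float
    sse: float
    r2_phase1: float
    r2_phase2: float
    intercept_um: float
    slope1: float
    slope2: float


def wound_centroid(
    frame: np.ndarray, roi: RoiSpec, min_pixels: int = 5
) -> tuple[float, float]:
    """Intensity-weighted centroid of the wound signal within an ROI.

    Pixels above the Otsu threshold of the ROI are weighted by intensity;
    when fewer than ``min_pixels`` pixels are selected (or the ROI is
    degenerate) the ROI centre is returned as a fallback.
    """
    mask = roi_mask(roi, frame.shape)
    vals = frame[mask]
    if vals.size == 0 or np.ptp(vals) == 0:
        return roi.centre
    thr = threshold_otsu(vals)
    sel = mask & (frame > thr)
    if sel.sum() < min_pixels:
        return roi.centre
    yy, xx = np.nonzero(sel)
    w = frame[yy, xx].astype(float)
    return float(np.average(yy, weights=w)), float(np.average(xx, weights=w))


def radial_profile(
    frame: np.ndarray,
    centre: tuple[float, float],
    pixel_size_um: float,
    bin_width_px: float = 1.0,
) -> RadialProfile:
    """Mean intensity in concentric annular bins around ``centre``.

    Bins are contiguous from radius 0; every in-bounds pixel contributes to
    exactly one bin, so total mass is conserved.  ``r_max`` is the centre of
    the bin with the highest mean (smallest radius on ties, flagged as a
    plateau).
    """
    h, w = frame.shape
    cy, cx = centre
    if not (0 <= cy <= h - 1 and 0 <= cx <= w - 1):
        raise ValueError(f"centre {centre} outside frame {frame.shape}")
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx).ravel()
    idx = np.floor(r / bin_width_px).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=frame.ravel().astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centres_px = (np.arange(n_bins) + 0.5) * bin_width_px
    valid = counts > 0
    best = np.nanargmax(np.where(valid, means, -np.inf))
    plateau = bool(np.sum(np.isclose(means, means[best], rtol=1e-12)) > 1)
    return RadialProfile(
        bin_centres_um=centres_px * pixel_size_um,
        mean_intensity=means,
        pixel_counts=counts,
        centre=(float(cy), float(cx)),
        bin_width_px=bin_width_px,
        r_max_um=float(centres_px[best] * pixel_size_um),
        r_max_is_plateau=plateau,
    )


def build_kymograph(
    movie: Movie,
    centre: tuple[float, float],
    stripe_half_height_px: int = 10,
) -> Kymograph:
    """AP-stripe kymograph: per frame, the column-wise mean over a horizontal
    stripe through the wound, normalised to its own maximum.

    All-zero rows stay zero (0/0 defined as 0).
    """
    t_count, h, w = movie.shape
    cy = int(round(centre[0]))
    y0 = max(0, cy - stripe_half_height_px)
    y1 = min(h, cy + stripe_half_height_px + 1)
    if y0 >= y1:
        raise ValueError("stripe does not intersect the frame")
    rows = movie.frames[:, y0:y1, :].mean(axis=1)
    maxima = rows.max(axis=1, keepdims=True)
    values = np.divide(rows, maxima, out=np.zeros_like(rows, dtype=float),
                       where=maxima > 0)
    return Kymograph(
        values=values,
        centre=(float(centre[0]), float(centre[1])),
        stripe_half_height_px=stripe_half_height_px,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )


def two_phase_fit(t_s: np.ndarray, r_um: np.ndarray) -> PhaseFit:
    """Continuous two-segment piecewise-linear least squares of r(t).

    The breakpoint is located by exhaustive search over the interior sample
    times (excluding the first and last two), minimising the total SSE of
    the hinge regression ``r ≈ a + b·t + c·max(0, t − t_b)``.  Closure
    velocities are reported as absolute slopes: ``v1 = |b|``,
    ``v2 = |b + c|``.
    """
    t = np.asarray(t_s, dtype=float)
    r = np.asarray(r_um, dtype=float)
    if t.ndim != 1 or t.shape != r.shape or len(t) < 6:
        raise ValueError("two_phase_fit needs >= 6 (t, r) samples")
    order = np.argsort(t, kind="stable")
    t, r = t[order], r[order]
    best = None
    for k in range(2, len(t) - 2):
        tb = t[k]
        hinge = np.maximum(0.0, t - tb)
        design = np.column_stack([np.ones_like(t), t, hinge])
        coef, *_ = np.linalg.lstsq(design, r, rcond=None)
        resid = r - design @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, tb, coef)
    sse, tb, (a, b, c) = best
    pre = t < tb
    post = ~pre

    def _r2(mask, slope, inter):
        rr = r[mask]
        if len(rr) < 2 or np.ptp(rr) == 0:
            return 1.0
        pred = inter + slope * t[mask]
        ss_res = float(np.sum((rr - pred) ** 2))
        ss_tot = float(np.sum((rr - rr.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    return PhaseFit(
        v1_um_s=abs(b),
        v2_um_s=abs(b + c),
        t_break_s=float(tb),
        sse=sse,
        r2_phase1=_r2(pre, b, a),
        r2_phase2=_r2(post, b + c, a - c * tb),
        intercept_um=float(a),
        slope1=float(b),
        slope2=float(b + c),
    )


# ---------------------------------------------------------------------------
# Huang automatic threshold (fuzzy Shannon entropy)
# ---------------------------------------------------------------------------

def _huang_measures(hist: np.ndarray) -> np.ndarray:
    """Fuzziness measure for every candidate threshold of a 256-bin histogram.

    Membership of grey level g to its class is
    ``μ(g) = 1 / (1 + |g − m_class| / C)`` with ``m_class`` the mean grey
    level of the class (background: levels ≤ T; foreground: > T) and ``C``
    the grey-level range.  The measure is the histogram-weighted Shannon
    entropy ``S(μ) = −μ ln μ − (1−μ) ln(1−μ)``; the threshold minimises it.
    Levels with empty histogram bins contribute nothing.
    """
    hist = np.asarray(hist, dtype=float)
    n = len(hist)
    levels = np.arange(n, dtype=float)
    nz = np.nonzero(hist)[0]
    if len(nz) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied levels")
    first, last = nz[0], nz[-1]
    c = float(last - first)
    w = np.cumsum(hist)
    s = np.cumsum(hist * levels)
    w_tot, s_tot = w[-1], s[-1]
    measures = np.full(n, np.inf)
    for t in range(first, last):  # candidate thresholds: class0 = levels <= t
        w0, s0 = w[t], s[t]
        w1, s1 = w_tot - w0, s_tot - s0
        if w0 == 0 or w1 == 0:
            continue
        mu0, mu1 = s0 / w0, s1 / w1
        dist = np.where(levels <= t, np.abs(levels - mu0), np.abs(levels - mu1))
        mu = 1.0 / (1.0 + dist / c)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        ent = np.where((mu <= 0) | (mu >= 1), 0.0, ent)
        measures[t] = float(np.sum(hist * ent))
    return measures


def huang_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Huang & Wang fuzzy-entropy automatic threshold.

    The image is min–max scaled onto ``n_bins`` integer levels; the
    returned threshold is the image-value upper edge of the best background
    class, i.e. pixels with ``value <= threshold`` are background.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("constant image: no threshold exists")
    scaled = np.clip(((img - lo) / (hi - lo) * (n_bins - 1)).round().astype(int),
                     0, n_bins - 1)
    hist = np.bincount(scaled.ravel(), minlength=n_bins)
    measures = _huang_measures(hist)
    t_best = int(np.argmin(measures))
    return lo + (t_best + 0.5) / (n_bins - 1) * (hi - lo)


def ring_area(
    frame: np.ndarray,
    roi: RoiSpec | None = None,
    pixel_size_um: float = 1.0,
    centre: tuple[float, float] | None = None,
) -> dict:
    """Area inside a bright ring, via Huang thresholding of an ROI.

    The ring is bright and the wound interior dark: "inside" is the
    connected below-threshold region containing the ROI centre.  Default
    ROI is an 80×80 px square centred on the wound.  Returns pixel and
    physical areas plus the binary inside mask (in ROI coordinates).
    """
    h, w = frame.shape
    if roi is None:
        c = centre if centre is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        size = min(80, h, w)
        roi = RoiSpec("rectangle", c, height_px=size, width_px=size)
    if roi.shape != "rectangle":
        raise ValueError("ring_area expects a rectangular ROI")
    y0, _, x0, _ = roi.bounds()
    iy0, ix0 = int(np.ceil(y0)), int(np.ceil(x0))
    sub = frame[iy0 : iy0 + roi.height_px, ix0 : ix0 + roi.width_px]
    thr = huang_threshold(sub)
    below = sub <= thr
    labels = label(below, connectivity=1)
    cy = int(round(roi.centre[0] - iy0))
    cx = int(round(roi.centre[1] - ix0))
    cy = min(max(cy, 0), sub.shape[0] - 1)
    cx = min(max(cx, 0), sub.shape[1] - 1)
    lab = labels[cy, cx]
    inside = labels == lab if lab != 0 else np.zeros_like(below)
    area_px = int(inside.sum())
    return {
        "threshold": thr,
        "area_px": area_px,
        "area_um2": area_px * pixel_size_um**2,
        "mask": inside,
        "centre_inside": bool(lab != 0),
    }


def intensity_across_wound(
    movie: Movie,
    centre: tuple[float, float],
    times_s: list[float],
    band_px: int = 3,
) -> list[dict]:
    """AP-oriented intensity profiles through the wound at requested times.

    Each profile is the mean over a ``band_px``-row horizontal band centred
    on the wound row; the x-axis is physical distance (µm) centred on the
    wound column.  Requested times outside the movie raise an error.
    """
    t_count, h, w = movie.shape
    cy = int(round(centre[0]))
    half = band_px // 2
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    out = []
    for ts in times_s:
        fi = int(round(ts / movie.frame_interval_s))
        if movie.t0_wound is not None:
            fi += movie.t0_wound
        if not 0 <= fi < t_count:
            raise ValueError(f"time {ts} s outside movie")
        profile = movie.frames[fi, y0:y1, :].mean(axis=0)
        x_um = (np.arange(w) - centre[1]) * movie.pixel_size_um
        out.append({"t_s": ts, "frame": fi, "x_um": x_um, "intensity": profile})
    return out
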