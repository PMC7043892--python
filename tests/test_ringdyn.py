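"""Radial profiles, kymographs, two-phase fits and Huang thresholding."""

import math

import numpy as np
import pytest

from epiwound import synthgen
from epiwound.imgio import Movie, RoiSpec
from epiwound.ringdyn import (
    build_kymograph,
    huang_threshold,
    intensity_across_wound,
    radial_profile,
    ring_area,
    two_phase_fit,
    wound_centroid,
)


def _ring_frame(size=128, centre=(63.5, 63.5), r=20.0, width=3.0,
                amp=100.0, bg=10.0):
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(yy - centre[0], xx - centre[1])
    return bg + amp * np.exp(-((d - r) ** 2) / (2 * (width / 2.355) ** 2))


# ---------------------------------------------------------------------------
# centroid + radial profile
# ---------------------------------------------------------------------------

def test_centroid_of_symmetric_ring():
    frame = _ring_frame()
    roi = RoiSpec("circle", (63.5, 63.5), radius_px=40)
    cy, cx = wound_centroid(frame, roi)
    assert cy == pytest.approx(63.5, abs=0.5)
    assert cx == pytest.approx(63.5, abs=0.5)


def test_centroid_fallback_on_uniform_roi():
    frame = np.full((64, 64), 9.0)
    roi = RoiSpec("circle", (30.0, 28.0), radius_px=10)
    assert wound_centroid(frame, roi) == (30.0, 28.0)


def test_centroid_tracks_programmed_centre():
    rng = np.random.default_rng(4)
    errs = []
    for _ in range(20):
        c = (63.5 + rng.uniform(-5, 5), 63.5 + rng.uniform(-5, 5))
        frame = _ring_frame(centre=c, r=12.0) + rng.normal(0, 2, (128, 128))
        cy, cx = wound_centroid(frame, RoiSpec("circle", (63.5, 63.5), radius_px=45))
        errs.append((cy - c[0]) ** 2 + (cx - c[1]) ** 2)
    assert math.sqrt(np.mean(errs)) < 1.0


def test_radial_profile_peak_at_ring_radius():
    frame = _ring_frame(r=10.0)
    prof = radial_profile(frame, (63.5, 63.5), pixel_size_um=1.0)
    assert prof.r_max_um == pytest.approx(10.0, abs=1.0)


def test_radial_profile_mass_conservation(rng):
    frame = rng.uniform(0, 50, (64, 64))
    prof = radial_profile(frame, (20.3, 41.7), pixel_size_um=0.1)
    total = np.nansum(prof.mean_intensity * prof.pixel_counts)
    assert total == pytest.approx(frame.sum(), rel=1e-6)
    assert prof.pixel_counts.sum() == 64 * 64


def test_uniform_disc_tie_breaks_to_smallest_radius():
    yy, xx = np.mgrid[0:64, 0:64]
    frame = (np.hypot(yy - 31.5, xx - 31.5) <= 15).astype(float) * 50.0
    prof = radial_profile(frame, (31.5, 31.5), pixel_size_um=1.0)
    assert prof.r_max_um == prof.bin_centres_um[0]
    assert prof.r_max_is_plateau


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

def test_static_line_gives_constant_normalised_column():
    frames = np.full((5, 64, 64), 1.0)
    frames[:, :, 30] = 50.0
    movie = Movie(frames, 0.1, 1.0)
    kymo = build_kymograph(movie, (32.0, 32.0), stripe_half_height_px=5)
    assert kymo.values.shape == (5, 64)
    np.testing.assert_allclose(kymo.values[:, 30], 1.0)
    assert (kymo.values.max(axis=1) == 1.0).all()


def test_all_zero_frame_stays_zero_row():
    frames = np.zeros((3, 64, 64))
    frames[1, :, 10] = 5.0
    movie = Movie(frames, 0.1, 1.0)
    kymo = build_kymograph(movie, (32.0, 32.0), 5)
    np.testing.assert_array_equal(kymo.values[0], 0.0)
    np.testing.assert_array_equal(kymo.values[2], 0.0)


def test_contracting_ring_edges_converge_at_2r():
    geometry = synthgen.MovieGeometry(n_frames=10, height=160, width=160,
                                      pixel_size_um=0.1, frame_interval_s=5.0,
                                      background=2.0)
    params = synthgen.RingParams(r0_um=6.0, v1_um_s=0.05, v2_um_s=0.005,
                                 t_break_s=25.0, ring_width_um=0.5)
    movie, gt = synthgen.generate_ring_movie(params, geometry, seed=0)
    kymo = build_kymograph(movie, (79.5, 79.5), 3)
    for t in range(10):
        row = kymo.values[t]
        left = np.argmax(row[:80])
        right = 80 + np.argmax(row[80:])
        sep_px = right - left
        r_px = gt.ring_radius_um["r_um"].iloc[t] / 0.1
        assert sep_px == pytest.approx(2 * r_px, abs=2.5)


# ---------------------------------------------------------------------------
# two-phase fit
# ---------------------------------------------------------------------------

def test_noiseless_piecewise_recovered_exactly():
    t = np.arange(0, 100, 2.0)
    t0 = 40.0
    r = np.where(t < t0, 8.0 - 0.08 * t, 8.0 - 0.08 * t0 - 0.008 * (t - t0))
    fit = two_phase_fit(t, r)
    assert fit.v1_um_s == pytest.approx(0.08, abs=1e-9)
    assert fit.v2_um_s == pytest.approx(0.008, abs=1e-9)
    assert fit.t_break_s == pytest.approx(t0, abs=1e-9)
    assert fit.sse <= 1e-9


def test_single_slope_gives_equal_phases():
    t = np.linspace(0, 50, 26)
    fit = two_phase_fit(t, 5.0 - 0.02 * t)
    assert fit.v1_um_s == pytest.approx(fit.v2_um_s, abs=1e-6)
    assert fit.sse <= 1e-12


def test_two_phase_sse_never_exceeds_single_line(rng):
    for _ in range(10):
        t = np.sort(rng.uniform(0, 60, 15))
        r = rng.uniform(0, 5, 15)
        fit = two_phase_fit(t, r)
        design = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(design, r, rcond=None)
        sse_line = float(np.sum((r - design @ coef) ** 2))
        assert fit.sse <= sse_line + 1e-9


def test_too_few_samples_is_error():
    with pytest.raises(ValueError):
        two_phase_fit(np.arange(5.0), np.arange(5.0))


# ---------------------------------------------------------------------------
# Huang threshold
# ---------------------------------------------------------------------------

def huang_oracle_bin(image: np.ndarray) -> int:
    """Naive exhaustive Huang threshold (best 256-bin index)."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.clip(((img - lo) / (hi - lo) * 255).round().astype(int), 0, 255)
    hist = np.bincount(scaled.ravel(), minlength=256)
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    c = float(last - first)
    best_t, best_m = None, None
    for t in range(first, last):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        m = 0.0
        for g in range(256):
            if hist[g] == 0:
                continue
            dist = abs(g - mu0) if g <= t else abs(g - mu1)
            mu = 1.0 / (1.0 + dist / c)
            if 0 < mu < 1:
                m += hist[g] * (-mu * math.log(mu) - (1 - mu) * math.log(1 - mu))
        if best_m is None or m < best_m:
            best_m, best_t = m, t
    return best_t


def test_huang_matches_exhaustive_oracle_on_random_images(rng):
    from epiwound.ringdyn import _huang_measures

    for _ in range(50):
        mode = rng.integers(0, 3)
        if mode == 0:
            img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        elif mode == 1:  # bimodal
            img = np.concatenate([
                rng.normal(60, 15, 300), rng.normal(180, 20, 276)
            ]).clip(0, 255).round().reshape(24, 24).astype(np.uint8)
        else:  # skewed
            img = (rng.exponential(40, (24, 24))).clip(0, 255).round().astype(np.uint8)
        if img.max() == img.min():
            continue
        hist = np.bincount(
            np.clip(((img - img.min()) / (img.max() - img.min()) * 255)
                    .round().astype(int), 0, 255).ravel(), minlength=256)
        ours = int(np.argmin(_huang_measures(hist)))
        assert ours == huang_oracle_bin(img)


def test_two_level_image_threshold_between_levels():
    yy, xx = np.mgrid[0:64, 0:64]
    d = np.hypot(yy - 31.5, xx - 31.5)
    img = np.full((64, 64), 50.0)
    img[(d >= 10) & (d <= 14)] = 200.0
    thr = huang_threshold(img)
    assert 50.0 < thr < 200.0
    out = ring_area(img, RoiSpec("rectangle", (31.5, 31.5),
                                 height_px=60, width_px=60), pixel_size_um=1.0)
    assert out["centre_inside"]
    # inside area = disc interior of radius 10 (pixel-centre rasterisation)
    assert out["area_px"] == pytest.approx(np.sum(d < 10), rel=0.05)


def test_threshold_within_image_range(rng):
    for _ in range(10):
        img = rng.uniform(0, 100, (32, 32))
        thr = huang_threshold(img)
        assert img.min() < thr <= img.max()


def test_constant_roi_is_degenerate_error():
    with pytest.raises(ValueError):
        huang_threshold(np.full((32, 32), 7.0))


def test_ring_area_tracks_generator_geometry():
    geometry = synthgen.MovieGeometry(n_frames=1, height=160, width=160,
                                      pixel_size_um=0.1, frame_interval_s=1.0,
                                      background=5.0)
    params = synthgen.RingParams(r0_um=4.0, v1_um_s=0.05, v2_um_s=0.005,
                                 t_break_s=10.0, ring_width_um=0.8)
    movie, gt = synthgen.generate_ring_movie(params, geometry, seed=3)
    r_px = gt.ring_radius_um["r_um"].iloc[0] / 0.1
    out = ring_area(movie.frames[0],
                    RoiSpec("rectangle", (79.5, 79.5), height_px=80, width_px=80),
                    pixel_size_um=0.1)
    # interior bounded by the inner flank of the Gaussian ring cross-section
    r_inner = r_px - 0.8 / 0.1 / 2
    assert out["area_px"] == pytest.approx(math.pi * r_inner**2, rel=0.3)


# ---------------------------------------------------------------------------
# line profiles
# ---------------------------------------------------------------------------

def test_profile_symmetric_and_peaks_at_ring():
    frame = _ring_frame(r=15.0)
    movie = Movie(np.repeat(frame[None], 3, axis=0), 1.0, 10.0)
    (prof,) = intensity_across_wound(movie, (63.5, 63.5), [10.0])
    x, v = prof["x_um"], prof["intensity"]
    peaks = x[np.argsort(v)[-2:]]
    assert sorted(np.sign(peaks)) == [-1.0, 1.0]
    assert np.abs(np.abs(peaks) - 15.0).max() <= 1.0


def test_profile_through_uniform_image_constant():
    movie = Movie(np.full((2, 32, 32), 4.0), 1.0, 1.0)
    (prof,) = intensity_across_wound(movie, (16.0, 16.0), [0.0])
    np.testing.assert_allclose(prof["intensity"], 4.0)
    with pytest.raises(ValueError):
        intensity_across_wound(movie, (16.0, 16.0), [100.0])
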