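"""Detection, linking (vs brute-force oracle), speeds and directionality."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiwound import comets, synthgen
from epiwound.comets import (
    AngleHistogram,
    LinkParams,
    SpotParams,
    Track,
    detect_spots,
    filter_min_displacement,
    link_tracks,
    match_frame_pair,
    spot_density,
    track_speed,
    track_vectors,
)
from epiwound.imgio import RoiSpec
from epiwound.synthgen import render_spots


def _table(points):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pd.DataFrame(
        {"y_px": pts[:, 0], "x_px": pts[:, 1], "response": np.ones(len(pts))}
    )


def _track_from_points(points, frames=None):
    pts = np.asarray(points, dtype=float)
    frames = np.arange(len(pts)) if frames is None else np.asarray(frames)
    return Track(0, pd.DataFrame(
        {"frame": frames, "y_px": pts[:, 0], "x_px": pts[:, 1],
         "response": np.ones(len(pts))}
    ))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def test_blank_frame_yields_no_spots():
    assert len(detect_spots(np.zeros((32, 32)))) == 0
    assert len(detect_spots(np.full((32, 32), 13.0))) == 0


def test_single_gaussian_spot_localised_within_half_pixel():
    frame = np.zeros((101, 101))
    render_spots(frame, [50.0], [50.0], [100.0], sigma=1.0)
    spots = detect_spots(frame, SpotParams(response_threshold=1.0))
    assert len(spots) == 1
    assert spots["y_px"].iloc[0] == pytest.approx(50.0, abs=0.5)
    assert spots["x_px"].iloc[0] == pytest.approx(50.0, abs=0.5)


def test_subpixel_offset_recovered():
    frame = np.zeros((64, 64))
    render_spots(frame, [30.3], [31.7], [100.0], sigma=1.0)
    spots = detect_spots(frame, SpotParams(response_threshold=1.0))
    assert spots["y_px"].iloc[0] == pytest.approx(30.3, abs=0.5)
    assert spots["x_px"].iloc[0] == pytest.approx(31.7, abs=0.5)


def test_twenty_separated_spots_all_matched_to_truth(rng):
    # rejection-sample 20 positions with pairwise distance >= 6 px
    pts = []
    while len(pts) < 20:
        cand = rng.uniform(8, 120, 2)
        if all(np.hypot(*(cand - p)) >= 6 for p in pts):
            pts.append(cand)
    pts = np.array(pts)
    frame = np.full((128, 128), 5.0)
    render_spots(frame, pts[:, 0], pts[:, 1], np.full(20, 60.0), sigma=1.0)
    noisy = frame + rng.normal(0, 1.0, frame.shape)
    spots = detect_spots(noisy)
    assert len(spots) == 20
    det = spots[["y_px", "x_px"]].to_numpy()
    d = np.hypot(pts[:, None, 0] - det[None, :, 0], pts[:, None, 1] - det[None, :, 1])
    # 1-1 matching within 1 px
    assert (d.min(axis=1) <= 1.0).all()
    assert len(set(d.argmin(axis=1))) == 20


# ---------------------------------------------------------------------------
# linking vs brute force
# ---------------------------------------------------------------------------

def brute_force_match(pts_a, pts_b, max_dist):
    """Enumerate all matchings; maximise links then minimise total distance."""
    na, nb = len(pts_a), len(pts_b)
    d = np.hypot(
        pts_a[:, None, 0] - pts_b[None, :, 0],
        pts_a[:, None, 1] - pts_b[None, :, 1],
    )
    best = (0, 0.0, [])
    b_indices = range(nb)
    for k in range(min(na, nb), -1, -1):
        found_any = False
        best_cost, best_links = None, None
        for a_sub in itertools.combinations(range(na), k):
            for b_perm in itertools.permutations(b_indices, k):
                if all(d[i, j] <= max_dist for i, j in zip(a_sub, b_perm)):
                    cost = sum(d[i, j] for i, j in zip(a_sub, b_perm))
                    if best_cost is None or cost < best_cost - 1e-12:
                        best_cost = cost
                        best_links = list(zip(a_sub, b_perm))
                        found_any = True
        if found_any:
            return best_cost, best_links
    return 0.0, []


def test_frame_pair_matching_equals_brute_force(rng):
    for trial in range(30):
        na, nb = rng.integers(0, 8, 2)
        pts_a = rng.uniform(0, 20, (na, 2))
        pts_b = rng.uniform(0, 20, (nb, 2))
        max_dist = float(rng.uniform(1, 6))
        links = match_frame_pair(pts_a, pts_b, max_dist)
        oracle_cost, oracle_links = brute_force_match(pts_a, pts_b, max_dist)
        assert len(links) == len(oracle_links)
        cost = sum(
            math.hypot(*(pts_a[i] - pts_b[j])) for i, j in links
        )
        assert cost == pytest.approx(oracle_cost, abs=1e-9)


def test_single_spot_track_links_over_ten_frames():
    tables = [_table([(10.0, 10.0 + t)]) for t in range(10)]
    tracks = link_tracks(tables, LinkParams(2.0, 1, 2.0))
    assert len(tracks) == 1
    assert tracks[0].n_spots == 10


def test_gap_of_one_frame_closed():
    tables = [
        _table([(10.0, 10.0 + t)]) if t != 5 else _table([])
        for t in range(10)
    ]
    tracks = link_tracks(tables, LinkParams(2.0, 1, 2.0))
    assert len(tracks) == 1
    assert tracks[0].n_spots == 9
    frames = tracks[0].spots["frame"].tolist()
    assert 5 not in frames and frames == sorted(frames)


def test_steps_beyond_link_radius_stay_singletons():
    tables = [_table([(10.0, 10.0 + 3.0 * t)]) for t in range(10)]
    tracks = link_tracks(tables, LinkParams(2.0, 1, 2.0))
    assert len(tracks) == 10
    assert all(t.n_spots == 1 for t in tracks)


def test_linking_conserves_spots(rng):
    tables = [_table(rng.uniform(0, 30, (int(rng.integers(0, 7)), 2)))
              for _ in range(12)]
    total = sum(len(t) for t in tables)
    tracks = link_tracks(tables, LinkParams(3.0, 1, 3.0))
    assert sum(t.n_spots for t in tracks) == total
    # no detection appears in two tracks
    seen = set()
    for tr in tracks:
        for _, s in tr.spots.iterrows():
            key = (int(s["frame"]), round(s["y_px"], 9), round(s["x_px"], 9))
            assert key not in seen
            seen.add(key)


# ---------------------------------------------------------------------------
# speeds and filters
# ---------------------------------------------------------------------------

def test_constant_step_speed_arithmetic():
    tr = _track_from_points([(10.0, 10.0 + 0.5 * t) for t in range(6)])
    s = track_speed(tr, pixel_size_um=0.1, frame_interval_s=0.5)
    assert s["mean_step_speed_um_s"] == pytest.approx(0.1, abs=1e-12)
    assert s["net_speed_um_s"] == pytest.approx(0.1, abs=1e-12)


def test_static_and_singleton_tracks():
    static = _track_from_points([(5.0, 5.0)] * 4)
    assert track_speed(static, 0.1, 0.5)["mean_step_speed_um_s"] == 0.0
    singleton = _track_from_points([(5.0, 5.0)])
    s = track_speed(singleton, 0.1, 0.5)
    assert not s["valid"] and math.isnan(s["mean_step_speed_um_s"])


def test_gap_step_uses_elapsed_time():
    tr = _track_from_points([(0.0, 0.0), (0.0, 2.0)], frames=[0, 2])
    s = track_speed(tr, pixel_size_um=1.0, frame_interval_s=1.0)
    assert s["mean_step_speed_um_s"] == pytest.approx(1.0)


def test_min_displacement_filter_thresholds():
    # 4 px in 120 s -> removed; 6 px in 100 s -> kept; oscillation -> removed
    dt = 10.0  # s/frame
    slow = _track_from_points([(0.0, 4.0 * t / 12) for t in range(13)])
    fast = _track_from_points([(0.0, 6.0 * t / 10) for t in range(11)])
    osc = _track_from_points([(0.0, (t % 2) * 1.0) for t in range(40)])
    kept = filter_min_displacement([slow, fast, osc], 0.1, dt,
                                   min_disp_px=5.0, window_s=120.0)
    assert [t is fast for t in kept] == [True]


def test_track_angles_basic_geometry():
    ap = _track_from_points([(10.0, 10.0), (10.0, 15.0)])  # along +x
    hist, table = track_vectors([ap], reference="ap_axis")
    assert table["angle_deg"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    toward = _track_from_points([(10.0, 10.0), (14.0, 14.0)])
    hist, table = track_vectors([toward], reference="wound_point",
                                wound_point=(18.0, 18.0))
    assert table["angle_deg"].iloc[0] == pytest.approx(0.0, abs=1e-5)

    away = _track_from_points([(10.0, 10.0), (6.0, 6.0)])
    _, table = track_vectors([away], reference="wound_point",
                             wound_point=(18.0, 18.0))
    assert table["angle_deg"].iloc[0] == pytest.approx(180.0, abs=1e-5)


def test_zero_displacement_excluded_and_frequencies_sum_to_one(rng):
    tracks = [_track_from_points([(0.0, 0.0)] * 3)]
    for _ in range(50):
        a = rng.uniform(0, 2 * np.pi)
        tracks.append(_track_from_points(
            [(10.0, 10.0), (10.0 + 3 * np.sin(a), 10.0 + 3 * np.cos(a))]))
    hist, _ = track_vectors(tracks, reference="ap_axis")
    assert hist.n_excluded == 1
    assert hist.n_tracks == 50
    assert hist.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
    assert (hist.frequencies >= 0).all()


def test_ap_histogram_invariant_to_translation_and_reflection(rng):
    pts = [
        [(rng.uniform(0, 50), rng.uniform(0, 50))] for _ in range(40)
    ]
    tracks, shifted, reflected = [], [], []
    for i, [(y, x)] in enumerate(pts):
        a = rng.uniform(0, 2 * np.pi)
        dy, dx = 4 * np.sin(a), 4 * np.cos(a)
        tracks.append(_track_from_points([(y, x), (y + dy, x + dx)]))
        shifted.append(_track_from_points([(y + 7, x + 3), (y + 7 + dy, x + 3 + dx)]))
        reflected.append(_track_from_points([(-y, x), (-(y + dy), x + dx)]))
    h0, _ = track_vectors(tracks, "ap_axis")
    h1, _ = track_vectors(shifted, "ap_axis")
    h2, _ = track_vectors(reflected, "ap_axis")
    np.testing.assert_allclose(h0.frequencies, h1.frequencies, atol=1e-12)
    # reflection about the AP axis maps axial angle a -> 180 - a: the
    # histogram is mirrored bin-for-bin
    np.testing.assert_allclose(h0.frequencies, h2.frequencies[::-1], atol=1e-12)


def test_isotropic_preset_angles_uniform():
    """Isotropic comet directions give a flat wound-angle histogram."""
    geometry = synthgen.MovieGeometry(
        n_frames=80, height=200, width=200, pixel_size_um=0.1,
        frame_interval_s=0.5, background=0.0,
    )
    params = synthgen.CometParams(
        speed_um_s=0.2, n_comets_per_frame=40, lifetime_frames=10,
        direction_mode="isotropic",
    )
    _, gt = synthgen.generate_comet_movie(params, geometry, seed=21)
    tracks = [
        _track_from_points(tr[["y_px", "x_px"]].to_numpy(),
                           frames=tr["frame"].to_numpy())
        for _, tr in gt.spots.groupby("object_id")
        if len(tr) >= 2
    ]
    assert len(tracks) >= 250
    hist, table = track_vectors(tracks, "ap_axis", n_bins=12)
    counts = (hist.frequencies * hist.n_tracks).round()
    assert stats.chisquare(counts).pvalue > 0.01


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def test_spot_density_arithmetic():
    roi = RoiSpec("rectangle", (50.0, 50.0), height_px=55, width_px=55)
    # 300 µm² at 0.316.. µm/px: use explicit numbers instead
    pixel = math.sqrt(300.0) / 55  # side 55 px -> 300 µm²
    inside = _table([(50.0 + dy, 50.0 + dx)
                     for dy in range(-3, 3) for dx in range(-5, 0)])
    outside = _table([(5.0, 5.0)])
    table = pd.concat([inside, outside], ignore_index=True)
    out = spot_density(table, roi, (100, 100), pixel)
    assert out["area_um2"] == pytest.approx(300.0, rel=1e-6)
    assert out["count"] == 30
    assert out["density_per_um2"] == pytest.approx(0.1, rel=1e-6)


def test_empty_roi_zero_and_zero_area_error():
    roi = RoiSpec("rectangle", (50.0, 50.0), height_px=10, width_px=10)
    out = spot_density(_table([(5.0, 5.0)]).iloc[:0], roi, (100, 100), 0.1)
    assert out["count"] == 0


def test_poisson_density_recovery(rng):
    """Mean detected density over 50 frames within 3 SE of the true rate."""
    lam = 25
    pixel = 0.2
    roi = RoiSpec("rectangle", (49.5, 49.5), height_px=100, width_px=100)
    counts = []
    tables = []
    for _ in range(50):
        n = rng.poisson(lam)
        pts = rng.uniform(5, 95, (n, 2))
        frame = np.full((100, 100), 3.0)
        render_spots(frame, pts[:, 0], pts[:, 1], np.full(n, 80.0), 1.0)
        tables.append(detect_spots(frame + rng.normal(0, 1, frame.shape)))
    out = spot_density(tables, roi, (100, 100), pixel)
    area = out["area_um2"]
    se = math.sqrt(lam / 50) / area
    # detections may miss overlapping spots; allow 3 SE plus 5% overlap loss
    assert out["density_per_um2"] == pytest.approx(lam / area, abs=3 * se + 0.05 * lam / area)
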