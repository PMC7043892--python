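"""End-to-end parameter-recovery pipelines over the synthetic presets.

Each pipeline runs the full measurement chain (preprocess → detect → link →
statistics) on a named preset and returns the recovered quantity, so the
generator's known ground truth turns every stage into a testable
parameter-recovery problem.

Linking radii follow the standard heuristic of ~1.5× the expected per-frame
displacement (they must exceed the step but stay well below the typical
inter-particle spacing); gap closing is enabled only where the expected
displacement is small enough that a closed gap cannot masquerade as a
cross-particle jump.  The comet regimes use the canonical 3 px blob /
2 px link / 1 frame gap parameters; the slow-cluster regimes are measured
on a 20 s substack with the 5-px minimum-displacement filter (120 s window
pre-wound, 420 s post-wound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import comets, preprocess, ringdyn, synthgen
from .imgio import Movie, RoiSpec

__all__ = [
    "SpeedPipelineConfig",
    "SPEED_PIPELINES",
    "recover_track_speeds",
    "grand_mean_speed",
    "ring_radius_trace",
    "recover_ring_phases",
]


@dataclass
class SpeedPipelineConfig:
    preset: str
    median_subtract: bool = True
    substack_stride: int = 1
    link: comets.LinkParams = None  # type: ignore[assignment]
    min_disp_px: float | None = None
    disp_window_s: float | None = None
    min_track_spots: int = 3
    true_speed_um_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.link is None:
            self.link = comets.LinkParams()


SPEED_PIPELINES: dict[str, SpeedPipelineConfig] = {
    # EB1 comets: ~1 px/frame (0.26·0.3/0.08) and ~0.6 px/frame regimes,
    # tracked with the canonical 2 px / gap 1 parameters
    "eb1_unwounded": SpeedPipelineConfig(
        "eb1_unwounded", link=comets.LinkParams(2.0, 1, 2.0),
        true_speed_um_s=0.26,
    ),
    "eb1_near_wound": SpeedPipelineConfig(
        "eb1_near_wound", link=comets.LinkParams(2.0, 1, 2.0),
        true_speed_um_s=0.16,
    ),
    # RAB-11 vesicles: 1.31·0.4/0.08 ≈ 6.6 px/frame → 10 px radius, no gaps
    "rab11": SpeedPipelineConfig(
        "rab11", link=comets.LinkParams(10.0, 0, 0.0),
        true_speed_um_s=1.31,
    ),
    # SNF-12 clusters on the 20 s substack: 0.017·20/0.08 ≈ 4.3 px/frame
    "snf12_unwounded": SpeedPipelineConfig(
        "snf12_unwounded", median_subtract=False, substack_stride=100,
        link=comets.LinkParams(7.0, 1, 7.0),
        min_disp_px=5.0, disp_window_s=120.0,
        true_speed_um_s=0.017,
    ),
    # post-wound directed clusters: 0.007·20/0.08 ≈ 1.8 px/frame
    "snf12_wounded": SpeedPipelineConfig(
        "snf12_wounded", median_subtract=False, substack_stride=100,
        link=comets.LinkParams(3.0, 1, 3.0),
        min_disp_px=5.0, disp_window_s=420.0,
        true_speed_um_s=0.007,
    ),
}


def recover_track_speeds(config: SpeedPipelineConfig, seed: int):
    """Run the full chain on one preset realisation.

    Returns ``(speeds, ground_truth)`` where ``speeds`` is the list of
    per-track mean step speeds (µm/s) of tracks with at least
    ``min_track_spots`` detections.
    """
    movie, gt = synthgen.make_preset(config.preset, seed)
    if config.substack_stride > 1:
        movie = preprocess.crop_substack(movie, frame_stride=config.substack_stride)
    if config.median_subtract:
        movie = preprocess.temporal_median_subtract(movie)
    spot_tables = comets.detect_movie(movie)
    tracks = comets.link_tracks(spot_tables, config.link)
    if config.min_disp_px is not None:
        tracks = comets.filter_min_displacement(
            tracks, movie.pixel_size_um, movie.frame_interval_s,
            min_disp_px=config.min_disp_px, window_s=config.disp_window_s,
        )
    speeds = [
        s["mean_step_speed_um_s"]
        for s in (
            comets.track_speed(t, movie.pixel_size_um, movie.frame_interval_s)
            for t in tracks
            if t.n_spots >= config.min_track_spots
        )
        if s["valid"]
    ]
    return speeds, gt


def grand_mean_speed(preset: str, seeds) -> float:
    """Mean over seeds of the per-seed mean track speed (µm/s)."""
    config = SPEED_PIPELINES[preset]
    per_seed = []
    for seed in seeds:
        speeds, _ = recover_track_speeds(config, seed)
        per_seed.append(float(np.mean(speeds)))
    return float(np.mean(per_seed))


def ring_radius_trace(movie: Movie, search_radius_px: float | None = None):
    """Per-frame wound centroid + max-intensity radius of the radial profile.

    Returns ``(t_s, r_um)`` arrays.
    """
    t_count, h, w = movie.shape
    centre0 = ((h - 1) / 2.0, (w - 1) / 2.0)
    if search_radius_px is None:
        search_radius_px = min(h, w) / 2.0 - 1
    search = RoiSpec("circle", centre0, radius_px=search_radius_px)
    r_um = np.empty(t_count)
    for t in range(t_count):
        c = ringdyn.wound_centroid(movie.frames[t], search)
        prof = ringdyn.radial_profile(movie.frames[t], c, movie.pixel_size_um)
        r_um[t] = prof.r_max_um
    t_s = np.arange(t_count) * movie.frame_interval_s
    return t_s, r_um


def recover_ring_phases(seed: int, preset: str = "ring_eb1") -> ringdyn.PhaseFit:
    """Generate a closing-ring preset and recover its P1/P2 velocities."""
    movie, _ = synthgen.make_preset(preset, seed)
    t_s, r_um = ring_radius_trace(movie)
    return ringdyn.two_phase_fit(t_s, r_um)
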