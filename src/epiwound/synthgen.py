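"""Synthetic fluorescence time-lapse generator with known ground truth.

Emulates the spinning-disk acquisitions the measurement pipeline is built
for: EB1 comets (fast diffraction-limited spots tracing growing microtubule
plus ends), motile vesicles with run-and-pause kinetics (RAB-11,
SNF-12-style clusters), contracting fluorescent wound rings, curvilinear
filament textures for orientation analysis, and accumulation discs for
recruitment traces.  Every generated object is echoed in a
:class:`GroundTruth` table so each measurement stage can be validated as a
parameter-recovery problem.

Determinism contract: ``(params, seed)`` reproduce the movie and ground
truth bit-exactly; independent sub-streams are derived from the seed via
``numpy.random.SeedSequence.spawn``.

Presets encode measured epidermal dynamics as generation parameters
(0.08 µm/px geometry):

========================  =================  =========  =====================
preset                    speed (µm/s)       dt (s)     motion
========================  =================  =========  =====================
``eb1_unwounded``         0.26 ± 0.10        0.3        straight, AP-biased
``eb1_near_wound``        0.16 ± 0.06        0.3        straight, AP-biased
``rab11``                 1.31 ± 0.33        0.4        long directed runs
``snf12_unwounded``       0.017 ± 0.005      0.2        few movers + static
``snf12_wounded``         0.007 ± 0.004      0.2        movers toward wound
``ring_eb1``              v2 = 0.008, v1 =   1.0        two-phase contraction
                          10·v2
========================  =================  =========  =====================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import erf

from .imgio import Movie

__all__ = [
    "CometParams",
    "RingParams",
    "FilamentFieldParams",
    "VesicleParams",
    "NoiseParams",
    "MovieGeometry",
    "GroundTruth",
    "generate_comet_movie",
    "generate_vesicle_movie",
    "generate_ring_movie",
    "generate_filament_image",
    "generate_accumulation_movie",
    "apply_noise",
    "render_spots",
    "PRESETS",
    "make_preset",
]


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MovieGeometry:
    """Frame geometry and calibration shared by all generators."""

    n_frames: int = 300
    height: int = 200
    width: int = 200
    pixel_size_um: float = 0.08
    frame_interval_s: float = 0.3
    background: float = 10.0
    background_texture_amp: float = 0.0   # low-frequency static texture
    background_texture_sigma_px: float = 8.0
    t0_wound: int | None = None


@dataclass
class CometParams:
    """Straight-moving transient spots (EB1 comet regime)."""

    speed_um_s: float = 0.26
    speed_cv: float = 0.0        # between-comet coefficient of variation
    n_comets_per_frame: float = 20.0
    lifetime_frames: float = 30.0
    psf_sigma_px: float = 1.0
    amplitude: float = 60.0
    direction_mode: str = "isotropic"  # ap_biased | isotropic | toward_point
    target_point: tuple[float, float] | None = None  # (y, x) for toward_point
    ap_jitter_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.speed_um_s <= 0:
            raise ParameterError("speed_um_s must be > 0")
        if self.speed_cv < 0:
            raise ParameterError("speed_cv must be >= 0")
        if self.n_comets_per_frame <= 0:
            raise ParameterError("n_comets_per_frame must be > 0")
        if self.lifetime_frames <= 1:
            raise ParameterError("lifetime_frames must be > 1")
        if self.direction_mode not in ("ap_biased", "isotropic", "toward_point"):
            raise ParameterError(f"unknown direction_mode {self.direction_mode!r}")
        if self.direction_mode == "toward_point" and self.target_point is None:
            raise ParameterError("toward_point mode needs target_point")


@dataclass
class VesicleParams:
    """Run-and-pause spot motion (RAB-11 vesicles, SNF-12 clusters).

    ``duty_cycle`` is the long-run fraction of time in the running state;
    1.0 reduces to comet-like constant motion, 0.0 to static spots.
    ``moving_fraction`` < 1 adds a permanently static subpopulation, as seen
    for SNF-12 where most apical clusters only vibrate in place.
    """

    speed_um_s: float = 1.31
    speed_cv: float = 0.0
    n_spots: int = 30
    duty_cycle: float = 1.0
    mean_run_frames: float = 20.0
    moving_fraction: float = 1.0
    psf_sigma_px: float = 1.0
    amplitude: float = 60.0
    direction_mode: str = "isotropic"
    target_point: tuple[float, float] | None = None
    ap_jitter_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.speed_um_s <= 0:
            raise ParameterError("speed_um_s must be > 0")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ParameterError("duty_cycle must be in [0, 1]")
        if not 0.0 <= self.moving_fraction <= 1.0:
            raise ParameterError("moving_fraction must be in [0, 1]")
        if self.direction_mode == "toward_point" and self.target_point is None:
            raise ParameterError("toward_point mode needs target_point")


@dataclass
class RingParams:
    """Contracting annulus centred on the wound.

    The radius follows ``r(t) = max(0, piecewise-linear)`` with slope ``-v1``
    before ``t_break_s`` and ``-v2`` after; a two-phase preset requires
    ``v1 > v2``.
    """

    r0_um: float = 6.0
    v1_um_s: float = 0.08
    v2_um_s: float = 0.008
    t_break_s: float = 45.0
    ring_width_um: float = 0.6
    amplitude: float = 60.0
    centre: tuple[float, float] | None = None  # (y, x) px; default frame centre

    def __post_init__(self) -> None:
        if self.r0_um <= 0 or self.v1_um_s <= 0 or self.v2_um_s <= 0:
            raise ParameterError("r0_um, v1_um_s, v2_um_s must be > 0")
        if self.t_break_s <= 0:
            raise ParameterError("t_break_s must be > 0")
        if self.r0_um <= self.ring_width_um:
            raise ParameterError("r0_um must exceed ring_width_um")

    def radius_um(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        r = np.where(
            t < self.t_break_s,
            self.r0_um - self.v1_um_s * t,
            self.r0_um
            - self.v1_um_s * self.t_break_s
            - self.v2_um_s * (t - self.t_break_s),
        )
        return np.maximum(r, 0.0)


@dataclass
class FilamentFieldParams:
    """Field of straight line segments with a prescribed orientation law.

    ``field_mode`` sets the true tangent at each filament midpoint:
    ``longitudinal`` (0°, the AP axis), ``circumferential`` (90°),
    ``orthoradial`` (perpendicular to the radius vector from ``centre``),
    ``radial`` (along the radius vector) or ``uniform_random``.
    Angles are axial, measured from +x in [0°, 180°).
    """

    field_mode: str = "uniform_random"
    centre: tuple[float, float] | None = None
    n_filaments: int = 300
    filament_length_px: float = 20.0
    jitter_deg: float = 0.0
    amplitude: float = 60.0
    line_sigma_px: float = 0.7

    def __post_init__(self) -> None:
        modes = ("longitudinal", "circumferential", "orthoradial", "radial",
                 "uniform_random")
        if self.field_mode not in modes:
            raise ParameterError(f"unknown field_mode {self.field_mode!r}")
        if self.field_mode in ("orthoradial", "radial") and self.centre is None:
            raise ParameterError(f"{self.field_mode} mode needs a centre")
        if self.n_filaments < 1:
            raise ParameterError("n_filaments must be >= 1")
        if self.jitter_deg < 0:
            raise ParameterError("jitter_deg must be >= 0")


@dataclass
class NoiseParams:
    """Acquisition noise: shot noise, read noise, bleaching, stage drift.

    ``out = Poisson(photon_scale · bleach(t) · in) / photon_scale
    + N(0, read_sigma)`` followed by a ``(dy, dx)·t`` translation and
    clipping at zero.  With ``photon_scale=0``, ``read_sigma=0``,
    ``bleach_rate_per_frame=0`` and zero drift the operator is the identity.
    """

    photon_scale: float = 0.0   # 0 disables shot noise
    read_sigma: float = 0.0
    bleach_rate_per_frame: float = 0.0
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_sigma < 0:
            raise ParameterError("noise scales must be >= 0")
        if self.bleach_rate_per_frame < 0:
            raise ParameterError("bleach_rate_per_frame must be >= 0")


@dataclass
class GroundTruth:
    """Generator-emitted truth for parameter-recovery tests.

    ``spots`` holds one row per object per frame
    (``object_id, frame, y_px, x_px, moving``); ``objects`` one row per
    object (speeds, birth/death, direction); ``ring_radius_um`` the true
    radius trace; ``orientation_deg`` a per-pixel axial angle map for
    filament images.  ``params`` echoes every generation parameter plus the
    seed, sufficient to re-render the movie bit-exactly.
    """

    params: dict
    seed: int
    spots: pd.DataFrame | None = None
    objects: pd.DataFrame | None = None
    ring_radius_um: pd.DataFrame | None = None
    orientation_deg: np.ndarray | None = None
    filaments: pd.DataFrame | None = None


def _echo(kind: str, geometry: MovieGeometry, params, noise: NoiseParams | None) -> dict:
    return {
        "kind": kind,
        "geometry": asdict(geometry),
        "params": asdict(params),
        "noise": asdict(noise) if noise is not None else None,
    }


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _pixel_integrated_gauss(offsets: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    """Integral of a unit-mass 1-D Gaussian over unit pixels at ``offsets``."""
    s = sigma * math.sqrt(2.0)
    return 0.5 * (
        erf((offsets + 0.5 - centre) / s) - erf((offsets - 0.5 - centre) / s)
    )


def render_spots(
    frame: np.ndarray, ys, xs, amplitudes, sigma: float
) -> np.ndarray:
    """Add pixel-integrated Gaussian spots to ``frame`` in place.

    ``amplitude`` is the peak height of the continuous Gaussian; the
    rendered total intensity of one spot is ``amplitude · 2πσ²`` (up to
    boundary truncation), which the energy-conservation test relies on.
    """
    h, w = frame.shape
    half = max(3, int(math.ceil(4 * sigma)))
    for y, x, a in zip(np.atleast_1d(ys), np.atleast_1d(xs), np.atleast_1d(amplitudes)):
        iy, ix = int(round(y)), int(round(x))
        y0, y1 = max(0, iy - half), min(h, iy + half + 1)
        x0, x1 = max(0, ix - half), min(w, ix + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        gy = _pixel_integrated_gauss(np.arange(y0, y1, dtype=float), y, sigma)
        gx = _pixel_integrated_gauss(np.arange(x0, x1, dtype=float), x, sigma)
        frame[y0:y1, x0:x1] += (a * 2 * math.pi * sigma**2) * np.outer(gy, gx)
    return frame


def _background(geometry: MovieGeometry, rng: np.random.Generator) -> np.ndarray:
    """Static background: constant offset plus optional smooth texture."""
    bg = np.full((geometry.height, geometry.width), float(geometry.background))
    if geometry.background_texture_amp > 0:
        tex = rng.standard_normal((geometry.height, geometry.width))
        tex = ndi.gaussian_filter(tex, geometry.background_texture_sigma_px)
        sd = tex.std()
        if sd > 0:
            bg += geometry.background_texture_amp * tex / sd
        bg = np.clip(bg, 0, None)
    return bg


def _draw_directions(mode, n, rng, origins=None, target=None, ap_jitter_deg=20.0):
    """Unit direction vectors (dy, dx) per object."""
    if mode == "isotropic":
        ang = rng.uniform(0, 2 * math.pi, n)
    elif mode == "ap_biased":
        # movement along ±x with Gaussian angular jitter, mimicking comets
        # running on haphazard longitudinal MT bundles
        sign = rng.choice([0.0, math.pi], n)
        ang = sign + np.deg2rad(ap_jitter_deg) * rng.standard_normal(n)
    elif mode == "toward_point":
        ty, tx = target
        dy = ty - origins[:, 0]
        dx = tx - origins[:, 1]
        ang = np.arctan2(dy, dx) + np.deg2rad(5.0) * rng.standard_normal(n)
    else:  # pragma: no cover
        raise ParameterError(mode)
    return np.stack([np.sin(ang), np.cos(ang)], axis=1)


def _draw_speeds(mean, cv, n, rng):
    """Per-object constant speeds, truncated to stay positive."""
    if cv == 0:
        return np.full(n, float(mean))
    speeds = mean * (1.0 + cv * rng.standard_normal(n))
    return np.clip(speeds, 0.05 * mean, None)


# ---------------------------------------------------------------------------
# spot-movie generators
# ---------------------------------------------------------------------------

def _spot_movie(
    geometry: MovieGeometry,
    births: np.ndarray,
    deaths: np.ndarray,
    starts: np.ndarray,
    dirs: np.ndarray,
    speeds_px_frame: np.ndarray,
    moving_mask_fn,
    amplitude: float,
    sigma: float,
    rng: np.random.Generator,
):
    """Shared renderer: straight (or paused) motion between birth and death."""
    t_count, h, w = geometry.n_frames, geometry.height, geometry.width
    bg = _background(geometry, rng)
    frames = np.empty((t_count, h, w), dtype=np.float64)
    for t in range(t_count):
        frames[t] = bg
    rows = []
    n = len(births)
    all_idx = np.arange(n)
    # per-object cumulative displacement since birth, honouring pause frames
    cum = np.zeros(n)
    for t in range(t_count):
        live = (births <= t) & (t < deaths)
        if np.any(live):
            idx = np.nonzero(live)[0]
            ys = starts[idx, 0] + dirs[idx, 0] * cum[idx]
            xs = starts[idx, 1] + dirs[idx, 1] * cum[idx]
            inb = (ys >= 0) & (ys <= h - 1) & (xs >= 0) & (xs <= w - 1)
            idx, ys, xs = idx[inb], ys[inb], xs[inb]
            if len(idx):
                render_spots(frames[t], ys, xs, np.full(len(idx), amplitude), sigma)
                moving_now = moving_mask_fn(idx, t)
                for o, y, x, m in zip(idx, ys, xs, moving_now):
                    rows.append((int(o), t, float(y), float(x), bool(m)))
        # advance cumulative displacement for the next frame
        adv = moving_mask_fn(all_idx, t) & (births <= t)
        cum += speeds_px_frame * adv.astype(float)
    spots = pd.DataFrame(rows, columns=["object_id", "frame", "y_px", "x_px", "moving"])
    return frames, spots


def generate_comet_movie(
    params: CometParams, geometry: MovieGeometry, seed: int,
    noise: NoiseParams | None = None,
) -> tuple[Movie, GroundTruth]:
    """Movie of straight-moving transient comets with full ground truth.

    Comets nucleate at Poisson-random times and uniform positions, travel in
    a straight line at a per-comet constant speed drawn from
    ``(speed_um_s, speed_cv)``, and disappear after an exponential lifetime
    (or on leaving the field).
    """
    step_px = params.speed_um_s * geometry.frame_interval_s / geometry.pixel_size_um
    if step_px > min(geometry.height, geometry.width):
        raise ParameterError(
            f"per-frame displacement {step_px:.1f} px exceeds frame size"
        )
    ss = np.random.SeedSequence(seed)
    rng_obj, rng_bg, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    birth_rate = params.n_comets_per_frame / params.lifetime_frames
    births, lifetimes = [], []
    # initial standing population, then per-frame Poisson nucleation
    n0 = rng_obj.poisson(params.n_comets_per_frame)
    births += [0] * n0
    for t in range(1, geometry.n_frames):
        births += [t] * rng_obj.poisson(birth_rate)
    births = np.array(births, dtype=int)
    n = len(births)
    lifetimes = np.maximum(
        2, rng_obj.exponential(params.lifetime_frames, n).round().astype(int)
    )
    deaths = births + lifetimes
    starts = np.column_stack(
        [
            rng_obj.uniform(0, geometry.height - 1, n),
            rng_obj.uniform(0, geometry.width - 1, n),
        ]
    )
    dirs = _draw_directions(
        params.direction_mode, n, rng_obj, starts, params.target_point,
        params.ap_jitter_deg,
    )
    speeds = _draw_speeds(params.speed_um_s, params.speed_cv, n, rng_obj)
    speeds_px = speeds * geometry.frame_interval_s / geometry.pixel_size_um

    frames, spots = _spot_movie(
        geometry, births, deaths, starts, dirs, speeds_px,
        lambda idx, t: np.ones(len(idx), dtype=bool),
        params.amplitude, params.psf_sigma_px, rng_bg,
    )
    objects = pd.DataFrame(
        {
            "object_id": np.arange(n),
            "speed_um_s": speeds,
            "birth_frame": births,
            "death_frame": deaths,
            "dir_y": dirs[:, 0],
            "dir_x": dirs[:, 1],
        }
    )
    movie = Movie(frames, geometry.pixel_size_um, geometry.frame_interval_s,
                  geometry.t0_wound)
    if noise is not None:
        movie = apply_noise(movie, noise, rng=rng_noise)
    gt = GroundTruth(
        params=_echo("comet", geometry, params, noise), seed=seed,
        spots=spots, objects=objects,
    )
    return movie, gt


def generate_vesicle_movie(
    params: VesicleParams, geometry: MovieGeometry, seed: int,
    noise: NoiseParams | None = None,
) -> tuple[Movie, GroundTruth]:
    """Run-and-pause spot movie (vesicle/cluster regime).

    A fixed population of ``n_spots`` persists for the whole movie.  A
    fraction ``moving_fraction`` alternates geometric-length run and pause
    states tuned to ``duty_cycle``; the rest are permanently static.  During
    pauses the true displacement is zero.
    """
    ss = np.random.SeedSequence(seed)
    rng_obj, rng_bg, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    n = params.n_spots
    t_count = geometry.n_frames
    births = np.zeros(n, dtype=int)
    deaths = np.full(n, t_count, dtype=int)
    starts = np.column_stack(
        [
            rng_obj.uniform(0, geometry.height - 1, n),
            rng_obj.uniform(0, geometry.width - 1, n),
        ]
    )
    dirs = _draw_directions(
        params.direction_mode, n, rng_obj, starts, params.target_point,
        params.ap_jitter_deg,
    )
    speeds = _draw_speeds(params.speed_um_s, params.speed_cv, n, rng_obj)
    speeds_px = speeds * geometry.frame_interval_s / geometry.pixel_size_um

    mover = rng_obj.uniform(size=n) < params.moving_fraction
    # two-state Markov chain with stationary running fraction = duty_cycle
    run_state = np.zeros((n, t_count), dtype=bool)
    if params.duty_cycle >= 1.0:
        run_state[mover] = True
    elif params.duty_cycle > 0.0:
        p_stop = 1.0 / params.mean_run_frames
        mean_pause = params.mean_run_frames * (1 - params.duty_cycle) / params.duty_cycle
        p_go = 1.0 / max(mean_pause, 1.0)
        state = rng_obj.uniform(size=n) < params.duty_cycle
        u = rng_obj.uniform(size=(t_count, n))
        for t in range(t_count):
            run_state[:, t] = state
            flip = np.where(state, u[t] < p_stop, u[t] < p_go)
            state = state ^ flip
        run_state[~mover] = False
    run_state[~mover] = False

    frames, spots = _spot_movie(
        geometry, births, deaths, starts, dirs, speeds_px,
        lambda idx, t: run_state[idx, t],
        params.amplitude, params.psf_sigma_px, rng_bg,
    )
    objects = pd.DataFrame(
        {
            "object_id": np.arange(n),
            "speed_um_s": speeds,
            "is_mover": mover,
            "dir_y": dirs[:, 0],
            "dir_x": dirs[:, 1],
            "run_fraction": run_state.mean(axis=1),
        }
    )
    movie = Movie(frames, geometry.pixel_size_um, geometry.frame_interval_s,
                  geometry.t0_wound)
    if noise is not None:
        movie = apply_noise(movie, noise, rng=rng_noise)
    gt = GroundTruth(
        params=_echo("vesicle", geometry, params, noise), seed=seed,
        spots=spots, objects=objects,
    )
    return movie, gt


# ---------------------------------------------------------------------------
# ring, filament and accumulation generators
# ---------------------------------------------------------------------------

def generate_ring_movie(
    params: RingParams, geometry: MovieGeometry, seed: int,
    noise: NoiseParams | None = None,
) -> tuple[Movie, GroundTruth]:
    """Contracting annulus movie with the true radius trace as ground truth.

    The annulus has a Gaussian radial cross-section of FWHM
    ``ring_width_um`` centred on ``r(t)``.
    """
    ss = np.random.SeedSequence(seed)
    rng_bg, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    h, w = geometry.height, geometry.width
    centre = params.centre or ((h - 1) / 2.0, (w - 1) / 2.0)
    r0_px = params.r0_um / geometry.pixel_size_um
    if r0_px + 3 > min(centre[0], centre[1], h - 1 - centre[0], w - 1 - centre[1]):
        raise ParameterError("r0_um does not fit inside the frame")
    t_s = np.arange(geometry.n_frames) * geometry.frame_interval_s
    r_um = params.radius_um(t_s)
    r_px = r_um / geometry.pixel_size_um
    sigma_r = (params.ring_width_um / geometry.pixel_size_um) / 2.3548

    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - centre[0], xx - centre[1])
    bg = _background(geometry, rng_bg)
    frames = np.empty((geometry.n_frames, h, w))
    for t in range(geometry.n_frames):
        frames[t] = bg + params.amplitude * np.exp(
            -((dist - r_px[t]) ** 2) / (2 * sigma_r**2)
        )
    movie = Movie(frames, geometry.pixel_size_um, geometry.frame_interval_s,
                  geometry.t0_wound)
    if noise is not None:
        movie = apply_noise(movie, noise, rng=rng_noise)
    gt = GroundTruth(
        params=_echo("ring", geometry, params, noise), seed=seed,
        ring_radius_um=pd.DataFrame(
            {"frame": np.arange(geometry.n_frames), "t_s": t_s, "r_um": r_um,
             "centre_y": centre[0], "centre_x": centre[1]}
        ),
    )
    return movie, gt


def _field_angle_deg(mode, yy, xx, centre, rng=None, jitter=0.0):
    """True axial tangent angle (deg in [0, 180)) of the orientation law."""
    if mode == "longitudinal":
        ang = np.zeros_like(np.asarray(yy, dtype=float))
    elif mode == "circumferential":
        ang = np.full_like(np.asarray(yy, dtype=float), 90.0)
    elif mode in ("radial", "orthoradial"):
        cy, cx = centre
        ang = np.rad2deg(np.arctan2(np.asarray(yy) - cy, np.asarray(xx) - cx))
        if mode == "orthoradial":
            ang = ang + 90.0
    elif mode == "uniform_random":
        ang = rng.uniform(0.0, 180.0, np.shape(yy))
    else:  # pragma: no cover
        raise ParameterError(mode)
    if jitter > 0 and rng is not None:
        ang = ang + jitter * rng.standard_normal(np.shape(yy))
    return np.mod(ang, 180.0)


def generate_filament_image(
    params: FilamentFieldParams, geometry: MovieGeometry, seed: int,
    noise: NoiseParams | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Single frame of straight filaments following an orientation law.

    Returns the rendered image and ground truth carrying both a per-filament
    angle table and a dense per-pixel map of the noiseless field law
    (evaluated without jitter), for validating structure-tensor estimates.
    """
    ss = np.random.SeedSequence(seed)
    rng, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    h, w = geometry.height, geometry.width
    mids = np.column_stack(
        [rng.uniform(0, h - 1, params.n_filaments),
         rng.uniform(0, w - 1, params.n_filaments)]
    )
    ang = _field_angle_deg(
        params.field_mode, mids[:, 0], mids[:, 1], params.centre,
        rng=rng, jitter=params.jitter_deg,
    )
    img = np.zeros((h, w))
    half = params.filament_length_px / 2.0
    # draw each segment as densely sampled pixel-integrated Gaussian points
    n_samples = max(4, int(math.ceil(params.filament_length_px * 2)))
    ts = np.linspace(-half, half, n_samples)
    seg_amp = params.amplitude / (
        2 * math.pi * params.line_sigma_px**2 * n_samples / params.filament_length_px
    )
    for (my, mx), a in zip(mids, ang):
        dy, dx = math.sin(math.radians(a)), math.cos(math.radians(a))
        render_spots(
            img, my + dy * ts, mx + dx * ts,
            np.full(n_samples, seg_amp), params.line_sigma_px,
        )
    img += geometry.background
    yy, xx = np.mgrid[0:h, 0:w]
    dense = _field_angle_deg(params.field_mode, yy, xx, params.centre,
                             rng=np.random.default_rng(0), jitter=0.0)
    gt = GroundTruth(
        params=_echo("filament", geometry, params, noise), seed=seed,
        orientation_deg=dense,
        filaments=pd.DataFrame(
            {"filament_id": np.arange(params.n_filaments),
             "mid_y_px": mids[:, 0], "mid_x_px": mids[:, 1],
             "angle_deg": ang}
        ),
    )
    if noise is not None:
        m = apply_noise(
            Movie(img[None], geometry.pixel_size_um, geometry.frame_interval_s),
            noise, rng=rng_noise,
        )
        img = m.frames[0]
    return img, gt


def generate_accumulation_movie(
    geometry: MovieGeometry, seed: int,
    t0_wound: int | None = None,
    disc_radius_um: float = 2.0,
    ramp_amplitude: float = 40.0,
    centre: tuple[float, float] | None = None,
    noise: NoiseParams | None = None,
) -> tuple[Movie, GroundTruth]:
    """Disc of intensity ramping up linearly after wounding (recruitment)."""
    ss = np.random.SeedSequence(seed)
    rng_bg, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    h, w = geometry.height, geometry.width
    t0 = geometry.t0_wound if t0_wound is None else t0_wound
    if t0 is None:
        raise ParameterError("accumulation movie needs t0_wound")
    centre = centre or ((h - 1) / 2.0, (w - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (
        np.hypot(yy - centre[0], xx - centre[1])
        <= disc_radius_um / geometry.pixel_size_um
    )
    bg = _background(geometry, rng_bg)
    frames = np.empty((geometry.n_frames, h, w))
    post = geometry.n_frames - t0
    for t in range(geometry.n_frames):
        frames[t] = bg
        if t >= t0 and post > 1:
            frames[t] = bg + disc * (ramp_amplitude * (t - t0) / (post - 1))
    movie = Movie(frames, geometry.pixel_size_um, geometry.frame_interval_s, t0)
    if noise is not None:
        movie = apply_noise(movie, noise, rng=rng_noise)
    gt = GroundTruth(
        params={"kind": "accumulation", "geometry": asdict(geometry),
                "params": {"disc_radius_um": disc_radius_um,
                           "ramp_amplitude": ramp_amplitude,
                           "t0_wound": t0, "centre": list(centre)},
                "noise": asdict(noise) if noise else None},
        seed=seed,
    )
    return movie, gt


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def apply_noise(
    movie: Movie, params: NoiseParams | None = None,
    seed: int | None = None, rng: np.random.Generator | None = None,
) -> Movie:
    """Apply shot/read noise, bleaching and linear stage drift to a movie.

    With all parameters at zero/identity the output equals the input
    bit-exactly.
    """
    if params is None:
        params = NoiseParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    frames = movie.frames.astype(np.float64, copy=True)
    t_count = movie.n_frames
    for t in range(t_count):
        f = frames[t]
        if params.bleach_rate_per_frame > 0:
            f = f * math.exp(-params.bleach_rate_per_frame * t)
        if params.photon_scale > 0:
            f = rng.poisson(params.photon_scale * f).astype(np.float64) / params.photon_scale
        if params.read_sigma > 0:
            f = f + params.read_sigma * rng.standard_normal(f.shape)
        dy, dx = params.drift_px_per_frame
        if (dy or dx) and t > 0:
            f = ndi.shift(f, (dy * t, dx * t), order=1, mode="constant",
                          cval=float(np.median(f)))
        frames[t] = f
    np.clip(frames, 0, None, out=frames)
    return movie.with_frames(frames)


# ---------------------------------------------------------------------------
# presets: the measured epidermal dynamics as generation parameters
# ---------------------------------------------------------------------------

#: SNR≈5 acquisition noise shared by the dynamic presets
_PRESET_NOISE = NoiseParams(photon_scale=1.0, read_sigma=2.0)


def _preset_eb1(speed: float, sd: float):
    def build(seed: int, n_frames: int = 300, size: int = 200):
        geometry = MovieGeometry(
            n_frames=n_frames, height=size, width=size,
            pixel_size_um=0.08, frame_interval_s=0.3,
            background=10.0, background_texture_amp=2.0,
        )
        params = CometParams(
            speed_um_s=speed, speed_cv=sd / speed, n_comets_per_frame=20,
            lifetime_frames=30, amplitude=60.0, direction_mode="ap_biased",
        )
        return generate_comet_movie(params, geometry, seed, noise=_PRESET_NOISE)
    return build


def _preset_rab11(seed: int, n_frames: int = 300, size: int = 200):
    geometry = MovieGeometry(
        n_frames=n_frames, height=size, width=size,
        pixel_size_um=0.08, frame_interval_s=0.4,
        background=10.0, background_texture_amp=2.0,
    )
    params = VesicleParams(
        speed_um_s=1.31, speed_cv=0.33 / 1.31, n_spots=25, duty_cycle=1.0,
        amplitude=60.0, direction_mode="isotropic",
    )
    return generate_vesicle_movie(params, geometry, seed, noise=_PRESET_NOISE)


def _preset_snf12(speed: float, sd: float, wounded: bool):
    def build(seed: int, n_frames: int | None = None, size: int = 150):
        if n_frames is None:
            # long enough to cover the displacement-filter window
            # (120 s unwounded, 420 s post-wound) at 0.2 s/frame
            n_frames = 2200 if wounded else 1300
        geometry = MovieGeometry(
            n_frames=n_frames, height=size, width=size,
            pixel_size_um=0.08, frame_interval_s=0.2,
            background=10.0, background_texture_amp=2.0,
            t0_wound=0 if wounded else None,
        )
        params = VesicleParams(
            speed_um_s=speed, speed_cv=sd / speed, n_spots=30,
            duty_cycle=1.0, moving_fraction=0.4 if wounded else 0.25,
            amplitude=60.0,
            direction_mode="toward_point" if wounded else "isotropic",
            target_point=((size - 1) / 2.0, (size - 1) / 2.0) if wounded else None,
        )
        return generate_vesicle_movie(params, geometry, seed, noise=_PRESET_NOISE)
    return build


def _preset_ring(seed: int, n_frames: int = 250, size: int = 200):
    geometry = MovieGeometry(
        n_frames=n_frames, height=size, width=size,
        pixel_size_um=0.08, frame_interval_s=1.0,
        background=10.0, t0_wound=0,
    )
    params = RingParams(
        r0_um=6.0, v1_um_s=0.08, v2_um_s=0.008, t_break_s=45.0,
        ring_width_um=0.6, amplitude=60.0,
    )
    return generate_ring_movie(params, geometry, seed, noise=_PRESET_NOISE)


def _preset_filament(mode: str, jitter: float):
    def build(seed: int, n_frames: int = 1, size: int = 250):
        geometry = MovieGeometry(
            n_frames=1, height=size, width=size,
            pixel_size_um=0.08, frame_interval_s=1.0, background=5.0,
        )
        centre = ((size - 1) / 2.0, (size - 1) / 2.0)
        # dense short-filament texture: enough independent orientations per
        # annular sector for pixel-level statistics
        params = FilamentFieldParams(
            field_mode=mode, centre=centre, n_filaments=1500,
            filament_length_px=14.0, jitter_deg=jitter, amplitude=60.0,
        )
        return generate_filament_image(params, geometry, seed)
    return build


def _preset_accumulation(seed: int, n_frames: int = 120, size: int = 128):
    geometry = MovieGeometry(
        n_frames=n_frames, height=size, width=size,
        pixel_size_um=0.08, frame_interval_s=1.0,
        background=10.0, t0_wound=n_frames // 3,
    )
    return generate_accumulation_movie(
        geometry, seed, noise=NoiseParams(photon_scale=1.0, read_sigma=1.0),
    )


PRESETS: dict = {
    # EB1 comet speeds, unwounded vs wound vicinity
    "eb1_unwounded": _preset_eb1(0.26, 0.10),
    "eb1_near_wound": _preset_eb1(0.16, 0.06),
    # RAB-11 recycling-endosome vesicles, long directed runs
    "rab11": _preset_rab11,
    # SNF-12 apical clusters: mostly static, few slow movers;
    # post-wound movers head for the wound point
    "snf12_unwounded": _preset_snf12(0.017, 0.005, wounded=False),
    "snf12_wounded": _preset_snf12(0.007, 0.004, wounded=True),
    # EB1 ring: slow-phase closure 0.008 µm/s, fast phase 10× faster
    "ring_eb1": _preset_ring,
    # filament textures for orientation analysis
    "filaments_orthoradial": _preset_filament("orthoradial", 5.0),
    "filaments_radial": _preset_filament("radial", 5.0),
    "filaments_uniform": _preset_filament("uniform_random", 0.0),
    "filaments_longitudinal": _preset_filament("longitudinal", 5.0),
    # post-wound recruitment disc
    "accumulation_disc": _preset_accumulation,
}


def make_preset(name: str, seed: int, **overrides):
    """Build a named preset; ``overrides`` pass through (n_frames, size)."""
    try:
        build = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return build(seed, **overrides)
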