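"""Synthetic countermovement-jump generator with exact ground truth.

Builds vertical GRF traces and camera frame picks whose true take-off
velocity, flight interval and jump height are known in closed form, so the
force-plate and video pipelines can be validated end to end.

The force trace is piecewise smooth: quiet stance at body weight W = m g,
a half-cosine unweighting dip, a propulsive bump whose amplitude is solved
so the net impulse from movement onset to take-off equals ``m * v_takeoff``
exactly, zero force during flight, and a landing spike that decays back to
stance.  A landing-flexion delay ``landing_delay`` lengthens the flight
beyond the ballistic ``2 v / g``: children (and most adults) land with
hips, knees and ankles flexed, i.e. with the CoM lower than at take-off,
which is precisely the mechanism by which flight-time methods overestimate
jump height relative to the impulse-momentum method.

The camera model quantizes the true take-off and landing instants to a
frame grid with a uniformly random phase; an observer model mis-picks each
boundary by one frame with a configurable probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from warnings import warn

import numpy as np

from .forceplate import G, ForceTrace

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_trace",
    "simulate_camera",
    "apply_observer",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated jump.

    Defaults describe a young (~9-year-old) athlete on a 1000 Hz plate
    filmed at 240 fps: body mass 33 kg, jump height 15 cm.
    """

    body_mass: float = 33.0          # kg
    true_jump_height: float = 0.15   # m, ballistic rise of the CoM
    quiet_duration: float = 2.0      # s of still standing before the dip
    unweighting_depth_frac: float = 0.3   # fraction of W removed at dip minimum
    unweighting_duration: float = 0.3     # s
    propulsion_duration: float = 0.3      # s, onset of push to take-off
    landing_delay: float = 0.0       # s of extra flight from flexed landing
    noise_sd: float = 0.0            # N, white sensor noise
    sample_rate: float = 1000.0      # Hz
    camera_fps: float = 240.0        # Hz
    observer_flip_prob: float = 0.2  # P(one-frame mis-pick per boundary)
    seed: int = 0
    # shape details; any shape satisfying the impulse contract is acceptable
    release_frac: float = 0.1        # fraction of propulsion in the final drop to 0 N
    landing_rise: float = 0.05       # s, touchdown to peak impact force
    landing_decay: float = 0.10      # s, impact peak back to stance
    landing_peak_factor: float = 3.0  # peak impact force in multiples of W
    tail_duration: float = 1.0       # s of stance after landing
    max_peak_factor: float = 8.0     # physiological cap on propulsive peak / W

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if self.true_jump_height < 0:
            raise ValueError("true_jump_height must be non-negative")
        if self.landing_delay < 0:
            raise ValueError("landing_delay must be non-negative")
        for name in ("quiet_duration", "unweighting_duration",
                     "propulsion_duration", "sample_rate", "camera_fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.unweighting_depth_frac < 1:
            raise ValueError("unweighting_depth_frac must be in [0, 1)")
        if not 0 <= self.observer_flip_prob <= 1:
            raise ValueError("observer_flip_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sample_rate < 2 * self.camera_fps:
            warn(
                "sample_rate below twice camera_fps; frame-pick timing will be "
                "coarser than the plate events",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimTruth:
    """Exact kinematic ground truth of one simulated jump."""

    v_takeoff: float     # m/s
    t_takeoff: float     # s from trace start
    t_landing: float     # s from trace start
    true_flight: float   # s, = 2 v / g + landing_delay
    true_height: float   # m
    landing_delay: float  # s


def _propulsive_peak(cfg: SimConfig, v_to: float) -> float:
    """Solve the propulsive peak force so the net take-off impulse is exact.

    Movement onset to take-off comprises the dip (net impulse
    ``-D T_d / 2`` with ``D = W * depth``), a half-cosine rise from
    ``W - D`` to the peak P, and a quarter-cosine release from P to zero
    force at take-off.  Setting the sum to ``m v_to`` is linear in P.
    """
    w = cfg.body_mass * G
    d = w * cfg.unweighting_depth_frac
    t_d = cfg.unweighting_duration
    t_f = cfg.release_frac * cfg.propulsion_duration
    t_r = cfg.propulsion_duration - t_f
    rhs = (
        cfg.body_mass * v_to
        + w * t_r / 2.0
        + w * t_f
        + d * t_d / 2.0
        + d * t_r / 2.0
    )
    peak = rhs / (t_r / 2.0 + 2.0 * t_f / math.pi)
    if peak > cfg.max_peak_factor * w:
        raise ValueError(
            f"true_jump_height {cfg.true_jump_height} m needs a propulsive peak of "
            f"{peak:.0f} N (> {cfg.max_peak_factor} x body weight); "
            "lengthen propulsion_duration or lower the target height"
        )
    return peak


def simulate_trace(cfg: SimConfig) -> tuple[ForceTrace, SimTruth]:
    """Generate one jump's GRF trace and its exact ground truth.

    With ``noise_sd = 0`` and ``landing_delay = 0`` the force-plate
    pipeline recovers the true height from take-off velocity to within
    ~2 mm and from flight time to within ~2 mm plus one sample of timing.
    A zero-height jump degenerates to quiet stance (no flight phase).
    """
    w = cfg.body_mass * G
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate

    if cfg.true_jump_height == 0 and cfg.landing_delay == 0:
        n = int(round((cfg.quiet_duration + cfg.tail_duration) * fs))
        force = np.full(n, w)
        if cfg.noise_sd > 0:
            force = force + rng.normal(0.0, cfg.noise_sd, size=n)
        trace = ForceTrace(force=force, sample_rate=fs)
        truth = SimTruth(0.0, math.nan, math.nan, 0.0, 0.0, 0.0)
        return trace, truth

    v_to = math.sqrt(2.0 * G * cfg.true_jump_height)
    true_flight = 2.0 * v_to / G + cfg.landing_delay
    peak = _propulsive_peak(cfg, v_to)

    d = w * cfg.unweighting_depth_frac
    s = w - d  # force at the dip minimum / start of the push
    t_d = cfg.unweighting_duration
    t_f = cfg.release_frac * cfg.propulsion_duration
    t_r = cfg.propulsion_duration - t_f

    t_onset = cfg.quiet_duration
    t_rise = t_onset + t_d
    t_fall = t_rise + t_r
    t_takeoff = t_fall + t_f
    t_landing = t_takeoff + true_flight
    t_impact = t_landing + cfg.landing_rise
    t_stance = t_impact + cfg.landing_decay
    t_end = t_stance + cfg.tail_duration

    t = np.arange(int(round(t_end * fs))) / fs
    force = np.full(t.size, w)

    m = (t >= t_onset) & (t < t_rise)  # unweighting dip: W -> W - D
    force[m] = w - d * (1.0 - np.cos(math.pi * (t[m] - t_onset) / t_d)) / 2.0
    m = (t >= t_rise) & (t < t_fall)   # push rise: W - D -> peak
    force[m] = s + (peak - s) * (1.0 - np.cos(math.pi * (t[m] - t_rise) / t_r)) / 2.0
    m = (t >= t_fall) & (t < t_takeoff)  # release: peak -> 0 at take-off
    force[m] = peak * np.cos(math.pi * (t[m] - t_fall) / (2.0 * t_f))
    m = (t >= t_takeoff) & (t < t_landing)  # flight
    force[m] = 0.0
    m = (t >= t_landing) & (t < t_impact)   # impact rise: 0 -> peak_factor * W
    force[m] = (cfg.landing_peak_factor * w
                * np.sin(math.pi * (t[m] - t_landing) / (2.0 * cfg.landing_rise)))
    m = (t >= t_impact) & (t < t_stance)    # impact decay: peak_factor * W -> W
    force[m] = w + (cfg.landing_peak_factor - 1.0) * w * np.cos(
        math.pi * (t[m] - t_impact) / (2.0 * cfg.landing_decay)
    )

    if cfg.noise_sd > 0:
        force = force + rng.normal(0.0, cfg.noise_sd, size=force.size)

    trace = ForceTrace(force=force, sample_rate=fs)
    truth = SimTruth(
        v_takeoff=v_to,
        t_takeoff=t_takeoff,
        t_landing=t_landing,
        true_flight=true_flight,
        true_height=cfg.true_jump_height,
        landing_delay=cfg.landing_delay,
    )
    return trace, truth


def simulate_camera(
    truth: SimTruth,
    fps: float,
    seed: int | np.random.Generator = 0,
    phase: float | None = None,
) -> tuple[int, int, float]:
    """Quantize the true flight interval to a camera frame grid.

    Frame ``k`` is exposed at time ``(k + phase) / fps`` with the phase
    drawn uniformly on [0, 1) — plate and camera are unsynchronized.  The
    first flight frame is the first frame strictly after take-off (the
    first frame showing the feet completely off the ground) and the first
    contact frame the first frame at or after landing.  Returns
    ``(first_flight_frame, first_contact_frame, phase)``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if not truth.t_landing > truth.t_takeoff:
        raise ValueError("no flight interval: t_landing must exceed t_takeoff")
    if phase is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        phase = float(rng.uniform(0.0, 1.0))
    if not 0 <= phase < 1:
        raise ValueError("phase must be in [0, 1)")
    # smallest k with (k + phase)/fps strictly > t_takeoff
    first_flight = math.floor(fps * truth.t_takeoff - phase) + 1
    # smallest k with (k + phase)/fps >= t_landing
    first_contact = math.ceil(fps * truth.t_landing - phase)
    return first_flight, first_contact, phase


def apply_observer(
    frames: tuple[int, int],
    flip_prob: float,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Perturb frame picks the way a human observer would.

    Each boundary is independently shifted by +-1 frame (sign equiprobable)
    with probability ``flip_prob``; with ``flip_prob = 1`` both boundaries
    move by exactly one frame.
    """
    if not 0 <= flip_prob <= 1:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for f in frames:
        if rng.uniform() < flip_prob:
            f += 1 if rng.uniform() < 0.5 else -1
        out.append(int(f))
    return out[0], out[1]


def _with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
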