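"""Force-plate processing for countermovement jumps.

Turns a raw vertical ground-reaction-force (GRF) trace into the two
force-plate jump heights used in method-comparison studies:

* ``JH_TIA`` — from time in the air, ``g * TIA**2 / 8``, assuming the
  body leaves and lands in the same posture so the centre of mass (CoM)
  follows a symmetric ballistic arc;
* ``JH_TOV`` — from take-off velocity, ``TOV**2 / (2 g)``, where TOV is
  obtained by impulse-momentum integration of the net force over the
  contact phase (the gold-standard method).

The trace is processed raw and unfiltered.  Events are detected with a
fixed force threshold (default 10 N): the first sufficiently long run of
sub-threshold samples is the flight phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid

#: Standard gravitational acceleration, m/s^2.
G = 9.81

__all__ = [
    "G",
    "ForceTrace",
    "FlightEvents",
    "VelocityTrace",
    "JumpResult",
    "estimate_body_weight",
    "detect_flight",
    "jump_height_from_tia",
    "integrate_velocity",
    "take_off_velocity",
    "jump_height_from_tov",
    "process_jump",
]


class NoFlightError(ValueError):
    """No qualifying flight phase in the trace."""


class NoLandingError(ValueError):
    """Flight phase runs to the end of the trace."""


class UnstableWeightWindowError(ValueError):
    """Quiet-standing window too noisy to estimate body weight."""


@dataclass(frozen=True)
class ForceTrace:
    """One jump's vertical GRF record.

    Parameters
    ----------
    force
        Vertical force samples in newtons, uniformly sampled.
    sample_rate
        Sampling rate in Hz.
    participant_id, trial_id
        Identifiers carried through to results.
    """

    force: np.ndarray
    sample_rate: float
    participant_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        force = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "force", force)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(force)):
            raise ValueError("force samples must be finite")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.force.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.force.size / self.sample_rate


@dataclass(frozen=True)
class FlightEvents:
    """Detected flight phase of one jump.

    ``takeoff_index`` is the first airborne sample (force below the
    threshold), ``landing_index`` the first re-contact sample, so the
    time in the air is ``(landing_index - takeoff_index) / sample_rate``.
    """

    body_weight: float
    takeoff_index: int
    landing_index: int
    sample_rate: float
    tia: float = field(init=False)

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if not self.takeoff_index < self.landing_index:
            raise ValueError("takeoff_index must precede landing_index")
        object.__setattr__(
            self, "tia", (self.landing_index - self.takeoff_index) / self.sample_rate
        )


@dataclass(frozen=True)
class VelocityTrace:
    """Per-sample vertical CoM velocity aligned to the force samples."""

    velocity: np.ndarray
    sample_rate: float


@dataclass(frozen=True)
class JumpResult:
    """Both jump heights plus diagnostics for one processed trace."""

    participant_id: str
    trial_id: str
    jh_tia: float
    jh_tov: float
    events: FlightEvents
    diagnostics: dict


def estimate_body_weight(
    trace: ForceTrace, window: float = 2.0, stability_tol: float = 5.0
) -> float:
    """Body weight (N) from the quiet-standing window at the start of the trace.

    The mean force over the first ``window`` seconds.  Rejects windows whose
    force SD exceeds ``stability_tol`` (N): a noisy window means the
    participant was moving and the baseline would bias the integration.
    """
    if window < 0.5:
        raise ValueError("weight window must be at least 0.5 s")
    n = int(round(window * trace.sample_rate))
    if n > trace.force.size:
        raise ValueError(
            f"weight window of {window} s exceeds trace duration "
            f"{trace.duration:.3f} s"
        )
    segment = trace.force[:n]
    sd = float(np.std(segment))
    if sd > stability_tol:
        raise UnstableWeightWindowError(
            f"quiet-window force SD {sd:.1f} N exceeds {stability_tol} N; "
            "choose a different window or check the trace start"
        )
    return float(np.mean(segment))


def detect_flight(
    trace: ForceTrace,
    threshold: float = 10.0,
    min_flight: float = 0.05,
    body_weight: float | None = None,
    weight_window: float = 2.0,
) -> FlightEvents:
    """Locate take-off and landing with a fixed force threshold.

    The flight phase is the first run of at least ``min_flight`` seconds of
    consecutive samples below ``threshold`` newtons; take-off is the first
    sample of that run and landing the first sample at or above the
    threshold after it.  The minimum-duration rule debounces brief noise
    dropouts in the raw, unfiltered signal.
    """
    if body_weight is None:
        body_weight = estimate_body_weight(trace, window=weight_window)
    below = trace.force < threshold
    min_samples = max(1, int(round(min_flight * trace.sample_rate)))
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    stops = np.concatenate((edges + 1, [below.size]))
    for start, stop in zip(starts, stops):
        if not below[start]:
            continue
        if stop - start < min_samples:
            continue
        if stop == below.size:
            raise NoLandingError(
                "flight phase runs to the end of the trace; no landing detected"
            )
        return FlightEvents(
            body_weight=body_weight,
            takeoff_index=int(start),
            landing_index=int(stop),
            sample_rate=trace.sample_rate,
        )
    raise NoFlightError(
        f"no flight detected: no run of >= {min_flight} s below {threshold} N"
    )


def jump_height_from_tia(tia: float) -> float:
    """Jump height (m) from time in the air: ``g * tia**2 / 8``.

    Valid under the projectile assumption that take-off and landing
    postures are identical, so the CoM is airborne for two equal
    half-flights.
    """
    if tia < 0:
        raise ValueError("time in the air must be non-negative")
    return G * tia**2 / 8.0


def integrate_velocity(trace: ForceTrace, body_weight: float) -> VelocityTrace:
    """Trapezoidal integration of net force to per-sample CoM velocity.

    Acceleration is ``(F - W) * g / W`` and velocity starts at zero at the
    beginning of the quiet-standing window (the start of the trace), the
    only instant where the CoM is known to be stationary.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    accel = (trace.force - body_weight) * G / body_weight
    vel = cumulative_trapezoid(accel, dx=trace.dt, initial=0.0)
    return VelocityTrace(velocity=vel, sample_rate=trace.sample_rate)


def take_off_velocity(
    vel: VelocityTrace,
    events: FlightEvents,
    convention: Literal["last_contact", "first_flight"] = "last_contact",
) -> float:
    """Take-off velocity (m/s): CoM velocity at the final data point before flight.

    ``last_contact`` (default) reads the velocity at the sample immediately
    before the first airborne sample; ``first_flight`` reads it at the first
    airborne sample itself.  At ordinary sampling rates the two differ by
    about one gravity-decrement of a millisecond.
    """
    if events.takeoff_index == 0:
        raise ValueError("take-off at the first sample; no contact phase precedes it")
    if convention == "last_contact":
        idx = events.takeoff_index - 1
    elif convention == "first_flight":
        idx = events.takeoff_index
    else:
        raise ValueError(f"unknown take-off velocity convention {convention!r}")
    return float(vel.velocity[idx])


def jump_height_from_tov(tov: float) -> float:
    """Jump height (m) from take-off velocity: ``tov**2 / (2 g)``.

    A negative ``tov`` is accepted (its square is used); callers should
    treat that as a failed integration rather than a jump.
    """
    return tov**2 / (2.0 * G)


def process_jump(
    trace: ForceTrace,
    threshold: float = 10.0,
    min_flight: float = 0.05,
    weight_window: float = 2.0,
    stability_tol: float = 5.0,
    tov_convention: Literal["last_contact", "first_flight"] = "last_contact",
) -> JumpResult:
    """Full per-jump pipeline: weight -> events -> integration -> both heights."""
    try:
        weight = estimate_body_weight(
            trace, window=weight_window, stability_tol=stability_tol
        )
        events = detect_flight(
            trace, threshold=threshold, min_flight=min_flight, body_weight=weight
        )
        vel = integrate_velocity(trace, weight)
        tov = take_off_velocity(vel, events, convention=tov_convention)
    except ValueError as exc:
        raise type(exc)(
            f"{trace.participant_id}/{trace.trial_id}: {exc}"
        ) from exc
    quiet_n = int(round(weight_window * trace.sample_rate))
    diagnostics = {
        "body_weight_n": weight,
        "quiet_sd_n": float(np.std(trace.force[:quiet_n])),
        "tia_s": events.tia,
        "tov_ms": tov,
        "takeoff_index": events.takeoff_index,
        "landing_index": events.landing_index,
    }
    return JumpResult(
        participant_id=trace.participant_id,
        trial_id=trace.trial_id,
        jh_tia=jump_height_from_tia(events.tia),
        jh_tov=jump_height_from_tov(tov),
        events=events,
        diagnostics=diagnostics,
    )
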