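"""Jump height from high-speed-video frame picks.

Smartphone apps in the MyJump family ask the user to mark two frames in a
slow-motion recording: the first frame in which the feet have completely
left the ground, and the first frame in which any foot is back in contact.
Flight time is the frame difference over the frame rate and height follows
the same ``g T^2 / 8`` ballistic formula used for force-plate flight time.
Frame picking quantizes the true take-off and landing times to the camera
grid (240 Hz here), bounding the flight-time error by roughly two frames.
"""

from __future__ import annotations

from dataclasses import dataclass

from .forceplate import G, jump_height_from_tia

__all__ = ["FramePick", "jump_height_from_frames", "observer_consensus",
           "frame_sensitivity_bound"]


@dataclass(frozen=True)
class FramePick:
    """One observer's frame picks for one jump.

    ``first_flight_frame`` counts as airborne and ``first_contact_frame``
    ends the flight, so the airborne frame count is their difference with
    no +1 (set ``inclusive=True`` in :func:`jump_height_from_frames` for
    the alternative convention).
    """

    first_flight_frame: int
    first_contact_frame: int
    fps: float
    observer_id: str = ""
    participant_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.first_contact_frame <= self.first_flight_frame:
            raise ValueError(
                "first_contact_frame must be after first_flight_frame "
                f"(got {self.first_flight_frame} -> {self.first_contact_frame})"
            )

    @property
    def flight_time(self) -> float:
        return (self.first_contact_frame - self.first_flight_frame) / self.fps


def jump_height_from_frames(pick: FramePick, inclusive: bool = False) -> float:
    """Jump height (m) from a frame pick.

    Flight time is ``(contact - flight) / fps`` (plus one frame when
    ``inclusive``), fed through the shared flight-time height formula.
    """
    frames = pick.first_contact_frame - pick.first_flight_frame
    if inclusive:
        frames += 1
    return jump_height_from_tia(frames / pick.fps)


def observer_consensus(
    pick_a: FramePick, pick_b: FramePick
) -> tuple[float, float, float]:
    """Heights (m) from two observers of the same jump, plus their difference.

    The observers are kept separate (no averaging): between-observer
    reliability is itself an agreement analysis.  Returns
    ``(height_a, height_b, height_a - height_b)``.
    """
    if pick_a.fps != pick_b.fps:
        raise ValueError(
            f"observers used different frame rates: {pick_a.fps} vs {pick_b.fps}"
        )
    ha = jump_height_from_frames(pick_a)
    hb = jump_height_from_frames(pick_b)
    return ha, hb, ha - hb


def frame_sensitivity_bound(flight_time: float, fps: float) -> float:
    """Worst-case height change (m) from a one-frame pick error.

    From ``h = g T^2 / 8``: shifting one boundary by a frame changes T by
    ``1/fps``, so ``|dh| <= g T / (4 fps) + g / (8 fps^2)``.
    """
    return G * flight_time / (4.0 * fps) + G / (8.0 * fps**2)
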