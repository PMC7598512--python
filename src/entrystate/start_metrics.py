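"""Predictor and response variables of a dive start.

Entry-instant variables (COM position/velocity, entry distance, trunk
entry angle) come from the reconstructed entry state; variables at the
instant the COM crosses the waterline (COMcrossWL) come from the
immersion simulation.  Response measures combine the take-off-referenced
times: TTO15 (head past the 15-m line), TTO5 (hip past the 5-m line),
the per-swimmer standardized z-score of TTO15, the horizontal hip
velocity at 5 m from the 4.5/5.5-m crossing times, and the composite
outcome5m score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body_model import AnthropometricProfile, ChainState, whole_body_com, wrap_angle, TRUNK
from .immersion_sim import ImmersionTrajectory, state_at_event

__all__ = [
    "EntryVariables",
    "StartRecord",
    "compute_entry_variables",
    "hip_velocity_at_5m",
    "outcome5m",
    "zscore15m",
    "records_to_frame",
]


@dataclass(frozen=True)
class EntryVariables:
    """The predictor set at water entry and at COMcrossWL.

    Angles follow the pool-frame convention: downward from the horizontal
    is negative.  ``hand_entry`` is the fingertip position; its x
    component is the entry distance X_ES.  ``direction_difference_cross``
    is the absolute wrapped angle between trunk axis and COM velocity
    direction at COMcrossWL.
    """

    com_entry: tuple[float, float]
    hand_entry: tuple[float, float]
    vx_entry: float
    vy_entry: float
    v_direction_entry: float
    v_magnitude_entry: float
    entry_angle_entry: float
    com_at_cross: tuple[float, float]
    v_direction_cross: float
    entry_angle_cross: float
    direction_difference_cross: float

    @property
    def entry_distance(self) -> float:
        return self.hand_entry[0]

    def as_dict(self) -> dict[str, float]:
        return {
            "com_x_entry": self.com_entry[0],
            "com_y_entry": self.com_entry[1],
            "hand_x_entry": self.hand_entry[0],
            "hand_y_entry": self.hand_entry[1],
            "vx_entry": self.vx_entry,
            "vy_entry": self.vy_entry,
            "v_direction_entry": self.v_direction_entry,
            "v_magnitude_entry": self.v_magnitude_entry,
            "entry_angle_entry": self.entry_angle_entry,
            "com_x_cross": self.com_at_cross[0],
            "com_y_cross": self.com_at_cross[1],
            "v_direction_cross": self.v_direction_cross,
            "entry_angle_cross": self.entry_angle_cross,
            "direction_difference_cross": self.direction_difference_cross,
        }


@dataclass
class StartRecord:
    """One dive start: identifiers, condition, entry variables, timings."""

    swimmer_id: str
    sex: str
    session: int
    condition: str
    block_time: float
    take_off_angle: float
    entry: EntryVariables
    time_to_15m_from_signal: float
    tto15: float
    tto5: float
    t_hip_45: float
    t_hip_55: float
    start_id: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.tto15 > self.tto5 > 0):
            raise ValueError("requires TTO15 > TTO5 > 0")
        if not self.time_to_15m_from_signal > self.tto15:
            raise ValueError("time from signal must exceed TTO15")

    @property
    def hip_velocity_5m(self) -> float:
        return hip_velocity_at_5m(self.t_hip_45, self.t_hip_55)

    @property
    def outcome5m(self) -> float:
        return outcome5m(self.hip_velocity_5m, self.tto5)


def _trunk_angle(state: ChainState) -> float:
    return state.configuration.segment_angles[TRUNK]


def compute_entry_variables(
    entry_state: ChainState,
    trajectory: ImmersionTrajectory,
    profile: AnthropometricProfile,
) -> EntryVariables:
    """Extract the full predictor set from entry state and immersion.

    Entry-instant values read off ``entry_state``; COMcrossWL values from
    the interpolated trajectory state at the COM-crossing event (raises if
    the event is absent).  The entry angle is the orientation of the
    hip-to-shoulder axis relative to the horizontal.
    """
    from .body_model import landmarks_from_configuration

    com, vcom = whole_body_com(profile, entry_state)
    lm = landmarks_from_configuration(profile, entry_state.configuration)
    vx, vy = float(vcom[0]), float(vcom[1])

    cross = state_at_event(trajectory, "com_cross")
    com_c, vcom_c = whole_body_com(profile, cross)
    vdir_c = math.atan2(vcom_c[1], vcom_c[0])
    ea_c = _trunk_angle(cross)
    return EntryVariables(
        com_entry=(float(com[0]), float(com[1])),
        hand_entry=(float(lm["fingertip"][0]), float(lm["fingertip"][1])),
        vx_entry=vx,
        vy_entry=vy,
        v_direction_entry=math.atan2(vy, vx),
        v_magnitude_entry=math.hypot(vx, vy),
        entry_angle_entry=_trunk_angle(entry_state),
        com_at_cross=(float(com_c[0]), float(com_c[1])),
        v_direction_cross=vdir_c,
        entry_angle_cross=ea_c,
        direction_difference_cross=abs(float(wrap_angle(ea_c - vdir_c))),
    )


def hip_velocity_at_5m(t_45: float, t_55: float) -> float:
    """Average horizontal hip velocity over the 4.5-5.5 m window (m/s)."""
    if not (t_55 > t_45 > 0):
        raise ValueError("crossing times must satisfy t_55 > t_45 > 0")
    return 1.0 / (t_55 - t_45)


def outcome5m(hip_velocity_5m: float, tto5: float) -> float:
    """Composite 5-m score: hip velocity at 5 m divided by TTO5."""
    if not tto5 > 0:
        raise ValueError("TTO5 must be > 0")
    return hip_velocity_5m / tto5


def zscore15m(tto15_values) -> np.ndarray:
    """Standardize one swimmer's TTO15 values (mean 0, sample SD 1)."""
    x = np.asarray(tto15_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 starts to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero TTO15 variance for this swimmer")
    return (x - x.mean()) / sd


def records_to_frame(records: list[StartRecord]) -> pd.DataFrame:
    """Flatten StartRecords into the analysis table (one row per start).

    Adds the derived columns ``hip_velocity_5m``, ``outcome5m`` and the
    per-swimmer ``zscore15m``.
    """
    rows = []
    for r in records:
        row = {
            "start_id": r.start_id,
            "swimmer_id": r.swimmer_id,
            "sex": r.sex,
            "session": r.session,
            "condition": r.condition,
            "block_time": r.block_time,
            "take_off_angle": r.take_off_angle,
            "time_to_15m_from_signal": r.time_to_15m_from_signal,
            "tto15": r.tto15,
            "tto5": r.tto5,
            "t_hip_45": r.t_hip_45,
            "t_hip_55": r.t_hip_55,
            "hip_velocity_5m": r.hip_velocity_5m,
            "outcome5m": r.outcome5m,
        }
        row.update(r.entry.as_dict())
        row.update(r.extras)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["zscore15m"] = df.groupby("swimmer_id")["tto15"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=1)
    )
    return df
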