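"""Planar five-segment body model of a diving swimmer.

The swimmer is modelled as five rigid segments -- left leg, right leg,
trunk, combined arms and head -- connected at the hip (legs/trunk) and at
the shoulder (arms/head to trunk).  Each segment carries mass, a centre of
mass at a fixed fraction of its length from the proximal end, and a moment
of inertia about its own COM expressed through a radius-of-gyration
fraction.  Segment inertial parameters are estimated from anthropometric
measurements with a Zatsiorsky-style coefficient table (relative masses,
COM and gyration fractions per sub-segment), composed into the five model
segments with the parallel-axis theorem.

Coordinate convention: x positive in the swimming direction, y positive
upward, origin at the intersection of start wall and water surface in the
sagittal plane of motion.  Segment angles are the orientation of the
proximal-to-distal axis measured counter-clockwise from the +x axis, so
directions pointing downward from the horizontal are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SEGMENT_NAMES",
    "TRUNK",
    "SegmentSpec",
    "AnthropometricProfile",
    "ChainConfiguration",
    "ChainState",
    "DEFAULT_COEFFICIENT_TABLE",
    "DEFAULT_COMPOSITION",
    "estimate_segment_parameters",
    "landmarks_from_configuration",
    "whole_body_com",
    "wrap_angle",
]

#: Model segment names in canonical order; the trunk is index 2.
SEGMENT_NAMES = ("left_leg", "right_leg", "trunk", "arms", "head")
TRUNK = 2

#: Segments attached to the trunk at the shoulder (the others share the hip).
_SHOULDER_ATTACHED = frozenset({"arms", "head"})

_G_DEFAULT = 9.81


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.remainder(theta + np.pi, 2.0 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class SegmentSpec:
    """Inertial parameters of one model segment.

    ``length`` is the proximal-to-distal landmark distance (m), ``mass``
    in kg, ``com_ratio`` the fraction of the length from the proximal end
    at which the segment COM lies, and ``gyradius_ratio`` the radius of
    gyration about the segment COM as a fraction of the length, i.e.
    ``I = mass * (gyradius_ratio * length)**2``.
    """

    name: str
    length: float
    mass: float
    com_ratio: float
    gyradius_ratio: float

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise ValueError(f"unknown segment name {self.name!r}")
        if not self.length > 0:
            raise ValueError(f"{self.name}: length must be > 0")
        if not self.mass > 0:
            raise ValueError(f"{self.name}: mass must be > 0")
        if not 0.0 <= self.com_ratio <= 1.0:
            raise ValueError(f"{self.name}: com_ratio must be in [0, 1]")
        if not self.gyradius_ratio > 0:
            raise ValueError(f"{self.name}: gyradius_ratio must be > 0")

    @property
    def inertia(self) -> float:
        """Moment of inertia about the segment COM (kg m^2)."""
        return self.mass * (self.gyradius_ratio * self.length) ** 2


@dataclass(frozen=True)
class AnthropometricProfile:
    """Whole-body inertial description used by every downstream module.

    ``hand_extension`` is the wrist-to-fingertip distance along the arm
    axis (the fingertip is modelled as a rigid extension of the combined
    arms segment).  ``body_width`` only matters for the pool-frame origin
    convention and defaults to 0.15 m.
    """

    segments: tuple[SegmentSpec, ...]
    total_mass: float
    hand_extension: float = 0.19
    body_width: float = 0.15
    sex: str = "unspecified"

    def __post_init__(self):
        names = tuple(s.name for s in self.segments)
        if names != SEGMENT_NAMES:
            raise ValueError(
                f"segments must appear in the order {SEGMENT_NAMES}, got {names}"
            )
        if not self.total_mass > 0:
            raise ValueError("total_mass must be > 0")
        if self.hand_extension < 0:
            raise ValueError("hand_extension must be >= 0")
        msum = sum(s.mass for s in self.segments)
        if abs(msum - self.total_mass) > 1e-9 * self.total_mass:
            raise ValueError(
                f"segment masses sum to {msum:.6f}, expected {self.total_mass:.6f}"
            )

    def segment(self, name: str) -> SegmentSpec:
        return self.segments[SEGMENT_NAMES.index(name)]

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.segments])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.segments])

    @property
    def inertias(self) -> np.ndarray:
        return np.array([s.inertia for s in self.segments])


@dataclass(frozen=True)
class ChainConfiguration:
    """Generalized coordinates: hip position and the five segment angles."""

    hip_position: tuple[float, float]
    segment_angles: tuple[float, ...]

    def __post_init__(self):
        if len(self.segment_angles) != 5:
            raise ValueError("expected 5 segment angles")
        object.__setattr__(
            self, "segment_angles", tuple(float(wrap_angle(a)) for a in self.segment_angles)
        )
        object.__setattr__(
            self, "hip_position", (float(self.hip_position[0]), float(self.hip_position[1]))
        )

    def as_array(self) -> np.ndarray:
        """Pack into the 7-vector (x_hip, y_hip, theta_1..theta_5)."""
        return np.array([*self.hip_position, *self.segment_angles])

    @staticmethod
    def from_array(q: np.ndarray) -> "ChainConfiguration":
        q = np.asarray(q, dtype=float)
        return ChainConfiguration((q[0], q[1]), tuple(q[2:7]))


@dataclass(frozen=True)
class ChainState:
    """Generalized coordinates and velocities of the chain at an instant."""

    configuration: ChainConfiguration
    hip_velocity: tuple[float, float]
    segment_angular_velocities: tuple[float, ...]

    def __post_init__(self):
        if len(self.segment_angular_velocities) != 5:
            raise ValueError("expected 5 angular velocities")
        vals = [*self.configuration.as_array(), *self.hip_velocity,
                *self.segment_angular_velocities]
        if not np.all(np.isfinite(vals)):
            raise ValueError("state contains non-finite values")

    def as_array(self) -> np.ndarray:
        """Pack into the 14-vector (q, qdot)."""
        return np.concatenate(
            [self.configuration.as_array(),
             np.array([*self.hip_velocity, *self.segment_angular_velocities])]
        )

    @staticmethod
    def from_array(y: np.ndarray) -> "ChainState":
        y = np.asarray(y, dtype=float)
        return ChainState(
            ChainConfiguration.from_array(y[:7]),
            (y[7], y[8]),
            tuple(y[9:14]),
        )


# ---------------------------------------------------------------------------
# Anthropometric estimation
# ---------------------------------------------------------------------------

#: Default sub-segment coefficient table: relative mass (fraction of total
#: body mass), COM position (fraction of sub-segment length from the
#: proximal end) and sagittal radius of gyration (fraction of length) per
#: body side where paired.  Values follow the adjusted Zatsiorsky segment
#: inertia fractions commonly used in sports biomechanics (de Leva style);
#: they are a documented default and can be overridden per study.
DEFAULT_COEFFICIENT_TABLE: dict[str, tuple[float, float, float]] = {
    # sub-segment: (mass_fraction, com_ratio, gyradius_ratio)
    "head_neck": (0.0694, 0.50, 0.36),
    "thorax": (0.1596, 0.45, 0.32),
    "abdomen": (0.1633, 0.45, 0.38),
    "pelvis": (0.1117, 0.35, 0.38),
    "upper_arm": (0.0271, 0.577, 0.285),
    "forearm": (0.0162, 0.457, 0.276),
    "hand": (0.0061, 0.79, 0.628),
    "thigh": (0.1416, 0.41, 0.329),
    "shank": (0.0433, 0.446, 0.255),
    "foot": (0.0137, 0.44, 0.257),
}

#: How sub-segments stack proximal-to-distal into the five model segments.
#: ``count`` doubles bilateral sub-segments merged into one model segment
#: (both arms move as one).  ``beyond`` marks mass lying distal to the
#: segment's distal landmark (pointed feet beyond the ankle, hands beyond
#: the wrist), placed collinearly on the segment axis.
DEFAULT_COMPOSITION: dict[str, list[dict]] = {
    "left_leg": [
        {"sub": "thigh", "count": 1},
        {"sub": "shank", "count": 1},
        {"sub": "foot", "count": 1, "beyond": True},
    ],
    "right_leg": [
        {"sub": "thigh", "count": 1},
        {"sub": "shank", "count": 1},
        {"sub": "foot", "count": 1, "beyond": True},
    ],
    "trunk": [
        {"sub": "pelvis", "count": 1},
        {"sub": "abdomen", "count": 1},
        {"sub": "thorax", "count": 1},
    ],
    "arms": [
        {"sub": "upper_arm", "count": 2},
        {"sub": "forearm", "count": 2},
        {"sub": "hand", "count": 2, "beyond": True},
    ],
    "head": [
        {"sub": "head_neck", "count": 1},
    ],
}


def estimate_segment_parameters(
    measurements: Mapping[str, float],
    total_mass: float,
    coefficient_table: Mapping[str, tuple[float, float, float]] | None = None,
    composition: Mapping[str, Sequence[Mapping]] | None = None,
    hand_extension: float | None = None,
    sex: str = "unspecified",
) -> AnthropometricProfile:
    """Estimate the five-segment inertial profile from anthropometry.

    ``measurements`` maps sub-segment names to measured lengths in metres
    (``<sub>_length_m`` keys are also accepted, matching the CSV layout).
    Sub-segment masses come from the coefficient table as fractions of
    ``total_mass`` and are then uniformly rescaled so the five model
    segments sum exactly to ``total_mass``.  Combined segments (a leg from
    thigh+shank+foot, the trunk from pelvis+abdomen+thorax, both arms
    merged) get their COM and inertia from mass-weighted composition with
    the parallel-axis theorem, the sub-segments laid end to end along the
    segment axis.  Sub-segments flagged ``beyond`` (feet, hands) add mass
    distal to the segment's distal landmark but do not extend the landmark
    length; the hand length is returned as ``hand_extension`` so the
    fingertip can be mapped as a rigid extension of the arms.
    """
    if not total_mass > 0:
        raise ValueError("total_mass must be > 0")
    table = dict(coefficient_table or DEFAULT_COEFFICIENT_TABLE)
    comp = composition or DEFAULT_COMPOSITION

    def sub_length(sub: str) -> float:
        for key in (sub, f"{sub}_length_m"):
            if key in measurements:
                val = float(measurements[key])
                if not val > 0:
                    raise ValueError(f"measurement for {sub!r} must be > 0")
                return val
        raise KeyError(f"missing length measurement for sub-segment {sub!r}")

    specs = []
    hand_ext = 0.0
    for name in SEGMENT_NAMES:
        parts = comp[name]
        offset = 0.0  # running proximal offset along the segment axis
        landmark_length = 0.0
        items = []  # (mass, com position along axis, own inertia)
        for part in parts:
            sub = part["sub"]
            if sub not in table:
                raise KeyError(f"coefficient table lacks sub-segment {sub!r}")
            frac, com_ratio, gyr = table[sub]
            length = sub_length(sub)
            mass = part.get("count", 1) * frac * total_mass
            d = offset + com_ratio * length
            items.append((mass, d, mass * (gyr * length) ** 2))
            offset += length
            if part.get("beyond"):
                if name == "arms":
                    hand_ext += length
            else:
                landmark_length = offset
        m = sum(it[0] for it in items)
        if not m > 0:
            raise ValueError(f"non-positive composed mass for segment {name!r}")
        com = sum(it[0] * it[1] for it in items) / m
        inertia = sum(I + mi * (d - com) ** 2 for mi, d, I in items)
        if not landmark_length > 0:
            raise ValueError(f"segment {name!r} has zero landmark length")
        specs.append(
            SegmentSpec(
                name=name,
                length=landmark_length,
                mass=m,
                com_ratio=min(com / landmark_length, 1.0),
                gyradius_ratio=float(np.sqrt(inertia / m) / landmark_length),
            )
        )

    scale = total_mass / sum(s.mass for s in specs)
    specs = [replace(s, mass=s.mass * scale) for s in specs]
    return AnthropometricProfile(
        segments=tuple(specs),
        total_mass=total_mass,
        hand_extension=hand_ext if hand_extension is None else hand_extension,
        sex=sex,
    )


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _axis(theta):
    return np.array([np.cos(theta), np.sin(theta)])


def _geometry(profile: AnthropometricProfile):
    """Per-segment (alpha, beta): segment COM = hip + alpha*u(theta_trunk)
    + beta*u(theta_k).  alpha is the trunk length for shoulder-attached
    segments and zero otherwise; beta = com_ratio * length."""
    Lt = profile.segments[TRUNK].length
    alpha = np.array(
        [Lt if s.name in _SHOULDER_ATTACHED else 0.0 for s in profile.segments]
    )
    beta = np.array([s.com_ratio * s.length for s in profile.segments])
    return alpha, beta


def landmarks_from_configuration(
    profile: AnthropometricProfile, config: ChainConfiguration
) -> dict[str, np.ndarray]:
    """Map a configuration to the digitized landmark set (plus fingertip).

    The hip is the configuration's reference point; the shoulder sits at
    the distal end of the trunk; ankles, wrist and vertex at the distal
    ends of legs, arms and head; the fingertip extends the arm axis by the
    hand extension.
    """
    hip = np.asarray(config.hip_position, dtype=float)
    ang = config.segment_angles
    lens = profile.lengths
    shoulder = hip + lens[TRUNK] * _axis(ang[TRUNK])
    wrist = shoulder + lens[3] * _axis(ang[3])
    return {
        "hip": hip,
        "ankle_L": hip + lens[0] * _axis(ang[0]),
        "ankle_R": hip + lens[1] * _axis(ang[1]),
        "shoulder": shoulder,
        "wrist": wrist,
        "fingertip": wrist + profile.hand_extension * _axis(ang[3]),
        "vertex": shoulder + lens[4] * _axis(ang[4]),
    }


def segment_com_positions(
    profile: AnthropometricProfile, config: ChainConfiguration
) -> np.ndarray:
    """(5, 2) array of segment COM positions."""
    hip = np.asarray(config.hip_position, dtype=float)
    ang = np.asarray(config.segment_angles)
    alpha, beta = _geometry(profile)
    ut = _axis(ang[TRUNK])
    uk = np.stack([_axis(a) for a in ang])
    return hip[None, :] + alpha[:, None] * ut[None, :] + beta[:, None] * uk


def whole_body_com(profile: AnthropometricProfile, state: ChainState):
    """Whole-body COM position and velocity (mass-weighted over segments)."""
    m = profile.masses
    pos = segment_com_positions(profile, state.configuration)
    ang = np.asarray(state.configuration.segment_angles)
    omg = np.asarray(state.segment_angular_velocities)
    alpha, beta = _geometry(profile)
    vt = omg[TRUNK] * np.array([-np.sin(ang[TRUNK]), np.cos(ang[TRUNK])])
    vk = omg[:, None] * np.stack(
        [np.array([-np.sin(a), np.cos(a)]) for a in ang]
    )
    vel = (
        np.asarray(state.hip_velocity)[None, :]
        + alpha[:, None] * vt[None, :]
        + beta[:, None] * vk
    )
    M = m.sum()
    return (m @ pos) / M, (m @ vel) / M


def com_offset_from_hip(profile: AnthropometricProfile, angles) -> np.ndarray:
    """COM position minus hip position for given segment angles."""
    ang = np.asarray(angles, dtype=float)
    alpha, beta = _geometry(profile)
    m = profile.masses
    ut = _axis(ang[TRUNK])
    uk = np.stack([_axis(a) for a in ang])
    offs = alpha[:, None] * ut[None, :] + beta[:, None] * uk
    return (m @ offs) / m.sum()
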