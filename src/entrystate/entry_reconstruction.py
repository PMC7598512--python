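"""Mechanically consistent reconstruction of the water-entry state.

Three digitized landmark frames (0.02 s apart, centred on water entry)
are fitted by three chain configurations that (a) respect the rigid
segment lengths exactly -- guaranteed by parameterizing each frame with
the hip position and five segment angles rather than free landmark
coordinates -- and (b) satisfy the ballistic COM constraint: during
flight the only external force is gravity, so the second central
difference of the whole-body COM over the triplet must equal (0, -g).
Subject to these constraints the weighted squared deviation between
modelled and measured landmark positions is minimized.

The ballistic constraint is enforced by construction: the third frame's
hip position is eliminated, COM_3 = 2 COM_2 - COM_1 + (0, -g) dt^2, which
turns the problem into an unconstrained nonlinear least squares over 19
parameters solved with Levenberg-Marquardt.  The entry state is the
middle-frame configuration with velocities from central differences over
2 dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .body_model import (
    AnthropometricProfile,
    ChainConfiguration,
    ChainState,
    com_offset_from_hip,
    landmarks_from_configuration,
    wrap_angle,
)

__all__ = [
    "RECONSTRUCTION_LANDMARKS",
    "LandmarkFrameTriplet",
    "ReconstructionResult",
    "fit_configuration_to_landmarks",
    "reconstruct_entry_state",
]

#: Landmarks digitized in the video frames (the fingertip is not among
#: them; it is a rigid extension of the arm segment).
RECONSTRUCTION_LANDMARKS = ("ankle_L", "ankle_R", "hip", "shoulder", "vertex", "wrist")


@dataclass(frozen=True)
class LandmarkFrameTriplet:
    """Three landmark maps at equally spaced instants around water entry."""

    times: tuple[float, float, float]
    frames: tuple[dict, dict, dict]
    weights: dict | None = None
    frame_dt: float = 0.02

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if len(t) != 3 or not np.all(np.diff(t) > 0):
            raise ValueError("times must be 3 strictly increasing instants")
        if not np.allclose(np.diff(t), self.frame_dt, rtol=0, atol=1e-9):
            raise ValueError(f"frame spacing must equal frame_dt={self.frame_dt}")
        for fr in self.frames:
            missing = [k for k in RECONSTRUCTION_LANDMARKS if k not in fr]
            if missing:
                raise ValueError(f"frame lacks landmarks: {missing}")
            for k in RECONSTRUCTION_LANDMARKS:
                if not np.all(np.isfinite(fr[k])):
                    raise ValueError(f"non-finite coordinates for landmark {k!r}")

    def weight(self, landmark: str) -> float:
        if self.weights is None:
            return 1.0
        w = float(self.weights.get(landmark, 1.0))
        if w < 0:
            raise ValueError("landmark weights must be nonnegative")
        return w


@dataclass
class ReconstructionResult:
    entry_state: ChainState
    configurations: tuple[ChainConfiguration, ChainConfiguration, ChainConfiguration]
    rms_residual: float
    per_landmark_residuals: dict
    converged: bool
    iterations: int


def fit_configuration_to_landmarks(
    frame: dict, profile: AnthropometricProfile
) -> ChainConfiguration:
    """Deterministic single-frame initialization from raw landmarks.

    The hip is taken directly from the measured hip point and each segment
    angle from the atan2 of the measured proximal-to-distal landmark pair;
    this ignores segment lengths and serves only as solver start.
    """
    hip = np.asarray(frame["hip"], dtype=float)
    sho = np.asarray(frame["shoulder"], dtype=float)

    def ang(p, d):
        v = np.asarray(d, dtype=float) - np.asarray(p, dtype=float)
        n = np.hypot(*v)
        if n < 1e-9:
            raise ValueError("landmark pair at zero distance")
        return math.atan2(v[1], v[0])

    angles = (
        ang(hip, frame["ankle_L"]),
        ang(hip, frame["ankle_R"]),
        ang(hip, sho),
        ang(sho, frame["wrist"]),
        ang(sho, frame["vertex"]),
    )
    return ChainConfiguration((hip[0], hip[1]), angles)


def _pack(frame_cfgs):
    c1, c2, c3 = frame_cfgs
    return np.concatenate(
        [c1.hip_position, c2.hip_position,
         c1.segment_angles, c2.segment_angles, c3.segment_angles]
    )


def _unpack(x, profile, g, dt):
    hip1 = x[0:2]
    hip2 = x[2:4]
    a1, a2, a3 = x[4:9], x[9:14], x[14:19]
    off1 = com_offset_from_hip(profile, a1)
    off2 = com_offset_from_hip(profile, a2)
    off3 = com_offset_from_hip(profile, a3)
    com1 = hip1 + off1
    com2 = hip2 + off2
    # ballistic elimination: COM acceleration is exactly (0, -g)
    com3 = 2.0 * com2 - com1 + np.array([0.0, -g]) * dt * dt
    hip3 = com3 - off3
    return (
        ChainConfiguration(tuple(hip1), tuple(a1)),
        ChainConfiguration(tuple(hip2), tuple(a2)),
        ChainConfiguration(tuple(hip3), tuple(a3)),
    )


def reconstruct_entry_state(
    triplet: LandmarkFrameTriplet,
    profile: AnthropometricProfile,
    g: float = 9.81,
    max_nfev: int = 400,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
) -> ReconstructionResult:
    """Fit a ballistically consistent chain motion to the landmark triplet.

    Returns the middle-frame entry state with velocities from central
    differences of the optimized configurations over ``2 * frame_dt``.
    Non-convergence within the evaluation budget is flagged on the result
    rather than raised.
    """
    dt = triplet.frame_dt
    w = np.array([triplet.weight(lm) for lm in RECONSTRUCTION_LANDMARKS])
    sqw = np.sqrt(np.repeat(w, 2))
    meas = [
        np.concatenate([np.asarray(fr[lm], dtype=float) for lm in RECONSTRUCTION_LANDMARKS])
        for fr in triplet.frames
    ]

    def modelled(cfg):
        lm = landmarks_from_configuration(profile, cfg)
        return np.concatenate([lm[k] for k in RECONSTRUCTION_LANDMARKS])

    def residuals(x):
        cfgs = _unpack(x, profile, g, dt)
        return np.concatenate(
            [sqw * (modelled(c) - m) for c, m in zip(cfgs, meas)]
        )

    init = tuple(fit_configuration_to_landmarks(fr, profile) for fr in triplet.frames)
    x0 = _pack(init)
    sol = least_squares(
        residuals, x0, method="lm", max_nfev=max_nfev, ftol=ftol, xtol=xtol
    )
    cfgs = _unpack(sol.x, profile, g, dt)

    res = sol.fun.reshape(3, len(RECONSTRUCTION_LANDMARKS), 2)
    per_lm = {
        lm: float(np.sqrt(np.mean(np.sum(res[:, i, :] ** 2, axis=1))))
        for i, lm in enumerate(RECONSTRUCTION_LANDMARKS)
    }
    rms = float(np.sqrt(np.mean(np.sum(res.reshape(-1, 2) ** 2, axis=1))))

    c1, c2, c3 = cfgs
    hip_vel = (np.asarray(c3.hip_position) - np.asarray(c1.hip_position)) / (2 * dt)
    ang_vel = wrap_angle(
        np.asarray(c3.segment_angles) - np.asarray(c1.segment_angles)
    ) / (2 * dt)
    entry = ChainState(c2, (hip_vel[0], hip_vel[1]), tuple(ang_vel))
    return ReconstructionResult(
        entry_state=entry,
        configurations=cfgs,
        rms_residual=rms,
        per_landmark_residuals=per_lm,
        converged=bool(sol.status > 0),
        iterations=int(sol.nfev),
    )
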