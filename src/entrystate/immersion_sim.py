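"""Forward dynamics of the immersing swimmer.

From the instant of water entry the five-link chain moves under gravity
alone as external force; visco-elastic moments at the four joints
(left leg-trunk, right leg-trunk, arms-trunk, head-trunk) pull the body
toward full extension, emulating the swimmer streamlining during
immersion.  No hydrodynamic forces act, so the whole-body COM follows the
projectile closed form and whole-body angular momentum about the COM is
conserved -- both serve as exact oracles for the integrator.

The equations of motion for the floating-base chain (7 generalized
coordinates: hip position plus five segment angles) are assembled from the
segment-COM Jacobians:

    M(q) qdd = Q_gravity + Q_joint - sum_k m_k J_k^T (Jdot_k qd)

with M(q) = sum_k m_k J_k^T J_k + diag rotational inertias.  Integration
is fixed-step classical Runge-Kutta; events (COM crossing the waterline,
full immersion of all landmarks) are located by linear interpolation
between bracketing steps.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .body_model import (
    TRUNK,
    AnthropometricProfile,
    ChainState,
    landmarks_from_configuration,
    segment_com_positions,
    whole_body_com,
    wrap_angle,
    _geometry,
)

__all__ = [
    "JointParams",
    "SimulationSettings",
    "ImmersionTrajectory",
    "JOINT_OFFSETS",
    "chain_accelerations",
    "simulate_immersion",
    "state_at_event",
    "entry_hole_diameter",
    "tune_joint_parameters",
    "angular_momentum_about_com",
    "mechanical_energy",
    "relative_joint_angles",
]

#: Joint definitions: (segment index, alignment offset).  A joint is at
#: full extension when theta_segment = theta_trunk + offset; the legs
#: trail behind the trunk, arms and head extend beyond the shoulder along
#: the trunk axis.
JOINT_OFFSETS = ((0, math.pi), (1, math.pi), (3, 0.0), (4, 0.0))


@dataclass(frozen=True)
class JointParams:
    """Visco-elastic joint parameters shared by the four joints.

    The elastic moment has a symmetric dead zone of half-width
    ``resting_angle`` around full extension: zero inside, linear with
    ``stiffness`` outside.  ``damping`` acts on the relative joint
    velocity everywhere.  The shipped defaults (1000 Nm/rad, 150 Nms/rad,
    zero resting angle) are the values selected by the entry-hole
    minimization; at zero resting angle the dead zone vanishes and the
    spring is purely linear.
    """

    stiffness: float = 1000.0
    damping: float = 150.0
    resting_angle: float = 0.0

    def __post_init__(self):
        if self.stiffness < 0 or self.damping < 0:
            raise ValueError("stiffness and damping must be >= 0")
        if not 0.0 <= self.resting_angle <= 0.35:
            raise ValueError("resting_angle must be in [0, 0.35] rad (~20 deg)")


@dataclass(frozen=True)
class SimulationSettings:
    dt: float = 1e-4
    max_time: float = 2.0
    g: float = 9.81
    waterline_y: float = 0.0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.max_time > self.dt:
            raise ValueError("max_time must exceed dt")


@dataclass
class ImmersionTrajectory:
    """Dense fixed-step trajectory with event times.

    ``states`` is an (n, 14) array of packed chain states on ``times``;
    ``t_com_cross``/``t_full_immersion`` are NaN when the event was not
    reached before ``max_time`` (then ``completed`` is False).
    """

    times: np.ndarray
    states: np.ndarray
    com_path: np.ndarray
    t_com_cross: float
    t_full_immersion: float
    completed: bool
    waterline_x_min: float
    waterline_x_max: float
    profile: AnthropometricProfile = field(repr=False)
    settings: SimulationSettings = field(repr=False)

    @property
    def t_entry(self) -> float:
        return 0.0

    def state_at(self, t: float) -> ChainState:
        """Linear interpolation of generalized coordinates/velocities."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"time {t} outside trajectory range")
        i = int(np.searchsorted(self.times, t, side="right") - 1)
        i = min(i, len(self.times) - 2)
        w = (t - self.times[i]) / (self.times[i + 1] - self.times[i])
        y = (1 - w) * self.states[i] + w * self.states[i + 1]
        # interpolate angles through the wrapped difference
        dth = wrap_angle(self.states[i + 1, 2:7] - self.states[i, 2:7])
        y[2:7] = wrap_angle(self.states[i, 2:7] + w * dth)
        return ChainState.from_array(y)


def relative_joint_angles(state: ChainState):
    """Relative angle and angular velocity at each joint (deviation from
    full extension), ordered as ``JOINT_OFFSETS``."""
    ang = np.asarray(state.configuration.segment_angles)
    omg = np.asarray(state.segment_angular_velocities)
    phi = np.array([wrap_angle(ang[k] - ang[TRUNK] - off) for k, off in JOINT_OFFSETS])
    phidot = np.array([omg[k] - omg[TRUNK] for k, _ in JOINT_OFFSETS])
    return phi, phidot


def _deadzone(phi: np.ndarray, theta0: float) -> np.ndarray:
    return np.sign(phi) * np.maximum(np.abs(phi) - theta0, 0.0)


def _mass_matrix_and_forces(y, profile, params, g):
    """Assemble M(q), bias and generalized forces for packed state y."""
    q, qd = y[:7], y[7:]
    ang = q[2:7]
    omg = qd[2:7]
    m = profile.masses
    I = profile.inertias
    alpha, beta = _geometry(profile)

    ct, st = math.cos(ang[TRUNK]), math.sin(ang[TRUNK])
    c = np.cos(ang)
    s = np.sin(ang)
    upt = np.array([-st, ct])          # u'(theta_trunk)
    ut = np.array([ct, st])
    upk = np.stack([-s, c], axis=1)    # (5, 2) u'(theta_k)
    uk = np.stack([c, s], axis=1)

    # Jacobians J_k (2 x 7) stacked as (5, 2, 7)
    J = np.zeros((5, 2, 7))
    J[:, 0, 0] = 1.0
    J[:, 1, 1] = 1.0
    J[:, :, 2 + TRUNK] += alpha[:, None] * upt[None, :]
    for k in range(5):
        J[k, :, 2 + k] += beta[k] * upk[k]

    M = np.einsum("k,kij,kil->jl", m, J, J)
    M[2:7, 2:7][np.diag_indices(5)] += I

    # velocity bias: Jdot_k qd = -alpha*thetadot_t^2*u_t - beta*omg_k^2*u_k
    jdqd = -alpha[:, None] * (omg[TRUNK] ** 2) * ut[None, :] \
        - beta[:, None] * (omg[:, None] ** 2) * uk
    bias = np.einsum("k,kij,ki->j", m, J, jdqd)

    # gravity
    grav = np.array([0.0, -g])
    Q = np.einsum("k,kij,i->j", m, J, grav)

    # visco-elastic joint moments
    for k, off in JOINT_OFFSETS:
        phi = wrap_angle(ang[k] - ang[TRUNK] - off)
        phidot = omg[k] - omg[TRUNK]
        mom = -params.stiffness * _deadzone(np.array(phi), params.resting_angle) \
            - params.damping * phidot
        mom = float(mom)
        Q[2 + k] += mom
        Q[2 + TRUNK] -= mom
    return M, bias, Q


def chain_accelerations(
    state: ChainState,
    profile: AnthropometricProfile,
    params: JointParams,
    g: float = 9.81,
) -> np.ndarray:
    """Generalized accelerations (hip acceleration, 5 angular accelerations).

    Newton-Euler/Lagrange dynamics of the floating five-link chain under
    gravity and the internal visco-elastic joint moments.
    """
    y = state.as_array()
    M, bias, Q = _mass_matrix_and_forces(y, profile, params, g)
    try:
        return np.linalg.solve(M, Q - bias)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - positive masses
        raise RuntimeError("singular chain mass matrix") from exc


def _rhs(y, profile, params, g):
    M, bias, Q = _mass_matrix_and_forces(y, profile, params, g)
    qdd = np.linalg.solve(M, Q - bias)
    out = np.empty(14)
    out[:7] = y[7:]
    out[7:] = qdd
    return out


def _landmark_ys(y, profile):
    state_cfg = ChainState.from_array(y).configuration
    lm = landmarks_from_configuration(profile, state_cfg)
    return np.array([p[1] for p in lm.values()]), lm


def _waterline_crossings(lm, waterline_y):
    """x-coordinates where body lines pierce the waterline."""
    lines = (
        ("hip", "ankle_L"),
        ("hip", "ankle_R"),
        ("hip", "shoulder"),
        ("shoulder", "fingertip"),   # arms incl. rigid hand extension
        ("shoulder", "vertex"),
    )
    xs = []
    for a, b in lines:
        (x1, y1), (x2, y2) = lm[a], lm[b]
        y1, y2 = y1 - waterline_y, y2 - waterline_y
        if y1 == 0.0:
            xs.append(x1)
        if y2 == 0.0:
            xs.append(x2)
        if (y1 > 0 > y2) or (y1 < 0 < y2):
            w = y1 / (y1 - y2)
            xs.append(x1 + w * (x2 - x1))
    return xs


def simulate_immersion(
    entry_state: ChainState,
    profile: AnthropometricProfile,
    params: JointParams | None = None,
    settings: SimulationSettings | None = None,
) -> ImmersionTrajectory:
    """Integrate the chain from water entry until full immersion.

    The entry state must have the fingertip at (or marginally below) the
    waterline and the COM above it.  Classical RK4 with the fixed step of
    ``settings.dt``; the COM-crossing and full-immersion event times are
    located by linear interpolation between bracketing steps.  If full
    immersion is not reached within ``max_time`` the trajectory is
    returned with ``completed=False``.
    """
    params = params or JointParams()
    settings = settings or SimulationSettings()
    g, dt, wl = settings.g, settings.dt, settings.waterline_y

    y = entry_state.as_array()
    lm_ys, lm = _landmark_ys(y, profile)
    if lm["fingertip"][1] > wl + 1e-6:
        raise ValueError("entry state must have the fingertip at or below the waterline")
    com0, _ = whole_body_com(profile, entry_state)
    if com0[1] <= wl:
        raise ValueError("entry state must have the COM above the waterline")

    n_max = int(math.ceil(settings.max_time / dt))
    times = [0.0]
    states = [y.copy()]
    coms = [com0.copy()]
    xs0 = _waterline_crossings(lm, wl)
    x_min = min(xs0) if xs0 else math.inf
    x_max = max(xs0) if xs0 else -math.inf

    t_cross = math.nan
    t_full = math.nan
    prev_com_y = com0[1]
    prev_max_lm = lm_ys.max()

    t = 0.0
    for _ in range(n_max):
        k1 = _rhs(y, profile, params, g)
        k2 = _rhs(y + 0.5 * dt * k1, profile, params, g)
        k3 = _rhs(y + 0.5 * dt * k2, profile, params, g)
        k4 = _rhs(y + dt * k3, profile, params, g)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt

        lm_ys, lm = _landmark_ys(y, profile)
        state = ChainState.from_array(y)
        com, _ = whole_body_com(profile, state)
        xs = _waterline_crossings(lm, wl)
        if xs:
            x_min = min(x_min, min(xs))
            x_max = max(x_max, max(xs))

        times.append(t)
        states.append(y.copy())
        coms.append(com.copy())

        if math.isnan(t_cross) and prev_com_y > wl >= com[1]:
            w = (prev_com_y - wl) / (prev_com_y - com[1])
            t_cross = t - dt + w * dt
        max_lm = lm_ys.max()
        if math.isnan(t_full) and prev_max_lm > wl >= max_lm:
            w = (prev_max_lm - wl) / (prev_max_lm - max_lm)
            t_full = t - dt + w * dt
        prev_com_y = com[1]
        prev_max_lm = max_lm
        if not math.isnan(t_full):
            break

    return ImmersionTrajectory(
        times=np.array(times),
        states=np.stack(states),
        com_path=np.stack(coms),
        t_com_cross=t_cross,
        t_full_immersion=t_full,
        completed=not math.isnan(t_full),
        waterline_x_min=x_min,
        waterline_x_max=x_max,
        profile=profile,
        settings=settings,
    )


def state_at_event(trajectory: ImmersionTrajectory, event: str) -> ChainState:
    """Interpolated chain state at ``'com_cross'`` or ``'full_immersion'``."""
    t = {"com_cross": trajectory.t_com_cross,
         "full_immersion": trajectory.t_full_immersion}.get(event)
    if t is None:
        raise ValueError(f"unknown event {event!r}")
    if math.isnan(t):
        raise ValueError(f"event {event!r} did not occur within the simulated time")
    return trajectory.state_at(t)


def entry_hole_diameter(
    trajectory: ImmersionTrajectory, profile: AnthropometricProfile | None = None
) -> float:
    """Horizontal extent of the waterline piercings over the immersion.

    The hole is the range max(x) - min(x) of all points where any body
    line segment (legs, trunk, arms with hand extension, head) intersected
    the waterline at any time step.  The body is a line model, so a
    perfectly streamlined vertical entry yields a vanishing hole.
    """
    if not trajectory.completed:
        raise ValueError("trajectory did not reach full immersion")
    if not np.isfinite(trajectory.waterline_x_min):
        raise ValueError("no waterline intersections recorded")
    return trajectory.waterline_x_max - trajectory.waterline_x_min


def tune_joint_parameters(
    entry_states: list[ChainState],
    grid: dict | None,
    profile: AnthropometricProfile,
    settings: SimulationSettings | None = None,
):
    """Heuristic grid search minimizing the mean entry-hole diameter.

    ``grid`` maps ``stiffness``/``resting_angle``/``damping`` to value
    sequences (defaults: stiffness 600..1000 Nm/rad in steps of 100,
    resting angle 0..20 deg in steps of 5, damping {5, 25, 50, 100, 150}
    Nms/rad).  Every entry state is simulated under every grid point; a
    grid point whose simulation fails to immerse scores +inf.  Ties are
    broken toward higher stiffness, then higher damping, then lower
    resting angle.  Returns ``(best JointParams, score table)`` where the
    table lists every grid point with its mean hole diameter.
    """
    if not entry_states:
        raise ValueError("entry_states must be non-empty")
    grid = grid or {}
    stiffnesses = list(grid.get("stiffness", [600.0, 700.0, 800.0, 900.0, 1000.0]))
    rest_angles = list(grid.get("resting_angle", list(np.deg2rad([0, 5, 10, 15, 20]))))
    dampings = list(grid.get("damping", [5.0, 25.0, 50.0, 100.0, 150.0]))
    if not (stiffnesses and rest_angles and dampings):
        raise ValueError("grid axes must be non-empty")

    rows = []
    for k, th0, b in itertools.product(stiffnesses, rest_angles, dampings):
        params = JointParams(stiffness=k, damping=b, resting_angle=th0)
        holes = []
        for st in entry_states:
            try:
                traj = simulate_immersion(st, profile, params, settings)
                holes.append(entry_hole_diameter(traj))
            except ValueError:
                holes.append(math.inf)
        rows.append(
            {"stiffness": k, "resting_angle": th0, "damping": b,
             "mean_hole": float(np.mean(holes))}
        )

    best = min(
        rows,
        key=lambda r: (r["mean_hole"], -r["stiffness"], -r["damping"], r["resting_angle"]),
    )
    best_params = JointParams(
        stiffness=best["stiffness"],
        damping=best["damping"],
        resting_angle=best["resting_angle"],
    )
    return best_params, rows


# ---------------------------------------------------------------------------
# Conserved quantities (oracles for the integrator)
# ---------------------------------------------------------------------------

def angular_momentum_about_com(profile: AnthropometricProfile, state: ChainState) -> float:
    """Whole-body angular momentum about the COM (kg m^2/s, CCW positive)."""
    m = profile.masses
    I = profile.inertias
    omg = np.asarray(state.segment_angular_velocities)
    pos = segment_com_positions(profile, state.configuration)
    ang = np.asarray(state.configuration.segment_angles)
    alpha, beta = _geometry(profile)
    upt = np.array([-math.sin(ang[TRUNK]), math.cos(ang[TRUNK])])
    upk = np.stack([[-math.sin(a), math.cos(a)] for a in ang])
    vel = (
        np.asarray(state.hip_velocity)[None, :]
        + alpha[:, None] * omg[TRUNK] * upt[None, :]
        + beta[:, None] * omg[:, None] * upk
    )
    com, vcom = whole_body_com(profile, state)
    r = pos - com[None, :]
    v = vel - vcom[None, :]
    spin = float(np.sum(I * omg))
    orbital = float(np.sum(m * (r[:, 0] * v[:, 1] - r[:, 1] * v[:, 0])))
    return spin + orbital


def mechanical_energy(
    profile: AnthropometricProfile,
    state: ChainState,
    params: JointParams,
    g: float = 9.81,
) -> float:
    """Kinetic + gravitational + elastic joint energy of the chain."""
    m = profile.masses
    I = profile.inertias
    omg = np.asarray(state.segment_angular_velocities)
    ang = np.asarray(state.configuration.segment_angles)
    alpha, beta = _geometry(profile)
    upt = np.array([-math.sin(ang[TRUNK]), math.cos(ang[TRUNK])])
    upk = np.stack([[-math.sin(a), math.cos(a)] for a in ang])
    vel = (
        np.asarray(state.hip_velocity)[None, :]
        + alpha[:, None] * omg[TRUNK] * upt[None, :]
        + beta[:, None] * omg[:, None] * upk
    )
    kinetic = 0.5 * float(np.sum(m * np.sum(vel**2, axis=1))) + 0.5 * float(
        np.sum(I * omg**2)
    )
    pos = segment_com_positions(profile, state.configuration)
    potential = g * float(np.sum(m * pos[:, 1]))
    phi, _ = relative_joint_angles(state)
    elastic = 0.5 * params.stiffness * float(
        np.sum(_deadzone(phi, params.resting_angle) ** 2)
    )
    return kinetic + potential + elastic
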