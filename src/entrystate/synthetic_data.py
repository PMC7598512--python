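"""Synthetic dive-start cohorts with the study's statistical structure.

The generator emulates the empirical design end to end: 14 swimmers
(8 men, 6 women) each performing 6 instruction conditions x 4 repeats
over three sessions (24 starts per swimmer); condition-specific entry
states (horizontal COM velocity, entry distance, entry angle at
COMcrossWL) drawn around the published condition means with sex,
between-swimmer and within-swimmer components; rigid ballistic flight to
water entry; landmark frames with Gaussian digitization noise (default
0.7 cm); and response times built from the fitted linear predictors
(TTO15 and TTO5 equations) plus a per-swimmer random intercept and a
Gaussian residual (default residual SD 0.23 s for TTO15).

Entry states are constructed perfectly aligned (all segments on one
axis with a common angular velocity).  Aligned states are an invariant
manifold of the immersion dynamics at zero resting angle, so their
evolution has a closed form (projectile COM plus uniform rotation); the
generator's fast path exploits this to produce COMcrossWL variables
analytically, while the slow path pushes every start through landmark
generation, reconstruction and the forward simulation.

Everything is driven by one seeded ``numpy.random.Generator``; identical
config and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .body_model import (
    TRUNK,
    AnthropometricProfile,
    ChainConfiguration,
    ChainState,
    estimate_segment_parameters,
    landmarks_from_configuration,
    whole_body_com,
    wrap_angle,
)
from .entry_reconstruction import RECONSTRUCTION_LANDMARKS, LandmarkFrameTriplet
from .start_metrics import EntryVariables, StartRecord

__all__ = [
    "CONDITIONS",
    "CohortConfig",
    "TakeOffState",
    "Cohort",
    "default_profile",
    "aligned_entry_state",
    "ballistic_flight",
    "propagate_rigid",
    "generate_landmark_triplet",
    "generate_cohort",
]

_G = 9.81

#: Per-condition targets: mean block time (s), take-off angle (rad),
#: horizontal COM velocity at entry (m/s), entry distance (m) and entry
#: angle at COMcrossWL (rad), with the dispersions used for block-phase
#: metadata.  These are the condition means of the study protocol.
CONDITIONS: dict[str, dict[str, float]] = {
    "regular": dict(block_time=0.75, bt_sd=0.05, take_off_angle=0.47, toa_sd=0.13,
                    vx=4.4, entry_distance=3.1, ea_cross=-0.66),
    "short_block_time": dict(block_time=0.70, bt_sd=0.05, take_off_angle=0.47,
                             toa_sd=0.14, vx=4.4, entry_distance=3.1, ea_cross=-0.66),
    "steep_take_off": dict(block_time=0.82, bt_sd=0.09, take_off_angle=0.66,
                           toa_sd=0.17, vx=3.9, entry_distance=3.2, ea_cross=-0.76),
    "flat_take_off": dict(block_time=0.82, bt_sd=0.06, take_off_angle=0.35,
                          toa_sd=0.10, vx=4.3, entry_distance=2.8, ea_cross=-0.72),
    "submax_effort": dict(block_time=0.86, bt_sd=0.07, take_off_angle=0.48,
                          toa_sd=0.13, vx=4.2, entry_distance=3.0, ea_cross=-0.72),
    "without_arms": dict(block_time=0.88, bt_sd=0.08, take_off_angle=0.48,
                         toa_sd=0.13, vx=4.3, entry_distance=3.0, ea_cross=-0.70),
}

#: Sub-segment lengths as fractions of standing height, used to build
#: synthetic anthropometric measurement sets.
_LENGTH_FRACTIONS = {
    "head_neck": 0.180,
    "thorax": 0.128,
    "abdomen": 0.084,
    "pelvis": 0.078,
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.108,
    "thigh": 0.245,
    "shank": 0.246,
    "foot": 0.120,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    The response-truth coefficients are ordered (intercept, vx at entry,
    entry distance, entry angle at COMcrossWL).  Dispersion defaults
    decompose the published pooled condition SDs into sex, between-swimmer
    and within-swimmer components; the split is a documented modelling
    choice because only the pooled values are reported.
    """

    n_male: int = 8
    n_female: int = 6
    repeats: int = 4
    conditions: tuple[str, ...] = tuple(CONDITIONS)
    seed: int = 0

    # response truth
    coef_tto15: tuple[float, float, float, float] = (9.623, -0.310, -0.575, -0.511)
    coef_tto5: tuple[float, float, float, float] = (2.033, -0.144, -0.106, -0.178)
    residual_sd_tto15: float = 0.23
    residual_sd_tto5: float = 0.042
    intercept_sd_tto15: float = 0.45
    intercept_sd_tto5: float = 0.10
    intercept_sex_shift_tto15: tuple[float, float] = (-0.146, 0.194)  # (male, female)
    intercept_sex_shift_tto5: tuple[float, float] = (-0.040, 0.053)

    # entry-state dispersions (between-swimmer, within-swimmer) and sex shifts
    vx_sex_shift: tuple[float, float] = (0.17, -0.23)
    vx_swimmer_sd: float = 0.12
    vx_within_sd: float = 0.15
    entry_distance_sex_shift: tuple[float, float] = (0.17, -0.23)
    entry_distance_swimmer_sd: float = 0.10
    entry_distance_within_sd: float = 0.12
    ea_cross_sex_shift: tuple[float, float] = (0.03, -0.04)
    ea_cross_swimmer_sd: float = 0.05
    ea_cross_within_sd: float = 0.09
    ea_entry_mean: float = -0.36
    ea_entry_swimmer_sd: float = 0.04
    ea_entry_within_sd: float = 0.08
    vy_entry_mean: float = -3.15
    vy_swimmer_sd: float = 0.15
    vy_within_sd: float = 0.25

    # landmark digitization
    landmark_noise_sd: float = 0.007
    frame_dt: float = 0.02

    # hip-timing plumbing (underwater glide profile)
    flight_time_mean: float = 0.30
    flight_time_sd: float = 0.02
    glide_decay_distance: float = 2.0
    swim_speed_mean: float = 1.9
    swim_speed_swimmer_sd: float = 0.15
    swim_speed_within_sd: float = 0.05

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        for name in ("residual_sd_tto15", "residual_sd_tto5", "intercept_sd_tto15",
                     "intercept_sd_tto5", "landmark_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TakeOffState:
    """Rigid-body state at the instant of take-off."""

    com_position: tuple[float, float]
    com_velocity: tuple[float, float]
    orientation: float
    angular_velocity: float

    def __post_init__(self):
        if not self.com_position[1] > 0:
            raise ValueError("take-off COM must be above the waterline")
        if not self.com_velocity[0] > 0:
            raise ValueError("take-off must move in the swimming direction")


@dataclass
class Cohort:
    """Generated cohort: analysis records plus full latent truth."""

    records: list[StartRecord]
    profiles: dict[str, AnthropometricProfile]
    entry_states: dict[str, ChainState]
    truth: dict
    config: CohortConfig


def default_profile(
    height: float = 1.86, total_mass: float = 78.9, sex: str = "male"
) -> AnthropometricProfile:
    """Anthropometric profile from height-proportional segment lengths."""
    measurements = {k: f * height for k, f in _LENGTH_FRACTIONS.items()}
    return estimate_segment_parameters(measurements, total_mass, sex=sex)


# ---------------------------------------------------------------------------
# Rigid flight mechanics
# ---------------------------------------------------------------------------

def _aligned_configuration(profile, trunk_angle, hip):
    a = trunk_angle
    return ChainConfiguration(
        tuple(hip), (wrap_angle(a + math.pi), wrap_angle(a + math.pi), a, a, a)
    )


def aligned_entry_state(
    profile: AnthropometricProfile,
    trunk_angle: float,
    fingertip: tuple[float, float],
    com_velocity: tuple[float, float],
    angular_velocity: float = 0.0,
) -> ChainState:
    """Fully extended, aligned chain with the fingertip pinned at a point.

    All segments lie on one axis at ``trunk_angle`` (legs trailing); the
    whole body translates with the given COM velocity and rotates rigidly
    at ``angular_velocity`` about the COM.
    """
    cfg0 = _aligned_configuration(profile, trunk_angle, (0.0, 0.0))
    lm = landmarks_from_configuration(profile, cfg0)
    ft0 = lm["fingertip"]
    hip = np.asarray(fingertip, dtype=float) - ft0
    cfg = _aligned_configuration(profile, trunk_angle, hip)

    state0 = ChainState(cfg, (0.0, 0.0), (0.0,) * 5)
    com, _ = whole_body_com(profile, state0)
    r = np.asarray(cfg.hip_position) - com
    w = angular_velocity
    hip_vel = (
        com_velocity[0] - w * r[1],
        com_velocity[1] + w * r[0],
    )
    return ChainState(cfg, hip_vel, (w,) * 5)


def propagate_rigid(
    state: ChainState, profile: AnthropometricProfile, t: float, g: float = _G
) -> ChainState:
    """Closed-form ballistic propagation of a rigid (common-omega) state.

    COM follows the projectile; the body rotates uniformly about the COM.
    Only valid when all angular velocities are equal, which holds for
    flight and for aligned immersion at zero resting angle.
    """
    omgs = np.asarray(state.segment_angular_velocities)
    if not np.allclose(omgs, omgs[0], atol=1e-12):
        raise ValueError("rigid propagation requires a common angular velocity")
    w = float(omgs[0])
    com0, vcom0 = whole_body_com(profile, state)
    com_t = com0 + np.asarray(vcom0) * t + 0.5 * np.array([0.0, -g]) * t * t
    vcom_t = np.asarray(vcom0) + np.array([0.0, -g]) * t

    c, s = math.cos(w * t), math.sin(w * t)
    R = np.array([[c, -s], [s, c]])
    hip0 = np.asarray(state.configuration.hip_position)
    hip_t = com_t + R @ (hip0 - com0)
    ang_t = tuple(wrap_angle(np.asarray(state.configuration.segment_angles) + w * t))
    r = hip_t - com_t
    hip_vel = (vcom_t[0] - w * r[1], vcom_t[1] + w * r[0])
    return ChainState(ChainConfiguration(tuple(hip_t), ang_t), hip_vel, (w,) * 5)


def ballistic_flight(
    takeoff: TakeOffState,
    profile: AnthropometricProfile,
    g: float = _G,
    max_flight_time: float = 3.0,
):
    """Fly the rigid aligned body from take-off to first fingertip contact.

    Returns ``(entry ChainState, entry time)``.  The fingertip height
    under projectile COM motion and uniform rotation is sampled densely,
    the first downward zero-crossing bracketed and refined by Brent root
    finding.  Raises if the fingertip never reaches the waterline within
    ``max_flight_time``.
    """
    cfg0 = _aligned_configuration(profile, takeoff.orientation, (0.0, 0.0))
    lm0 = landmarks_from_configuration(profile, cfg0)
    state_ref = ChainState(cfg0, (0.0, 0.0), (0.0,) * 5)
    com_ref, _ = whole_body_com(profile, state_ref)
    d = lm0["fingertip"] - com_ref  # fingertip offset from COM at t=0 frame
    r0 = math.hypot(*d)
    phi0 = math.atan2(d[1], d[0])
    x0, y0 = takeoff.com_position
    vx, vy = takeoff.com_velocity
    w = takeoff.angular_velocity

    def fingertip_y(t):
        return y0 + vy * t - 0.5 * g * t * t + r0 * math.sin(phi0 + w * t)

    if fingertip_y(0.0) <= 0.0:
        t_entry = 0.0
    else:
        ts = np.linspace(0.0, max_flight_time, 3001)
        ys = np.array([fingertip_y(t) for t in ts])
        below = np.nonzero(ys <= 0.0)[0]
        if below.size == 0:
            raise ValueError("fingertip never reaches the waterline in flight")
        i = below[0]
        t_entry = brentq(fingertip_y, ts[i - 1], ts[i], xtol=1e-12)

    com_t = np.array([x0 + vx * t_entry, y0 + vy * t_entry - 0.5 * g * t_entry**2])
    vcom_t = (vx, vy - g * t_entry)
    angle_t = takeoff.orientation + w * t_entry
    fingertip_t = com_t + r0 * np.array(
        [math.cos(phi0 + w * t_entry), math.sin(phi0 + w * t_entry)]
    )
    state = aligned_entry_state(
        profile, wrap_angle(angle_t), tuple(fingertip_t), vcom_t, w
    )
    return state, float(t_entry)


def generate_landmark_triplet(
    entry_state: ChainState,
    profile: AnthropometricProfile,
    noise_sd: float = 0.007,
    frame_dt: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> LandmarkFrameTriplet:
    """Project the ballistic body at -dt, 0, +dt and add digitization noise.

    Noise is i.i.d. Gaussian per landmark coordinate, emulating manual
    video digitization; the same seed yields the same triplet.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    frames = []
    for t in (-frame_dt, 0.0, frame_dt):
        st = propagate_rigid(entry_state, profile, t)
        lm = landmarks_from_configuration(profile, st.configuration)
        frame = {}
        for name in RECONSTRUCTION_LANDMARKS:
            noise = rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 else np.zeros(2)
            frame[name] = np.asarray(lm[name], dtype=float) + noise
        frames.append(frame)
    return LandmarkFrameTriplet(
        times=(-frame_dt, 0.0, frame_dt), frames=tuple(frames), frame_dt=frame_dt
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _session_layout(conditions, rng):
    """Assign conditions to the three sessions: 'regular' is always in
    session 1; the remaining conditions are shuffled into the 1+2+2 slots."""
    others = [c for c in conditions if c != "regular"]
    perm = list(rng.permutation(others))
    layout = {}
    if "regular" in conditions:
        layout["regular"] = 1
    slots = [1] * (2 - ("regular" in conditions)) + [2, 2, 3, 3]
    for cond, sess in zip(perm, slots):
        layout[cond] = sess
    return layout


def _hip_crossing_times(x_entry_hip, vx, tto5, v_swim, decay_distance):
    """4.5/5.5-m hip crossing times around TTO5 from a spatial glide decay.

    The hip speed decays in space from the entry speed toward the
    swimmer's underwater swim speed,

        v(x) = v_swim + (vx - v_swim) exp(-(x - x_entry) / d0),

    so a start that enters faster or further along carries more speed to
    the 5-m line.  The crossing times are placed around the drawn TTO5 by
    the closed-form time-of-passage integral of this profile, which keeps
    t45 < TTO5 < t55 exactly consistent with the local speed.
    """
    d0 = decay_distance
    a = v_swim
    b = vx - v_swim
    if not (vx > 0 and a > 0):
        raise ValueError("speeds must be positive")

    def passage_time(x1, x2):
        # integral of dx / (a + b exp(-(x - xe)/d0)) from x1 to x2
        def F(x):
            u = x - x_entry_hip
            return u / a + (d0 / a) * math.log(a + b * math.exp(-u / d0))
        return F(x2) - F(x1)

    t45 = tto5 - passage_time(4.5, 5.0)
    t55 = tto5 + passage_time(5.0, 5.5)
    return t45, t55


def _entry_variables_analytic(profile, state, g=_G):
    """COMcrossWL variables in closed form for an aligned rigid entry."""
    com, vcom = whole_body_com(profile, state)
    lm = landmarks_from_configuration(profile, state.configuration)
    vx, vy = float(vcom[0]), float(vcom[1])
    y0 = float(com[1])
    t_c = (vy + math.sqrt(vy * vy + 2.0 * g * y0)) / g
    w = state.segment_angular_velocities[TRUNK]
    ea_entry = state.configuration.segment_angles[TRUNK]
    ea_cross = float(wrap_angle(ea_entry + w * t_c))
    vdir_cross = math.atan2(vy - g * t_c, vx)
    return EntryVariables(
        com_entry=(float(com[0]), y0),
        hand_entry=(float(lm["fingertip"][0]), float(lm["fingertip"][1])),
        vx_entry=vx,
        vy_entry=vy,
        v_direction_entry=math.atan2(vy, vx),
        v_magnitude_entry=math.hypot(vx, vy),
        entry_angle_entry=ea_entry,
        com_at_cross=(float(com[0]) + vx * t_c, 0.0),
        v_direction_cross=vdir_cross,
        entry_angle_cross=ea_cross,
        direction_difference_cross=abs(float(wrap_angle(ea_cross - vdir_cross))),
    ), t_c


def generate_cohort(
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Generate a full synthetic cohort.

    For every swimmer: sex-specific anthropometrics and random intercepts;
    for every start: condition-specific entry-state draws, an aligned
    entry ChainState whose analytic immersion yields the COMcrossWL
    variables, responses from the truth equations plus intercept and
    residual, and hip-timing data consistent with the drawn TTO5.  The
    returned truth ledger contains every latent draw, sufficient to
    reproduce each response exactly.
    """
    config = config or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    c15 = config.coef_tto15
    c5 = config.coef_tto5
    records: list[StartRecord] = []
    profiles: dict[str, AnthropometricProfile] = {}
    entry_states: dict[str, ChainState] = {}
    truth_swimmers = {}
    truth_starts = []

    sexes = ["male"] * config.n_male + ["female"] * config.n_female
    for i, sex in enumerate(sexes):
        sid = f"sw{i + 1:02d}"
        s_idx = 0 if sex == "male" else 1
        height = rng.normal(1.86 if sex == "male" else 1.73, 0.04)
        mass = rng.normal(78.9 if sex == "male" else 65.6, 5.0 if sex == "male" else 7.5)
        height = max(height, 1.4)
        mass = max(mass, 40.0)
        profile = default_profile(height, mass, sex)
        profiles[sid] = profile

        b15 = config.intercept_sex_shift_tto15[s_idx] + rng.normal(0, config.intercept_sd_tto15)
        b5 = config.intercept_sex_shift_tto5[s_idx] + rng.normal(0, config.intercept_sd_tto5)
        off_vx = config.vx_sex_shift[s_idx] + rng.normal(0, config.vx_swimmer_sd)
        off_x = config.entry_distance_sex_shift[s_idx] + rng.normal(
            0, config.entry_distance_swimmer_sd)
        off_ea = config.ea_cross_sex_shift[s_idx] + rng.normal(0, config.ea_cross_swimmer_sd)
        off_eae = rng.normal(0, config.ea_entry_swimmer_sd)
        off_vy = rng.normal(0, config.vy_swimmer_sd)
        v_swim_i = max(config.swim_speed_mean + rng.normal(0, config.swim_speed_swimmer_sd), 1.0)
        layout = _session_layout(config.conditions, rng)
        truth_swimmers[sid] = dict(
            sex=sex, height=float(height), mass=float(mass),
            intercept_tto15=float(b15), intercept_tto5=float(b5),
            offset_vx=float(off_vx), offset_entry_distance=float(off_x),
            offset_ea_cross=float(off_ea), offset_ea_entry=float(off_eae),
            offset_vy=float(off_vy), swim_speed=float(v_swim_i),
            session_layout=dict(layout),
        )

        for cond in config.conditions:
            spec = CONDITIONS[cond]
            for rep in range(config.repeats):
                start_id = f"{sid}_{cond}_{rep + 1}"
                vx = spec["vx"] + off_vx + rng.normal(0, config.vx_within_sd)
                vx = max(vx, 2.0)
                xes = spec["entry_distance"] + off_x + rng.normal(
                    0, config.entry_distance_within_sd)
                ea_cross_t = spec["ea_cross"] + off_ea + rng.normal(
                    0, config.ea_cross_within_sd)
                ea_cross_t = min(ea_cross_t, -0.2)
                ea_entry = config.ea_entry_mean + off_eae + rng.normal(
                    0, config.ea_entry_within_sd)
                ea_entry = float(np.clip(ea_entry, -1.2, -0.1))
                vy = config.vy_entry_mean + off_vy + rng.normal(0, config.vy_within_sd)
                vy = min(vy, -1.5)
                block_time = rng.normal(spec["block_time"], spec["bt_sd"])
                take_off_angle = rng.normal(spec["take_off_angle"], spec["toa_sd"])
                t_flight = max(rng.normal(config.flight_time_mean,
                                          config.flight_time_sd), 0.15)

                # aligned entry state; omega chosen so the rigid rotation
                # reaches the target entry angle at COM crossing
                probe = aligned_entry_state(profile, ea_entry, (xes, 0.0), (vx, vy), 0.0)
                com0, _ = whole_body_com(profile, probe)
                t_c = (vy + math.sqrt(vy * vy + 2 * _G * com0[1])) / _G
                omega = (ea_cross_t - ea_entry) / t_c
                state = aligned_entry_state(profile, ea_entry, (xes, 0.0), (vx, vy), omega)
                entry, t_c = _entry_variables_analytic(profile, state)
                entry_states[start_id] = state

                eps15 = rng.normal(0, config.residual_sd_tto15)
                eps5 = rng.normal(0, config.residual_sd_tto5)
                ea_c = entry.entry_angle_cross
                tto15 = c15[0] + c15[1] * vx + c15[2] * xes + c15[3] * ea_c + b15 + eps15
                tto5 = c5[0] + c5[1] * vx + c5[2] * xes + c5[3] * ea_c + b5 + eps5

                hip_x = float(state.configuration.hip_position[0])
                v_s = max(v_swim_i + rng.normal(0, config.swim_speed_within_sd), 1.0)
                t45, t55 = _hip_crossing_times(
                    hip_x, vx, tto5, v_s, config.glide_decay_distance
                )
                # the hip cannot reach 4.5 m before water entry: shift the
                # (rare) infeasible draw forward in time
                tto5_clamped = tto5
                if t45 < t_flight + 0.02:
                    shift = t_flight + 0.02 - t45
                    tto5_clamped = tto5 + shift
                    t45 += shift
                    t55 += shift
                tto15 = max(tto15, tto5_clamped + 0.5)

                rec = StartRecord(
                    swimmer_id=sid,
                    sex=sex,
                    session=layout.get(cond, 1),
                    condition=cond,
                    block_time=float(block_time),
                    take_off_angle=float(take_off_angle),
                    entry=entry,
                    time_to_15m_from_signal=float(block_time + tto15),
                    tto15=float(tto15),
                    tto5=float(tto5_clamped),
                    t_hip_45=float(t45),
                    t_hip_55=float(t55),
                    start_id=start_id,
                )
                records.append(rec)
                truth_starts.append(dict(
                    start_id=start_id, swimmer_id=sid, condition=cond,
                    vx=float(vx), entry_distance=float(xes),
                    ea_cross_target=float(ea_cross_t), ea_cross=float(ea_c),
                    ea_entry=float(ea_entry), vy=float(vy),
                    eps_tto15=float(eps15), eps_tto5=float(eps5),
                    tto15=float(tto15), tto5=float(tto5_clamped),
                    tto5_unclamped=float(tto5), t_flight=float(t_flight),
                    t_com_cross=float(t_c), glide_swim_speed=float(v_s),
                    omega=float((ea_cross_t - ea_entry) / t_c),
                ))

    truth = dict(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        swimmers=truth_swimmers,
        starts=truth_starts,
    )
    return Cohort(records=records, profiles=profiles,
                  entry_states=entry_states, truth=truth, config=config)
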