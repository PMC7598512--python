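import math

import numpy as np
import pytest

from entrystate.body_model import ChainConfiguration, ChainState, whole_body_com
from entrystate.immersion_sim import (
    JointParams,
    SimulationSettings,
    angular_momentum_about_com,
    chain_accelerations,
    entry_hole_diameter,
    mechanical_energy,
    relative_joint_angles,
    simulate_immersion,
    state_at_event,
    tune_joint_parameters,
)
from entrystate.synthetic_data import aligned_entry_state

G = 9.81


def bend(state, darm=0.0, dhead=0.0, dlegL=0.0, warm=0.0, profile=None):
    """Perturb joint angles; if a profile is given, drop the body so the
    fingertip stays at/below the waterline (the entry precondition)."""
    y = state.as_array()
    y[5] += darm
    y[6] += dhead
    y[2] += dlegL
    y[12] += warm
    st = ChainState.from_array(y)
    if profile is not None:
        from entrystate.body_model import landmarks_from_configuration
        lm = landmarks_from_configuration(profile, st.configuration)
        ft_y = lm["fingertip"][1]
        if ft_y > 0.0:
            y[1] -= ft_y + 1e-9
            st = ChainState.from_array(y)
    return st


# ---------------------------------------------------------------------------
# chain_accelerations
# ---------------------------------------------------------------------------

def test_aligned_extended_body_freefalls(profile):
    """All joints at full extension with zero relative velocity: joint
    moments vanish and the COM accelerates at exactly (0, -g)."""
    st = aligned_entry_state(profile, -0.5, (3.0, 0.0), (4.0, -3.0), 0.0)
    qdd = chain_accelerations(st, profile, JointParams())
    # zero angular velocity, no moments -> no angular acceleration
    np.testing.assert_allclose(qdd[2:], 0.0, atol=1e-10)
    np.testing.assert_allclose(qdd[:2], [0.0, -G], atol=1e-10)


def test_free_joint_chain_conserves_angular_momentum(profile):
    """With zero stiffness/damping the chain is free; internal forces do
    not change the whole-body angular momentum about the COM."""
    st = bend(
        aligned_entry_state(profile, -0.4, (3.0, 0.0), (4.0, -3.0), -1.5),
        darm=0.6, dhead=-0.3, dlegL=0.4, warm=2.0,
    )
    free = JointParams(stiffness=0.0, damping=0.0)
    dt = 1e-6
    qdd = chain_accelerations(st, profile, free)
    y = st.as_array()
    yp = y.copy()
    yp[:7] += dt * y[7:]
    yp[7:] += dt * qdd
    L0 = angular_momentum_about_com(profile, st)
    L1 = angular_momentum_about_com(profile, ChainState.from_array(yp))
    assert abs(L1 - L0) / abs(L0) < 1e-8


@pytest.fixture(scope="module")
def lagrangian_oracle(profile):
    """Independent symbolic derivation of the chain dynamics.

    Kinetic and potential energy are written in sympy from the segment
    COM kinematics; the elastic joint moments come from the potential
    U = k/2 * phi^2 (zero resting angle) and damping from a Rayleigh
    dissipation function R = b/2 * phidot^2.  Accelerations solve
    M qdd = rhs with M the Hessian of T in the velocities.
    """
    import sympy as sp

    m = profile.masses
    I = profile.inertias
    lens = profile.lengths
    com_r = np.array([s.com_ratio for s in profile.segments])
    Lt = lens[2]

    q = sp.symbols("x y t0 t1 t2 t3 t4")
    qd = sp.symbols("vx vy w0 w1 w2 w3 w4")
    k_s, b_s, g_s = sp.symbols("k b g")
    x, y = q[0], q[1]
    th = q[2:7]
    om = qd[2:7]

    alpha = [0.0, 0.0, 0.0, Lt, Lt]
    beta = [com_r[i] * lens[i] for i in range(5)]
    T = 0
    V = 0
    for i in range(5):
        px = x + alpha[i] * sp.cos(th[2]) + beta[i] * sp.cos(th[i])
        py = y + alpha[i] * sp.sin(th[2]) + beta[i] * sp.sin(th[i])
        vx_i = qd[0] - alpha[i] * om[2] * sp.sin(th[2]) - beta[i] * om[i] * sp.sin(th[i])
        vy_i = qd[1] + alpha[i] * om[2] * sp.cos(th[2]) + beta[i] * om[i] * sp.cos(th[i])
        T += sp.Rational(1, 2) * m[i] * (vx_i**2 + vy_i**2) \
            + sp.Rational(1, 2) * I[i] * om[i] ** 2
        V += m[i] * g_s * py

    joints = [(0, sp.pi), (1, sp.pi), (3, 0), (4, 0)]
    U = 0
    R = 0
    for j, off in joints:
        phi = th[j] - th[2] - off
        U += sp.Rational(1, 2) * k_s * phi**2
        R += sp.Rational(1, 2) * b_s * (om[j] - om[2]) ** 2

    L = T - V - U
    dLdqd = [sp.diff(L, v) for v in qd]
    M_sym = sp.Matrix([[sp.diff(e, v) for v in qd] for e in dLdqd])
    # d/dt(dL/dqd) = M qdd + (d dL/dqd / dq) qd
    conv = sp.Matrix(
        [sum(sp.diff(dLdqd[i], q[j]) * qd[j] for j in range(7)) for i in range(7)]
    )
    rhs = sp.Matrix([sp.diff(L, q[i]) - sp.diff(R, qd[i]) for i in range(7)]) - conv
    fM = sp.lambdify(q + qd + (k_s, b_s, g_s), M_sym, "numpy")
    frhs = sp.lambdify(q + qd + (k_s, b_s, g_s), rhs, "numpy")

    def oracle(state, params, g=G):
        from entrystate.body_model import wrap_angle

        yv = state.as_array()
        # the symbolic joint potential uses the raw angle difference; move
        # each distal angle onto the branch nearest full extension (legs
        # near theta_trunk + pi, arms/head near theta_trunk) -- a 2*pi
        # shift changes nothing else
        t2 = yv[4]
        for idx, off in ((2, math.pi), (3, math.pi), (5, 0.0), (6, 0.0)):
            yv[idx] = t2 + off + wrap_angle(yv[idx] - t2 - off)
        args = tuple(yv[:7]) + tuple(yv[7:]) + (params.stiffness, params.damping, g)
        M = np.asarray(fM(*args), dtype=float)
        r = np.asarray(frhs(*args), dtype=float).ravel()
        return np.linalg.solve(M, r)

    return oracle


def test_accelerations_match_symbolic_lagrangian(profile, lagrangian_oracle, rng):
    """Random states: the hand-assembled Newton-Euler accelerations agree
    with the independent sympy Lagrangian derivation to 1e-8."""
    params = JointParams(stiffness=850.0, damping=60.0, resting_angle=0.0)
    for _ in range(8):
        trunk = rng.uniform(-1.2, 0.5)
        angles = (
            trunk + math.pi + rng.uniform(-0.4, 0.4),
            trunk + math.pi + rng.uniform(-0.4, 0.4),
            trunk,
            trunk + rng.uniform(-0.4, 0.4),
            trunk + rng.uniform(-0.4, 0.4),
        )
        # keep raw (unwrapped) angles so the symbolic phi matches branches
        y = np.concatenate([
            rng.uniform(-1, 3, 2), angles,
            rng.uniform(-5, 5, 2), rng.uniform(-4, 4, 5),
        ])
        st = ChainState(
            ChainConfiguration((y[0], y[1]), tuple(np.asarray(angles))),
            (y[7], y[8]), tuple(y[9:14]),
        )
        got = chain_accelerations(st, profile, params)
        want = lagrangian_oracle(st, params)
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-8)


# ---------------------------------------------------------------------------
# simulate_immersion
# ---------------------------------------------------------------------------

def test_com_path_is_projectile(profile, typical_entry):
    """Internal joint moments cannot move the COM: the simulated COM path
    equals the closed-form projectile to 1e-6 m."""
    traj = simulate_immersion(typical_entry, profile,
                              settings=SimulationSettings(dt=1e-4, max_time=0.5))
    com0, vcom0 = whole_body_com(profile, typical_entry)
    t = traj.times[:, None]
    expected = com0[None, :] + np.asarray(vcom0)[None, :] * t \
        + 0.5 * np.array([0.0, -G])[None, :] * t**2
    assert np.max(np.abs(traj.com_path - expected)) < 1e-6


def test_angular_momentum_conserved(profile, typical_entry):
    bent = bend(typical_entry, darm=0.35, dhead=-0.2, warm=1.0, profile=profile)
    traj = simulate_immersion(bent, profile)
    L0 = angular_momentum_about_com(profile, bent)
    drift = [
        abs(angular_momentum_about_com(profile, ChainState.from_array(s)) - L0)
        for s in traj.states[:: max(len(traj.states) // 20, 1)]
    ]
    assert max(drift) / abs(L0) < 1e-6


def test_rigid_rotation_is_invariant_manifold(profile):
    """Aligned start with common angular velocity and zero resting angle:
    relative joint angles remain zero and the body angle advances by
    omega * t."""
    w = -1.8
    st = aligned_entry_state(profile, -0.45, (3.0, 0.0), (4.2, -3.0), w)
    traj = simulate_immersion(st, profile)
    final = ChainState.from_array(traj.states[-1])
    phi, _ = relative_joint_angles(final)
    np.testing.assert_allclose(phi, 0.0, atol=1e-9)
    t_end = traj.times[-1]
    expected = -0.45 + w * t_end
    assert final.configuration.segment_angles[2] == pytest.approx(expected, abs=1e-8)


def test_energy_monotone_with_damping(profile, typical_entry):
    bent = bend(typical_entry, darm=0.4, warm=2.0, profile=profile)
    params = JointParams(stiffness=800.0, damping=80.0)
    traj = simulate_immersion(bent, profile, params)
    E = [mechanical_energy(profile, ChainState.from_array(s), params)
         for s in traj.states[::50]]
    diffs = np.diff(E)
    assert np.all(diffs <= 1e-9)


def test_energy_conserved_without_damping(profile, typical_entry):
    bent = bend(typical_entry, darm=0.3, warm=1.0, profile=profile)
    params = JointParams(stiffness=800.0, damping=0.0)
    traj = simulate_immersion(bent, profile, params,
                              SimulationSettings(dt=1e-4, max_time=0.3))
    E = [mechanical_energy(profile, ChainState.from_array(s), params)
         for s in traj.states[::100]]
    assert (max(E) - min(E)) / abs(E[0]) < 1e-6


def test_step_halving_convergence(profile, typical_entry):
    """Event times from RK4 converge as dt shrinks: halving dt changes the
    COM-crossing time by far less than the coarse-step error scale."""
    bent = bend(typical_entry, darm=0.25, warm=0.8, profile=profile)
    t_coarse = simulate_immersion(
        bent, profile, settings=SimulationSettings(dt=4e-4)).t_com_cross
    t_mid = simulate_immersion(
        bent, profile, settings=SimulationSettings(dt=2e-4)).t_com_cross
    t_fine = simulate_immersion(
        bent, profile, settings=SimulationSettings(dt=1e-4)).t_com_cross
    assert abs(t_mid - t_fine) <= abs(t_coarse - t_mid) + 1e-9
    assert abs(t_coarse - t_fine) < 1e-5


class TestEvents:
    def test_com_at_cross_is_on_waterline(self, profile, typical_entry):
        traj = simulate_immersion(typical_entry, profile)
        st = state_at_event(traj, "com_cross")
        com, _ = whole_body_com(profile, st)
        assert abs(com[1]) < 1e-9

    def test_cross_time_matches_projectile_closed_form(self, profile, typical_entry):
        traj = simulate_immersion(typical_entry, profile)
        com0, vcom0 = whole_body_com(profile, typical_entry)
        y0, vy = com0[1], vcom0[1]
        t_closed = (vy + math.sqrt(vy * vy + 2 * G * y0)) / G
        assert traj.t_com_cross == pytest.approx(t_closed, abs=1e-7)

    def test_full_immersion_after_com_cross(self, profile, rng):
        for _ in range(10):
            st = bend(
                aligned_entry_state(
                    profile,
                    rng.uniform(-0.6, -0.25),
                    (rng.uniform(2.6, 3.4), 0.0),
                    (rng.uniform(3.8, 4.8), rng.uniform(-3.6, -2.6)),
                    rng.uniform(-2.5, -0.5),
                ),
                darm=rng.uniform(-0.2, 0.2),
                dhead=rng.uniform(-0.2, 0.2),
                profile=profile,
            )
            traj = simulate_immersion(st, profile)
            assert traj.completed
            assert 0.0 <= traj.t_com_cross <= traj.t_full_immersion

    def test_absent_event_raises(self, profile, typical_entry):
        traj = simulate_immersion(
            typical_entry, profile, settings=SimulationSettings(dt=1e-4, max_time=0.05)
        )
        assert not traj.completed
        with pytest.raises(ValueError, match="full_immersion"):
            state_at_event(traj, "full_immersion")

    def test_entry_preconditions_enforced(self, profile):
        airborne = aligned_entry_state(profile, -0.4, (3.0, 0.5), (4.0, -3.0), 0.0)
        with pytest.raises(ValueError, match="fingertip"):
            simulate_immersion(airborne, profile)


class TestEntryHole:
    def test_vertical_streamlined_entry_leaves_no_hole(self, profile):
        """Body axis, velocity and rotation all vertical: every body line
        crosses the waterline at the same x, so the hole vanishes."""
        st = aligned_entry_state(profile, -math.pi / 2, (2.0, 0.0), (1e-6, -5.0), 0.0)
        traj = simulate_immersion(st, profile)
        assert entry_hole_diameter(traj) < 1e-6

    def test_bent_entry_makes_larger_hole(self, profile, typical_entry):
        base = simulate_immersion(typical_entry, profile)
        bent = bend(typical_entry, darm=0.35, profile=profile)  # arms 20 deg off the trunk line
        bent_traj = simulate_immersion(bent, profile)
        assert entry_hole_diameter(bent_traj) > entry_hole_diameter(base)

    def test_hole_translation_invariant(self, profile, typical_entry):
        y = typical_entry.as_array()
        y[0] += 1.5
        shifted = ChainState.from_array(y)
        t0 = simulate_immersion(typical_entry, profile)
        t1 = simulate_immersion(shifted, profile)
        assert entry_hole_diameter(t1) == pytest.approx(
            entry_hole_diameter(t0), abs=1e-9
        )

    def test_incomplete_trajectory_rejected(self, profile, typical_entry):
        traj = simulate_immersion(
            typical_entry, profile, settings=SimulationSettings(dt=1e-4, max_time=0.05)
        )
        with pytest.raises(ValueError, match="full immersion"):
            entry_hole_diameter(traj)


class TestTuneJointParameters:
    def test_defaults_are_selected_study_values(self):
        p = JointParams()
        assert p.stiffness == 1000.0
        assert p.damping == 150.0
        assert p.resting_angle == 0.0

    def test_single_grid_point_returned(self, profile, typical_entry):
        grid = {"stiffness": [900.0], "resting_angle": [0.0], "damping": [50.0]}
        best, table = tune_joint_parameters(
            [typical_entry], grid, profile, SimulationSettings(dt=5e-4)
        )
        assert best == JointParams(stiffness=900.0, damping=50.0, resting_angle=0.0)
        assert len(table) == 1

    def test_argmin_matches_bruteforce_rescoring(self, profile, typical_entry):
        entries = [typical_entry, bend(typical_entry, darm=0.2, warm=0.5, profile=profile)]
        grid = {"stiffness": [700.0, 1000.0], "resting_angle": [0.0],
                "damping": [20.0, 150.0]}
        settings = SimulationSettings(dt=5e-4)
        best, table = tune_joint_parameters(entries, grid, profile, settings)

        # independent exhaustive re-scoring
        scores = {}
        for k in grid["stiffness"]:
            for b in grid["damping"]:
                holes = []
                for st in entries:
                    tr = simulate_immersion(
                        st, profile, JointParams(stiffness=k, damping=b), settings
                    )
                    holes.append(entry_hole_diameter(tr))
                scores[(k, b)] = np.mean(holes)
        want = min(scores, key=lambda kb: (scores[kb], -kb[0], -kb[1]))
        assert (best.stiffness, best.damping) == want
        got_scores = {(r["stiffness"], r["damping"]): r["mean_hole"] for r in table}
        for kb, s in scores.items():
            assert got_scores[kb] == pytest.approx(s, rel=1e-12)

    def test_empty_entries_rejected(self, profile):
        with pytest.raises(ValueError, match="non-empty"):
            tune_joint_parameters([], None, profile)
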