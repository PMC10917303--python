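"""Skeleton dynamics: closed forms, a symbolic oracle, conservation,
contact, passive torques and the differentiability audit."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from morphsim import Morphology
from morphsim.dynamics import (
    contact_forces,
    dynamics_components,
    forward_dynamics_residual,
    mtp_passive_torque,
    passive_joint_torques,
    torque_actuator_dynamics,
    torque_actuator_torque,
)
from morphsim.kinematics import PlanarKinematics
from morphsim.model import apply_segment_scaling


@pytest.fixture(scope="module")
def pend_setup(pendulum):
    kin = PlanarKinematics(pendulum)
    scaled = apply_segment_scaling(pendulum, Morphology.generic(pendulum))
    return kin, scaled


class TestClosedForms:
    def test_pendulum_mass_matrix(self, pend_setup):
        kin, scaled = pend_setup
        M, G, C = dynamics_components(kin, np.zeros(4), np.zeros(4), scaled)
        assert M[3, 3] == pytest.approx(2.0 * 0.5**2, rel=1e-12)

    def test_pendulum_gravity_at_horizontal(self, pend_setup):
        kin, scaled = pend_setup
        q = np.array([0, 0, 0, np.pi / 2])
        _, G, _ = dynamics_components(kin, q, np.zeros(4), scaled)
        assert abs(G[3]) == pytest.approx(2.0 * 9.81 * 0.5, rel=1e-12)

    def test_mass_matrix_symmetric_positive_definite(self, desk_model, desk_kin, generic):
        scaled = apply_segment_scaling(desk_model, generic)
        rng = np.random.default_rng(0)
        q = np.concatenate([[0, 1.0, 0.1], rng.uniform(-0.5, 0.5, 6)])
        M, _, _ = dynamics_components(desk_kin, q, np.zeros(9), scaled)
        np.testing.assert_allclose(M, M.T, atol=1e-9)
        assert np.all(np.linalg.eigvalsh(M) > 0)


class TestSymbolicOracle:
    def test_desk_mass_matrix_vs_lagrangian(self, desk_model, desk_kin, generic):
        """Mass matrix against an independently hand-derived symbolic
        Lagrangian of the known desk topology, at random poses."""
        scaled = apply_segment_scaling(desk_model, generic)
        x, y, th = sp.symbols("x y th")
        qs = {c: sp.Symbol(c) for c in desk_model.coordinates[3:]}
        t = sp.Symbol("t")
        # time-dependent coordinates for velocities
        fs = {n: sp.Function(n)(t) for n in ["x", "y", "th", *qs]}
        L_T, L_S = 0.44, 0.43
        ke = 0
        segs = {s.name: s for s in desk_model.segments}

        def body_ke(pos, ang, m, i_zz):
            vx, vy = sp.diff(pos[0], t), sp.diff(pos[1], t)
            w = sp.diff(ang, t)
            return m / 2 * (vx**2 + vy**2) + i_zz / 2 * w**2

        torso = segs["torso"]
        pos_t = (fs["x"] + torso.com[0] * sp.cos(fs["th"]) - torso.com[1] * sp.sin(fs["th"]),
                 fs["y"] + torso.com[0] * sp.sin(fs["th"]) + torso.com[1] * sp.cos(fs["th"]))
        ke += body_ke(pos_t, fs["th"], torso.mass, torso.inertia[2])
        for side in ("r", "l"):
            a_th = fs["th"] + fs[f"hip_{side}_q"]
            a_sh = a_th + fs[f"knee_{side}_q"]
            a_ft = a_sh + fs[f"ankle_{side}_q"]
            hip = (fs["x"], fs["y"])
            knee = (hip[0] + L_T * sp.sin(a_th), hip[1] - L_T * sp.cos(a_th))
            ankle = (knee[0] + L_S * sp.sin(a_sh), knee[1] - L_S * sp.cos(a_sh))
            for name, org, ang in ((f"thigh_{side}", hip, a_th),
                                   (f"shank_{side}", knee, a_sh),
                                   (f"foot_{side}", ankle, a_ft)):
                s = segs[name]
                cx, cy = s.com
                pos = (org[0] + cx * sp.cos(ang) - cy * sp.sin(ang),
                       org[1] + cx * sp.sin(ang) + cy * sp.cos(ang))
                ke += body_ke(pos, ang, s.mass, s.inertia[2])
        names = ["x", "y", "th"] + list(qs)
        vels = [sp.Symbol(f"d{n}") for n in names]
        subs = {}
        for n, v in zip(names, vels):
            subs[sp.diff(fs[n], t)] = v
            subs[fs[n]] = sp.Symbol(n)
        ke = ke.subs(subs)
        M_sym = sp.Matrix([[sp.diff(ke, vi, vj) for vj in vels] for vi in vels])
        M_fun = sp.lambdify([sp.Symbol(n) for n in names], M_sym, "numpy")

        rng = np.random.default_rng(1)
        for _ in range(5):
            q = np.concatenate([[0.3, 1.0, 0.2], rng.uniform(-0.6, 0.6, 6)])
            M_num, _, _ = dynamics_components(desk_kin, q, np.zeros(9), scaled)
            np.testing.assert_allclose(M_num, np.array(M_fun(*q), dtype=float),
                                       rtol=1e-9, atol=1e-10)


class TestConservation:
    def test_ballistic_energy_conserved(self, desk_model, desk_kin, generic):
        """No muscles, contact or passive torques: total mechanical
        energy constant to relative 1e-6 over 1 s."""
        scaled = apply_segment_scaling(desk_model, generic)
        rng = np.random.default_rng(1)
        q0 = np.concatenate([[0, 2.0, 0.1], rng.uniform(-0.3, 0.3, 6)])
        qd0 = rng.uniform(-1, 1, 9)

        def ode(t, yv):
            q, qd = yv[:9], yv[9:]
            M, G, C = dynamics_components(desk_kin, q, qd, scaled)
            return np.concatenate([qd, np.linalg.solve(M, G + C)])

        def energy(yv):
            q, qd = yv[:9], yv[9:]
            M, _, _ = dynamics_components(desk_kin, q, qd, scaled)
            fr = desk_kin.frames(q, scaled)
            pe = sum(scaled.seg_mass[i] * 9.81 *
                     desk_kin.point_world(fr, i, scaled.seg_com[i])[1]
                     for i in range(7))
            return 0.5 * qd @ M @ qd + pe

        sol = solve_ivp(ode, (0, 1.0), np.concatenate([q0, qd0]),
                        rtol=1e-10, atol=1e-12)
        e0, e1 = energy(sol.y[:, 0]), energy(sol.y[:, -1])
        assert abs(e1 - e0) / abs(e0) < 1e-6

    def test_static_balance_zero_residual(self, desk_model, desk_kin, generic):
        """A pose held by exactly the gravity load has zero residual."""
        scaled = apply_segment_scaling(desk_model, generic)
        q = np.concatenate([[0, 2.0, 0.0], [0.4, -0.6, 0.2, -0.1, -0.3, 0.5]])
        _, G, _ = dynamics_components(desk_kin, q, np.zeros(9), scaled)
        r = forward_dynamics_residual(desk_kin, q, np.zeros(9), np.zeros(9), -G,
                                      scaled, include_contact=False,
                                      include_passive=False)
        np.testing.assert_allclose(r, 0.0, atol=1e-9)


class TestContact:
    def test_no_force_above_ground(self, desk_model, desk_kin, generic):
        scaled = apply_segment_scaling(desk_model, generic)
        q = np.zeros(9)
        q[1] = 1.10  # feet well above ground
        f = contact_forces(desk_kin, q, np.zeros(9), scaled)
        assert np.max(np.abs(f)) < 1e-4

    def test_static_normal_force_closed_form(self, desk_model, desk_kin, generic):
        """Penetration delta at rest: F_n = k delta^1.5 (up to smoothing)."""
        scaled = apply_segment_scaling(desk_model, generic)
        cs = desk_model.contact_spheres[0]
        q = np.zeros(9)
        fr = desk_kin.frames(q, scaled)
        si = desk_model._seg_index[cs.segment]
        p = desk_kin.point_world(fr, si, np.array(cs.location))
        delta = 0.03  # well above the smoothing band
        q[1] = -(p[1] - cs.radius) - delta  # root drop to penetrate by delta
        f, per = contact_forces(desk_kin, q, np.zeros(9), scaled,
                                return_sphere_forces=True)
        name, pw, force = per[0]
        assert force[1] == pytest.approx(cs.stiffness * delta**cs.exponent, rel=0.02)

    def test_friction_opposes_slip(self, desk_model, desk_kin, generic):
        scaled = apply_segment_scaling(desk_model, generic)
        q = np.zeros(9)
        q[1] = 0.99  # slight penetration at the feet
        qd = np.zeros(9)
        qd[0] = 1.0  # sliding forward
        _, per = contact_forces(desk_kin, q, qd, scaled, return_sphere_forces=True)
        for name, pw, force in per:
            if force[1] > 1.0:
                assert force[0] < 0.0

    def test_contact_smooth_through_touchdown(self, desk_model, desk_kin, generic):
        """d f_c / d y is continuous across the touchdown band."""
        scaled = apply_segment_scaling(desk_model, generic)
        ys = np.linspace(1.0, 1.02, 2001)
        d = np.empty_like(ys)
        for k, y in enumerate(ys):
            q = np.zeros(9, dtype=complex)
            q[1] = y + 1e-30j
            f = contact_forces(desk_kin, q, np.zeros(9), scaled)
            d[k] = f[1].imag / 1e-30
        assert np.all(np.isfinite(d))
        assert np.max(np.abs(np.diff(d))) < 0.05 * (1 + np.max(np.abs(d)))


class TestPassiveAndActuators:
    def test_neutral_zone_negligible(self, desk_model):
        q = np.zeros(9)
        q[desk_model.coord_index("hip_r_q")] = 0.6  # mid-range
        tau = passive_joint_torques(desk_model, q, np.zeros(9))
        assert abs(tau[desk_model.coord_index("hip_r_q")]) < 0.05

    def test_damping_magnitude(self, desk_model):
        qd = np.zeros(9)
        j = desk_model.coord_index("hip_r_q")
        qd[j] = 1.0
        tau = passive_joint_torques(desk_model, np.zeros(9), qd)
        tau0 = passive_joint_torques(desk_model, np.zeros(9), np.zeros(9))
        assert abs(tau[j] - tau0[j]) == pytest.approx(0.1, rel=1e-9)

    def test_limit_torque_restores(self, desk_model):
        j = desk_model.coord_index("hip_r_q")
        theta_u = desk_model.joints[1].passive.theta_u
        q = np.zeros(9)
        q[j] = theta_u + 0.15
        tau = passive_joint_torques(desk_model, q, np.zeros(9))
        assert tau[j] < -1.0  # pushes back toward mid-range

    @pytest.mark.parametrize("mode,expected", [("sprint", 40.0), ("marathon", 25.0)])
    def test_mtp_stiffness(self, mode, expected):
        assert abs(mtp_passive_torque(1.0, 0.0, mode)) == pytest.approx(expected)

    def test_mtp_zero_and_damping(self):
        assert mtp_passive_torque(0.0, 0.0, "sprint") == 0.0
        assert abs(mtp_passive_torque(0.0, 1.0, "marathon")) == pytest.approx(1.9)
        with pytest.raises(ValueError):
            mtp_passive_torque(0.0, 0.0, "jump")

    def test_actuator_dynamics(self):
        assert torque_actuator_dynamics(0.3, 0.3) == 0.0
        assert torque_actuator_dynamics(1.0, 0.0) == pytest.approx(1 / 0.035, rel=1e-12)
        e = np.linspace(-1, 1, 11)
        a = np.linspace(1, -1, 11)
        np.testing.assert_allclose(torque_actuator_dynamics(e, a), (e - a) / 0.035)

    @pytest.mark.parametrize("a,expected", [(1.0, 150.0), (0.0, 0.0), (-1.0, -150.0)])
    def test_actuator_torque(self, a, expected):
        assert torque_actuator_torque(a) == pytest.approx(expected)


class TestDifferentiability:
    def test_gradients_match_finite_differences(self, desk_model, desk_kin, generic):
        """Complex-step gradients of contact, passive and skeleton
        residual match central differences to relative 1e-5."""
        scaled = apply_segment_scaling(desk_model, generic)
        rng = np.random.default_rng(3)

        def skel(q, qd, qdd):
            return forward_dynamics_residual(desk_kin, q, qd, qdd,
                                             np.zeros(9, dtype=q.dtype), scaled)

        for _ in range(10):
            q = np.concatenate([[0, 0.97, 0.05], rng.uniform(-0.4, 0.4, 6)])
            qd = rng.uniform(-3, 3, 9)
            qdd = rng.uniform(-20, 20, 9)
            for j in rng.integers(0, 9, 3):
                e = np.zeros(9)
                e[j] = 1e-30
                cs = skel(q + 1j * e, qd, qdd).imag / 1e-30
                h = 1e-6
                eh = np.zeros(9)
                eh[j] = h
                fd = (skel(q + eh, qd, qdd) - skel(q - eh, qd, qdd)) / (2 * h)
                scale = np.maximum(np.abs(cs), 1.0)
                assert np.max(np.abs(cs - fd) / scale) < 1e-5
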