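"""Hill-type muscle machinery: curves, activation and contraction dynamics."""

import numpy as np
import pytest
from scipy.optimize import brentq, curve_fit
from scipy.integrate import solve_ivp

from morphsim.model import ScaledMuscle
from morphsim import muscle as mus


CURVES = mus.DEFAULT_CURVES


def make_muscle(f_max=1000.0, l_m_opt=0.1, l_t_slack=0.2, alpha=0.1, k_t=35.0):
    return ScaledMuscle("test", f_max / 6e5, f_max, l_m_opt, l_t_slack,
                        f_max / 6e5 * l_m_opt, alpha, k_t)


class TestActivationDynamics:
    def test_equilibrium(self):
        assert mus.activation_dynamics(0.5, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_fast_activation_rate(self):
        """e=1, a=0: rate -> 1/tau_act = 66.7 /s in the sharp-blend limit."""
        sharp = mus.ActivationParams(blend_width=1e-3)
        rate = mus.activation_dynamics(1.0, 0.0, sharp)
        assert rate == pytest.approx(1.0 / 0.015, rel=1e-6)

    def test_deactivation_time_constant_by_fit(self):
        """Decay from a=1 with e=0 recovers tau ~ 60 ms by exponential fit."""
        sharp = mus.ActivationParams(blend_width=5e-3)
        sol = solve_ivp(lambda t, a: mus.activation_dynamics(0.0, a[0], sharp),
                        (0, 0.5), [1.0], rtol=1e-10, atol=1e-12, dense_output=True)
        t = np.linspace(0, 0.5, 400)
        a = sol.sol(t)[0]
        (tau,), _ = curve_fit(lambda t, tau: np.exp(-t / tau), t, a, p0=[0.05])
        assert tau == pytest.approx(0.060, rel=0.02)

    def test_smooth_blend_is_continuous(self):
        """da/de continuous across the blend region (complex-step scan)."""
        e = np.linspace(0.2, 0.8, 4001)
        d = np.imag(mus.activation_dynamics(e + 1e-30j, 0.5)) / 1e-30
        assert np.max(np.abs(np.diff(d))) < 0.5  # no jump on a 1.5e-4 grid


class TestCurves:
    def test_normalizations(self):
        f_act, f_pas, f_v, f_t = mus.hill_curves_eval(CURVES, 1.0, 0.0, 0.0)
        assert f_act == pytest.approx(1.0, abs=5e-3)
        assert f_v == pytest.approx(1.0, abs=5e-3)
        assert abs(f_pas) < 5e-3
        assert abs(f_t) <= 0.02  # documented tendon curve offset at zero strain

    def test_force_velocity_monotone_decreasing_in_shortening(self):
        v = np.linspace(-1.0, 1.0, 201)  # normalized fiber velocity
        fv = CURVES.f_v(v)
        assert np.all(np.diff(fv) > 0)  # increasing in v => decreasing in shortening
        assert fv[0] < 0.1 and fv[-1] > 1.2

    def test_tendon_curve_inversion(self):
        # exact up to the soft floor guarding the inversion (abs ~1e-5)
        for ft in (0.01, 0.3, 1.0, 2.0):
            lt = CURVES.lt_norm_from_force(ft, 35.0)
            assert CURVES.f_tendon(lt, 35.0) == pytest.approx(ft, abs=2e-5)


class TestContractionDynamics:
    def test_isometric_optimum_equilibrium(self):
        """a=1, fiber at optimum, zero velocity: residual vanishes at the
        force found by an independent scalar root solve."""
        p = make_muscle()
        lt = CURVES.lt_norm_from_force(np.cos(p.alpha_m), p.k_t) * p.l_t_slack
        l_mt = lt + p.l_m_opt * np.cos(p.alpha_m)

        def res(ftn):
            return float(mus.contraction_dynamics_residual(
                1.0, ftn, 0.0, l_mt, 0.0, p, normalized=True))

        root = brentq(res, 1e-6, 3.0, xtol=1e-14)
        assert mus.contraction_dynamics_residual(
            1.0, root, 0.0, l_mt, 0.0, p, normalized=True) == pytest.approx(0.0, abs=1e-12)
        # the root is the isometric equilibrium near cos(alpha)
        assert root == pytest.approx(np.cos(p.alpha_m), rel=0.05)

    def test_inconsistent_tendon_force_gives_residual(self):
        p = make_muscle()
        lt = CURVES.lt_norm_from_force(np.cos(p.alpha_m), p.k_t) * p.l_t_slack
        l_mt = lt + p.l_m_opt * np.cos(p.alpha_m)
        r0 = mus.contraction_dynamics_residual(1.0, np.cos(p.alpha_m), 0.0, l_mt, 0.0, p,
                                               normalized=True)
        r1 = mus.contraction_dynamics_residual(1.0, 1.1 * np.cos(p.alpha_m), 0.0, l_mt,
                                               0.0, p, normalized=True)
        assert abs(r1) > abs(r0) + 1e-3

    def test_stiff_tendon_limit_matches_rigid_closed_form(self):
        """k_T large: solved isometric force approaches the rigid-tendon value."""
        p = make_muscle(k_t=400.0)
        l_mt = p.l_t_slack + 0.95 * p.l_m_opt * np.cos(p.alpha_m)
        f = mus.initialize_tendon_forces([p], np.array([1.0]), np.array([l_mt]))[0]
        # rigid tendon: fiber length from geometry at slack tendon
        w = p.l_m_opt * np.sin(p.alpha_m)
        proj = l_mt - p.l_t_slack
        l_m = np.hypot(proj, w)
        ln = l_m / p.l_m_opt
        f_rigid = p.f_max_iso * (CURVES.f_act(ln) + CURVES.f_pas(ln)) * proj / l_m
        assert f == pytest.approx(f_rigid, rel=0.02)

    def test_residual_smooth_in_all_inputs(self):
        """C1 continuity: complex-step derivative scan has no jumps."""
        p = make_muscle()
        l_mt = p.l_t_slack + p.l_m_opt
        fts = np.linspace(0.01, 1.5, 1001)
        d = np.imag(mus.contraction_dynamics_residual(
            0.5, fts + 1e-30j, 0.0, l_mt, 0.0, p, normalized=True)) / 1e-30
        assert np.all(np.isfinite(d))
        assert np.max(np.abs(np.diff(d))) < 0.1

    def test_nonphysical_fiber_state_flagged_not_raised(self):
        p = make_muscle()
        r = mus.contraction_dynamics_residual(0.5, 0.2, 0.0, 0.05, 0.0, p,
                                              normalized=True)
        assert np.isfinite(r) and abs(r) > 0.01


class TestTorquesAndInit:
    def test_single_muscle_torque_arithmetic(self):
        tau = mus.muscle_joint_torques(np.array([1000.0]), np.array([[0.05]]))
        assert tau[0] == pytest.approx(50.0, abs=1e-12)

    def test_zero_force_zero_torque_and_linearity(self):
        rng = np.random.default_rng(0)
        R = rng.normal(size=(6, 4)) * 0.05
        f = rng.uniform(0, 2000, 6)
        assert np.allclose(mus.muscle_joint_torques(np.zeros(6), R), 0.0)
        t1 = mus.muscle_joint_torques(f, R)
        assert np.allclose(mus.muscle_joint_torques(2 * f, R), 2 * t1)

    def test_biarticular_torque_matches_virtual_work(self, desk_model, desk_geo, generic):
        """tau = R f agrees with the tendon-excursion (virtual work)
        computation -dl/dq * f for the biarticular gastrocnemius."""
        mi = desk_model._muscle_index["gastroc_r"]
        q = np.zeros(9)
        q[desk_model.coord_index("knee_r_q")] = -0.4
        lmt, R, _ = desk_geo.eval(q, generic)
        f = 800.0
        forces = np.zeros(18)
        forces[mi] = f
        tau = mus.muscle_joint_torques(forces, R)
        h = 1e-6
        for cname in ("knee_r_q", "ankle_r_q"):
            j = desk_model.coord_index(cname)
            e = np.zeros(9)
            e[j] = h
            lp, _, _ = desk_geo.eval(q + e, generic)
            lm_, _, _ = desk_geo.eval(q - e, generic)
            dl = (lp[mi] - lm_[mi]) / (2 * h)
            assert tau[j] == pytest.approx(-dl * f, abs=1e-4)

    def test_initialize_passive_slack(self):
        p = make_muscle()
        l_mt = p.l_t_slack + 0.7 * p.l_m_opt  # short: passive slack
        f = mus.initialize_tendon_forces([p], np.array([0.0]), np.array([l_mt]))
        assert abs(f[0]) < 0.02 * p.f_max_iso

    def test_initialize_matches_root_oracle_and_deterministic(self):
        p = make_muscle()
        l_mt = p.l_t_slack + 1.02 * p.l_m_opt * np.cos(p.alpha_m)
        f1 = mus.initialize_tendon_forces([p], np.array([1.0]), np.array([l_mt]))
        f2 = mus.initialize_tendon_forces([p], np.array([1.0]), np.array([l_mt]))
        assert f1[0] == f2[0]
        root = brentq(lambda ftn: float(mus.contraction_dynamics_residual(
            1.0, ftn, 0.0, l_mt, 0.0, p, normalized=True)), 1e-8, 3.5, xtol=1e-13)
        assert f1[0] == pytest.approx(root * p.f_max_iso, rel=1e-8)

    def test_solved_force_bounds(self, desk_model, desk_geo, generic):
        """Static forces stay in [0, F_max (1 + f_pas_max)/cos(alpha)]."""
        from morphsim.model import build_scaled_model
        scaled = build_scaled_model(desk_model, generic, desk_geo.lmt_anatomical)
        rng = np.random.default_rng(2)
        rom = desk_model.rom_bounds()
        lb = np.array([rom[c][0] for c in desk_model.coordinates])
        ub = np.array([rom[c][1] for c in desk_model.coordinates])
        for _ in range(5):
            q = rng.uniform(lb, ub)
            a = rng.uniform(0, 1, 18)
            lmt, _, _ = desk_geo.eval(q, generic)
            f = mus.initialize_tendon_forces(scaled.muscles, a, lmt)
            for fi, p in zip(f, scaled.muscles):
                fpm = CURVES.f_pas(2.0)  # generous passive ceiling
                assert -1e-6 <= fi <= p.f_max_iso * (1 + fpm) / np.cos(p.alpha_m) + 1e-6

    def test_pcsa_doubling_doubles_rigid_limit_force(self):
        p1 = make_muscle(f_max=1000.0, k_t=400.0)
        p2 = make_muscle(f_max=2000.0, k_t=400.0)
        l_mt = p1.l_t_slack + p1.l_m_opt * np.cos(p1.alpha_m)
        f1 = mus.initialize_tendon_forces([p1], np.array([1.0]), np.array([l_mt]))[0]
        f2 = mus.initialize_tendon_forces([p2], np.array([1.0]), np.array([l_mt]))[0]
        assert f2 == pytest.approx(2 * f1, rel=1e-3)
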