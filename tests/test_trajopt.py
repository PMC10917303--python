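"""Gait-problem transcription structure: variable counts, symmetry maps,
objectives, morphology constraints and derived metrics."""

import numpy as np
import pytest

from morphsim import Morphology
from morphsim.analysis import morphology_constraint_check, torque_capacity
from morphsim.deskmodel import desk_mirror_maps
from morphsim.gait import GaitProblem, GaitProblemSpec


@pytest.fixture(scope="module")
def marathon_problem(desk_model):
    return GaitProblem(desk_model, GaitProblemSpec(task="marathon", n_mesh=4))


@pytest.fixture(scope="module")
def sprint_pv_problem(desk_model):
    return GaitProblem(desk_model, GaitProblemSpec(task="sprint", free_pv=True, n_mesh=4))


class TestTranscriptionCounts:
    def test_variable_counting_formula(self, marathon_problem):
        pr = marathon_problem
        tr = pr.transcription
        n_mesh, d = pr.spec.n_mesh, pr.spec.degree
        M = n_mesh * d
        # states at t0 and every collocation node, controls per node, h
        expected = pr.nx * (M + 1) + pr.nu * M + 1
        assert tr.nz == expected

    def test_constraint_counting(self, marathon_problem):
        pr = marathon_problem
        tr = pr.transcription
        M = pr.spec.n_mesh * pr.spec.degree
        # collocation + algebraic per node, periodicity minus the free
        # forward position, plus the imposed-speed row
        expected = M * pr.nx + M * (pr.nm + pr.nq) + (pr.nx - 1) + 1
        assert tr.nc == expected

    def test_free_volume_adds_pair_variables_and_budget_row(self, desk_model,
                                                            marathon_problem):
        pr_pv = GaitProblem(desk_model, GaitProblemSpec(task="marathon",
                                                        free_pv=True, n_mesh=4))
        base = marathon_problem.transcription
        tr = pr_pv.transcription
        assert pr_pv.n_pv == desk_model.n_muscles // 2  # left-right tied pairs
        assert tr.nz == base.nz + pr_pv.n_pv
        assert tr.nc == base.nc + 1  # the total-volume budget row
        # the per-muscle +20 % caps are variable bounds
        lb, ub = tr.solver_bounds()
        np.testing.assert_allclose(ub[tr.i_p] * tr.z_scale[tr.i_p], 1.2)
        np.testing.assert_allclose(lb[tr.i_p] * tr.z_scale[tr.i_p], 1.0)

    def test_free_segments_adds_scale_variables_and_bmi_row(self, desk_model,
                                                            marathon_problem):
        pr_ps = GaitProblem(desk_model, GaitProblemSpec(task="marathon",
                                                        free_ps=True, n_mesh=4))
        base = marathon_problem.transcription
        assert pr_ps.n_ps == 3 * len(desk_model.scaling_groups())
        assert pr_ps.transcription.nz == base.nz + pr_ps.n_ps
        assert pr_ps.transcription.nc == base.nc + 1  # BMI window row


class TestSymmetry:
    def test_mirror_involution(self, marathon_problem):
        pr = marathon_problem
        rng = np.random.default_rng(0)
        x = rng.normal(size=pr.nx)
        np.testing.assert_allclose(pr.mirror_state(pr.mirror_state(x)), x, atol=1e-14)

    def test_symmetric_state_zero_residual(self, marathon_problem, desk_model):
        pr = marathon_problem
        mperm, cperm, csign = desk_mirror_maps(desk_model)
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 18)
        a = 0.5 * (a + a[mperm])  # symmetric activations
        ftn = np.full(18, 0.4)
        q = np.zeros(9)
        qd = np.zeros(9)
        x = np.concatenate([a, ftn, q, qd])
        res = pr.boundary(x, x, 0.03, np.zeros(0))
        # the periodicity rows vanish (speed row excluded)
        assert np.max(np.abs(res[:-1])) < 1e-14

    def test_left_right_index_map(self, desk_model):
        mperm, cperm, csign = desk_mirror_maps(desk_model)
        i_hip_l = desk_model.coord_index("hip_l_q")
        i_hip_r = desk_model.coord_index("hip_r_q")
        assert cperm[i_hip_l] == i_hip_r and cperm[i_hip_r] == i_hip_l
        assert cperm[desk_model.coord_index("root_x")] == desk_model.coord_index("root_x")
        names = [m.name for m in desk_model.muscles]
        assert names[mperm[names.index("soleus_r")]] == "soleus_l"
        np.testing.assert_array_equal(mperm[mperm], np.arange(18))


class TestObjectives:
    def test_marathon_normalized_by_distance(self, marathon_problem):
        pr = marathon_problem
        x0 = np.zeros(pr.nx)
        xend = np.zeros(pr.nx)
        xend[pr.i_q[pr.iq_x]] = 1.0
        j1 = pr.mayer(x0, xend, 0.03, np.zeros(0), integral=2.0)
        xend2 = xend.copy()
        xend2[pr.i_q[pr.iq_x]] = 2.0
        j2 = pr.mayer(x0, xend2, 0.03, np.zeros(0), integral=2.0)
        assert j2 == pytest.approx(j1 / 2.0, rel=1e-6)

    def test_sprint_objective_structure(self, desk_model):
        pr = GaitProblem(desk_model, GaitProblemSpec(task="sprint", n_mesh=4))
        x0 = np.zeros(pr.nx)
        xend = np.zeros(pr.nx)
        h = 0.05
        # zero average speed: only the 1e-6 marathon contribution remains
        xend[pr.i_q[pr.iq_x]] = 0.0
        j0 = pr.mayer(x0, xend, h, np.zeros(0), integral=1.0)
        assert j0 == pytest.approx(1e-6 * 1.0 / 0.2, rel=0.2)  # soft-floored distance
        # larger speed at fixed energy strictly decreases the objective
        prev = j0
        for disp in (0.4, 0.8, 1.6):
            xend[pr.i_q[pr.iq_x]] = disp
            j = pr.mayer(x0, xend, h, np.zeros(0), integral=1.0)
            assert j < prev
            prev = j
        # and matches -v^2 kinematics
        v = 1.6 / (4 * h)
        assert prev == pytest.approx(-(v**2) + 1e-6 * 1.0 / 1.6, rel=1e-6)

    def test_objective_terms_match_independent_quadrature(self, marathon_problem):
        """The transcription objective equals a trapezoid-free Radau
        quadrature of the integrand computed directly."""
        pr = marathon_problem
        tr = pr.transcription
        z = pr.initial_guess()
        x, u, p, h = tr._node_args(z)
        _, _, L = pr.node_eval(x, u, p)
        integral = h * np.sum(tr.wq * L)
        x0 = z[tr.i_x0]
        disp = x[-1, pr.i_q[pr.iq_x]] - x0[pr.i_q[pr.iq_x]]
        # the distance normalization carries a soft floor inert at
        # realistic strides up to ~1e-6 relative
        assert tr.objective(z) == pytest.approx(integral / disp, rel=1e-5)


class TestMorphologyConstraints:
    def test_individual_cap_violation(self, desk_model, generic):
        m = generic.copy()
        m.p_v[2] = 1.25
        v = morphology_constraint_check(desk_model, m)
        assert any("p_v" in name for name, *_ in v)

    def test_total_budget_violation(self, desk_model, generic):
        m = generic.copy()
        m.p_v[:] = 1.06
        v = morphology_constraint_check(desk_model, m)
        assert any("total volume" in name for name, *_ in v)

    def test_generic_clean(self, desk_model, generic):
        assert morphology_constraint_check(desk_model, generic) == []

    def test_budget_row_in_transcription(self, sprint_pv_problem):
        pr = sprint_pv_problem
        p = np.full(pr.n_pv, 1.05)
        rel = pr.par_ineq(p)
        assert rel[0] == pytest.approx(0.05, rel=1e-9)
        lb, ub = pr.par_ineq_bounds()
        assert ub[0] == pytest.approx(0.05)


class TestDerivedMetrics:
    def test_speed_displacement_identity(self, marathon_problem):
        from morphsim.gait import GaitSolution
        from morphsim.ocp import SolveResult
        pr = marathon_problem
        tr = pr.transcription
        z = pr.initial_guess()
        x0, xn, un, h, p = tr.unpack(z)
        sol = GaitSolution(pr, SolveResult(
            success=True, status="test", objective=0.0, constr_violation=0.0,
            n_iter=0, x0=x0, x_nodes=xn, u_nodes=un, h=h, p=p, z=z))
        assert sol.average_speed * sol.duration == pytest.approx(sol.displacement, rel=1e-12)
        # printed-value consistency: frequency = speed / step length
        assert sol.step_frequency == pytest.approx(sol.average_speed / sol.step_length,
                                                   rel=1e-12)

    def test_sprint_stride_arithmetic(self):
        # speed 8.13 m/s at 1.93 m steps implies ~4.2 steps per second
        assert 8.13 / 1.93 == pytest.approx(4.2, abs=0.02)

    def test_torque_capacity_linear_in_strength(self, desk_model, generic):
        caps = torque_capacity(desk_model, generic, coordinates=["ankle_r_q"], n_grid=3)
        doubled = generic.copy()
        doubled.p_v[:] = 2.0  # doubles every muscle volume, hence F_max_iso
        caps2 = torque_capacity(desk_model, doubled, coordinates=["ankle_r_q"], n_grid=3)
        for sign in ("+", "-"):
            assert caps2["ankle_r_q"][sign] == pytest.approx(
                2 * caps["ankle_r_q"][sign], rel=1e-6)

    def test_capacity_normalized_to_generic_is_unity(self, desk_model, generic):
        caps = torque_capacity(desk_model, generic, coordinates=["knee_r_q"], n_grid=3)
        norm = {s: caps["knee_r_q"][s] / caps["knee_r_q"][s] for s in ("+", "-")}
        assert norm == {"+": 1.0, "-": 1.0}


class TestExperimentMatrix:
    def test_matrix_wiring_with_stub_solver(self, desk_model):
        """Ten records; cross-evaluation sims consume the right morphology."""
        from morphsim.experiments import run_experiment_matrix
        from morphsim.gait import GaitSolution
        from morphsim.ocp import SolveResult

        calls = []

        def stub(problem, warm):
            tr = problem.transcription
            z = problem.initial_guess()
            x0, xn, un, h, p = tr.unpack(z)
            if problem.spec.free_pv:
                p = np.full(problem.n_pv, 1.01)
                z = tr.pack(x0, xn, un, h, p)
                x0, xn, un, h, p = tr.unpack(z)
            calls.append((problem.spec.task, problem.spec.free_ps,
                          problem.spec.free_pv,
                          problem.spec.fixed_morphology))
            return GaitSolution(problem, SolveResult(
                success=True, status="stub", objective=0.0, constr_violation=0.0,
                n_iter=0, x0=x0, x_nodes=xn, u_nodes=un, h=h, p=p, z=z))

        records, sols = run_experiment_matrix(
            desk_model, seed=1, spec_kw={"n_mesh": 4}, solver=stub)
        assert len(records) == 10
        assert all(r.error is None for r in records)
        # sims 5 and 6 consume sims 3 and 4's morphologies
        assert calls[4][3] is not None and calls[5][3] is not None
        # sims 9/10 consume trained volumes from sims 7/8
        assert np.allclose(calls[8][3].p_v, 1.01)
        assert np.allclose(calls[9][3].p_v, 1.01)
        # determinism of the record table under the same seed
        records2, _ = run_experiment_matrix(
            desk_model, seed=1, spec_kw={"n_mesh": 4}, solver=stub)
        assert [r.speed for r in records2] == [r.speed for r in records]
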