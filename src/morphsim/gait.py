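"""Predictive gait problems: sprint and marathon, with optional free
morphology (segment dimensions and/or muscle volumes).

A half gait cycle is transcribed with third-order Radau collocation and
implicit muscle/skeleton dynamics: tendon-force derivatives and
coordinate accelerations are controls, and the Hill contraction
equations and skeleton equations of motion enter as algebraic
constraints at every collocation node.  Left-right symmetry turns the
half cycle into a periodic gait: the mirrored end state must equal the
initial state, with the root forward position excluded (progression)
and either constrained to an imposed average speed (marathon) or
rewarded in the objective (sprint).

The marathon objective is the weighted sum of squared muscle metabolic
power, squared muscle activations (fatigue), squared coordinate
accelerations (smoothness), squared joint-limit torques (ligament
strain) and squared torque-actuator activations, integrated over the
half cycle and normalized by the distance travelled.  The sprint
objective is -v_avg^2 plus a 1e-6 contribution of the marathon
objective for numerical conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from . import muscle as mus
from .collocation import build_collocation_grid
from .dynamics import contact_forces, passive_joint_torques
from .geometry_fast import FastGeometry
from .kinematics import PlanarKinematics
from .metabolics import DEFAULT_METABOLIC, J_PER_KCAL, MARATHON_DISTANCE_M, MUSCLE_DENSITY
from .model import Morphology, MusculoskeletalModel
from .ocp import OCP, SolveResult, Transcription
from .smooth import safe_exp, soft_floor

__all__ = ["ObjectiveWeights", "GaitProblemSpec", "GaitProblem", "GaitSolution"]


@dataclass
class ObjectiveWeights:
    metabolic: float = 1e-4  # on squared per-muscle metabolic power (W^2)
    activation: float = 2.0
    acceleration: float = 1e-5  # on squared coordinate accelerations
    limit_torque: float = 1e-3
    actuator: float = 1.0


@dataclass
class GaitProblemSpec:
    """One predictive simulation: task, morphology freedom, bounds, solver."""

    task: str = "marathon"  # "sprint" | "marathon"
    free_ps: bool = False
    free_pv: bool = False
    imposed_speed: float = 3.33  # m/s, marathon only
    n_mesh: int = 25
    degree: int = 3
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    ps_bounds: tuple = (0.8, 1.2)
    bmi_bounds: tuple = (17.5, 25.5)
    pv_individual_max: float = 1.2  # +20 % per muscle
    pv_total_increase: float = 0.05  # +5 % summed over all muscles
    fixed_morphology: Morphology | None = None  # evaluate a given morphology
    seed: int = 0
    maxiter: int = 1500
    stage_iters: int = 40  # LM iterations per homotopy stage
    retire_rounds: int = 8  # adaptive crutch-retirement attempts
    duration_bounds: tuple = (0.15, 0.5)  # s, half gait cycle
    guess_speed: float | None = None
    guess_step_frequency: float | None = None

    def __post_init__(self):
        if self.task not in ("sprint", "marathon"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.free_ps and self.free_pv:
            raise ValueError("free_ps and free_pv are mutually exclusive here")


class GaitProblem:
    def __init__(self, model: MusculoskeletalModel, spec: GaitProblemSpec,
                 mirror_maps=None):
        self.model = model
        self.spec = spec
        self.kin = PlanarKinematics(model)
        self.geo = FastGeometry(model, self.kin)
        self.grid = build_collocation_grid(spec.n_mesh, spec.degree)
        nm, nq, nt = model.n_muscles, model.n_coordinates, model.n_torque_actuators
        self.nm, self.nq, self.nt = nm, nq, nt
        self.nx = 2 * nm + nt + 2 * nq
        # controls: e_m, e_T, dF_t, qddot, plus auxiliary torques on every
        # coordinate used only as a vanishing homotopy crutch (bounds 0 in
        # the physical problem)
        self.nu = 2 * nm + nt + 2 * nq

        if mirror_maps is None:
            from .deskmodel import desk_mirror_maps
            mirror_maps = desk_mirror_maps(model)
        self.mperm, self.cperm, self.csign = mirror_maps

        # --- generic constants ------------------------------------------
        groups = model.scaling_groups()
        self.groups = groups
        self.gidx = {g: i for i, g in enumerate(groups)}
        self.seg_group = np.array([self.gidx[s.scaling_group] for s in model.segments])
        self.seg_mass_gen = np.array([s.mass for s in model.segments])
        self.seg_com_gen = np.array([s.com for s in model.segments])
        self.seg_izz_gen = np.array([s.inertia[2] for s in model.segments])
        self.joint_loc_gen = np.array([j.location_in_parent for j in model.joints])
        self.joint_pgroup = np.array(
            [self.gidx[model.segment(j.parent).scaling_group] if j.parent else 0
             for j in model.joints]
        )
        self.joint_has_parent = np.array([j.parent is not None for j in model.joints])
        self.m_lopt = np.array([m.l_m_opt for m in model.muscles])
        self.m_lts = np.array([m.l_t_slack for m in model.muscles])
        self.m_alpha = np.array([m.alpha_m for m in model.muscles])
        self.m_kt = np.array([m.k_t for m in model.muscles])
        self.m_sigma = np.array([m.sigma for m in model.muscles])
        self.m_vol_gen = np.array([m.volume for m in model.muscles])
        self.m_fmax_gen = np.array([m.f_max_iso for m in model.muscles])
        self.total_mass_gen = self.seg_mass_gen.sum()
        self.stature_seg_idx = np.array([model._seg_index[n] for n in model.stature_segments])
        self.stature_len = np.array([model.segment(n).length_axes[1] for n in model.stature_segments])
        # generic anatomical muscle-tendon lengths
        ones = np.ones((len(groups), 3))
        off0 = self._offsets(ones)
        l0, _, _ = self.geo.eval(np.zeros(nq), ones, off0)
        self.lmt0_gen = l0
        self.act_coord = np.array([model.coord_index(t.coordinate) for t in model.torque_actuators], dtype=int)
        self.act_gain = np.array([t.gain for t in model.torque_actuators])
        self.act_tau = np.array([t.tau for t in model.torque_actuators])
        # torque-actuator mirror: permutation induced by the coordinate mirror
        if nt:
            cm = {c: i for i, c in enumerate(self.act_coord)}
            self.tperm = np.array([cm[self.cperm[c]] for c in self.act_coord])
        else:
            self.tperm = np.zeros(0, dtype=int)

        # morphology parameter layout
        self.n_ps = 3 * len(groups) if spec.free_ps else 0
        if spec.free_pv:
            pair_of = {}
            pairs = []
            for i in range(nm):
                j = self.mperm[i]
                a, b = min(i, j), max(i, j)
                if (a, b) not in pair_of:
                    pair_of[(a, b)] = len(pairs)
                    pairs.append((a, b))
            self.pv_pair_index = np.array([pair_of[(min(i, self.mperm[i]), max(i, self.mperm[i]))]
                                           for i in range(nm)])
            self.n_pv = len(pairs)
        else:
            self.pv_pair_index = None
            self.n_pv = 0
        self.npar = self.n_ps + self.n_pv

        base = spec.fixed_morphology or Morphology.generic(model)
        self.base_sscale = np.stack([np.asarray(base.p_s[g], float) for g in groups])
        self.base_pv = np.asarray(base.p_v, float)

        self.i_q = 2 * nm + nt + np.arange(nq)
        self.i_qd = 2 * nm + nt + nq + np.arange(nq)
        self.iq_x = self.kin.ix  # root forward coordinate index
        # homotopy parameters used during feasibility search
        self.contact_scale = 1.0
        self.contact_smoothing = 5e-3
        self.gravity_scale = 1.0
        self.descent_objective = "task"  # or "aux" during crutch retirement
        self._build_ocp()

    # ------------------------------------------------------------------
    def _offsets(self, sscale):
        off = np.array(self.joint_loc_gen, dtype=sscale.dtype)
        sc = sscale[self.joint_pgroup, :2]
        off = np.where(self.joint_has_parent[:, None], self.joint_loc_gen * sc, self.joint_loc_gen)
        return off

    def morph_arrays(self, p):
        """All morphology-dependent arrays from the parameter vector p.

        Cached on the byte pattern of p: during coordination-only solves
        the morphology is fixed, so the scaling work is done once.
        """
        p = np.asarray(p)
        key = p.tobytes()
        cached = getattr(self, "_morph_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        out = self._morph_arrays_impl(p)
        self._morph_cache = (key, out)
        return out

    def _morph_arrays_impl(self, p):
        dtype = p.dtype if p.size else float
        sscale = self.base_sscale.astype(dtype, copy=True)
        pv = self.base_pv.astype(dtype, copy=True)
        if self.n_ps:
            sscale = p[: self.n_ps].reshape(len(self.groups), 3)
        if self.n_pv:
            pv = p[self.n_ps:][self.pv_pair_index]
        ss = sscale[self.seg_group]
        r_m = ss[:, 0] * ss[:, 1] * ss[:, 2]
        seg_mass = self.seg_mass_gen * r_m
        seg_com = self.seg_com_gen * ss[:, :2]
        seg_izz = self.seg_izz_gen * r_m * (ss[:, 0] ** 2 + ss[:, 1] ** 2) / 2.0
        offsets = self._offsets(sscale)
        mass_ratio = seg_mass.sum() / self.total_mass_gen
        lmt0, _, _ = self.geo.eval(np.zeros(self.nq), sscale, offsets)
        ratio = lmt0 / self.lmt0_gen
        l_opt = self.m_lopt * ratio
        l_ts = self.m_lts * ratio
        vol = self.m_vol_gen * mass_ratio * pv
        pcsa = vol / l_opt
        fmax = pcsa * self.m_sigma
        scaled = SimpleNamespace(
            joint_offsets=offsets,
            seg_mass=seg_mass,
            seg_com=seg_com,
            seg_inertia=seg_izz,
            morphology=SimpleNamespace(p_s={g: sscale[i] for g, i in self.gidx.items()}),
        )
        musc = SimpleNamespace(
            f_max_iso=fmax, l_m_opt=l_opt, l_t_slack=l_ts,
            alpha_m=self.m_alpha, k_t=self.m_kt, volume=vol,
        )
        return sscale, pv, scaled, musc

    def anthropometrics(self, p):
        sscale, _, scaled, _ = self.morph_arrays(p)
        mass = scaled.seg_mass.sum()
        stature = np.sum(self.stature_len * sscale[self.seg_group[self.stature_seg_idx], 1])
        return mass, stature, mass / stature**2

    # ------------------------------------------------------------------
    def split_state(self, x):
        nm, nt, nq = self.nm, self.nt, self.nq
        return (x[..., :nm], x[..., nm:nm + nt], x[..., nm + nt:2 * nm + nt],
                x[..., 2 * nm + nt:2 * nm + nt + nq], x[..., 2 * nm + nt + nq:])

    def split_controls(self, u):
        nm, nt, nq = self.nm, self.nt, self.nq
        return (u[..., :nm], u[..., nm:nm + nt], u[..., nm + nt:2 * nm + nt],
                u[..., 2 * nm + nt:2 * nm + nt + nq], u[..., 2 * nm + nt + nq:])

    def mirror_state(self, x):
        a, aT, ftn, q, qd = self.split_state(x)
        return np.concatenate([
            a[..., self.mperm], aT[..., self.tperm], ftn[..., self.mperm],
            (q[..., self.cperm] * self.csign), (qd[..., self.cperm] * self.csign),
        ], axis=-1)

    # ------------------------------------------------------------------
    def node_eval(self, x, u, p):
        nm, nq, nt = self.nm, self.nq, self.nt
        a, aT, ftn, q, qd = self.split_state(x)
        em, eT, dftn, qdd, aux = self.split_controls(u)
        sscale, pv, scaled, mp = self.morph_arrays(p)

        lmt, R, ldot = self.geo.eval(q, sscale, scaled.joint_offsets, qdot=qd)
        # explicit state derivatives
        adot = mus.activation_dynamics(em, a)
        xdot_parts = [adot]
        if nt:
            xdot_parts.append((eT - aT) / self.act_tau)
        xdot_parts += [dftn, qd, qdd]
        xdot = np.concatenate(xdot_parts, axis=-1)

        # implicit contraction dynamics
        curves = mus.DEFAULT_CURVES
        ln, vn, cos_a, _ = mus.fiber_state_from_tendon(
            ftn, dftn, lmt, ldot, mp.l_m_opt, mp.l_t_slack, mp.alpha_m, mp.k_t, curves)
        f_act = curves.f_act(ln)
        f_v = curves.f_v(vn)
        f_pas = curves.f_pas(ln)
        g_muscle = cos_a * (a * f_act * f_v + f_pas + curves.beta * vn) - ftn

        # implicit skeleton dynamics
        f_t = ftn * mp.f_max_iso
        tau = np.sum(R * f_t[..., :, None], axis=-2)
        tau = tau + passive_joint_torques(self.model, q, qd)
        if nt:
            tau_t = np.zeros(tau.shape, dtype=tau.dtype)
            tau_t[..., self.act_coord] = self.act_gain * aT
            tau = tau + tau_t
        f_c = contact_forces(self.kin, q, qd, scaled,
                             stiffness_scale=self.contact_scale,
                             smoothing=self.contact_smoothing)
        tau_id = self.kin.inverse_dynamics(
            q, qd, qdd, scaled, gravity=self.model.gravity * self.gravity_scale)
        g_skel = tau_id - tau - f_c - aux
        g = np.concatenate([g_muscle, g_skel], axis=-1)

        # objective integrand
        if self.descent_objective == "aux":
            self._last_power = np.zeros(a.shape)
            return xdot, g, np.sum((aux / 10.0) ** 2, axis=-1)
        w = self.spec.weights
        m_mass = mp.volume * MUSCLE_DENSITY
        f_ce = mp.f_max_iso * a * f_act * f_v
        ldot_m = vn * (curves.v_max * mp.l_m_opt)
        from .metabolics import metabolic_power
        power = metabolic_power(a, ln, ldot_m, f_ce, m_mass, fl_factor=f_act)
        tau_lim = self._limit_torques(q)
        L = (
            w.metabolic * np.sum(power**2, axis=-1)
            + w.activation * np.sum(a**2, axis=-1)
            + w.acceleration * np.sum(qdd**2, axis=-1)
            + w.limit_torque * np.sum(tau_lim**2, axis=-1)
        )
        if nt:
            L = L + w.actuator * np.sum(aT**2, axis=-1)
        self._last_power = power
        return xdot, g, L

    def _limit_torques(self, q):
        """Exponential joint-limit torques only (no damping)."""
        out = np.zeros(q.shape, dtype=q.dtype)
        for j in self.model.joints:
            if j.passive is None:
                continue
            pjp = j.passive
            for c in j.coordinates:
                k = self.model.coord_index(c)
                qi = q[..., k]
                out[..., k] = (pjp.k_u1 * safe_exp(pjp.k_u2 * (qi - pjp.theta_u))
                               + pjp.k_l1 * safe_exp(pjp.k_l2 * (pjp.theta_l - qi)))
        return out

    # ------------------------------------------------------------------
    def boundary(self, x0, xend, h, p):
        res = self.mirror_state(xend) - np.asarray(x0, dtype=np.result_type(x0, xend))
        keep = np.ones(self.nx, dtype=bool)
        keep[self.i_q[self.iq_x]] = False  # forward progression is free
        rows = [res[keep]]
        if self.spec.task == "marathon":
            T = self.spec.n_mesh * h
            disp = xend[self.i_q[self.iq_x]] - x0[self.i_q[self.iq_x]]
            rows.append(np.atleast_1d(disp - self.spec.imposed_speed * T))
        return np.concatenate(rows)

    def mayer(self, x0, xend, h, p, integral):
        if self.descent_objective == "aux":
            return integral
        disp = xend[self.i_q[self.iq_x]] - x0[self.i_q[self.iq_x]]
        # soft floor keeps the normalization defined while iterates are
        # far from a locomoting trajectory; inert at realistic strides
        j_marathon = integral / soft_floor(disp, 0.2, eps=1e-3)
        if self.spec.task == "marathon":
            return j_marathon
        T = self.spec.n_mesh * h
        v = disp / T
        return -(v**2) + 1e-6 * j_marathon

    def par_ineq(self, p):
        rows = []
        if self.n_ps:
            mass, stature, bmi = self.anthropometrics(p)
            rows.append(np.atleast_1d(bmi))
        if self.n_pv:
            pv = p[self.n_ps:][self.pv_pair_index]
            rel_inc = np.sum(self.m_vol_gen * (pv - 1.0)) / np.sum(self.m_vol_gen)
            rows.append(np.atleast_1d(rel_inc))
        return np.concatenate(rows)

    def par_ineq_bounds(self):
        lb, ub = [], []
        if self.n_ps:
            lb.append(self.spec.bmi_bounds[0]); ub.append(self.spec.bmi_bounds[1])
        if self.n_pv:
            lb.append(-np.inf); ub.append(self.spec.pv_total_increase)
        return np.array(lb), np.array(ub)

    # ------------------------------------------------------------------
    def _build_ocp(self):
        spec = self.spec
        model = self.model
        nm, nq, nt = self.nm, self.nq, self.nt
        rom = model.rom_bounds()
        q_lb = np.array([rom[c][0] for c in model.coordinates])
        q_ub = np.array([rom[c][1] for c in model.coordinates])
        x_lb = np.concatenate([np.zeros(nm), -np.ones(nt), np.zeros(nm), q_lb, -60 * np.ones(nq)])
        x_ub = np.concatenate([np.ones(nm), np.ones(nt), 3.5 * np.ones(nm), q_ub, 60 * np.ones(nq)])
        u_lb = np.concatenate([np.zeros(nm), -np.ones(nt), -300 * np.ones(nm),
                               -3000 * np.ones(nq), np.zeros(nq)])
        u_ub = np.concatenate([np.ones(nm), np.ones(nt), 300 * np.ones(nm),
                               3000 * np.ones(nq), np.zeros(nq)])
        x0_lb, x0_ub = x_lb.copy(), x_ub.copy()
        x0_lb[self.i_q[self.iq_x]] = 0.0  # pin the starting forward position
        x0_ub[self.i_q[self.iq_x]] = 0.0

        p_lb, p_ub, p_scale = [], [], []
        if self.n_ps:
            p_lb += [spec.ps_bounds[0]] * self.n_ps
            p_ub += [spec.ps_bounds[1]] * self.n_ps
            p_scale += [1.0] * self.n_ps
        if self.n_pv:
            p_lb += [1.0] * self.n_pv
            p_ub += [spec.pv_individual_max] * self.n_pv
            p_scale += [1.0] * self.n_pv

        x_scale = np.concatenate([np.ones(nm), np.ones(nt), np.ones(nm), np.ones(nq), 10 * np.ones(nq)])
        # the small crutch-torque scale makes the minimum-norm
        # feasibility steps reluctant to lean on the crutch
        u_scale = np.concatenate([np.ones(nm), np.ones(nt), 50 * np.ones(nm),
                                  300 * np.ones(nq), 5 * np.ones(nq)])
        g_scale = np.concatenate([np.ones(nm), np.full(nq, 200.0)])
        g_scale[nm + self.iq_x] = 750.0
        g_scale[nm + self.kin.iy] = 750.0

        n_boundary = self.nx - 1 + (1 if spec.task == "marathon" else 0)
        self.ocp = OCP(
            nx=self.nx, nu=self.nu, npar=self.npar,
            node_eval=self.node_eval, ng=nm + nq,
            mayer=self.mayer, boundary=self.boundary, n_boundary=n_boundary,
            par_ineq=self.par_ineq if self.npar else None,
            par_ineq_bounds=self.par_ineq_bounds() if self.npar else None,
            x_lb=x_lb, x_ub=x_ub, u_lb=u_lb, u_ub=u_ub,
            x0_lb=x0_lb, x0_ub=x0_ub,
            h_lb=spec.duration_bounds[0] / spec.n_mesh,
            h_ub=spec.duration_bounds[1] / spec.n_mesh,
            p_lb=np.array(p_lb), p_ub=np.array(p_ub),
            x_scale=x_scale, u_scale=u_scale,
            p_scale=np.array(p_scale) if p_scale else None,
            h_scale=0.02,
            f_con_scale=x_scale, g_con_scale=g_scale,
        )
        self.transcription = Transcription(self.ocp, self.grid)

    # ------------------------------------------------------------------
    def initial_guess(self, warm: SolveResult | None = None):
        """Kinematic running guess plus static muscle equilibrium; or a
        warm start from a previous solution."""
        tr = self.transcription
        if warm is not None:
            p0 = self._default_p()
            nold = warm.p.shape[0]
            if nold == self.npar:
                p0 = warm.p.copy()
            return tr.pack(warm.x0, warm.x_nodes, warm.u_nodes, warm.h, p0)
        spec = self.spec
        v = spec.guess_speed or (spec.imposed_speed if spec.task == "marathon" else 7.0)
        f_step = spec.guess_step_frequency or (3.5 if spec.task == "marathon" else 4.2)
        T = 1.0 / f_step
        h = T / spec.n_mesh
        # node times
        t_nodes = np.concatenate(
            [i * h + self.grid.tau * h for i in range(spec.n_mesh)])
        nm, nq = self.nm, self.nq
        M = self.grid.n_nodes

        amp = {"hip": 0.4, "knee": 0.45, "ankle": 0.08}
        off = {"hip": 0.15, "knee": -0.55, "ankle": -0.02}
        phase = {"hip": 0.0, "knee": 1.2, "ankle": 0.5}

        def q_of(t):
            q = np.zeros(t.shape + (nq,))
            qd = np.zeros_like(q)
            qdd = np.zeros_like(q)
            w = np.pi / T
            q[..., self.iq_x] = v * t
            qd[..., self.iq_x] = v
            # slight vertical bounce, one oscillation per step
            q[..., self.kin.iy] = 0.92 + 0.02 * np.sin(2 * np.pi * t / T)
            qd[..., self.kin.iy] = 0.02 * (2 * np.pi / T) * np.cos(2 * np.pi * t / T)
            qdd[..., self.kin.iy] = -0.02 * (2 * np.pi / T) ** 2 * np.sin(2 * np.pi * t / T)
            q[..., self.kin.ipitch] = -0.05
            for side, ph_leg in (("r", 0.0), ("l", np.pi)):
                for jn in ("hip", "knee", "ankle"):
                    k = self.model.coord_index(f"{jn}_{side}_q")
                    arg = w * t + ph_leg + phase[jn]
                    q[..., k] = off[jn] + amp[jn] * np.cos(arg)
                    qd[..., k] = -amp[jn] * w * np.sin(arg)
                    qdd[..., k] = -amp[jn] * w**2 * np.cos(arg)
            return q, qd, qdd

        q_n, qd_n, qdd_n = q_of(t_nodes)
        q_0, qd_0, _ = q_of(np.array(0.0))
        # drop the root so the lowest contact sphere grazes the ground
        sscale0, _, scaled0, _ = self.morph_arrays(self._default_p())
        frames = self.kin.frames(q_n, scaled0)
        min_bottom = np.inf
        for cs in self.model.contact_spheres:
            si = self.model._seg_index[cs.segment]
            seg = self.model.segments[si]
            s = scaled0.morphology.p_s[seg.scaling_group]
            loc = np.array([cs.location[0] * s[0], cs.location[1] * s[1]])
            pw = self.kin.point_world(frames, si, loc)
            min_bottom = min(min_bottom, float(np.min(pw[..., 1])) - cs.radius)
        q_n[..., self.kin.iy] -= min_bottom - 0.002
        q_0[..., self.kin.iy] -= min_bottom - 0.002
        # static tendon forces at the anatomical activation level
        a0 = 0.15
        sscale, pv, scaled, mp = self.morph_arrays(self._default_p())
        from .model import ScaledMuscle
        smus = [ScaledMuscle(self.model.muscles[i].name, 0.0, mp.f_max_iso[i],
                             mp.l_m_opt[i], mp.l_t_slack[i], 0.0, mp.alpha_m[i], mp.k_t[i])
                for i in range(nm)]
        lmt_n, _, _ = self.geo.eval(q_n, sscale, scaled.joint_offsets)
        ftn_n = np.zeros((M, nm))
        for k in range(M):
            ftn_n[k] = mus.initialize_tendon_forces(smus, np.full(nm, a0), lmt_n[k]) / mp.f_max_iso
        lmt_0, _, _ = self.geo.eval(q_0, sscale, scaled.joint_offsets)
        ftn_0 = mus.initialize_tendon_forces(smus, np.full(nm, a0), lmt_0) / mp.f_max_iso

        # tendon-force derivative controls consistent with the collocation
        # operator applied to the static force profile
        d = self.grid.degree
        dftn_n = np.zeros((M, nm))
        C = self.grid.C
        for i in range(spec.n_mesh):
            start = ftn_0 if i == 0 else ftn_n[i * d - 1]
            Xs = np.concatenate([start[None, :], ftn_n[i * d:(i + 1) * d]], axis=0)
            for j in range(d):
                dftn_n[i * d + j] = np.einsum("r,rm->m", C[:, j], Xs) / h

        x_nodes = np.concatenate([
            np.full((M, nm), a0), np.zeros((M, self.nt)), ftn_n, q_n, qd_n], axis=-1)
        x0 = np.concatenate([np.full(nm, a0), np.zeros(self.nt), ftn_0, q_0, qd_0])
        u_nodes = np.concatenate([
            np.full((M, nm), a0), np.zeros((M, self.nt)), dftn_n,
            qdd_n, np.zeros((M, nq))], axis=-1)
        # crutch torques that zero the skeleton residual at the guess
        p0 = self._default_p()
        _, g0, _ = self.node_eval(x_nodes, u_nodes, p0)
        u_nodes[:, 2 * nm + self.nt + nq:] = g0[:, nm:nm + nq]
        return tr.pack(x0, x_nodes, u_nodes, h, p0)

    def _default_p(self):
        p = []
        if self.n_ps:
            p.append(self.base_sscale.ravel())
        if self.n_pv:
            # representative per-pair values from the base morphology
            seen = {}
            vals = np.ones(self.n_pv)
            for i in range(self.nm):
                vals[self.pv_pair_index[i]] = self.base_pv[i]
            p.append(vals)
        return np.concatenate(p) if p else np.zeros(0)

    # ------------------------------------------------------------------
    # (aux torque bound Nm, contact stiffness scale, smoothing band m):
    # the feasibility search starts with generous auxiliary torques on
    # every coordinate (which make the kinematic guess nearly feasible)
    # and hardens contact to its physical stiffness and smoothing band;
    # the remaining crutch bound is then annealed to zero adaptively
    # (aux torque bound Nm, contact stiffness scale, smoothing band m):
    # generous crutch torques make the kinematic guess nearly feasible
    # while contact hardens; the remaining crutch is retired by adaptive
    # geometric decay at physical contact
    DEFAULT_CONTINUATION = (
        (1000.0, 0.08, 0.03), (300.0, 0.17, 0.02), (100.0, 0.5, 0.01),
        (30.0, 1.0, 5e-3),
    )
    HARDENING = ()

    def set_homotopy(self, aux_bound, contact_scale, smoothing):
        self.contact_scale = contact_scale
        self.contact_smoothing = smoothing
        nmnt = 2 * self.nm + self.nt + self.nq
        self.ocp.u_lb[nmnt:] = -aux_bound
        self.ocp.u_ub[nmnt:] = aux_bound
        self.transcription.invalidate_cache()

    def solve(self, guess=None, warm: SolveResult | None = None,
              continuation=None, verbose=0, **kw) -> "GaitSolution":
        """Feasibility via the crutch-torque/contact continuation, then
        projected-gradient descent at the physical parameters."""
        if guess is None:
            guess = self.initial_guess(warm=warm)
        kw.setdefault("maxiter", self.spec.maxiter)
        stage_iters = self.spec.stage_iters
        tr = self.transcription
        clb, cub = tr.constraint_bounds()
        zs = np.asarray(guess, float) / tr.z_scale
        if continuation is None:
            continuation = self.DEFAULT_CONTINUATION if warm is None else ()
        aux_last, soft = 0.0, (1.0, self.contact_smoothing)
        for aux_b, s, eps in continuation:
            self.set_homotopy(aux_b, s, eps)
            lb, ub = tr.solver_bounds()
            zs = np.clip(zs, lb, ub)
            zs = tr.lm_feasibility(zs, lb, ub, clb, cub, tol=1e-8,
                                   max_iter=stage_iters,
                                   verbose=max(verbose - 1, 0))
            aux_last, soft = aux_b, (s, eps)
            if verbose:
                c = tr.constraints_scaled(zs)
                r, act = tr._residual(c, clb, cub)
                print(f"[homotopy aux={aux_b} k={s} eps={eps}] "
                      f"viol {np.max(np.abs(r[act])):.2e}", flush=True)
        if aux_last > 0:
            zs = self._anneal_aux(zs, aux_last, soft, clb, cub, stage_iters, verbose)
        self.set_homotopy(0.0, 1.0, self.contact_smoothing)
        lb, ub = tr.solver_bounds()
        zs = np.clip(zs, lb, ub)
        res = tr.solve(zs * tr.z_scale, verbose=verbose, **kw)
        return GaitSolution(self, res)

    def _aux_slice(self):
        return slice(2 * self.nm + self.nt + self.nq, None)

    def _max_aux(self, tr, zs):
        un = tr.unpack(zs * tr.z_scale)[2]
        return float(np.max(np.abs(un[:, self._aux_slice()]), initial=0.0))

    def _anneal_aux(self, zs, aux, soft, clb, cub, stage_iters, verbose,
                    tol=1e-8):
        """Retire the crutch torques at the soft contact setting by
        geometric decay with adaptive step control, then close the
        crutch bounds to zero exactly (still at soft contact)."""
        tr = self.transcription
        k, eps = soft
        sl = self._aux_slice()
        iu = tr.i_uc[:, sl]
        bound, decay = aux, 0.5
        z_good = zs.copy()
        rounds = 0
        while bound > 0.05 and rounds < self.spec.retire_rounds:
            rounds += 1
            bound_next = bound * decay if bound * decay >= 0.05 else 0.0
            z_phys = z_good * tr.z_scale
            z_phys[iu] = np.clip(z_phys[iu] * decay, -max(bound_next, 1e-9),
                                 max(bound_next, 1e-9))
            self.set_homotopy(bound_next, k, eps)
            lb, ub = tr.solver_bounds()
            z_try = tr.lm_feasibility(np.clip(z_phys / tr.z_scale, lb, ub),
                                      lb, ub, clb, cub, tol=tol,
                                      max_iter=stage_iters)
            c = tr.constraints_scaled(z_try)
            r, act = tr._residual(c, clb, cub)
            v = np.max(np.abs(r[act]), initial=0.0)
            if verbose:
                print(f"[retire] bound {bound:.3g} -> {bound_next:.3g}: "
                      f"viol {v:.2e}", flush=True)
            if v < 2e-5:
                z_good, bound = z_try, bound_next
                decay = max(decay * 0.85, 0.3)
            else:
                decay = np.sqrt(decay)
                if decay > 0.97:
                    if verbose:
                        print("[retire] stalled; residual crutch remains",
                              flush=True)
                    break
        self.set_homotopy(0.0, k, eps)
        lb, ub = tr.solver_bounds()
        return tr.lm_feasibility(np.clip(z_good, lb, ub), lb, ub, clb, cub,
                                 tol=tol, max_iter=2 * stage_iters)

    def morphology_from_p(self, p) -> Morphology:
        sscale, pv, _, _ = self.morph_arrays(np.asarray(p, float))
        return Morphology(p_s={g: np.real(sscale[i]).astype(float) for g, i in self.gidx.items()},
                          p_v=np.real(pv).astype(float))


# =========================================================================
# Solution wrapper and derived metrics
# =========================================================================


class GaitSolution:
    """Converged (or diagnostic) trajectory plus derived gait metrics."""

    def __init__(self, problem: GaitProblem, result: SolveResult):
        self.problem = problem
        self.result = result

    @property
    def converged(self):
        return self.result.constr_violation < 1e-6

    @property
    def duration(self):
        return self.problem.spec.n_mesh * self.result.h

    @property
    def displacement(self):
        iq = self.problem.i_q[self.problem.iq_x]
        return float(np.real(self.result.x_nodes[-1, iq] - self.result.x0[iq]))

    @property
    def average_speed(self):
        return self.displacement / self.duration

    @property
    def step_length(self):
        return self.displacement

    @property
    def step_frequency(self):
        return 1.0 / self.duration

    def objective_breakdown(self):
        """Integrated value of each objective term over the half cycle."""
        pr = self.problem
        tr = pr.transcription
        x, u, p, h = tr._node_args(self.result.z)
        w = pr.spec.weights
        a, aT, ftn, q, qd = pr.split_state(x)
        em, eT, dftn, qdd, aux = pr.split_controls(u)
        _, _, _ = pr.node_eval(x, u, p)  # refresh cached powers
        power = pr._last_power
        wq = tr.wq * h
        tau_lim = pr._limit_torques(q)
        terms = {
            "J_metabolic": w.metabolic * float(np.sum(wq * np.sum(power**2, axis=-1))),
            "J_am": w.activation * float(np.sum(wq * np.sum(a**2, axis=-1))),
            "J_acc": w.acceleration * float(np.sum(wq * np.sum(qdd**2, axis=-1))),
            "J_limit": w.limit_torque * float(np.sum(wq * np.sum(tau_lim**2, axis=-1))),
            "J_aT": w.actuator * float(np.sum(wq * np.sum(aT**2, axis=-1))) if pr.nt else 0.0,
            "l_gaitcycle": self.displacement,
            "v_avg": self.average_speed,
        }
        terms["metabolic_energy_J"] = float(np.sum(wq * np.sum(power, axis=-1)))
        return terms

    def marathon_kcal(self):
        """Whole-marathon metabolic cost from the unsquared energy."""
        terms = self.objective_breakdown()
        cost_per_m = terms["metabolic_energy_J"] / self.displacement / J_PER_KCAL
        from .metabolics import marathon_energy
        return marathon_energy(cost_per_m)

    def morphology(self) -> Morphology:
        return self.problem.morphology_from_p(self.result.p)

    # ------------------------------------------------------------------
    def reintegrate(self, substeps: int = 40):
        """Integrate the solved controls with a fine fixed-step RK4 from
        the solved initial state; return the max state mismatch at mesh
        boundaries, normalized by the state scale."""
        pr = self.problem
        grid = pr.grid
        res = self.result
        h = res.h
        d = grid.degree
        x = np.array(res.x0, float)
        err = 0.0
        scale = pr.transcription.x_scale
        p = res.p
        for i in range(grid.n_mesh):
            u_nodes = res.u_nodes[i * d:(i + 1) * d]

            def u_of(s):
                return grid.interpolate_controls(u_nodes, s)

            def f(s, xx):
                xd, _, _ = pr.node_eval(xx[None, :], u_of(s)[None, :], p)
                return xd[0]

            n = substeps
            dt = 1.0 / n
            for k in range(n):
                s = k * dt
                k1 = f(s, x)
                k2 = f(s + dt / 2, x + h * dt / 2 * k1)
                k3 = f(s + dt / 2, x + h * dt / 2 * k2)
                k4 = f(s + dt, x + h * dt * k3)
                x = x + h * dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            x_end = res.x_nodes[(i + 1) * d - 1]
            err = max(err, float(np.max(np.abs(x - x_end) / scale)))
            x = np.array(x_end, float)  # restart from collocation state
        return err
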