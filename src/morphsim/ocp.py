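"""Generic direct-collocation transcription with implicit dynamics.

An :class:`OCP` describes one optimal-control problem in physical
units through a single vectorized node function

    node_eval(x, u, p) -> (xdot, g, L)

evaluated at all collocation nodes at once (x of shape (M, nx)), where
``xdot`` is the explicit part of the state derivative, ``g`` algebraic
(implicit-dynamics) residuals imposed as equality path constraints and
``L`` the objective integrand.  Boundary conditions couple the initial
and final state (periodicity, imposed average speed), the interval
length h is itself a decision variable, and global parameters ``p``
(morphology) may enter every function.

The transcription assembles a sparse NLP for scipy's ``trust-constr``:
the collocation equations' linear part is a precomputed sparse matrix,
and all nonlinear Jacobian blocks are obtained with complex-step
directional derivatives swept simultaneously across nodes — exact to
machine precision because every model function is complex-analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import lsqr, splu


def _min_norm_factor(J, lam):
    """Factorization for damped minimum-norm steps dz = J^T (J J^T + lam^2 I)^-1 (-r).

    Returns a solver closure; exact (to factorization accuracy)
    regardless of conditioning, reusable across several right-hand
    sides (chord iterations)."""
    JJt = (J @ J.T).tocsc()
    n = JJt.shape[0]
    A = JJt + (lam**2) * sparse.identity(n, format="csc")
    try:
        lu = splu(A)

        def step(r):
            return J.T @ lu.solve(-r)
    except RuntimeError:
        def step(r):
            return lsqr(J, -r, damp=lam, atol=1e-12, btol=1e-12, iter_lim=3000)[0]
    return step


def _min_norm_step(J, r, lam):
    return _min_norm_factor(J, lam)(r)


def _null_space_project(J, g, lam=1e-8):
    """Project g onto the (approximate) null space of J."""
    JJt = (J @ J.T).tocsc()
    n = JJt.shape[0]
    A = JJt + (lam**2) * sparse.identity(n, format="csc")
    try:
        w = splu(A).solve(J @ g)
    except RuntimeError:
        w = lsqr(J.T, g, atol=1e-12, btol=1e-12, iter_lim=3000)[0]
    return g - J.T @ w

from .collocation import CollocationGrid

__all__ = ["OCP", "Transcription", "SolveResult"]

_CSTEP = 1e-100


@dataclass
class OCP:
    nx: int
    nu: int
    npar: int
    node_eval: Callable  # (x(M,nx), u(M,nu), p) -> (xdot, g | None, L | None)
    ng: int = 0
    mayer: Callable | None = None  # (x0, xend, h, p, integral) -> scalar
    boundary: Callable | None = None  # (x0, xend, h, p) -> equality residuals
    n_boundary: int = 0
    par_ineq: Callable | None = None  # p -> values; with par_ineq_bounds
    par_ineq_bounds: tuple | None = None  # (lb, ub) arrays
    # physical bounds
    x_lb: np.ndarray | None = None
    x_ub: np.ndarray | None = None
    u_lb: np.ndarray | None = None
    u_ub: np.ndarray | None = None
    x0_lb: np.ndarray | None = None  # overrides x_lb for the initial state
    x0_ub: np.ndarray | None = None
    h_lb: float = 1e-4
    h_ub: float = 1.0
    p_lb: np.ndarray | None = None
    p_ub: np.ndarray | None = None
    # scaling (typical magnitudes; solver works in scaled variables)
    x_scale: np.ndarray | None = None
    u_scale: np.ndarray | None = None
    p_scale: np.ndarray | None = None
    h_scale: float = 0.1
    f_con_scale: np.ndarray | None = None  # row scaling of collocation eqs
    g_con_scale: np.ndarray | None = None  # row scaling of algebraic eqs


@dataclass
class SolveResult:
    success: bool
    status: str
    objective: float
    constr_violation: float
    n_iter: int
    x0: np.ndarray
    x_nodes: np.ndarray  # (M, nx)
    u_nodes: np.ndarray  # (M, nu)
    h: float
    p: np.ndarray
    z: np.ndarray
    extra: dict = field(default_factory=dict)


def _ones(v, n):
    return np.ones(n) if v is None else np.asarray(v, dtype=float)


class Transcription:
    def __init__(self, ocp: OCP, grid: CollocationGrid):
        self.ocp = ocp
        self.grid = grid
        nx, nu, npar = ocp.nx, ocp.nu, ocp.npar
        d, N = grid.degree, grid.n_mesh
        M = N * d
        self.M = M
        # variable layout: X0 | Xc (M*nx) | Uc (M*nu) | h | p
        self.i_x0 = np.arange(nx)
        self.i_xc = nx + np.arange(M * nx).reshape(M, nx)
        off = nx + M * nx
        self.i_uc = off + np.arange(M * nu).reshape(M, nu)
        self.i_h = off + M * nu
        self.i_p = self.i_h + 1 + np.arange(npar)
        self.nz = self.i_h + 1 + npar

        self.x_scale = _ones(ocp.x_scale, nx)
        self.u_scale = _ones(ocp.u_scale, nu)
        self.p_scale = _ones(ocp.p_scale, npar)
        self.z_scale = np.empty(self.nz)
        self.z_scale[self.i_x0] = self.x_scale
        self.z_scale[self.i_xc] = self.x_scale
        if nu:
            self.z_scale[self.i_uc] = self.u_scale
        self.z_scale[self.i_h] = ocp.h_scale
        self.z_scale[self.i_p] = self.p_scale

        self.f_con_scale = _ones(ocp.f_con_scale, nx)
        self.g_con_scale = _ones(ocp.g_con_scale, ocp.ng)

        # constraint layout: collocation (M*nx) | algebraic (M*ng) | boundary
        self.r_coll = np.arange(M * nx).reshape(M, nx)
        off = M * nx
        self.r_alg = off + np.arange(M * ocp.ng).reshape(M, ocp.ng) if ocp.ng else np.zeros((M, 0), int)
        off += M * ocp.ng
        self.r_bnd = off + np.arange(ocp.n_boundary)
        off += ocp.n_boundary
        self.n_eq = off
        self.n_pineq = 0
        if ocp.par_ineq is not None:
            self.n_pineq = len(np.atleast_1d(ocp.par_ineq_bounds[0]))
        self.r_pineq = off + np.arange(self.n_pineq)
        self.nc = off + self.n_pineq

        # start-state variable indices per interval
        self.start_cols = np.empty((N, nx), dtype=int)
        self.start_cols[0] = self.i_x0
        for i in range(1, N):
            self.start_cols[i] = self.i_xc[i * d - 1]

        # constant linear part of the collocation equations: sum_r C[r,j] X_r
        rows, cols, vals = [], [], []
        for i in range(N):
            for j in range(d):
                r = self.r_coll[i * d + j]
                c0 = grid.C[0, j]
                rows.append(r); cols.append(self.start_cols[i]); vals.append(np.full(nx, c0))
                for rr in range(1, d + 1):
                    rows.append(r)
                    cols.append(self.i_xc[i * d + rr - 1])
                    vals.append(np.full(nx, grid.C[rr, j]))
        self.A_lin = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_eq + self.n_pineq, self.nz),
        ).tocsr()

        # quadrature weight per node (B_j, tiled over intervals)
        self.wq = np.tile(grid.B, N)

        # rows that are soft regularizers rather than physical
        # constraints (e.g. homotopy crutch-retirement rows): they join
        # the least-squares steps but not the convergence test
        self.soft_rows = np.zeros(self.nc, dtype=bool)

        self._cache_key = None
        self._cache = None

    # ------------------------------------------------------------------
    def pack(self, x0, x_nodes, u_nodes, h, p):
        z = np.empty(self.nz)
        z[self.i_x0] = x0
        z[self.i_xc] = x_nodes
        if self.ocp.nu:
            z[self.i_uc] = u_nodes
        z[self.i_h] = h
        z[self.i_p] = p
        return z

    def unpack(self, z):
        return (
            z[self.i_x0],
            z[self.i_xc],
            z[self.i_uc] if self.ocp.nu else np.zeros((self.M, 0)),
            float(np.real(z[self.i_h])),
            z[self.i_p],
        )

    # ------------------------------------------------------------------
    def _node_args(self, z):
        x = z[self.i_xc]
        u = z[self.i_uc] if self.ocp.nu else np.zeros((self.M, 0), dtype=z.dtype)
        return x, u, z[self.i_p], z[self.i_h]

    def constraints(self, z):
        """Constraint vector in physical units (unscaled rows)."""
        ocp, grid = self.ocp, self.grid
        x, u, p, h = self._node_args(z)
        xdot, g, _ = ocp.node_eval(x, u, p)
        c = np.zeros(self.nc, dtype=z.dtype)
        c[: self.n_eq][self.r_coll.ravel()] = (self.A_lin[: self.M * ocp.nx] @ z) - (h * xdot).ravel()
        if ocp.ng:
            c[self.r_alg.ravel()] = np.asarray(g).ravel()
        if ocp.n_boundary:
            xend = x[-1]
            c[self.r_bnd] = ocp.boundary(z[self.i_x0], xend, h, p)
        if self.n_pineq:
            c[self.r_pineq] = ocp.par_ineq(p)
        return c

    def objective(self, z):
        ocp = self.ocp
        x, u, p, h = self._node_args(z)
        _, _, L = ocp.node_eval(x, u, p)
        integral = h * np.sum(self.wq * np.asarray(L)) if L is not None else 0.0
        if ocp.mayer is None:
            return integral
        return ocp.mayer(z[self.i_x0], x[-1], h, p, integral)

    # ------------------------------------------------------------------
    def _linearize(self, z):
        """Constraints, objective, sparse Jacobian and gradient at z.

        One pass of complex-step sweeps shared between the constraint
        Jacobian and the objective gradient.
        """
        ocp, grid = self.ocp, self.grid
        nx, nu, npar, ng = ocp.nx, ocp.nu, ocp.npar, ocp.ng
        M = self.M
        x, u, p, h = self._node_args(z)
        xdot0, g0, L0 = ocp.node_eval(x, u, p)
        has_L = L0 is not None

        c0 = self.constraints(z)
        # directional sweeps: the x and u directions are stacked into the
        # leading batch axis so all node-local derivatives come from two
        # vectorized evaluations; p directions are few and swept singly
        ndir = nx + nu + npar
        df = np.empty((ndir, M, nx))
        dg = np.empty((ndir, M, ng)) if ng else None
        dL = np.empty((ndir, M)) if has_L else None

        def record(sl, fd, gd, Ld):
            df[sl] = fd
            if ng:
                dg[sl] = gd
            if has_L:
                dL[sl] = Ld

        xc = np.broadcast_to(x, (nx, M, nx)).astype(complex)
        xc[np.arange(nx), :, np.arange(nx)] += 1j * _CSTEP
        fd, gd, Ld = ocp.node_eval(xc, np.broadcast_to(u, (nx, M, nu)), p)
        record(slice(0, nx), fd.imag / _CSTEP,
               None if not ng else np.asarray(gd).imag / _CSTEP,
               None if not has_L else np.asarray(Ld).imag / _CSTEP)
        if nu:
            uc = np.broadcast_to(u, (nu, M, nu)).astype(complex)
            uc[np.arange(nu), :, np.arange(nu)] += 1j * _CSTEP
            fd, gd, Ld = ocp.node_eval(np.broadcast_to(x, (nu, M, nx)), uc, p)
            record(slice(nx, nx + nu), fd.imag / _CSTEP,
                   None if not ng else np.asarray(gd).imag / _CSTEP,
                   None if not has_L else np.asarray(Ld).imag / _CSTEP)
        for k in range(npar):
            pc = p.astype(complex)
            pc[k] += 1j * _CSTEP
            fd, gd, Ld = ocp.node_eval(x, u, pc)
            record(nx + nu + k, fd.imag / _CSTEP,
                   None if not ng else np.asarray(gd).imag / _CSTEP,
                   None if not has_L else np.asarray(Ld).imag / _CSTEP)

        # ---- assemble sparse Jacobian ---------------------------------
        rows, cols, vals = [], [], []

        def add_block(r_idx, c_idx, block):
            # r_idx (nr,), c_idx (nc,), block (nr, nc)
            rr, cc = np.meshgrid(r_idx, c_idx, indexing="ij")
            rows.append(rr.ravel())
            cols.append(cc.ravel())
            vals.append(block.ravel())

        for m in range(M):
            # collocation rows: -h * d f_m, plus -f_m in the h column
            blk = np.empty((nx, nx + nu + npar))
            blk[:, :] = -h * df[:, m, :].T
            add_block(self.r_coll[m], self.i_xc[m], blk[:, :nx])
            if nu:
                add_block(self.r_coll[m], self.i_uc[m], blk[:, nx : nx + nu])
            if npar:
                add_block(self.r_coll[m], self.i_p, blk[:, nx + nu :])
            add_block(self.r_coll[m], np.array([self.i_h]), -xdot0[m][:, None])
            if ng:
                gblk = dg[:, m, :].T
                add_block(self.r_alg[m], self.i_xc[m], gblk[:, :nx])
                if nu:
                    add_block(self.r_alg[m], self.i_uc[m], gblk[:, nx : nx + nu])
                if npar:
                    add_block(self.r_alg[m], self.i_p, gblk[:, nx + nu :])

        # boundary rows: complex step over (x0, xend, h, p)
        if ocp.n_boundary:
            x0 = z[self.i_x0]
            xend = x[-1]
            bcols = np.concatenate([self.i_x0, self.i_xc[-1], [self.i_h], self.i_p])
            nb = ocp.n_boundary
            bjac = np.empty((nb, len(bcols)))
            args = [x0.astype(complex), xend.astype(complex), complex(h), p.astype(complex)]
            slot = 0
            for ai, alen in ((0, nx), (1, nx), (2, 1), (3, npar)):
                for k in range(alen):
                    a = [np.array(v, copy=True) if hasattr(v, "__len__") else v for v in args]
                    if alen == 1 and ai == 2:
                        a[2] = a[2] + 1j * _CSTEP
                    else:
                        a[ai][k] += 1j * _CSTEP
                    bjac[:, slot] = np.asarray(ocp.boundary(a[0], a[1], a[2], a[3])).imag / _CSTEP
                    slot += 1
            add_block(self.r_bnd, bcols, bjac)

        if self.n_pineq:
            pc_jac = np.empty((self.n_pineq, npar))
            for k in range(npar):
                pc = p.astype(complex)
                pc[k] += 1j * _CSTEP
                pc_jac[:, k] = np.asarray(ocp.par_ineq(pc)).imag / _CSTEP
            add_block(self.r_pineq, self.i_p, pc_jac)

        J = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.nc, self.nz),
        ).tocsr()
        J = J + self.A_lin

        # ---- objective and gradient -----------------------------------
        grad = np.zeros(self.nz)
        integral = h * np.sum(self.wq * np.asarray(L0)) if has_L else 0.0
        if ocp.mayer is not None:
            x0 = z[self.i_x0]
            xend = x[-1]
            obj = ocp.mayer(x0, xend, h, p, integral)
            # partials of mayer
            def my(x0_, xend_, h_, p_, I_):
                return ocp.mayer(x0_, xend_, h_, p_, I_)
            m_I = np.imag(my(x0, xend, h, p, integral + 1j * _CSTEP)) / _CSTEP
            for k in range(nx):
                a = x0.astype(complex); a[k] += 1j * _CSTEP
                grad[self.i_x0[k]] += np.imag(my(a, xend, h, p, integral)) / _CSTEP
                b = xend.astype(complex); b[k] += 1j * _CSTEP
                grad[self.i_xc[-1][k]] += np.imag(my(x0, b, h, p, integral)) / _CSTEP
            grad[self.i_h] += np.imag(my(x0, xend, h + 1j * _CSTEP, p, integral)) / _CSTEP
            for k in range(npar):
                a = p.astype(complex); a[k] += 1j * _CSTEP
                grad[self.i_p[k]] += np.imag(my(x0, xend, h, a, integral)) / _CSTEP
        else:
            obj = integral
            m_I = 1.0
        if has_L:
            w = m_I * h * self.wq  # (M,)
            grad_x = (dL[:nx] * w).T  # (M, nx)
            np.add.at(grad, self.i_xc.ravel(), grad_x.ravel())
            if nu:
                grad_u = (dL[nx : nx + nu] * w).T
                np.add.at(grad, self.i_uc.ravel(), grad_u.ravel())
            if npar:
                grad[self.i_p] += m_I * h * (dL[nx + nu :] * self.wq).sum(axis=1)
            grad[self.i_h] += m_I * np.sum(self.wq * np.asarray(L0))
        return c0, J, float(np.real(obj)), grad

    # ------------------------------------------------------------------
    def _linearize_cached(self, z_scaled):
        key = z_scaled.tobytes()
        if key != self._cache_key:
            z = z_scaled * self.z_scale
            c, J, obj, grad = self._linearize(z)
            cs = self._row_scale()
            c_s = c / cs
            J_s = sparse.diags(1.0 / cs) @ J @ sparse.diags(self.z_scale)
            grad_s = grad * self.z_scale
            self._cache = (c_s, J_s.tocsr(), obj, grad_s)
            self._cache_key = key
        return self._cache

    def _row_scale(self):
        cs = np.ones(self.nc)
        cs[self.r_coll.ravel()] = np.tile(self.f_con_scale, self.M)
        if self.ocp.ng:
            cs[self.r_alg.ravel()] = np.tile(self.g_con_scale, self.M)
        return cs

    # ------------------------------------------------------------------
    def solver_bounds(self):
        ocp = self.ocp
        nx, nu = ocp.nx, ocp.nu
        lb = np.full(self.nz, -np.inf)
        ub = np.full(self.nz, np.inf)
        x_lb = _ones(ocp.x_lb, nx) * (-np.inf) if ocp.x_lb is None else np.asarray(ocp.x_lb, float)
        x_ub = _ones(ocp.x_ub, nx) * (np.inf) if ocp.x_ub is None else np.asarray(ocp.x_ub, float)
        lb[self.i_xc] = x_lb
        ub[self.i_xc] = x_ub
        lb[self.i_x0] = x_lb if ocp.x0_lb is None else np.asarray(ocp.x0_lb, float)
        ub[self.i_x0] = x_ub if ocp.x0_ub is None else np.asarray(ocp.x0_ub, float)
        if nu:
            lb[self.i_uc] = -np.inf if ocp.u_lb is None else np.asarray(ocp.u_lb, float)
            ub[self.i_uc] = np.inf if ocp.u_ub is None else np.asarray(ocp.u_ub, float)
        lb[self.i_h] = ocp.h_lb
        ub[self.i_h] = ocp.h_ub
        if ocp.npar:
            lb[self.i_p] = -np.inf if ocp.p_lb is None else np.asarray(ocp.p_lb, float)
            ub[self.i_p] = np.inf if ocp.p_ub is None else np.asarray(ocp.p_ub, float)
        return lb / self.z_scale, ub / self.z_scale

    def constraint_bounds(self):
        lb = np.zeros(self.nc)
        ub = np.zeros(self.nc)
        if self.n_pineq:
            cs = self._row_scale()[self.r_pineq]
            lb[self.r_pineq] = np.asarray(self.ocp.par_ineq_bounds[0], float) / cs
            ub[self.r_pineq] = np.asarray(self.ocp.par_ineq_bounds[1], float) / cs
        return lb, ub

    def invalidate_cache(self):
        """Call after changing anything the node function closes over
        (e.g. a homotopy parameter)."""
        self._cache_key = None
        self._cache = None

    def constraints_scaled(self, zs):
        """Row-scaled constraint vector at a scaled iterate (no Jacobian)."""
        return self.constraints(zs * self.z_scale) / self._row_scale()

    # ------------------------------------------------------------------
    def _residual(self, c, clb, cub):
        """(residual vector, active-row mask) of the (near-)active set."""
        is_eq = np.abs(clb - cub) < 1e-14
        r_up = c - cub
        r_lo = clb - c
        act = is_eq | (r_up > -1e-7) | (r_lo > -1e-7)
        resid = np.where(is_eq, c - cub,
                         np.where(r_up > -1e-7, np.maximum(r_up, 0.0),
                                  -np.maximum(r_lo, 0.0)))
        return resid, act

    def lm_feasibility(self, zs, lb, ub, clb, cub, tol=1e-9, max_iter=120,
                       lam0=1e-3, verbose=0):
        """Damped Gauss-Newton (Levenberg-Marquardt) projection onto the
        constraint manifold, respecting variable bounds by clipping.
        Returns the refined scaled iterate."""
        zs = np.clip(zs, lb, ub)
        lam = lam0
        c = self.constraints_scaled(zs)
        resid, act = self._residual(c, clb, cub)
        best = np.linalg.norm(resid[act]) if act.any() else 0.0
        hard = ~self.soft_rows
        prev_best = np.inf
        for it in range(max_iter):
            c, J, _, _ = self._linearize_cached(zs)
            resid, act = self._residual(c, clb, cub)
            rmax = np.max(np.abs(resid[act & hard]), initial=0.0)
            if verbose:
                print(f"  [lm {it:3d}] max|r| {rmax:.3e}  ||r|| {np.linalg.norm(resid[act]):.3e}  lam {lam:.1e}")
            if rmax < tol and best >= 0.998 * prev_best:
                break
            prev_best = best
            Ja = J[act].tocsr()
            improved = False
            for _try in range(6):
                solver = _min_norm_factor(Ja, lam)
                # chord iterations: reuse the factorization for several
                # cheap steps while they keep reducing the residual
                for _chord in range(12):
                    c_cur = self.constraints_scaled(zs)
                    r_cur, _ = self._residual(c_cur, clb, cub)
                    dz = solver(r_cur[act])
                    dmax = np.max(np.abs(dz), initial=0.0)
                    if dmax > 50.0:
                        dz *= 50.0 / dmax
                    stepped = False
                    # full step, then a second-order correction with the
                    # same factorization (handles manifold curvature),
                    # then plain backtracking
                    z_new = np.clip(zs + dz, lb, ub)
                    c_new = self.constraints_scaled(z_new)
                    r_new, a_new = self._residual(c_new, clb, cub)
                    n_new = np.linalg.norm(r_new[a_new]) if a_new.any() else 0.0
                    if n_new < best:
                        zs, best, improved, stepped = z_new, n_new, True, True
                    else:
                        z_soc = np.clip(z_new + solver(r_new[act]), lb, ub)
                        c_soc = self.constraints_scaled(z_soc)
                        r_soc, a_soc = self._residual(c_soc, clb, cub)
                        n_soc = np.linalg.norm(r_soc[a_soc]) if a_soc.any() else 0.0
                        if n_soc < best:
                            zs, best, improved, stepped = z_soc, n_soc, True, True
                        else:
                            for t in (0.5, 0.25, 0.1):
                                z_new = np.clip(zs + t * dz, lb, ub)
                                c_new = self.constraints_scaled(z_new)
                                r_new, a_new = self._residual(c_new, clb, cub)
                                n_new = np.linalg.norm(r_new[a_new]) if a_new.any() else 0.0
                                if n_new < best:
                                    zs, best, improved, stepped = z_new, n_new, True, True
                                    break
                    if not stepped or best < tol:
                        break
                if improved:
                    lam = max(lam / 3.0, 1e-7)
                    break
                lam = min(lam * 10.0, 1e4)
            if not improved:
                break
        return zs

    def reduced_descent(self, zs, lb, ub, clb, cub, max_iter=60, step0=0.5,
                        restore_tol=1e-8, verbose=0, min_step=1e-4):
        """Projected-gradient descent on the constraint manifold.

        Each iteration projects the objective gradient onto the null
        space of the active constraint Jacobian, takes a bounded step,
        restores feasibility with a few LM iterations, and accepts the
        point only if the objective decreased — so the method is
        monotone in the objective along feasible iterates.
        """
        zs = self.lm_feasibility(zs, lb, ub, clb, cub, tol=restore_tol)
        c, J, obj, grad = self._linearize_cached(zs)
        r0, a0 = self._residual(c, clb, cub)
        # feasibility acceptance is relative to the starting violation, so
        # descent still works from a partially converged start
        v_accept = max(100 * restore_tol,
                       1.2 * float(np.max(np.abs(r0[a0]), initial=0.0)))
        step = step0
        for it in range(max_iter):
            resid, act = self._residual(c, clb, cub)
            # treat bound-active variables as fixed in the projection
            at_lb = (zs - lb < 1e-9) & (grad > 0)
            at_ub = (ub - zs < 1e-9) & (grad < 0)
            free = ~(at_lb | at_ub)
            Ja = J[act][:, free].tocsr()
            gf = grad[free]
            gproj = _null_space_project(Ja, gf)
            gnorm = np.max(np.abs(gproj), initial=0.0)
            if verbose:
                print(f"  [rg {it:3d}] obj {obj:.6e}  |gproj| {gnorm:.3e}  step {step:.2e}")
            if gnorm < 1e-9:
                break
            dz = np.zeros(self.nz)
            dz[free] = -gproj / gnorm  # normalized: 'step' is max scaled move
            accepted = False
            while step >= min_step:
                z_try = np.clip(zs + step * dz, lb, ub)
                z_try = self.lm_feasibility(z_try, lb, ub, clb, cub,
                                            tol=restore_tol, max_iter=20)
                c_t, J_t, obj_t, grad_t = self._linearize_cached(z_try)
                r_t, a_t = self._residual(c_t, clb, cub)
                feas_ok = np.max(np.abs(r_t[a_t]), initial=0.0) < v_accept
                if self.n_pineq:
                    # parameter-only inequalities (budgets, BMI) are
                    # exactly satisfiable and must not drift
                    feas_ok &= np.max(np.abs(r_t[self.r_pineq]), initial=0.0) < 1e-8
                if feas_ok and obj_t < obj - 1e-12:
                    zs, c, J, obj, grad = z_try, c_t, J_t, obj_t, grad_t
                    step = min(step * 1.6, 4 * step0)
                    accepted = True
                    break
                step *= 0.4
            if not accepted:
                break
        return zs

    # ------------------------------------------------------------------
    def solve(self, z0, maxiter=60, verbose=0, polish=True, polish_tol=1e-9,
              feas_tol=1e-9, step0=0.5, descend=True) -> SolveResult:
        """Solve the transcribed NLP from the physical-units guess z0.

        Two phases: damped Gauss-Newton projection onto the constraint
        manifold, then projected-gradient descent along it (``maxiter``
        outer iterations), then a final feasibility polish on the
        active set.
        """
        z0s = np.asarray(z0, float) / self.z_scale
        lb, ub = self.solver_bounds()
        z0s = np.clip(z0s, lb, ub)
        clb, cub = self.constraint_bounds()
        zs = self.lm_feasibility(z0s, lb, ub, clb, cub, tol=feas_tol,
                                 max_iter=80, verbose=max(verbose - 1, 0))
        n_iter = 0
        if descend and maxiter > 0:
            zs = self.reduced_descent(zs, lb, ub, clb, cub, max_iter=maxiter,
                                      step0=step0, verbose=verbose)
            n_iter = maxiter
        if polish:
            zs = self._polish(zs, lb, ub, clb, cub, tol=polish_tol)
        z = zs * self.z_scale
        c = self.constraints(z)
        viol = self._violation(c, clb, cub)
        x0, xn, un, h, p = self.unpack(z)
        return SolveResult(
            success=bool(viol < 1e-6),
            status="feasible" if viol < 1e-6 else f"constraint violation {viol:.2e}",
            objective=float(self.objective(z)),
            constr_violation=float(viol),
            n_iter=n_iter,
            x0=x0, x_nodes=xn, u_nodes=un, h=h, p=np.array(p, float),
            z=z,
            extra={},
        )

    def _violation(self, c, clb, cub):
        cs = self._row_scale()
        cl = c / cs
        return float(np.max(np.maximum(np.maximum(clb - cl, cl - cub), 0.0)))

    def _polish(self, zs, lb, ub, clb, cub, tol=1e-9, max_iter=25):
        """Gauss-Newton feasibility refinement on the (near-)active
        constraint set: minimum-norm Newton steps onto c(z) = target,
        treating inequality rows as equalities only when they are
        active at the current point.  Variables are kept inside their
        bounds; the objective is not touched."""
        zs = zs.copy()
        for _ in range(max_iter):
            c, J, _, _ = self._linearize_cached(zs)
            r_up = c - cub
            r_lo = clb - c
            act = (np.abs(clb - cub) < 1e-14) | (r_up > -1e-7) | (r_lo > -1e-7)
            resid = np.where(np.abs(clb - cub) < 1e-14, c - cub,
                             np.where(r_up > -1e-7, np.maximum(r_up, 0.0),
                                      -np.maximum(r_lo, 0.0)))
            resid = resid[act]
            if np.max(np.abs(resid), initial=0.0) < tol:
                break
            Ja = J[act].tocsr()
            dz = _min_norm_step(Ja, resid, 1e-7)
            dmax = np.max(np.abs(dz), initial=0.0)
            if dmax > 2.0:  # scaled-variable trust region
                dz *= 2.0 / dmax
            step = 1.0
            base = np.max(np.abs(resid))
            base_norm = np.linalg.norm(resid)
            for _ls in range(8):
                z_new = np.clip(zs + step * dz, lb, ub)
                c_new = self.constraints_scaled(z_new)
                r_new, a_new = self._residual(c_new, clb, cub)
                v = float(np.max(np.abs(r_new[a_new]), initial=0.0))
                # accept on max-violation decrease, or on 2-norm decrease
                # without max increase (fixes subdominant rows such as
                # parameter budgets)
                if v < base or (v <= base * (1 + 1e-12)
                                and np.linalg.norm(r_new[a_new]) < base_norm):
                    zs = z_new
                    break
                step *= 0.5
            else:
                break
        return zs

    def _viol_vec(self, c, clb, cub):
        return float(np.max(np.maximum(np.maximum(clb - c, c - cub), 0.0), initial=0.0))
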