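"""Planar tree kinematics, complex-safe and vectorized over batches.

Conventions: the ground frame has x forward and y up; rotations are
counter-clockwise positive about the out-of-plane z axis.  The root
segment carries a planar free joint (x, y, pitch); every other segment
attaches to its parent through a revolute joint at a point fixed in the
parent frame (scaled per axis by the parent's morphology factors).

Every function accepts real or complex inputs and broadcasts over
leading batch axes, which is what makes complex-step differentiation of
the whole simulator possible.
"""

from __future__ import annotations

import numpy as np

from .model import MusculoskeletalModel, ScaledModel

__all__ = ["PlanarKinematics"]


def _rot(theta, p):
    """Rotate 2-vectors p (…, 2) by angles theta (…)."""
    c, s = np.cos(theta), np.sin(theta)
    px, py = p[..., 0], p[..., 1]
    out = np.empty(np.broadcast_shapes(c.shape if hasattr(c, "shape") else (), px.shape) + (2,),
                   dtype=np.result_type(theta, p))
    out[..., 0] = c * px - s * py
    out[..., 1] = s * px + c * py
    return out


def _perp(v):
    """z-hat cross v for planar vectors: (-v_y, v_x)."""
    out = np.empty_like(v)
    out[..., 0] = -v[..., 1]
    out[..., 1] = v[..., 0]
    return out


class PlanarKinematics:
    """Precomputed tree structure plus forward-kinematics evaluation.

    The root joint must be the first joint and of type ``planar-free``
    with coordinates ordered (x, y, pitch).
    """

    def __init__(self, model: MusculoskeletalModel):
        self.model = model
        root_joint = model.joints[0]
        if root_joint.type != "planar-free":
            raise ValueError("first joint must be the planar-free root joint")
        self.ix, self.iy, self.ipitch = (model.coord_index(c) for c in root_joint.coordinates)
        self.root_segment = model._seg_index[root_joint.child]

        n = len(model.segments)
        self.parent = np.full(n, -1, dtype=int)  # parent segment index
        self.joint_of = np.full(n, -1, dtype=int)  # joint index attaching segment
        self.coord_of = np.full(n, -1, dtype=int)  # revolute coordinate index
        for k, j in enumerate(model.joints):
            ci = model._seg_index[j.child]
            self.joint_of[ci] = k
            if j.parent is not None:
                self.parent[ci] = model._seg_index[j.parent]
                self.coord_of[ci] = model.coord_index(j.coordinates[0])
        # topological order (parents before children)
        order, seen = [], set()

        def visit(i):
            if i in seen:
                return
            if self.parent[i] >= 0:
                visit(self.parent[i])
            seen.add(i)
            order.append(i)

        for i in range(n):
            visit(i)
        self.order = order
        # rotational ancestor coordinates per segment (incl. root pitch)
        self.rot_ancestors: list[list[int]] = []
        for i in range(n):
            anc = [self.ipitch]
            chain = []
            k = i
            while self.parent[k] >= 0:
                chain.append(self.coord_of[k])
                k = self.parent[k]
            anc.extend(reversed(chain))
            self.rot_ancestors.append(anc)
        # world origin of the rotation attached to coordinate c lives at the
        # origin of the segment whose joint carries c (root pitch: root origin)
        self.coord_segment = {self.ipitch: self.root_segment}
        for i in range(n):
            if self.coord_of[i] >= 0:
                self.coord_segment[self.coord_of[i]] = i

    # ------------------------------------------------------------------
    def frames(self, q, scaled: ScaledModel, qdot=None, qddot=None):
        """World frames of every segment, with optional velocity level.

        Parameters are batched: ``q`` has shape (..., nq).  Returns a dict
        with per-segment arrays stacked on axis -2 (origins) / -1 (angles):
        ``origin`` (..., nseg, 2), ``theta`` (..., nseg), and when
        ``qdot``/``qddot`` are given also ``v_origin``, ``omega``,
        ``a_origin``, ``alpha``.
        """
        q = np.asarray(q)
        nseg = len(self.model.segments)
        batch = q.shape[:-1]
        dtype = np.result_type(q, scaled.joint_offsets)
        origin = np.zeros(batch + (nseg, 2), dtype=dtype)
        theta = np.zeros(batch + (nseg,), dtype=dtype)
        want_vel = qdot is not None
        want_acc = qddot is not None
        if want_vel:
            qdot = np.asarray(qdot)
            dtype = np.result_type(dtype, qdot)
            v_origin = np.zeros(batch + (nseg, 2), dtype=dtype)
            omega = np.zeros(batch + (nseg,), dtype=dtype)
        if want_acc:
            qddot = np.asarray(qddot)
            dtype = np.result_type(dtype, qddot)
            a_origin = np.zeros(batch + (nseg, 2), dtype=dtype)
            alpha = np.zeros(batch + (nseg,), dtype=dtype)

        for i in self.order:
            if self.parent[i] < 0:
                origin[..., i, 0] = q[..., self.ix]
                origin[..., i, 1] = q[..., self.iy]
                theta[..., i] = q[..., self.ipitch]
                if want_vel:
                    v_origin[..., i, 0] = qdot[..., self.ix]
                    v_origin[..., i, 1] = qdot[..., self.iy]
                    omega[..., i] = qdot[..., self.ipitch]
                if want_acc:
                    a_origin[..., i, 0] = qddot[..., self.ix]
                    a_origin[..., i, 1] = qddot[..., self.iy]
                    alpha[..., i] = qddot[..., self.ipitch]
                continue
            p = self.parent[i]
            off = scaled.joint_offsets[self.joint_of[i]]
            r = _rot(theta[..., p], np.broadcast_to(off, batch + (2,)))
            origin[..., i, :] = origin[..., p, :] + r
            theta[..., i] = theta[..., p] + q[..., self.coord_of[i]]
            if want_vel:
                omega[..., i] = omega[..., p] + qdot[..., self.coord_of[i]]
                v_origin[..., i, :] = v_origin[..., p, :] + omega[..., p, None] * _perp(r)
            if want_acc:
                alpha[..., i] = alpha[..., p] + qddot[..., self.coord_of[i]]
                a_origin[..., i, :] = (
                    a_origin[..., p, :]
                    + alpha[..., p, None] * _perp(r)
                    - omega[..., p, None] ** 2 * r
                )

        out = {"origin": origin, "theta": theta}
        if want_vel:
            out["v_origin"] = v_origin
            out["omega"] = omega
        if want_acc:
            out["a_origin"] = a_origin
            out["alpha"] = alpha
        return out

    # ------------------------------------------------------------------
    def point_world(self, frames, segment: int, p_local):
        """World position of a point fixed in a segment frame (scaled already)."""
        th = frames["theta"][..., segment]
        return frames["origin"][..., segment, :] + _rot(th, np.broadcast_to(p_local, th.shape + (2,)))

    def point_velocity(self, frames, segment: int, p_local):
        th = frames["theta"][..., segment]
        r = _rot(th, np.broadcast_to(p_local, th.shape + (2,)))
        return frames["v_origin"][..., segment, :] + frames["omega"][..., segment, None] * _perp(r)

    def point_jacobian_columns(self, frames, segment: int, p_world):
        """Nonzero columns of the translational point Jacobian.

        Returns ``(coord_indices, columns)`` where columns has shape
        (..., n_cols, 2): the root translations contribute unit columns
        and every rotational ancestor coordinate c contributes
        z-hat x (p - o_c) with o_c the world origin of that rotation.
        """
        cols_idx = [self.ix, self.iy] + self.rot_ancestors[segment]
        batch = p_world.shape[:-1]
        cols = np.zeros(batch + (len(cols_idx), 2), dtype=p_world.dtype)
        cols[..., 0, 0] = 1.0
        cols[..., 1, 1] = 1.0
        for k, c in enumerate(self.rot_ancestors[segment]):
            o_c = frames["origin"][..., self.coord_segment[c], :]
            cols[..., 2 + k, :] = _perp(p_world - o_c)
        return cols_idx, cols

    # ------------------------------------------------------------------
    def inverse_dynamics(self, q, qdot, qddot, scaled: ScaledModel, gravity=None):
        """Generalized forces M(q) qddot + C(q, qdot) + G(q).

        Computed by propagating accelerations down the tree and
        assembling Jacobian-transpose contributions of every body's
        Newton-Euler wrench (gravity included as a COM force), which for
        a tree structure equals the standard inverse dynamics.  Signs:
        the returned vector is the applied generalized force required to
        realize ``qddot``, i.e. the left-hand side of the equations of
        motion.
        """
        q = np.asarray(q)
        qdot = np.asarray(qdot)
        qddot = np.asarray(qddot)
        fr = self.frames(q, scaled, qdot=qdot, qddot=qddot)
        batch = q.shape[:-1]
        nq = self.model.n_coordinates
        dtype = np.result_type(q, qdot, qddot, scaled.seg_mass)
        tau = np.zeros(batch + (nq,), dtype=dtype)
        g = self.model.gravity if gravity is None else gravity
        for i in range(len(self.model.segments)):
            m = scaled.seg_mass[i]
            izz = scaled.seg_inertia[i]
            rc = _rot(fr["theta"][..., i], np.broadcast_to(scaled.seg_com[i], batch + (2,)))
            p_c = fr["origin"][..., i, :] + rc
            a_c = (
                fr["a_origin"][..., i, :]
                + fr["alpha"][..., i, None] * _perp(rc)
                - fr["omega"][..., i, None] ** 2 * rc
            )
            # force at COM: m * (a_c + g y-hat); torque about COM: I alpha
            f = m * a_c
            f_y = f[..., 1] + m * g
            f = np.stack([f[..., 0], f_y], axis=-1)
            n_z = izz * fr["alpha"][..., i]
            cols_idx, cols = self.point_jacobian_columns(fr, i, p_c)
            for k, c in enumerate(cols_idx):
                tau[..., c] = tau[..., c] + np.sum(cols[..., k, :] * f, axis=-1)
            for c in self.rot_ancestors[i]:
                tau[..., c] = tau[..., c] + n_z
        return tau
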