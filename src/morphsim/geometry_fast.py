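"""Vectorized evaluation of the analytic via-point muscle geometry.

Mathematically identical to :class:`morphsim.geometry.AnalyticGeometry`
(cross-checked in the test suite) but evaluates all muscles and all
batch nodes with array operations, which is what the trajectory
optimizer's Jacobian sweeps need.  Only via-point paths are supported;
the reference implementation handles the pulley variant.
"""

from __future__ import annotations

import numpy as np

from .kinematics import PlanarKinematics, _rot, _perp
from .model import MusculoskeletalModel

__all__ = ["FastGeometry"]


class FastGeometry:
    def __init__(self, model: MusculoskeletalModel, kin: PlanarKinematics | None = None):
        self.model = model
        self.kin = kin or PlanarKinematics(model)
        groups = model.scaling_groups()
        self.group_index = {g: i for i, g in enumerate(groups)}
        pt_seg, pt_local, pt_group = [], [], []
        ea, eb, em = [], [], []
        for mi, m in enumerate(model.muscles):
            if m.path.kind != "via":
                raise ValueError("FastGeometry supports via-point paths only")
            first = len(pt_seg)
            for seg_name, xy in m.path.points:
                seg = model.segment(seg_name)
                pt_seg.append(model._seg_index[seg_name])
                pt_local.append(xy)
                pt_group.append(self.group_index[seg.scaling_group])
            for k in range(len(m.path.points) - 1):
                ea.append(first + k)
                eb.append(first + k + 1)
                em.append(mi)
        self.pt_seg = np.array(pt_seg)
        self.pt_local = np.array(pt_local, dtype=float)
        self.pt_group = np.array(pt_group)
        self.ea, self.eb, self.em = np.array(ea), np.array(eb), np.array(em)
        nq = model.n_coordinates
        # rotational-ancestor incidence of each point's segment
        self.rot_coords = sorted(self.kin.coord_segment.keys())
        self.amask = np.zeros((len(pt_seg), nq), dtype=bool)
        for pi, si in enumerate(self.pt_seg):
            for c in self.kin.rot_ancestors[si]:
                self.amask[pi, c] = True
        self.coord_seg = np.zeros(nq, dtype=int)
        for c, s in self.kin.coord_segment.items():
            self.coord_seg[c] = s
        # sparse (edge, coordinate) incidence: a pair contributes to the
        # moment arm only when the coordinate rotates exactly one edge end
        pe, pc, p_aa, p_ab = [], [], [], []
        for e in range(len(self.ea)):
            for c in self.rot_coords:
                aa = self.amask[self.ea[e], c]
                ab = self.amask[self.eb[e], c]
                if aa != ab:
                    pe.append(e)
                    pc.append(c)
                    p_aa.append(1.0 if aa else 0.0)
                    p_ab.append(1.0 if ab else 0.0)
        self.pair_e = np.array(pe)
        self.pair_c = np.array(pc)
        self.pair_m = self.em[self.pair_e]
        self.pair_aa = np.array(p_aa)
        self.pair_ab = np.array(p_ab)

    def eval(self, q, seg_scale, joint_offsets, qdot=None):
        """(l_mt, R, ldot_mt) for all muscles at all batch nodes.

        ``seg_scale`` has shape (n_groups, 3) and may be complex;
        ``joint_offsets`` (n_joints, 2) already scaled.
        """
        q = np.asarray(q)
        kin = self.kin
        frames = kin.frames(q, _Offsets(joint_offsets))
        batch = q.shape[:-1]
        loc = self.pt_local * seg_scale[self.pt_group, :2]  # (P, 2)
        th = frames["theta"][..., self.pt_seg]  # (..., P)
        pw = frames["origin"][..., self.pt_seg, :] + _rot(th, np.broadcast_to(loc, th.shape + (2,)))
        d = pw[..., self.eb, :] - pw[..., self.ea, :]  # (..., E, 2)
        elen = np.sqrt(np.sum(d * d, axis=-1))
        u = d / elen[..., None]
        nm, nq = self.model.n_muscles, self.model.n_coordinates
        dtype = pw.dtype
        lmt = np.zeros(batch + (nm,), dtype=dtype)
        lmt_t = np.moveaxis(lmt, -1, 0)
        np.add.at(lmt_t, self.em, np.moveaxis(elen, -1, 0))
        # moment arms via the sparse (edge, coordinate) incidence: each
        # pair contributes -u . d(P_b - P_a)/dq_c with dP/dq_c the planar
        # point-Jacobian column perp(P - O_c) of the rotated end only
        o_c = frames["origin"][..., self.coord_seg[self.pair_c], :]  # (..., K, 2)
        pa = pw[..., self.ea[self.pair_e], :]
        pb = pw[..., self.eb[self.pair_e], :]
        rel = (_perp(pb - o_c) * self.pair_ab[:, None]
               - _perp(pa - o_c) * self.pair_aa[:, None])
        contrib = np.sum(u[..., self.pair_e, :] * rel, axis=-1)  # (..., K)
        R = np.zeros(batch + (nm, nq), dtype=dtype)
        R_mt = np.moveaxis(contrib, -1, 0)  # (K, ...)
        R_dst = np.moveaxis(R, (len(batch), len(batch) + 1), (0, 1))  # (nm, nq, ...)
        np.add.at(R_dst, (self.pair_m, self.pair_c), -R_mt)
        ldot = None
        if qdot is not None:
            ldot = -np.sum(R * np.asarray(qdot)[..., None, :], axis=-1)
        return lmt, R, ldot


class _Offsets:
    """Duck-typed carrier of scaled joint offsets for the kinematics."""

    def __init__(self, joint_offsets):
        self.joint_offsets = np.asarray(joint_offsets)
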