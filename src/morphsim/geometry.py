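"""Closed-form differentiable muscle-tendon geometry.

Muscle paths are polylines through via points fixed in segment frames
(optionally a pulley path with constant wrap radii about the spanned
joints).  Lengths, moment arms and muscle-tendon velocities are exact,
infinitely differentiable functions of the pose ``q`` and the segment
scale factors ``p_s``: via points scale per axis with their segment's
factors, so the geometry responds to morphology exactly like the
skeleton does.

Sign convention (used package-wide): the moment arm of muscle m about
coordinate j is ``r_mj = -d l_mt / d q_j``; a positive moment arm means
the muscle shortens as q_j increases and produces a positive
generalized torque ``tau_j = r_mj * F_t``.  Muscle-tendon velocity
follows from the tendon-excursion identity, ``ldot_mt = -R qdot``
(equivalently ``(d l_mt/d q) qdot``).
"""

from __future__ import annotations

import numpy as np

from .kinematics import PlanarKinematics, _rot
from .model import Morphology, MusculoskeletalModel, ScaledModel, apply_segment_scaling, segment_scale

__all__ = ["AnalyticGeometry"]


class AnalyticGeometry:
    """Evaluate l_mt, moment arms and velocities for every muscle."""

    def __init__(self, model: MusculoskeletalModel, kin: PlanarKinematics | None = None):
        self.model = model
        self.kin = kin or PlanarKinematics(model)
        for m in model.muscles:
            if m.path is None:
                raise ValueError(f"muscle {m.name!r} has no path definition")
        self._seg_index = model._seg_index

    # ------------------------------------------------------------------
    def _scaled_points(self, muscle, morph: Morphology):
        pts = []
        for seg_name, p in muscle.path.points:
            seg = self.model.segment(seg_name)
            sx, sy, _ = segment_scale(morph, seg)
            pts.append((self._seg_index[seg_name], np.stack([p[0] * sx, p[1] * sy], axis=-1)))
        return pts

    def _polyline(self, muscle, frames, morph: Morphology):
        """World positions of the path points, shape (..., npts, 2)."""
        pts = self._scaled_points(muscle, morph)
        world = [self.kin.point_world(frames, si, pl) for si, pl in pts]
        return [p[0] for p in pts], np.stack(world, axis=-2)

    # ------------------------------------------------------------------
    def eval(self, q, morph: Morphology, qdot=None, scaled: ScaledModel | None = None):
        """(l_mt, R, ldot_mt) for all muscles.

        Shapes: l_mt (..., nm); R (..., nm, nq); ldot_mt (..., nm) or
        None when ``qdot`` is omitted.  ``scaled`` may be passed to
        reuse precomputed joint offsets.
        """
        q = np.asarray(q)
        if scaled is None:
            scaled = apply_segment_scaling(self.model, morph)
        frames = self.kin.frames(q, scaled)
        nm = self.model.n_muscles
        nq = self.model.n_coordinates
        batch = q.shape[:-1]
        dtype = np.result_type(q, scaled.joint_offsets, *[np.asarray(v) for v in morph.p_s.values()])
        lmt = np.zeros(batch + (nm,), dtype=dtype)
        R = np.zeros(batch + (nm, nq), dtype=dtype)
        for mi, muscle in enumerate(self.model.muscles):
            if muscle.path.kind == "via":
                segs, pts = self._polyline(muscle, frames, morph)
                d = pts[..., 1:, :] - pts[..., :-1, :]
                elen = np.sqrt(np.sum(d * d, axis=-1))
                lmt[..., mi] = np.sum(elen, axis=-1)
                u = d / elen[..., None]
                # dl/dq_j = sum_edges u . (dP_k+1/dq_j - dP_k/dq_j); r = -dl/dq
                jac_cols = []
                for k, si in enumerate(segs):
                    idx, cols = self.kin.point_jacobian_columns(frames, si, pts[..., k, :])
                    jac_cols.append(dict(zip(idx, np.moveaxis(cols, -2, 0))))
                for e in range(d.shape[-2]):
                    ua = u[..., e, :]
                    for j, col in jac_cols[e + 1].items():
                        if j in (self.kin.ix, self.kin.iy):
                            continue
                        R[..., mi, j] -= np.sum(ua * col, axis=-1)
                    for j, col in jac_cols[e].items():
                        if j in (self.kin.ix, self.kin.iy):
                            continue
                        R[..., mi, j] += np.sum(ua * col, axis=-1)
            else:  # pulley
                segs, pts = self._polyline(muscle, frames, morph)
                d = pts[..., -1, :] - pts[..., 0, :]
                base = np.sqrt(np.sum(d * d, axis=-1))
                total = base
                for cname, rho in muscle.path.radii.items():
                    j = self.model.coord_index(cname)
                    child = self.model.segments[self.kin.coord_segment[j]]
                    s = segment_scale(morph, child)
                    rho_s = rho * (s[0] + s[1]) / 2.0
                    total = total - rho_s * q[..., j]
                    R[..., mi, j] = R[..., mi, j] + rho_s
                lmt[..., mi] = total
                # base-line contribution to moment arms about spanned joints
                u = d / base[..., None]
                idx0, cols0 = self.kin.point_jacobian_columns(frames, segs[0], pts[..., 0, :])
                idx1, cols1 = self.kin.point_jacobian_columns(frames, segs[-1], pts[..., -1, :])
                for j, col in zip(idx1, np.moveaxis(cols1, -2, 0)):
                    if j not in (self.kin.ix, self.kin.iy):
                        R[..., mi, j] -= np.sum(u * col, axis=-1)
                for j, col in zip(idx0, np.moveaxis(cols0, -2, 0)):
                    if j not in (self.kin.ix, self.kin.iy):
                        R[..., mi, j] += np.sum(u * col, axis=-1)
        ldot = None
        if qdot is not None:
            qdot = np.asarray(qdot)
            ldot = -np.sum(R * qdot[..., None, :], axis=-1)
        return lmt, R, ldot

    # ------------------------------------------------------------------
    def eval_muscle(self, muscle_name: str, q, morph: Morphology):
        """(l_mt, moment-arm row over all coordinates) for one muscle."""
        if muscle_name not in self.model._muscle_index:
            raise KeyError(f"unknown muscle {muscle_name!r}")
        mi = self.model._muscle_index[muscle_name]
        lmt, R, _ = self.eval(q, morph)
        return lmt[..., mi], R[..., mi, :]

    def lmt_anatomical(self, muscle_name: str, morph: Morphology):
        """Muscle-tendon length in the anatomical pose q = 0."""
        q = np.zeros(self.model.n_coordinates)
        l, _ = self.eval_muscle(muscle_name, q, morph)
        return l
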