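"""Scaling-aware skeleton dynamics: passive torques, torque actuators,
Hunt-Crossley foot-ground contact and the implicit equations of motion.

Everything here is a smooth (complex-safe) function of
``(q, qdot, qddot, p_s)``; contact uses a smoothed penetration and a
tanh-regularized friction law so no branch introduces a derivative
discontinuity.  The ground is the plane y = 0; gravity acts along -y.
"""

from __future__ import annotations

import numpy as np

from .kinematics import PlanarKinematics, _rot, _perp
from .model import MusculoskeletalModel, ScaledModel
from .smooth import safe_exp, softplus, smooth_pos as _smooth_pos

__all__ = [
    "passive_joint_torques",
    "mtp_passive_torque",
    "torque_actuator_dynamics",
    "torque_actuator_torque",
    "contact_forces",
    "forward_dynamics_residual",
    "dynamics_components",
]

MTP_PARAMS = {
    "sprint": {"stiffness": 40.0, "damping": 0.4},  # Nm/rad, Nm s/rad
    "marathon": {"stiffness": 25.0, "damping": 1.9},
}


def passive_joint_torques(model: MusculoskeletalModel, q, qdot):
    """Exponential joint-limit torques plus damping, per coordinate.

    tau = k_u1 exp(k_u2 (q - theta_u)) + k_l1 exp(k_l2 (theta_l - q)) - d qdot
    with k_u1 < 0 and k_l1 > 0 so both limit terms restore toward
    mid-range.  Coordinates without passive parameters get zero.
    """
    q = np.asarray(q)
    qdot = np.asarray(qdot)
    tau = np.zeros(np.broadcast_shapes(q.shape, qdot.shape), dtype=np.result_type(q, qdot))
    for j in model.joints:
        if j.passive is None:
            continue
        p = j.passive
        for c in j.coordinates:
            k = model.coord_index(c)
            qi, vi = q[..., k], qdot[..., k]
            tau[..., k] = (
                p.k_u1 * safe_exp(p.k_u2 * (qi - p.theta_u))
                + p.k_l1 * safe_exp(p.k_l2 * (p.theta_l - qi))
                - p.damping * vi
            )
    return tau


def mtp_passive_torque(q_mtp, qdot_mtp, mode: str):
    """Linear spring-damper torque of the metatarsophalangeal joint.

    Sprint: 40 Nm/rad, 0.4 Nm s/rad; marathon: 25 Nm/rad, 1.9 Nm s/rad.
    """
    if mode not in MTP_PARAMS:
        raise ValueError(f"unknown MTP mode {mode!r}; use 'sprint' or 'marathon'")
    p = MTP_PARAMS[mode]
    return -(p["stiffness"] * np.asarray(q_mtp) + p["damping"] * np.asarray(qdot_mtp))


def torque_actuator_dynamics(e_t, a_t, tau: float = 0.035):
    """First-order excitation-to-activation law: da/dt = (e - a)/tau."""
    return (np.asarray(e_t) - np.asarray(a_t)) / tau


def torque_actuator_torque(a_t, gain: float = 150.0):
    """Ideal actuator torque: 150 Nm at saturated activation."""
    return gain * np.asarray(a_t)


# -------------------------------------------------------------------------
# Contact
# -------------------------------------------------------------------------


def contact_forces(kin: PlanarKinematics, q, qdot, scaled: ScaledModel,
                   smoothing: float = 5e-3, v_trans: float = 0.2,
                   stiffness_scale: float = 1.0,
                   return_sphere_forces: bool = False):
    """Generalized forces from sphere-on-plane Hunt-Crossley contact.

    Normal force k * d^p * (1 + 3/2 c ddot) with the penetration d and
    the dissipation bracket passed through smooth positive parts
    (p = 1.5 Hertzian by default; p = 1 a linear compliant layer);
    tangential force -mu F_n tanh(v_x / v_trans).  Identically smooth
    through touchdown; effectively zero when every sphere is above the
    ground beyond the smoothing band.
    """
    model = kin.model
    q = np.asarray(q)
    qdot = np.asarray(qdot)
    frames = kin.frames(q, scaled, qdot=qdot)
    nq = model.n_coordinates
    batch = np.broadcast_shapes(q.shape[:-1], qdot.shape[:-1])
    dtype = np.result_type(q, qdot, scaled.joint_offsets)
    f_gen = np.zeros(batch + (nq,), dtype=dtype)
    per_sphere = []
    for cs in model.contact_spheres:
        si = model._seg_index[cs.segment]
        seg = model.segments[si]
        s = np.asarray(scaled.morphology.p_s[seg.scaling_group])
        loc = np.stack([cs.location[0] * s[0], cs.location[1] * s[1]], axis=-1)
        p = kin.point_world(frames, si, loc)
        v = kin.point_velocity(frames, si, loc)
        depth = cs.radius - p[..., 1]  # penetration of sphere bottom
        d = softplus(depth, smoothing)
        ddot = -v[..., 1]
        bracket = _smooth_pos(1.0 + 1.5 * cs.dissipation * ddot, 5e-2)
        fn = stiffness_scale * cs.stiffness * d ** cs.exponent * bracket
        ft = -cs.friction * fn * np.tanh(v[..., 0] / v_trans)
        force = np.stack([ft, fn], axis=-1)
        idx, cols = kin.point_jacobian_columns(frames, si, p)
        for k, c in enumerate(idx):
            f_gen[..., c] = f_gen[..., c] + np.sum(cols[..., k, :] * force, axis=-1)
        per_sphere.append((cs.name, p, force))
    if return_sphere_forces:
        return f_gen, per_sphere
    return f_gen


# -------------------------------------------------------------------------
# Equations of motion
# -------------------------------------------------------------------------


def forward_dynamics_residual(kin: PlanarKinematics, q, qdot, qddot, tau_applied,
                              scaled: ScaledModel, include_contact: bool = True,
                              include_passive: bool = True):
    """Implicit skeleton dynamics residual.

    residual = M(q) qddot + C(q, qdot) + G(q) - tau_applied - tau_pas - f_c

    where ``tau_applied`` already contains muscle and actuator torques
    (pass zeros for a ballistic skeleton).  Zero iff the equations of
    motion hold; smooth in every input including the morphology inside
    ``scaled``.
    """
    tau_id = kin.inverse_dynamics(q, qdot, qddot, scaled)
    rhs = np.asarray(tau_applied)
    if include_passive:
        rhs = rhs + passive_joint_torques(kin.model, q, qdot)
    if include_contact:
        rhs = rhs + contact_forces(kin, q, qdot, scaled)
    return tau_id - rhs


def dynamics_components(kin: PlanarKinematics, q, qdot, scaled: ScaledModel):
    """(M, G, C) with the sign convention qddot = M^-1 (G + C + tau + f_c).

    M is the symmetric mass matrix; G collects gravity loads and C the
    Coriolis/centrifugal loads, both moved to the right-hand side.
    Batched over leading axes of q.
    """
    q = np.asarray(q)
    qdot = np.asarray(qdot)
    nq = kin.model.n_coordinates
    zero = np.zeros_like(q)
    g_load = kin.inverse_dynamics(q, zero, zero, scaled)
    c_load = kin.inverse_dynamics(q, qdot, zero, scaled) - g_load
    batch = q.shape[:-1]
    M = np.zeros(batch + (nq, nq), dtype=g_load.dtype)
    for k in range(nq):
        e = np.zeros_like(q)
        e[..., k] = 1.0
        M[..., :, k] = kin.inverse_dynamics(q, zero, e, scaled) - g_load
    return M, -g_load, -c_load
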