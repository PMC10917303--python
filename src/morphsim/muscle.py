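"""Hill-type muscle-tendon machinery.

Characteristic curves follow the smooth tanh/exponential/Gaussian
parameterization that is standard for direct-collocation gait work:
active force-length as a sum of three Gaussians (peak 1 at normalized
length 1), passive force-length exponential, logarithmic force-velocity
(value 1 at zero velocity), and an exponential tendon force-strain
curve parameterized by the dimensionless stiffness ``k_t``.  All
coefficients live in :class:`HillCurves` and can be overridden from
config; the package's guarantees depend only on the normalization
properties, not on specific coefficients.

Contraction dynamics are implicit with tendon force as a state: given
``(F_t, dF_t/dt, l_mt, ldot_mt)`` the fiber state follows from
inverting the tendon curve under a constant-width pennation model, and
the residual expresses the Hill equilibrium
``F_t = cos(alpha) * F_max_iso * (a f_act f_v + f_pas + beta vtilde)``.
The residual is returned on the normalized (dimensionless) force scale
for conditioning; it is zero iff the equilibrium holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .smooth import safe_exp, soft_floor

__all__ = [
    "HillCurves",
    "ActivationParams",
    "activation_dynamics",
    "hill_curves_eval",
    "fiber_state_from_tendon",
    "contraction_dynamics_residual",
    "muscle_joint_torques",
    "initialize_tendon_forces",
]


@dataclass
class HillCurves:
    """Coefficient set for the four characteristic curves."""

    # active force-length Gaussians (amplitude, center, width, width-slope)
    afl: tuple = (
        (0.815, 1.055, 0.162, 0.063),
        (0.433, 0.717, -0.030, 0.200),
        (0.100, 1.000, 0.354, 0.000),
    )
    # passive force-length
    kpe: float = 4.0
    e0: float = 0.6
    # force-velocity (logarithmic)
    d1: float = -0.318
    d2: float = -8.149
    d3: float = -0.374
    d4: float = 0.886
    # tendon force-strain: f_T = c1 exp(k_t (lt_norm - c2)) - c3
    c1: float = 0.2
    c2: float = 0.995
    c3: float = 0.25
    # fiber damping (normalized) and max shortening velocity in l_opt/s
    beta: float = 0.01
    v_max: float = 10.0

    def f_act(self, ln):
        out = 0.0
        for b1, b2, b3, b4 in self.afl:
            w = b3 + b4 * ln
            out = out + b1 * np.exp(-0.5 * (ln - b2) ** 2 / w**2)
        return out

    def f_pas(self, ln):
        return (safe_exp(self.kpe * (ln - 1.0) / self.e0) - 1.0) / (np.exp(self.kpe) - 1.0)

    def f_v(self, vn):
        z = self.d2 * vn + self.d3
        return self.d1 * np.log(z + np.sqrt(z**2 + 1.0)) + self.d4

    def f_tendon(self, lt_norm, k_t):
        return self.c1 * safe_exp(k_t * (lt_norm - self.c2)) - self.c3

    def lt_norm_from_force(self, ft_norm, k_t):
        """Invert the tendon curve: normalized tendon length from F_t/F_max.

        The argument is soft-floored away from zero so the inversion
        stays defined at transiently non-physical (negative) forces.
        """
        arg = soft_floor(ft_norm + self.c3, 0.02)
        return self.c2 + np.log(arg / self.c1) / k_t


DEFAULT_CURVES = HillCurves()


@dataclass
class ActivationParams:
    """First-order activation dynamics with a smooth rate blend."""

    tau_act: float = 0.015  # s
    tau_deact: float = 0.060  # s
    # half-width of the sigmoid blend in (e - a); the wide default keeps
    # the rate law gently nonlinear for the optimizer, while small values
    # recover the sharp two-rate limit used when fitting time constants
    blend_width: float = 0.5

    def validate(self):
        if self.tau_act <= 0 or self.tau_deact <= 0:
            raise ValueError("activation time constants must be > 0")


DEFAULT_ACTIVATION = ActivationParams()


def activation_dynamics(e_m, a_m, params: ActivationParams = DEFAULT_ACTIVATION):
    """da/dt: (e-a)/tau_act when e > a, (e-a)/tau_deact when e < a, smoothly blended."""
    d = e_m - a_m
    s = 0.5 * (1.0 + np.tanh(d / params.blend_width))
    rate = s / params.tau_act + (1.0 - s) / params.tau_deact
    return d * rate


def hill_curves_eval(curves: HillCurves, ln, vn, tendon_strain, k_t=35.0):
    """(f_act, f_pas, f_v, f_tendon) at normalized fiber length ``ln``,
    normalized fiber velocity ``vn`` and tendon strain."""
    return (
        curves.f_act(ln),
        curves.f_pas(ln),
        curves.f_v(vn),
        curves.f_tendon(1.0 + np.asarray(tendon_strain), k_t),
    )


def fiber_state_from_tendon(ft_norm, dft_norm, l_mt, ldot_mt, l_m_opt, l_t_slack, alpha_m, k_t,
                            curves: HillCurves = DEFAULT_CURVES):
    """Fiber kinematics implied by the tendon state (constant-width pennation).

    Returns (ln, vn, cos_alpha, l_t) with ln = l_m / l_m_opt and
    vn = ldot_m / (v_max l_m_opt).
    """
    lt_norm = curves.lt_norm_from_force(ft_norm, k_t)
    l_t = lt_norm * l_t_slack
    w = l_m_opt * np.sin(alpha_m)  # constant fiber width
    # minimum-fiber-length guard: the projected fiber length floors
    # smoothly at a quarter of the optimal length, so a slack muscle
    # keeps a well-defined, mildly curved fiber state
    proj = soft_floor(l_mt - l_t, 0.25 * l_m_opt, eps=0.05 * l_m_opt)
    l_m = np.sqrt(proj**2 + w**2)
    cos_a = proj / l_m
    # tendon rate from dF_t/dt:  dft = c1 k exp(.) * ldot_t / l_t_slack
    ldot_t = dft_norm * l_t_slack / (k_t * soft_floor(ft_norm + curves.c3, 0.02))
    ldot_m = (ldot_mt - ldot_t) * cos_a
    ln = l_m / l_m_opt
    vn = ldot_m / (curves.v_max * l_m_opt)
    return ln, vn, cos_a, l_t


def contraction_dynamics_residual(a_m, f_t, dft_dt, l_mt, ldot_mt, params,
                                  curves: HillCurves = DEFAULT_CURVES,
                                  normalized: bool = False):
    """Implicit Hill contraction residual (dimensionless).

    ``params`` is a :class:`morphsim.model.ScaledMuscle` (or anything
    with f_max_iso, l_m_opt, l_t_slack, alpha_m, k_t).  With
    ``normalized=True``, ``f_t`` and ``dft_dt`` are already on the
    F/F_max_iso scale.  Zero iff the Hill equilibrium holds; smooth in
    every input (a non-physical fiber state yields a nonzero, still
    finite and differentiable residual rather than an exception).
    """
    if normalized:
        ftn, dftn = f_t, dft_dt
    else:
        ftn = f_t / params.f_max_iso
        dftn = dft_dt / params.f_max_iso
    ln, vn, cos_a, _ = fiber_state_from_tendon(
        ftn, dftn, l_mt, ldot_mt, params.l_m_opt, params.l_t_slack, params.alpha_m, params.k_t, curves
    )
    fce = a_m * curves.f_act(ln) * curves.f_v(vn) + curves.f_pas(ln) + curves.beta * vn
    return cos_a * fce - ftn


def muscle_joint_torques(f_t, R):
    """tau = R^T-contraction of tendon forces onto coordinates.

    ``f_t`` (..., nm) in N, ``R`` (..., nm, nq) in m, positive moment
    arm => positive torque.  Linear in the forces.
    """
    f_t = np.asarray(f_t)
    R = np.asarray(R)
    if f_t.shape[-1] != R.shape[-2]:
        raise ValueError(f"force vector length {f_t.shape[-1]} != moment-arm rows {R.shape[-2]}")
    return np.sum(R * f_t[..., :, None], axis=-2)


def initialize_tendon_forces(scaled_muscles, a_m, l_mt, curves: HillCurves = DEFAULT_CURVES):
    """Static-equilibrium tendon forces at zero velocities (per muscle root find).

    Returns forces in N.  When no equilibrium exists in bounds the
    passive-only force at a rigid tendon is used as a fallback.
    """
    a_m = np.atleast_1d(a_m)
    l_mt = np.atleast_1d(l_mt)
    out = np.zeros(len(scaled_muscles))
    for i, p in enumerate(scaled_muscles):
        def res(ftn, p=p, i=i):
            return float(
                contraction_dynamics_residual(
                    a_m[i], ftn, 0.0, l_mt[i], 0.0, p, curves, normalized=True
                )
            )
        lo, hi = 1e-8, 3.5
        try:
            flo, fhi = res(lo), res(hi)
            if flo * fhi > 0:
                raise ValueError
            out[i] = brentq(res, lo, hi, xtol=1e-12, rtol=1e-12) * p.f_max_iso
        except ValueError:
            # passive fallback: rigid tendon at slack
            w = p.l_m_opt * np.sin(p.alpha_m)
            proj = l_mt[i] - p.l_t_slack
            l_m = np.sqrt(proj**2 + w**2)
            fp = max(curves.f_pas(l_m / p.l_m_opt), 0.0)
            out[i] = fp * p.f_max_iso * proj / l_m
    return out
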