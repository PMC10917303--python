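"""Smooth numerical safeguards.

The trajectory optimizer may evaluate model functions at iterates that
transiently violate the physical variable bounds.  Every model function
must therefore stay finite and at least C^1 on the whole real line;
these helpers implement the standard guards: a smooth positive part, a
soft floor, and an exponential with linear extension above a cap.  All
are complex-analytic in the operative branch, so complex-step
differentiation remains exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["smooth_pos", "soft_floor", "safe_exp"]


def smooth_pos(x, eps):
    """0.5 (x + sqrt(x^2 + eps^2)): smooth max(x, 0); equals x up to
    O(eps^2 / x) for x >> eps."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def soft_floor(x, lo, eps=1e-4):
    """Smooth max(x, lo); deviation from x is O(eps^2) for x >> lo."""
    return lo + smooth_pos(x - lo, eps)


def softplus(x, eps):
    """eps * log(1 + exp(x / eps)): smooth max(x, 0) whose tail decays
    exponentially (negligible a few eps below zero, equals x a few eps
    above); linear extension of the exponent keeps it overflow-free."""
    x = np.asarray(x)
    t = x / eps
    big = np.real(t) > 30.0
    small = np.real(t) < -30.0
    t_safe = np.where(big | small, 0.0, t)
    out = eps * np.log1p(np.exp(t_safe))
    return np.where(big, x, np.where(small, 0.0 * x, out))


def safe_exp(x, cap=30.0):
    """exp(x) for x <= cap, linear extension exp(cap)(1 + x - cap) above;
    continuous with continuous first derivative, never overflows."""
    x = np.asarray(x)
    big = np.real(x) > cap
    out = np.exp(np.where(big, 0.0, x))
    return np.where(big, np.exp(cap) * (1.0 + (x - cap)), out)
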