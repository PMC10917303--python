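"""Radau collocation grids.

Degree-d Radau IIA nodes on (0, 1] (right endpoint included), with the
Lagrange-basis differentiation matrix, continuity vector and quadrature
weights used by the transcription: on one mesh interval of length h
with interval-start state X_0 and node states X_1..X_d,

    sum_r C[r, j] X_r = h * f(X_j, U_j)      (collocation equations)
    X_end = sum_r D[r] X_r                   (= X_d for Radau)
    integral ~= h * sum_j B[j] L(X_j, U_j)   (quadrature)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre, polynomial as P

__all__ = ["CollocationGrid", "radau_points", "build_collocation_grid"]


def radau_points(degree: int) -> np.ndarray:
    """Radau IIA collocation points on (0, 1], right endpoint included.

    The points are the roots of P_{d-1}(x) - P_d(x) (Legendre), mapped
    from [-1, 1] to [0, 1]; x = 1 is always a root.
    """
    if degree < 1 or degree > 9:
        raise ValueError(f"unsupported collocation degree {degree}")
    c = np.zeros(degree + 1)
    c[degree - 1] = 1.0
    c[degree] = -1.0
    roots = legendre.legroots(c)
    pts = np.sort((np.real(roots) + 1.0) / 2.0)
    pts[-1] = 1.0
    return pts


@dataclass
class CollocationGrid:
    """Nodes and weights of a Radau scheme on n_mesh intervals."""

    n_mesh: int
    degree: int
    tau: np.ndarray  # collocation points, shape (degree,), in (0, 1]
    C: np.ndarray  # (degree+1, degree) differentiation matrix
    D: np.ndarray  # (degree+1,) end-state interpolation
    B: np.ndarray  # (degree,) quadrature weights

    @property
    def n_nodes(self) -> int:
        """Total collocation nodes over the mesh."""
        return self.n_mesh * self.degree

    def interpolate_controls(self, u_nodes, s):
        """Lagrange interpolation of per-node control values at local
        time s in [0, 1] of one interval; u_nodes shape (degree, nu)."""
        vals = np.zeros(u_nodes.shape[1])
        for j in range(self.degree):
            lj = 1.0
            for r in range(self.degree):
                if r != j:
                    lj *= (s - self.tau[r]) / (self.tau[j] - self.tau[r])
            vals += lj * u_nodes[j]
        return vals


def build_collocation_grid(n_mesh: int, degree: int = 3) -> CollocationGrid:
    if n_mesh < 1:
        raise ValueError("n_mesh must be >= 1")
    tau = radau_points(degree)
    pts = np.concatenate([[0.0], tau])  # basis points t_0..t_d
    d = degree
    C = np.zeros((d + 1, d))
    D = np.zeros(d + 1)
    B = np.zeros(d)
    for r in range(d + 1):
        # Lagrange basis polynomial L_r over pts
        coeffs = np.array([1.0])
        for k in range(d + 1):
            if k != r:
                coeffs = P.polymul(coeffs, np.array([-pts[k], 1.0]) / (pts[r] - pts[k]))
        D[r] = P.polyval(1.0, coeffs)
        dcoeffs = P.polyder(coeffs)
        for j in range(d):
            C[r, j] = P.polyval(tau[j], dcoeffs)
        integ = P.polyint(coeffs)
        if r >= 1:
            B[r - 1] = P.polyval(1.0, integ) - P.polyval(0.0, integ)
    return CollocationGrid(n_mesh=n_mesh, degree=degree, tau=tau, C=C, D=D, B=B)
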