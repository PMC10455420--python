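"""Shared numerical oracles for the test suite.

These stay independent of the closed-form code paths they check: finite
differences for derivatives, and a general Newton root finder for
equilibria.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root

from cbb_ants import jacobian, rhs


def fd_jacobian(y, p, h_rel: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the vector field."""
    y = np.asarray(y, dtype=float)
    J = np.zeros((3, 3))
    for j in range(3):
        h = h_rel * max(1.0, abs(y[j]))
        e = np.zeros(3)
        e[j] = h
        J[:, j] = (rhs(y + e, p) - rhs(y - e, p)) / (2.0 * h)
    return J


def _safe_rhs(y, p):
    if not np.all(np.isfinite(y)):
        return np.full(3, 1e12)
    return rhs(y, p)


def _safe_jac(y, p):
    if not np.all(np.isfinite(y)):
        return np.eye(3)
    return jacobian(y, p)


def find_roots_from_starts(p, starts, residual_tol: float = 1e-9) -> list[np.ndarray]:
    """Converged Newton roots of the vector field from the given starts."""
    roots = []
    for y0 in starts:
        sol = root(_safe_rhs, y0, args=(p,), jac=_safe_jac, method="hybr")
        if sol.success and np.linalg.norm(_safe_rhs(sol.x, p)) <= residual_tol * (
            1.0 + np.linalg.norm(sol.x)
        ):
            roots.append(sol.x)
    return roots


def matches_some(point, references, tol: float = 1e-6) -> bool:
    """True if the point lies within clustering tolerance of any reference."""
    return any(
        np.linalg.norm(point - ref) <= tol * (1.0 + np.linalg.norm(ref)) for ref in references
    )
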