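"""Vector field, Jacobian and invariance region of the borer-ant system.

State is ``y = (A, I, H)``: adult borers, immature borers, ants.  The
dynamics are

    dA/dt = omega*I - mu*A - alpha*A*H
    dI/dt = phi*A*(1 - I/q) - omega*I - theta*I - delta*I*H
    dH/dt = (r + epsilon*alpha*A + epsilon*delta*I) * H * (1 - H/k)

Adults are recruited by maturation and lost to non-predation mortality and
mass-action ant predation; immatures are produced by oviposition with
logistic regulation at the berry carrying capacity ``q``; the ants grow
logistically towards ``k`` with a growth bonus from consumed prey.

The box ``Omega = [0, omega*q/mu] x [0, q] x [0, k]`` is positively
invariant: the planes ``H = 0`` and ``H = k`` are themselves invariant, and
the vector field points inward on the remaining faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "rhs",
    "jacobian",
    "reduced_rhs",
    "reduced_jacobian",
    "a_max",
    "RegionOmega",
    "omega_region",
]


def _check_state(y, dim: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (dim,):
        raise ValueError(f"state must have shape ({dim},), got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state must be finite, got {y}")
    return y


def rhs(y, p: ModelParams) -> np.ndarray:
    """Time derivative (dA, dI, dH) at state ``y = (A, I, H)``."""
    A, I, H = _check_state(y, 3)
    dA = p.omega * I - p.mu * A - p.alpha * A * H
    dI = p.phi * A * (1.0 - I / p.q) - p.omega * I - p.theta * I - p.delta * I * H
    dH = (p.r + p.epsilon * p.alpha * A + p.epsilon * p.delta * I) * H * (1.0 - H / p.k)
    return np.array([dA, dI, dH])


def jacobian(y, p: ModelParams) -> np.ndarray:
    """3x3 Jacobian of :func:`rhs` evaluated at ``y``."""
    A, I, H = _check_state(y, 3)
    logistic = 1.0 - H / p.k
    growth = p.r + p.epsilon * p.alpha * A + p.epsilon * p.delta * I
    return np.array(
        [
            [-p.mu - p.alpha * H, p.omega, -p.alpha * A],
            [
                p.phi * (1.0 - I / p.q),
                -p.phi * A / p.q - p.omega - p.theta - p.delta * H,
                -p.delta * I,
            ],
            [
                p.epsilon * p.alpha * H * logistic,
                p.epsilon * p.delta * H * logistic,
                growth * (1.0 - 2.0 * H / p.k),
            ],
        ]
    )


def reduced_rhs(y, p: ModelParams) -> np.ndarray:
    """Planar dynamics on the ant-free plane H = 0: (dA, dI)."""
    A, I = _check_state(y, 2)
    dA = p.omega * I - p.mu * A
    dI = p.phi * A * (1.0 - I / p.q) - p.omega * I - p.theta * I
    return np.array([dA, dI])


def reduced_jacobian(y, p: ModelParams) -> np.ndarray:
    A, I = _check_state(y, 2)
    return np.array(
        [
            [-p.mu, p.omega],
            [p.phi * (1.0 - I / p.q), -p.phi * A / p.q - p.omega - p.theta],
        ]
    )


def a_max(p: ModelParams, mu: float | None = None) -> float:
    """Upper bound omega*q/mu of the adult population inside Omega.

    ``mu`` overrides the parameter set's value (the bound is conventionally
    quoted at a reference mortality when mu itself is being varied).
    """
    mu = p.mu if mu is None else float(mu)
    if mu <= 0:
        raise ValueError(f"a_max requires mu > 0, got {mu}")
    return p.omega * p.q / mu


@dataclass(frozen=True)
class RegionOmega:
    """The positively invariant box [0, a_upper] x [0, i_upper] x [0, h_upper]."""

    a_upper: float
    i_upper: float
    h_upper: float

    def contains(self, y, slack: float = 0.0) -> bool:
        A, I, H = np.asarray(y, dtype=float)
        return (
            -slack <= A <= self.a_upper + slack
            and -slack <= I <= self.i_upper + slack
            and -slack <= H <= self.h_upper + slack
        )


def omega_region(p: ModelParams) -> RegionOmega:
    return RegionOmega(a_upper=a_max(p), i_upper=p.q, h_upper=p.k)
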