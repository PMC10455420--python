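"""Closed-form equilibria of the full and predator-free systems.

The full system has four equilibria:

    E1 = (0, 0, 0)                       extinction of everything
    E2 = (q*omega/mu*(B0-1)/B0, q*(B0-1)/B0, 0)      borers without ants
    E3 = (0, 0, k)                       ants alone at capacity
    E4 = (q*omega/(k*alpha+mu)*(Psi0-1)/Psi0, q*(Psi0-1)/Psi0, k)  coexistence

E2 loses biological sense when B0 < 1 (negative components) and collides
with E1 at B0 = 1; E4 likewise against Psi0 and E3.  On the plane H = 0 the
reduced system has the projections E1_reduced = (0,0) and E2_reduced = the
first two components of E2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import reduced_rhs, rhs
from .params import ModelParams
from .thresholds import compute_B0, compute_Psi0

__all__ = ["Equilibrium", "CollisionReport", "equilibria", "reduced_equilibria"]

#: relative tolerance on |threshold - 1| for declaring an equilibrium collision;
#: thresholds are closed-form, so this only needs to absorb rounding noise.
COLLISION_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    label: str
    coords: np.ndarray
    biological_sense: bool
    exists_distinct: bool = True
    collided_with: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))


@dataclass(frozen=True)
class CollisionReport:
    pair: tuple[str, str]
    at_parameter: float  # the mu at which the collision was detected
    condition: str  # which threshold equals 1


def _residual_ok(y: np.ndarray, p: ModelParams, planar: bool = False) -> bool:
    f = reduced_rhs(y, p) if planar else rhs(y, p)
    return float(np.linalg.norm(f)) < 1e-8 * (1.0 + float(np.linalg.norm(y)))


def equilibria(
    p: ModelParams, tol: float = COLLISION_TOL
) -> tuple[list[Equilibrium], list[CollisionReport]]:
    """All four closed-form equilibria, with sense flags and collision reports.

    Biological sense means every component >= 0 (non-strict, so collided
    equilibria with exact zeros stay admissible).  Each equilibrium flagged
    with sense is residual-checked against the vector field as a guard.
    """
    B0 = compute_B0(p)
    Psi0 = compute_Psi0(p)
    collisions: list[CollisionReport] = []

    e1 = Equilibrium("E1", np.zeros(3), biological_sense=True)
    e3 = Equilibrium("E3", np.array([0.0, 0.0, p.k]), biological_sense=True)

    e2_coords = np.array(
        [p.q * p.omega / p.mu * (B0 - 1.0) / B0, p.q * (B0 - 1.0) / B0, 0.0]
    )
    e2_collided = abs(B0 - 1.0) <= tol
    e2 = Equilibrium(
        "E2",
        e2_coords,
        biological_sense=bool(np.all(e2_coords >= 0.0)),
        exists_distinct=not e2_collided,
        collided_with="E1" if e2_collided else None,
    )
    if e2_collided:
        collisions.append(CollisionReport(("E2", "E1"), p.mu, "B0 = 1"))

    lam = p.k * p.alpha + p.mu
    e4_coords = np.array(
        [p.q * p.omega / lam * (Psi0 - 1.0) / Psi0, p.q * (Psi0 - 1.0) / Psi0, p.k]
    )
    e4_collided = abs(Psi0 - 1.0) <= tol
    e4 = Equilibrium(
        "E4",
        e4_coords,
        biological_sense=bool(np.all(e4_coords >= 0.0)),
        exists_distinct=not e4_collided,
        collided_with="E3" if e4_collided else None,
    )
    if e4_collided:
        collisions.append(CollisionReport(("E4", "E3"), p.mu, "Psi0 = 1"))

    eqs = [e1, e2, e3, e4]
    for eq in eqs:
        if eq.biological_sense and not _residual_ok(eq.coords, p):
            raise AssertionError(f"closed-form equilibrium {eq.label} failed residual check")
    return eqs, collisions


def reduced_equilibria(p: ModelParams, tol: float = COLLISION_TOL) -> list[Equilibrium]:
    """Equilibria of the predator-free planar system."""
    B0 = compute_B0(p)
    e1 = Equilibrium("E1_reduced", np.zeros(2), biological_sense=True)
    coords = np.array([p.q * p.omega / p.mu * (B0 - 1.0) / B0, p.q * (B0 - 1.0) / B0])
    collided = abs(B0 - 1.0) <= tol
    e2 = Equilibrium(
        "E2_reduced",
        coords,
        biological_sense=bool(np.all(coords >= 0.0)),
        exists_distinct=not collided,
        collided_with="E1_reduced" if collided else None,
    )
    for eq in (e1, e2):
        if eq.biological_sense and not _residual_ok(eq.coords, p, planar=True):
            raise AssertionError(f"closed-form equilibrium {eq.label} failed residual check")
    return [e1, e2]
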