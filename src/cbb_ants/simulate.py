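"""Numerical integration, invariance checking and convergence detection.

Integration uses an adaptive stiff-capable solver (LSODA) at tight default
tolerances (rtol 1e-8, atol 1e-10).  Non-negativity is never clipped:
a solver defect would surface as an invariance violation instead of being
masked.  Populations are O(10-10^3), so the default convergence tolerance
is 1e-3 absolute over a trailing window of 10% of the integration span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium, equilibria
from .model import RegionOmega, jacobian, omega_region, rhs
from .params import ModelParams
from .stability import LAS, classify

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "check_invariance",
    "ConvergenceResult",
    "detect_convergence",
    "planar_portrait",
    "predicted_attractor",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # shape (n, 3): columns A, I, H
    params: ModelParams
    stats: dict = field(default_factory=dict)

    @property
    def terminal(self) -> np.ndarray:
        return self.y[-1]


def integrate(
    p: ModelParams,
    y0,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 1001,
    method: str = "LSODA",
    warn_outside: bool = True,
) -> Trajectory:
    """Integrate the system from ``y0`` over ``[0, t_end]``.

    A start outside the invariant box triggers a warning, not an error (the
    dynamics are defined on all of the non-negative octant).
    """
    y0 = np.asarray(y0, dtype=float)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if warn_outside and not omega_region(p).contains(y0):
        warnings.warn(f"initial state {y0} lies outside the invariant region")
    t_eval = np.linspace(0.0, float(t_end), n_points)
    sol = solve_ivp(
        lambda t, y: rhs(y, p),
        (0.0, float(t_end)),
        y0,
        method=method,
        jac=lambda t, y: jacobian(y, p),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message} (nfev={sol.nfev})")
    return Trajectory(
        t=sol.t,
        y=sol.y.T,
        params=p,
        stats={"nfev": sol.nfev, "njev": sol.njev, "rtol": rtol, "atol": atol, "method": method},
    )


def check_invariance(
    traj: Trajectory, region: RegionOmega | None = None, slack: float = 1e-6
) -> tuple[bool, tuple[float, str, float] | None]:
    """True iff every sampled state stays in the box up to ``slack``.

    Returns the earliest violation as (time, component, value) otherwise.
    """
    region = omega_region(traj.params) if region is None else region
    uppers = np.array([region.a_upper, region.i_upper, region.h_upper])
    names = ("A", "I", "H")
    low_bad = traj.y < -slack
    high_bad = traj.y > uppers + slack
    bad = low_bad | high_bad
    if not bad.any():
        return True, None
    i, j = np.argwhere(bad)[0]
    return False, (float(traj.t[i]), names[j], float(traj.y[i, j]))


@dataclass(frozen=True)
class ConvergenceResult:
    target_label: str | None
    terminal_distance: float
    converged: bool


def detect_convergence(
    traj: Trajectory,
    candidates: list[Equilibrium] | None = None,
    tol: float = 1e-3,
    window: float | None = None,
) -> ConvergenceResult:
    """Which equilibrium (if any) the trajectory has settled at.

    The trajectory converged to a candidate iff its maximum distance to the
    candidate's coordinates over the trailing ``window`` (default: 10% of
    the span) is below ``tol``.
    """
    if candidates is None:
        candidates = [e for e in equilibria(traj.params)[0] if e.biological_sense]
    span = traj.t[-1] - traj.t[0]
    window = 0.1 * span if window is None else float(window)
    if window > span:
        raise ValueError(f"window {window} exceeds trajectory span {span}")
    tail = traj.y[traj.t >= traj.t[-1] - window]
    best_label, best_dist = None, np.inf
    for eq in candidates:
        if eq.coords.shape != (traj.y.shape[1],):
            continue
        dist = float(np.max(np.linalg.norm(tail - eq.coords, axis=1)))
        if dist < best_dist:
            best_label, best_dist = eq.label, dist
    converged = best_dist < tol
    return ConvergenceResult(best_label if converged else None, best_dist, converged)


def planar_portrait(
    p: ModelParams,
    plane: str,
    starts,
    t_end: float = 5000.0,
    **kwargs,
) -> list[Trajectory]:
    """Trajectories on one of the invariant predator planes.

    ``plane`` is ``"H0"`` (no ants) or ``"Hk"`` (ants at capacity).  Starts
    may be (A, I) pairs, lifted onto the plane, or full (A, I, H) triples
    that must sit exactly on it.
    """
    if plane not in ("H0", "Hk"):
        raise ValueError("plane must be 'H0' or 'Hk'")
    h_plane = 0.0 if plane == "H0" else p.k
    trajs = []
    for start in starts:
        start = np.asarray(start, dtype=float)
        if start.shape == (2,):
            y0 = np.array([start[0], start[1], h_plane])
        elif start.shape == (3,):
            if start[2] != h_plane:
                raise ValueError(f"start {start} is not on plane H = {h_plane}")
            y0 = start
        else:
            raise ValueError(f"start must be length 2 or 3, got shape {start.shape}")
        trajs.append(integrate(p, y0, t_end=t_end, **kwargs))
    return trajs


def predicted_attractor(p: ModelParams) -> Equilibrium:
    """The equilibrium the stability analysis predicts as the attractor for
    interior initial conditions with ants present (H0 > 0).

    In the collision regime mu = mu* (nonhyperbolic E3 = E4) the merged
    ants-only equilibrium still attracts the interior; it is returned there.
    """
    eqs = {e.label: e for e in equilibria(p)[0]}
    verdicts = {c.label: c.verdict for c in classify(p)}
    for label, verdict in verdicts.items():
        if verdict == LAS:
            return eqs[label]
    if verdicts["E3"] == "nonhyperbolic" and verdicts["E4"] == "nonhyperbolic":
        return eqs["E3"]
    raise ValueError("no attracting equilibrium predicted for these parameters")
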