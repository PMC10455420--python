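"""Transcritical-bifurcation certificates and the one-parameter diagram.

Two transcritical bifurcations organise the dynamics as the adult
non-predation mortality mu increases: the coexistence equilibrium E4
crosses the ants-only equilibrium E3 at mu = mu*, and on the ant-free plane
the borer equilibrium crosses the origin at mu = mu**.  Both are certified
with the three Sotomayor scalars

    c1 = w . f_mu,   c2 = w . (Df_mu v),   c3 = w . D2f(v, v)

built from the right/left null eigenvectors v, w of the Jacobian at the
critical parameter; the transcritical case requires c1 = 0 and c2, c3 both
nonzero.  Closed forms exist here (with eigenvectors normalised to second
component 1):

    at E3,  mu*:   c1 = 0,  c2 = -(k*delta+theta+omega)^2/(phi*omega),
                   c3 = -2*(k*delta+theta+omega)/q
    at the planar origin, mu**:  the same with k*delta dropped.

Each scalar is also recomputed by finite differences of the vector field as
an internal cross-check.

The module also provides a numeric instability demonstration for the
extinction equilibrium E1 via the Liapunov function V = H on the half-ball
S of radius rho/2, rho = min(r/(epsilon*sqrt(alpha^2+delta^2)), k): V
strictly increases along trajectories with H > 0 until they leave S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibria import equilibria
from .model import jacobian, reduced_jacobian, reduced_rhs, rhs
from .params import ModelParams
from .simulate import integrate
from .stability import LAS, classify
from .thresholds import compute_mu_star, compute_mu_double_star

__all__ = [
    "SotomayorResult",
    "sotomayor_check",
    "LyapunovDemo",
    "lyapunov_rho",
    "lyapunov_instability_demo",
    "BifurcationDiagram",
    "bifurcation_diagram",
]


@dataclass(frozen=True)
class SotomayorResult:
    equilibrium: str
    mu_bif: float
    v: np.ndarray
    w: np.ndarray
    c1: float
    c2: float
    c3: float
    c1_numeric: float
    c2_numeric: float
    c3_numeric: float
    verdict: str  # "transcritical" | "inconclusive"


def _null_vectors(J: np.ndarray, zero_tol: float) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eig(J)
    i = int(np.argmin(np.abs(vals)))
    if abs(vals[i]) > zero_tol:
        raise ValueError(
            f"no near-zero eigenvalue at the candidate bifurcation point "
            f"(smallest |lambda| = {abs(vals[i]):.3g})"
        )
    v = np.real(vecs[:, i])
    wals, wecs = np.linalg.eig(J.T)
    j = int(np.argmin(np.abs(wals)))
    w = np.real(wecs[:, j])
    # normalise as printed: second component = 1
    if abs(v[1]) < 1e-12 or abs(w[1]) < 1e-12:
        raise ValueError("null eigenvector has vanishing second component")
    return v / v[1], w / w[1]


def sotomayor_check(
    equilibrium: str,
    p: ModelParams,
    mu_bif: float | None = None,
    cross_check_rtol: float = 1e-4,
) -> SotomayorResult:
    """Sotomayor scalars and transcritical verdict at E3 (full system) or
    the planar origin ``E1_reduced`` (ant-free system).

    ``mu_bif`` defaults to the exact closed-form critical value (mu* for
    E3, mu** for the planar origin).  Raises if the Jacobian at ``mu_bif``
    has no near-zero eigenvalue.
    """
    if equilibrium == "E3":
        planar = False
        mu_bif = compute_mu_star(p) if mu_bif is None else float(mu_bif)
        if mu_bif <= 0:
            raise ValueError("mu* <= 0: E3 never loses hyperbolicity for admissible mu")
        p_bif = p.replace(mu=mu_bif)
        y0 = np.array([0.0, 0.0, p.k])
        kdto = p.k * p.delta + p.theta + p.omega
    elif equilibrium == "E1_reduced":
        planar = True
        mu_bif = compute_mu_double_star(p) if mu_bif is None else float(mu_bif)
        p_bif = p.replace(mu=mu_bif)
        y0 = np.zeros(2)
        kdto = p.theta + p.omega
    else:
        raise ValueError(f"no transcritical certificate implemented at {equilibrium!r}")

    f = reduced_rhs if planar else rhs
    jac = reduced_jacobian if planar else jacobian
    J = jac(y0, p_bif)
    scale = 1.0 + np.linalg.norm(J)
    v, w = _null_vectors(J, zero_tol=1e-8 * scale)

    # closed forms (second-component-1 normalisation)
    c1 = 0.0
    c2 = -(kdto**2) / (p.phi * p.omega)
    c3 = -2.0 * kdto / p.q

    # finite-difference cross-check of all three scalars
    h_mu = 1e-6 * max(1.0, mu_bif)
    f_mu = (f(y0, p_bif.replace(mu=mu_bif + h_mu)) - f(y0, p_bif.replace(mu=mu_bif - h_mu))) / (
        2.0 * h_mu
    )
    c1_num = float(w @ f_mu)
    dJ_dmu = (
        jac(y0, p_bif.replace(mu=mu_bif + h_mu)) - jac(y0, p_bif.replace(mu=mu_bif - h_mu))
    ) / (2.0 * h_mu)
    c2_num = float(w @ (dJ_dmu @ v))
    h = 1e-4 * (1.0 + float(np.linalg.norm(y0)))
    d2f_vv = (f(y0 + h * v, p_bif) - 2.0 * f(y0, p_bif) + f(y0 - h * v, p_bif)) / h**2
    c3_num = float(w @ d2f_vv)

    for name, closed, num in (("c2", c2, c2_num), ("c3", c3, c3_num)):
        if abs(closed - num) > cross_check_rtol * abs(closed):
            raise AssertionError(
                f"Sotomayor scalar {name} closed form {closed:.6g} disagrees with "
                f"finite differences {num:.6g}"
            )

    zero_tol = 1e-8 * scale
    transcritical = abs(c1_num) <= zero_tol and abs(c2_num) > zero_tol and abs(c3_num) > zero_tol
    return SotomayorResult(
        equilibrium=equilibrium,
        mu_bif=mu_bif,
        v=v,
        w=w,
        c1=c1,
        c2=c2,
        c3=c3,
        c1_numeric=c1_num,
        c2_numeric=c2_num,
        c3_numeric=c3_num,
        verdict="transcritical" if transcritical else "inconclusive",
    )


def lyapunov_rho(p: ModelParams) -> float:
    """Radius rho = min(r/(epsilon*sqrt(alpha^2+delta^2)), k) of the
    Liapunov neighbourhood around the extinction equilibrium."""
    pred = p.epsilon * np.hypot(p.alpha, p.delta)
    return float(min(p.r / pred, p.k)) if pred > 0 else float(p.k)


@dataclass(frozen=True)
class LyapunovDemo:
    rho: float
    sample_starts: np.ndarray  # (n, 3)
    escape_times: np.ndarray  # (n,)
    min_dVdt_inside: float  # min of dH/dt over all sampled states inside S

    @property
    def all_escaped(self) -> bool:
        return bool(np.all(np.isfinite(self.escape_times)))


def lyapunov_instability_demo(
    p: ModelParams,
    n_starts: int = 20,
    seed: int = 20230675,
    t_end: float = 50_000.0,
) -> LyapunovDemo:
    """Demonstrate instability of E1 with the Liapunov function V = H.

    Starts are drawn in the biologically admissible part of U ∩ S (H > 0,
    inside the half-ball of radius rho/2); each trajectory is integrated
    until it leaves S, and the growth of V = H while inside S is recorded.
    The construction is independent of the net reproduction rate, so it
    covers the nonhyperbolic case B0 = 1.
    """
    rho = lyapunov_rho(p)
    radius = rho / 2.0
    rng = np.random.default_rng(seed)
    starts = []
    while len(starts) < n_starts:
        y = rng.uniform(0.0, radius, size=3)
        if np.linalg.norm(y) < radius and y[2] > 1e-3 * radius:
            starts.append(y)
    starts = np.array(starts)

    escape_times = np.full(n_starts, np.inf)
    min_dVdt = np.inf
    for i, y0 in enumerate(starts):
        traj = integrate(p, y0, t_end=t_end, warn_outside=False)
        norms = np.linalg.norm(traj.y, axis=1)
        inside = norms < radius
        dV = np.array([rhs(y, p)[2] for y in traj.y[inside]])
        if dV.size:
            min_dVdt = min(min_dVdt, float(dV.min()))
        outside_idx = np.flatnonzero(~inside)
        if outside_idx.size:
            escape_times[i] = traj.t[outside_idx[0]]
    return LyapunovDemo(rho, starts, escape_times, float(min_dVdt))


@dataclass(frozen=True)
class BifurcationDiagram:
    mu_grid: np.ndarray
    branches: pd.DataFrame  # columns: mu, label, A, I, H, stable, biological_sense, verdict
    bif_points: dict = field(default_factory=dict)  # {"mu_star": ..., "mu_double_star": ...}


def bifurcation_diagram(
    p: ModelParams,
    mu_min: float,
    mu_max: float,
    n_grid: int = 200,
    include_critical: bool = True,
) -> BifurcationDiagram:
    """Equilibrium branches and their stability over a grid of mu.

    The exact critical values mu* and mu** are inserted into the grid when
    they fall inside the range (so the nonhyperbolic points are sampled);
    a warning is issued when the range misses them.
    """
    if not (0.0 < mu_min < mu_max):
        raise ValueError("need 0 < mu_min < mu_max")
    mu_star = compute_mu_star(p)
    mu_dstar = compute_mu_double_star(p)
    grid = np.linspace(mu_min, mu_max, n_grid)
    for crit, name in ((mu_star, "mu*"), (mu_dstar, "mu**")):
        if mu_min <= crit <= mu_max:
            if include_critical:
                grid = np.sort(np.append(grid, crit))
        else:
            warnings.warn(f"grid [{mu_min}, {mu_max}] does not contain {name} = {crit:.6g}")

    rows = []
    for mu in grid:
        p_mu = p.replace(mu=float(mu))
        eqs, _ = equilibria(p_mu)
        verdicts = {c.label: c.verdict for c in classify(p_mu)}
        for eq in eqs:
            rows.append(
                {
                    "mu": float(mu),
                    "label": eq.label,
                    "A": eq.coords[0],
                    "I": eq.coords[1],
                    "H": eq.coords[2],
                    "stable": verdicts[eq.label] == LAS,
                    "biological_sense": eq.biological_sense,
                    "verdict": verdicts[eq.label],
                }
            )
    return BifurcationDiagram(
        mu_grid=grid,
        branches=pd.DataFrame(rows),
        bif_points={"mu_star": mu_star, "mu_double_star": mu_dstar},
    )
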