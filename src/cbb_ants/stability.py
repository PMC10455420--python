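"""Eigenvalue analysis and stability classification of the equilibria.

All four equilibria of the full system (and both of the reduced planar
system) admit closed-form real eigenvalues, because in each case the
Jacobian block-decouples into the predator direction and a 2x2 borer block
whose discriminant is a sum of squares and positive terms.  The closed
forms are implemented here; ``eigen_numeric`` recomputes them with a dense
eigenvalue solver on the Jacobian as an independent oracle.

Classification follows the mortality-threshold cases: with
mu* < mu** the five regimes

    mu < mu*            coexistence equilibrium E4 is LAS, E1/E2/E3 unstable
    mu = mu*            E4 collides with E3 (transcritical, nonhyperbolic)
    mu* < mu < mu**     E3 (ants only) is LAS; E4 loses biological sense
    mu = mu**           E2 collides with E1 (transcritical on the H=0 plane)
    mu > mu**           E3 LAS; E2 and E4 lose biological sense

E1 is unstable in every regime (a saddle when hyperbolic; by the direct
Liapunov method with V = H when B0 = 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .equilibria import equilibria, reduced_equilibria
from .model import jacobian, reduced_jacobian
from .params import ModelParams
from .thresholds import compute_B0, compute_Psi0, compute_mu_star, compute_mu_double_star

__all__ = [
    "EigenSet",
    "StabilityClassification",
    "NoBiologicalSenseError",
    "eigen_closed_form",
    "eigen_numeric",
    "verdict_from_eigenvalues",
    "classify",
]

LAS = "locally_asymptotically_stable"
SADDLE = "unstable_saddle"
UNSTABLE = "unstable"
NONHYPERBOLIC = "nonhyperbolic"
NO_SENSE = "no_biological_sense"

#: |lambda| below this (scaled by 1 + ||J||) counts as a zero eigenvalue
ZERO_EIG_TOL = 1e-8


class NoBiologicalSenseError(ValueError):
    """Requested analysis at an equilibrium with negative components."""


@dataclass(frozen=True)
class EigenSet:
    label: str
    lambdas: tuple[float, ...]  # ordered per the per-equilibrium labelling
    Lambda: float  # k*alpha + mu
    Delta_sum: float  # k*alpha + k*delta + theta + mu + omega
    method: str  # "closed_form" | "numeric"


@dataclass(frozen=True)
class StabilityClassification:
    label: str
    verdict: str
    governing_condition: str


def _planar_pair(trace: float, disc_sqrt: float) -> tuple[float, float]:
    # (more negative root, sign-determining root) of x^2 - trace*x + det
    return 0.5 * (trace - disc_sqrt), 0.5 * (trace + disc_sqrt)


def eigen_closed_form(label: str, p: ModelParams) -> EigenSet:
    """Closed-form eigenvalues at the named equilibrium.

    The third (or second, planar) slot always holds the eigenvalue whose
    sign is governed by the relevant threshold, so the collision cases show
    the zero there.
    """
    B0 = compute_B0(p)
    Psi0 = compute_Psi0(p)
    Lam = p.k * p.alpha + p.mu
    Delta_sum = p.k * p.alpha + p.k * p.delta + p.theta + p.mu + p.omega

    if label == "E1":
        s = math.sqrt((p.theta - p.mu + p.omega) ** 2 + 4.0 * p.phi * p.omega)
        lam2, lam3 = _planar_pair(-(p.theta + p.mu + p.omega), s)
        lambdas = (p.r, lam2, lam3)
    elif label == "E2":
        if B0 < 1.0:
            raise NoBiologicalSenseError("E2 has no biological sense when B0 < 1")
        lam1 = (
            p.q * p.epsilon * (p.theta + p.omega)
            * (p.alpha * p.omega + p.delta * p.mu) * (B0 - 1.0)
            / (p.phi * p.omega)
            + p.r
        )
        s = math.sqrt((p.mu**2 - p.phi * p.omega) ** 2 + 4.0 * p.mu**3 * (p.theta + p.omega))
        lam2, lam3 = _planar_pair(-(p.mu**2 + p.phi * p.omega) / p.mu, s / p.mu)
        lambdas = (lam1, lam2, lam3)
    elif label == "E3":
        s = math.sqrt(
            (p.k * p.alpha + p.mu - p.k * p.delta - p.theta - p.omega) ** 2
            + 4.0 * p.phi * p.omega
        )
        lam2, lam3 = _planar_pair(-Delta_sum, s)
        lambdas = (-p.r, lam2, lam3)
    elif label == "E4":
        if Psi0 < 1.0:
            raise NoBiologicalSenseError("E4 has no biological sense when Psi0 < 1")
        kdto = p.k * p.delta + p.theta + p.omega
        lam1 = -(
            p.q * p.epsilon * kdto
            * (p.alpha * p.omega + p.k * p.alpha * p.delta + p.delta * p.mu)
            * (Psi0 - 1.0)
            / (p.phi * p.omega)
            + p.r
        )
        s = math.sqrt((Lam**2 - p.phi * p.omega) ** 2 + 4.0 * kdto * Lam**3)
        lam2, lam3 = _planar_pair(-(Lam**2 + p.phi * p.omega) / Lam, s / Lam)
        lambdas = (lam1, lam2, lam3)
    elif label == "E1_reduced":
        s = math.sqrt((p.theta - p.mu + p.omega) ** 2 + 4.0 * p.phi * p.omega)
        lambdas = _planar_pair(-(p.theta + p.mu + p.omega), s)
    elif label == "E2_reduced":
        if B0 < 1.0:
            raise NoBiologicalSenseError("E2_reduced has no biological sense when B0 < 1")
        s = math.sqrt((p.mu**2 - p.phi * p.omega) ** 2 + 4.0 * p.mu**3 * (p.theta + p.omega))
        lambdas = _planar_pair(-(p.mu**2 + p.phi * p.omega) / p.mu, s / p.mu)
    else:
        raise ValueError(f"unknown equilibrium label {label!r}")
    return EigenSet(label, tuple(float(x) for x in lambdas), Lam, Delta_sum, "closed_form")


def _coords_for(label: str, p: ModelParams) -> np.ndarray:
    if label.endswith("_reduced"):
        eqs = {e.label: e for e in reduced_equilibria(p)}
    else:
        eqs = {e.label: e for e in equilibria(p)[0]}
    return eqs[label].coords


def eigen_numeric(label: str, p: ModelParams) -> EigenSet:
    """Numeric eigenvalue oracle at the named equilibrium.

    Eigenvalues of the dense Jacobian, matched to the closed-form labelling
    by nearest closed-form value when the closed form exists (ascending
    order otherwise).  Imaginary parts are checked to be negligible: the
    system has no complex eigenvalues at its equilibria.
    """
    coords = _coords_for(label, p)
    J = reduced_jacobian(coords, p) if label.endswith("_reduced") else jacobian(coords, p)
    eigs = np.linalg.eigvals(J)
    scale = 1.0 + np.linalg.norm(J)
    if np.max(np.abs(eigs.imag)) > 1e-9 * scale:
        raise AssertionError(f"unexpected complex eigenvalues at {label}: {eigs}")
    vals = np.sort(eigs.real)
    try:
        ref = eigen_closed_form(label, p).lambdas
        best = min(
            itertools.permutations(vals),
            key=lambda perm: sum((a - b) ** 2 for a, b in zip(perm, ref)),
        )
        vals = np.array(best)
    except NoBiologicalSenseError:
        pass
    Lam = p.k * p.alpha + p.mu
    Delta_sum = p.k * p.alpha + p.k * p.delta + p.theta + p.mu + p.omega
    return EigenSet(label, tuple(float(v) for v in vals), Lam, Delta_sum, "numeric")


def verdict_from_eigenvalues(lambdas, J_scale: float = 1.0, tol: float = ZERO_EIG_TOL) -> str:
    """Sign-based verdict: LAS / saddle / unstable / nonhyperbolic."""
    lams = np.asarray(lambdas, dtype=float)
    if np.any(np.abs(lams) <= tol * J_scale):
        return NONHYPERBOLIC
    if np.all(lams < 0):
        return LAS
    if np.all(lams > 0):
        return UNSTABLE
    return SADDLE


def _mu_case(p: ModelParams, rel_tol: float = 1e-9) -> int:
    mu_star = compute_mu_star(p)
    mu_dstar = compute_mu_double_star(p)
    tol_s = rel_tol * max(1.0, abs(mu_star))
    tol_d = rel_tol * max(1.0, mu_dstar)
    if abs(p.mu - mu_star) <= tol_s:
        return 2
    if abs(p.mu - mu_dstar) <= tol_d:
        return 4
    if p.mu < mu_star:
        return 1
    if p.mu < mu_dstar:
        return 3
    return 5


def classify(p: ModelParams) -> list[StabilityClassification]:
    """Stability verdict for E1..E4 in the five mortality regimes."""
    case = _mu_case(p)
    B0 = compute_B0(p)
    Psi0 = compute_Psi0(p)
    out: list[StabilityClassification] = []

    if case == 4:
        out.append(StabilityClassification(
            "E1", NONHYPERBOLIC,
            f"B0 = 1 (mu = mu**): zero eigenvalue; unstable by the direct Liapunov method (V = H)",
        ))
    else:
        out.append(StabilityClassification(
            "E1", SADDLE, f"always unstable; B0 = {B0:.6g} sets the sign of the third eigenvalue"
        ))

    if case in (1, 2, 3):
        out.append(StabilityClassification("E2", SADDLE, f"B0 = {B0:.6g} > 1"))
    elif case == 4:
        out.append(StabilityClassification(
            "E2", NONHYPERBOLIC, "B0 = 1: E2 collides with E1 (unstable)"
        ))
    else:
        out.append(StabilityClassification("E2", NO_SENSE, f"B0 = {B0:.6g} < 1"))

    if case == 1:
        out.append(StabilityClassification("E3", SADDLE, f"Psi0 = {Psi0:.6g} > 1"))
    elif case == 2:
        out.append(StabilityClassification(
            "E3", NONHYPERBOLIC,
            "Psi0 = 1 (mu = mu*): transcritical collision with E4; attracts after the exchange",
        ))
    else:
        out.append(StabilityClassification("E3", LAS, f"Psi0 = {Psi0:.6g} < 1"))

    if case == 1:
        out.append(StabilityClassification("E4", LAS, f"Psi0 = {Psi0:.6g} > 1 (mu < mu*)"))
    elif case == 2:
        out.append(StabilityClassification(
            "E4", NONHYPERBOLIC, "Psi0 = 1: E4 collides with E3"
        ))
    else:
        out.append(StabilityClassification("E4", NO_SENSE, f"Psi0 = {Psi0:.6g} < 1"))
    return out
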