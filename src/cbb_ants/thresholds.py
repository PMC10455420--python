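"""Net-reproduction thresholds and the bifurcation values of mu.

Two dimensionless thresholds govern the long-run fate of the borer:

    B0   = phi*omega / (mu*(theta+omega))                 (no predator)
    Psi0 = phi*omega / ((k*alpha+mu)*(k*delta+theta+omega))  (ants at capacity)

Each is a net reproduction rate: expected adult daughters per adult over its
lifetime.  Psi0 < B0 whenever predation acts (k > 0 and alpha+delta > 0).
Solving each threshold = 1 for the adult non-predation mortality mu gives
the two transcritical bifurcation values

    mu*  = phi*omega/(k*delta+theta+omega) - k*alpha      (Psi0 = 1)
    mu** = phi*omega/(theta+omega)                        (B0 = 1)

with mu* < mu** under the same predation condition.  mu* may be negative
when k*alpha exceeds phi*omega/(k*delta+theta+omega); it is reported
verbatim (eradication is then predicted for every mu > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "compute_B0",
    "compute_Psi0",
    "compute_mu_star",
    "compute_mu_double_star",
    "Thresholds",
    "compute_thresholds",
]


def compute_B0(p: ModelParams, mu: float | None = None) -> float:
    """Predator-free net reproduction rate B0 = phi*omega/(mu*(theta+omega))."""
    mu = p.mu if mu is None else float(mu)
    if mu <= 0:
        raise ValueError(f"B0 requires mu > 0, got {mu}")
    return p.phi * p.omega / (mu * (p.theta + p.omega))


def compute_Psi0(p: ModelParams, mu: float | None = None) -> float:
    """Net reproduction rate with the predator at capacity k."""
    mu = p.mu if mu is None else float(mu)
    denom = (p.k * p.alpha + mu) * (p.k * p.delta + p.theta + p.omega)
    if denom <= 0:
        raise ValueError("Psi0 undefined: (k*alpha + mu) must be positive")
    return p.phi * p.omega / denom


def compute_mu_star(p: ModelParams) -> float:
    """Value of mu at which Psi0 = 1 (may be <= 0; reported verbatim)."""
    return p.phi * p.omega / (p.k * p.delta + p.theta + p.omega) - p.k * p.alpha


def compute_mu_double_star(p: ModelParams) -> float:
    """Value of mu at which B0 = 1."""
    return p.phi * p.omega / (p.theta + p.omega)


@dataclass(frozen=True)
class Thresholds:
    B0: float
    Psi0: float
    mu_star: float
    mu_double_star: float

    @property
    def eradication_for_all_mu(self) -> bool:
        """True when mu* <= 0: predation alone drives Psi0 below 1."""
        return self.mu_star <= 0.0


def compute_thresholds(p: ModelParams) -> Thresholds:
    return Thresholds(
        B0=compute_B0(p),
        Psi0=compute_Psi0(p),
        mu_star=compute_mu_star(p),
        mu_double_star=compute_mu_double_star(p),
    )
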