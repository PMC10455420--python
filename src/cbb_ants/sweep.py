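"""Management scenarios: predation rates vs the eradication effort.

Eradication of the borer requires mu >= mu*(alpha, delta).  Translating the
rate into an operational figure, the number of adult borers that must be
killed daily by non-predation means (traps, targeted spraying) is

    required_deaths = ceil(A_max * mu*),   A_max = omega*q/mu_ref,

where A_max is the adult bound of the invariant region at a reference
mortality mu_ref (the lowest mortality considered, 0.03/day by default).
The ceiling matches the "at least this many" reading.  Raising either
predation rate lowers mu* and therefore the required effort; without any
predation the analogous figure uses mu** instead and is much larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import a_max
from .params import ModelParams
from .thresholds import compute_mu_star, compute_mu_double_star

__all__ = ["ScenarioRow", "SweepTable", "sweep", "no_predation_requirement"]

DEFAULT_MU_REF = 0.03


@dataclass(frozen=True)
class ScenarioRow:
    alpha: float
    delta: float
    mu_star: float
    required_deaths: int


@dataclass(frozen=True)
class SweepTable:
    rows: list[ScenarioRow]
    mu_ref: float
    params_base: ModelParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "alpha": r.alpha,
                    "delta": r.delta,
                    "mu_star": r.mu_star,
                    "required_deaths": r.required_deaths,
                }
                for r in self.rows
            ]
        )


def _required_deaths(adult_bound: float, mu_star: float) -> int:
    # mu* <= 0 means predation alone suffices: no extra deaths needed
    return math.ceil(adult_bound * mu_star) if mu_star > 0 else 0


def sweep(
    params_base: ModelParams,
    pairs: list[tuple[float, float]],
    mu_ref: float = DEFAULT_MU_REF,
) -> SweepTable:
    """One scenario row per (alpha, delta) pair, other parameters fixed."""
    if mu_ref <= 0:
        raise ValueError("mu_ref must be positive")
    if not pairs:
        raise ValueError("need at least one (alpha, delta) pair")
    adult_bound = a_max(params_base, mu=mu_ref)
    rows = []
    for alpha, delta in pairs:
        if alpha < 0 or delta < 0:
            raise ValueError(f"predation rates must be non-negative, got ({alpha}, {delta})")
        p = params_base.replace(alpha=float(alpha), delta=float(delta))
        mu_star = compute_mu_star(p)
        rows.append(ScenarioRow(float(alpha), float(delta), mu_star,
                                _required_deaths(adult_bound, mu_star)))
    return SweepTable(rows=rows, mu_ref=float(mu_ref), params_base=params_base)


def no_predation_requirement(p: ModelParams, mu_ref: float = DEFAULT_MU_REF) -> int:
    """Daily adult deaths needed for eradication without any ant predation:
    ceil(A_max * mu**)."""
    if mu_ref <= 0:
        raise ValueError("mu_ref must be positive")
    mu_dstar = compute_mu_double_star(p)
    return _required_deaths(a_max(p, mu=mu_ref), mu_dstar)
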