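"""Seeded synthetic parameter sets and initial states.

All randomized tests draw their inputs here.  Ranges are centred on the
baseline table: carrying capacities and the conversion efficiency are
sampled uniformly, while the per-day rates are sampled log-uniformly so the
net-reproduction thresholds land on both sides of 1.  The ant capacity k is
drawn as a fraction of q (fewer ants than borers).  A master seed is fanned
out into one substream per draw, so extending a batch never reshuffles
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import omega_region
from .params import ModelParams

__all__ = ["ParamRanges", "sample_params", "sample_states_in_omega", "regime_params"]

_RATE_RANGE = (1e-3, 3.0)


@dataclass(frozen=True)
class ParamRanges:
    q: tuple[float, float] = (100.0, 5000.0)
    k_frac: tuple[float, float] = (0.02, 0.2)  # k = k_frac * q
    r: tuple[float, float] = _RATE_RANGE
    alpha: tuple[float, float] = _RATE_RANGE
    delta: tuple[float, float] = _RATE_RANGE
    epsilon: tuple[float, float] = (0.05, 1.0)
    theta: tuple[float, float] = _RATE_RANGE
    mu: tuple[float, float] = _RATE_RANGE
    phi: tuple[float, float] = _RATE_RANGE
    omega: tuple[float, float] = _RATE_RANGE

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            low, high = getattr(self, name)
            if not (low < high):
                raise ValueError(f"range for {name!r} must satisfy low < high")
            if low <= 0:
                raise ValueError(f"range for {name!r} must be positive")


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def sample_params(
    ranges: ParamRanges | None = None, n: int = 1, seed: int = 0
) -> list[ModelParams]:
    """Draw ``n`` independent valid parameter sets."""
    if n <= 0:
        raise ValueError("n must be positive")
    ranges = ranges or ParamRanges()
    out = []
    for child in np.random.SeedSequence(seed).spawn(n):
        rng = np.random.default_rng(child)
        q = rng.uniform(*ranges.q)
        out.append(
            ModelParams(
                q=q,
                k=q * rng.uniform(*ranges.k_frac),
                r=_loguniform(rng, *ranges.r),
                alpha=_loguniform(rng, *ranges.alpha),
                delta=_loguniform(rng, *ranges.delta),
                epsilon=rng.uniform(*ranges.epsilon),
                theta=_loguniform(rng, *ranges.theta),
                mu=_loguniform(rng, *ranges.mu),
                phi=_loguniform(rng, *ranges.phi),
                omega=_loguniform(rng, *ranges.omega),
            )
        )
    return out


def sample_states_in_omega(
    p: ModelParams, n: int = 1, seed: int = 0, positive_H: bool = False
) -> list[np.ndarray]:
    """Uniform draws inside the invariant box of ``p``.

    ``positive_H=True`` keeps the ant component strictly positive (needed
    by attractor tests: the interior basin argument requires H0 > 0).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    region = omega_region(p)
    uppers = np.array([region.a_upper, region.i_upper, region.h_upper])
    out = []
    for child in np.random.SeedSequence(seed).spawn(n):
        rng = np.random.default_rng(child)
        y = rng.uniform(0.0, 1.0, size=3) * uppers
        if positive_H and y[2] <= 0.0:  # measure-zero guard
            y[2] = np.nextafter(0.0, 1.0) * uppers[2]
        out.append(y)
    return out


def regime_params(case: int, base: ModelParams) -> ModelParams:
    """Return ``base`` with mu set to a representative of one of the five
    mortality regimes (1: mu<mu*, 2: mu=mu*, 3: mu*<mu<mu**, 4: mu=mu**,
    5: mu>mu**).  Cases 2 and 4 use the exact closed-form critical values.
    """
    from .thresholds import compute_mu_star, compute_mu_double_star

    mu_star = compute_mu_star(base)
    mu_dstar = compute_mu_double_star(base)
    if case in (1, 2) and mu_star <= 0:
        raise ValueError(
            "mu* <= 0 for these parameters: predation alone eradicates the pest, "
            "so no coexistence regime exists"
        )
    if case == 1:
        mu = 0.03 if 0.03 < mu_star else mu_star / 2.0
    elif case == 2:
        mu = mu_star
    elif case == 3:
        mu = (max(mu_star, 0.0) + mu_dstar) / 2.0
    elif case == 4:
        mu = mu_dstar
    elif case == 5:
        mu = 2.0 * mu_dstar
    else:
        raise ValueError(f"case must be 1..5, got {case}")
    return base.replace(mu=mu)
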