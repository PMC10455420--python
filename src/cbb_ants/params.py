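"""Model parameters and configuration I/O.

The model has ten parameters: two carrying capacities (``q`` for immature
coffee berry borers, ``k`` for predatory ants), the ants' intrinsic growth
rate ``r``, two mass-action predation rates (``alpha`` on adults, ``delta``
on immatures), a biomass conversion efficiency ``epsilon``, the natural
death rate ``theta`` of immatures, the non-predation death rate ``mu`` of
adults, the oviposition rate ``phi`` and the immature-to-adult development
rate ``omega``.  All rates are per day; populations are average counts.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["ModelParams", "load_params", "baseline_params", "PARAM_KEYS"]

PARAM_KEYS = ("q", "k", "r", "alpha", "delta", "epsilon", "theta", "mu", "phi", "omega")


@dataclass(frozen=True)
class ModelParams:
    """Validated parameter set.

    Validation happens once, at construction; downstream operations assume a
    valid instance.  ``alpha = delta = 0`` is allowed (decoupled model: the
    ants follow a pure logistic equation), but ``mu = 0`` is rejected — adult
    borers die of natural causes, and both the adult bound ``omega*q/mu`` and
    the predator-free coexistence equilibrium are undefined without it.
    """

    q: float
    k: float
    r: float
    alpha: float
    delta: float
    epsilon: float
    theta: float
    mu: float
    phi: float
    omega: float

    def __post_init__(self) -> None:
        for name in PARAM_KEYS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be a finite number, got {value!r}")
            object.__setattr__(self, name, float(value))
        for name in ("q", "k", "r", "theta", "mu", "phi", "omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be positive, got {getattr(self, name)}")
        for name in ("alpha", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"predation rate {name!r} must be non-negative")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError(f"conversion efficiency epsilon must lie in (0, 1], got {self.epsilon}")

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_KEYS}


def _from_mapping(mapping: dict) -> ModelParams:
    unknown = set(mapping) - set(PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys in config: {sorted(unknown)}")
    missing = set(PARAM_KEYS) - set(mapping)
    if missing:
        raise ValueError(f"missing parameter keys in config: {sorted(missing)}")
    return ModelParams(**{key: float(mapping[key]) for key in PARAM_KEYS})


def load_params(path: str | Path) -> ModelParams:
    """Read a flat parameter config (JSON or TOML, keys = parameter names)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    elif path.suffix.lower() == ".toml":
        mapping = tomllib.loads(text)
    else:
        # sniff: JSON objects start with '{'
        stripped = text.lstrip()
        mapping = json.loads(text) if stripped.startswith("{") else tomllib.loads(text)
    if not isinstance(mapping, dict):
        raise ValueError("parameter config must be a flat mapping of name -> value")
    return _from_mapping(mapping)


def baseline_params(mu: float | None = None) -> ModelParams:
    """The packaged baseline parameter set (k = q/20; mu defaults to 0.03).

    These values are illustrative, not field-calibrated; the adult
    non-predation death rate ``mu`` is the natural knob to vary.
    """
    fixture = resources.files("cbb_ants.data").joinpath("baseline_params.toml")
    params = _from_mapping(tomllib.loads(fixture.read_text()))
    if mu is not None:
        params = params.replace(mu=mu)
    return params
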