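"""Dimensionless parameters of the two-strain MDOL consortium model.

The model describes a two-step degradation pathway S -> I -> P split
between two strains.  The *Detoxifier* carries out the first reaction
(S -> I) and thereby lowers its own intracellular substrate burden; the
*Embezzler* carries out the second reaction (I -> P) and synthesizes the
final product P -- the sole growth-limiting resource of both strains --
inside its own cytoplasm, privatizing whatever it does not leak.

All quantities are dimensionless.  Symbols follow the standard notation
for this model family:

=============  ===========================================================
``alpha1``     maximum rate of the first reaction (S -> I, Detoxifier)
``alpha2``     maximum rate of the second reaction (I -> P, Embezzler)
``beta2``      half-saturation constant of the second reaction
``bg``         half-saturation constant of product consumption / growth
``Cp``         maximum product-consumption rate
``y``          biomass yield per unit product consumed
``gamma_s``    passive transport coefficient of S across the membrane
``gamma_i``    passive transport coefficient of I
``gamma_p``    passive transport coefficient of P
``rho``        carrying capacity of total biomass
``s0``         initial extracellular substrate concentration
``theta``      degree of substrate toxicity
=============  ===========================================================

Substrate toxicity multiplies the growth rate of each strain by a factor
that decreases with that strain's *intracellular* substrate concentration
(see :func:`mdolsim.well_mixed.toxicity_factor`).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = ["ModelParams", "TOXICITY_FORMS", "load_params", "save_params"]

#: Supported shapes of the growth-inhibition factor t(s_in).
TOXICITY_FORMS = ("none", "reciprocal", "exponential", "linear")


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless rate, transport and growth constants of the batch model.

    Defaults are the representative parameter set used throughout the
    package: y=1e-4, Cp=10, bg=1, alpha1=1e4, alpha2=1e3, beta2=1,
    gamma_s=gamma_i=gamma_p=1, rho=1e-2, with reciprocal substrate
    toxicity of degree theta=0.0032 (the measured toxicity of salicylate
    in the experimental system this model family describes).
    """

    alpha1: float = 1.0e4
    alpha2: float = 1.0e3
    beta2: float = 1.0
    bg: float = 1.0
    Cp: float = 10.0
    y: float = 1.0e-4
    gamma_s: float = 1.0
    gamma_i: float = 1.0
    gamma_p: float = 1.0
    rho: float = 1.0e-2
    s0: float = 100.0
    theta: float = 0.0032
    toxicity_form: str = "reciprocal"
    #: Optional first-order death rate; the dimensionless growth equations
    #: are logistic without explicit death, so this defaults to 0.
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "Cp", "y", "gamma_s", "gamma_i",
                     "gamma_p", "s0", "theta", "death_rate"):
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ValueError(f"parameter {name!r} must be >= 0, got {v!r}")
        for name in ("beta2", "bg", "rho"):
            v = getattr(self, name)
            if not (v > 0.0):
                raise ValueError(f"parameter {name!r} must be > 0, got {v!r}")
        if self.toxicity_form not in TOXICITY_FORMS:
            raise ValueError(
                f"toxicity_form must be one of {TOXICITY_FORMS}, "
                f"got {self.toxicity_form!r}")

    @property
    def effective_theta(self) -> float:
        """Toxicity degree actually applied (0 when toxicity is disabled)."""
        return 0.0 if self.toxicity_form == "none" else self.theta

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _params_from_mapping(data: Mapping[str, Any]) -> ModelParams:
    known = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParams(**data)


def load_params(path: str | pathlib.Path) -> ModelParams:
    """Read a flat YAML/JSON parameter file; unknown keys are rejected."""
    path = pathlib.Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return _params_from_mapping(data)


def save_params(params: ModelParams, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    data = params.as_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
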