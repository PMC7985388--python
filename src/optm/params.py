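"""Laboratory parameter sets for the cumulative transition-metal OP score.

Each set bundles, per metal i:

* ``r_i``   — specific oxidative potential, uM-DTT min^-1 uM^-1, measured
  by a laboratory DTT assay on the dissolved metal;
* ``chi_i`` — water-soluble fraction of the total metal, assumed constant
  in time and space;
* ``f_i``   — multiplicative simulation bias-correction factor (inverse of
  the simulation-to-observation median concentration ratio); by convention
  f_i = 1 when scoring observed concentrations.

Two built-in sets, "CA" and "F", carry the specific-OP values of two
independent laboratories; they share chi and f and differ only in r, and
their spread (roughly an order of magnitude in the summed score) is the
dominant uncertainty of the method.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .metals import METAL_IDS

__all__ = ["OPParameterSet", "builtin_parameters", "load_parameters", "save_parameters"]

_R_CA = {"Cu": 1.80, "Mn": 0.720, "Fe": 0.0361, "V": 0.10, "Ni": 0.106}
_R_F = {"Cu": 7.69, "Mn": 0.398, "Fe": 0.616, "V": 10.0, "Ni": 4.08}
_CHI = {"Cu": 0.66, "Mn": 0.54, "Fe": 0.23, "V": 0.90, "Ni": 0.73}
_F = {"Cu": 0.303, "Mn": 0.833, "Fe": 0.909, "V": 0.385, "Ni": 0.270}


@dataclass(frozen=True)
class OPParameterSet:
    """Per-metal (r, chi, f) triplets for one laboratory parameterization."""

    label: str
    r: Mapping[str, float]
    chi: Mapping[str, float]
    f: Mapping[str, float] = field(default_factory=lambda: dict.fromkeys(METAL_IDS, 1.0))

    def __post_init__(self) -> None:
        for name, mapping in (("r", self.r), ("chi", self.chi), ("f", self.f)):
            missing = set(METAL_IDS) - set(mapping)
            if missing:
                raise ValueError(f"{name} missing metals: {sorted(missing)}")
        for m, v in self.r.items():
            if v < 0:
                raise ValueError(f"r[{m}] must be >= 0, got {v}")
        for m, v in self.chi.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"chi[{m}] must lie in [0, 1], got {v}")
        for m, v in self.f.items():
            if v <= 0:
                raise ValueError(f"f[{m}] must be > 0, got {v}")

    def weight(self, metal: str, apply_f: bool = False) -> float:
        """r_i * chi_i (* f_i), the per-molar-unit score weight of a metal."""
        w = self.r[metal] * self.chi[metal]
        return w * self.f[metal] if apply_f else w

    def with_f(self, f: Mapping[str, float], label: str | None = None) -> "OPParameterSet":
        """Return a copy carrying new bias-correction factors."""
        return dataclasses.replace(self, f=dict(f), label=label or self.label)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "r": dict(self.r),
            "chi": dict(self.chi),
            "f": dict(self.f),
        }


def builtin_parameters(label: str) -> OPParameterSet:
    """Return one of the built-in laboratory parameter sets.

    Parameters
    ----------
    label : {"CA", "F"}
        Which laboratory's specific-OP values to use.  The two sets share
        the water solubilities and bias-correction factors.
    """
    if label == "CA":
        return OPParameterSet("CA", dict(_R_CA), dict(_CHI), dict(_F))
    if label == "F":
        return OPParameterSet("F", dict(_R_F), dict(_CHI), dict(_F))
    raise ValueError(f"unknown parameter-set label {label!r}; valid labels: CA, F")


def load_parameters(path: str | Path) -> OPParameterSet:
    """Read a parameter set from a YAML file (keys: label, r, chi, f)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return OPParameterSet(
            label=str(data.get("label", "custom")),
            r={k: float(v) for k, v in data["r"].items()},
            chi={k: float(v) for k, v in data["chi"].items()},
            f={k: float(v) for k, v in data.get("f", dict.fromkeys(METAL_IDS, 1.0)).items()},
        )
    except KeyError as exc:
        raise ValueError(f"parameter file {path} missing required key {exc}") from None


def save_parameters(params: OPParameterSet, path: str | Path) -> None:
    """Write a parameter set as YAML; round-trips bit-exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
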