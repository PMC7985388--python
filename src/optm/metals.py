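"""Registry of the DTT-active transition metals and mass/molar conversion.

The cumulative oxidative-potential score is built on the five transition
metals that dominate DTT (dithiothreitol) consumption in ambient aerosol:
Cu, Mn, Fe, V and Ni.  Concentrations are handled in ng m^-3 (mass basis)
but the laboratory specific-OP coefficients are per molar unit, so every
scoring step converts to nmol m^-3 using IUPAC standard atomic masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetalSpecies", "METALS", "METAL_IDS", "get_metal", "mass_to_molar"]


@dataclass(frozen=True)
class MetalSpecies:
    """One DTT-active transition metal.

    Attributes
    ----------
    id : str
        Element symbol used throughout the pipeline ("Cu", "Mn", ...).
    oxidation_label : str
        Oxidation state assumed in the laboratory DTT experiments,
        e.g. "Cu(II)"; "Fe(*)" denotes an equal Fe(II)/Fe(III) mix.
    atomic_mass : float
        IUPAC standard atomic mass, g mol^-1.
    """

    id: str
    oxidation_label: str
    atomic_mass: float

    def __post_init__(self) -> None:
        if self.atomic_mass <= 0:
            raise ValueError(f"atomic_mass must be positive, got {self.atomic_mass}")


#: The default registry: exactly the five DTT-active metals, in the
#: conventional reporting order.
METALS: tuple[MetalSpecies, ...] = (
    MetalSpecies("Cu", "Cu(II)", 63.546),
    MetalSpecies("Mn", "Mn(II)", 54.938),
    MetalSpecies("Fe", "Fe(*)", 55.845),
    MetalSpecies("V", "V(V)", 50.942),
    MetalSpecies("Ni", "Ni(II)", 58.693),
)

METAL_IDS: tuple[str, ...] = tuple(m.id for m in METALS)

_BY_ID = {m.id: m for m in METALS}


def get_metal(metal_id: str) -> MetalSpecies:
    """Look up a metal by element symbol; raises KeyError with valid ids."""
    try:
        return _BY_ID[metal_id]
    except KeyError:
        raise KeyError(
            f"unknown metal {metal_id!r}; valid ids: {', '.join(METAL_IDS)}"
        ) from None


def mass_to_molar(value, metal: MetalSpecies | str):
    """Convert a mass concentration (ng m^-3) to molar (nmol m^-3).

    Parameters
    ----------
    value : float or array-like
        Mass concentration, ng m^-3; must be non-negative (NaN allowed,
        propagates).
    metal : MetalSpecies or str
        The metal whose atomic mass divides the value.

    Returns
    -------
    float or ndarray, nmol m^-3.
    """
    if isinstance(metal, str):
        metal = get_metal(metal)
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("mass concentration must be non-negative")
    out = arr / metal.atomic_mass
    return float(out) if np.isscalar(value) else out
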