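"""Tagged concentration containers and the cumulative OP score.

The score for one air sample is

    OP_tm* = sum_i  r_i * chi_i * T_i * f_i        [nmol-DTT min^-1 m^-3]

with T_i the total (soluble + insoluble) concentration of metal i in
nmol m^-3, r_i the laboratory specific OP, chi_i the constant water-soluble
fraction and f_i the simulation bias correction (f_i = 1 for observations).
Because the score is linear in T_i, it decomposes exactly over any tagging
of the concentrations — source category, origin, emission sector — and all
apportionment downstream is plain accounting on those tags.

Concentrations are carried in long format (one value per
time/location/metal/category/origin/sector cell), the natural shape for
both station series and unrolled gridded model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metals import METAL_IDS, get_metal
from .params import OPParameterSet

__all__ = [
    "CATEGORIES",
    "ORIGINS",
    "DUST_SECTOR",
    "KEY_COLUMNS",
    "ConcentrationSet",
    "OPField",
    "SizeClassMap",
    "compute_op",
    "metal_share",
]

CATEGORIES = ("SUB", "COR", "MD")  # anthropogenic submicron / anthropogenic coarse / mineral dust
ORIGINS = ("domestic", "foreign")
DUST_SECTOR = "dust"  # reserved sector tag for mineral-dust entries

KEY_COLUMNS = ["time", "location", "metal", "category", "origin", "sector"]
COLUMNS = KEY_COLUMNS + ["value"]


class SchemaError(ValueError):
    """A long-format table violates the tagged-concentration schema."""


def _validate_frame(df: pd.DataFrame, *, what: str) -> pd.DataFrame:
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{what} missing required columns: {missing_cols}")
    df = df.copy()
    t = pd.to_datetime(df["time"])
    if isinstance(t.dtype, pd.DatetimeTZDtype):
        # serialized with an explicit offset; internally we work in naive
        # local wall-clock time (daily boundaries at local midnight)
        t = t.dt.tz_localize(None)
    df["time"] = t
    df["value"] = pd.to_numeric(df["value"])

    def offending(mask: pd.Series) -> list[int]:
        # 1-based data-row numbers, as a reader of the source CSV would count
        return [int(i) + 1 for i in np.flatnonzero(mask.to_numpy())[:20]]

    bad = ~df["metal"].isin(METAL_IDS)
    if bad.any():
        raise SchemaError(f"{what}: unknown metal ids at rows {offending(bad)}")
    bad = ~df["category"].isin(CATEGORIES)
    if bad.any():
        raise SchemaError(f"{what}: unknown categories at rows {offending(bad)}")
    bad = ~df["origin"].isin(ORIGINS)
    if bad.any():
        raise SchemaError(f"{what}: unknown origins at rows {offending(bad)}")
    bad = (df["category"] == "MD") & (df["sector"] != DUST_SECTOR)
    if bad.any():
        raise SchemaError(
            f"{what}: mineral-dust rows must carry sector {DUST_SECTOR!r}; rows {offending(bad)}"
        )
    bad = (df["category"] != "MD") & (df["sector"] == DUST_SECTOR)
    if bad.any():
        raise SchemaError(
            f"{what}: anthropogenic rows may not carry sector {DUST_SECTOR!r}; rows {offending(bad)}"
        )
    bad = df["value"].notna() & (df["value"] < 0)
    if bad.any():
        raise SchemaError(f"{what}: negative values at rows {offending(bad)}")
    dup = df.duplicated(KEY_COLUMNS, keep=False)
    if dup.any():
        raise SchemaError(f"{what}: duplicate tag cells at rows {offending(dup)}")
    return df


def _conservative_sum(df: pd.DataFrame, by: list[str]) -> pd.Series:
    """Group sum that propagates NaN (a missing constituent poisons the total)."""
    keys = [df[c] for c in by]
    total = df["value"].groupby(keys, sort=True, observed=True).sum()
    has_nan = df["value"].isna().groupby(keys, sort=True, observed=True).any()
    return total.mask(has_nan)


@dataclass
class ConcentrationSet:
    """Tagged total-metal concentrations, ng m^-3, in long format.

    Each row addresses one (time, location, metal, category, origin,
    sector) cell; values may be NaN (missing).  Mineral-dust (MD) rows
    carry the reserved sector "dust" and never an anthropogenic sector.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame, what="ConcentrationSet")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def metals(self) -> list[str]:
        return sorted(self.frame["metal"].unique(), key=METAL_IDS.index)

    def total(self) -> pd.Series:
        """Tag-summed concentration per (time, location, metal); NaN-conservative."""
        return _conservative_sum(self.frame, ["time", "location", "metal"])


@dataclass
class OPField:
    """Per-tag contributions to OP_tm*, nmol-DTT min^-1 m^-3.

    Same long layout as :class:`ConcentrationSet`; metadata records which
    laboratory parameter set produced it and whether the simulation bias
    correction f was applied.
    """

    frame: pd.DataFrame
    params_label: str = "CA"
    f_applied: bool = False

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame, what="OPField")

    def total(self) -> pd.Series:
        """Total score per (time, location), summed over metals and tags."""
        return _conservative_sum(self.frame, ["time", "location"])

    def total_by_metal(self) -> pd.Series:
        return _conservative_sum(self.frame, ["time", "location", "metal"])

    def select(self, **tags) -> "OPField":
        """Subset by tag values, e.g. ``op.select(category=["SUB", "COR"])``."""
        df = self.frame
        for col, val in tags.items():
            vals = [val] if isinstance(val, str) else list(val)
            df = df[df[col].isin(vals)]
        return OPField(df.reset_index(drop=True), self.params_label, self.f_applied)


@dataclass
class SizeClassMap:
    """Category -> size-class mapping used for the particle-size accounting.

    The model's anthropogenic submicron category maps to PM2.5, the
    anthropogenic coarse category to PMc (the PM10 - PM2.5 increment) and
    mineral dust to its own class; PM10 is their sum and stands in for TSP
    (the model carries no super-10-um mass).  Fine dust mass that in
    reality belongs to PM2.5 is deliberately not reassigned.
    """

    mapping: dict = field(
        default_factory=lambda: {"SUB": "PM2.5", "COR": "PMc", "MD": "dust"}
    )

    def __post_init__(self) -> None:
        if set(self.mapping) != set(CATEGORIES):
            raise ValueError(f"mapping must cover exactly the categories {CATEGORIES}")
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("size-class mapping must be one-to-one")

    def size_class(self, category: str) -> str:
        try:
            return self.mapping[category]
        except KeyError:
            raise KeyError(f"unknown category {category!r}") from None


def compute_op(
    conc: ConcentrationSet, params: OPParameterSet, apply_f: bool = False
) -> OPField:
    """Score tagged concentrations: per cell, r_i * chi_i * (f_i) * T_i / M_i.

    Parameters
    ----------
    conc : ConcentrationSet
        Tagged total-metal concentrations, ng m^-3.
    params : OPParameterSet
        Laboratory parameter set (built-in "CA"/"F" or custom).
    apply_f : bool
        Apply the per-metal simulation bias correction f_i.  Leave False
        when scoring observed concentrations (the observed-score
        convention is f_i = 1).

    Returns
    -------
    OPField with the same tag layout; missing inputs stay missing.
    """
    present = set(conc.frame["metal"].unique())
    missing = sorted(present - set(params.r))
    if missing:
        raise ValueError(f"parameter set {params.label!r} missing metals: {missing}")
    factor = {
        m: params.weight(m, apply_f) / get_metal(m).atomic_mass for m in present
    }
    df = conc.frame.copy()
    df["value"] = df["value"] * df["metal"].map(factor)
    return OPField(df, params_label=params.label, f_applied=apply_f)


def metal_share(op: OPField) -> pd.DataFrame:
    """Per-metal fractional contributions to the score at each (time, location).

    Returns a frame indexed by (time, location) with one column per metal;
    rows where the total is zero or not fully observed are NaN.  Shares sum
    to 1 wherever defined.
    """
    per_metal = op.total_by_metal().unstack("metal")
    total = per_metal.sum(axis=1, skipna=False)
    shares = per_metal.div(total.where(total > 0), axis=0)
    return shares
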