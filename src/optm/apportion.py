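"""Source apportionment of the OP score by tag accounting.

Because the score is linear in the tagged concentrations, the contribution
of any tag subset (anthropogenic vs dust, fine vs coarse, domestic vs
transboundary, emission sector) is simply the sum of its cells, and every
fraction below is a ratio of such sums.  Temporal aggregation follows the
same rule: a windowed or seasonal fraction is the ratio of window-summed
numerator and denominator (ratio of means), never a mean of daily ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metals import get_metal
from .params import OPParameterSet
from .scoring import OPField, SizeClassMap, _conservative_sum

__all__ = [
    "SECTOR_REGISTRY",
    "SectorEmissionTable",
    "RegionMask",
    "total_by_size",
    "fraction_anthropogenic",
    "fraction_fine",
    "fraction_domestic",
    "windowed_fraction",
    "seasonal_mean",
    "regional_stats",
    "sector_op_emission",
    "SEASONS",
]

#: Anthropogenic emission sectors of the national transition-metal
#: inventory; the synthetic generator and the emission-table reader accept
#: additional names, these are only the canonical ones.
SECTOR_REGISTRY = (
    "road_brake",
    "iron_steel",
    "power_plants",
    "road_exhaust",
    "railway",
    "navigation",
    "incineration",
    "other_industries_nonmetals",
    "other_metal_industries",
)

#: Meteorological seasons of a single-year study; winter = Jan, Feb, Dec
#: of the same calendar year.
SEASONS = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


# ---------------------------------------------------------------------------
# size-class accounting

def total_by_size(op: OPField, size_map: SizeClassMap | None = None) -> pd.DataFrame:
    """Score totals per size class at each (time, location).

    Columns: PM2.5 (anthropogenic submicron), PMc (anthropogenic coarse),
    dust (mineral dust) and their exact sum PM10 (== TSP for the model,
    which carries no super-10-um mass).
    """
    size_map = size_map or SizeClassMap()
    df = op.frame.copy()
    df["size_class"] = df["category"].map(size_map.size_class)
    keys = ["time", "location", "size_class"]
    sums = _conservative_sum(df, keys).unstack("size_class")
    counts = df.groupby(keys).size().unstack("size_class", fill_value=0)
    classes = ["PM2.5", "PMc", "dust"]
    sums = sums.reindex(columns=classes)
    counts = counts.reindex(columns=classes, fill_value=0)
    # a class with no rows at a cell contributes exactly zero; a class whose
    # rows exist but are partly missing stays missing (conservative)
    out = sums.where(counts > 0, 0.0)
    out["PM10"] = out["PM2.5"] + out["PMc"] + out["dust"]
    return out


# ---------------------------------------------------------------------------
# instantaneous fractions

def _ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    num = num.reindex(den.index, fill_value=0.0)
    return num / den.where(den != 0)


def _tag_sum(op: OPField, **tags) -> pd.Series:
    sub = op.select(**tags) if tags else op
    return _conservative_sum(sub.frame, ["time", "location"])


def fraction_anthropogenic(op: OPField) -> pd.Series:
    """(SUB + COR) / (SUB + COR + MD) per (time, location); NaN where total 0."""
    return _ratio(_tag_sum(op, category=["SUB", "COR"]), _tag_sum(op))


def fraction_fine(op: OPField) -> pd.Series:
    """SUB / (SUB + COR): fine-mode share of the anthropogenic score."""
    return _ratio(
        _tag_sum(op, category=["SUB"]), _tag_sum(op, category=["SUB", "COR"])
    )


def fraction_domestic(op: OPField, include_dust: bool = False) -> pd.Series:
    """Domestic share of the anthropogenic score per (time, location).

    Mineral dust is excluded from numerator and denominator by default
    (the conventional reading: dust is natural, the domestic/transboundary
    split concerns anthropogenic emissions).  ``include_dust=True`` counts
    dust in the denominator instead.
    """
    cats = ["SUB", "COR", "MD"] if include_dust else ["SUB", "COR"]
    den = _tag_sum(op, category=cats)
    num = _tag_sum(op, category=["SUB", "COR"], origin=["domestic"])
    return _ratio(num, den)


# ---------------------------------------------------------------------------
# temporal aggregation

def windowed_fraction(
    numerator: pd.Series, denominator: pd.Series, window: int = 10
) -> pd.Series:
    """Blockwise ratio-of-sums over consecutive non-overlapping windows.

    Both inputs are indexed by (time, location).  Blocks are ``window``
    days long, anchored at the first timestamp of the series; days missing
    in either input are dropped pairwise, and a block with no valid day is
    missing.  The result is indexed by (block start time, location).
    """
    if window < 1:
        raise ValueError("window must be >= 1 day")
    df = pd.DataFrame({"num": numerator, "den": denominator}).reset_index()
    t0 = df["time"].min()
    block = ((df["time"] - t0).dt.days // window).astype(int)
    df["block_start"] = t0 + pd.to_timedelta(block * window, unit="D")
    valid = df.dropna(subset=["num", "den"])
    g = valid.groupby(["block_start", "location"], sort=True)
    out = g["num"].sum() / g["den"].sum().where(lambda s: s != 0)
    # re-emit empty blocks as missing
    all_blocks = pd.MultiIndex.from_frame(
        df[["block_start", "location"]].drop_duplicates()
    ).sortlevel()[0]
    return out.reindex(all_blocks)


def seasonal_mean(
    values: pd.Series, seasons: dict[str, tuple[int, ...]] = SEASONS
) -> pd.DataFrame:
    """Arithmetic seasonal means of a (time, location)-indexed series.

    Returns a frame indexed by location with one column per season plus
    "annual" (mean over all timestamps); a season with no data is NaN.
    """
    df = values.rename("value").reset_index()
    month = df["time"].dt.month
    cols = {}
    for name, months in seasons.items():
        sel = df[month.isin(months)]
        cols[name] = sel.groupby("location")["value"].mean()
    cols["annual"] = df.groupby("location")["value"].mean()
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# regional statistics

@dataclass
class RegionMask:
    """Named analysis regions as sets of locations (sites or grid cells).

    Analysis regions are disjoint; an optional total region (e.g. the
    whole country) may overlap them and is exempt from the disjointness
    rule.
    """

    regions: dict[str, set] = field(default_factory=dict)
    total_region: str | None = None

    def __post_init__(self) -> None:
        self.regions = {k: set(v) for k, v in self.regions.items()}
        seen: dict = {}
        for name, locs in self.regions.items():
            if not locs:
                raise ValueError(f"region {name!r} is empty")
            if name == self.total_region:
                continue
            for loc in locs:
                if loc in seen:
                    raise ValueError(
                        f"location {loc!r} assigned to both {seen[loc]!r} and {name!r}"
                    )
                seen[loc] = name


def regional_stats(
    values: pd.Series, mask: RegionMask, statistic: str = "mean"
) -> pd.Series:
    """Unweighted spatial mean or maximum of a per-location field by region.

    ``values`` is indexed by location (e.g. an annual-mean fraction);
    ``statistic`` is "mean" or "max".
    """
    if statistic not in ("mean", "max"):
        raise ValueError("statistic must be 'mean' or 'max'")
    out = {}
    for name, locs in mask.regions.items():
        present = values.index.intersection(sorted(locs))
        if present.empty:
            raise ValueError(f"region {name!r} has no locations in the field")
        sel = values.loc[present]
        out[name] = float(sel.mean()) if statistic == "mean" else float(sel.max())
    return pd.Series(out, name=statistic)


# ---------------------------------------------------------------------------
# sector accounting on emissions

@dataclass
class SectorEmissionTable:
    """Sector x metal x size-class annual emission masses.

    Long format with columns region, sector, metal, size_class (PM2.5 or
    PM10, cumulative: PM10 includes PM2.5), emission (mass per year,
    arbitrary but consistent units).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["region", "sector", "metal", "size_class", "emission"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"emission table missing columns: {missing}")
        df = self.frame.copy()
        df["emission"] = pd.to_numeric(df["emission"])
        if (df["emission"] < 0).any():
            raise ValueError("emissions must be non-negative")
        bad = ~df["size_class"].isin(["PM2.5", "PM10"])
        if bad.any():
            raise ValueError("size_class must be PM2.5 or PM10")
        wide = df.pivot_table(
            index=["region", "sector", "metal"],
            columns="size_class",
            values="emission",
            aggfunc="sum",
        )
        if {"PM2.5", "PM10"} <= set(wide.columns):
            both = wide.dropna(subset=["PM2.5", "PM10"])
            viol = both[both["PM10"] < both["PM2.5"] - 1e-9 * both["PM2.5"].abs()]
            if len(viol):
                raise ValueError(
                    f"PM10 emission below PM2.5 for {list(viol.index[:5])}"
                )
        self.frame = df

    def sectors(self) -> list[str]:
        return sorted(self.frame["sector"].unique())


def sector_op_emission(
    table: SectorEmissionTable,
    params: OPParameterSet,
    size_class: str = "PM10",
    apply_f: bool = False,
    region: str | None = None,
) -> pd.DataFrame:
    """OP-weighted annual emissions per sector and their relative shares.

    For sector s:  W_s = sum_i r_i chi_i (f_i) E_{s,i} / M_i, i.e. the
    sector's emissions scored with the same molar weights as ambient
    concentrations; shares are W_s / sum W and sum to 1.
    """
    if size_class not in ("PM2.5", "PM10"):
        raise ValueError("size_class must be PM2.5 or PM10")
    df = table.frame[table.frame["size_class"] == size_class]
    if region is not None:
        df = df[df["region"] == region]
        if df.empty:
            raise ValueError(f"no rows for region {region!r}")
    missing = sorted(set(df["metal"].unique()) - set(params.r))
    if missing:
        raise ValueError(f"parameter set {params.label!r} missing metals: {missing}")
    weight = {
        m: params.weight(m, apply_f) / get_metal(m).atomic_mass
        for m in df["metal"].unique()
    }
    w = (df["emission"] * df["metal"].map(weight)).groupby(df["sector"]).sum()
    total = w.sum()
    out = pd.DataFrame({"op_weighted_emission": w})
    out["share"] = w / total if total > 0 else np.nan
    return out.sort_values("share", ascending=False)
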