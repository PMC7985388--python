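"""Paired model/observation evaluation and median-ratio bias calibration.

The evaluation bundle follows standard air-quality model practice: sample
count N, observation median, simulation-to-observation median ratio,
Pearson correlation, the fractions of pairs within a factor of two (Fa2)
and five (Fa5) of the observations, RMSE, and NRMSE (RMSE divided by the
observation mean).

Calibration inverts the same median ratio per metal: the bias-correction
factor is f_i = median(obs_i) / median(sim_i), estimated on pooled paired
daily concentrations, and the same f_i is applied to every size class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedSeries", "EvaluationReport", "pair_daily", "evaluate", "derive_bias_factors"]


@dataclass
class PairedSeries:
    """Daily-aligned (sim, obs) values with no missing entries.

    ``frame`` has columns time (one row per calendar day, strictly
    increasing), sim and obs.
    """

    frame: pd.DataFrame
    name: str = ""
    units: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in ("time", "sim", "obs") if c not in df.columns]
        if missing:
            raise ValueError(f"paired series missing columns: {missing}")
        if df[["sim", "obs"]].isna().any().any():
            raise ValueError("paired series may not contain missing values")
        if not df["time"].is_monotonic_increasing or df["time"].duplicated().any():
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.frame)


def pair_daily(
    sim: pd.Series, obs: pd.Series, name: str = "", units: str = "", site: str = ""
) -> PairedSeries:
    """Align two time-indexed series on calendar day (local time).

    Multiple records on one day are averaged before pairing; days missing
    in either series are dropped.  An empty overlap yields an empty
    PairedSeries, not an error.
    """

    def daily(s: pd.Series) -> pd.Series:
        s = s.dropna()
        idx = pd.to_datetime(s.index)
        if idx.tz is not None:
            # explicit offsets denote local time; day boundaries are local midnight
            idx = idx.tz_localize(None)
        return s.groupby(idx.normalize()).mean()

    d_sim, d_obs = daily(sim), daily(obs)
    days = d_sim.index.intersection(d_obs.index).sort_values()
    frame = pd.DataFrame(
        {"time": days, "sim": d_sim.loc[days].to_numpy(), "obs": d_obs.loc[days].to_numpy()}
    )
    return PairedSeries(frame, name=name, units=units, site=site)


@dataclass
class EvaluationReport:
    """The statistic bundle for one paired sim/obs daily series.

    Undefined statistics (zero observation median or mean, constant
    series) are NaN, never silently dropped.
    """

    n: int
    obs_median: float
    sim_obs_ratio: float
    pearson_r: float
    fa2: float
    fa5: float
    rmse: float
    nrmse: float
    name: str = ""
    units: str = ""
    site: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "units": self.units,
            "site": self.site,
            "n": self.n,
            "obs_median": self.obs_median,
            "sim_obs_ratio": self.sim_obs_ratio,
            "pearson_r": self.pearson_r,
            "fa2": self.fa2,
            "fa5": self.fa5,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_json_float)
            fh.write("\n")

    def __str__(self) -> str:
        cols = ["N", "Obs median", "Sim:Obs", "R", "Fa2", "Fa5", "RMSE", "NRMSE"]
        vals = [
            f"{self.n}",
            f"{self.obs_median:.4g}",
            f"{self.sim_obs_ratio:.3g}",
            f"{self.pearson_r:.3g}",
            f"{self.fa2:.3g}",
            f"{self.fa5:.3g}",
            f"{self.rmse:.4g}",
            f"{self.nrmse:.3g}",
        ]
        width = [max(len(c), len(v)) for c, v in zip(cols, vals)]
        head = "  ".join(c.rjust(w) for c, w in zip(cols, width))
        body = "  ".join(v.rjust(w) for v, w in zip(vals, width))
        title = f"{self.name} [{self.units}] at {self.site}".strip(" []at")
        return (f"{title}\n" if title else "") + head + "\n" + body


def _json_float(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    raise TypeError(x)


def evaluate(pairs: PairedSeries) -> EvaluationReport:
    """Compute the evaluation statistics for a paired daily series.

    Fa2/Fa5 boundaries are inclusive (a ratio of exactly 2 counts as
    within a factor of two) and pairs with a zero observation are excluded
    from their denominators.
    """
    if pairs.n == 0:
        raise ValueError("cannot evaluate an empty paired series")
    sim = pairs.frame["sim"].to_numpy(dtype=float)
    obs = pairs.frame["obs"].to_numpy(dtype=float)
    n = len(sim)

    obs_median = float(np.median(obs))
    sim_median = float(np.median(sim))
    ratio = sim_median / obs_median if obs_median != 0 else np.nan

    if n >= 2 and np.std(sim) > 0 and np.std(obs) > 0:
        r = float(stats.pearsonr(sim, obs).statistic)
    else:
        r = np.nan

    nonzero = obs != 0
    if nonzero.any():
        q = sim[nonzero] / obs[nonzero]
        fa2 = float(np.mean((q >= 0.5) & (q <= 2.0)))
        fa5 = float(np.mean((q >= 0.2) & (q <= 5.0)))
    else:
        fa2 = fa5 = np.nan

    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    obs_mean = float(np.mean(obs))
    nrmse = rmse / obs_mean if obs_mean != 0 else np.nan

    return EvaluationReport(
        n=n,
        obs_median=obs_median,
        sim_obs_ratio=ratio,
        pearson_r=r,
        fa2=fa2,
        fa5=fa5,
        rmse=rmse,
        nrmse=nrmse,
        name=pairs.name,
        units=pairs.units,
        site=pairs.site,
    )


def derive_bias_factors(
    sim: pd.DataFrame, obs: pd.DataFrame, pool_locations: bool = True
) -> dict[str, float]:
    """Per-metal bias-correction factors from paired concentration series.

    Both inputs are long frames with columns time, metal, value and
    optionally location.  For each metal the daily series are paired (per
    location, then pooled by default) and

        f_i = median(obs_i) / median(sim_i),

    the inverse of the simulation-to-observation median ratio.

    Raises if a metal's simulated median is zero.
    """
    del pool_locations  # pooled estimation is the only implemented mode
    factors: dict[str, float] = {}
    for metal in sorted(set(sim["metal"]) & set(obs["metal"])):
        pooled_sim, pooled_obs = [], []
        s_m = sim[sim["metal"] == metal]
        o_m = obs[obs["metal"] == metal]
        locations = (
            sorted(set(s_m.get("location", pd.Series(["_"])))
                   & set(o_m.get("location", pd.Series(["_"]))))
            if "location" in s_m.columns and "location" in o_m.columns
            else [None]
        )
        for loc in locations:
            s = s_m if loc is None else s_m[s_m["location"] == loc]
            o = o_m if loc is None else o_m[o_m["location"] == loc]
            paired = pair_daily(
                pd.Series(s["value"].to_numpy(), index=pd.to_datetime(s["time"])),
                pd.Series(o["value"].to_numpy(), index=pd.to_datetime(o["time"])),
            )
            pooled_sim.append(paired.frame["sim"].to_numpy())
            pooled_obs.append(paired.frame["obs"].to_numpy())
        all_sim = np.concatenate(pooled_sim) if pooled_sim else np.array([])
        all_obs = np.concatenate(pooled_obs) if pooled_obs else np.array([])
        if len(all_sim) == 0:
            continue
        med_sim = float(np.median(all_sim))
        if med_sim == 0:
            raise ValueError(f"zero simulated median for metal {metal!r}")
        factors[metal] = float(np.median(all_obs)) / med_sim
    return factors
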