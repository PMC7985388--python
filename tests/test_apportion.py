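"""Apportionment: size classes, fractions, windows, seasons, regions, sectors."""

import numpy as np
import pandas as pd
import pytest

from optm import (
    RegionMask,
    SectorEmissionTable,
    builtin_parameters,
    compute_op,
    fraction_anthropogenic,
    fraction_domestic,
    fraction_fine,
    regional_stats,
    seasonal_mean,
    sector_op_emission,
    total_by_size,
    windowed_fraction,
)

from conftest import make_conc, random_tagged_frame

CA = builtin_parameters("CA")


def brute_force_fraction(op_frame, num_rows, den_rows):
    """Explicit-loop ratio of tag sums per (time, location)."""
    out = {}
    for (t, loc), group in op_frame.groupby(["time", "location"]):
        num = den = 0.0
        for _, row in group.iterrows():
            if den_rows(row):
                den += row["value"]
            if num_rows(row):
                num += row["value"]
        out[(t, loc)] = num / den if den > 0 else np.nan
    return out


class TestTotalBySize:
    def test_sub_only_field_is_all_fine(self):
        op = compute_op(
            make_conc([("2013-01-01", "a", "Cu", "SUB", "domestic", "road_brake", 10.0)]),
            CA,
        )
        sizes = total_by_size(op)
        assert sizes["PM2.5"].iloc[0] == sizes["PM10"].iloc[0]
        assert sizes["PMc"].iloc[0] == 0 and sizes["dust"].iloc[0] == 0

    def test_additivity_of_classes(self):
        rows = [
            ("2013-01-01", "a", "Cu", "SUB", "domestic", "road_brake", 3.0),
            ("2013-01-01", "a", "Cu", "COR", "domestic", "road_brake", 1.0),
            ("2013-01-01", "a", "Cu", "MD", "foreign", "dust", 2.0),
        ]
        op = compute_op(make_conc(rows), CA)
        sizes = total_by_size(op)
        assert sizes["PM10"].iloc[0] == pytest.approx(
            sizes[["PM2.5", "PMc", "dust"]].iloc[0].sum(), abs=1e-12
        )

    def test_pm10_equals_brute_force_total(self, rng):
        conc = random_tagged_frame(rng)
        op = compute_op(conc, CA)
        sizes = total_by_size(op)
        brute = op.frame.groupby(["time", "location"])["value"].sum()
        assert np.allclose(sizes["PM10"].to_numpy(), brute.to_numpy(), rtol=1e-10)


class TestFractions:
    def test_no_dust_means_fully_anthropogenic(self):
        op = compute_op(
            make_conc([("2013-01-01", "a", "Cu", "SUB", "domestic", "road_brake", 5.0)]),
            CA,
        )
        assert fraction_anthropogenic(op).iloc[0] == pytest.approx(1.0)

    def test_half_dust(self):
        rows = [
            ("2013-01-01", "a", "Cu", "SUB", "domestic", "road_brake", 2.0),
            ("2013-01-01", "a", "Cu", "MD", "foreign", "dust", 2.0),
        ]
        op = compute_op(make_conc(rows), CA)
        assert fraction_anthropogenic(op).iloc[0] == pytest.approx(0.5)

    def test_fine_fraction_quarter(self):
        rows = [
            ("2013-01-01", "a", "Cu", "SUB", "domestic", "road_brake", 1.0),
            ("2013-01-01", "a", "Cu", "COR", "domestic", "road_brake", 3.0),
        ]
        op = compute_op(make_conc(rows), CA)
        assert fraction_fine(op).iloc[0] == pytest.approx(0.25)

    def test_domestic_three_quarters_excludes_dust(self):
        rows = [
            ("2013-01-01", "a", "Cu", "SUB", "domestic", "road_brake", 3.0),
            ("2013-01-01", "a", "Cu", "SUB", "foreign", "iron_steel", 1.0),
            ("2013-01-01", "a", "Cu", "MD", "foreign", "dust", 50.0),
        ]
        op = compute_op(make_conc(rows), CA)
        assert fraction_domestic(op).iloc[0] == pytest.approx(0.75)
        # with dust counted in the denominator the share shrinks
        assert fraction_domestic(op, include_dust=True).iloc[0] < 0.75

    def test_fractions_match_brute_force_on_random_field(self, rng):
        op = compute_op(random_tagged_frame(rng), CA)
        cases = {
            "anth": (
                fraction_anthropogenic(op),
                lambda r: r["category"] in ("SUB", "COR"),
                lambda r: True,
            ),
            "fine": (
                fraction_fine(op),
                lambda r: r["category"] == "SUB",
                lambda r: r["category"] in ("SUB", "COR"),
            ),
            "dom": (
                fraction_domestic(op),
                lambda r: r["category"] in ("SUB", "COR") and r["origin"] == "domestic",
                lambda r: r["category"] in ("SUB", "COR"),
            ),
        }
        for name, (series, num_rule, den_rule) in cases.items():
            brute = brute_force_fraction(op.frame, num_rule, den_rule)
            for key, expected in brute.items():
                assert series.loc[key] == pytest.approx(expected, rel=1e-10), name

    def test_fraction_bounds_and_complements(self, rng):
        op = compute_op(random_tagged_frame(rng), CA)
        fa = fraction_anthropogenic(op).dropna()
        assert ((fa >= 0) & (fa <= 1)).all()
        dust_share = 1 - fa
        total = op.total()
        dust = op.select(category=["MD"]).total().reindex(total.index, fill_value=0)
        assert np.allclose(dust_share, (dust / total).reindex(fa.index), atol=1e-10)
        fd = fraction_domestic(op).dropna()
        anth = op.select(category=["SUB", "COR"])
        foreign = (
            anth.select(origin=["foreign"]).total().reindex(anth.total().index, fill_value=0)
        )
        assert np.allclose(1 - fd, (foreign / anth.total()).reindex(fd.index), atol=1e-10)


class TestWindowedFraction:
    def _series(self, values, location="a"):
        times = pd.date_range("2013-01-01", periods=len(values), freq="D")
        idx = pd.MultiIndex.from_product([times, [location]], names=["time", "location"])
        return pd.Series(list(values), index=idx)

    def test_constant_fields_reproduce_instantaneous_fraction(self):
        num, den = self._series([2.0] * 6), self._series([8.0] * 6)
        out = windowed_fraction(num, den, window=3)
        assert np.allclose(out.dropna(), 0.25)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        out = windowed_fraction(self._series([1.0, 3.0]), self._series([2.0, 4.0]), window=2)
        assert out.iloc[0] == pytest.approx(4.0 / 6.0)

    def test_window_one_reproduces_instantaneous(self):
        num, den = self._series([1.0, 2.0, 3.0]), self._series([2.0, 8.0, 4.0])
        out = windowed_fraction(num, den, window=1)
        assert np.allclose(out.to_numpy(), [0.5, 0.25, 0.75])

    def test_all_missing_block_is_missing(self):
        num = self._series([1.0, np.nan, np.nan, 4.0])
        den = self._series([2.0, np.nan, np.nan, 8.0])
        out = windowed_fraction(num, den, window=2)
        assert out.iloc[0] == pytest.approx(0.5)
        assert out.iloc[1] == pytest.approx(0.5)
        out2 = windowed_fraction(num.iloc[:3], den.iloc[:3], window=2)
        assert np.isnan(out2.iloc[1])

    def test_window_longer_than_series_gives_single_block(self):
        out = windowed_fraction(self._series([1.0, 3.0]), self._series([2.0, 4.0]), window=100)
        assert len(out) == 1


class TestSeasonalMean:
    def _month_series(self):
        times = pd.date_range("2013-01-01", "2013-12-31", freq="D")
        idx = pd.MultiIndex.from_product([times, ["a"]], names=["time", "location"])
        return pd.Series(times.month.astype(float), index=idx)

    def test_month_index_field(self):
        out = seasonal_mean(self._month_series())
        assert out.loc["a", "spring"] == pytest.approx(4.0)  # mean of 3,4,5
        assert out.loc["a", "winter"] == pytest.approx(
            (1 * 31 + 2 * 28 + 12 * 31) / 90.0
        )

    def test_constant_field(self):
        s = self._month_series() * 0 + 7.0
        out = seasonal_mean(s)
        assert np.allclose(out.loc["a"], 7.0)

    def test_absent_season_is_missing(self):
        times = pd.date_range("2013-06-01", periods=10, freq="D")
        idx = pd.MultiIndex.from_product([times, ["a"]], names=["time", "location"])
        out = seasonal_mean(pd.Series(1.0, index=idx))
        assert np.isnan(out.loc["a", "winter"])
        assert out.loc["a", "summer"] == 1.0


class TestRegionalStats:
    def test_uniform_field(self):
        mask = RegionMask({"east": {"a", "b"}, "west": {"c"}})
        values = pd.Series(0.5, index=pd.Index(["a", "b", "c"], name="location"))
        assert (regional_stats(values, mask, "mean") == 0.5).all()
        assert (regional_stats(values, mask, "max") == 0.5).all()

    def test_mean_and_max(self):
        mask = RegionMask({"east": {"a", "b"}})
        values = pd.Series({"a": 0.4, "b": 0.6})
        values.index.name = "location"
        assert regional_stats(values, mask, "mean")["east"] == pytest.approx(0.5)
        assert regional_stats(values, mask, "max")["east"] == pytest.approx(0.6)

    def test_matches_brute_force_loop(self, rng):
        locs = [f"s{i}" for i in range(12)]
        values = pd.Series(rng.random(12), index=pd.Index(locs, name="location"))
        mask = RegionMask({"r1": set(locs[:5]), "r2": set(locs[5:])})
        means = regional_stats(values, mask, "mean")
        for name, members in mask.regions.items():
            acc = [values[loc] for loc in members]
            assert means[name] == pytest.approx(sum(acc) / len(acc), rel=1e-12)

    def test_empty_region_and_overlap_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RegionMask({"east": set()})
        with pytest.raises(ValueError, match="assigned to both"):
            RegionMask({"east": {"a"}, "west": {"a"}})
        # the total region is allowed to overlap
        RegionMask({"japan": {"a", "b"}, "east": {"a"}, "west": {"b"}}, total_region="japan")


class TestSectorOP:
    def _table(self, rows):
        return SectorEmissionTable(
            pd.DataFrame(rows, columns=["region", "sector", "metal", "size_class", "emission"])
        )

    def test_single_sector_share_is_one(self):
        t = self._table([("japan", "road_brake", "Cu", "PM10", 12.0)])
        out = sector_op_emission(t, CA, "PM10")
        assert out["share"].iloc[0] == pytest.approx(1.0)

    def test_two_sectors_with_equal_weight(self):
        # equal OP-weighted emissions: same metal, same amount
        t = self._table(
            [
                ("japan", "road_brake", "Cu", "PM10", 5.0),
                ("japan", "iron_steel", "Cu", "PM10", 5.0),
            ]
        )
        out = sector_op_emission(t, CA, "PM10")
        assert np.allclose(out["share"], 0.5)

    def test_brute_force_and_row_order_invariance(self, rng):
        rows = []
        for sector in ("road_brake", "iron_steel", "navigation"):
            for metal in ("Cu", "Fe", "Ni"):
                rows.append(("japan", sector, metal, "PM10", float(rng.gamma(2, 3))))
        t = self._table(rows)
        out = sector_op_emission(t, CA, "PM10")
        from optm import get_metal

        brute = {}
        for region, sector, metal, _, emission in rows:
            w = CA.r[metal] * CA.chi[metal] * emission / get_metal(metal).atomic_mass
            brute[sector] = brute.get(sector, 0.0) + w
        total = sum(brute.values())
        for sector, w in brute.items():
            assert out.loc[sector, "share"] == pytest.approx(w / total, rel=1e-12)
        shuffled = self._table([rows[i] for i in rng.permutation(len(rows))])
        out2 = sector_op_emission(shuffled, CA, "PM10")
        pd.testing.assert_frame_equal(out, out2)

    def test_shares_invariant_to_unit_rescaling(self, rng):
        rows = [
            ("japan", s, m, "PM10", float(rng.gamma(2, 3)))
            for s in ("road_brake", "navigation")
            for m in ("Cu", "V")
        ]
        t1 = self._table(rows)
        t2 = self._table([(r, s, m, c, e * 1000.0) for r, s, m, c, e in rows])
        assert np.allclose(
            sector_op_emission(t1, CA)["share"], sector_op_emission(t2, CA)["share"]
        )

    def test_pm10_below_pm25_rejected(self):
        with pytest.raises(ValueError, match="PM10"):
            self._table(
                [
                    ("japan", "road_brake", "Cu", "PM10", 1.0),
                    ("japan", "road_brake", "Cu", "PM2.5", 2.0),
                ]
            )
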