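import numpy as np
import pandas as pd
import pytest

from optm import ConcentrationSet, SyntheticConfig, generate_truth


def make_conc(rows):
    """Build a ConcentrationSet from (time, location, metal, category, origin,
    sector, value) tuples."""
    return ConcentrationSet(
        pd.DataFrame(
            rows,
            columns=["time", "location", "metal", "category", "origin", "sector", "value"],
        )
    )


def single_cell(metal="Cu", value=63.546, category="SUB", origin="domestic",
                sector="road_brake", time="2013-01-01", location="yonago"):
    return make_conc([(time, location, metal, category, origin, sector, value)])


def random_tagged_frame(rng, n_days=12, sites=("a", "b"), metals=("Cu", "Fe")):
    """Small random tagged field covering all categories and origins."""
    times = pd.date_range("2013-01-01", periods=n_days, freq="D")
    rows = []
    for t in times:
        for s in sites:
            for m in metals:
                for cat, origin, sector in [
                    ("SUB", "domestic", "road_brake"),
                    ("SUB", "foreign", "iron_steel"),
                    ("COR", "domestic", "road_brake"),
                    ("COR", "foreign", "navigation"),
                    ("MD", "foreign", "dust"),
                ]:
                    rows.append((t, s, m, cat, origin, sector, float(rng.gamma(2.0, 5.0))))
    return make_conc(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20130101)


@pytest.fixture
def small_truth():
    """One season of noisy tagged synthetic data, one site."""
    return generate_truth(SyntheticConfig(seed=7, n_days=90))


@pytest.fixture
def noise_free_config():
    return SyntheticConfig(
        seed=11,
        n_days=40,
        seasonal_amplitude=0.0,
        conc_sigma=0.0,
        tag_sigma=0.0,
        dust_pulse_prob=0.0,
        obs_sigma=0.0,
        missing_prob=0.0,
    )
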