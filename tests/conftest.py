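import numpy as np
import pandas as pd
import pytest

from hwcc import design, simulate
from hwcc.hwi import ThresholdSet


def make_climate(tmax, tmin, loc="A", start="2019-07-01", drop=()):
    """Single-location climate frame over consecutive days; ``drop`` removes days."""
    dates = pd.date_range(start, periods=len(tmax), freq="D")
    df = pd.DataFrame(
        {"location_id": loc, "date": dates, "tmax": tmax, "tmin": tmin}
    )
    return df.drop(index=list(drop)).reset_index(drop=True)


def make_thresholds(tx, tn, locs=("A",)):
    vals = pd.DataFrame(
        {"tmax_threshold": tx, "tmin_threshold": tn}, index=pd.Index(locs, name="location_id")
    )
    return ThresholdSet(values=vals)


@pytest.fixture()
def six_day_example():
    """Hand series with one 2-day event and one isolated exceedance day."""
    climate = make_climate(
        tmax=[29.0, 31.0, 32.0, 29.0, 31.0, 29.0],
        tmin=[14.0, 14.0, 16.0, 14.0, 14.0, 14.0],
    )
    return climate, make_thresholds(30.0, 15.0)


def random_small_panel(rng, n_strata=10, n_days=5, lam=3.0):
    """Random informative panel: one stratum per location, Poisson counts."""
    rows = []
    for s in range(n_strata):
        for d in range(n_days):
            rows.append(
                {
                    "location_id": f"L{s:02d}",
                    "date": pd.Timestamp("2019-07-01") + pd.Timedelta(days=7 * d),
                    "count": int(rng.poisson(lam)) + (1 if d == 0 else 0),
                    "dhwi": float(rng.gamma(1.0, 1.0)),
                    "nhwi": float(rng.gamma(1.0, 1.0)),
                    "dhw_flag": 0,
                    "nhw_flag": 0,
                }
            )
    return design.add_stratum_keys(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down effect scenario reused by slower integration-style tests."""
    cfg = simulate.make_scenario(
        "paper_anchored", seed=31, n_locations=10, analysis_years=2,
        reference_years=15,
    )
    return simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_panel(small_study):
    return design.assemble_panel(
        small_study.health, small_study.exposure, cause="mental"
    )
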