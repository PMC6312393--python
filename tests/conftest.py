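import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wheatgains import datasets
from wheatgains.trial_data import Panel, build_registry

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def tiny_registry_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variety": ["ALPHA", "BRAVO", "CHARLIE"],
            "release_year": [1992, 1993, 1995],
            "wheat_type": ["winter", "winter", "winter"],
        }
    )


@pytest.fixture
def tiny_registry(tiny_registry_frame):
    return build_registry(tiny_registry_frame)


@pytest.fixture
def tiny_panel_frame() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    rows = []
    for plot, region in [("P1", "free_state_dryland"), ("P2", "western_cape")]:
        for year in (2000, 2001, 2002):
            for variety in ("ALPHA", "BRAVO", "CHARLIE"):
                for rep in (1, 2):
                    rows.append(
                        {
                            "plot_id": plot,
                            "region": region,
                            "trial_year": year,
                            "variety": variety,
                            "yield_kg_ha": float(rng.uniform(1000, 4000)),
                            "planting": int(rng.integers(0, 2)),
                            "irrigated": 0,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_panel(tiny_panel_frame, tiny_registry) -> Panel:
    return Panel(tiny_panel_frame, tiny_registry)


@pytest.fixture(scope="session")
def variety_summary() -> pd.DataFrame:
    return datasets.load_variety_summary()


@pytest.fixture(scope="session")
def summary_panel(variety_summary) -> Panel:
    """Panel whose per-variety mean yields equal the published summary means.

    Two observations per variety at mean +/- SD reproduce each published
    mean exactly, which is all the ratio/difference descriptive checks
    need.
    """
    rows = []
    for r in variety_summary.itertuples(index=False):
        for rep, sign in ((1, -1.0), (2, 1.0)):
            rows.append(
                {
                    "plot_id": "P001",
                    "region": "free_state_dryland",
                    "trial_year": 2013,
                    "variety": r.variety,
                    "yield_kg_ha": float(r.mean_yield_kg_ha)
                    + sign * float(r.sd_yield_kg_ha),
                    "planting": 1,
                    "irrigated": int(r.pct_irrigated > 50),
                    "replicate": rep,
                }
            )
    registry = build_registry(
        variety_summary[["variety", "release_year", "wheat_type"]]
    )
    return Panel(pd.DataFrame(rows), registry)


@pytest.fixture(scope="session")
def oracle_panel() -> Panel:
    """A fixed 30-row panel small enough for explicit matrix oracles."""
    rng = np.random.default_rng(77)
    rows = []
    for plot in ("P1", "P2", "P3"):
        for year in (2000, 2001):
            for variety, rep in [("A", 1), ("A", 2), ("B", 1), ("B", 2), ("C", 1)]:
                rows.append(
                    {
                        "plot_id": plot,
                        "region": {"P1": "r1", "P2": "r2", "P3": "r3"}[plot],
                        "trial_year": year,
                        "variety": variety,
                        "yield_kg_ha": float(rng.uniform(1500, 4500)),
                        "planting": int(rng.integers(0, 2)),
                        "irrigated": 0,
                        "replicate": rep,
                    }
                )
    registry = build_registry(
        pd.DataFrame(
            {
                "variety": ["A", "B", "C"],
                "release_year": [1992, 1994, 1998],
                "wheat_type": ["winter"] * 3,
            }
        )
    )
    return Panel(pd.DataFrame(rows), registry)


@pytest.fixture(scope="session")
def reference_gains():
    """Gain series for the three economically tracked wheat types, to 2015."""
    from wheatgains.genetic_gain import cumulative_gain

    ref = datasets.load_reference_coefficients()
    return {
        wt: cumulative_gain(
            float(ref.loc[wt, "jp_yield"]),
            int(ref.loc[wt, "first_release_year"]),
            2015,
            wheat_type=wt,
        )
        for wt in datasets.ECON_TYPES
    }
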