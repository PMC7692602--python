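import numpy as np
import pandas as pd
import pytest

from gxecohort.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One shared small synthetic study (complete data, no missingness)."""
    return simulate_study(SimulationConfig(n_subjects=400, n_fsa=12, seed=42))


@pytest.fixture(scope="session")
def toy_panel():
    """Two-FSA, two-quarter retail panel small enough to hand-check."""
    rows = []
    for fsa, quarter, store in [("H3A", "2011Q1", "s1"), ("H3A", "2011Q2", "s1"),
                                ("J4B", "2011Q1", "s1")]:
        for cat, n_sku, price, servings in [("vegetables", 4, 3.0, 4),
                                            ("soft_drinks", 2, 2.5, 6)]:
            for sku in range(1, n_sku + 1):
                rows.append({
                    "fsa": fsa, "quarter": quarter, "week": 1, "store": store,
                    "category": cat, "sku": f"{cat[:3]}{sku}",
                    "price": price + 0.1 * sku, "servings": servings,
                    "promoted": sku == 1, "on_display": sku <= 2,
                    "available": True,
                })
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
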