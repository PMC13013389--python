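import numpy as np
import pandas as pd
import pytest

from nutrisurv.ffq import compute_daily_intakes
from nutrisurv.index import compute_di, cumulative_average
from nutrisurv.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One small generated cohort shared across survival tests."""
    cfg = GeneratorConfig(n_participants=1200, n_visits=3)
    items, responses, outcomes, truth = generate_cohort(cfg, seed=424242)
    return {"config": cfg, "items": items, "responses": responses,
            "outcomes": outcomes, "truth": truth}


@pytest.fixture(scope="session")
def small_exposure(small_cohort):
    """Pipeline-computed cumulative-average DI for the small cohort."""
    items = small_cohort["items"]
    intakes = compute_daily_intakes(small_cohort["responses"], items)
    di = compute_di(intakes.items, items.set_index("item_id")["score"])
    return cumulative_average(di)


@pytest.fixture()
def toy_items():
    """Three-item table with simple round numbers for hand arithmetic."""
    return pd.DataFrame({
        "item_id": [1, 2, 3],
        "portion_g": [100.0, 50.0, 200.0],
        "energy_kcal": [200.0, 400.0, 50.0],
        "protein_g": [10.0, 5.0, 1.0],
        "fibre_g": [2.0, 0.0, 1.5],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
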