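import numpy as np
import pandas as pd
import pytest

from snacksub import (GeneratorConfig, build_composite, generate_dataset,
                      load_nut_items, model1, model2)


@pytest.fixture(scope="session")
def nut_items():
    return load_nut_items()


@pytest.fixture(scope="session")
def composite_tree(nut_items):
    return build_composite(nut_items, "tree_nut")


@pytest.fixture(scope="session")
def composite_almond(nut_items):
    return build_composite(nut_items, "almond_only")


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared across tests (n=300 persons)."""
    config = GeneratorConfig(n_persons=300, seed=42)
    persons, foods, days = generate_dataset(config)
    return config, persons, foods, days


@pytest.fixture(scope="session")
def all_models(composite_tree, composite_almond):
    return {
        "model1_tree_nut": model1(composite_tree),
        "model2_tree_nut": model2(composite_tree),
        "model1_almond_only": model1(composite_almond),
        "model2_almond_only": model2(composite_almond),
    }


def toy_design(n=128, n_strata=16, seed=0, weight_sigma=0.3):
    """Persons table with a two-PSU-per-stratum design for BRR tests."""
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    return pd.DataFrame({
        "person_id": [f"p{k:04d}" for k in i],
        "survey_weight": np.exp(rng.normal(0, weight_sigma, n)),
        "stratum_id": [f"s{k % n_strata:02d}" for k in i],
        "psu_id": [f"s{k % n_strata:02d}_u{(k // n_strata) % 2}" for k in i],
    })
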