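import numpy as np
import pandas as pd
import pytest

import dietmod as dm


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable deterministic fixture: (recall, foods)."""
    return dm.make_toy_fixture()


@pytest.fixture(scope="session")
def toy_childday(toy):
    recall, foods = toy
    childday = dm.compute_intakes(recall, foods)
    childday, _ = dm.flag_energy_outliers(childday)
    return childday


@pytest.fixture(scope="session")
def milks():
    return dm.load_milks()


@pytest.fixture(scope="session")
def refs():
    return dm.load_references()


@pytest.fixture(scope="session")
def small_survey():
    """A modest synthetic survey reused across tests: (recall, foods, truth)."""
    spec = dm.PopulationSpec(n_children=1500, seed=11)
    return dm.generate_survey(spec)


@pytest.fixture(scope="session")
def small_childday(small_survey):
    recall, foods, _ = small_survey
    childday = dm.compute_intakes(recall, foods)
    childday, _ = dm.flag_energy_outliers(childday)
    return childday[~childday["energy_outlier"]].reset_index(drop=True)
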