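import numpy as np
import pytest

from preyniche import datasets
from preyniche.core_data import Predator, PreyRecord


@pytest.fixture(scope="session")
def cogh_table():
    return datasets.study_table("CoGH")


@pytest.fixture(scope="session")
def kleinmond_table():
    return datasets.study_table("Kleinmond")


@pytest.fixture()
def rng():
    return np.random.default_rng(20140701)


@pytest.fixture()
def small_study():
    """Three predators, ten prey records over two taxa, plus one env sample."""
    predators = [
        Predator("p1", "X_laevis", "CoGH", svl_mm=65.0),
        Predator("p2", "X_laevis", "CoGH", svl_mm=48.0),
        Predator("p3", "X_gilli", "CoGH", svl_mm=41.0),
    ]
    records = [
        PreyRecord("stomach", "CoGH", "Ostracoda", predator_id="p1", count=2),
        PreyRecord("stomach", "CoGH", "Ostracoda", predator_id="p1", count=1),
        PreyRecord("stomach", "CoGH", "Daphnia", predator_id="p1", count=5,
                   habitat_class="zooplankton"),
        PreyRecord("stomach", "CoGH", "Ostracoda", predator_id="p2", count=1),
        PreyRecord("stomach", "CoGH", "Daphnia", predator_id="p2", count=2,
                   habitat_class="zooplankton"),
        PreyRecord("stomach", "CoGH", "Ostracoda", predator_id="p3", count=4),
        PreyRecord("stomach", "CoGH", "Daphnia", predator_id="p3", count=1,
                   habitat_class="zooplankton"),
        PreyRecord("environment", "CoGH", "Ostracoda", count=30,
                   sampling_method="core"),
        PreyRecord("environment", "CoGH", "Daphnia", count=70,
                   habitat_class="zooplankton", sampling_method="filter"),
        PreyRecord("stomach", "CoGH", "sloughed_skin", predator_id="p2",
                   non_prey_flag="sloughed_skin"),
    ]
    return records, predators
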