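import numpy as np
import pytest

from lignintrace import SampleModel, default_shift_table, named_regions
from lignintrace.presets import control_model, study_model


@pytest.fixture(scope="session")
def table():
    return default_shift_table()

@pytest.fixture(scope="session")
def regions():
    return named_regions()


@pytest.fixture(scope="session")
def wt_phe():
    """Phe-labeled WT root model (p = 0.31)."""
    return study_model("WT", "Phe")


@pytest.fixture(scope="session")
def control():
    """Unlabeled control: same background, p = 0."""
    return control_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def pure_g():
    return SampleModel(
        composition={"G": 1.0, "S": 0.0, "H": 0.0, "FA": 0.0, "pCA": 0.0},
        labeling_fraction=0.0,
    )
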