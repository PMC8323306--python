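import numpy as np
import pandas as pd
import pytest

from mitoflex.betaox.model import ParameterSet, default_parameters
from mitoflex.omics import OmicsTable
from mitoflex.synth import CohortConfig


@pytest.fixture
def params() -> ParameterSet:
    return default_parameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_config() -> CohortConfig:
    """A small, fast cohort for interface/pipeline tests."""
    return CohortConfig(seed=7, n_young=3, n_old=3)


def make_omics(values: np.ndarray, ages, diets, analytes=None, classes=None) -> OmicsTable:
    """Build an OmicsTable from a raw array and per-sample labels."""
    values = np.asarray(values, dtype=float)
    n_analytes, n_samples = values.shape
    if analytes is None:
        analytes = [f"a{i}" for i in range(n_analytes)]
    samples = [f"s{i}" for i in range(n_samples)]
    frame = pd.DataFrame(values, index=pd.Index(analytes, name="analyte"),
                         columns=samples)
    sheet = pd.DataFrame({"age": ages, "diet": diets}, index=samples)
    cls = None
    if classes is not None:
        cls = pd.Series(classes, index=frame.index, name="class")
    return OmicsTable(values=frame, samples=sheet, classes=cls)
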