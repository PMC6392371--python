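import numpy as np
import pandas as pd
import pytest

from lizardgrowth import GrowthCurve, GrowthParams, ModelFamily

# published per-sex estimates used throughout as realistic parameter sets
MALE_LL = dict(family=ModelFamily.LOGISTIC_BY_LENGTH, a1=46.46, r=0.0053)
FEMALE_VB = dict(family=ModelFamily.VON_BERTALANFFY, a1=52.81, r=0.0017)
L0 = 22.1


@pytest.fixture
def male_curve() -> GrowthCurve:
    return GrowthCurve(MALE_LL["family"], GrowthParams(MALE_LL["a1"], MALE_LL["r"]), L0)


@pytest.fixture
def female_curve() -> GrowthCurve:
    return GrowthCurve(FEMALE_VB["family"], GrowthParams(FEMALE_VB["a1"], FEMALE_VB["r"]), L0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


def capture_table(rows) -> pd.DataFrame:
    """Build a capture table from (id, sex, date, svl) tuples."""
    frame = pd.DataFrame(rows, columns=["id", "sex", "date", "svl_mm"])
    frame["date"] = pd.to_datetime(frame["date"])
    frame["mass_g"] = np.nan
    return frame
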