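import numpy as np
import pandas as pd
import pytest

from crossomics import FeatureMatrix, SimulationDesign, generate_study


@pytest.fixture(scope="session")
def small_design():
    return SimulationDesign(
        seed=11,
        n_subjects=10,
        n_serum_conc=20,
        n_serum_pct=10,
        n_csf=8,
        n_species=25,
        n_diet_affected=5,
        n_dx_affected=5,
        missing_rate=0.02,
        n_outlier_samples=1,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    return generate_study(small_design)


def make_matrix(values: np.ndarray, kind: str = "concentration", prefix: str = "f") -> FeatureMatrix:
    """Quick FeatureMatrix around a raw numpy array."""
    n, p = values.shape
    cols = [f"{prefix}{j}" for j in range(p)]
    vals = pd.DataFrame(values, index=[f"s{i}" for i in range(n)], columns=cols)
    meta = pd.DataFrame(
        {"fluid": "serum", "value_kind": kind, "group": "g"}, index=pd.Index(cols, name="feature")
    )
    return FeatureMatrix(vals, meta)
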