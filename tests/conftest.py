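import numpy as np
import pandas as pd
import pytest

from senemeth import synthetic_data as sd
from senemeth.io_formats import BetaMatrix, StudyDesign


@pytest.fixture(scope="session")
def small_params():
    return sd.SimulationParams(n_cpgs=400, n_dm_culture=(8, 8),
                               n_dm_aging=(8, 8), seed=11)


@pytest.fixture(scope="session")
def small_study(small_params):
    return sd.generate_methylation_study(small_params)


@pytest.fixture(scope="session")
def small_annotation(small_params):
    return sd.generate_annotation(small_params)


@pytest.fixture
def tiny_beta():
    return BetaMatrix(pd.DataFrame(
        [[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]],
        index=["cg1", "cg2", "cg3"], columns=["s1", "s2"],
    ))


@pytest.fixture
def four_donor_design():
    rows = []
    for i, age in enumerate(["young", "young", "elderly", "elderly"]):
        donor = f"D{i + 1}"
        for pg in ("early", "late"):
            rows.append({"sample_id": f"{donor}_{pg}", "donor_id": donor,
                         "passage_group": pg, "age_group": age})
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


def random_beta(rng: np.random.Generator, n: int = 20, k: int = 4,
                missing: float = 0.0) -> BetaMatrix:
    vals = rng.random((n, k))
    if missing > 0:
        vals[rng.random((n, k)) < missing] = np.nan
    return BetaMatrix(pd.DataFrame(
        vals, index=[f"cg{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(k)],
    ))
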