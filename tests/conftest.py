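import numpy as np
import pytest

import wolfberry as wb


@pytest.fixture(scope="session")
def table2() -> wb.QualityDataset:
    return wb.load_table2()


@pytest.fixture(scope="session")
def ref_rsm() -> wb.QuadraticRSM:
    return wb.reference_rsm()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def space() -> wb.FactorSpace:
    return wb.wolfberry_space()
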