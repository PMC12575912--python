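import numpy as np
import pytest

import lvikit as lk

# group-level median parameter sets used throughout the tests
# (LVI-positive / LVI-negative), in mm^2/s and fractions
LVI_POS_IVIM = lk.IVIMParams(d=0.72e-3, dstar=75.06e-3, f=0.4156)
LVI_NEG_IVIM = lk.IVIMParams(d=0.96e-3, dstar=68.19e-3, f=0.410)
LVI_POS_DKI = lk.DKIParams(dapp=2.29e-3, kapp=0.84)
LVI_NEG_DKI = lk.DKIParams(dapp=2.69e-3, kapp=0.70)


@pytest.fixture(scope="session")
def ivim_scheme():
    return lk.make_bvalue_scheme("ivim")


@pytest.fixture(scope="session")
def dki_scheme():
    return lk.make_bvalue_scheme("dki")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-calibrated cohort (26 LVI+ / 47 LVI-, two readers)."""
    return lk.generate_cohort(lk.default_cohort_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
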