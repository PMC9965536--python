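import warnings

import pytest

from pbbm import (
    MechPeffLite,
    calibration_measurements,
    default_compound,
    default_disposition,
    default_dlm_config,
    default_psd,
    fit_logkmw,
    ptrans0_from_logp,
)
from pbbm.micelle import InfeasibleSolubilityWarning


@pytest.fixture(scope="session")
def compound():
    return default_compound()


@pytest.fixture(scope="session")
def partition(compound):
    """Micelle partition fitted to the packaged calibration media pair."""
    return fit_logkmw(calibration_measurements("oa_ch"), compound)


@pytest.fixture(scope="session")
def mech(compound):
    return MechPeffLite(p_trans0=ptrans0_from_logp(compound.logP))


@pytest.fixture(scope="session")
def psd():
    return default_psd()


@pytest.fixture(scope="session")
def dlm():
    return default_dlm_config()


@pytest.fixture(scope="session")
def disposition():
    return default_disposition()


@pytest.fixture(autouse=True)
def _quiet_infeasible_media():
    """Noise can push a synthetic medium below its aqueous solubility;
    the fitter warns and drops it, which is expected in recovery runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InfeasibleSolubilityWarning)
        yield
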