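import numpy as np
import pytest

from brainpbpk import (
    default_physiology,
    default_time_grid,
    icv_infusion,
    iv_bolus,
    load_drug,
    simulate,
)
from brainpbpk.synth import default_design, generate_dataset

BW = 0.310  # kg, mean rat body weight used throughout the study design


@pytest.fixture(scope="session")
def phys():
    return default_physiology()


@pytest.fixture(scope="session")
def egfr():
    return load_drug("EGFRvIII-TCB")


@pytest.fixture(scope="session")
def iv_sim(phys, egfr):
    """15 mg/kg IV bolus, 48 h."""
    return simulate(phys, egfr, [iv_bolus(15.0, BW, egfr.MW)], default_time_grid(48.0))


@pytest.fixture(scope="session")
def icv3_sim(phys, egfr):
    """3 mg/kg ICV infusion, 48 h."""
    return simulate(
        phys, egfr, [icv_infusion(3.0, BW, egfr.MW)], default_time_grid(48.0)
    )


@pytest.fixture(scope="session")
def icv1_sim(phys, egfr):
    return simulate(
        phys, egfr, [icv_infusion(1.0, BW, egfr.MW)], default_time_grid(48.0)
    )


@pytest.fixture(scope="session")
def noisefree_df(phys, egfr):
    """Three-arm synthetic study with all residual SDs set to zero."""
    design = default_design(egfr).replace(
        prop_sd_serum=0.0, add_sd_csf_nM=0.0, add_sd_isf_nM=0.0
    )
    return generate_dataset(design, phys, egfr, seed=11)
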