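import numpy as np
import pytest

from hcqpbpk import (DosingRegimen, PBPKModel, build_reference_adult,
                     default_time_grid, load_drug)


@pytest.fixture(scope="session")
def drug():
    return load_drug()


@pytest.fixture(scope="session")
def reference_adult():
    return build_reference_adult("F", 22.6, 63.5)


@pytest.fixture(scope="session")
def iv_regimen():
    return DosingRegimen(route="iv_infusion", dose_base=155.0, infusion_duration=30.0)


@pytest.fixture(scope="session")
def oral_regimen():
    return DosingRegimen(route="oral", dose_base=155.0)


@pytest.fixture(scope="session")
def iv_simulation(drug, reference_adult, iv_regimen):
    """One reference IV run shared by engine/NCA tests (0-72 h, 0.1 h grid)."""
    model = PBPKModel(reference_adult, drug, iv_regimen)
    return model.simulate(times=default_time_grid(72.0, 0.1), rtol=1e-8, atol=1e-10)


@pytest.fixture(scope="session")
def oral_simulation(drug, reference_adult, oral_regimen):
    model = PBPKModel(reference_adult, drug, oral_regimen)
    return model.simulate(times=default_time_grid(72.0, 0.1), rtol=1e-8, atol=1e-10)
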