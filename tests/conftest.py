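import numpy as np
import pandas as pd
import pytest

from tdi import AgreementData, MixedModelFit, SimulationScenario, generate_dataset
from tdi.model_fit import difference_params

# Parameter estimates of the blood-pressure device comparison (manual
# sphygmomanometer vs automatic monitor, 384 subjects, duplicate readings):
# device effect 2.174 mmHg, error variance 52.867, subject variance 380.187.
CASE = {
    "beta_diff": 2.174,
    "intercept": 133.369,
    "sigma2_alpha": 380.187,
    "sigma2_gamma": 0.0,
    "sigma2_e": 52.867,
    "n": 384,
    "m": 2,
}
CASE_SIGMA_D = np.sqrt(2 * CASE["sigma2_e"])  # 10.2827...


@pytest.fixture(scope="session")
def case_fit() -> MixedModelFit:
    return MixedModelFit(method="reported", include_interaction=False, **CASE)


@pytest.fixture(scope="session")
def case_total(case_fit):
    return difference_params(case_fit, "total")


@pytest.fixture(scope="session")
def case_intra(case_fit):
    return difference_params(case_fit, "intra")


@pytest.fixture(scope="session")
def case_inter(case_fit):
    return difference_params(case_fit, "inter")


@pytest.fixture(scope="session")
def bp_like_data() -> AgreementData:
    """A medium synthetic dataset under the blood-pressure-like conditions."""
    scenario = SimulationScenario(beta_diff=2.174, sigma2_e=52.867, n=60, seed=11)
    return generate_dataset(scenario, 11)


@pytest.fixture()
def tiny_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": ["s1"] * 4,
            "device": ["a", "a", "b", "b"],
            "replicate": [1, 2, 1, 2],
            "value": [1.0, 1.5, 2.0, 2.5],
        }
    )
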