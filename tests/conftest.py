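import math
from pathlib import Path

import pytest

from gr_eam import (
    DEFAULT_RT,
    gr_isoform_family,
    isoform_model,
    reference_frustrated_params,
    two_domain_model,
)

CONFIG_DIR = Path(__file__).resolve().parents[1] / "configs"

# Exact rational expectations for the reference frustrated parameter set
# (every Boltzmann weight a power of two; hand-enumerable):
# weights (R,F,D = 000..111): 1, 1, 1, 4, 2, 16, 1/8, 1
REF_Q = 209 / 8  # 26.125
REF_ACTIVITY = 24 / 209  # 3 / 26.125
REF_AFFINITY = 160 / 209  # 20 / 26.125
# with the R-DBD coupling ablated to zero: weights 1, 1, 1, 4, 2, 4, 1/8, 1/4
ABLATED_Q = 107 / 8  # 13.375
ABLATED_ACTIVITY = 18 / 107  # 2.25 / 13.375
ABLATED_AFFINITY = 58 / 107  # 7.25 / 13.375


@pytest.fixture(scope="session")
def ref_params():
    return reference_frustrated_params()


@pytest.fixture()
def model_a(ref_params):
    """Three-domain A-isoform model at the reference frustrated set."""
    return isoform_model(
        "A",
        ref_params["dG_R"],
        ref_params["dG_F"],
        ref_params["dG_D"],
        ref_params["dg_RF"],
        ref_params["dg_RD"],
        ref_params["dg_FD"],
    )


@pytest.fixture()
def model_c3(ref_params):
    """Two-domain C3 model sharing the reference F/DBD parameters."""
    return two_domain_model(
        "C3", ref_params["dG_F"], ref_params["dG_D"], ref_params["dg_FD"]
    )


@pytest.fixture(scope="session")
def family():
    return gr_isoform_family()


@pytest.fixture(scope="session")
def config_dir():
    return CONFIG_DIR
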