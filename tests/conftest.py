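import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from procat import (
    GradedResponseModel,
    make_fixture_bank,
    make_fixture_responses,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bank():
    """The default synthetic 10-item, 7-category instrument."""
    return make_fixture_bank()


@pytest.fixture(scope="session")
def recovery():
    """Simulate n=1000 responses from the known fixture bank and recalibrate.

    Shared by the parameter-recovery, EM-monotonicity and end-to-end checks
    so the (deterministic) EM runs once per session.
    """
    bank = make_fixture_bank()
    data = make_fixture_responses(bank, 1000, seed=11)
    model = GradedResponseModel().fit(data)
    return bank, data, model


def true_false_params(bank, model):
    a_true = np.array([it.discrimination for it in bank])
    a_hat = np.array([it.discrimination for it in model.item_bank_])
    b_true = np.concatenate([it.thresholds for it in bank])
    b_hat = np.concatenate([it.thresholds for it in model.item_bank_])
    return a_true, a_hat, b_true, b_hat
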