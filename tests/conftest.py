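import numpy as np
import pandas as pd
import pytest

from cfrl import build_schedule, draw_outcomes, get_model, resolve_parameters, simulate_agent
from cfrl.fitting import FitOptions


@pytest.fixture(scope="session")
def design_complete():
    return build_schedule(feedback="complete", seed=11)


@pytest.fixture(scope="session")
def design_partial():
    return build_schedule(feedback="partial", seed=11)


@pytest.fixture(scope="session")
def confirmation():
    return get_model("Confirmation")


@pytest.fixture(scope="session")
def one_model():
    return get_model("One")


@pytest.fixture(scope="session")
def sim_dataset(design_complete, confirmation):
    """One Confirmation-model agent on the full 192-trial complete-feedback task."""
    rng = np.random.default_rng(42)
    params = resolve_parameters(confirmation, [5.0, 0.4, 0.1])
    outcomes = draw_outcomes(design_complete, rng)
    return simulate_agent(confirmation, params, design_complete, outcomes, rng)


@pytest.fixture(scope="session")
def fast_options():
    return FitOptions(n_restarts=4, seed=3)


def make_manual_dataset(choices, r_c, r_u=None, instance=0, session=1, label="Symmetric"):
    """Hand-built single-context dataset for oracle checks."""
    n = len(choices)
    return pd.DataFrame(
        {
            "subject": 0,
            "session": session,
            "context_label": label,
            "context_instance": instance,
            "context_trial": np.arange(1, n + 1),
            "choice": list(choices),
            "outcome_chosen": list(r_c),
            "outcome_unchosen": list(r_u) if r_u is not None else np.nan,
        }
    )
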