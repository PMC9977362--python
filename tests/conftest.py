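import numpy as np
import pytest

from betalat.pipeline import tiny_run_config, run_group


@pytest.fixture(scope="session")
def session_schedule():
    from betalat.schedule import build_session

    return build_session(np.random.default_rng(42))


@pytest.fixture(scope="session")
def tiny_group_result():
    """One reduced-scale group run with the default planted effects."""
    return run_group(tiny_run_config(n_subjects=6, seed=7, snr=2.0))
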