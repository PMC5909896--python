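import pytest

from dapasat.staircase import StaircaseConfig, run_session, scripted_responder


@pytest.fixture
def default_config() -> StaircaseConfig:
    return StaircaseConfig()


@pytest.fixture
def worked_13_session():
    """The published 13-trial scoring sequence h-H-H-H-m-h-H-H-m-h-H-H-m."""
    cfg = StaircaseConfig(n_trials=13)
    return run_session(cfg, scripted_responder("hHHHmhHHmhHHm"), seed=0)


@pytest.fixture
def all_correct_session(default_config):
    return run_session(
        default_config, scripted_responder("h" * default_config.n_trials), seed=0
    )
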