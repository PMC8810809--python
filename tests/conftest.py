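import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirglucose.cli import simulate_cohorts
from nirglucose.cohort import NIR_FIELDS
from nirglucose.config import load_config
from nirglucose.model import GlucoseSDNN
from nirglucose.network import TrainingConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fast_training() -> TrainingConfig:
    """Reduced-budget trainer for unit tests that only exercise mechanics."""
    return TrainingConfig(epochs=150, early_stop_patience=30, n_restarts=1, seed=0)


@pytest.fixture(scope="session")
def default_run():
    """One full study-scale run: 401 training / 234 disjoint test subjects
    simulated under generator defaults, network trained at default settings.

    Session-scoped because the default fit takes tens of seconds; the fitted
    objects are treated as read-only by every consumer.
    """
    cfg = load_config(seed=1)
    train_df, test_df, _ = simulate_cohorts(cfg)
    results = GlucoseSDNN.from_dataframe(train_df).fit(cfg.training)
    return {"config": cfg, "train": train_df, "test": test_df, "results": results}


@pytest.fixture(scope="session")
def nir_only_run(default_run):
    """Ablated model trained on the same cohort with the NIR bands only."""
    cfg = default_run["config"]
    res = GlucoseSDNN.from_dataframe(default_run["train"], features=NIR_FIELDS).fit(cfg.training)
    return {"config": cfg, "results": res}


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
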