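import pytest

from vitaplan.config import default_config
from vitaplan.intake import EarTable
from vitaplan.pipeline import Pipeline
from vitaplan.regions import Region, RegionProfile

# one full pipeline is shared by all tests; calibration and the fitted
# surveys are deterministic for a (config, seed) pair
PIPELINE_SEED = 1
PIPELINE_N = 60_000


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def pipeline(cfg):
    return Pipeline.from_config(cfg, seed=PIPELINE_SEED, n_children=PIPELINE_N)


@pytest.fixture(scope="session")
def ear_table(cfg):
    return EarTable.from_config(cfg)


@pytest.fixture(scope="session")
def profiles(pipeline):
    return {region: cal.profile for region, cal in pipeline.calibrations.items()}


@pytest.fixture(scope="session")
def toy_profile():
    """A hand-built profile for generator unit tests (no calibration needed)."""
    return RegionProfile(
        region=Region.NORTH,
        baseline_inadequate_prev=0.5,
        intake_median=200.0,
        between_cv=1.0,
        within_cv=0.5,
        oil_consumer_frac=0.5,
        oil_g_day_dist=(10.0, 0.6),
        bouillon_consumer_frac=0.9,
        bouillon_g_day_dist=(2.0, 0.6),
        maize_consumer_frac=0.4,
        maize_kcal_day_dist=(300.0, 0.6),
        vas_reach=0.6,
        base_child_population=1000.0,
    )
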