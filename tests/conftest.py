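import numpy as np
import pytest

from eddi.screen import ScreenConfig, run_screen, screened_features
from eddi.synthetic import demo_study

#: reduced-size forest settings used throughout the suite so repeated
#: cross-validation loops stay fast; the pipeline defaults stay at
#: 500 trees / 10x5 CV
FAST_FOREST = dict(n_trees=100, cv_folds=10, cv_repeats=2)


@pytest.fixture(scope="session")
def demo_dataset():
    """Standard demo fixture: 200 cells, 2 co-dependencies, 60 genes,
    10 planted pairs covering all seven modes, moderate noise."""
    return demo_study(seed=11)


@pytest.fixture(scope="session")
def demo_screen(demo_dataset):
    """Screen records + passing feature sets for the demo fixture."""
    records = run_screen(
        demo_dataset.expression, demo_dataset.dependency, ScreenConfig(seed=11)
    )
    return records, screened_features(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
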