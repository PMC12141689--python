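import pandas as pd
import pytest

from motionlat.components import ComponentExtractor
from motionlat.config import scaled_config
from motionlat.laterality import LateralityScorer
from motionlat.layout import ChannelLayout
from motionlat.preprocess import preprocess_epochs
from motionlat.simulate import CohortSimulator


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Tiny noise-free cohort: the generator -> pipeline identity case."""
    return scaled_config({"TC": 3, "WS": 3}, n_trials=6, noise_sd=0.0,
                         artifact_rate=0.0, seed=101)


@pytest.fixture(scope="session")
def noise_free_run(noise_free_cfg, layout):
    """truth, component table and laterality table for the noise-free cohort."""
    sim = CohortSimulator(noise_free_cfg, layout)
    truth = sim.truth()
    ep = sim.epochs(truth, with_artifacts=False)
    avgs = preprocess_epochs(ep, layout)
    comp = ComponentExtractor(layout).transform(avgs)
    lat = LateralityScorer().transform(comp)
    return truth, comp, lat


def measure_cohort(truth, cfg, layout):
    """Run simulate -> preprocess -> components -> laterality per subject."""
    sim = CohortSimulator(cfg, layout)
    frames = []
    for i in range(len(truth)):
        ep = sim.epochs(truth.iloc[[i]])
        avgs = preprocess_epochs(ep, layout)
        frames.append(ComponentExtractor(layout).transform(avgs))
    comp = pd.concat(frames, ignore_index=True)
    return comp, LateralityScorer().transform(comp)
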