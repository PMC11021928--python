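import warnings

import numpy as np
import pytest

from phenomoult import moultfit, synthdata


@pytest.fixture(scope="session")
def big_truth():
    """Latent truth for a sizeable default colony (all four categories)."""
    cfg = synthdata.default_config(n_individuals=120, n_years=3, seed=11)
    truth = synthdata.generate_truth(cfg)
    return cfg, synthdata.truth_to_frame(truth)


@pytest.fixture(scope="session")
def small_colony():
    """A small observed adult colony shared by fitting tests."""
    cfg = synthdata.default_config(
        n_individuals=12, categories=("adult_reproductive",), n_years=2, seed=21
    )
    truth, calendar, records = synthdata.generate_colony(cfg)
    return {
        "config": cfg,
        "truth": synthdata.truth_to_frame(truth),
        "calendar": calendar,
        "sightings": synthdata.sightings_to_frame(records),
    }


@pytest.fixture(scope="session")
def small_fit(small_colony):
    cycles = moultfit.group_cycles(small_colony["sightings"])
    eligible, _ = moultfit.filter_cycles(cycles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = moultfit.fit_hierarchical(
            eligible, moultfit.SamplerConfig(chains=2, draws=500, warmup=600, seed=3)
        )
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
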