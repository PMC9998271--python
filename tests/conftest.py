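import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from plastevol import AnalysisConfig, PlasticityModel, SimParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim_fit():
    """A fitted model at the study's default conditions (moderate effects)."""
    model = PlasticityModel.from_simulation(
        SimParams(n_genes=2500, rng_seed=7), config=AnalysisConfig(rng_seed=7)
    )
    return model, model.fit()


@pytest.fixture(scope="session")
def strong_sim_fit():
    """Strong, low-noise effects: used for recall and set-membership checks."""
    params = SimParams(
        n_genes=1200,
        lfc_scale=4.0,
        dispersion_mean=0.01,
        frac_cec=0.0125,  # 15 true CEC genes
        frac_dp=0.0125,
        rng_seed=5,
    )
    model = PlasticityModel.from_simulation(params, config=AnalysisConfig(rng_seed=5))
    return model, model.fit()


@pytest.fixture()
def toy_design():
    """The standard 24-sample design (4 populations x 2 treatments x 3 clones)."""
    from plastevol.simulate import _build_design

    return _build_design(SimParams(n_genes=10))


@pytest.fixture()
def toy_counts(toy_design):
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.poisson(100, size=(50, len(toy_design))),
        index=[f"g{i}" for i in range(50)],
        columns=toy_design.sample_ids,
    )
    from plastevol import CountMatrix

    return CountMatrix(data)
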