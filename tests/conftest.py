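import numpy as np
import pytest

from ktrcycle import simulate


@pytest.fixture(scope="session")
def small_movie():
    """A small rendered movie with divisions, shared across test modules."""
    cfg = simulate.SimConfig(n_cells=9, duration_hours=20.0, rng_seed=5)
    traces, truth = simulate.simulate_traces(cfg)
    return cfg, traces, truth


@pytest.fixture(scope="session")
def small_pipeline(small_movie):
    """Full pipeline result on the small movie."""
    from ktrcycle import pipeline

    cfg, traces, truth = small_movie
    return pipeline.process_simulation(truth, cfg)


@pytest.fixture(scope="session")
def fixed_field():
    stack, truth = simulate.render_fixed_field(
        n_cells=12, puncta_per_cell=np.tile([0, 5, 12], 4),
        prb_positive_fraction=0.5, edu_positive_fraction=0.5, seed=17)
    return stack, truth
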