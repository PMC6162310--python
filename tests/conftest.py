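import numpy as np
import pytest

from sbtmig import geometry, hmm, simulator


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def generative_params():
    """3-state model at the fitted scale of the real tracks, occupancy-targeted."""
    return simulator.default_params()


@pytest.fixture(scope="session")
def small_population():
    """Modest synthetic deployment shared across segmentation/summary tests."""
    cfg = simulator.SimConfig(n_fish=30, seed=424242)
    trackset, truth = simulator.simulate_population(cfg)
    return cfg, trackset, truth


@pytest.fixture(scope="session")
def recovery_simulation(generative_params):
    """100 tracks x 500 steps drawn straight from the 3-state model."""
    states, obs = simulator.simulate_observations(
        generative_params, n_steps=500, n_tracks=100, rng=np.random.default_rng(777))
    return states, obs


@pytest.fixture(scope="session")
def recovery_fit(recovery_simulation):
    """Pooled EM fit of the recovery simulation from the neutral default init."""
    _, obs = recovery_simulation
    return hmm.fit_em(list(obs))


@pytest.fixture(scope="session")
def decoded_population(small_population):
    """Observations + pooled fit + per-track decodings for the population."""
    cfg, trackset, _ = small_population
    obs = [geometry.step_observations(geometry.distance_to_gab(tr, cfg.gab))[0]
           for tr in trackset]
    fit = hmm.fit_em(obs, n_restarts=3)
    decodings = hmm.decode_tracks(obs, fit.params)
    return obs, fit, decodings
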