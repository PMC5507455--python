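import numpy as np
import pytest

import lightcast as lc
from lightcast.synthetic import CastScript, TrialScript, TurnScript, simulate_trial

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def cfg():
    return lc.Config()


@pytest.fixture(scope="session")
def nominal_spot():
    return lc.LightSpot.nominal()


@pytest.fixture(scope="session")
def f46(cfg):
    """Noise-free F46 fixture: simulations, truths, and full analysis."""
    spec = lc.make_fixture("F46", seed=FIXTURE_SEED)
    sims = lc.simulate_fixture(spec, cfg)
    result = lc.analyze([t for t, _ in sims], spec.arena, cfg)
    return spec, sims, result


@pytest.fixture(scope="session")
def f35(cfg):
    spec = lc.make_fixture("F35", seed=FIXTURE_SEED)
    sims = lc.simulate_fixture(spec, cfg)
    result = lc.analyze([t for t, _ in sims], spec.arena, cfg)
    return spec, sims, result


@pytest.fixture(scope="session")
def single_cast_trial(cfg, nominal_spot):
    """One scripted successful 1-cast turn, noise-free."""
    script = TrialScript(turns=(
        TurnScript(init_distance=8.0,
                   casts=(CastScript(target_offset_px=22.0, end_inside_light=False),)),
    ))
    return simulate_trial(script, nominal_spot, cfg, trial_id="single_cast")


def rand_walk(rng, n, scale=1.0):
    return np.cumsum(rng.normal(0.0, scale, size=(n, 2)), axis=0)
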