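import numpy as np
import pytest
import sympy as sp

import odeident as oi


@pytest.fixture(scope="session")
def models():
    """All bundled example models, built once."""
    return {fid: oi.build_fixture(fid) for fid in oi.FIXTURE_IDS}


@pytest.fixture(scope="session")
def systems(models):
    """Compiled sensitivity systems, shared across tests."""
    cache = {}

    def get(fid):
        if fid not in cache:
            cache[fid] = oi.assemble_sensitivity_system(models[fid])
        return cache[fid]

    return get


def classify_default(fid, seed=0, config=None, **kw):
    """Classify a fixture's default scenario (helper shared by tests)."""
    from odeident.fixtures import default_config, default_scenario

    model = oi.build_fixture(fid)
    _, pattern, _ = default_scenario(fid, seed=seed)
    cfg = config or default_config(fid)
    return oi.classify_pattern(model, pattern, cfg, seed=seed, **kw)


def symbols(names):
    return sp.symbols(names, seq=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
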