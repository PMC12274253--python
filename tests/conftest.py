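import pytest

import protocells as pc


@pytest.fixture(scope="session")
def fig5_trajectories():
    """Trajectories of the three commensurable-clock experiments."""
    out = {}
    for name in ("fig5_init50", "fig5_init60", "fig5_init21000"):
        cfg = pc.preset(name)
        out[name] = pc.run(cfg.schedule, cfg.model, cfg.init)
    return out


@pytest.fixture(scope="session")
def fig7_trajectories():
    """Trajectories of the three x-inflow experiments."""
    out = {}
    for name in ("fig7_b10000", "fig7_b20000", "fig7_b30000"):
        cfg = pc.preset(name)
        out[name] = pc.run(cfg.schedule, cfg.model, cfg.init)
    return out
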