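import pytest

import obesim as ob


@pytest.fixture(scope="session")
def cfg() -> ob.Config:
    """Default (baseline) configuration."""
    return ob.load_config()


@pytest.fixture(scope="session")
def baseline_traj(cfg: ob.Config) -> ob.Trajectory:
    """No-intervention run over the full 520-week horizon."""
    return ob.integrate(cfg.initial_state, cfg.params, cfg.simulation)


@pytest.fixture(scope="session")
def full_sweep(cfg: ob.Config):
    """The complete 6-scenario x 15-alternative sweep plus baseline rows."""
    return ob.run_sweep(
        cfg.params,
        cfg.initial_state,
        magnitude=cfg.magnitude,
        discount=cfg.discount,
        config=cfg.simulation,
    )
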