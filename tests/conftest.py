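import numpy as np
import pytest

import notchemt as ne
from notchemt.scenarios import decay_only_params


@pytest.fixture(scope="session")
def params_on():
    return ne.default_params()


@pytest.fixture(scope="session")
def params_off():
    return ne.default_params(numb_enabled=False)


@pytest.fixture(scope="session")
def decay_params():
    return decay_only_params()


@pytest.fixture(scope="session")
def thresholds(params_off):
    """Branch-anchored phenotype thresholds (calibrated once per session)."""
    return ne.calibrate_thresholds(params_off, seed=0)


@pytest.fixture(scope="session")
def diagram_off(params_off, thresholds):
    """Numb-off bifurcation diagram over J_ext, labelled."""
    return ne.scan_bifurcation("J_ext", (0.0, 3000.0), n_points=60,
                               params=params_off, seed=5,
                               thresholds=thresholds)


@pytest.fixture(scope="session")
def diagram_on(params_on, thresholds):
    return ne.scan_bifurcation("J_ext", (0.0, 3000.0), n_points=60,
                               params=params_on, seed=5,
                               thresholds=thresholds)


@pytest.fixture(scope="session")
def tristable_env(diagram_off):
    """An environment inside the Numb-off tristable window."""
    counts = diagram_off.stable_count()
    idx = np.flatnonzero(counts >= 3)
    assert idx.size, "default parameters must have a tristable window"
    centre = int(idx[len(idx) // 2])
    return ne.Environment(N_ext=10000.0,
                          J_ext=float(diagram_off.grid[centre]))


@pytest.fixture(scope="session")
def small_jagged_run(params_off, thresholds):
    """A small Jagged-dominated lattice run (10x10, 120 h) plus its map."""
    cfg = ne.LatticeConfig(rows=10, cols=10, g_J=80.0, g_D=20.0,
                           duration=120.0, seed=12)
    init = ne.random_initial_lattice(cfg, params_off, replicate=0)
    snaps = ne.integrate_lattice(init, cfg, params_off)
    pmap = ne.classify_lattice(snaps[-1].grid, thresholds)
    return cfg, snaps, pmap
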