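import numpy as np
import pytest

from sptwells.simulate import SimConfig, WellSpec, simulate_well
from sptwells.traj_core import ensemble_from_arrays


@pytest.fixture(scope="session")
def bench_well_ens():
    """A 4 kT benchmark well in a reflecting 2×2 μm region (shared)."""
    spec = WellSpec((0.0, 0.0), 0.15, 0.15, 0.0, 0.4, 0.1)
    cfg = SimConfig(
        dt_obs=0.02, n_traj=300, traj_len=40, seed=11, dt_sim=0.02 / 50,
        domain=(-1.0, -1.0, 1.0, 1.0),
    )
    return spec, simulate_well(spec, cfg)


@pytest.fixture(scope="session")
def brownian_ens():
    """Free Brownian motion at matched sampling density (E = 0 control)."""
    rng = np.random.default_rng(21)
    paths = []
    for _ in range(300):
        x0 = rng.random(2) * 2 - 1
        steps = rng.normal(0, np.sqrt(2 * 0.1 * 0.02), (39, 2))
        paths.append(np.vstack([x0, x0 + np.cumsum(steps, axis=0)]))
    return ensemble_from_arrays(paths, 0.02)
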