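"""Shared fixtures; the expensive level-4 runs are session-scoped."""

import numpy as np
import pytest

from nucleomech import morphodynamics as md
from nucleomech import shell_mesh as smesh
from nucleomech import shell_model as sm

PRESETS = ("stiff", "medium", "soft")
SEEDS = (1, 2, 3)
RUN_DT = 2e-5      # sampling step resolving the collapse chronology
RUN_TMAX = 0.05    # all presets reach membrane contact well before this


@pytest.fixture(scope="session")
def level2_shell():
    return smesh.build_icosphere(2, 1.0)


@pytest.fixture(scope="session")
def reference4():
    """Relaxed level-4 reference shell (zero-pressure equilibrium)."""
    return sm.relax_shell(sm.reference_shell(4))


@pytest.fixture(scope="session")
def preset_runs(reference4):
    """Simulated trajectories + morpho series for all presets and seeds."""
    out = {}
    for seed in SEEDS:
        for preset in PRESETS:
            params = sm.preset_parameters(preset, seed=seed, t_max=RUN_TMAX, dt=RUN_DT)
            traj = sm.simulate(reference4, params, sample_stride=1)
            series = md.morpho_series(traj, reference4, params, classify_stride=5)
            out[(preset, seed)] = (params, traj, series)
    return out


@pytest.fixture(scope="session")
def perturbed_level2(level2_shell):
    rng = np.random.default_rng(7)
    return level2_shell.vertices + rng.normal(0, 0.02, level2_shell.vertices.shape)
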