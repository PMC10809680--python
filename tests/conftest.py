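import numpy as np
import pandas as pd
import pytest

import neurodeconv as nd


@pytest.fixture(scope="session")
def atomic_model():
    """Default-scale atomic model: 5 types, 100 DMPs per direction, delta 0.4."""
    return nd.generate_atomic_profiles(seed=11)


@pytest.fixture(scope="session")
def reference(atomic_model):
    """Ten-fraction reference with modest measurement noise (SD 0.02)."""
    return nd.sample_reference(atomic_model, noise_sd=0.02, seed=12)


@pytest.fixture(scope="session")
def noiseless_reference(atomic_model):
    return nd.sample_reference(atomic_model, noise_sd=0.0, seed=13)


@pytest.fixture(scope="session")
def small_model(atomic_model, reference):
    """ANOVA model for preset panel 1, trained on the noisy reference."""
    ref, sheet = reference
    return nd.anova_select(ref, sheet, nd.get_preset_panel("1"))


def simplex_grid_search(bulk, mu, resolution=0.001, w_max=1.2):
    """Brute-force oracle: best non-negative weights on a coarse-to-fine grid.

    Minimises ||bulk - mu w||^2 over w >= 0 by nested refinement around the
    best grid point, reaching the requested resolution.  Independent of the
    package's solver.
    """
    k = mu.shape[1]
    lo = np.zeros(k)
    hi = np.full(k, w_max)
    step = 0.1
    best = None
    while True:
        axes = [np.arange(lo[d], hi[d] + 1e-12, step) for d in range(k)]
        mesh = np.meshgrid(*axes, indexing="ij")
        cand = np.column_stack([m.ravel() for m in mesh])
        resid = bulk[:, None] - mu @ cand.T
        obj = np.einsum("ij,ij->j", resid, resid)
        best = cand[np.argmin(obj)]
        if step <= resolution:
            return best
        lo = np.maximum(best - step, 0.0)
        hi = best + step
        step /= 10.0


@pytest.fixture(scope="session")
def grid_search_oracle():
    return simplex_grid_search
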