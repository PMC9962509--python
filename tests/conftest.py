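import numpy as np
import pytest

import gaitesn as g


@pytest.fixture(scope="session")
def small_dataset():
    """3+3 participants x 3 speeds x 12 s, default profiles, fixed seed."""
    return g.generate_dataset(3, 3, 3, duration=12.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_profiles():
    healthy = g.GaitProfile(noise_sd=0.0)
    mkoa = g.GaitProfile(
        group="mkoa", mean_speed=0.75, speed_sd=0.23, cycle_duration_mean=1.30,
        cycle_duration_cv=0.06, stance_proportion=0.66, vgrf_valley_depth=0.0,
        impact_sharpness=0.7, noise_sd=0.0,
    )
    return healthy, mkoa


def power_iteration_radius(w: np.ndarray, n_warm: int = 400, m: int = 40,
                           seed: int = 0) -> float:
    """Spectral radius via power iteration refined by a Krylov projection.

    Independent of the full dense eigendecomposition the implementation uses:
    renormalized power iterations align a start vector with the dominant
    invariant subspace, then an Arnoldi basis of dimension ``m`` projects the
    operator onto that subspace and the dominant Ritz value's magnitude is
    returned (handles real, complex-pair and clustered dominance).
    """
    n = w.shape[0]
    m = min(m, n)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x /= np.linalg.norm(x)
    for _ in range(n_warm):
        y = w @ x
        ny = np.linalg.norm(y)
        if ny == 0:
            return 0.0
        x = y / ny
    # Arnoldi on the warmed start vector
    q = np.zeros((n, m + 1))
    h = np.zeros((m + 1, m))
    q[:, 0] = x
    for k in range(m):
        v = w @ q[:, k]
        for j in range(k + 1):
            h[j, k] = q[:, j] @ v
            v -= h[j, k] * q[:, j]
        h[k + 1, k] = np.linalg.norm(v)
        if h[k + 1, k] < 1e-14:
            m = k + 1
            break
        q[:, k + 1] = v / h[k + 1, k]
    ritz = np.linalg.eigvals(h[:m, :m])
    return float(np.max(np.abs(ritz)))


@pytest.fixture(scope="session")
def power_radius():
    return power_iteration_radius
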