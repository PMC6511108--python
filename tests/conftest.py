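import numpy as np
import pytest

from svdconn import (
    StraightBundle,
    TensorFieldSpec,
    TrackingConfig,
    make_parcellation,
    make_tensor_field,
    track,
)

GRID = (30, 12, 12)


@pytest.fixture(scope="session")
def straight_volume():
    """One straight bundle along +x spanning the grid, isotropic background."""
    bundle = StraightBundle(start=[1.0, 5.5, 5.5], direction=[1, 0, 0],
                            length=27.0, radius=2.0)
    return make_tensor_field(
        TensorFieldSpec(grid_dims=GRID, bundles=[bundle], background_fa=0.0)
    )


@pytest.fixture(scope="session")
def straight_tractogram(straight_volume):
    return track(straight_volume, TrackingConfig(seed_spacing=2.0, step_mm=0.5))


@pytest.fixture(scope="session")
def two_region_parcellation():
    return make_parcellation(1, GRID)


def brute_force_efficiencies(w: np.ndarray) -> tuple[float, float]:
    """Independent Floyd-Warshall oracle for global and local efficiency."""

    def floyd_global(mat: np.ndarray) -> float:
        m = mat.shape[0]
        if m < 2:
            return 0.0
        d = np.full((m, m), np.inf)
        np.fill_diagonal(d, 0.0)
        for i in range(m):
            for j in range(m):
                if i != j and mat[i, j] > 0:
                    d[i, j] = 1.0 / mat[i, j]
        for k in range(m):
            for i in range(m):
                for j in range(m):
                    if d[i, k] + d[k, j] < d[i, j]:
                        d[i, j] = d[i, k] + d[k, j]
        total = 0.0
        for i in range(m):
            for j in range(m):
                if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                    total += 1.0 / d[i, j]
        return total / (m * (m - 1))

    n = w.shape[0]
    eglob = floyd_global(w)
    eloc_sum = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) >= 2:
            eloc_sum += floyd_global(w[np.ix_(nbrs, nbrs)])
    return eglob, eloc_sum / n


def random_weighted_graph(rng: np.random.Generator, n_max: int = 20) -> np.ndarray:
    n = int(rng.integers(3, n_max + 1))
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < rng.uniform(0.1, 0.8)
    vals = rng.uniform(0.1, 5.0, size=len(iu)) * mask
    w[iu, ju] = vals
    w[ju, iu] = vals
    return w
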