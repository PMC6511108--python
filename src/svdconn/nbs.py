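"""Network-Based Statistic: edgewise GLM inference with cluster-extent
familywise-error control by permutation.

A general linear model is fitted at every edge of the stacked connectomes; a
contrast t-statistic is thresholded (default t >= 3.1, roughly the p = 0.001
tail of the t distribution at cohort-scale degrees of freedom) and connected
components of suprathreshold edges are measured by extent (edge count). The
familywise-corrected p-value of each observed component is the fraction of
permutations whose *maximal* component is at least as large. Nuisance
covariates are respected with the Freedman-Lane scheme: residuals of the
reduced (nuisance-only) model are permuted, the nuisance fit added back, and
the full model refitted on the reconstructed data. Tests are one-sided; a
two-tailed analysis runs the positive and negative contrasts separately at
half the overall alpha (0.025 per tail by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .connectome import Connectome

__all__ = [
    "DesignMatrix",
    "Contrast",
    "NBSResult",
    "edgewise_glm",
    "suprathreshold_components",
    "nbs_test",
]


@dataclass
class DesignMatrix:
    """Participants x named predictors; must include any intercept explicitly."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data)
        X = self.data.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def columns(self) -> list:
        return list(self.data.columns)


@dataclass
class Contrast:
    """One coefficient per design column; direction picks the tested tail."""

    vector: np.ndarray
    direction: str = "positive"

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.any(self.vector):
            raise ValueError("contrast vector must not be all zero")
        if self.direction not in ("positive", "negative"):
            raise ValueError("direction must be 'positive' or 'negative'")


@dataclass
class NBSResult:
    edge_t: np.ndarray
    components: list  # list of lists of (i, j) node index pairs
    component_sizes: list
    null_max_sizes: np.ndarray
    corrected_p: np.ndarray
    t_threshold: float
    n_permutations: int
    alpha: float
    seed: Optional[int]
    significant: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.significant is None:
            self.significant = np.asarray(self.corrected_p) < self.alpha


def _stack_edges(
    connectomes: Sequence[Union[Connectome, np.ndarray]],
    min_coverage: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Return (Y, iu, ju, n_nodes): participants x tested-edges weight matrix."""
    mats = [c.weights if isinstance(c, Connectome) else np.asarray(c, float)
            for c in connectomes]
    n_nodes = mats[0].shape[0]
    iu, ju = np.triu_indices(n_nodes, k=1)
    Y = np.stack([m[iu, ju] for m in mats])
    coverage = (Y > 0).mean(axis=0)
    keep = coverage >= max(min_coverage, np.finfo(float).tiny)
    return Y[:, keep], iu[keep], ju[keep], n_nodes


def _glm_t(Y: np.ndarray, X: np.ndarray, c: np.ndarray,
           pinvX: np.ndarray, hat_c: float, df: int) -> np.ndarray:
    """Vectorized OLS contrast t over the columns of Y."""
    B = pinvX @ Y                      # p x E
    R = Y - X @ B                      # n x E
    sigma2 = (R * R).sum(axis=0) / df
    num = c @ B
    with np.errstate(invalid="ignore", divide="ignore"):
        t = num / np.sqrt(hat_c * sigma2)
    # a (near-)perfectly fitted edge carries no evidence: t defined as 0
    degenerate = sigma2 <= 1e-12 * ((Y * Y).mean(axis=0) + np.finfo(float).tiny)
    t[degenerate | ~np.isfinite(t)] = 0.0
    return t


def edgewise_glm(
    connectomes: Sequence[Union[Connectome, np.ndarray]],
    design: DesignMatrix,
    contrast: Contrast,
    min_coverage: float = 0.0,
) -> np.ndarray:
    """Contrast t-statistic of an OLS fit at every tested edge.

    Edges are tested where at least a ``min_coverage`` fraction of
    participants has nonzero weight (default: any participant). Returns a
    symmetric n_nodes x n_nodes matrix, zero at untested edges.
    """
    X = design.matrix
    n, p = X.shape
    if len(connectomes) != n:
        raise ValueError("row count of design must equal number of connectomes")
    if n < p + 2:
        raise ValueError("need at least design-columns + 2 participants")
    if len(contrast.vector) != p:
        raise ValueError("contrast length must match design columns")
    Y, iu, ju, n_nodes = _stack_edges(connectomes, min_coverage)
    pinvX = np.linalg.pinv(X)
    hat_c = float(contrast.vector @ np.linalg.inv(X.T @ X) @ contrast.vector)
    df = n - np.linalg.matrix_rank(X)
    t = _glm_t(Y, X, contrast.vector, pinvX, hat_c, df)
    out = np.zeros((n_nodes, n_nodes))
    out[iu, ju] = t
    out[ju, iu] = t
    return out


def _max_component_size(iu: np.ndarray, ju: np.ndarray, mask: np.ndarray) -> int:
    """Edge count of the largest connected component among masked edges (union-find)."""
    idx = np.nonzero(mask)[0]
    m = len(idx)
    if m <= 1:
        return m
    parent: dict = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k in idx:
        a, b = int(iu[k]), int(ju[k])
        for node in (a, b):
            if node not in parent:
                parent[node] = node
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    counts: dict = {}
    for k in idx:
        root = find(int(iu[k]))
        counts[root] = counts.get(root, 0) + 1
    return max(counts.values())


def suprathreshold_components(
    edge_t: np.ndarray, t_threshold: float
) -> tuple[list, list]:
    """Connected components of the graph of edges with t >= threshold.

    Returns (components, sizes); each component is a list of (i, j) node
    pairs and its size is the edge count (cluster extent).
    """
    edge_t = np.asarray(edge_t, dtype=float)
    if not np.allclose(edge_t, edge_t.T):
        raise ValueError("t-matrix must be symmetric")
    iu, ju = np.triu_indices(edge_t.shape[0], k=1)
    mask = edge_t[iu, ju] >= t_threshold
    idx = np.nonzero(mask)[0]
    # union-find over nodes touched by suprathreshold edges
    parent: dict = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k in idx:
        a, b = int(iu[k]), int(ju[k])
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict = {}
    for k in idx:
        root = find(int(iu[k]))
        comps.setdefault(root, []).append((int(iu[k]), int(ju[k])))
    components = sorted(comps.values(), key=len, reverse=True)
    return components, [len(c) for c in components]


def nbs_test(
    connectomes: Sequence[Union[Connectome, np.ndarray]],
    design: DesignMatrix,
    contrast: Contrast,
    t_threshold: float = 3.1,
    n_permutations: int = 10000,
    alpha: float = 0.025,
    seed: Optional[int] = None,
    min_coverage: float = 0.0,
) -> NBSResult:
    """Permutation familywise inference on suprathreshold component extent.

    The null distribution records the maximal component size of each
    Freedman-Lane permutation; corrected p of an observed component of size
    s is (1 + #{null >= s}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a very coarse p-value")
    X = design.matrix
    n, p = X.shape
    c = contrast.vector
    if len(c) != p:
        raise ValueError("contrast length must match design columns")
    if len(connectomes) != n:
        raise ValueError("row count of design must equal number of connectomes")
    if n < p + 2:
        raise ValueError("need at least design-columns + 2 participants")
    sign = 1.0 if contrast.direction == "positive" else -1.0
    c_eff = sign * c

    Y, iu, ju, n_nodes = _stack_edges(connectomes, min_coverage)
    pinvX = np.linalg.pinv(X)
    hat_c = float(c_eff @ np.linalg.inv(X.T @ X) @ c_eff)
    df = n - np.linalg.matrix_rank(X)

    t_obs = _glm_t(Y, X, c_eff, pinvX, hat_c, df)
    obs_mask = t_obs >= t_threshold
    # full symmetric matrix of observed (signed) t values
    edge_t = np.zeros((n_nodes, n_nodes))
    edge_t[iu, ju] = sign * t_obs
    edge_t[ju, iu] = sign * t_obs
    sup = np.zeros((n_nodes, n_nodes))
    sup[iu[obs_mask], ju[obs_mask]] = 1.0
    sup[ju[obs_mask], iu[obs_mask]] = 1.0
    components, sizes = suprathreshold_components(sup, 0.5)

    # Freedman-Lane: reduced model = columns with zero contrast weight.
    nuisance = np.abs(c) == 0
    rng = np.random.default_rng(seed)
    if nuisance.any():
        Z = X[:, nuisance]
        pinvZ = np.linalg.pinv(Z)
        fitted = Z @ (pinvZ @ Y)
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted

    null_max = np.empty(n_permutations, dtype=int)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        Yb = fitted + resid[perm]
        tb = _glm_t(Yb, X, c_eff, pinvX, hat_c, df)
        null_max[b] = _max_component_size(iu, ju, tb >= t_threshold)

    sizes_arr = np.asarray(sizes)
    corrected_p = np.array(
        [(1 + np.count_nonzero(null_max >= s)) / (1 + n_permutations) for s in sizes_arr]
    )
    return NBSResult(
        edge_t=edge_t,
        components=components,
        component_sizes=sizes,
        null_max_sizes=null_max,
        corrected_p=corrected_p,
        t_threshold=t_threshold,
        n_permutations=n_permutations,
        alpha=alpha,
        seed=seed,
    )
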