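"""Length-corrected structural connectome construction.

Each unordered region pair (i, j) is weighted by the streamlines whose two
endpoints fall in the two regions:

    w(e_ij) = sum over streamlines n in N_ij of 1 / (kappa * l_n)

where l_n is streamline length in mm and kappa the seed density in seeds per
millimetre. Dividing by kappa * l corrects for the number of seeds per
millimetre: a streamline of length l collects about kappa * l seeds, each of
which reconstructs the same trajectory, so without the correction long
connections would be weighted up in proportion to their length. Edges below
a weight threshold (default 1) are removed as likely false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tractography import Streamline, Tractogram

__all__ = [
    "Parcellation",
    "Connectome",
    "EdgeWeightConfig",
    "assign_endpoints",
    "build_connectome",
]


@dataclass
class Parcellation:
    """Integer label volume (0 = unlabeled) with node names and voxel->mm affine."""

    labels: np.ndarray
    node_names: dict
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.node_names)
        if missing:
            raise ValueError(f"node_names missing labels: {sorted(missing)}")

    @property
    def label_ids(self) -> list:
        """Sorted labels, defining node order in the connectivity matrix."""
        return sorted(self.node_names)

    def label_at_mm(self, point_mm: np.ndarray) -> Optional[int]:
        """Label of the voxel containing a mm point; None if outside or unlabeled.

        Voxel i covers the half-open interval [i - 0.5, i + 0.5) of the
        continuous voxel coordinate: a point exactly on a voxel boundary is
        assigned by the floor of its corner coordinate, i.e. to the upper
        voxel.
        """
        inv = np.linalg.inv(self.affine)
        vc = inv[:3, :3] @ np.asarray(point_mm, dtype=float) + inv[:3, 3]
        idx = np.floor(vc + 0.5).astype(int)  # voxel centres at integer coords
        if np.any(idx < 0) or np.any(idx >= np.array(self.labels.shape)):
            return None
        lab = int(self.labels[tuple(idx)])
        return lab if lab != 0 else None


@dataclass
class Connectome:
    """Weighted undirected node-labeled connectivity matrix."""

    weights: np.ndarray
    node_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be zero")
        if not self.node_names:
            self.node_names = [f"node{i + 1}" for i in range(n)]
        if len(self.node_names) != n:
            raise ValueError("node_names length must match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class EdgeWeightConfig:
    seeds_per_mm: float = 2.0  # 1 / seed_spacing for the default 0.5 mm grid
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.seeds_per_mm <= 0 or self.threshold <= 0:
            raise ValueError("seeds_per_mm and threshold must be positive")


def assign_endpoints(
    streamline: Streamline, parcellation: Parcellation
) -> tuple[Optional[int], Optional[int]]:
    """Labels of the voxels containing the streamline's two terminal points."""
    return (
        parcellation.label_at_mm(streamline.points[0]),
        parcellation.label_at_mm(streamline.points[-1]),
    )


def build_connectome(
    tractogram: Tractogram,
    parcellation: Parcellation,
    config: EdgeWeightConfig = EdgeWeightConfig(),
) -> Connectome:
    """Aggregate a tractogram into a length-corrected, thresholded connectome.

    Streamlines with an unlabeled endpoint or both endpoints in the same
    region contribute to no edge. Entries below ``config.threshold`` are
    zeroed; entries at exactly the threshold are kept. Thresholded weights
    are retained (not binarized) for downstream weighted metrics.
    """
    ids = parcellation.label_ids
    index = {lab: k for k, lab in enumerate(ids)}
    n = len(ids)
    w = np.zeros((n, n))
    for sl in tractogram.streamlines:
        if sl.length_mm <= 0:
            raise ValueError("streamline of zero length")
        a, b = assign_endpoints(sl, parcellation)
        if a is None or b is None or a == b:
            continue
        contrib = 1.0 / (config.seeds_per_mm * sl.length_mm)
        i, j = index[a], index[b]
        w[i, j] += contrib
        w[j, i] += contrib
    # keep-if->= with a relative tolerance so exact-boundary weights survive
    # floating-point accumulation of the 1/(kappa*l) terms
    w[w < config.threshold * (1.0 - 1e-9)] = 0.0
    np.fill_diagonal(w, 0.0)
    return Connectome(w, [parcellation.node_names[lab] for lab in ids])
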