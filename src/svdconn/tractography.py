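"""Deterministic whole-volume streamline tractography on a diffusion tensor field.

Streamlines are seeded on a regular millimetre grid, propagated in both the
orthograde and retrograde directions along the principal eigenvector of the
trilinearly interpolated tensor, and terminated when fractional anisotropy
drops below a threshold, when the turning angle between successive principal
eigenvectors reaches the angle threshold, when a maximum length is reached,
or when the streamline leaves the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TensorVolume",
    "Streamline",
    "Tractogram",
    "TrackingConfig",
    "fractional_anisotropy",
    "principal_direction",
    "seed_grid",
    "track",
]

# Lower-triangular component order used on disk and in interpolation.
TENSOR_COMPONENT_ORDER = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")
_TRI_I = np.array([0, 0, 1, 0, 1, 2])
_TRI_J = np.array([0, 1, 1, 2, 2, 2])

_DEGENERACY_TOL = 1e-10


@dataclass
class TensorVolume:
    """A 3-D grid of symmetric diffusion tensors with voxel geometry.

    ``tensors`` has shape ``(nx, ny, nz, 3, 3)``; ``affine`` maps voxel
    indices (voxel centres) to mm coordinates.
    """

    tensors: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be 3 positive values (mm)")
        if self.affine is None:
            self.affine = np.diag(np.append(self.voxel_size, 1.0))
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2)):
            raise ValueError("tensors must be symmetric")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def to_components(self) -> np.ndarray:
        """Return the 6 unique components, lower-triangular order, shape (nx,ny,nz,6)."""
        return self.tensors[..., _TRI_I, _TRI_J]

    @classmethod
    def from_components(
        cls, comps: np.ndarray, voxel_size, affine: Optional[np.ndarray] = None
    ) -> "TensorVolume":
        comps = np.asarray(comps, dtype=float)
        t = np.zeros(comps.shape[:3] + (3, 3))
        t[..., _TRI_I, _TRI_J] = comps
        t[..., _TRI_J, _TRI_I] = comps
        return cls(t, np.asarray(voxel_size, dtype=float), affine)

    def mm_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(points_mm)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_mm(self, points_vox: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_vox)
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def interpolate(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinearly interpolate tensors at mm points.

        Returns ``(tensors, inside)`` where ``tensors`` has shape (m, 3, 3)
        and ``inside`` marks points within the interpolatable region (between
        the centres of the boundary voxels).
        """
        vc = self.mm_to_voxel(points_mm)
        dims = np.array(self.dims)
        inside = np.all((vc >= 0.0) & (vc <= dims - 1), axis=1)
        vc_cl = np.clip(vc, 0.0, dims - 1.0)
        i0 = np.minimum(np.floor(vc_cl).astype(int), dims - 2 if np.all(dims > 1) else 0)
        i0 = np.clip(i0, 0, np.maximum(dims - 2, 0))
        frac = vc_cl - i0
        comps = self.to_components()
        out = np.zeros((vc.shape[0], 6))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ix = np.clip(i0[:, 0] + dx, 0, dims[0] - 1)
                    iy = np.clip(i0[:, 1] + dy, 0, dims[1] - 1)
                    iz = np.clip(i0[:, 2] + dz, 0, dims[2] - 1)
                    w = (
                        (frac[:, 0] if dx else 1 - frac[:, 0])
                        * (frac[:, 1] if dy else 1 - frac[:, 1])
                        * (frac[:, 2] if dz else 1 - frac[:, 2])
                    )
                    out += w[:, None] * comps[ix, iy, iz]
        t = np.zeros((vc.shape[0], 3, 3))
        t[:, _TRI_I, _TRI_J] = out
        t[:, _TRI_J, _TRI_I] = out
        return t, inside


@dataclass
class Streamline:
    """An ordered polyline in mm coordinates with a fixed step length."""

    points: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("a streamline needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(np.abs(seg - self.step) > 1e-6):
            raise ValueError("consecutive points must be `step` mm apart")

    @property
    def length_mm(self) -> float:
        return float((len(self.points) - 1) * self.step)


@dataclass
class Tractogram:
    """A set of streamlines plus the configuration that generated them."""

    streamlines: list
    config: "TrackingConfig"

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class TrackingConfig:
    seed_spacing: float = 0.5
    fa_threshold: float = 0.2
    angle_threshold_deg: float = 45.0
    step_mm: float = 0.5
    max_length_mm: float = 300.0

    def __post_init__(self) -> None:
        if min(self.seed_spacing, self.fa_threshold, self.angle_threshold_deg,
               self.step_mm, self.max_length_mm) <= 0:
            raise ValueError("all tracking parameters must be positive")
        if not 0 < self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in (0, 1)")
        if self.angle_threshold_deg > 90:
            raise ValueError("angle_threshold_deg must lie in (0, 90]")


def fractional_anisotropy(tensor: np.ndarray) -> float:
    """FA of a symmetric tensor: sqrt(3/2) * ||lam - mean(lam)|| / ||lam||."""
    tensor = np.asarray(tensor, dtype=float)
    lam = np.linalg.eigvalsh(tensor)
    norm = np.linalg.norm(lam)
    if norm == 0:
        raise ValueError("FA is undefined for the zero tensor")
    return float(np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm)


def _fa_batch(tensors: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh(tensors)
    norm = np.linalg.norm(lam, axis=-1)
    dev = np.linalg.norm(lam - lam.mean(axis=-1, keepdims=True), axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    fa[norm == 0] = 0.0
    return fa


def principal_direction(
    tensor: np.ndarray, previous: Optional[np.ndarray] = None
) -> Optional[np.ndarray]:
    """Unit eigenvector of the largest eigenvalue, or None on degeneracy.

    The sign is chosen to continue the current streamline (positive dot
    product with ``previous``); for the first step the convention is that the
    first non-zero component is positive.
    """
    lam, vec = np.linalg.eigh(np.asarray(tensor, dtype=float))
    if lam[2] - lam[1] <= _DEGENERACY_TOL * max(abs(lam[2]), 1e-300):
        return None
    v = vec[:, 2]
    if previous is not None:
        if float(v @ previous) < 0:
            v = -v
    else:
        nz = np.nonzero(np.abs(v) > 1e-12)[0]
        if len(nz) and v[nz[0]] < 0:
            v = -v
    return v / np.linalg.norm(v)


def _propagate(
    volume: TensorVolume,
    start: np.ndarray,
    direction: np.ndarray,
    config: TrackingConfig,
    cos_thresh: float,
    max_steps: int,
) -> list:
    """Walk from ``start`` along ``direction``; return the points beyond the start."""
    points = []
    p = start
    d = direction
    for _ in range(max_steps):
        nxt = p + config.step_mm * d
        t, inside = volume.interpolate(nxt[None, :])
        if not inside[0]:
            break
        fa = _fa_batch(t)[0]
        if fa < config.fa_threshold:
            break
        d_new = principal_direction(t[0], previous=d)
        if d_new is None:
            break
        if float(d @ d_new) < cos_thresh:  # turning angle >= threshold
            break
        points.append(nxt)
        p, d = nxt, d_new
    return points


def seed_grid(volume: TensorVolume, seed_spacing: float) -> np.ndarray:
    """Evenly spaced mm seed grid spanning the volume's voxel-centre box."""
    dims = np.array(volume.dims)
    lo = volume.voxel_to_mm(np.zeros((1, 3)))[0]
    hi = volume.voxel_to_mm((dims - 1)[None, :].astype(float))[0]
    axes = [np.arange(min(lo[k], hi[k]), max(lo[k], hi[k]) + 1e-9, seed_spacing)
            for k in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)


def track(
    volume: TensorVolume,
    config: TrackingConfig = TrackingConfig(),
    seeds: Optional[np.ndarray] = None,
) -> Tractogram:
    """Whole-volume deterministic tractography.

    One candidate streamline per seed on an evenly spaced ``seed_spacing`` mm
    grid wherever interpolated FA clears the threshold (``seeds`` overrides
    the grid with explicit mm points); each seed is propagated in both
    directions and the halves concatenated. Streamlines shorter than two
    steps are discarded.
    """
    if np.any(config.step_mm >= volume.voxel_size * np.array(volume.dims)):
        raise ValueError("step_mm must be smaller than the volume extent")
    grid = seed_grid(volume, config.seed_spacing) if seeds is None \
        else np.atleast_2d(np.asarray(seeds, dtype=float))
    tensors, inside = volume.interpolate(grid)
    fa = _fa_batch(tensors)
    seed_mask = inside & (fa >= config.fa_threshold)
    seeds = grid[seed_mask]
    seed_tensors = tensors[seed_mask]

    cos_thresh = float(np.cos(np.deg2rad(config.angle_threshold_deg)))
    streamlines: list[Streamline] = []
    for seed, t in zip(seeds, seed_tensors):
        d0 = principal_direction(t)
        if d0 is None:
            continue
        max_steps = int(np.floor(config.max_length_mm / config.step_mm))
        fwd = _propagate(volume, seed, d0, config, cos_thresh, max_steps)
        bwd = _propagate(volume, seed, -d0, config, cos_thresh, max_steps - len(fwd))
        pts = bwd[::-1] + [seed] + fwd
        if len(pts) < 3:  # fewer than 2 steps
            continue
        streamlines.append(Streamline(np.array(pts), config.step_mm))
    return Tractogram(streamlines, config)
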