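"""Synthetic tensor fields, parcellations, and cohorts for end-to-end testing.

The cohort generator encodes the causal structure the downstream analysis is
designed to detect: small-vessel-disease burden (log-normal white-matter
hyperintensity volume, Poisson lacunar-infarct count) attenuates all
connectome weights multiplicatively, which lowers global efficiency; apathy
loads on global efficiency with a configurable standardized effect and, in
addition, attenuates a planted edge subnetwork; depressive symptoms
correlate with apathy but have zero loading on network weights, so the
apathy/depression dissociation is testable. Multiplicative attenuation is
used because weighted global efficiency is then exactly proportional to the
common weight factor, making parameter recovery provable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, Parcellation
from .graph_metrics import density, global_efficiency, local_efficiency
from .stats import assign_group
from .tractography import TensorVolume

__all__ = [
    "StraightBundle",
    "ArcBundle",
    "TensorFieldSpec",
    "CohortSpec",
    "make_tensor_field",
    "make_parcellation",
    "default_base_connectome",
    "simulate_cohort",
]


# --------------------------------------------------------------------------
# Tensor-field phantoms
# --------------------------------------------------------------------------

@dataclass
class StraightBundle:
    """A straight fiber bundle: a tube around a line segment."""

    start: Sequence[float]  # mm
    direction: Sequence[float]  # unit tangent
    length: float  # mm
    radius: float  # tube radius, mm
    principal_diffusivity: float = 1.7
    secondary_diffusivity: float = 0.3

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)
        if min(self.principal_diffusivity, self.secondary_diffusivity) <= 0:
            raise ValueError("diffusivities must be positive")

    def tangent_and_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = points - self.start
        t = np.clip(rel @ self.direction, 0.0, self.length)
        nearest = self.start + t[:, None] * self.direction
        dist = np.linalg.norm(points - nearest, axis=1)
        tangents = np.broadcast_to(self.direction, points.shape)
        return tangents, dist


@dataclass
class ArcBundle:
    """A circular-arc bundle in a z = const plane."""

    center: Sequence[float]  # mm
    arc_radius: float  # mm, radius of the centreline circle
    start_angle_deg: float
    end_angle_deg: float
    radius: float  # tube radius, mm
    principal_diffusivity: float = 1.7
    secondary_diffusivity: float = 0.3

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.end_angle_deg <= self.start_angle_deg:
            raise ValueError("end angle must exceed start angle")
        if min(self.principal_diffusivity, self.secondary_diffusivity) <= 0:
            raise ValueError("diffusivities must be positive")

    def tangent_and_distance(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rel = points - self.center
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        lo, hi = np.deg2rad(self.start_angle_deg), np.deg2rad(self.end_angle_deg)
        # map angles into a window containing the span before clamping
        phi = np.where(phi < lo - np.pi, phi + 2 * np.pi, phi)
        phi = np.where(phi > hi + np.pi, phi - 2 * np.pi, phi)
        phi = np.clip(phi, lo, hi)
        nearest = self.center + self.arc_radius * np.column_stack(
            [np.cos(phi), np.sin(phi), np.zeros_like(phi)]
        )
        dist = np.linalg.norm(points - nearest, axis=1)
        tangents = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
        return tangents, dist


@dataclass
class TensorFieldSpec:
    grid_dims: tuple
    voxel_size: tuple = (1.0, 1.0, 1.0)
    bundles: list = field(default_factory=list)
    background_fa: float = 0.05
    background_md: float = 0.7  # mean diffusivity of the background tensor
    noise_sd: float = 0.0
    crossing_policy: Optional[str] = None  # None | 'sum' | 'overwrite'
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_fa < 1:
            raise ValueError("background_fa must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.crossing_policy not in (None, "sum", "overwrite"):
            raise ValueError("crossing_policy must be None, 'sum' or 'overwrite'")


def _axial_tensor(tangents: np.ndarray, d_par: float, d_perp: float) -> np.ndarray:
    """Axially symmetric tensors with principal axis along each tangent."""
    outer = tangents[:, :, None] * tangents[:, None, :]
    return (d_par - d_perp) * outer + d_perp * np.eye(3)


def _background_eigenvalues(fa: float, md: float) -> tuple[float, float]:
    """Eigenvalues (a, b, b) of an axially symmetric tensor with given FA.

    For lam = (a, b, b), FA = (a - b) / sqrt(a^2 + 2 b^2); solve for a at
    b = 1 and rescale so the mean diffusivity is ``md``.
    """
    if fa == 0:
        a = b = 1.0
    else:
        f2 = fa * fa
        a = (1 + np.sqrt(1 - (1 - f2) * (1 - 2 * f2))) / (1 - f2)
        b = 1.0
    scale = 3 * md / (a + 2 * b)
    return a * scale, b * scale


def make_tensor_field(spec: TensorFieldSpec) -> TensorVolume:
    """Build a tensor volume whose in-bundle voxels have principal
    eigenvector tangent to the bundle geometry.

    Voxels covered by more than one bundle raise an error unless a crossing
    policy is declared ('sum' adds the tensors, which makes the principal
    direction degenerate at orthogonal crossings and so terminates tracking
    there; 'overwrite' keeps the last bundle listed).
    """
    dims = tuple(int(d) for d in spec.grid_dims)
    vs = np.asarray(spec.voxel_size, dtype=float)
    idx = np.stack(np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"), axis=-1)
    points = idx.reshape(-1, 3) * vs  # voxel centres, default affine diag(vs)

    a_bg, b_bg = _background_eigenvalues(spec.background_fa, spec.background_md)
    bg = np.diag([a_bg, b_bg, b_bg])
    tensors = np.broadcast_to(bg, (points.shape[0], 3, 3)).copy()
    covered = np.zeros(points.shape[0], dtype=int)

    for bundle in spec.bundles:
        tangents, dist = bundle.tangent_and_distance(points)
        inside = dist <= bundle.radius
        clash = inside & (covered > 0)
        if np.any(clash) and spec.crossing_policy is None:
            raise ValueError(
                "bundles overlap; declare crossing_policy='sum' or 'overwrite'"
            )
        t_in = _axial_tensor(
            tangents[inside], bundle.principal_diffusivity, bundle.secondary_diffusivity
        )
        if spec.crossing_policy == "sum":
            tensors[inside] = np.where(
                clash[inside, None, None], tensors[inside] + t_in, t_in
            )
        else:
            tensors[inside] = t_in
        covered[inside] += 1

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=(points.shape[0], 3, 3))
        noise = (noise + np.swapaxes(noise, -1, -2)) / 2
        tensors = tensors + noise
        lam, vec = np.linalg.eigh(tensors)
        lam = np.clip(lam, 0.0, None)  # keep tensors positive semi-definite
        tensors = np.einsum("...ij,...j,...kj->...ik", vec, lam, vec)

    return TensorVolume(tensors.reshape(dims + (3, 3)), vs)


# --------------------------------------------------------------------------
# Parcellation phantoms
# --------------------------------------------------------------------------

def _hemisphere_grid(n: int, extents: tuple) -> tuple:
    """Smallest box grid (ga, gb, gc) with ga*gb*gc >= n fitting in extents."""
    best = None
    ex, ey, ez = extents
    for ga in range(1, ex + 1):
        for gb in range(1, ey + 1):
            gc = -(-n // (ga * gb))
            if gc <= ez and ga * gb * gc >= n:
                cells = ga * gb * gc
                if best is None or cells < best[0]:
                    best = (cells, ga, gb, gc)
    if best is None:
        raise ValueError(f"{n} regions per hemisphere do not fit in the grid")
    return best[1:]


def make_parcellation(
    n_per_hemisphere: int,
    grid_dims: tuple,
    voxel_size: tuple = (1.0, 1.0, 1.0),
    boxes: Optional[dict] = None,
) -> Parcellation:
    """Axis-aligned box parcellation: 2*n_per_hemisphere non-overlapping
    regions, labels 1..2n, the left hemisphere in the lower half of x.

    ``boxes`` overrides the automatic layout with an explicit mapping
    label -> (x0, x1, y0, y1, z0, z1) voxel slices (half-open); overlapping
    boxes raise an error.
    """
    dims = tuple(int(d) for d in grid_dims)
    labels = np.zeros(dims, dtype=np.int32)
    if boxes is not None:
        for lab, (x0, x1, y0, y1, z0, z1) in boxes.items():
            region = labels[x0:x1, y0:y1, z0:z1]
            if np.any(region != 0):
                raise ValueError(f"box for label {lab} overlaps an earlier box")
            labels[x0:x1, y0:y1, z0:z1] = lab
        names = {lab: f"region{lab:02d}" for lab in boxes}
    else:
        n = int(n_per_hemisphere)
        hx = dims[0] // 2
        if hx < 1:
            raise ValueError("grid too small to split into hemispheres")
        ga, gb, gc = _hemisphere_grid(n, (hx, dims[1], dims[2]))
        names = {}
        for hemi, (x_off, prefix) in enumerate([(0, "L"), (dims[0] - hx, "R")]):
            placed = 0
            for i in range(ga):
                for j in range(gb):
                    for k in range(gc):
                        if placed >= n:
                            break
                        lab = hemi * n + placed + 1
                        x0 = x_off + i * hx // ga
                        x1 = x_off + (i + 1) * hx // ga
                        y0, y1 = j * dims[1] // gb, (j + 1) * dims[1] // gb
                        z0, z1 = k * dims[2] // gc, (k + 1) * dims[2] // gc
                        if x1 <= x0 or y1 <= y0 or z1 <= z0:
                            raise ValueError("region boxes collapse to zero volume")
                        labels[x0:x1, y0:y1, z0:z1] = lab
                        names[lab] = f"{prefix}{placed + 1:02d}"
                        placed += 1
        if len(names) != 2 * n:
            raise ValueError("failed to place all regions")
    affine = np.diag(np.append(np.asarray(voxel_size, dtype=float), 1.0))
    return Parcellation(labels, names, affine)


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative settings for a synthetic small-vessel-disease cohort.

    ``effect_size`` is the standardized loading of the apathy latent on
    global efficiency; ``edge_effect`` (default: equal to ``effect_size``)
    scales the additional log-weight attenuation of ``apathy_edge_set``
    per standard deviation of apathy; ``svd_effect`` is the log-weight
    attenuation per standard deviation of SVD burden. ``group_fractions``
    are the target (apathy, depression, comorbid, control) mix used to
    calibrate the AES/CESD cut-score quantiles.
    """

    n_participants: int = 331
    parcellation_nodes: int = 90
    base_connectome: Optional[Connectome] = None
    svd_effect: float = 0.15
    apathy_edge_set: tuple = ()
    effect_size: float = 0.8
    edge_effect: Optional[float] = None
    noise_sd: float = 0.1  # per-edge log-normal measurement noise
    integrity_noise_sd: float = 0.1  # participant-level log-scale network noise
    depression_corr: float = 0.5
    group_fractions: tuple = (26 / 331, 48 / 331, 32 / 331, 225 / 331)
    wmh_log_mean: float = 1.5  # log of normalized WMH volume (mL)
    wmh_log_sd: float = 1.0
    li_rate: float = 0.8  # Poisson mean lacunar-infarct count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must not be negative")
        if self.integrity_noise_sd < 0:
            raise ValueError("integrity_noise_sd must not be negative")
        if not 0 <= abs(self.effect_size) <= 1:
            raise ValueError("effect_size is a standardized loading in [-1, 1]")
        if not np.isclose(sum(self.group_fractions), 1.0):
            raise ValueError("group_fractions must sum to 1")
        if self.edge_effect is None:
            self.edge_effect = self.effect_size


def default_base_connectome(n_nodes: int = 90, seed: int = 0) -> Connectome:
    """A connected weighted template network: a weighted ring (so the graph
    is never disconnected) plus random long-range edges, weights on the
    scale of thresholded length-corrected streamline counts."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        j = (i + 1) % n_nodes
        w[i, j] = w[j, i] = rng.uniform(2.0, 6.0)
    iu, ju = np.triu_indices(n_nodes, k=2)
    extra = rng.random(len(iu)) < 0.15
    vals = rng.uniform(1.5, 5.0, size=len(iu))
    w[iu[extra], ju[extra]] = vals[extra]
    w[ju[extra], iu[extra]] = vals[extra]
    return Connectome(w)


def _zs(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_cohort(
    spec: CohortSpec, compute_metrics: bool = True
) -> tuple[list, pd.DataFrame]:
    """Draw a cohort of connectomes and its clinical covariate table.

    Per participant i: SVD burden B_i combines z-scored log WMH volume and
    lacunar count; every weight of the base connectome is attenuated by
    exp(-svd_effect * B_i) times participant- and edge-level log-normal
    noise; the apathy latent loads on the cohort-standardized global
    efficiency with ``effect_size`` plus independent noise; the planted
    ``apathy_edge_set`` is further attenuated by exp(-edge_effect * z(A));
    depression correlates with apathy but never touches the weights.
    Identical spec + seed reproduces identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    base = spec.base_connectome
    if base is None:
        base = default_base_connectome(
            spec.parcellation_nodes, seed=int(rng.integers(2**31))
        )
    bw = base.weights
    iu, ju = np.triu_indices(base.n_nodes, k=1)
    present = bw[iu, ju] > 0
    present_set = {(int(a), int(b)) for a, b in zip(iu[present], ju[present])}
    planted = [tuple(sorted((int(a), int(b)))) for a, b in spec.apathy_edge_set]
    if not set(planted) <= present_set:
        raise ValueError("apathy_edge_set must be a subset of base connectome edges")

    # SVD burden: skewed lesion markers combined on the z scale
    wmh = np.exp(rng.normal(spec.wmh_log_mean, spec.wmh_log_sd, size=n))
    li = rng.poisson(spec.li_rate, size=n)
    li_sd = li.std(ddof=1)
    z_li = (li - li.mean()) / li_sd if li_sd > 0 else np.zeros(n)
    burden = 0.7 * _zs(np.log1p(wmh)) + 0.3 * z_li

    # per-participant attenuation and noise, drawn before efficiency is known
    integrity = rng.normal(0.0, spec.integrity_noise_sd, size=n)
    log_scale = -spec.svd_effect * burden + integrity
    edge_noise = rng.normal(0.0, spec.noise_sd, size=(n, len(iu))) if spec.noise_sd > 0 \
        else np.zeros((n, len(iu)))

    weights = []
    eff = np.empty(n)
    for i in range(n):
        w = np.zeros_like(bw)
        vals = bw[iu, ju] * np.exp(log_scale[i] + edge_noise[i])
        vals[~present] = 0.0
        w[iu, ju] = vals
        w[ju, iu] = vals
        weights.append(w)
        eff[i] = global_efficiency(w)

    z_eff = _zs(eff)
    resid_sd = float(np.sqrt(max(0.0, 1.0 - spec.effect_size**2)))
    apathy = -spec.effect_size * z_eff + resid_sd * rng.normal(size=n)
    z_apathy = _zs(apathy)
    depression = spec.depression_corr * z_apathy + np.sqrt(
        1 - spec.depression_corr**2
    ) * rng.normal(size=n)
    z_dep = _zs(depression)

    if planted and spec.edge_effect:
        for i in range(n):
            factor = np.exp(-spec.edge_effect * z_apathy[i])
            for a, b in planted:
                weights[i][a, b] *= factor
                weights[i][b, a] *= factor

    # AES / CESD scales calibrated so the cut scores land on the quantiles
    # implied by the target group fractions
    f_ap, f_dep, f_co, _ = spec.group_fractions
    t_a = np.quantile(z_apathy, 1.0 - (f_ap + f_co))
    t_d = np.quantile(z_dep, 1.0 - (f_dep + f_co))
    aes = np.clip(np.round(34 + 6.0 * (z_apathy - t_a)), 18, 72).astype(int)
    cesd = np.clip(np.round(16 + 8.0 * (z_dep - t_d)), 0, 60).astype(int)
    group = [assign_group(a, c) for a, c in zip(aes, cesd)]

    age = np.clip(np.round(65 + 3.0 * burden + rng.normal(0, 8, size=n)), 40, 95)
    sex = np.where(rng.random(n) < 0.56, "male", "female")
    mmse = np.clip(np.round(28.1 - 0.7 * z_apathy - 0.3 * burden
                            + rng.normal(0, 1.3, size=n)), 10, 30).astype(int)
    education = np.clip(np.round(4 - 0.3 * z_apathy + rng.normal(0, 1.5, size=n)),
                        1, 7).astype(int)
    p_anti = 1.0 / (1.0 + np.exp(-(-2.2 + 1.2 * z_dep)))
    antidepressant = rng.random(n) < p_anti

    connectomes = [Connectome(w, list(base.node_names)) for w in weights]
    table = pd.DataFrame(
        {
            "participant": np.arange(1, n + 1),
            "AES": aes,
            "CESD": cesd,
            "age": age.astype(int),
            "sex": sex,
            "education": education,
            "MMSE": mmse,
            "WMH": wmh,
            "LI": li,
            "antidepressant": antidepressant,
            "group": group,
        }
    )
    if compute_metrics:
        table["density"] = [density(c) for c in connectomes]
        table["global_efficiency"] = [global_efficiency(c) for c in connectomes]
        table["local_efficiency"] = [local_efficiency(c) for c in connectomes]
    return connectomes, table
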