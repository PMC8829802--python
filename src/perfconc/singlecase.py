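"""Single-subject hypoperfusion mapping against a small control cohort.

A patient's map is compared voxelwise to the control sample with the
Crawford–Howell modified t statistic,

    t = (x − mean) / (sd · √((n+1)/n)),   df = n − 1,

which treats the control mean and SD as sample estimates and so keeps the
type-I error at its nominal level even for very small n. Hypoperfusion is
one-sided (lower tail), and suprathreshold voxels must form connected
clusters at least as large as a 10 mm-diameter sphere to survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .grid import VoxelGrid, check_same_grid
from .pet import CBFMap

__all__ = [
    "ControlGroupStats",
    "TStatMap",
    "ClusterSet",
    "control_group_stats",
    "crawford_howell_t",
    "critical_t",
    "hypoperfusion_mask",
    "min_cluster_extent",
    "label_clusters",
    "apply_extent_threshold",
    "hypoperfusion_pipeline",
    "type1_error_sim",
]


@dataclass
class ControlGroupStats:
    """Voxelwise control-cohort mean and sample SD with a joint validity mask."""

    grid: VoxelGrid
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    valid: np.ndarray
    scale: str = "absolute"

    def __post_init__(self):
        if self.n_controls < 2:
            raise ValueError("need at least two controls")
        for name in ("mean", "sd", "valid"):
            self.grid.check_volume(getattr(self, name), name)
        self.valid = self.valid.astype(bool)
        if np.any(self.sd[self.valid] < 0):
            raise ValueError("SD must be non-negative")


@dataclass
class TStatMap:
    grid: VoxelGrid
    t: np.ndarray
    degrees_of_freedom: int
    valid: np.ndarray

    def __post_init__(self):
        self.grid.check_volume(self.t, "t map")
        self.grid.check_volume(self.valid, "validity mask")
        self.valid = self.valid.astype(bool)
        if not np.all(np.isfinite(self.t[self.valid])):
            raise ValueError("t values must be finite where valid")


@dataclass
class ClusterSet:
    """Connected-component labeling of a suprathreshold mask."""

    labels: np.ndarray  # int, 0 = background
    sizes: np.ndarray  # voxel count per label (index 0 ↔ label 1)
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)


def control_group_stats(control_maps: list[CBFMap]) -> ControlGroupStats:
    """Voxelwise sample mean and SD (n−1 denominator) over the control maps;
    validity is the intersection of the inputs' validity masks."""
    if len(control_maps) < 2:
        raise ValueError("need at least two control maps")
    first = control_maps[0]
    scales = {m.scale for m in control_maps}
    if len(scales) != 1:
        raise ValueError("control maps mix absolute and relative scales")
    for m in control_maps[1:]:
        check_same_grid(first.grid, m.grid)
    stack = np.stack([m.values for m in control_maps], axis=-1)
    valid = np.all(np.stack([m.valid for m in control_maps], axis=-1), axis=-1)
    return ControlGroupStats(
        grid=first.grid,
        mean=stack.mean(axis=-1),
        sd=stack.std(axis=-1, ddof=1),
        n_controls=len(control_maps),
        valid=valid,
        scale=first.scale,
    )


def crawford_howell_t(patient: CBFMap, group: ControlGroupStats) -> TStatMap:
    """Crawford–Howell modified t per voxel; voxels with zero control SD
    (or invalid in patient or controls) are excluded."""
    check_same_grid(patient.grid, group.grid)
    if patient.scale != group.scale:
        raise ValueError(
            f"scale mismatch: patient is {patient.scale}, controls are {group.scale}"
        )
    n = group.n_controls
    factor = np.sqrt((n + 1) / n)
    valid = patient.valid & group.valid & (group.sd > 0)
    t = np.zeros(patient.grid.shape)
    t[valid] = (patient.values[valid] - group.mean[valid]) / (group.sd[valid] * factor)
    return TStatMap(grid=patient.grid, t=t, degrees_of_freedom=n - 1, valid=valid)


def critical_t(n_controls: int, alpha: float = 0.05) -> float:
    """Upper-α quantile of Student's t with n − 1 degrees of freedom."""
    if n_controls < 2:
        raise ValueError("need at least two controls")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.t.ppf(1.0 - alpha, df=n_controls - 1))


def hypoperfusion_mask(tmap: TStatMap, t_crit: float) -> np.ndarray:
    """Lower-tail threshold: valid voxels with t ≤ −t_crit."""
    if t_crit <= 0:
        raise ValueError("critical t must be positive")
    return tmap.valid & (tmap.t <= -t_crit)


def min_cluster_extent(sphere_diameter_mm: float, voxel_size_mm) -> int:
    """Voxel count of a sphere-equivalent cluster-extent threshold:
    floor((π/6)·d³ / voxel volume), clamped to at least 1. For anisotropic
    voxels the voxel volume is the product of the edge lengths."""
    if sphere_diameter_mm <= 0:
        raise ValueError("sphere diameter must be positive")
    v = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if np.any(v <= 0):
        raise ValueError("voxel size must be positive")
    vol = float(np.prod(v)) if v.size > 1 else float(v[0] ** 3)
    count = int(np.floor((np.pi / 6.0) * sphere_diameter_mm**3 / vol))
    return max(count, 1)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(mask: np.ndarray, connectivity: int = 26) -> ClusterSet:
    """Connected components of a boolean volume under face (6), edge (18)
    or corner (26) adjacency."""
    labels, n = ndimage.label(mask.astype(bool), structure=_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return ClusterSet(labels=labels, sizes=sizes, connectivity=connectivity)


def apply_extent_threshold(clusters: ClusterSet, min_voxels: int) -> np.ndarray:
    """Retain voxels of clusters whose size is ≥ min_voxels (a cluster
    exactly at the sphere-equivalent count survives)."""
    if min_voxels < 1:
        raise ValueError("minimum cluster extent must be ≥ 1")
    if clusters.n_clusters == 0:
        return np.zeros(clusters.labels.shape, dtype=bool)
    keep = np.concatenate([[False], clusters.sizes >= min_voxels])
    return keep[clusters.labels]


def hypoperfusion_pipeline(
    patient: CBFMap,
    group: ControlGroupStats,
    alpha: float = 0.05,
    sphere_diameter_mm: float = 10.0,
    connectivity: int = 26,
) -> tuple[np.ndarray, TStatMap, ClusterSet]:
    """Full single-case chain: t map → one-sided threshold → clusters →
    extent rule. Returns the final mask plus intermediates."""
    tmap = crawford_howell_t(patient, group)
    tc = critical_t(group.n_controls, alpha)
    raw = hypoperfusion_mask(tmap, tc)
    clusters = label_clusters(raw, connectivity)
    min_vox = min_cluster_extent(sphere_diameter_mm, patient.grid.voxel_size)
    return apply_extent_threshold(clusters, min_vox), tmap, clusters


def type1_error_sim(
    n_controls: int = 13,
    n_patients_null: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    use_z_threshold: bool = False,
) -> float:
    """Empirical false-positive rate of the single-case test under the null.

    Controls and null patients are drawn from one normal distribution; each
    null patient is tested with the Crawford–Howell statistic against the
    lower-tail critical t (or, for comparison, against the naive normal
    quantile when ``use_z_threshold`` is set, which inflates the rate for
    small control groups).
    """
    if n_patients_null < 1:
        raise ValueError("need at least one null draw")
    rng = np.random.default_rng(seed)
    controls = rng.standard_normal((n_patients_null, n_controls))
    patients = rng.standard_normal(n_patients_null)
    mean = controls.mean(axis=1)
    sd = controls.std(axis=1, ddof=1)
    t = (patients - mean) / (sd * np.sqrt((n_controls + 1) / n_controls))
    if use_z_threshold:
        thresh = float(stats.norm.ppf(1.0 - alpha))
    else:
        thresh = critical_t(n_controls, alpha)
    return float(np.mean(t <= -thresh))
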