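"""Digital brain phantom: concentric ellipsoidal grey matter, white matter
and ventricular CSF with spherical hypoperfused lesions and smoothly varying
arterial transit times. The phantom is the ground truth every simulated
measurement is derived from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid

__all__ = ["TissuePhantom", "LesionSpec", "build_phantom", "LABELS"]

LABELS = {"background": 0, "gm": 1, "wm": 2, "csf": 3, "lesion": 4}

# normalized ellipsoid radii delimiting the tissue shells
_GM_INNER = 0.75  # GM occupies (0.75, 1]
_CSF_OUTER = 0.22  # central CSF occupies [0, 0.22]
# relative M0 per tissue (arbitrary units)
_M0 = {"gm": 1.0, "wm": 0.7, "csf": 1.4}


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal lesion: center (mm), radius (mm), and the fraction
    by which CBF is reduced inside it (1.0 = no flow)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    cbf_reduction: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if not 0.0 <= self.cbf_reduction <= 1.0:
            raise ValueError("cbf_reduction must lie in [0, 1]")


@dataclass
class TissuePhantom:
    """Label volume plus ground-truth CBF / ATT / M0 maps on a common grid."""

    grid: VoxelGrid
    labels: np.ndarray  # int, 0 bg / 1 GM / 2 WM / 3 CSF / 4 lesion
    true_cbf: np.ndarray  # ml/100 g/min
    true_att: np.ndarray  # ms
    m0: np.ndarray  # a.u.
    brain_mask: np.ndarray  # bool

    def __post_init__(self):
        for name in ("labels", "true_cbf", "true_att", "m0", "brain_mask"):
            self.grid.check_volume(getattr(self, name), name)
        if np.any(self.true_cbf < 0):
            raise ValueError("true CBF must be non-negative")
        if np.any(self.true_cbf[~self.brain_mask] != 0):
            raise ValueError("true CBF must be zero outside the brain mask")
        if np.any((self.labels == LABELS["lesion"]) & ~self.brain_mask):
            raise ValueError("lesion voxels must lie inside the brain mask")

    @property
    def brain_volume_ml(self) -> float:
        return float(self.brain_mask.sum()) * self.grid.voxel_volume_mm3 / 1000.0

    def brain_mass_g(self, brain_density: float = 1.05) -> float:
        return self.brain_volume_ml * brain_density

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def mean_cbf(self) -> float:
        """Mass-weighted (= volume-weighted, uniform density) whole-brain CBF."""
        return float(self.true_cbf[self.brain_mask].mean())


def _normalized_radius(grid: VoxelGrid) -> np.ndarray:
    x, y, z = grid.coordinates_mm()
    ext = grid.extent_mm
    center = [e / 2.0 for e in ext]
    semi = (0.45 * ext[0], 0.45 * ext[1], 0.42 * ext[2])
    return np.sqrt(
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )


def build_phantom(
    grid: VoxelGrid,
    lesion_spec: list[LesionSpec] | None = None,
    gm_cbf: float = 60.0,
    wm_cbf: float = 20.0,
    att_range: tuple[float, float] = (800.0, 1800.0),
    seed: int = 0,
) -> TissuePhantom:
    """Build a concentric-ellipsoid brain phantom with known ground truth.

    Grey matter forms the outer ellipsoidal shell, white matter the interior,
    and a small central ellipsoid is ventricular CSF (zero perfusion,
    excluded from the brain mask). Lesion spheres overwrite GM/WM labels and
    reduce the local CBF by their stated fraction. The arterial transit time
    is a seeded, smoothly varying random field rescaled to ``att_range``.

    Parameters
    ----------
    gm_cbf, wm_cbf : float
        Tissue perfusion in ml/100 g/min; must satisfy gm_cbf > wm_cbf > 0.
    att_range : (float, float)
        Bounds of the transit-time field in ms.
    """
    if not gm_cbf > wm_cbf > 0:
        raise ValueError("expected gm_cbf > wm_cbf > 0")
    att_lo, att_hi = float(att_range[0]), float(att_range[1])
    if att_lo < 0 or att_hi < att_lo:
        raise ValueError("invalid ATT range")
    lesions = list(lesion_spec or [])

    rho = _normalized_radius(grid)
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[rho <= 1.0] = LABELS["wm"]
    labels[(rho <= 1.0) & (rho > _GM_INNER)] = LABELS["gm"]
    labels[rho <= _CSF_OUTER] = LABELS["csf"]

    cbf = np.zeros(grid.shape)
    cbf[labels == LABELS["gm"]] = gm_cbf
    cbf[labels == LABELS["wm"]] = wm_cbf

    brain = (labels == LABELS["gm"]) | (labels == LABELS["wm"])

    # M0 reflects the underlying tissue and is assigned before lesions
    # overwrite labels (a perfusion deficit does not change water content)
    m0 = np.zeros(grid.shape)
    m0[labels == LABELS["gm"]] = _M0["gm"]
    m0[labels == LABELS["wm"]] = _M0["wm"]
    m0[labels == LABELS["csf"]] = _M0["csf"]

    x, y, z = grid.coordinates_mm()
    for les in lesions:
        cx, cy, cz = les.center_mm
        # nearest voxel to the requested center must be brain tissue
        idx = tuple(
            int(np.clip(round(c / v - 0.5), 0, n - 1))
            for c, v, n in zip(les.center_mm, grid.voxel_size, grid.shape)
        )
        if not brain[idx]:
            raise ValueError(
                f"lesion center {les.center_mm} mm falls outside the brain mask"
            )
        dist2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        inside = (dist2 <= les.radius_mm**2) & brain
        labels[inside] = LABELS["lesion"]
        cbf[inside] *= 1.0 - les.cbf_reduction

    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal(grid.shape), sigma=6.0)
    span = field.max() - field.min()
    if span == 0:
        field = np.zeros_like(field)
    else:
        field = (field - field.min()) / span
    att = np.zeros(grid.shape)
    att[brain] = att_lo + (att_hi - att_lo) * field[brain]

    return TissuePhantom(
        grid=grid, labels=labels, true_cbf=cbf, true_att=att, m0=m0, brain_mask=brain
    )
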