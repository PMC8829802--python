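"""Absolute CBF from dynamic ¹⁵O-water PET without arterial sampling.

The quantifier (PMRFlow) replaces the arterial input function with two
measurable quantities: the whole-brain time-activity curve and whole-brain
CBF from phase-contrast MRI. Integrating the one-tissue model over the scan
and eliminating the input function gives, per voxel i,

    f_i = ∫₀ᵀ C_i dt / [ (1/f_wb) ∫₀ᵀ C_wb dt
                          + (1/(100λ)) ∫₀ᵀ∫₀ᵗ C_wb ds dt
                          − (1/(100λ)) ∫₀ᵀ∫₀ᵗ C_i ds dt ],

with f in ml/100 g/min, time in minutes and λ in ml/g. Setting C_i = C_wb
makes the double-integral terms cancel and returns f_wb identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid, check_same_grid
from .phantom import LABELS
from .simulate import DynamicPETImage, PCFlowMeasurement

__all__ = [
    "TimeActivityCurve",
    "PMRFlowParams",
    "CBFMap",
    "frame_midpoint_tac",
    "pc_whole_brain_cbf",
    "pmrflow_cbf",
    "smooth_gaussian",
    "gm_wm_contrast",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity (kBq/ml) at frame-midpoint times (s)."""

    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and activity must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("TAC times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity", a)


@dataclass(frozen=True)
class PMRFlowParams:
    """λ (ml/g) and the integration time T (s, default 5 min)."""

    lambda_partition: float = 0.9
    integration_time: float = 300.0

    def __post_init__(self):
        if self.lambda_partition <= 0:
            raise ValueError("partition coefficient must be positive")
        if self.integration_time <= 0:
            raise ValueError("integration time must be positive")


@dataclass
class CBFMap:
    """3-D perfusion map — the common currency of all comparisons.

    ``modality`` tags the source (pet | asl_sd | asl_te), ``scale`` whether
    values are absolute (ml/100 g/min) or relative to a reference mean.
    Voxels outside ``valid`` carry no meaningful value.
    """

    grid: VoxelGrid
    values: np.ndarray
    modality: str
    scale: str = "absolute"
    valid: np.ndarray = None

    def __post_init__(self):
        self.grid.check_volume(self.values, "CBF map")
        if self.modality not in ("pet", "asl_sd", "asl_te"):
            raise ValueError(f"unknown modality tag {self.modality!r}")
        if self.scale not in ("absolute", "relative"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.grid.check_volume(self.valid, "validity mask")
            self.valid = self.valid.astype(bool)
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("CBF values must be finite inside the validity mask")

    def masked_mean(self, mask: np.ndarray) -> float:
        sel = mask.astype(bool) & self.valid
        if not sel.any():
            raise ValueError("no valid voxels in the requested mask")
        return float(self.values[sel].mean())


def frame_midpoint_tac(dynamic: DynamicPETImage, mask: np.ndarray) -> TimeActivityCurve:
    """Mean activity over the mask per frame, timestamped at frame midpoints."""
    dynamic.grid.check_volume(mask, "TAC mask")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("TAC mask is empty")
    act = dynamic.frames[mask].mean(axis=0)
    return TimeActivityCurve(times=dynamic.schedule.midpoints, activity=act)


def pc_whole_brain_cbf(pc: PCFlowMeasurement) -> float:
    """Whole-brain CBF (ml/100 g/min) from phase-contrast vessel data:
    each vessel contributes mean velocity × area (cm/s × mm² → 0.6 ml/min);
    the summed inflow is scaled by brain mass."""
    flow_ml_min = float(np.sum(pc.velocity_cm_s * pc.area_mm2 * 0.6))
    return 100.0 * flow_ml_min / pc.brain_mass_g


def _integration_weights(times_min: np.ndarray) -> np.ndarray:
    """Trapezoid weights w with ∫ y dt ≈ w·y on the given time samples."""
    dt = np.diff(times_min)
    w = np.zeros_like(times_min)
    w[:-1] += dt / 2.0
    w[1:] += dt / 2.0
    return w


def pmrflow_cbf(
    dynamic: DynamicPETImage,
    wb_tac: TimeActivityCurve,
    f_wb: float,
    params: PMRFlowParams = PMRFlowParams(),
) -> CBFMap:
    """Voxelwise CBF by the PC-MRI-calibrated integral formula.

    All integrals use the trapezoid rule on frame-midpoint samples with an
    implicit (t=0, activity=0) anchor, truncated at the integration time T
    (when T exceeds the last midpoint, integration stops there). Voxels
    whose denominator is non-positive are marked invalid rather than
    clipped; downstream statistics exclude them.
    """
    if f_wb <= 0:
        raise ValueError("whole-brain CBF must be positive")
    mid = dynamic.schedule.midpoints
    if wb_tac.times.shape != mid.shape or not np.allclose(wb_tac.times, mid):
        raise ValueError("whole-brain TAC does not share the dynamic image's frame schedule")
    T = params.integration_time
    if T > dynamic.schedule.total_duration + 1e-9:
        raise ValueError("integration time exceeds the scan duration")

    keep = mid <= T
    times_s = np.concatenate([[0.0], mid[keep]])
    t_min = times_s / 60.0
    cwb = np.concatenate([[0.0], wb_tac.activity[keep]])

    nvox = int(np.prod(dynamic.grid.shape))
    ci = np.concatenate(
        [np.zeros((nvox, 1)), dynamic.frames.reshape(nvox, -1)[:, keep]], axis=1
    )

    w = _integration_weights(t_min)
    int_ci = ci @ w  # ∫ C_i dt, kBq/ml · min
    int_cwb = float(cwb @ w)
    cum_ci = cumulative_trapezoid(ci, t_min, axis=1, initial=0.0)
    dbl_ci = cum_ci @ w  # ∫∫ C_i
    dbl_cwb = float(cumulative_trapezoid(cwb, t_min, initial=0.0) @ w)

    lam100 = 100.0 * params.lambda_partition
    denom = int_cwb / f_wb + dbl_cwb / lam100 - dbl_ci / lam100
    valid = denom > 0
    values = np.zeros(nvox)
    values[valid] = int_ci[valid] / denom[valid]
    return CBFMap(
        grid=dynamic.grid,
        values=values.reshape(dynamic.grid.shape),
        modality="pet",
        scale="absolute",
        valid=valid.reshape(dynamic.grid.shape),
    )


def smooth_gaussian(volume, fwhm: float, grid: VoxelGrid = None, mask: np.ndarray = None):
    """Separable Gaussian smoothing with σ = FWHM/(2√(2 ln 2)) per axis, in mm.

    Accepts a :class:`CBFMap` (smoothed within its validity mask, returning
    a new map) or a bare array (optionally with an explicit mask). Smoothing
    is renormalized within the mask so constants are preserved; fwhm = 0 is
    the identity.
    """
    if fwhm < 0:
        raise ValueError("FWHM must be non-negative")
    if isinstance(volume, CBFMap):
        data = volume.values
        grid = volume.grid
        mask = volume.valid
    else:
        data = np.asarray(volume, dtype=float)
        if grid is None:
            raise ValueError("a VoxelGrid is required when smoothing a bare array")
        if mask is None:
            mask = np.ones(data.shape, dtype=bool)
    if fwhm == 0:
        out = data.copy()
    else:
        sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in grid.voxel_size]
        m = mask.astype(float)
        num = gaussian_filter(np.where(mask, data, 0.0), sigma_vox)
        den = gaussian_filter(m, sigma_vox)
        out = np.zeros_like(data)
        inside = den > 1e-12
        out[inside] = num[inside] / den[inside]
        out[~mask] = 0.0
    if isinstance(volume, CBFMap):
        return CBFMap(
            grid=grid, values=out, modality=volume.modality, scale=volume.scale,
            valid=volume.valid.copy(),
        )
    return out


def gm_wm_contrast(cbf_map: CBFMap, labels: np.ndarray) -> float:
    """Grey-to-white-matter contrast: mean CBF over GM voxels divided by the
    mean over WM voxels (valid voxels only)."""
    cbf_map.grid.check_volume(labels, "labels")
    gm = (labels == LABELS["gm"]) & cbf_map.valid
    wm = (labels == LABELS["wm"]) & cbf_map.valid
    if not gm.any() or not wm.any():
        raise ValueError("GM and WM label sets must both be non-empty")
    wm_mean = cbf_map.values[wm].mean()
    if wm_mean == 0:
        raise ValueError("white-matter mean is zero; contrast undefined")
    return float(cbf_map.values[gm].mean() / wm_mean)
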