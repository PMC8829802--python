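"""Simulated raw measurements: dynamic ¹⁵O-water PET, phase-contrast vessel
flow, and single-delay / time-encoded pCASL acquisitions, all derived from a
:class:`~perfconc.phantom.TissuePhantom` with controlled Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid, check_same_grid
from .hadamard import HadamardScheme, hadamard_timing
from .kinetics import ASLParams, InputFunction, buxton_signal, one_tissue_response
from .phantom import TissuePhantom

__all__ = [
    "FrameSchedule",
    "DynamicPETImage",
    "PCFlowMeasurement",
    "ASLAcquisition",
    "default_frame_schedule",
    "simulate_pet_dynamic",
    "simulate_pc",
    "simulate_asl_sd",
    "simulate_asl_te",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frame timing in seconds."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.frame_start, dtype=float)
        d = np.asarray(self.frame_duration, dtype=float)
        if s.ndim != 1 or s.shape != d.shape or s.size == 0:
            raise ValueError("frame_start and frame_duration must be matching 1-D arrays")
        if np.any(d <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(s[1:], (s + d)[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frame_start", s)
        object.__setattr__(self, "frame_duration", d)

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        d = np.asarray(durations, dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(d)[:-1]])
        return cls(frame_start=starts, frame_duration=d)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1])


def default_frame_schedule() -> FrameSchedule:
    """The 5-minute dynamic schedule: 3 s × 20, 5 s × 6, 10 s × 6, 30 s × 5
    (37 frames, 300 s)."""
    return FrameSchedule.from_durations([3.0] * 20 + [5.0] * 6 + [10.0] * 6 + [30.0] * 5)


@dataclass
class DynamicPETImage:
    """4-D tracer activity (kBq/ml) with its frame schedule."""

    grid: VoxelGrid
    frames: np.ndarray  # (nx, ny, nz, n_frames)
    schedule: FrameSchedule

    def __post_init__(self):
        self.grid.check_volume(self.frames, "dynamic PET")
        if self.frames.ndim != 4 or self.frames.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame count {self.frames.shape[-1] if self.frames.ndim == 4 else '?'} "
                f"does not match the schedule ({self.schedule.n_frames} frames)"
            )


@dataclass
class PCFlowMeasurement:
    """Per-vessel phase-contrast measurements feeding whole-brain CBF."""

    velocity_cm_s: np.ndarray  # mean velocity per vessel
    area_mm2: np.ndarray  # cross-sectional area per vessel
    brain_mass_g: float

    def __post_init__(self):
        v = np.atleast_1d(np.asarray(self.velocity_cm_s, dtype=float))
        a = np.atleast_1d(np.asarray(self.area_mm2, dtype=float))
        if v.shape != a.shape or v.size < 1:
            raise ValueError("need matching velocity/area entries for ≥ 1 vessel")
        if np.any(a <= 0):
            raise ValueError("vessel areas must be positive")
        if self.brain_mass_g <= 0:
            raise ValueError("brain mass must be positive")
        self.velocity_cm_s = v
        self.area_mm2 = a


@dataclass
class ASLAcquisition:
    """Raw pCASL volumes: interleaved control/label pairs (single-delay
    mode, ``scheme is None``) or N Hadamard-encoded volumes (time-encoded
    mode), plus the M0 calibration volume."""

    grid: VoxelGrid
    volumes: np.ndarray  # (nx, ny, nz, n_volumes)
    m0: np.ndarray
    params: ASLParams
    scheme: HadamardScheme | None = None

    def __post_init__(self):
        self.grid.check_volume(self.volumes, "ASL volumes")
        self.grid.check_volume(self.m0, "M0")
        n = self.volumes.shape[-1]
        if self.scheme is None:
            if n % 2 != 0:
                raise ValueError(f"single-delay mode needs an even volume count, got {n}")
        elif n != self.scheme.n_encode:
            raise ValueError(
                f"time-encoded mode needs {self.scheme.n_encode} volumes, got {n}"
            )

    @property
    def mode(self) -> str:
        return "sd" if self.scheme is None else "te"


def simulate_pet_dynamic(
    phantom: TissuePhantom,
    aif: InputFunction,
    schedule: FrameSchedule,
    noise_sd: float = 0.0,
    seed: int = 0,
    lambda_partition: float = 0.9,
    fine_dt: float = 0.05,
) -> DynamicPETImage:
    """Integrate the one-tissue model per voxel and average over frames.

    The continuous tissue curve is solved on a fine time grid (exact for a
    piecewise-linear input function) once per unique perfusion value, then
    time-averaged over each frame. When ``noise_sd`` > 0, independent
    Gaussian noise with standard deviation noise_sd/√(frame duration) is
    added per voxel and frame, mimicking count statistics.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if schedule.total_duration > aif.times[-1] + 1e-9:
        raise ValueError("frame schedule extends beyond the input-function support")

    lam = lambda_partition
    n_fine = int(round(schedule.total_duration / fine_dt))
    t_fine = np.linspace(0.0, schedule.total_duration, n_fine + 1)
    ca_fine = aif.sample(t_fine)

    f_flat = phantom.true_cbf.ravel()
    uniq, inverse = np.unique(f_flat, return_inverse=True)
    curves = one_tissue_response(uniq, lam, t_fine, ca_fine)

    # frame averages by trapezoid over the fine samples inside each frame
    frame_means = np.zeros((uniq.size, schedule.n_frames))
    for k, (s, e) in enumerate(zip(schedule.frame_start, schedule.frame_end)):
        i0 = int(round(s / fine_dt))
        i1 = int(round(e / fine_dt))
        seg = curves[:, i0 : i1 + 1]
        frame_means[:, k] = np.trapezoid(seg, dx=fine_dt, axis=1) / (e - s)

    frames = frame_means[inverse].reshape(phantom.grid.shape + (schedule.n_frames,))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd / np.sqrt(schedule.frame_duration)
        frames = frames + rng.standard_normal(frames.shape) * sigma
    return DynamicPETImage(grid=phantom.grid, frames=frames, schedule=schedule)


def simulate_pc(
    phantom: TissuePhantom,
    target_fwb: float,
    n_vessels: int = 4,
    seed: int = 0,
    brain_density: float = 1.05,
) -> PCFlowMeasurement:
    """Draw per-vessel velocities/areas in physiological ranges and rescale
    them so the implied whole-brain CBF equals ``target_fwb`` exactly.

    Brain mass is the phantom's brain volume times the tissue density.
    """
    if target_fwb <= 0:
        raise ValueError("target whole-brain CBF must be positive")
    if n_vessels < 1:
        raise ValueError("need at least one vessel")
    rng = np.random.default_rng(seed)
    # carotid/vertebral-like ranges
    vel = rng.uniform(15.0, 40.0, size=n_vessels)  # cm/s
    area = rng.uniform(8.0, 30.0, size=n_vessels)  # mm²
    mass = phantom.brain_mass_g(brain_density)
    # cm/s × mm² = 10 mm³/s = 0.6 ml/min
    implied = 100.0 * np.sum(vel * area * 0.6) / mass
    vel *= target_fwb / implied
    return PCFlowMeasurement(velocity_cm_s=vel, area_mm2=area, brain_mass_g=mass)


def simulate_asl_sd(
    phantom: TissuePhantom,
    params: ASLParams,
    n_pairs: int = 16,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ASLAcquisition:
    """Single-delay acquisition: interleaved (control, label) volumes.

    The control volume is the M0-proportional static signal; the label
    volume subtracts the single-compartment difference signal evaluated at
    readout time LD + PLD with the phantom's per-voxel perfusion and
    transit time. Independent Gaussian noise is added per volume.
    """
    if n_pairs < 1:
        raise ValueError("need at least one label/control pair")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t_read = params.label_duration + params.post_label_delay
    dm = buxton_signal(
        phantom.true_cbf, phantom.true_att, t_read, params.label_duration, phantom.m0, params
    )
    control = phantom.m0
    label = control - dm
    vols = np.empty(phantom.grid.shape + (2 * n_pairs,))
    vols[..., 0::2] = control[..., None]
    vols[..., 1::2] = label[..., None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vols = vols + rng.standard_normal(vols.shape) * noise_sd
    return ASLAcquisition(
        grid=phantom.grid, volumes=vols, m0=phantom.m0.copy(), params=params, scheme=None
    )


def _te_sub_bolus_signals(phantom: TissuePhantom, scheme: HadamardScheme, params: ASLParams):
    """ΔM per sub-bolus (shape grid + (N−1,)), each evaluated at its own
    effective labeling duration and post-labeling delay."""
    plds, lds = hadamard_timing(scheme)
    dms = np.empty(phantom.grid.shape + (len(lds),))
    for k, (pld, ld) in enumerate(zip(plds, lds)):
        dms[..., k] = buxton_signal(
            phantom.true_cbf, phantom.true_att, ld + pld, ld, phantom.m0, params
        )
    return dms


def simulate_asl_te(
    phantom: TissuePhantom,
    scheme: HadamardScheme,
    params: ASLParams,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ASLAcquisition:
    """Time-encoded acquisition: each of the N volumes is the static signal
    minus the summed difference signals of the sub-boli that are in the
    label state for that volume (encoding entry +1)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    dms = _te_sub_bolus_signals(phantom, scheme, params)
    labeled = (scheme.encoding_matrix > 0).astype(float)  # (N, N−1)
    vols = phantom.m0[..., None] - dms @ labeled.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vols = vols + rng.standard_normal(vols.shape) * noise_sd
    return ASLAcquisition(
        grid=phantom.grid, volumes=vols, m0=phantom.m0.copy(), params=params, scheme=scheme
    )
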