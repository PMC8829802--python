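"""Kinetic signal models: the ¹⁵O-water one-tissue compartment and the
single-compartment (Buxton) pCASL difference signal.

Units follow imaging convention: perfusion f in ml/100 g/min, the partition
coefficient λ in ml/g, MR timing in ms, PET timing in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticConstants",
    "ASLParams",
    "InputFunction",
    "gamma_variate_aif",
    "one_tissue_response",
    "buxton_signal",
]


@dataclass(frozen=True)
class KineticConstants:
    """Physiological constants shared by the PET and ASL models.

    Defaults follow the ASL consensus recommendations: λ = 0.9 ml/g,
    blood T1 = 1650 ms, pCASL labeling efficiency α = 0.85. Background
    suppression with two inversion pulses retains ≈ 0.91² ≈ 0.83 of the
    difference signal. Brain density 1.05 g/ml.
    """

    lambda_partition: float = 0.9  # ml/g
    t1_blood: float = 1650.0  # ms
    labeling_efficiency: float = 0.85
    brain_density: float = 1.05  # g/ml

    def __post_init__(self):
        if self.lambda_partition <= 0:
            raise ValueError("partition coefficient must be positive")
        if self.t1_blood <= 0:
            raise ValueError("blood T1 must be positive")
        # α = 0 is allowed as the degenerate "no labeling" case
        if not 0 <= self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency must lie in [0, 1]")
        if self.brain_density <= 0:
            raise ValueError("brain density must be positive")


@dataclass(frozen=True)
class ASLParams:
    """pCASL sequence parameters: labeling duration and post-labeling delay
    in ms, kinetic constants, and the background-suppression attenuation of
    the difference signal."""

    label_duration: float = 1800.0  # ms
    post_label_delay: float = 2000.0  # ms
    constants: KineticConstants = field(default_factory=KineticConstants)
    background_suppression_factor: float = 0.83
    # apparent tissue T1 for the decay of labeled water; None = use blood T1
    t1_tissue: float | None = None

    def __post_init__(self):
        if self.label_duration <= 0:
            raise ValueError("label duration must be positive")
        if self.post_label_delay < 0:
            raise ValueError("post-labeling delay must be non-negative")
        if not 0 < self.background_suppression_factor <= 1:
            raise ValueError("background suppression factor must lie in (0, 1]")

    @property
    def t1_apparent(self) -> float:
        return self.constants.t1_blood if self.t1_tissue is None else self.t1_tissue


@dataclass(frozen=True)
class InputFunction:
    """Arterial input function: tracer activity (kBq/ml) sampled at strictly
    increasing times (s), zero at time zero."""

    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and activity must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("input-function times must be strictly increasing")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("input-function activity must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity", a)

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the sampled support."""
        return np.interp(t, self.times, self.activity, left=0.0, right=0.0)


def gamma_variate_aif(
    peak_time: float,
    peak_value: float,
    shape: float,
    times: np.ndarray,
) -> InputFunction:
    """Synthesize a gamma-variate bolus input function.

    a(t) = peak_value · (t/t_p)^shape · exp(shape·(1 − t/t_p)),

    which is zero at t = 0 and attains its unique maximum ``peak_value``
    at ``peak_time``.
    """
    if peak_time <= 0 or peak_value <= 0:
        raise ValueError("peak_time and peak_value must be positive")
    if shape <= 0:
        raise ValueError("shape must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.clip(t, 0.0, None) / peak_time
        act = peak_value * rel**shape * np.exp(shape * (1.0 - rel))
    act = np.where(t <= 0, 0.0, act)
    return InputFunction(times=t, activity=act)


def one_tissue_response(
    f: np.ndarray,
    lambda_partition: float,
    aif_times: np.ndarray,
    aif_activity: np.ndarray,
) -> np.ndarray:
    """Tissue activity C(t) of the one-tissue ¹⁵O-water model.

    Solves dC/dt = k1·Ca(t) − k2·C with k1 = f/(100·60) per second and
    k2 = k1/λ, for each perfusion value in ``f`` (ml/100 g/min), on the
    time grid of the supplied (already finely sampled) input function.

    The integrator is exact for a piecewise-linear Ca, so constant and
    linear segments of the forcing incur no discretization error.

    Returns an array of shape ``(len(f), len(aif_times))``.
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    t = np.asarray(aif_times, dtype=float)
    ca = np.asarray(aif_activity, dtype=float)
    n = t.size
    out = np.zeros((f.size, n))
    k1 = f / 6000.0  # per s
    k2 = k1 / lambda_partition
    dt = np.diff(t)
    for j, (a1, a2) in enumerate(zip(k1, k2)):
        if a1 == 0.0:
            continue
        c = np.zeros(n)
        E = np.exp(-a2 * dt)
        # exact update for Ca linear on [t_i, t_i+1]:
        #   C_{i+1} = C_i·E + k1·[Ca_i·g1 + (Ca_{i+1}−Ca_i)·g2]
        # with g1 = (1−E)/k2 and g2 = (dt − g1)/(k2·dt)·... (see below)
        g1 = (1.0 - E) / a2
        g2 = (dt - g1) / (a2 * dt)
        for i in range(n - 1):
            c[i + 1] = c[i] * E[i] + a1 * (ca[i] * g1[i] + (ca[i + 1] - ca[i]) * g2[i])
        out[j] = c
    return out


def buxton_signal(f, att, t, ld, m0, params: ASLParams):
    """pCASL difference signal ΔM of the single-compartment kinetic model.

    Piecewise in readout time ``t`` (ms after the start of labeling):
    zero before the label arrives (t < ATT); during inflow
    (ATT ≤ t < ATT + LD) the signal rises with apparent-T1 saturation;
    afterwards it decays with the apparent T1. The amplitude is
    2·α·(M0/λ)·(f/6000)·T1app·exp(−ATT/T1b), further attenuated by the
    background-suppression factor. ``m0`` is the *tissue* equilibrium
    magnetization; the labeled magnetization is arterial, hence the
    division by the blood–brain partition coefficient λ (this is what
    makes the consensus single-delay quantification formula, which carries
    λ in its numerator, the exact inverse of this model).

    ``f`` (ml/100 g/min), ``att`` (ms) and ``m0`` may be arrays of a common
    broadcast shape; ``t`` and ``ld`` are scalars in ms.
    """
    f = np.asarray(f, dtype=float)
    att = np.asarray(att, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(att < 0):
        raise ValueError("arterial transit time must be non-negative")
    if ld <= 0:
        raise ValueError("label duration must be positive")
    if np.any(np.asarray(t) < 0):
        raise ValueError("readout time must be non-negative")
    c = params.constants
    t1b_s = c.t1_blood / 1000.0
    t1app_s = params.t1_apparent / 1000.0
    amp = (
        2.0
        * c.labeling_efficiency
        * params.background_suppression_factor
        * (m0 / c.lambda_partition)
        * (f / 6000.0)
        * t1app_s
        * np.exp(-att / c.t1_blood)
    )
    rising = 1.0 - np.exp(-np.clip(t - att, 0.0, None) / (1000.0 * t1app_s))
    plateau = 1.0 - np.exp(-ld / (1000.0 * t1app_s))
    decay = np.exp(-np.clip(t - att - ld, 0.0, None) / (1000.0 * t1app_s))
    dm = np.where(
        t < att,
        0.0,
        np.where(t < att + ld, amp * rising, amp * plateau * decay),
    )
    return dm
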