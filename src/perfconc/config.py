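"""Run configuration for the end-to-end simulation + concordance pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .grid import VoxelGrid
from .hadamard import HadamardScheme, free_lunch_scheme
from .kinetics import ASLParams, KineticConstants
from .pet import PMRFlowParams
from .phantom import LesionSpec

__all__ = ["PatientSpec", "RunConfig", "default_patient_cohort", "matched_noiseless_config"]


@dataclass(frozen=True)
class PatientSpec:
    """A simulated patient: subtype label plus lesion geometry given as
    fractions of the grid extent (so cohorts scale with the grid)."""

    subject_id: str
    subtype: str
    lesions: tuple  # of (center fractions, radius mm, cbf reduction)

    def lesion_specs(self, grid: VoxelGrid) -> list[LesionSpec]:
        ext = grid.extent_mm
        out = []
        for frac, radius, reduction in self.lesions:
            center = tuple(f * e for f, e in zip(frac, ext))
            out.append(LesionSpec(center_mm=center, radius_mm=radius, cbf_reduction=reduction))
        return out


def default_patient_cohort() -> list[PatientSpec]:
    """Eight patients, two per subtype, with subtype-flavoured lesion
    geometry (frontal/temporal-pole for bvFTD, left-lateralized perisylvian
    for nfPPA, deep midline for PSP, left temporal for svFTD). Lesions are
    spheres of 8–10 mm radius with a 50% perfusion reduction."""
    c = [
        PatientSpec("bvFTD1", "bvFTD", (((0.35, 0.25, 0.50), 10.0, 0.5),
                                        ((0.65, 0.25, 0.50), 10.0, 0.5))),
        PatientSpec("bvFTD2", "bvFTD", (((0.38, 0.28, 0.55), 10.0, 0.5),
                                        ((0.62, 0.28, 0.45), 9.0, 0.5))),
        PatientSpec("nfPPA1", "nfPPA", (((0.30, 0.45, 0.45), 9.0, 0.5),)),
        PatientSpec("nfPPA2", "nfPPA", (((0.32, 0.40, 0.50), 9.0, 0.5),
                                        ((0.40, 0.30, 0.45), 8.0, 0.5))),
        PatientSpec("PSP1", "PSP", (((0.50, 0.45, 0.35), 8.0, 0.5),)),
        PatientSpec("PSP2", "PSP", (((0.50, 0.42, 0.38), 8.0, 0.5),
                                    ((0.50, 0.30, 0.55), 8.0, 0.5))),
        PatientSpec("svFTD1", "svFTD", (((0.28, 0.55, 0.42), 10.0, 0.5),)),
        PatientSpec("svFTD2", "svFTD", (((0.28, 0.50, 0.45), 10.0, 0.5),
                                        ((0.70, 0.55, 0.42), 8.0, 0.5))),
    ]
    return c


@dataclass
class RunConfig:
    """Everything a pipeline run needs; validated at construction.

    Between-subject biology: each subject's GM and WM CBF are drawn from
    normal distributions (means/SDs below). ``matched_patients`` pins the
    patients' baseline tissue CBF at the population means so they differ
    from controls only by their lesions — the configuration used for the
    noiseless-limit demonstrations.
    """

    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((64, 64, 48), (2.0, 2.0, 2.0)))
    gm_cbf_mean: float = 60.0
    wm_cbf_mean: float = 20.0
    gm_cbf_sd: float = 6.0
    wm_cbf_sd: float = 2.0
    att_range: tuple = (800.0, 1800.0)
    n_controls: int = 13
    patients: list = field(default_factory=default_patient_cohort)
    matched_patients: bool = False

    aif_peak_time: float = 30.0  # s
    aif_peak_value: float = 30.0  # kBq/ml
    aif_shape: float = 3.0
    pet_noise_sd: float = 0.5  # kBq/ml (per √s of frame duration)
    asl_noise_sd: float = 0.002  # a.u. per volume
    n_pairs: int = 16

    constants: KineticConstants = field(default_factory=KineticConstants)
    asl_params_sd: ASLParams = None
    asl_params_te: ASLParams = None
    scheme: HadamardScheme = field(default_factory=free_lunch_scheme)
    pmrflow: PMRFlowParams = field(default_factory=PMRFlowParams)

    alpha: float = 0.05
    sphere_diameter_mm: float = 10.0
    connectivity: int = 26
    fwhm_pet: float = 6.0  # mm
    fwhm_asl: float = 8.0  # mm
    seed: int = 0

    def __post_init__(self):
        if self.asl_params_sd is None:
            self.asl_params_sd = ASLParams(
                label_duration=1800.0, post_label_delay=2000.0, constants=self.constants
            )
        if self.asl_params_te is None:
            self.asl_params_te = ASLParams(
                label_duration=float(self.scheme.sub_bolus_durations[0]),
                post_label_delay=float(self.scheme.final_pld),
                constants=self.constants,
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_controls < 2:
            raise ValueError("need at least two controls")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.pmrflow.integration_time > 300.0 + 1e-9:
            raise ValueError("integration time exceeds the 300 s scan")
        if min(self.fwhm_pet, self.fwhm_asl) < 0:
            raise ValueError("smoothing FWHM must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load scalar overrides from a YAML mapping (grid given as
        ``grid: {shape: [..], voxel_size: [..]}``)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "grid" in raw:
            g = raw.pop("grid")
            kwargs["grid"] = VoxelGrid(tuple(g["shape"]), tuple(g.get("voxel_size", (2, 2, 2))))
        for key in (
            "gm_cbf_mean", "wm_cbf_mean", "gm_cbf_sd", "wm_cbf_sd", "n_controls",
            "matched_patients", "aif_peak_time", "aif_peak_value", "aif_shape",
            "pet_noise_sd", "asl_noise_sd", "n_pairs", "alpha", "sphere_diameter_mm",
            "connectivity", "fwhm_pet", "fwhm_asl", "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "att_range" in raw:
            kwargs["att_range"] = tuple(raw["att_range"])
        return cls(**kwargs)


def matched_noiseless_config(**overrides) -> RunConfig:
    """The noiseless-limit configuration: no measurement noise, patients
    matched to the population baseline, and equal (zero) smoothing for all
    modalities so that modality masks are comparable voxel-for-voxel.
    Controls keep their between-subject biological variability."""
    kwargs = dict(
        pet_noise_sd=0.0,
        asl_noise_sd=0.0,
        matched_patients=True,
        fwhm_pet=0.0,
        fwhm_asl=0.0,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
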