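"""Volumetric I/O (NIfTI-1 via nibabel), tabular exports, and cohort
manifests."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid, check_same_grid
from .kinetics import InputFunction
from .pet import TimeActivityCurve
from .simulate import PCFlowMeasurement

__all__ = [
    "read_volume",
    "write_volume",
    "write_tac_csv",
    "read_tac_csv",
    "write_pc_csv",
    "read_pc_csv",
    "CohortManifest",
]


def write_volume(volume: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with the grid's voxel sizes on
    the affine diagonal."""
    grid.check_volume(volume, "volume")
    affine = np.diag(list(grid.voxel_size) + [1.0])
    data = volume
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.voxel_size + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path, expected_grid: VoxelGrid = None):
    """Read a NIfTI-1 volume; returns (array, VoxelGrid). If an expected
    grid is given, a mismatch raises with both grids named."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=tuple(data.shape[:3]), voxel_size=tuple(float(z) for z in zooms))
    if expected_grid is not None:
        check_same_grid(expected_grid, grid)
    return data, grid


def write_tac_csv(tac: TimeActivityCurve | InputFunction, path) -> None:
    pd.DataFrame({"time_s": tac.times, "activity_kBq_ml": tac.activity}).to_csv(
        path, index=False
    )


def read_tac_csv(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    return TimeActivityCurve(
        times=df["time_s"].to_numpy(), activity=df["activity_kBq_ml"].to_numpy()
    )


def write_pc_csv(pc: PCFlowMeasurement, path) -> None:
    pd.DataFrame(
        {
            "vessel": np.arange(1, pc.velocity_cm_s.size + 1),
            "velocity_cm_s": pc.velocity_cm_s,
            "area_mm2": pc.area_mm2,
        }
    ).to_csv(path, index=False)


def read_pc_csv(path, brain_mass_g: float) -> PCFlowMeasurement:
    df = pd.read_csv(path)
    return PCFlowMeasurement(
        velocity_cm_s=df["velocity_cm_s"].to_numpy(),
        area_mm2=df["area_mm2"].to_numpy(),
        brain_mass_g=brain_mass_g,
    )


@dataclass
class CohortManifest:
    """Subject roster for a case-control run: one row per subject with a
    role (control | patient), an optional disease-subtype label, and file
    paths per modality."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "role")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"manifest is missing the {col!r} column")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            raise ValueError("subject ids must be unique")
        bad = set(self.table["role"]) - {"control", "patient"}
        if bad:
            raise ValueError(f"unknown roles in manifest: {sorted(bad)}")
        if (self.table["role"] == "control").sum() < 2:
            raise ValueError("a case-control run needs at least two controls")

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path))

    def controls(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "control"]

    def patients(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "patient"]
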