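"""ROI atlases for regional hypoperfusion classification.

The default roster mirrors the regions typically assessed in
frontotemporal-dementia perfusion studies: twelve disease-associated ROIs
plus one posterior (occipital) reference region. For the synthetic phantom
the atlas is a deterministic geometric parcellation of the brain mask; real
parcellations can be loaded as a label volume plus a name table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .phantom import TissuePhantom

__all__ = ["ROIAtlas", "build_synthetic_atlas", "DEFAULT_ROI_NAMES"]

DEFAULT_ROI_NAMES = [
    "amygdala",
    "anterior_cingulate",
    "inferior_frontal_gyrus",
    "insula",
    "midbrain",
    "orbitofrontal_gyrus",
    "precuneus",
    "supplementary_motor_area",
    "superior_frontal_gyrus",
    "temporal_pole",
    "middle_temporal_gyrus",
    "superior_temporal_gyrus",
    "occipital_lobe",  # reference region
]


@dataclass
class ROIAtlas:
    """Integer label volume with a label → name table and a designated
    reference region; every named ROI must be non-empty."""

    grid: VoxelGrid
    labels: np.ndarray
    names: dict[int, str]
    reference_roi: str

    def __post_init__(self):
        self.grid.check_volume(self.labels, "atlas labels")
        if self.reference_roi not in self.names.values():
            raise ValueError(f"reference ROI {self.reference_roi!r} not in the name table")
        present = set(np.unique(self.labels)) - {0}
        for lab, name in self.names.items():
            if lab not in present:
                raise ValueError(f"ROI {name!r} (label {lab}) is empty in the atlas volume")

    @property
    def roi_labels(self) -> list[int]:
        return sorted(self.names)

    def mask(self, name: str) -> np.ndarray:
        for lab, n in self.names.items():
            if n == name:
                return self.labels == lab
        raise KeyError(name)

    def disease_labels(self) -> list[int]:
        return [lab for lab in self.roi_labels if self.names[lab] != self.reference_roi]


def build_synthetic_atlas(phantom: TissuePhantom, names: list[str] = None) -> ROIAtlas:
    """Deterministic 13-region parcellation of the phantom brain.

    The posterior fifth of the brain (larger y) is the reference region;
    the remainder is split into 12 sectors (3 axial slabs × 2 × 2
    in-plane quadrants). Region names follow ``DEFAULT_ROI_NAMES`` purely
    as a roster — the synthetic geometry does not reproduce anatomy.
    """
    names = list(names or DEFAULT_ROI_NAMES)
    if len(names) != 13:
        raise ValueError("expected 12 disease ROIs plus one reference name")
    brain = phantom.brain_mask
    idx = np.argwhere(brain)
    y = idx[:, 1]
    y_lo, y_hi = y.min(), y.max()
    y_ref = y_lo + 0.8 * (y_hi - y_lo)  # posterior 20% → reference

    labels = np.zeros(phantom.grid.shape, dtype=np.int16)
    ref_label = 13
    ref_sel = idx[y >= y_ref]
    labels[tuple(ref_sel.T)] = ref_label

    rest = idx[y < y_ref]
    xs, ys, zs = rest[:, 0], rest[:, 1], rest[:, 2]
    # percentile-based splits keep all sectors populated
    z_edges = np.percentile(zs, [100 / 3, 200 / 3])
    x_med = np.median(xs)
    y_med = np.median(ys)
    z_bin = np.digitize(zs, z_edges)  # 0..2
    x_bin = (xs > x_med).astype(int)
    y_bin = (ys > y_med).astype(int)
    sector = z_bin * 4 + x_bin * 2 + y_bin + 1  # 1..12
    labels[xs, ys, zs] = sector

    name_table = {i + 1: n for i, n in enumerate(names[:12])}
    name_table[ref_label] = names[12]
    return ROIAtlas(
        grid=phantom.grid, labels=labels, names=name_table, reference_roi=names[12]
    )
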