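"""Small built-in reference tables.

``ftd_overlap_reference`` holds published per-patient overlap-analysis
values (overlap / adjacent / isolated percentages of the ASL hypoperfusion
mask relative to the ¹⁵O-water mask, plus the Jaccard index) from a
PET/pCASL concordance cohort of nine patients across FTD subtypes and PSP,
for both the time-encoded (FL_TE) and single-delay (SD) pCASL variants and
for absolute and relative CBF. These serve as regression fixtures for the
summary statistics and as a worked example of ``summarize_columns``.
"""

from __future__ import annotations

import pandas as pd

_PATIENTS = [
    "bvFTD1", "bvFTD2", "nfPPA1", "nfPPA2", "PSP1", "PSP2",
    "svFTD1", "svFTD2", "svFTD3",
]

_TABLES = {
    ("fl_te", "absolute"): {
        "overlap": [32, 44, 21, 12, 19, 8, 76, 17, 40],
        "adjacent": [68, 56, 78, 26, 78, 90, 24, 26, 60],
        "isolated": [0, 0, 1, 62, 3, 2, 0, 56, 0],
        "jaccard": [0.18, 0.27, 0.08, 0.05, 0.10, 0.05, 0.00, 0.04, 0.24],
    },
    ("sd", "absolute"): {
        "overlap": [32, 55, 44, 27, 23, 15, 59, 83, 51],
        "adjacent": [68, 45, 54, 32, 76, 80, 32, 16, 48],
        "isolated": [0, 0, 3, 41, 0, 5, 9, 1, 1],
        "jaccard": [0.20, 0.36, 0.21, 0.12, 0.14, 0.09, 0.05, 0.28, 0.37],
    },
    ("fl_te", "relative"): {
        "overlap": [10, 4, 22, 29, 22, 2, 41, 46, 22],
        "adjacent": [86, 73, 75, 60, 77, 84, 53, 49, 65],
        "isolated": [4, 23, 2, 11, 2, 14, 6, 5, 12],
        "jaccard": [0.04, 0.02, 0.06, 0.11, 0.09, 0.01, 0.05, 0.10, 0.05],
    },
    ("sd", "relative"): {
        "overlap": [19, 15, 43, 35, 25, 10, 68, 80, 43],
        "adjacent": [75, 72, 56, 51, 74, 72, 31, 19, 46],
        "isolated": [6, 13, 1, 14, 0, 19, 1, 1, 11],
        "jaccard": [0.12, 0.10, 0.21, 0.19, 0.15, 0.05, 0.25, 0.38, 0.25],
    },
}


def ftd_overlap_reference(variant: str = "fl_te", scale: str = "absolute") -> pd.DataFrame:
    """Per-patient overlap/adjacent/isolated percentages and Jaccard index.

    Parameters
    ----------
    variant : {"fl_te", "sd"}
        Time-encoded or single-delay pCASL compared against ¹⁵O-water.
    scale : {"absolute", "relative"}
        Whether the underlying hypoperfusion maps used absolute or
        whole-brain-normalized CBF.
    """
    key = (variant, scale)
    if key not in _TABLES:
        raise ValueError(f"no reference table for variant={variant!r}, scale={scale!r}")
    return pd.DataFrame(_TABLES[key], index=pd.Index(_PATIENTS, name="patient"))
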