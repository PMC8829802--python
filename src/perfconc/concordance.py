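"""Agreement between two modalities' hypoperfusion maps and CBF values.

Mask-level agreement: ROI classification with sensitivity/specificity
against the reference modality, partition of the test mask into
overlapping / adjacent / isolated voxels, the Jaccard index, and the
percent change in cluster volume. Value-level agreement: per-ROI mean CBF,
ordinary least-squares regression, Bland–Altman limits, and per-ROI group
tests between patients and controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .atlas import ROIAtlas
from .pet import CBFMap
from .singlecase import _structure, label_clusters

__all__ = [
    "ROIClassification",
    "ConcordanceSummary",
    "classify_roi_hypoperfusion",
    "sensitivity_specificity",
    "overlap_partition",
    "jaccard",
    "cluster_volume_change",
    "roi_mean_cbf",
    "regress_rois",
    "bland_altman",
    "group_roi_test",
    "summarize_columns",
    "concordance_summary",
]


@dataclass
class ROIClassification:
    """Per-ROI hypoperfusion call and the largest in-ROI cluster size."""

    hypoperfused: dict[str, bool]
    largest_cluster: dict[str, int]


@dataclass
class ConcordanceSummary:
    """One subject-pair row of the overlap analysis."""

    sensitivity: float
    specificity: float
    overlap_pct: float
    adjacent_pct: float
    isolated_pct: float
    jaccard: float
    volume_change_pct: float


def classify_roi_hypoperfusion(
    mask: np.ndarray,
    atlas: ROIAtlas,
    min_voxels: int,
    connectivity: int = 26,
) -> ROIClassification:
    """Classify each ROI as hypoperfused if the mask, restricted to that
    ROI, contains a connected cluster of at least ``min_voxels`` voxels.
    A cluster straddling two ROIs contributes only its in-ROI voxels to
    each."""
    atlas.grid.check_volume(mask, "hypoperfusion mask")
    mask = mask.astype(bool)
    flags, largest = {}, {}
    for lab in atlas.roi_labels:
        name = atlas.names[lab]
        roi_mask = mask & (atlas.labels == lab)
        cl = label_clusters(roi_mask, connectivity)
        size = int(cl.sizes.max()) if cl.n_clusters else 0
        largest[name] = size
        flags[name] = size >= min_voxels
    return ROIClassification(hypoperfused=flags, largest_cluster=largest)


def sensitivity_specificity(
    test: ROIClassification, reference: ROIClassification
) -> tuple[float, float]:
    """ROI-level agreement with the reference modality: sensitivity is the
    fraction of reference-positive ROIs also called by the test modality,
    specificity the fraction of reference-negative ROIs cleared by both.
    Undefined proportions (no positives / no negatives in the reference)
    are returned as NaN."""
    rois = sorted(reference.hypoperfused)
    if sorted(test.hypoperfused) != rois:
        raise ValueError("classifications cover different ROI rosters")
    ref_pos = [r for r in rois if reference.hypoperfused[r]]
    ref_neg = [r for r in rois if not reference.hypoperfused[r]]
    if ref_pos:
        sens = sum(test.hypoperfused[r] for r in ref_pos) / len(ref_pos)
    else:
        sens = float("nan")
    if ref_neg:
        spec = sum(not test.hypoperfused[r] for r in ref_neg) / len(ref_neg)
    else:
        spec = float("nan")
    return float(sens), float(spec)


def overlap_partition(
    test_mask: np.ndarray, ref_mask: np.ndarray, connectivity: int = 26
) -> tuple[float, float, float]:
    """Partition the test mask into overlapping, adjacent and isolated
    voxels, as percentages of the test mask.

    Overlap = test ∩ reference. The remaining test voxels are grouped into
    connected components; a component touching any overlap voxel (under the
    same connectivity) is adjacent, otherwise isolated.
    """
    test_mask = test_mask.astype(bool)
    ref_mask = ref_mask.astype(bool)
    if test_mask.shape != ref_mask.shape:
        raise ValueError("masks must share the grid")
    n_test = int(test_mask.sum())
    if n_test == 0:
        raise ValueError("test mask is empty; partition percentages are undefined")
    overlap = test_mask & ref_mask
    rest = test_mask & ~overlap
    struct = _structure(connectivity)
    labels, n = ndimage.label(rest, structure=struct)
    n_overlap = int(overlap.sum())
    n_adjacent = 0
    if n:
        touching = ndimage.binary_dilation(overlap, structure=struct)
        adj_labels = np.unique(labels[touching & rest])
        adj_labels = adj_labels[adj_labels > 0]
        if adj_labels.size:
            n_adjacent = int(np.isin(labels, adj_labels).sum())
    n_isolated = n_test - n_overlap - n_adjacent
    return tuple(100.0 * np.array([n_overlap, n_adjacent, n_isolated]) / n_test)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean volumes; 0 when both empty."""
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share the grid")
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return float((a & b).sum() / union)


def cluster_volume_change(ref_mask: np.ndarray, test_mask: np.ndarray) -> float:
    """Percent change in hypoperfused volume relative to the reference:
    100·(|ref| − |test|)/|ref|; positive when the test modality detects
    less."""
    n_ref = int(np.count_nonzero(ref_mask))
    if n_ref == 0:
        raise ValueError("reference mask is empty")
    n_test = int(np.count_nonzero(test_mask))
    return 100.0 * (n_ref - n_test) / n_ref


def roi_mean_cbf(cbf_map: CBFMap, atlas: ROIAtlas) -> dict[str, float]:
    """Mean of valid voxels per ROI; NaN where an ROI has no valid voxel."""
    atlas.grid.check_volume(cbf_map.values, "CBF map")
    out = {}
    for lab in atlas.roi_labels:
        sel = (atlas.labels == lab) & cbf_map.valid
        out[atlas.names[lab]] = float(cbf_map.values[sel].mean()) if sel.any() else float("nan")
    return out


def _paired_finite(x, y):
    x = np.asarray(list(x.values()) if isinstance(x, dict) else x, dtype=float)
    y = np.asarray(list(y.values()) if isinstance(y, dict) else y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("per-ROI value sets differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def regress_rois(x_means, y_means) -> tuple[float, float, float]:
    """Ordinary least squares of y on x over paired ROI means, returning
    (intercept, slope, Pearson R)."""
    x, y = _paired_finite(x_means, y_means)
    if x.size < 3:
        raise ValueError("need at least three paired finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; regression undefined")
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue)


def bland_altman(x_means, y_means) -> tuple[float, float, float]:
    """Bland–Altman agreement of paired ROI means: mean difference (y − x)
    and the 95% limits bias ± 1.96·SD (sample SD)."""
    x, y = _paired_finite(x_means, y_means)
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def group_roi_test(
    patient_values: pd.DataFrame,
    control_values: pd.DataFrame,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-ROI comparison of patient vs control subjects.

    Inputs are subject × ROI tables. By default a Welch (unequal-variance)
    two-sample t-test is applied per ROI, appropriate for independent
    groups; ``paired=True`` switches to a paired test on matched rows.
    Returns a table with t and two-sided p per ROI.
    """
    if len(patient_values) < 2 or len(control_values) < 2:
        raise ValueError("each group needs at least two subjects")
    rois = list(patient_values.columns)
    if list(control_values.columns) != rois:
        raise ValueError("groups cover different ROI rosters")
    rows = []
    for roi in rois:
        a = patient_values[roi].to_numpy(dtype=float)
        b = control_values[roi].to_numpy(dtype=float)
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"roi": roi, "t": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows).set_index("roi")


def summarize_columns(
    values: pd.DataFrame, decimals: dict[str, int] | int | None = None
) -> pd.DataFrame:
    """Column-wise mean ± sample SD of a per-subject metric table, with
    per-column rounding (e.g. percentages to 1 decimal, Jaccard to 2)."""
    if len(values) < 2:
        raise ValueError("need at least two rows to summarize")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = pd.DataFrame({"mean": mean, "sd": sd})
    if decimals is not None:
        if isinstance(decimals, int):
            out = out.round(decimals)
        else:
            for col, dec in decimals.items():
                if col in out.index:
                    out.loc[col] = out.loc[col].round(dec)
    return out


def concordance_summary(
    test_mask: np.ndarray,
    ref_mask: np.ndarray,
    atlas: ROIAtlas,
    min_voxels: int,
    connectivity: int = 26,
) -> ConcordanceSummary:
    """Assemble the full mask-level agreement row for one subject pair."""
    test_cls = classify_roi_hypoperfusion(test_mask, atlas, min_voxels, connectivity)
    ref_cls = classify_roi_hypoperfusion(ref_mask, atlas, min_voxels, connectivity)
    sens, spec = sensitivity_specificity(test_cls, ref_cls)
    ov, adj, iso = overlap_partition(test_mask, ref_mask, connectivity)
    return ConcordanceSummary(
        sensitivity=sens,
        specificity=spec,
        overlap_pct=ov,
        adjacent_pct=adj,
        isolated_pct=iso,
        jaccard=jaccard(test_mask, ref_mask),
        volume_change_pct=cluster_volume_change(ref_mask, test_mask),
    )
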