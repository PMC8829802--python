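"""End-to-end driver: simulate a control cohort and patient set, quantify
CBF by all three modalities, build single-case hypoperfusion maps, and
assemble the concordance tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .asl import (
    fit_te_cbf_att,
    hadamard_decode,
    normalize_to_wb,
    pairwise_subtract,
    quantify_sd_cbf,
    relative_cbf,
)
from .atlas import ROIAtlas, build_synthetic_atlas
from .concordance import ConcordanceSummary, concordance_summary, roi_mean_cbf
from .config import RunConfig
from .kinetics import gamma_variate_aif
from .pet import CBFMap, frame_midpoint_tac, pc_whole_brain_cbf, pmrflow_cbf, smooth_gaussian
from .phantom import build_phantom
from .singlecase import (
    control_group_stats,
    hypoperfusion_pipeline,
    min_cluster_extent,
)
from .simulate import (
    default_frame_schedule,
    simulate_asl_sd,
    simulate_asl_te,
    simulate_pc,
    simulate_pet_dynamic,
)

__all__ = ["PipelineResult", "run_pipeline"]

MODALITIES = ("pet", "asl_sd", "asl_te")
SCALES = ("absolute", "relative")


@dataclass
class PipelineResult:
    """Bundle of everything a run produces."""

    config: RunConfig
    atlas: ROIAtlas
    subjects: pd.DataFrame  # subject_id, role, subtype, gm/wm baseline, f_wb
    concordance: pd.DataFrame  # per patient × ASL modality × scale
    roi_means: pd.DataFrame  # per subject × modality × scale × ROI
    masks: dict  # (subject_id, modality, scale) -> boolean volume
    lesion_truth: dict  # subject_id -> boolean volume of true lesion voxels
    min_cluster_voxels: int

    def write(self, outdir) -> None:
        """Write the tabular outputs and a provenance record."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.concordance.to_csv(out / "concordance.csv", index=False)
        self.roi_means.to_csv(out / "roi_means.csv", index=False)
        prov = {
            "package_version": _pkg_version,
            "seed": self.config.seed,
            "grid": {"shape": self.config.grid.shape, "voxel_size": self.config.grid.voxel_size},
            "n_controls": self.config.n_controls,
            "n_patients": len(self.config.patients),
            "alpha": self.config.alpha,
            "min_cluster_voxels": self.min_cluster_voxels,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))


def _quantify_subject(cfg: RunConfig, phantom, aif, schedule, seeds):
    """All three absolute CBF maps for one subject, smoothed and intensity
    normalized to the subject's phase-contrast whole-brain CBF."""
    brain = phantom.brain_mask

    pc = simulate_pc(phantom, target_fwb=phantom.mean_cbf(), seed=seeds["pc"],
                     brain_density=cfg.constants.brain_density)
    f_wb = pc_whole_brain_cbf(pc)

    dyn = simulate_pet_dynamic(
        phantom, aif, schedule, noise_sd=cfg.pet_noise_sd, seed=seeds["pet"],
        lambda_partition=cfg.constants.lambda_partition,
    )
    wb_tac = frame_midpoint_tac(dyn, brain)
    pet_map = pmrflow_cbf(dyn, wb_tac, f_wb, cfg.pmrflow)

    sd_acq = simulate_asl_sd(
        phantom, cfg.asl_params_sd, n_pairs=cfg.n_pairs,
        noise_sd=cfg.asl_noise_sd, seed=seeds["sd"],
    )
    sd_map = quantify_sd_cbf(pairwise_subtract(sd_acq), sd_acq.m0, cfg.asl_params_sd)

    te_acq = simulate_asl_te(
        phantom, cfg.scheme, cfg.asl_params_te,
        noise_sd=cfg.asl_noise_sd, seed=seeds["te"],
    )
    te_map, _att = fit_te_cbf_att(
        hadamard_decode(te_acq), te_acq.m0, cfg.asl_params_te, mask=brain
    )

    maps = {}
    for key, m, fwhm in (
        ("pet", pet_map, cfg.fwhm_pet),
        ("asl_sd", sd_map, cfg.fwhm_asl),
        ("asl_te", te_map, cfg.fwhm_asl),
    ):
        m = CBFMap(grid=m.grid, values=m.values, modality=m.modality,
                   scale=m.scale, valid=m.valid & brain)
        m = smooth_gaussian(m, fwhm)
        m = normalize_to_wb(m, f_wb, brain)
        maps[(key, "absolute")] = m
        maps[(key, "relative")] = relative_cbf(m, brain)
    return maps, f_wb


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full study simulation under one configuration and seed.

    Deterministic: all randomness (biological variability, noise, vessel
    draws) derives from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule = default_frame_schedule()
    aif_t = np.arange(0.0, schedule.total_duration + 10.0, 0.5)
    aif = gamma_variate_aif(cfg.aif_peak_time, cfg.aif_peak_value, cfg.aif_shape, aif_t)

    # reference anatomy for the atlas: lesion-free phantom at population means
    ref_phantom = build_phantom(
        cfg.grid, None, cfg.gm_cbf_mean, cfg.wm_cbf_mean, cfg.att_range, seed=0
    )
    atlas = build_synthetic_atlas(ref_phantom)
    min_vox = min_cluster_extent(cfg.sphere_diameter_mm, cfg.grid.voxel_size)

    def draw_seeds():
        return {k: int(rng.integers(2**31)) for k in ("att", "pet", "pc", "sd", "te")}

    subject_rows = []
    control_maps = {key: [] for key in [(m, s) for m in MODALITIES for s in SCALES]}
    patient_maps = {}
    lesion_truth = {}

    roster = [(f"control{i + 1:02d}", "control", "", None) for i in range(cfg.n_controls)]
    roster += [(p.subject_id, "patient", p.subtype, p) for p in cfg.patients]

    for subject_id, role, subtype, spec in roster:
        gm = float(rng.normal(cfg.gm_cbf_mean, cfg.gm_cbf_sd))
        wm = float(rng.normal(cfg.wm_cbf_mean, cfg.wm_cbf_sd))
        seeds = draw_seeds()
        if role == "patient" and cfg.matched_patients:
            gm, wm = cfg.gm_cbf_mean, cfg.wm_cbf_mean
        gm = max(gm, cfg.wm_cbf_mean + 1.0)
        wm = min(max(wm, 1.0), gm - 1.0)
        lesions = spec.lesion_specs(cfg.grid) if spec is not None else None
        phantom = build_phantom(cfg.grid, lesions, gm, wm, cfg.att_range, seed=seeds["att"])
        maps, f_wb = _quantify_subject(cfg, phantom, aif, schedule, seeds)
        subject_rows.append(
            {"subject_id": subject_id, "role": role, "subtype": subtype,
             "gm_cbf": gm, "wm_cbf": wm, "f_wb_pc": f_wb}
        )
        if role == "control":
            for key, m in maps.items():
                control_maps[key].append(m)
        else:
            patient_maps[subject_id] = maps
            lesion_truth[subject_id] = phantom.labels == 4

    group = {key: control_group_stats(mlist) for key, mlist in control_maps.items()}

    masks = {}
    conc_rows = []
    roi_rows = []

    def add_roi_rows(subject_id, role, maps):
        for (mod, scale), m in maps.items():
            for roi, val in roi_mean_cbf(m, atlas).items():
                roi_rows.append(
                    {"subject_id": subject_id, "role": role, "modality": mod,
                     "scale": scale, "roi": roi, "mean_cbf": val}
                )

    # control ROI means come from the stored control maps
    for key, mlist in control_maps.items():
        for i, m in enumerate(mlist):
            mod, scale = key
            for roi, val in roi_mean_cbf(m, atlas).items():
                roi_rows.append(
                    {"subject_id": f"control{i + 1:02d}", "role": "control",
                     "modality": mod, "scale": scale, "roi": roi, "mean_cbf": val}
                )

    for subject_id, maps in patient_maps.items():
        add_roi_rows(subject_id, "patient", maps)
        for (mod, scale), m in maps.items():
            mask, _t, _cl = hypoperfusion_pipeline(
                m, group[(mod, scale)], alpha=cfg.alpha,
                sphere_diameter_mm=cfg.sphere_diameter_mm,
                connectivity=cfg.connectivity,
            )
            masks[(subject_id, mod, scale)] = mask
        for asl_mod in ("asl_sd", "asl_te"):
            for scale in SCALES:
                test = masks[(subject_id, asl_mod, scale)]
                ref = masks[(subject_id, "pet", scale)]
                row = {"subject_id": subject_id, "modality": asl_mod, "scale": scale}
                if test.any() and ref.any():
                    s = concordance_summary(test, ref, atlas, min_vox, cfg.connectivity)
                    row.update(vars(s))
                else:
                    row.update({k: float("nan") for k in (
                        "sensitivity", "specificity", "overlap_pct",
                        "adjacent_pct", "isolated_pct")})
                    row["jaccard"] = 0.0 if (test.any() or ref.any()) else float("nan")
                    row["volume_change_pct"] = (
                        100.0 if (ref.any() and not test.any()) else float("nan")
                    )
                conc_rows.append(row)

    return PipelineResult(
        config=cfg,
        atlas=atlas,
        subjects=pd.DataFrame(subject_rows),
        concordance=pd.DataFrame(conc_rows),
        roi_means=pd.DataFrame(roi_rows),
        masks=masks,
        lesion_truth=lesion_truth,
        min_cluster_voxels=min_vox,
    )
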