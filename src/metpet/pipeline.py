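"""Config-driven pipeline binding the stages together.

One YAML/JSON config describes a paired-scan experiment (a phantom or real
SUL volumes), the quantification thresholds, and an optional simulated
cohort analysis; :func:`run_pipeline` executes the stages in order —
volumes -> lesions -> response -> cohort statistics — logging every
threshold actually used, and writes per-stage artifacts plus a combined
JSON report.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import CohortSimSpec, make_cohort
from .io import write_report, write_volume
from .lesions import (
    TargetLesionSet,
    detect_new_lesions,
    find_lesions,
    hottest_lesion,
    match_lesions,
    select_targets,
)
from .phantoms import (
    FollowupSpec,
    LesionSpec,
    LiverRegionSpec,
    PhantomSpec,
    make_followup,
    make_phantom,
)
from .response import classify_percist, summarize_burden
from .stats import km_fit, optimal_cutoff
from .sul import (
    SulVolume,
    liver_background,
    measurability_threshold,
    segmentation_threshold,
)

log = logging.getLogger("metpet")


def phantom_spec_from_config(cfg: dict, seed: Optional[int] = None) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain config mapping."""
    liver = None
    if "liver" in cfg:
        lv = cfg["liver"]
        liver = LiverRegionSpec(
            center_mm=tuple(lv["center_mm"]),
            radius_mm=float(lv.get("radius_mm", 30.0)),
            mean_sul=float(lv["mean_sul"]),
            sd_sul=float(lv.get("sd_sul", 0.0)),
            label=int(lv.get("label", 1)),
        )
    lesions = tuple(
        LesionSpec(
            id=str(l["id"]),
            center_mm=tuple(l["center_mm"]),
            radii_mm=tuple(l["radii_mm"]),
            peak_sul=float(l["peak_sul"]),
            organ_label=int(l["organ_label"]),
            profile=str(l.get("profile", "plateau")),
        )
        for l in cfg.get("lesions", [])
    )
    return PhantomSpec(
        grid_shape=tuple(cfg["grid_shape"]),
        voxel_spacing_mm=tuple(cfg["voxel_spacing_mm"]),
        background_sul=float(cfg.get("background_sul", 0.5)),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        liver_region=liver,
        lesions=lesions,
        rng_seed=int(cfg.get("rng_seed", 0) if seed is None else seed),
    )


def followup_spec_from_config(cfg: dict, seed: Optional[int] = None) -> FollowupSpec:
    new = tuple(
        LesionSpec(
            id=str(l["id"]),
            center_mm=tuple(l["center_mm"]),
            radii_mm=tuple(l["radii_mm"]),
            peak_sul=float(l["peak_sul"]),
            organ_label=int(l["organ_label"]),
            profile=str(l.get("profile", "plateau")),
        )
        for l in cfg.get("new_lesions", [])
    )
    return FollowupSpec(
        factors={str(k): float(v) for k, v in cfg.get("factors", {}).items()},
        new_lesions=new,
        rng_seed=cfg.get("rng_seed", seed),
    )


def cohort_spec_from_config(cfg: dict, seed: Optional[int] = None) -> CohortSimSpec:
    kwargs: dict[str, Any] = dict(cfg)
    if seed is not None:
        kwargs["rng_seed"] = seed
    return CohortSimSpec(**kwargs)


def assess_pair(baseline_vol: SulVolume, baseline_organs,
                followup_vol: SulVolume, followup_organs,
                liver_center_mm, liver_diameter_mm: float = 30.0,
                exclude_labels=(), match_radius_mm: float = 20.0,
                strict_percist: bool = False) -> dict:
    """Quantify a baseline/follow-up SUL pair and assess response.

    Returns a JSON-ready dict: liver background and thresholds per scan,
    per-lesion tables, hottest-lesion dSUL, PERCIST category, and the
    target-lesion burden summary (resolved lesions contribute 0 to
    follow-up sums).
    """
    bg_b = liver_background(baseline_vol, liver_center_mm, liver_diameter_mm)
    bg_f = liver_background(followup_vol, liver_center_mm, liver_diameter_mm)
    log.info("baseline liver: mean=%.3f sd=%.3f seg_thr=%.3f meas_thr=%.3f",
             bg_b.mean_sul, bg_b.sd_sul, segmentation_threshold(bg_b),
             measurability_threshold(bg_b))
    log.info("follow-up liver: mean=%.3f sd=%.3f seg_thr=%.3f meas_thr=%.3f",
             bg_f.mean_sul, bg_f.sd_sul, segmentation_threshold(bg_f),
             measurability_threshold(bg_f))

    lesions_b = find_lesions(baseline_vol, baseline_organs, bg_b,
                             exclude_labels=exclude_labels, id_prefix="B")
    lesions_f = find_lesions(followup_vol, followup_organs, bg_f,
                             exclude_labels=exclude_labels, id_prefix="F")

    targets = select_targets(lesions_b)
    corr = match_lesions(targets, lesions_f, match_radius_mm=match_radius_mm)
    new_flag, new_ids = detect_new_lesions(corr)

    fu_by_id = {l.id: l for l in lesions_f}
    matched_fu = TargetLesionSet(fu_by_id[fid] for _, fid in corr.pairs)

    hot_b = hottest_lesion(lesions_b)
    hot_f_sul = hottest_lesion(lesions_f).sul_max if lesions_f else None
    assessment = classify_percist(hot_b.sul_max, hot_f_sul, new_lesion=new_flag,
                                  strict_percist=strict_percist)
    burden = summarize_burden(targets, matched_fu) if len(targets) else None

    report: dict[str, Any] = {
        "liver": {
            "baseline": {"mean_sul": bg_b.mean_sul, "sd_sul": bg_b.sd_sul},
            "followup": {"mean_sul": bg_f.mean_sul, "sd_sul": bg_f.sd_sul},
        },
        "thresholds": {
            "baseline_segmentation": segmentation_threshold(bg_b),
            "baseline_measurability": measurability_threshold(bg_b),
            "followup_segmentation": segmentation_threshold(bg_f),
            "followup_measurability": measurability_threshold(bg_f),
        },
        "n_lesions": {"baseline": len(lesions_b), "followup": len(lesions_f)},
        "baseline_hottest_sul": assessment.baseline_hottest_sul,
        "followup_hottest_sul": assessment.followup_hottest_sul,
        "delta_sul_pct": assessment.delta_sul_pct,
        "new_lesion": assessment.new_lesion,
        "new_lesion_ids": list(new_ids),
        "category": assessment.category.value,
        "responder": assessment.responder,
        "matched_pairs": [list(p) for p in corr.pairs],
        "resolved_baseline_ids": list(corr.unmatched_baseline),
    }
    if burden is not None:
        report.update({
            "bsum_sul": burden.bsum_sul,
            "bsum_mtv_cm3": burden.bsum_mtv_cm3,
            "bsum_tlg_g": burden.bsum_tlg_g,
            "dsum_sul_pct": burden.dsum_sul_pct,
            "dsum_mtv_pct": burden.dsum_mtv_pct,
            "dsum_tlg_pct": burden.dsum_tlg_pct,
        })
    return report


def analyze_cohort(cohort: pd.DataFrame, outcome: str,
                   predictors: list[str],
                   cutoff_search: bool = True,
                   min_group_fraction: float = 0.15) -> dict:
    """Survival analysis of one endpoint over a set of predictor columns.

    Boolean predictors are compared directly by log-rank; continuous ones
    go through the median-outward optimal-cutoff search when enabled.
    """
    from .stats import log_rank  # local to keep module import light

    times = cohort[f"{outcome}_months"].to_numpy(float)
    events = cohort[f"{outcome}_event"].to_numpy(bool)
    overall = km_fit(times, events, label=outcome)
    result: dict[str, Any] = {
        "outcome": outcome,
        "n": int(len(cohort)),
        "events": int(events.sum()),
        "median_months": overall.median_months,
        "median_ci": list(overall.median_ci),
        "predictors": {},
    }
    for col in predictors:
        vals = cohort[col]
        if vals.dtype == bool or vals.nunique() <= 2:
            grp = vals.astype(bool).to_numpy()
            lr = log_rank(times[~grp], events[~grp], times[grp], events[grp])
            result["predictors"][col] = {
                "type": "binary",
                "p": lr["p"],
                "statistic": lr["statistic"],
                "median_low": km_fit(times[~grp], events[~grp]).median_months,
                "median_high": km_fit(times[grp], events[grp]).median_months,
            }
        elif cutoff_search:
            cut = optimal_cutoff(vals.to_numpy(float), times, events,
                                 min_group_fraction=min_group_fraction)
            result["predictors"][col] = {
                "type": "cutoff_search",
                "cutoff": cut.cutoff,
                "p": cut.p,
                "statistic": cut.statistic,
                "n_low": cut.n_low,
                "n_high": cut.n_high,
                "median_low": cut.median_low,
                "median_high": cut.median_high,
            }
    return result


def run_pipeline(config: dict, out_dir: str | Path,
                 seed: Optional[int] = None) -> dict:
    """Execute the configured stages and write artifacts under ``out_dir``.

    Recognized top-level config keys: ``phantom`` (with optional nested
    ``followup``), ``quantify`` (liver center/diameter, match radius), and
    ``cohort`` (simulation spec plus ``analyze`` options).  Returns the
    combined report dict (also written to ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": seed}

    if "phantom" in config:
        pspec = phantom_spec_from_config(config["phantom"], seed=seed)
        vol_b, org_b, truth_b = make_phantom(pspec)
        write_volume(vol_b, out / "baseline_pet.nii.gz")
        write_volume(org_b, out / "baseline_organs.nii.gz",
                     spacing=vol_b.spacing, origin=vol_b.origin)
        truth_b.to_csv(out / "baseline_truth.csv", index=False)

        fu_cfg = config["phantom"].get("followup")
        if fu_cfg is not None:
            fspec = followup_spec_from_config(fu_cfg, seed=seed)
            vol_f, org_f, truth_f = make_followup(pspec, fspec)
            write_volume(vol_f, out / "followup_pet.nii.gz")
            write_volume(org_f, out / "followup_organs.nii.gz",
                         spacing=vol_f.spacing, origin=vol_f.origin)
            truth_f.to_csv(out / "followup_truth.csv", index=False)

            q = config.get("quantify", {})
            liver_center = q.get("liver_center_mm")
            if liver_center is None and pspec.liver_region is not None:
                liver_center = pspec.liver_region.center_mm
            if liver_center is None:
                raise ValueError("no liver center configured and no liver region in phantom")
            report["response"] = assess_pair(
                vol_b, org_b, vol_f, org_f,
                liver_center_mm=liver_center,
                liver_diameter_mm=float(q.get("liver_diameter_mm", 30.0)),
                exclude_labels=tuple(q.get("exclude_labels", ())),
                match_radius_mm=float(q.get("match_radius_mm", 20.0)),
                strict_percist=bool(q.get("strict_percist", False)),
            )

    if "cohort" in config:
        ccfg = dict(config["cohort"])
        analyze_cfg = ccfg.pop("analyze", {})
        cspec = cohort_spec_from_config(ccfg, seed=seed)
        cohort, truth = make_cohort(cspec)
        cohort.to_csv(out / "cohort.csv", index=False)
        report["cohort_truth"] = truth
        report["analysis"] = {
            outcome: analyze_cohort(
                cohort, outcome,
                predictors=list(analyze_cfg.get("predictors", ["dct", "bsum_mtv"])),
                cutoff_search=bool(analyze_cfg.get("cutoff_search", True)),
                min_group_fraction=float(analyze_cfg.get("min_group_fraction", 0.15)),
            )
            for outcome in analyze_cfg.get("outcomes", ["pfs", "os"])
        }

    write_report(report, out / "report.json")
    return report
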