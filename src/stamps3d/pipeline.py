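"""Pipeline driver: simulate -> dic -> strain -> mask -> metrics -> stats.

Each stage reads its inputs from the run directory (or from the previous
stage in memory), writes CSV/PNG/JSON artifacts and appends itself to a
run manifest recording inputs, outputs, the resolved configuration hash,
seed and timings.  Re-running with an identical configuration is
bit-identical for all non-floating outputs and reproducible to write
precision for floating CSVs.

The ``simulate`` stage produces two things: the *full-design* synthetic
study table (every participant x condition x repeat, drawn analytically
from the effect profile), and rendered stereo image quartets for a small
number of trials.  The imaging stages (dic/strain/mask) run on the
rendered trials and validate the measurement chain end-to-end; the
study-level stages (metrics/stats) run on the study table.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .dic import run_stereo_dic
from .errors import Stamps3dError
from .io import (
    PipelineConfig,
    config_hash,
    dump_config,
    read_image,
    write_csv,
    write_image,
    write_json,
)
from .mask import MaskTemplateConfig, assign_regions, build_default_template, register_mask
from .metrics import regional_peaks, repeatability_cv, summarize_medians
from .stats import condition_comparison, normality_screen, strain_pressure_correlation
from .strain import compute_surface_strain, fit_anatomical_frame
from .synthetic import (
    Bump,
    SpeckleSpec,
    StudyDesign,
    default_effect_profile,
    default_stereo_rig,
    make_deformation,
    make_insole_surface,
    render_stereo_pair,
    simulate_study,
)

ALL_STAGES = ("simulate", "dic", "strain", "mask", "metrics", "stats")

#: Regions given a rendered deformation bump in synthetic trials.  A sparse
#: set keeps the bumps inside their regions at desk-scale render sizes.
RENDERED_BUMP_REGIONS = ("heel", "midfoot_lateral", "hallux")

__all__ = ["run_pipeline", "ALL_STAGES", "build_scene", "bump_profile_for_regions"]


def build_scene(config: PipelineConfig):
    """Construct the surface, cameras and mask template from a config."""
    spec = SpeckleSpec(seed=config.seed, **config.speckle.model_dump())
    ins = config.insole
    surface = make_insole_surface(
        length_mm=ins.length_mm, width_mm=ins.width_mm, contoured=ins.contoured,
        arch_height_mm=ins.arch_height_mm, side=ins.side, spec=spec,
        thickness_mm=ins.thickness_mm)
    cam = config.cameras
    cam1, cam2 = default_stereo_rig(
        target_mm=(ins.length_mm / 2.0, 0.0, 0.0),
        standoff_mm=cam.standoff_mm, vergence_deg=cam.vergence_deg,
        image_size_px=(cam.image_width_px, cam.image_height_px))
    template = build_default_template(MaskTemplateConfig(**config.mask.model_dump()))
    return surface, cam1, cam2, template


def bump_profile_for_regions(surface, template, transform, truths_pct: dict,
                             radius_mm: float) -> list[Bump]:
    """Place one indentation bump at each requested region's centroid.

    The peak indentation depth is chosen so the true out-of-plane strain
    (depth / layer thickness) — and hence S_MAG at the bump centre —
    equals the requested regional truth in percent.
    """
    frame = transform.frame
    bumps = []
    for region, truth in truths_pct.items():
        c = np.asarray(template.regions[region].centroid.coords)[0]
        f = transform.template_to_frame(np.array([c]))[0]
        w = frame.origin[:2] + f[0] * frame.ap_axis[:2] + f[1] * frame.ml_axis[:2]
        depth = truth / 100.0 * surface.thickness_mm
        bumps.append(Bump(region, (float(w[0]), float(w[1])), radius_mm,
                          0.0, depth))
    return bumps


def _effect_profile(config: PipelineConfig) -> pd.DataFrame:
    if config.study.effect_profile is not None:
        return pd.DataFrame(config.study.effect_profile).T[list(config.study.conditions)]
    return default_effect_profile(config.study.conditions)


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stage range and return the run manifest.

    ``stages`` is an ordered subset of :data:`ALL_STAGES` (default: all).
    Later stages read earlier stages' artifacts from ``config.output_dir``
    when not run in the same invocation, so ``metrics -> stats`` can run
    on a hand-written study table without any images.  A stage failure
    halts the chain; the manifest written so far is preserved with the
    failing stage's diagnostics.
    """
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages.sort(key=ALL_STAGES.index)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
        "outputs": {},
    }
    dump_config(config, out / "config.yaml")

    surface, cam1, cam2, template = build_scene(config)
    frame = fit_anatomical_frame(surface.outline, surface.side)
    transform = register_mask(template, surface.outline, surface.side, frame)
    profile = _effect_profile(config)

    def _record(stage, t0, outputs):
        manifest["stages"].append({
            "stage": stage,
            "seconds": round(time.time() - t0, 3),
            "outputs": [str(p) for p in outputs],
        })
        for p in outputs:
            manifest["outputs"][Path(p).name] = str(p)

    try:
        if "simulate" in stages:
            t0 = time.time()
            outputs = []
            design = StudyDesign(n_participants=config.study.n_participants,
                                 conditions=tuple(config.study.conditions),
                                 n_repeats=config.study.n_repeats,
                                 seed=config.seed)
            table, truth = simulate_study(
                design, profile, noise_cv=config.study.noise_cv,
                target_rho=config.study.target_rho,
                pressure_cv=config.study.pressure_cv,
                between_participant_sd=config.study.between_participant_sd)
            outputs.append(write_csv(out / "study_table.csv", table))
            outputs.append(write_json(out / "study_truth.json", {
                "effect_profile": truth["effect_profile"].to_dict(),
                "target_rho": truth["target_rho"],
                "pressure_condition": truth["pressure_condition"],
                "design": dataclasses.asdict(design),
            }))
            cond = config.study.conditions[-1]
            for j in range(config.render.n_rendered_trials):
                truths = {r: float(profile.loc[r, cond])
                          for r in RENDERED_BUMP_REGIONS}
                bumps = bump_profile_for_regions(surface, template, transform,
                                                 truths, config.render.bump_radius_mm)
                deformation = make_deformation(surface, bumps, seed=config.seed + j)
                pre1, pre2 = render_stereo_pair(surface, None, cam1, cam2,
                                                config.render.background,
                                                config.render.supersample)
                post1, post2 = render_stereo_pair(surface, deformation, cam1, cam2,
                                                  config.render.background,
                                                  config.render.supersample)
                for name, img in (("pre1", pre1), ("pre2", pre2),
                                  ("post1", post1), ("post2", post2)):
                    outputs.append(write_image(out / f"trial{j:02d}_{name}.png", img))
                outputs.append(write_csv(
                    out / f"trial{j:02d}_truth.csv", deformation.strain_truth))
            _record("simulate", t0, outputs)

        trial_ids = sorted({p.name.split("_")[0] for p in out.glob("trial*_pre1.png")})

        fields = {}
        if "dic" in stages:
            t0 = time.time()
            outputs = []
            from .io import write_displacement_field
            for tid in trial_ids:
                imgs = [read_image(out / f"{tid}_{n}.png")
                        for n in ("pre1", "pre2", "post1", "post2")]
                fld = run_stereo_dic(*imgs, cam1, cam2, config.dic.to_config())
                fields[tid] = fld
                outputs.append(write_displacement_field(
                    out / f"{tid}_displacements.csv", fld))
                if fld.invalid_fraction > 0.05:
                    manifest["warnings"].append(
                        f"{tid}: {fld.invalid_fraction:.1%} nodes invalid")
            _record("dic", t0, outputs)

        strains = {}
        if "strain" in stages:
            t0 = time.time()
            outputs = []
            from .io import read_displacement_field, write_strain_field
            for tid in trial_ids:
                fld = fields.get(tid)
                if fld is None:
                    fld = read_displacement_field(out / f"{tid}_displacements.csv",
                                                  config.dic.to_config())
                sf = compute_surface_strain(
                    fld, frame, thickness_mm=surface.thickness_mm,
                    neighborhood_radius_mm=config.strain.neighborhood_radius_mm,
                    radius_factor=config.strain.radius_factor)
                strains[tid] = sf
                outputs.append(write_strain_field(out / f"{tid}_strain.csv", sf))
            _record("strain", t0, outputs)

        if "mask" in stages:
            t0 = time.time()
            outputs = []
            from .io import write_strain_field
            measured = []
            for tid, sf in strains.items():
                asg = assign_regions(sf.points, transform, template,
                                     outline=surface.outline)
                outputs.append(write_strain_field(out / f"{tid}_strain_regions.csv",
                                                  sf, region_labels=asg.labels))
                peaks = regional_peaks(sf, asg)
                measured.append({"trial": tid, **peaks})
            if measured:
                outputs.append(write_csv(out / "measured_peaks.csv",
                                         pd.DataFrame(measured)))
            _record("mask", t0, outputs)

        if "metrics" in stages:
            t0 = time.time()
            table = pd.read_csv(out / "study_table.csv")
            summary = summarize_medians(table)
            cell_cv, cond_cv = repeatability_cv(table[table.region != "global"])
            outputs = [
                write_csv(out / "summary_medians.csv", summary),
                write_csv(out / "repeatability_cv.csv", cell_cv),
                write_csv(out / "condition_median_cv.csv", cond_cv.reset_index()),
            ]
            _record("metrics", t0, outputs)

        if "stats" in stages:
            t0 = time.time()
            table = pd.read_csv(out / "study_table.csv")
            screen, recommendation = normality_screen(table)
            comparison = condition_comparison(table)
            stats_summary = {"normality_recommendation": recommendation}
            try:
                corr = strain_pressure_correlation(
                    table, condition=config.study.conditions[-1])
                stats_summary["spearman_rho"] = corr.rho
                stats_summary["spearman_p"] = corr.pvalue
                stats_summary["band"] = corr.band
                stats_summary["significant"] = corr.significant
            except Stamps3dError as exc:
                manifest["warnings"].append(f"correlation skipped: {exc}")
            outputs = [
                write_csv(out / "normality_screen.csv", screen),
                write_csv(out / "condition_comparison.csv", comparison),
                write_json(out / "stats_summary.json", stats_summary),
            ]
            _record("stats", t0, outputs)
    finally:
        write_json(out / "manifest.json", manifest)
    return manifest
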