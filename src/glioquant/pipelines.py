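"""End-to-end pipelines for both experimental arms.

``run_organoid_pipeline`` goes from (synthetic or loaded) image stacks to a
per-cell distance table, invasion summary and group tests;
``run_sc_pipeline`` goes from (synthetic or loaded) count matrices to cell
annotations, proportion shifts and volcano records.  Every run writes its
outputs as CSV plus a JSON manifest recording all parameters, seeds and
software versions, sufficient to re-run the exact analysis.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .geometry import (detect_spots, mesh_area, mesh_volume,
                       outside_mask_resurface, pad_stack, reconstruct_surface,
                       shortest_distance)
from .invasion_stats import (compare_multi_groups, compare_two_groups,
                             normalize_distances, summarize_invasion)
from .synth3d import DepthLaw, ImagingParams, generate_scene, render_stack, \
    scene_to_truth_table
from .synth_sc import ScDesign, generate_barnyard, generate_cycle_cohort, \
    read_mtx
from .sc_quant import (proportion_shift, qc_filter, rank_sum_de,
                       score_cell_cycle, species_assign, volcano_classify)

__all__ = ["run_organoid_pipeline", "run_sc_pipeline"]


def _write_manifest(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    manifest = {
        "glioquant_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "config": config.to_dict(),
    }
    manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))


# --------------------------------------------------------------------------
# organoid arm
# --------------------------------------------------------------------------

def run_organoid_pipeline(config: PipelineConfig) -> dict:
    """Simulate (or load), measure and test the organoid invasion arm.

    In ``image`` mode each organoid is rendered, padded with blank slices,
    surfaced twice (pass 1 then the outside-mask pass 2), tumor cells are
    detected as spots and their signed distances to the pass-2 surface
    measured.  In ``table`` mode the ground-truth depths are used directly
    (fast path for statistics-level work).  Group tests run on per-organoid
    invading-cell counts: a two-sample t-test for 2 groups, one-way ANOVA +
    Tukey HSD for more.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    detail_um = float(p.get("detail_um", 25.0))
    spot_d = float(p.get("spot_diameter_um", 10.0))
    n_blank = int(p.get("n_blank", 50))
    fill_value = float(p.get("fill_value", 150.0))
    inside_positive = bool(p.get("inside_positive", True))
    imaging = ImagingParams(**config.imaging)

    tables, organoid_meta = [], []
    scene_counter = 0
    for group in config.groups:
        name = group["name"]
        law = DepthLaw.from_spec(group["depth_law"])
        for k in range(int(group["n_organoids"])):
            seed = config.seed * 10_000 + scene_counter
            scene_counter += 1
            oid = f"{name}_{k}"
            scene = generate_scene(
                organoid_radius=float(group["radius_um"]),
                n_nuclei=(int(group["n_nuclei"]) if "n_nuclei" in group else None),
                n_tumor=int(group["n_tumor"]),
                depth_law=law,
                seed=seed,
                shrinkage=float(group.get("shrinkage", 1.0)),
            )
            if config.mode == "table":
                tab = scene_to_truth_table(scene, organoid_id=oid, group=name)
                tab = tab.rename(columns={"true_depth_um": "distance_um"})
                tables.append(tab)
                organoid_meta.append({"organoid_id": oid, "group": name,
                                      "n_cells": len(tab)})
                continue

            stack = render_stack(scene, imaging)
            stack = pad_stack(stack, n_blank=n_blank)
            mesh1 = reconstruct_surface(stack, detail_um=detail_um)
            mesh2 = outside_mask_resurface(
                stack, mesh1, fill_value=fill_value,
                extend_um=float(p.get("extend_um", 150.0)))
            spots = detect_spots(
                stack, diameter_um=spot_d,
                threshold_rel=float(p.get("spot_threshold_rel", 0.1)))
            tab = shortest_distance(spots, mesh2, organoid_id=oid, group=name,
                                    inside_positive=inside_positive)
            tables.append(tab)
            mesh2.export(outdir / f"{oid}_surface.obj")
            organoid_meta.append({
                "organoid_id": oid, "group": name, "n_cells": len(tab),
                "volume_um3": mesh_volume(mesh2),
                "area_um2": mesh_area(mesh2),
            })

    table = pd.concat(tables, ignore_index=True)
    table = normalize_distances(table)
    reference = p.get("reference_group", config.groups[0]["name"])
    summary = summarize_invasion(table, reference_group=reference)

    counts_by_group = {
        g: sub["n_invading"].to_numpy(dtype=float)
        for g, sub in summary.per_organoid.groupby("group", sort=False)
    }
    if len(counts_by_group) == 1:
        test = None
    elif len(counts_by_group) == 2:
        (a, va), (b, vb) = counts_by_group.items()
        test = compare_two_groups(va, vb)
    else:
        test = compare_multi_groups(counts_by_group)

    table.to_csv(outdir / "distance_table.csv", index=False)
    summary.per_organoid.to_csv(outdir / "invasion_summary.csv", index=False)
    (outdir / "invasion_summary.json").write_text(json.dumps({
        "threshold_um": summary.threshold_um,
        "reference_group": summary.reference_group,
        "group_invading": {g: int(v.sum())
                           for g, v in counts_by_group.items()},
    }, indent=2))
    if test is not None:
        test.to_frame().to_csv(outdir / "group_test.csv", index=False)
    pd.DataFrame(organoid_meta).to_csv(outdir / "organoid_summary.csv",
                                       index=False)
    from .invasion_stats import kde_profile
    from .plots import plot_distance_boxes, plot_stacked_kde

    by_organoid = {oid: sub["normalized_distance_um"].to_numpy()
                   for oid, sub in table.groupby("organoid_id", sort=False)
                   if len(sub) > 0}
    if by_organoid:
        grid, curves = kde_profile(by_organoid)
        plot_stacked_kde(grid, curves, path=outdir / "kde_profile.png")
        plot_distance_boxes(table, path=outdir / "distance_boxes.png")

    _write_manifest(outdir, config, {"invasion_threshold_um":
                                     summary.threshold_um})
    return {"table": table, "summary": summary, "test": test,
            "organoids": pd.DataFrame(organoid_meta), "outdir": outdir}


# --------------------------------------------------------------------------
# single-cell arm
# --------------------------------------------------------------------------

def run_sc_pipeline(config: PipelineConfig) -> dict:
    """Species separation, QC, cell-cycle scoring and proportion shifts.

    With a generator design the pipeline simulates a barnyard capture for
    species assignment and a two-arm cycle cohort for phase analysis; with
    ``inputs: {mtx_dir: ...}`` it reads an MTX triplet instead.  Outputs:
    cell annotations, phase (and cluster, when present) proportion shifts,
    and — when ``run_de`` is set — a rank-sum + Bonferroni volcano table.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params

    if config.inputs.get("mtx_dir"):
        adata = read_mtx(config.inputs["mtx_dir"])
    else:
        design = ScDesign(seed=config.seed, **config.design)
        adata = generate_cycle_cohort(design)
        barnyard = generate_barnyard(design)
        species_assign(barnyard,
                       threshold_pct=float(p.get("species_threshold_pct", 90)))
        barnyard.obs.to_csv(outdir / "barnyard_annotation.csv")

    keep = qc_filter(
        adata,
        min_genes=int(p.get("min_genes", 200)),
        max_genes=int(p.get("max_genes", 6000)),
        max_mito_pct=float(p.get("max_mito_pct", 10.0)),
    )
    passed = adata[keep.to_numpy()].copy()
    score_cell_cycle(passed, n_bins=int(p.get("n_bins", 24)),
                     n_ctrl=int(p.get("n_ctrl", 100)), seed=config.seed)

    shift = proportion_shift(passed.obs, category="phase")
    results = {"annotation": passed.obs, "phase_shift": shift,
               "outdir": outdir}
    passed.obs.to_csv(outdir / "cell_annotation.csv")
    shift.to_csv(outdir / "phase_shift.csv", index=False)

    if "cluster_true" in passed.obs and passed.obs["cluster_true"].nunique() > 1:
        cshift = proportion_shift(passed.obs, category="cluster_true")
        cshift.to_csv(outdir / "cluster_shift.csv", index=False)
        results["cluster_shift"] = cshift

    if p.get("run_de", False):
        de = rank_sum_de(passed)
        volcano = volcano_classify(
            de, fc_thresh=float(p.get("fc_thresh", 0.23)),
            p_thresh=float(p.get("p_thresh", 1e-8)))
        volcano.to_csv(outdir / "volcano.csv", index=False)
        results["volcano"] = volcano

    arm_counts = passed.obs.groupby("arm", observed=True).size()
    (outdir / "pass_filter_counts.json").write_text(json.dumps({
        "per_arm": arm_counts.to_dict(),
        "total": int(arm_counts.sum()),
    }, indent=2))
    _write_manifest(outdir, config, {"n_pass_filter": int(keep.sum())})
    return results


def arm_totals(per_arm_counts: dict) -> dict:
    """Aggregate per-arm pass-filter cell counts into a report total."""
    counts = pd.Series(per_arm_counts, dtype="int64")
    return {"per_arm": counts.to_dict(), "total": int(counts.sum())}


__all__.append("arm_totals")
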