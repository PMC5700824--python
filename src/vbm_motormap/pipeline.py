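"""End-to-end orchestration: score, map, correct, cluster, report.

The full analysis mirrors the study design: subscore computation and
cross-correlation, five voxel-wise correlation maps (total + four
subscores) with permutation FWE correction (optionally small-volume
corrected within the striatum), a GLM controlling age and sex, cluster
extraction with atlas labels, and post-hoc cluster-averaged correlation
tables — bundled into a markdown report that logs seeds, mask sizes and
thresholds (both permutation and Bonferroni) for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vbm_motormap import __version__
from vbm_motormap.clinical import (
    SUBSCORE_LABELS,
    cross_correlation_matrix,
    read_clinical_csv,
    select_nearest_visit,
    subscore_table,
    write_correlation_csv,
)
from vbm_motormap.clusters import (
    CIRCULARITY_NOTE,
    AtlasVolume,
    extract_clusters,
    posthoc_cluster_correlations,
)
from vbm_motormap.synthetic import (
    default_ground_truth,
    make_toy_atlas,
    simulate_clinical,
    simulate_gm,
)
from vbm_motormap.voxelstats import (
    GMVolumeStack,
    MaskVolume,
    bonferroni_threshold,
    build_analysis_mask,
    fit_voxelwise_glm,
    fwe_maxT,
    small_volume_correction,
    voxelwise_pearson,
)

__all__ = ["AnalysisConfig", "run_full_analysis", "StageError"]

STRIATAL_REGIONS = ("caudate_L", "caudate_R", "putamen_L", "putamen_R")


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        self.code = f"E_{stage.upper()}"
        super().__init__(f"[{self.code}] stage '{stage}' failed: {message}")


@dataclass
class AnalysisConfig:
    out_dir: str = "vbm_out"
    force: bool = False
    seed: int = 42
    alpha: float = 0.05
    n_perm: int = 1000
    tail: str = "one_neg"
    connectivity: int = 18
    min_mean_intensity: float = 0.05
    scores: tuple[str, ...] = SUBSCORE_LABELS
    svc_regions: tuple[str, ...] | None = STRIATAL_REGIONS
    # inputs: either paths ...
    gm4d: str | None = None
    clinical: str | None = None
    atlas: str | None = None
    atlas_names: str | None = None
    scan_date: str | None = None
    # ... or a synthetic cohort
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(cfg: AnalysisConfig, rng_seed: int):
    if cfg.gm4d:
        if not (cfg.clinical and cfg.atlas and cfg.atlas_names):
            raise StageError("load", "gm4d given but clinical/atlas inputs missing")
        atlas = AtlasVolume.from_nifti(cfg.atlas, cfg.atlas_names)
        records = read_clinical_csv(cfg.clinical)
        import datetime as dt

        scan = (
            dt.date.fromisoformat(cfg.scan_date)
            if cfg.scan_date
            else min(r.visit_date for r in records)
        )
        by_subject: dict[str, list] = {}
        for r in records:
            by_subject.setdefault(r.subject_id, []).append(r)
        chosen = [select_nearest_visit(v, scan) for v in by_subject.values()]
        scored = subscore_table(chosen)
        stack = GMVolumeStack.from_nifti(cfg.gm4d, subject_ids=list(scored["subject_id"]))
        truth = None
    else:
        syn = dict(cfg.synthetic)
        n = int(syn.get("n", 364))
        shape = tuple(syn.get("shape", (40, 48, 40)))
        spacing = float(syn.get("spacing_mm", 4.0))
        atlas = make_toy_atlas(shape, spacing)
        clinical = simulate_clinical(n=n, seed=rng_seed)
        truth = default_ground_truth(atlas, seed=rng_seed + 1)
        stack = simulate_gm(clinical, atlas, truth)
        scored = clinical
    return stack, atlas, scored, truth


def run_full_analysis(cfg: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle; returns a result dict."""
    out = Path(cfg.out_dir)
    if out.exists() and any(out.iterdir()) and not cfg.force:
        raise StageError("setup", f"output dir {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    try:
        stack, atlas, scored, truth = _load_inputs(cfg, cfg.seed)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", str(exc)) from exc

    report: list[str] = [
        "# Voxel-wise GM / motor-severity analysis",
        "",
        f"- package version: {__version__}",
        f"- n subjects: {stack.n_subjects}",
        f"- seed: {cfg.seed}; alpha: {cfg.alpha}; n_perm: {cfg.n_perm}; tail: {cfg.tail}",
    ]
    results: dict = {"n_subjects": stack.n_subjects, "maps": {}}

    try:
        corr = cross_correlation_matrix(scored[list(SUBSCORE_LABELS)])
        write_correlation_csv(corr, out / "subscore_correlations.csv")
        scored.to_csv(out / "subscores.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cross_correlation", str(exc)) from exc
    report += [
        "",
        "## Subscore cross-correlation",
        "",
        corr.as_frame().round(4).to_string(),
        "",
        f"df = {corr.df}; critical |r| at alpha {corr.alpha} (two-tailed) = "
        f"{corr.critical_value:.4f}",
    ]
    results["cross_correlation"] = corr

    try:
        mask = build_analysis_mask(stack, cfg.min_mean_intensity)
        svc_mask = None
        if cfg.svc_regions:
            svc_mask = MaskVolume(
                atlas.region_mask(*cfg.svc_regions), provenance="striatal SVC"
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("mask", str(exc)) from exc
    report += ["", f"Analysis mask: {mask.n_voxels} voxels"]
    if svc_mask is not None:
        report.append(f"Small-volume mask: {svc_mask.n_voxels} voxels")

    df = stack.n_subjects - 2
    for score in cfg.scores:
        try:
            x = scored[score].to_numpy(dtype=float)
            design = pd.DataFrame({"UPDRS3": x})
            stat = voxelwise_pearson(stack, x, mask, tail=cfg.tail)
            null = fwe_maxT(
                stack, design, "pearson", mask,
                alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed, tail=cfg.tail,
            )
            bonf = bonferroni_threshold(cfg.alpha, mask.n_voxels, df, cfg.tail)
            clusters = extract_clusters(
                stat, null.threshold, tail=cfg.tail,
                connectivity=cfg.connectivity, affine=stack.affine, atlas=atlas,
            )
            entry = {"stat": stat, "null": null, "clusters": clusters, "bonferroni": bonf}
            if svc_mask is not None:
                entry["svc"] = small_volume_correction(
                    stack, design, "pearson", mask, svc_mask,
                    alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed, tail=cfg.tail,
                )
            results["maps"][score] = entry
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"map_{score}", str(exc)) from exc

        report += [
            "",
            f"## Statistic map: {score}",
            "",
            f"- permutation FWE threshold (maxT, alpha {cfg.alpha}): {null.threshold:.3f}",
            f"- Bonferroni threshold ({mask.n_voxels} voxels): {bonf:.3f}",
            f"- suprathreshold clusters: {len(clusters)}",
        ]
        if "svc" in entry:
            report.append(f"- SVC threshold: {entry['svc'].threshold:.3f}")
        if len(clusters):
            report += ["", clusters.table.round(3).to_string(index=False)]
            clusters.to_tsv(out / f"clusters_{score}.tsv")
            try:
                posthoc = posthoc_cluster_correlations(stack, clusters, scored)
                posthoc.to_csv(out / f"posthoc_{score}.csv", index=False)
                report += ["", posthoc.round(4).to_string(index=False), "", CIRCULARITY_NOTE]
            except Exception as exc:  # noqa: BLE001
                raise StageError(f"posthoc_{score}", str(exc)) from exc

    try:
        covs = scored[["total", "age", "sex"]].rename(
            columns={"total": "UPDRS3", "age": "Age", "sex": "Sex"}
        )
        glm = fit_voxelwise_glm(stack, covs, mask)
        results["glm"] = glm
    except Exception as exc:  # noqa: BLE001
        raise StageError("glm", str(exc)) from exc
    report += [
        "",
        "## GLM (GM ~ intercept + UPDRS3 + Age + Sex)",
        "",
        f"- residual df: {glm.residual_df}",
        f"- design columns: {', '.join(glm.design_summary['column'])}",
    ]

    (out / "report.md").write_text("\n".join(report) + "\n")
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "n_perm": cfg.n_perm,
        "tail": cfg.tail,
        "n_subjects": stack.n_subjects,
        "mask_voxels": mask.n_voxels,
        "df": df,
        "clusters_per_score": {s: len(results["maps"][s]["clusters"]) for s in cfg.scores},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    results["summary"] = summary
    results["truth"] = truth
    return results
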