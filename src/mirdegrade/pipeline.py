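"""End-to-end orchestration: simulate → analyze → report.

Each stage writes deterministic TSV/JSON artifacts plus a run manifest
(config snapshot, input digests, seed, output paths, tool version); identical
manifests imply bit-identical outputs.  The report stage assembles a single
markdown document from the analyze outputs, marking skipped stages instead of
failing on them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .classify import build_evidence, classify, version_bias_summary
from .cluster import (
    complete_linkage,
    cut_tree,
    cluster_version_summary,
    euclidean_distances,
)
from .homology import group_homology_fraction, homology_screen
from .io import (
    read_expression_matrix,
    read_mirbase_annotation,
    read_sample_metadata,
    read_transcripts,
    write_expression_matrix,
    write_mirbase_annotation,
    write_sample_metadata,
    write_transcripts,
    flags_path_for,
)
from .model import AnalysisConfig, ExpressionMatrix, ValidationError
from .preprocess import detection_fallback, detection_filter, glog_normalize, top_variance
from .simulate import SimConfig, simulate_study
from .stats import (
    correlation_screen,
    detected_counts_by_era,
    differential_expression,
)

log = logging.getLogger("mirdegrade")

__all__ = [
    "run_simulate",
    "run_analyze",
    "run_report",
    "load_scenario",
    "build_manifest",
]

STAGES = (
    "preprocess",
    "correlation",
    "differential_expression",
    "era_counts",
    "clustering",
    "classification",
    "homology",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    config: dict, inputs: Sequence[Path], outputs: Sequence[Path], seed: int
) -> dict:
    return {
        "tool": "mirdegrade",
        "version": _version,
        "seed": seed,
        "config": config,
        "inputs": {Path(p).name: _sha256(Path(p)) for p in inputs},
        "outputs": sorted(Path(p).name for p in outputs),
    }


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_scenario(path) -> tuple[SimConfig, AnalysisConfig]:
    """Read a YAML scenario file with optional ``simulation:`` and
    ``analysis:`` sections."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError("scenario file must be a mapping")
    bad = set(doc) - {"simulation", "analysis"}
    if bad:
        raise ValidationError(f"unknown scenario section(s): {sorted(bad)}")
    sim = SimConfig.from_dict(doc.get("simulation") or {})
    cfg = AnalysisConfig.from_dict(doc.get("analysis") or {})
    return sim, cfg


# ---------------------------------------------------------------------------
# simulate


def run_simulate(sim: SimConfig, outdir) -> dict:
    """Write both simulated experiments plus annotation, truth, transcripts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(sim)

    paths = {
        "timecourse": outdir / "timecourse_expression.tsv",
        "timecourse_meta": outdir / "timecourse_meta.tsv",
        "control": outdir / "control_expression.tsv",
        "control_meta": outdir / "control_meta.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
        "transcripts": outdir / "transcripts.fasta",
    }
    write_expression_matrix(study.timecourse, paths["timecourse"])
    write_sample_metadata(study.timecourse_meta, paths["timecourse_meta"])
    write_expression_matrix(study.control, paths["control"])
    write_sample_metadata(study.control_meta, paths["control_meta"])
    write_mirbase_annotation(study.annotation, paths["annotation"])
    pd.DataFrame(
        [
            {
                "mirna_id": t.mirna_id,
                "klass": t.klass,
                "baseline_log2": t.baseline_log2,
                "effect_log2": t.effect_log2,
                "first_version": t.first_version,
            }
            for t in study.truth
        ]
    ).to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    write_transcripts(study.transcripts, paths["transcripts"])

    outputs = list(paths.values()) + [
        flags_path_for(paths["timecourse"]),
        flags_path_for(paths["control"]),
    ]
    manifest = build_manifest(
        {"simulation": sim.to_dict()}, [], outputs, sim.seed
    )
    _write_json(manifest, outdir / "manifest.json")
    log.info("simulate: wrote %d files to %s", len(outputs) + 1, outdir)
    return manifest


# ---------------------------------------------------------------------------
# analyze


@dataclass
class AnalyzeResult:
    summary: dict
    outputs: dict


def _load_matrix(path: Path, cfg: AnalysisConfig) -> ExpressionMatrix:
    m = read_expression_matrix(path)
    if not flags_path_for(path).exists():
        log.info(
            "no detection flags for %s; applying percentile fallback (q=%s)",
            path,
            cfg.detection_fallback_quantile,
        )
        m = detection_fallback(m, cfg.detection_fallback_quantile)
    return m


def run_analyze(
    timecourse_path,
    timecourse_meta_path,
    control_path=None,
    control_meta_path=None,
    annotation_path=None,
    transcripts_path=None,
    config: Optional[AnalysisConfig] = None,
    outdir="analysis",
) -> AnalyzeResult:
    """Run preprocess → screens → DE → clustering → classification
    (→ homology when transcripts are given) and write all result tables,
    a JSON summary of headline counts, and a manifest."""
    cfg = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = [Path(timecourse_path), Path(timecourse_meta_path)]
    tc_raw = _load_matrix(Path(timecourse_path), cfg)
    tc_meta = read_sample_metadata(timecourse_meta_path)
    annotation = None
    if annotation_path is not None:
        annotation = read_mirbase_annotation(annotation_path)
        inputs.append(Path(annotation_path))

    if cfg.exclude_samples:
        keep = [s for s in tc_raw.sample_ids if s not in set(cfg.exclude_samples)]
        tc_raw = tc_raw.select_samples(keep)
        tc_meta = [m for m in tc_meta if m.sample_id not in set(cfg.exclude_samples)]

    summary: dict = {"config": cfg.to_dict(), "stages": {}}
    outputs: dict = {}

    # --- preprocess (detection filter after exclusions, then normalize)
    tc_filt = detection_filter(tc_raw, cfg.min_detect_samples)
    tc_norm = glog_normalize(tc_filt)
    write_expression_matrix(tc_norm, outdir / "timecourse_normalized.tsv")
    outputs["timecourse_normalized"] = outdir / "timecourse_normalized.tsv"
    summary["stages"]["preprocess"] = {
        "n_mirnas_input": tc_raw.n_mirnas,
        "n_samples": tc_raw.n_samples,
        "n_mirnas_retained": tc_filt.n_mirnas,
        "min_detect_samples": cfg.min_detect_samples,
    }

    # --- correlation screens (RIN over all samples, time per temperature)
    corr_counts = {}
    for cov in ("rin", "time_4C", "time_RT"):
        res = correlation_screen(tc_norm, tc_meta, cov, cfg)
        df = pd.DataFrame(
            [
                {
                    "mirna_id": r.mirna_id,
                    "r": r.r,
                    "p": r.p,
                    "p_adj": r.p_adj,
                    "call": r.call,
                }
                for r in res
            ]
        )
        p = outdir / f"correlation_{cov}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        outputs[f"correlation_{cov}"] = p
        corr_counts[cov] = {
            "n_significant": int(sum(r.call != "ns" for r in res)),
            "n_positive": int(sum(r.call == "positive" for r in res)),
            "n_negative": int(sum(r.call == "negative" for r in res)),
        }
    summary["stages"]["correlation"] = corr_counts

    # --- differential expression, liver time-course samples
    liver_ids = [
        m.sample_id
        for m in tc_meta
        if m.tissue == "liver" and m.sample_id in tc_norm.values.columns
    ]
    de_summary: dict = {}
    try:
        de = differential_expression(
            tc_norm.select_samples(liver_ids),
            tc_meta,
            rin_cutoff=cfg.rin_cutoff,
            fold_change=cfg.fold_change,
            alpha=cfg.alpha,
            center=cfg.fc_center,
        )
        df = pd.DataFrame(
            [
                {
                    "mirna_id": r.mirna_id,
                    "median_low": r.median_low,
                    "median_high": r.median_high,
                    "log2fc": r.log2fc,
                    "p": r.p,
                    "p_adj": r.p_adj,
                    "significant": r.significant,
                }
                for r in de
            ]
        )
        p = outdir / "de_liver.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        outputs["de_liver"] = p
        de_summary = {
            "n_significant": int(sum(r.significant for r in de)),
            "n_up_low_quality": int(sum(r.significant and r.log2fc > 0 for r in de)),
            "n_down_low_quality": int(
                sum(r.significant and r.log2fc < 0 for r in de)
            ),
            "rin_cutoff": cfg.rin_cutoff,
        }
    except ValidationError as e:
        log.warning("differential expression skipped: %s", e)
        de_summary = {"skipped": str(e)}
    summary["stages"]["differential_expression"] = de_summary

    # --- detected counts by annotation era (liver samples)
    if annotation is not None:
        era = detected_counts_by_era(
            tc_filt, annotation, cfg.era_bins, sample_ids=liver_ids
        )
        p = outdir / "era_counts_liver.tsv"
        era.to_csv(p, sep="\t", index_label="era", lineterminator="\n")
        outputs["era_counts_liver"] = p
        summary["stages"]["era_counts"] = {
            "total_detected_per_sample": {
                s: int(era[s].sum()) for s in era.columns
            }
        }

    # --- clustering: samples (all retained miRNAs) and top-variance view
    dend_samples = complete_linkage(euclidean_distances(tc_norm, axis="samples"))
    (outdir / "sample_dendrogram.nwk").write_text(
        dend_samples.to_newick() + "\n", encoding="utf-8"
    )
    outputs["sample_dendrogram"] = outdir / "sample_dendrogram.nwk"
    sample_cut = cut_tree(dend_samples, min(3, dend_samples.n_leaves))
    pd.DataFrame(
        sorted(sample_cut.labels.items()), columns=["sample_id", "cluster"]
    ).to_csv(outdir / "sample_clusters.tsv", sep="\t", index=False,
             lineterminator="\n")
    outputs["sample_clusters"] = outdir / "sample_clusters.tsv"
    tv = top_variance(tc_norm, min(cfg.top_variance_n, tc_norm.n_mirnas))
    write_expression_matrix(tv, outdir / "top_variance.tsv")
    outputs["top_variance"] = outdir / "top_variance.tsv"
    clustering_summary: dict = {"n_samples_clustered": dend_samples.n_leaves}

    # --- control experiment: preprocess + miRNA clustering + classification
    cls_summary: dict = {}
    homology_summary: dict = {}
    if control_path is not None and control_meta_path is not None:
        ctl_raw = _load_matrix(Path(control_path), cfg)
        ctl_meta = read_sample_metadata(control_meta_path)
        inputs += [Path(control_path), Path(control_meta_path)]
        ctl_filt = detection_filter(ctl_raw, cfg.min_detect_samples)
        ctl_norm = glog_normalize(ctl_filt)
        write_expression_matrix(ctl_norm, outdir / "control_normalized.tsv")
        outputs["control_normalized"] = outdir / "control_normalized.tsv"

        k = min(cfg.n_clusters, ctl_norm.n_mirnas)
        dend_mirnas = complete_linkage(euclidean_distances(ctl_norm, axis="mirnas"))
        assign = cut_tree(dend_mirnas, k)
        pd.DataFrame(
            sorted(assign.labels.items()), columns=["mirna_id", "cluster"]
        ).to_csv(outdir / "mirna_clusters.tsv", sep="\t", index=False,
                 lineterminator="\n")
        outputs["mirna_clusters"] = outdir / "mirna_clusters.tsv"
        clustering_summary["n_mirna_clusters"] = k
        clustering_summary["mirna_cluster_sizes"] = {
            str(lab): len(assign.members_of(lab)) for lab in range(1, k + 1)
        }
        if annotation is not None:
            ann_ids = {a.mirna_id for a in annotation}
            if set(assign.labels) <= ann_ids:
                cvs = cluster_version_summary(assign, annotation)
                p = outdir / "cluster_version_summary.tsv"
                cvs.to_csv(p, sep="\t", lineterminator="\n")
                outputs["cluster_version_summary"] = p

        evidence = build_evidence(ctl_norm, ctl_meta, timecourse=None)
        classifications = classify(
            evidence, fold_change=cfg.fold_change, annotation=annotation
        )
        rows = []
        for c in classifications:
            ev = c.evidence
            rows.append(
                {
                    "mirna_id": c.mirna_id,
                    "label": c.label,
                    "delta_degraded": (
                        "" if ev.delta_degraded is None else ev.delta_degraded
                    ),
                    "dnase_delta": (
                        "" if ev.dnase_delta is None else ev.dnase_delta
                    ),
                    "detected_depleted_degraded": ev.detected_depleted_degraded,
                    "detected_depleted_intact": ev.detected_depleted_intact,
                    "detected_intact": ev.detected_intact,
                    "first_version": (
                        "" if c.first_version is None else c.first_version
                    ),
                }
            )
        p = outdir / "classification.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False, lineterminator="\n")
        outputs["classification"] = p
        label_counts: dict[str, int] = {}
        for c in classifications:
            label_counts[c.label] = label_counts.get(c.label, 0) + 1
        cls_summary["label_counts"] = label_counts
        if annotation is not None:
            vb = version_bias_summary(classifications, cfg.era_bins)
            p = outdir / "version_bias.tsv"
            vb.to_csv(p, sep="\t", index_label="label", lineterminator="\n")
            outputs["version_bias"] = p
            cls_summary["median_version_by_label"] = vb.attrs[
                "median_version_by_label"
            ]
            cls_summary["kruskal_p"] = vb.attrs["kruskal_p"]

        # --- homology, grouped by classification label
        if transcripts_path is not None and annotation is not None:
            transcripts = read_transcripts(transcripts_path)
            inputs.append(Path(transcripts_path))
            ann_in = [a for a in annotation if a.mirna_id in set(ctl_norm.mirna_ids)]
            hits = homology_screen(
                ann_in, transcripts, cfg.homology_min_frac, cfg.homology_max_mismatch
            )
            hit_ids = {h.mirna_id for h in hits}
            p = outdir / "homology_hits.tsv"
            pd.DataFrame(
                [
                    {
                        "transcript_id": h.transcript_id,
                        "start": h.window_start,
                        "end": h.window_start + h.window_length,
                        "mirna_id": h.mirna_id,
                        "mismatches": h.mismatches,
                        "overlap_frac": h.overlap_frac,
                    }
                    for h in hits
                ],
                columns=[
                    "transcript_id",
                    "start",
                    "end",
                    "mirna_id",
                    "mismatches",
                    "overlap_frac",
                ],
            ).to_csv(p, sep="\t", index=False, lineterminator="\n")
            outputs["homology_hits"] = p
            flags = {a.mirna_id: a.mirna_id in hit_ids for a in ann_in}
            grouping = {
                c.mirna_id: c.label
                for c in classifications
                if c.mirna_id in flags
            }
            fractions = group_homology_fraction(flags, grouping)
            homology_summary = {
                "n_flagged": len(hit_ids),
                "fraction_by_label": {
                    str(kk): float(vv) for kk, vv in sorted(fractions.items())
                },
            }

    summary["stages"]["clustering"] = clustering_summary
    if cls_summary:
        summary["stages"]["classification"] = cls_summary
    if homology_summary:
        summary["stages"]["homology"] = homology_summary

    _write_json(summary, outdir / "summary.json")
    outputs["summary"] = outdir / "summary.json"
    manifest = build_manifest(
        cfg.to_dict(), inputs, [p for p in outputs.values()], cfg.seed
    )
    _write_json(manifest, outdir / "manifest.json")
    return AnalyzeResult(summary=summary, outputs=outputs)


# ---------------------------------------------------------------------------
# report


def run_report(analysis_dir, out_path=None) -> tuple[str, int]:
    """Assemble a markdown report from analyze outputs.

    Returns (report text, exit status): status 0 when every stage is present,
    2 when some stage is marked "not run".
    """
    analysis_dir = Path(analysis_dir)
    summary_path = analysis_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {analysis_dir}")
    with open(summary_path, "r", encoding="utf-8") as fh:
        summary = json.load(fh)
    stages = summary.get("stages", {})

    lines = ["# mirdegrade analysis report", ""]
    partial = False
    for stage in STAGES:
        lines.append(f"## {stage}")
        lines.append("")
        info = stages.get(stage)
        if not info:
            lines.append("*not run*")
            lines.append("")
            partial = True
            continue
        lines.extend(_render_dict(info))
        lines.append("")
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    return text, (2 if partial else 0)


def _render_dict(d: dict, indent: int = 0) -> list[str]:
    out = []
    pad = "  " * indent
    for k in sorted(d):
        v = d[k]
        if isinstance(v, dict):
            out.append(f"{pad}- **{k}**:")
            out.extend(_render_dict(v, indent + 1))
        else:
            out.append(f"{pad}- **{k}**: {v}")
    return out
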