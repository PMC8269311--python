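"""One-command reproducible run: simulate -> preprocess -> qc -> diff -> clusters -> crossmap.

A run directory contains a config snapshot, per-stage outputs, preprocess
reports and a line-oriented log, sufficient to re-run bit-identically: one
RNG stream is seeded once per run and all stochastic stages draw from it
in a fixed order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import differential, preprocess, qc
from .clusters import correlation_matrix, find_conserved_clusters, shared_panel_matrix
from .crossplatform import band_summary, cross_platform_records, records_frame, shared_metabolites
from .io import write_abundance_table, write_cluster_set, write_matrix, write_records
from .model import Constants, ValidationError
from .simulate import GeneratorConfig, cellbox_design, generate_platform, texus54_design


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "exofoot_run"
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    constants: dict = field(default_factory=dict)  # Constants overrides
    outlier_threshold: float = 0.8
    outlier_confirmations: list = field(default_factory=list)  # sample ids approved for removal
    auto_confirm_flagged: bool = False
    cluster_threshold: float = 0.8
    cluster_min_size: int = 2
    center_lo: float = 0.5
    center_hi: float = 2.0
    bar_fdr_cutoff: float = 0.5
    merge_ground_qc: bool = True

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


class RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines = []

    def log(self, stage: str, message: str) -> None:
        self.lines.append(f"[{stage}] {message}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _write_json(payload, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_all(config: RunConfig) -> Path:
    """Execute every stage, writing all intermediates into the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run.log")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    constants = Constants(**config.constants) if config.constants else Constants()

    stage = "simulate"
    try:
        gen = GeneratorConfig(seed=config.seed, **config.generator)
        from .simulate import build_truth

        truth = build_truth(gen)
        raw = {
            "TEXUS54": generate_platform(texus54_design(), truth),
            "CELLBOX": generate_platform(cellbox_design(), truth),
        }
        _write_json(truth.as_dict(), out / "truth.json")
        for plat, table in raw.items():
            write_abundance_table(
                table,
                out / f"raw_{plat}.tsv",
                out / f"meta_{plat}.tsv",
                out / f"metabolites_{plat}.tsv",
            )
            log.log(stage, f"{plat}: {table.values.shape[0]} metabolites x {table.values.shape[1]} measurements")

        stage = "preprocess"
        rma, reports = _preprocess_pair(raw, constants, log)

        stage = "qc"
        dropped = {}
        for plat in ("TEXUS54", "CELLBOX"):
            flagged = qc.flag_outlier_samples(rma[plat], threshold=config.outlier_threshold)
            for sid, score in flagged:
                log.log(stage, f"{plat}: flagged outlier candidate {sid} (max-fraction {score:.3f})")
            confirmed = {sid for sid, _ in flagged} & set(config.outlier_confirmations)
            if config.auto_confirm_flagged:
                confirmed |= {sid for sid, _ in flagged}
            if confirmed:
                dropped[plat] = sorted(confirmed)
                keep = raw[plat].measurements.index[
                    ~raw[plat].measurements["biological_sample_id"].isin(confirmed)
                ]
                raw[plat] = raw[plat].subset_measurements(keep)
                log.log(stage, f"{plat}: removed confirmed outlier sample(s) {sorted(confirmed)}")
        if dropped:
            rma, reports = _preprocess_pair(raw, constants, log, note="post-outlier")
        for plat in ("TEXUS54", "CELLBOX"):
            pca = qc.run_pca(rma[plat])
            write_matrix(pca.scores, out / f"pca_scores_{plat}.tsv", index_label="sample_id")
            hm = qc.heatmap_matrix(rma[plat])
            write_matrix(hm.values.loc[hm.row_order, hm.col_order], out / f"heatmap_{plat}.tsv")
            log.log(stage, f"{plat}: PC1 explains {pca.explained_variance_fraction[0]:.3f} of variance")
        if config.merge_ground_qc:
            tex = rma["TEXUS54"]
            merged = qc.merge_ground(tex, list(tex.group_columns("ground")), merged_id="GROUND-MEAN")
            write_matrix(qc.run_pca(merged).scores, out / "pca_scores_TEXUS54_merged_ground.tsv",
                         index_label="sample_id")

        stage = "diff"
        recs = {
            "hypg": differential.differential_records(rma["TEXUS54"], "hypg_vs_ground", "single_sample", constants),
            "ug": differential.differential_records(rma["TEXUS54"], "ug_vs_ground", "single_sample", constants),
            "long": differential.differential_records(rma["CELLBOX"], "flight_vs_ground", "two_sample", constants),
        }
        for key, table_key, contrast in (
            ("hypg", "TEXUS54", "hypg"), ("ug", "TEXUS54", "ug"), ("long", "CELLBOX", "long"),
        ):
            write_records(recs[key], out / f"differential_{key}.tsv", record_type="DifferentialRecord")
            bars = differential.bar_export(rma[table_key], recs[key], config.bar_fdr_cutoff)
            bars.to_csv(out / f"bars_{key}.tsv", sep="\t", index=False, float_format="%.12g")
            n_sig = sum(r.band != "ns" for r in recs[key])
            log.log(stage, f"{contrast}: {n_sig}/{len(recs[key])} metabolites in a significance band")

        stage = "clusters"
        shared = shared_metabolites(rma["TEXUS54"].values.index, rma["CELLBOX"].values.index)
        cm_tex = correlation_matrix(rma["TEXUS54"], cluster=False)
        cm_cb = correlation_matrix(rma["CELLBOX"], cluster=False)
        cm1 = shared_panel_matrix(cm_tex, shared)
        cm2 = shared_panel_matrix(cm_cb, shared, order_from=cm1)
        write_matrix(cm1.r, out / "correlation_TEXUS54_shared.tsv")
        write_matrix(cm2.r, out / "correlation_CELLBOX_shared.tsv")
        cluster_set = find_conserved_clusters(cm1, cm2, config.cluster_threshold, config.cluster_min_size)
        write_cluster_set(cluster_set, out / "conserved_clusters.tsv")
        log.log(stage, f"{len(shared)} shared metabolites; {len(cluster_set.clusters)} conserved cluster(s)")

        stage = "crossmap"
        xrecords = cross_platform_records(
            recs["ug"], recs["long"], recs["hypg"], cluster_set, config.center_lo, config.center_hi
        )
        write_records(xrecords, out / "crossmap.tsv", record_type="CrossPlatformRecord")
        summary_tbl = band_summary(recs["hypg"], recs["ug"], recs["long"], cluster_set, metabolites=shared)
        summary_tbl.to_csv(out / "band_summary.tsv", sep="\t", index=False, na_rep="")
        quad_counts = records_frame(xrecords)["quadrant"].value_counts().to_dict() if xrecords else {}
        log.log(stage, f"quadrant occupancy: {json.dumps(quad_counts, sort_keys=True)}")

        summary = {
            "seed": config.seed,
            "n_shared_metabolites": len(shared),
            "n_conserved_clusters": len(cluster_set.clusters),
            "dropped_outliers": dropped,
            "significant_counts": {k: int(sum(r.band != "ns" for r in v)) for k, v in recs.items()},
            "quadrant_counts": {k: int(v) for k, v in sorted(quad_counts.items())},
            "preprocess": {plat: rep.as_dict() for plat, rep in reports.items()},
        }
        _write_json(summary, out / "summary.json")
    except Exception as exc:
        log.log(stage, f"FAILED: {exc}")
        log.flush()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.flush()
    return out


def _preprocess_pair(raw, constants, log, note=""):
    rma_tex, rep_tex = preprocess.preprocess_platform(raw["TEXUS54"], constants)
    rma_cb, rep_cb = preprocess.preprocess_platform(raw["CELLBOX"], constants, reference=rma_tex)
    suffix = f" ({note})" if note else ""
    log.log(
        "preprocess",
        f"TEXUS54{suffix}: kept {rma_tex.values.shape[0]} metabolites, "
        f"removed {rep_tex.removed_unannotated} unannotated, "
        f"{len(rep_tex.filtered_missingness)} by missingness, "
        f"{len(rep_tex.removed_problematic)} problematic",
    )
    log.log(
        "preprocess",
        f"CELLBOX{suffix}: kept {rma_cb.values.shape[0]} metabolites, "
        f"removed {rep_cb.removed_unannotated} unannotated, "
        f"{len(rep_cb.filtered_missingness)} by missingness, "
        f"{len(rep_cb.removed_problematic)} problematic; scale factor {rep_cb.scale_factor:.6g}",
    )
    return {"TEXUS54": rma_tex, "CELLBOX": rma_cb}, {"TEXUS54": rep_tex, "CELLBOX": rep_cb}
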