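"""End-to-end orchestration: QC -> DM calling -> markers -> clustering -> panel.

A run is driven by a :class:`PipelineConfig` (usually loaded from YAML),
executes the stages in order and writes every result table to a run
directory, together with a manifest recording the configuration, its
hash, the seed and package version, so a rerun with the same config is
byte-identical (timestamps excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster_panel import (
    DEFAULT_PANEL_GENES,
    build_panel_matrix,
    cluster_purity,
    hierarchical_cluster,
    select_clustering_probes,
    single_locus_call,
)
from .dm_marker import call_dm, select_specific_markers, tabulate_dm
from .io_formats import (
    BetaMatrix,
    ValidationError,
    read_beta_matrix,
    read_probe_annotation,
    write_result_table,
)
from .qc_filter import QCConfig, filter_probes

__all__ = ["PipelineConfig", "run_pipeline", "report_summary"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    beta_path: str
    samplesheet_path: str
    annotation_path: str
    out_dir: str
    detection_path: str | None = None
    reference: str = "NK"
    detection_p_max: float = 0.05
    entity_sd_max: float = 0.2
    detection_scope: str = "any_sample"
    sd_ddof: int = 1
    dm_threshold: float = 0.3
    panel_genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    marker_gene: str = "THBS1"
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"
    standardize_rows: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "panel_genes" in raw:
            raw["panel_genes"] = tuple(raw["panel_genes"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"incomplete pipeline config: {exc}") from exc

    def validate_paths(self) -> None:
        paths = [self.beta_path, self.samplesheet_path, self.annotation_path]
        if self.detection_path:
            paths.append(self.detection_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"input files not found: {missing}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # the destination is not part of the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write results under ``config.out_dir``.

    Returns the run directory.  Any stage failure raises with the stage
    name attached.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    def save(table: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash={chash}\n")
            table.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")

    stage = "load"
    try:
        matrix = read_beta_matrix(
            config.beta_path,
            config.samplesheet_path,
            config.detection_path,
            reference=config.reference,
        )
        annotation = read_probe_annotation(config.annotation_path)

        stage = "qc"
        qc_config = QCConfig(
            detection_p_max=config.detection_p_max,
            entity_sd_max=config.entity_sd_max,
            detection_scope=config.detection_scope,
            sd_ddof=config.sd_ddof,
        )
        filtered, qc_report = filter_probes(matrix, annotation, qc_config)
        save(qc_report.to_frame(), "qc_probe_reasons.tsv")
        qc_summary = pd.DataFrame(
            [
                {
                    "n_input_probes": qc_report.n_input_probes,
                    "n_removed_detection": qc_report.n_removed_detection,
                    "n_removed_sd": qc_report.n_removed_sd,
                    "n_remaining_probes": qc_report.n_remaining_probes,
                    "n_remaining_genes": qc_report.n_remaining_genes,
                    "detection_scope": qc_config.detection_scope,
                    "sd_ddof": qc_config.sd_ddof,
                }
            ]
        )
        save(qc_summary, "qc_summary.tsv")

        stage = "dm_calling"
        tumors = filtered.tumor_entities
        callsets = {
            t: call_dm(filtered, annotation, t, config.reference, config.dm_threshold)
            for t in tumors
        }
        save(
            pd.concat([cs.to_frame() for cs in callsets.values()]),
            "dm_calls.tsv",
        )
        save(
            pd.concat([tabulate_dm(cs, annotation) for cs in callsets.values()]),
            "dm_counts_by_stratum.tsv",
        )

        stage = "specific_markers"
        markers = select_specific_markers(
            filtered, annotation, tumors, config.reference, config.dm_threshold
        )
        save(markers.table, "specific_markers.tsv")
        save(markers.counts(), "specific_marker_counts.tsv")

        stage = "clustering"
        probes, n_union = select_clustering_probes(callsets.values())
        union_beta = filtered.beta.loc[probes]
        gene_of = annotation["gene_symbol"]
        n_union_genes = gene_of.reindex(probes).dropna().nunique()
        dend = hierarchical_cluster(
            union_beta,
            axis="samples",
            metric=config.cluster_metric,
            method=config.cluster_linkage,
            standardize_rows=config.standardize_rows,
        )
        purity = cluster_purity(dend, filtered.entity_of)
        (out / "dm_sites_dendrogram.nwk").write_text(dend.to_newick() + "\n")

        stage = "panel"
        panel, excluded = build_panel_matrix(filtered.beta, gene_of, config.panel_genes)
        panel_out = panel.reset_index()
        save(panel_out, "panel_matrix.tsv")
        panel_dend = hierarchical_cluster(
            panel,
            axis="samples",
            metric=config.cluster_metric,
            method=config.cluster_linkage,
        )
        panel_purity = cluster_purity(
            panel_dend, filtered.entity_of.loc[panel.columns]
        )
        (out / "panel_dendrogram.nwk").write_text(panel_dend.to_newick() + "\n")
        purity_table = pd.DataFrame(
            [
                {
                    "matrix": "dm_sites",
                    "n_probes": n_union,
                    "n_genes": n_union_genes,
                    "k": purity.k,
                    "purity": purity.purity,
                },
                {
                    "matrix": "panel",
                    "n_probes": len(config.panel_genes),
                    "n_genes": len(config.panel_genes),
                    "k": panel_purity.k,
                    "purity": panel_purity.purity,
                },
            ]
        )
        save(purity_table, "cluster_purity.tsv")

        stage = "single_locus"
        marker_values = panel.loc[config.marker_gene]
        ref_samples = [
            s
            for s in panel.columns
            if filtered.entity_of[s] == config.reference
        ]
        ref_mean = float(marker_values[ref_samples].mean())
        calls = pd.DataFrame(
            {
                "sample_id": panel.columns,
                "entity": filtered.entity_of.loc[panel.columns].to_numpy(),
                "marker_value": marker_values.to_numpy(),
                "reference_mean": ref_mean,
                "call": [
                    single_locus_call(v, ref_mean, config.dm_threshold)
                    for v in marker_values
                ],
            }
        )
        save(calls, "single_locus_calls.tsv")

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "config_hash": chash,
            "seed": config.seed,
            "version": __version__,
            "excluded_panel_samples": excluded,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def report_summary(run_dir: str | Path) -> str:
    """One-page text summary of a completed run directory."""
    run_dir = Path(run_dir)
    lines = [f"run summary: {run_dir}"]
    warnings: list[str] = []

    def load(name: str) -> pd.DataFrame | None:
        path = run_dir / name
        if not path.exists():
            warnings.append(f"missing {name}")
            return None
        return pd.read_csv(path, sep="\t", comment="#")

    qc = load("qc_summary.tsv")
    if qc is not None:
        r = qc.iloc[0]
        lines.append(
            f"QC: {r.n_input_probes} probes in -> {r.n_remaining_probes} retained "
            f"({r.n_removed_detection} removed by detection p, {r.n_removed_sd} by "
            f"entity SD); {r.n_remaining_genes} genes remain"
        )
        if r.n_removed_detection == 0:
            lines.append("  note: no probes removed by detection p "
                         "(detection matrix may be absent)")
    counts = load("dm_counts_by_stratum.tsv")
    if counts is not None:
        lines.append("differential methylation (probes / genes):")
        for _, row in counts.iterrows():
            lines.append(
                f"  {row.contrast:>16} {row.stratum:>10} {row.direction:>5}: "
                f"{row.n_probes} probes ({row.n_genes} genes)"
            )
    mk = load("specific_marker_counts.tsv")
    if mk is not None:
        lines.append("group-specific marker genes:")
        for _, row in mk.iterrows():
            lines.append(
                f"  {row.group:>6}: {row.n_hyper_genes} hyper, {row.n_hypo_genes} hypo"
                + (
                    f" ({row.n_both_directions} in both directions)"
                    if row.n_both_directions
                    else ""
                )
            )
    pur = load("cluster_purity.tsv")
    if pur is not None:
        for _, row in pur.iterrows():
            lines.append(
                f"clustering [{row.matrix}]: {row.n_probes} features, "
                f"k={row.k}, purity={row.purity:.3f}"
            )
    calls = load("single_locus_calls.tsv")
    if calls is not None:
        conf = calls.groupby(["entity", "call"]).size()
        lines.append("single-locus marker calls (entity x call):")
        for (entity, call), n in conf.items():
            lines.append(f"  {entity:>6} {call}: {n}")
    if warnings:
        lines.append("warnings: " + "; ".join(warnings))
    return "\n".join(lines)
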