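"""Pipeline orchestration: configuration, stage wiring, run report.

Stages are optional and independent: whichever inputs the configuration
provides are processed, in method order — read cleaning, unigene
selection + TPM, length filter + ORF calls + assembly stats, homology
filtering / ortholog assignment / interaction transfer, topology, null
models.  Every run writes a JSON report with the effective configuration,
package version, per-stage outputs and content checksums; identical
configuration and inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from . import homology, nullmodels, topology, unigenes

log = logging.getLogger("interolog")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run.

    Thresholds default to the homology-transfer values: E-value < 1e-6,
    identity > 50%, query coverage > 80%, unigene length > 300 bp, read
    N-fraction <= 5%.
    """

    out_dir: str = "interolog_out"
    # inputs (all optional; a stage runs iff its inputs are present)
    reads_fastq: str | None = None
    isoform_table: str | None = None
    unigenes_fasta: str | None = None
    hit_tables: dict = field(default_factory=dict)  # species -> path
    edge_tables: dict = field(default_factory=dict)  # species -> path
    unigene_edges: str | None = None  # precomputed network, topology-only runs
    ground_truth: str | None = None  # JSON sidecar for recovery checks
    # thresholds
    evalue_max: float = 1e-6
    identity_min: float = 50.0
    coverage_min: float = 80.0
    min_edge_score: float = 0.0
    min_unigene_length: int = 300
    max_unknown_fraction: float = 0.05
    adapters: list = field(
        default_factory=lambda: [unigenes.READ1_ADAPTER, unigenes.READ2_ADAPTER]
    )
    # null models
    null_replicates: int = 3
    p_rewire: float = 0.1
    seed: int = 0
    threads: int = 1  # accepted for interface symmetry; results never depend on it

    def __post_init__(self):
        if not 0 <= self.max_unknown_fraction <= 1:
            raise ValueError("max_unknown_fraction must be in [0, 1]")
        if self.null_replicates < 1:
            raise ValueError("null_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key not in ("hit_tables", "edge_tables"):
                flat.update(val)  # sectioned layout: flatten one level
            else:
                flat[key] = val
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()

    def register(name: str, path: Path):
        report["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 3)}

    # -- read cleaning ------------------------------------------------------
    if config.reads_fastq:
        stage("clean_reads")
        try:
            with open(config.reads_fastq) as fh:
                reads = list(unigenes.parse_fastq(fh))
            kept, rep = unigenes.clean_reads(
                reads,
                adapters=config.adapters,
                max_unknown_fraction=config.max_unknown_fraction,
            )
        except ValueError as exc:
            raise RuntimeError(f"[clean_reads] {exc}") from exc
        p = out / "clean_reads.fastq"
        with open(p, "w") as fh:
            SeqIO.write(kept, fh, "fastq")
        register("clean_reads.fastq", p)
        report["stages"]["clean_reads"].update(
            total=rep.total, kept=rep.kept, dropped_n=rep.dropped_n,
            trimmed=rep.trimmed,
        )

    # -- unigene selection + TPM -------------------------------------------
    if config.isoform_table:
        stage("select_unigenes")
        try:
            iso = unigenes.read_isoform_table(config.isoform_table)
            chosen = unigenes.select_unigenes(iso)
            tpm = unigenes.compute_tpm(iso) if "expected_count" in iso.columns else None
        except ValueError as exc:
            raise RuntimeError(f"[select_unigenes] {exc}") from exc
        p = out / "unigene_selection.tsv"
        pd.DataFrame(
            sorted(chosen.items()), columns=["gene_id", "transcript_id"]
        ).to_csv(p, sep="\t", index=False)
        register("unigene_selection.tsv", p)
        if tpm is not None:
            p = out / "tpm.tsv"
            tpm.rename_axis("transcript_id").round(6).to_csv(p, sep="\t")
            register("tpm.tsv", p)
        report["stages"]["select_unigenes"]["n_genes"] = len(chosen)

    # -- unigene FASTA: length filter, ORFs, assembly stats ----------------
    if config.unigenes_fasta:
        stage("orfs")
        seqs = list(SeqIO.parse(config.unigenes_fasta, "fasta"))
        if not seqs:
            raise RuntimeError("[orfs] unigene FASTA contains no sequences")
        stats = unigenes.assembly_stats([len(r.seq) for r in seqs])
        retained = unigenes.filter_by_length(seqs, config.min_unigene_length)
        calls = [unigenes.find_longest_orf(str(r.seq), r.id) for r in retained]
        p = out / "orfs.tsv"
        pd.DataFrame(
            {
                "unigene_id": [c.unigene_id for c in calls],
                "found": [c.found for c in calls],
                "strand": [c.strand for c in calls],
                "frame": [c.frame for c in calls],
                "start": [c.start for c in calls],
                "end": [c.end for c in calls],
                "has_stop": [c.has_stop for c in calls],
                "protein": [c.protein for c in calls],
            }
        ).to_csv(p, sep="\t", index=False)
        register("orfs.tsv", p)
        p = out / "assembly_stats.tsv"
        pd.DataFrame([asdict(stats)]).to_csv(p, sep="\t", index=False)
        register("assembly_stats.tsv", p)
        report["stages"]["orfs"].update(
            n_input=len(seqs), n_retained=len(retained),
            n50=stats.n50, mean_length=stats.mean_length,
        )

    # -- homology transfer ---------------------------------------------------
    edges = None
    if config.hit_tables and config.edge_tables:
        stage("homology_transfer")
        assignments = []
        ref_edges = {}
        for species, path in sorted(config.hit_tables.items()):
            hits = homology.read_blast_tab(path)
            filtered = homology.filter_hits(
                hits,
                evalue_max=config.evalue_max,
                identity_min=config.identity_min,
                coverage_min=config.coverage_min,
            )
            assignments.append(homology.assign_orthologs(filtered, species))
        for species, path in sorted(config.edge_tables.items()):
            ref_edges[species] = homology.read_reference_edges(path)
        edges = homology.transfer_interactions(
            assignments, ref_edges, min_score=config.min_edge_score
        )
        p = out / "unigene_edges.tsv"
        homology.write_edge_set_tsv(edges, p)
        register("unigene_edges.tsv", p)
        p = out / "ortholog_assignments.tsv"
        homology.write_assignment_tsv(assignments, p)
        register("ortholog_assignments.tsv", p)
        report["stages"]["homology_transfer"].update(
            n_species=len(assignments),
            n_assigned=sum(len(a.mapping) for a in assignments),
            n_edges=len(edges),
        )
        if config.ground_truth:
            with open(config.ground_truth) as fh:
                truth = json.load(fh)
            expected = {tuple(sorted(e)) for e in truth["expected_edges"]}
            report["exact_recovery"] = edges == expected
            report["stages"]["homology_transfer"]["expected_edges"] = len(expected)

    # -- topology + null models ---------------------------------------------
    g = None
    if edges is not None:
        g = topology.graph_from_edges(edges)
    elif config.unigene_edges:
        g = topology.read_edge_tsv(config.unigene_edges)
    if g is not None and g.number_of_nodes() > 0:
        stage("topology")
        summary = topology.topology_summary(g)
        p = out / "topology_summary.json"
        p.write_text(summary.to_json())
        register("topology_summary.json", p)
        p = out / "degree_distribution.tsv"
        summary.degree_dist.to_frame().to_csv(p, sep="\t", index=False)
        register("degree_distribution.tsv", p)
        for name, curve in (
            ("knn_curve.tsv", summary.knn_curve),
            ("clustering_curve.tsv", summary.clustering_curve),
        ):
            p = out / name
            pd.DataFrame(
                sorted(curve.items()), columns=["degree", "value"]
            ).to_csv(p, sep="\t", index=False)
            register(name, p)
        report["stages"]["topology"].update(
            n_components=summary.n_components,
            giant_nodes=summary.giant_nodes,
            giant_edges=summary.giant_edges,
            clustering=summary.clustering,
            avg_shortest_path=summary.avg_path_length,
        )

        stage("null_models")
        rows = nullmodels.null_model_table(
            g,
            replicates=config.null_replicates,
            seed=config.seed,
            p_rewire=config.p_rewire,
        )
        p = out / "null_models.tsv"
        nullmodels.null_table_frame(rows).to_csv(p, sep="\t", index=False)
        register("null_models.tsv", p)

    report["runtime_s"] = round(time.time() - t0, 3)
    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
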