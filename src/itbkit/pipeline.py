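"""End-to-end orchestration: load -> align -> filter -> identities/motifs ->
distances -> NJ -> bootstrap -> root -> family groups -> pairing analysis.

All outputs are plain text (TSV / Newick / JSON) so that identical
configuration and seed reproduce byte-identical result files; the run
manifest records parameters, the seed and a checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import alignment as al
from . import pairing as pr
from . import phylo as ph
from .motifs import scan_cyto_motifs
from .records import read_fasta, read_metadata_tsv
from .tree import root_with_outgroup, write_newick

logger = logging.getLogger("itbkit")


@dataclass
class PipelineConfig:
    """Inputs and parameters for a full analysis run.

    Sequence inputs may be omitted (``fasta=None``), in which case the
    phylogenetic stages are skipped and only the pairing analysis runs; the
    pairing table may likewise be omitted.  ``aligned`` declares that the
    FASTA rows are already aligned (gapped) and the progressive aligner
    should not run.
    """

    fasta: str | None = None
    metadata: str | None = None
    pairing_table: str | None = None  # None -> packaged fixture
    aligned: bool = False
    max_gap_fraction: float = 0.0
    bootstrap: int = 100
    support_threshold: int = 90
    outgroup: str | None = None
    root_beta: str = "4"
    seed: int = 0
    outdir: str = "itbkit_out"

    def __post_init__(self) -> None:
        if self.bootstrap < 1:
            raise ValueError("bootstrap replicate count must be >= 1")
        if not (0 <= self.support_threshold <= 100):
            raise ValueError("support threshold must be in [0, 100]")
        if not (0.0 <= self.max_gap_fraction <= 1.0):
            raise ValueError("max_gap_fraction must be in [0, 1]")


@dataclass
class RunReport:
    """In-memory results of a pipeline run, mirrored to files in ``outdir``."""

    config: PipelineConfig
    identity_summary: dict | None = None
    motif_hits: list = field(default_factory=list)
    distance_matrix: ph.DistanceMatrix | None = None
    tree_newick: str | None = None
    family_partition: ph.FamilyPartition | None = None
    ligand_counts: dict[str, int] | None = None
    alpha_counts: dict[str, int] | None = None
    path_hypothesis: pr.EvolutionaryPathHypothesis | None = None
    skipped: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(outdir: Path, name: str, text: str, manifest: dict) -> None:
    path = outdir / name
    path.write_text(text)
    manifest["outputs"][name] = _sha256(path)


def run_full_analysis(cfg: PipelineConfig, msa: al.MultipleAlignment | None = None) -> RunReport:
    """Run every stage the configuration enables and write the report.

    ``msa`` may be passed directly (e.g. from the simulator), bypassing
    FASTA loading.  Any stage failure raises with the stage name prefixed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg)
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "max_gap_fraction": cfg.max_gap_fraction,
            "bootstrap": cfg.bootstrap,
            "support_threshold": cfg.support_threshold,
            "outgroup": cfg.outgroup,
            "root_beta": cfg.root_beta,
        },
        "outputs": {},
    }
    report.manifest = manifest

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is None:
                    logger.info("stage %-16s ok     %.2fs", name, dt)
                else:
                    logger.error("stage %-16s FAILED %.2fs: %s", name, dt, exc)
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    # ---- sequence stages -------------------------------------------------
    if msa is None and cfg.fasta:
        with stage("load"):
            metadata = read_metadata_tsv(cfg.metadata) if cfg.metadata else {}
            if cfg.aligned:
                msa = al.read_aligned_fasta(cfg.fasta, metadata)
            else:
                records = read_fasta(cfg.fasta, metadata)
                with stage("align"):
                    msa = al.progressive_align(records)

    if msa is not None:
        with stage("filter_columns"):
            filtered = al.exclude_ambiguous_columns(msa, cfg.max_gap_fraction)
            al.write_aligned_fasta(filtered, outdir / "alignment.filtered.fasta")
            manifest["outputs"]["alignment.filtered.fasta"] = _sha256(
                outdir / "alignment.filtered.fasta"
            )

        with stage("identities_motifs"):
            if filtered.n_rows >= 2:
                report.identity_summary = al.family_identity_summary(filtered)
            hits = []
            for rec in msa.records:
                hits.extend(scan_cyto_motifs(rec.sequence, rec.id))
            report.motif_hits = hits
            lines = ["record_id\tmotif_class\tstart\tmatched_text"]
            for h in hits:
                lines.append(f"{h.record_id}\t{h.motif_class}\t{h.start}\t{h.matched_text}")
            _write(outdir, "motif_hits.tsv", "\n".join(lines) + "\n", manifest)

        with stage("distances"):
            dm = ph.kimura_distance_matrix(filtered)
            report.distance_matrix = dm
            _write(outdir, "distances.tsv", dm.to_tsv(), manifest)
            _write(outdir, "distances.phylip", dm.to_phylip(), manifest)

        with stage("bootstrap_nj"):
            tree = ph.bootstrap_support(filtered, cfg.bootstrap, cfg.seed)

        if cfg.outgroup:
            with stage("root"):
                tree = root_with_outgroup(tree, cfg.outgroup)
            with stage("family_groups"):
                labels = {
                    rec.id: rec.family for rec in msa.records if rec.family is not None
                }
                if len(labels) == len(msa.records):
                    report.family_partition = ph.family_groups(
                        tree, labels, cfg.support_threshold
                    )
                else:
                    report.skipped.append("family_groups")
        else:
            report.skipped.extend(["root", "family_groups"])

        report.tree_newick = write_newick(tree)
        _write(outdir, "tree.nwk", report.tree_newick + "\n", manifest)
    else:
        report.skipped.extend(
            ["load", "align", "filter_columns", "identities_motifs", "distances",
             "bootstrap_nj", "root", "family_groups"]
        )

    # ---- pairing stages --------------------------------------------------
    with stage("pairing"):
        table = pr.load_pairing_table(cfg.pairing_table)
        report.ligand_counts = pr.ligand_count_per_beta(table)
        report.alpha_counts = pr.alpha_partner_count(table)
        graph = pr.shared_alpha_graph(table)
        _write(outdir, "shared_alpha_graph.tsv", graph.to_edge_tsv(), manifest)
        fallback = None
        if report.family_partition is not None:
            # Phylogenetic groups (family labels ITB<n> -> beta token n).
            fallback = [
                {fam.removeprefix("ITB") for fam in group}
                for group in report.family_partition.groups
            ]
        elif "2" in graph.nodes:
            fallback = [{"2", "7"}]
        hypothesis = pr.infer_evolutionary_paths(graph, cfg.root_beta, fallback)
        report.path_hypothesis = hypothesis
        _write(outdir, "evolutionary_paths.tsv", hypothesis.to_tsv(), manifest)
        _write(outdir, "evolutionary_paths.dot", hypothesis.to_dot(), manifest)

    # ---- summary ---------------------------------------------------------
    with stage("report"):
        summary = {
            "skipped": sorted(report.skipped),
            "identity_summary": report.identity_summary,
            "n_motif_hits": len(report.motif_hits),
            "family_groups": (
                report.family_partition.as_sorted_sets()
                if report.family_partition
                else None
            ),
            "ligand_counts": report.ligand_counts,
            "alpha_counts": report.alpha_counts,
            "path_edges": (
                list(report.path_hypothesis.edges) if report.path_hypothesis else None
            ),
        }
        _write(
            outdir,
            "summary.json",
            json.dumps(summary, indent=2, sort_keys=True) + "\n",
            manifest,
        )
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return report
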