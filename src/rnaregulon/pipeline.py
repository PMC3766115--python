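"""End-to-end orchestration of the regulon reconstruction stages.

import -> operons -> site assignment -> CRON clustering (+ operon
extension) -> T-box specificity split -> functional classification ->
statistics.  Stages communicate through plain data objects and every
stage output is written as TSV/JSON, so any stage can be rerun or
swapped.  A run manifest records parameter values and input checksums;
outputs are a pure function of inputs plus configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .assignment import AssignmentResult, assign_sites, build_regulons, deduplicate_hits
from .classify import assign_categories, category_counts
from .crons import accept_crons, assemble_regulogs, build_crons, extend_operons
from .model import Cron, Genome, Regulog
from .operons import infer_operons
from .stats import (
    DistributionMatrix,
    lineage_stats,
    lineage_totals_from_regulogs,
    motif_stats,
    ofc_proportions,
    tandem_stats,
)
from .tbox import call_specificity, read_alignment, split_tbox_regulogs

logger = logging.getLogger(__name__)


@dataclass
class AnnotationInput:
    path: str
    genome_id: str
    taxgroup_id: str
    format: str = "tsv"


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run.

    Defaults follow the reconstruction conventions: 200 nt operon gap,
    site window 500 nt upstream to 100 nt downstream of the start
    codon, CRON acceptance at conservation 0.5 in at least two genomes,
    operon extension capped at 300 nt.
    """

    annotations: list[AnnotationInput]
    sites_path: str
    orthology_path: str
    registry_path: str
    functional_map_path: str
    outdir: str
    tbox_alignment_path: str = ""
    tbox_reference_id: str = ""
    tbox_codon_span: tuple[int, int, int] = (0, 0, 0)
    tbox_alignment_format: str = "fasta"
    max_gap: int = 200
    merge_overlaps: bool = True
    upstream: int = 500
    downstream: int = 100
    min_conservation: float = 0.5
    min_genomes: int = 2
    extension_cap: int = 300
    merge_jaccard: float = 0.5


@dataclass
class PipelineResult:
    genomes: dict[str, Genome] = field(default_factory=dict)
    operons: dict[str, list] = field(default_factory=dict)
    assignment: AssignmentResult = field(default_factory=AssignmentResult)
    crons: list[Cron] = field(default_factory=list)
    regulogs: list[Regulog] = field(default_factory=list)
    specificity_calls: list = field(default_factory=list)
    unassigned_tbox_sites: list[str] = field(default_factory=list)
    category_assignments: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the report bundle to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    # --- import -----------------------------------------------------------
    registry = rio.read_registry(config.registry_path)
    fmap = rio.read_functional_map(config.functional_map_path)
    for ann in config.annotations:
        genome = rio.read_annotations(
            ann.path,
            format=ann.format,
            genome_id=ann.genome_id,
            taxgroup_id=ann.taxgroup_id,
        )
        result.genomes[genome.genome_id] = genome
    orthology = rio.read_orthology(config.orthology_path, genomes=result.genomes)
    sites = rio.read_sites(config.sites_path, registry)

    # --- operons ----------------------------------------------------------
    for genome_id, genome in result.genomes.items():
        result.operons[genome_id] = infer_operons(
            genome, max_gap=config.max_gap, merge_overlaps=config.merge_overlaps
        )
    _write_operons(result, outdir / "operons.tsv")

    # --- assignment -------------------------------------------------------
    deduped = deduplicate_hits(sites)
    merged = AssignmentResult()
    for genome_id, genome in result.genomes.items():
        genome_sites = [s for s in deduped if s.genome_id == genome_id]
        part = assign_sites(
            genome_sites,
            result.operons[genome_id],
            upstream=config.upstream,
            downstream=config.downstream,
        )
        merged.regulated_operons.extend(part.regulated_operons)
        merged.ambiguous.extend(part.ambiguous)
        merged.orphans.extend(part.orphans)
    result.assignment = merged
    _write_assignments(merged, outdir / "assignments.tsv")
    rio.write_sites(merged.orphans, outdir / "orphan_sites.tsv")

    # --- CRON clustering --------------------------------------------------
    regulons = build_regulons(merged.regulated_operons)
    taxgroup_of = {g.genome_id: g.taxgroup_id for g in result.genomes.values()}
    by_cell: dict[tuple[str, str], list] = defaultdict(list)
    for regulon in regulons:
        by_cell[(regulon.motif_id, taxgroup_of[regulon.genome_id])].append(regulon)
    genomes_by_tax: dict[str, list[Genome]] = defaultdict(list)
    for genome in result.genomes.values():
        genomes_by_tax[genome.taxgroup_id].append(genome)

    extension_log: list[str] = []
    for (motif_id, taxgroup_id), cell_regulons in sorted(by_cell.items()):
        crons = build_crons(
            cell_regulons, orthology, taxgroup_id, merge_jaccard=config.merge_jaccard
        )
        accept_crons(
            crons,
            genomes_by_tax[taxgroup_id],
            orthology,
            registry=registry,
            min_conservation=config.min_conservation,
            min_genomes=config.min_genomes,
        )
        for cron in crons:
            if cron.accepted:
                extension_log += extend_operons(
                    cron,
                    result.genomes,
                    orthology,
                    extension_cap=config.extension_cap,
                )
        result.crons.extend(crons)
    _write_crons(result.crons, outdir / "crons.tsv")
    (outdir / "extension_log.txt").write_text("\n".join(extension_log) + "\n")

    regulogs = assemble_regulogs(result.crons)

    # --- T-box specificity ------------------------------------------------
    if config.tbox_alignment_path:
        alignment = read_alignment(
            config.tbox_alignment_path,
            reference_id=config.tbox_reference_id,
            reference_codon_span=config.tbox_codon_span,
            format=config.tbox_alignment_format,
        )
        calls = call_specificity(alignment)
        result.specificity_calls = calls
        _write_calls(calls, outdir / "tbox_calls.tsv")
        tbox_motifs = {m.motif_id for m in registry if m.motif_class == "tbox"}
        lineage_tbox = [r for r in regulogs if r.motif_id in tbox_motifs]
        others = [r for r in regulogs if r.motif_id not in tbox_motifs]
        specific, unassigned = split_tbox_regulogs(lineage_tbox, calls)
        result.unassigned_tbox_sites = unassigned
        regulogs = others + specific
    result.regulogs = regulogs
    _write_regulogs(regulogs, outdir / "regulogs.tsv")

    # --- classification ---------------------------------------------------
    assignments = assign_categories(regulogs, fmap)
    result.category_assignments = assignments
    sfc_counts = category_counts(assignments, level="SFC")
    _write_counts(sfc_counts, outdir / "sfc_counts.tsv", "sfc")
    ofc_counts = category_counts(assignments, level="OFC")
    _write_counts(ofc_counts, outdir / "ofc_counts.tsv", "ofc")

    # --- statistics -------------------------------------------------------
    genomes_per_tax = {
        tax: len(gs) for tax, gs in genomes_by_tax.items()
    }
    totals = lineage_totals_from_regulogs(regulogs, genomes_per_tax)
    table2 = lineage_stats(totals)
    table2.to_csv(outdir / "lineage_stats.tsv", sep="\t", index=False)
    per_motif = motif_stats(regulogs)
    per_motif.to_csv(outdir / "motif_stats.tsv", sep="\t", index=False)
    matrix = DistributionMatrix.from_regulogs(
        regulogs, registry, list(genomes_per_tax)
    )
    matrix.presence.to_csv(outdir / "distribution_matrix.tsv", sep="\t")
    proportions = ofc_proportions(sfc_counts, fmap, scope="motif")

    tandem_by_motif = {}
    ros_by_motif = defaultdict(list)
    for ro in merged.regulated_operons:
        ros_by_motif[ro.motif_id].append(ro)
    for motif_id, ros in sorted(ros_by_motif.items()):
        frac, mean_size = tandem_stats(ros)
        tandem_by_motif[motif_id] = {
            "tandem_fraction": frac,
            "mean_operon_size": mean_size,
        }

    result.summary = {
        "n_genomes": len(result.genomes),
        "n_sites_input": len(sites),
        "n_sites_deduplicated": len(deduped),
        "n_sites_assigned": merged.assigned_site_count,
        "n_sites_ambiguous": len(merged.ambiguous),
        "n_sites_orphan": len(merged.orphans),
        "n_regulated_operons": len(merged.regulated_operons),
        "n_crons": len(result.crons),
        "n_crons_accepted": sum(1 for c in result.crons if c.accepted),
        "n_regulogs": len(regulogs),
        "total_regulated_genes": sum(r.total_genes for r in regulogs),
        "distribution_groups": matrix.groups,
        "ofc_proportions_by_motif": proportions,
        "tandem_stats_by_motif": tandem_by_motif,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    _write_manifest(config, outdir / "run_manifest.json")
    return result


def run_from_bundle(bundle_dir: str | Path, outdir: str | Path, **overrides) -> PipelineResult:
    """Run the full pipeline on a simulator-emitted bundle directory."""
    bundle_dir = Path(bundle_dir)
    manifest = pd.read_csv(bundle_dir / "genomes.tsv", sep="\t", dtype=str)
    annotations = [
        AnnotationInput(
            path=str(bundle_dir / row.path),
            genome_id=row.genome_id,
            taxgroup_id=row.taxgroup_id,
            format=row.format,
        )
        for row in manifest.itertuples(index=False)
    ]
    kwargs = dict(
        annotations=annotations,
        sites_path=str(bundle_dir / "sites.tsv"),
        orthology_path=str(bundle_dir / "orthology.tsv"),
        registry_path=str(bundle_dir / "registry.tsv"),
        functional_map_path=str(bundle_dir / "functional_map.tsv"),
        outdir=str(outdir),
    )
    alignment_path = bundle_dir / "tbox_alignment.afa"
    truth_path = bundle_dir / "ground_truth.json"
    if alignment_path.exists() and truth_path.exists():
        with open(truth_path) as fh:
            ref = json.load(fh).get("tbox_reference")
        if ref:
            kwargs.update(
                tbox_alignment_path=str(alignment_path),
                tbox_reference_id=ref["reference_id"],
                tbox_codon_span=tuple(ref["codon_span"]),
                tbox_alignment_format="fasta",
            )
    kwargs.update(overrides)
    return run_pipeline(RunConfig(**kwargs))


# ---------------------------------------------------------------------------
# recovery scoring against a ground-truth manifest


def evaluate_recovery(result: PipelineResult, ground_truth: dict) -> dict:
    """Precision/recall of regulated-operon recovery.

    An operon is identified by ``(genome_id, motif_id, leader gene)``.
    A planted operon is recovered when an accepted CRON contains a
    regulated operon with the same key; predicted operons outside the
    ground truth count against precision.
    """
    truth_keys = set()
    for reg in ground_truth["planted_regulons"]:
        for genome_id, gene_ids in reg["operons"].items():
            truth_keys.add((genome_id, reg["motif_id"], gene_ids[0]))
    predicted = set()
    for cron in result.crons:
        if not cron.accepted:
            continue
        for ro in cron.operons:
            predicted.add(
                (ro.genome_id, ro.motif_id, ro.operon.leader_anchor.gene_id)
            )
    tp = len(predicted & truth_keys)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth_keys) if truth_keys else float("nan")
    return {
        "true_positives": tp,
        "predicted": len(predicted),
        "planted": len(truth_keys),
        "precision": precision,
        "recall": recall,
    }


# ---------------------------------------------------------------------------
# writers


def _write_operons(result: PipelineResult, path: Path) -> None:
    rows = []
    for genome_id in sorted(result.operons):
        for op in result.operons[genome_id]:
            rows.append(
                {
                    "operon_id": op.operon_id,
                    "genome_id": op.genome_id,
                    "contig": op.contig_id,
                    "strand": op.strand,
                    "genes": ",".join(g.gene_id for g in op.genes),
                }
            )
    pd.DataFrame(
        rows, columns=["operon_id", "genome_id", "contig", "strand", "genes"]
    ).to_csv(path, sep="\t", index=False)


def _write_assignments(assignment: AssignmentResult, path: Path) -> None:
    rows = [
        {
            "motif_id": ro.motif_id,
            "genome_id": ro.genome_id,
            "operon_id": ro.operon.operon_id,
            "site_ids": ",".join(s.site_id for s in ro.sites),
            "tandem": ro.tandem,
            "distance_to_start": ro.site_to_start_distance,
        }
        for ro in assignment.regulated_operons
    ]
    pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "genome_id",
            "operon_id",
            "site_ids",
            "tandem",
            "distance_to_start",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_crons(crons: list[Cron], path: Path) -> None:
    rows = []
    for cron in crons:
        members = ";".join(
            f"{gid}:" + ",".join(ro.operon.operon_id for ro in ros)
            for gid, ros in sorted(cron.members.items())
        )
        rows.append(
            {
                "cron_id": cron.cron_id,
                "motif_id": cron.motif_id,
                "taxgroup": cron.taxgroup_id,
                "anchor_group": cron.anchor_group,
                "conservation": round(cron.conservation, 4),
                "accepted": cron.accepted,
                "reject_reason": cron.reject_reason,
                "members": members,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "cron_id",
            "motif_id",
            "taxgroup",
            "anchor_group",
            "conservation",
            "accepted",
            "reject_reason",
            "members",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_regulogs(regulogs: list[Regulog], path: Path) -> None:
    rows = []
    for r in regulogs:
        by_genome: dict[str, list[str]] = defaultdict(list)
        for ro in r.regulated_operons:
            by_genome[ro.genome_id].append("-".join(g.gene_id for g in ro.operon.genes))
        for genome_id, operon_strings in sorted(by_genome.items()):
            rows.append(
                {
                    "motif_id": r.motif_id,
                    "taxgroup": r.taxgroup_id,
                    "specificity": r.specificity_group,
                    "genome_id": genome_id,
                    "operons": ";".join(operon_strings),
                }
            )
    pd.DataFrame(
        rows, columns=["motif_id", "taxgroup", "specificity", "genome_id", "operons"]
    ).to_csv(path, sep="\t", index=False)


def _write_calls(calls, path: Path) -> None:
    rows = [
        {
            "site_id": c.site_id,
            "codon": c.codon,
            "amino_acid": c.amino_acid,
            "specificity_group": c.specificity_group,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["site_id", "codon", "amino_acid", "specificity_group"]
    ).to_csv(path, sep="\t", index=False)


def _write_counts(counts: dict, path: Path, level: str) -> None:
    rows = []
    for (motif_id, taxgroup_id), counter in sorted(counts.items()):
        for category, n in sorted(counter.items()):
            rows.append(
                {
                    "motif_id": motif_id,
                    "taxgroup": taxgroup_id,
                    level: category,
                    "genes": n,
                }
            )
    pd.DataFrame(rows, columns=["motif_id", "taxgroup", level, "genes"]).to_csv(
        path, sep="\t", index=False
    )


def _write_manifest(config: RunConfig, path: Path) -> None:
    params = {
        "max_gap": config.max_gap,
        "merge_overlaps": config.merge_overlaps,
        "upstream": config.upstream,
        "downstream": config.downstream,
        "min_conservation": config.min_conservation,
        "min_genomes": config.min_genomes,
        "extension_cap": config.extension_cap,
        "merge_jaccard": config.merge_jaccard,
    }
    checksums = {}
    inputs = [config.sites_path, config.orthology_path, config.registry_path,
              config.functional_map_path] + [a.path for a in config.annotations]
    if config.tbox_alignment_path:
        inputs.append(config.tbox_alignment_path)
    for p in inputs:
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        checksums[Path(p).name] = digest
    with open(path, "w") as fh:
        json.dump(
            {"parameters": params, "input_sha256": checksums}, fh, indent=1,
            sort_keys=True,
        )
        fh.write("\n")
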