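"""Cross-genome clustering of regulated operons into CRONs.

Within one taxonomic group and one motif family, regulated operons from
different genomes are clustered into CRONs (Clusters of co-Regulated
Orthologous operoNs).  Clustering is anchor-first: operons whose leader
genes fall in the same ortholog group seed one cluster; clusters whose
member operons share most of their gene content (Jaccard index of their
ortholog-group sets >= 0.5) are then merged as connected components.

Each CRON is scored by regulatory conservation — the fraction of
anchor-bearing genomes in the group that carry a regulated member — and
accepted or rejected on configurable thresholds, with a rescue path for
high-confidence sites in sparsely sampled lineages.  Accepted CRONs can
have their operons extended downstream where orthology across the other
members supports a longer transcription unit, and are finally assembled
into per-(motif, lineage) regulogs.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict

import networkx as nx

from .model import (
    Cron,
    Genome,
    MotifRegistry,
    OrthologyMap,
    RegulatedOperon,
    Regulog,
    Regulon,
)
from .operons import intergenic_gap

logger = logging.getLogger(__name__)

UNASSIGNED_PREFIX = "unassigned:"


def _leader_group(ro: RegulatedOperon, orthology: OrthologyMap) -> str:
    leader = ro.operon.leader_anchor
    group = orthology.group_of(ro.genome_id, leader.gene_id)
    return group if group is not None else f"{UNASSIGNED_PREFIX}{leader.gene_id}"


def _og_set(ros: list[RegulatedOperon], orthology: OrthologyMap) -> set[str]:
    """Union of ortholog groups over all genes of the member operons."""
    out: set[str] = set()
    for ro in ros:
        for gene in ro.operon.genes:
            g = orthology.group_of(ro.genome_id, gene.gene_id)
            if g is not None:
                out.add(g)
    return out


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def build_crons(
    regulons: list[Regulon],
    orthology: OrthologyMap,
    taxgroup_id: str,
    merge_jaccard: float = 0.5,
) -> list[Cron]:
    """Cluster one motif family's regulated operons across a lineage.

    ``regulons`` must all carry the same motif family.  Operons with an
    orthology-unmapped leader seed singleton clusters anchored at
    ``unassigned:<gene_id>``.
    """
    motifs = {r.motif_id for r in regulons}
    if len(motifs) > 1:
        raise ValueError(f"build_crons received multiple motif families: {motifs}")
    if not regulons:
        return []
    motif_id = motifs.pop()

    seeds: dict[str, list[RegulatedOperon]] = defaultdict(list)
    for regulon in regulons:
        for ro in regulon.regulated_operons:
            seeds[_leader_group(ro, orthology)].append(ro)

    anchors = sorted(seeds)
    graph = nx.Graph()
    graph.add_nodes_from(anchors)
    content = {a: _og_set(seeds[a], orthology) for a in anchors}
    for a, b in itertools.combinations(anchors, 2):
        if jaccard(content[a], content[b]) >= merge_jaccard:
            graph.add_edge(a, b)

    crons: list[Cron] = []
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for i, component in enumerate(components, start=1):
        members: dict[str, list[RegulatedOperon]] = defaultdict(list)
        anchor_votes: list[str] = []
        for anchor in sorted(component):
            for ro in seeds[anchor]:
                members[ro.genome_id].append(ro)
                anchor_votes.append(anchor)
        # primary anchor: the most common leader group, ties lexicographic
        counts = defaultdict(int)
        for a in anchor_votes:
            counts[a] += 1
        anchor = min(counts, key=lambda a: (-counts[a], a))
        crons.append(
            Cron(
                cron_id=f"{motif_id}:{taxgroup_id}:cron{i}",
                motif_id=motif_id,
                taxgroup_id=taxgroup_id,
                anchor_group=anchor,
                members=dict(members),
            )
        )
    return crons


def score_conservation(
    cron: Cron, taxgroup_genomes: list[Genome], orthology: OrthologyMap
) -> float:
    """Regulated-genome count over anchor-bearing genome count.

    The denominator counts only genomes of the lineage that possess at
    least one gene of the anchor ortholog group, so gene absence
    (e.g. auxotrophy) does not penalise regulatory conservation.
    """
    if cron.anchor_group.startswith(UNASSIGNED_PREFIX):
        bearing = cron.regulated_genomes
    else:
        lineage = {g.genome_id for g in taxgroup_genomes}
        bearing = orthology.genomes_with_group(cron.anchor_group) & lineage
        # regulated genomes always count as anchor-bearing
        bearing |= cron.regulated_genomes
    if not bearing:
        logger.warning("CRON %s: no anchor-bearing genomes", cron.cron_id)
        return 0.0
    return len(cron.regulated_genomes) / len(bearing)


def accept_crons(
    crons: list[Cron],
    taxgroup_genomes: list[Genome],
    orthology: OrthologyMap,
    registry: MotifRegistry | None = None,
    min_conservation: float = 0.5,
    min_genomes: int = 2,
) -> list[Cron]:
    """Score and flag CRONs for inclusion in the final regulon models.

    Accepted iff conservation >= ``min_conservation`` and the CRON is
    regulated in >= ``min_genomes`` genomes, OR (rescue path) the CRON
    is regulated in a single genome whose best site score exceeds the
    motif family's configured high-confidence threshold.
    """
    for cron in crons:
        cron.conservation = score_conservation(cron, taxgroup_genomes, orthology)
        n_reg = len(cron.regulated_genomes)
        if cron.conservation >= min_conservation and n_reg >= min_genomes:
            cron.accepted = True
            cron.reject_reason = ""
            continue
        rescue = False
        if n_reg == 1 and registry is not None and cron.motif_id in registry:
            best = max(s.score for ro in cron.operons for s in ro.sites)
            rescue = best >= registry[cron.motif_id].high_conf_threshold
        if rescue:
            cron.accepted = True
            cron.reject_reason = ""
        else:
            cron.accepted = False
            reasons = []
            if cron.conservation < min_conservation:
                reasons.append(
                    f"conservation {cron.conservation:.2f} < {min_conservation}"
                )
            if n_reg < min_genomes:
                reasons.append(f"regulated genomes {n_reg} < {min_genomes}")
            cron.reject_reason = "; ".join(reasons)
    return crons


def extend_operons(
    cron: Cron,
    genomes: dict[str, Genome],
    orthology: OrthologyMap,
    extension_cap: int = 300,
    min_support: float = 0.5,
) -> list[str]:
    """Extend member operons downstream where orthology supports it.

    For each member operon, the next same-strand downstream gene is
    appended when its gap is within ``extension_cap`` nt AND its
    ortholog group occurs in at least ``min_support`` of the *other*
    member operons of the CRON.  Applied iteratively to a fixed point.
    Returns a log of extension events.
    """
    events: list[str] = []
    changed = True
    while changed:
        changed = False
        member_ogs = {
            id(ro): _og_set([ro], orthology) for ro in cron.operons
        }
        for ro in cron.operons:
            genome = genomes[ro.genome_id]
            candidate = _next_downstream_gene(ro, genome)
            if candidate is None:
                continue
            gene, gap = candidate
            if gap > extension_cap:
                continue
            og = orthology.group_of(ro.genome_id, gene.gene_id)
            if og is None:
                continue
            others = [o for o in cron.operons if o is not ro]
            if not others:
                continue
            support = sum(1 for o in others if og in member_ogs[id(o)])
            if support / len(others) >= min_support:
                ro.operon.genes.append(gene)
                events.append(
                    f"{cron.cron_id}: appended {gene.gene_id} (gap {gap}, "
                    f"support {support}/{len(others)}) to {ro.operon.operon_id}"
                )
                changed = True
    return events


def _next_downstream_gene(ro: RegulatedOperon, genome: Genome):
    """The nearest same-strand gene past the operon's 3' end, with its gap."""
    op = ro.operon
    current_ids = {g.gene_id for g in op.genes}
    contig_genes = genome.genes_on(op.contig_id)
    lo, hi = op.span
    if op.strand == "+":
        following = [g for g in contig_genes if g.start > hi and g.gene_id not in current_ids]
        if not following:
            return None
        nxt = min(following, key=lambda g: g.start)
        if nxt.strand != op.strand:
            return None
        return nxt, intergenic_gap(op.genes[-1], nxt)
    else:
        preceding = [g for g in contig_genes if g.end < lo and g.gene_id not in current_ids]
        if not preceding:
            return None
        nxt = max(preceding, key=lambda g: g.end)
        if nxt.strand != op.strand:
            return None
        return nxt, intergenic_gap(nxt, op.genes[-1])


def assemble_regulogs(crons: list[Cron]) -> list[Regulog]:
    """Bundle accepted CRONs into per-(motif, lineage) regulogs.

    Motif/lineage combinations with only rejected CRONs yield no
    regulog.  Tandem sites count individually in ``total_sites`` while
    their operon counts once.
    """
    grouped: dict[tuple[str, str], list[Cron]] = defaultdict(list)
    for cron in crons:
        if cron.accepted:
            grouped[(cron.motif_id, cron.taxgroup_id)].append(cron)
    return [
        Regulog(motif_id=m, taxgroup_id=t, crons=cs)
        for (m, t), cs in sorted(grouped.items())
    ]
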