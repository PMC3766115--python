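"""Assignment of RNA sites to their target operons.

A riboswitch or RNA leader acts on the operon whose start codon it
abuts.  Following the genome-scan convention used in regulon
reconstruction, a site is assignable to an operon when the site's
gene-proximal end falls between 500 nt upstream and 100 nt downstream
of the leader gene's start codon, on the same strand.  The proximal end
is the site coordinate closest to the regulated ORF: the site *end* on
plus-strand operons and the site *start* on minus-strand operons
(aptamers abut the ORF they regulate).

Before assignment, overlapping hits of the same family are reduced to
the strongest one; after assignment, two or more same-family sites on
one operon mark a tandem arrangement (glycine-riboswitch style) but the
operon is still counted once.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .model import Operon, RegulatedOperon, Regulon, RnaSite


def deduplicate_hits(sites: list[RnaSite]) -> list[RnaSite]:
    """Collapse overlapping same-family hits to the highest-scoring one.

    Greedy by descending score; ties broken by leftmost start, then by
    site_id.  Hits of different motif families or genomes never suppress
    each other.
    """
    kept: list[RnaSite] = []
    by_group: dict[tuple[str, str, str], list[RnaSite]] = defaultdict(list)
    for s in sites:
        by_group[(s.genome_id, s.motif_id, s.contig_id)].append(s)
    for group in by_group.values():
        group.sort(key=lambda s: (-s.score, s.start, s.site_id))
        survivors: list[RnaSite] = []
        for s in group:
            if not any(s.overlaps(t) for t in survivors):
                survivors.append(s)
        kept.extend(survivors)
    kept.sort(key=lambda s: (s.genome_id, s.motif_id, s.contig_id, s.start, s.site_id))
    return kept


def proximal_end(site: RnaSite, strand: str) -> int:
    """The site coordinate nearest the regulated ORF on ``strand``."""
    return site.end if strand == "+" else site.start


def signed_distance(site: RnaSite, operon: Operon) -> int:
    """Signed nt distance from the site's proximal end to the leader
    start codon, in gene orientation (negative = upstream)."""
    anchor = operon.leader_anchor.start_codon
    pos = proximal_end(site, operon.strand)
    return pos - anchor if operon.strand == "+" else anchor - pos


@dataclass
class AssignmentResult:
    """Outcome of site-to-operon assignment for one genome.

    Conservation of sites holds: every deduplicated site appears in
    exactly one of assigned / ambiguous / orphans.
    """

    regulated_operons: list[RegulatedOperon] = field(default_factory=list)
    ambiguous: list[tuple[RnaSite, list[str]]] = field(default_factory=list)
    orphans: list[RnaSite] = field(default_factory=list)

    @property
    def assigned_site_count(self) -> int:
        return sum(len(ro.sites) for ro in self.regulated_operons)


def assign_sites(
    sites: list[RnaSite],
    operons: list[Operon],
    upstream: int = 500,
    downstream: int = 100,
) -> AssignmentResult:
    """Assign deduplicated sites to operons via the upstream window.

    A site qualifies for an operon when strands match and its signed
    distance lies in ``[-upstream, +downstream]``.  A site qualifying
    for several operons (divergent anchors) goes to the one with the
    nearer start codon; an exact distance tie is left unassigned and
    reported as ambiguous.  Same-family sites landing on one operon are
    pooled into a single RegulatedOperon with ``tandem=True``.
    """
    by_contig_strand: dict[tuple[str, str], list[Operon]] = defaultdict(list)
    for op in operons:
        by_contig_strand[(op.contig_id, op.strand)].append(op)

    result = AssignmentResult()
    # (motif_id, operon_id) -> list of (site, distance)
    hits: dict[tuple[str, str], list[tuple[RnaSite, int]]] = defaultdict(list)
    operon_by_id = {op.operon_id: op for op in operons}

    for site in sites:
        candidates: list[tuple[int, Operon]] = []
        for op in by_contig_strand.get((site.contig_id, site.strand), []):
            d = signed_distance(site, op)
            if -upstream <= d <= downstream:
                candidates.append((d, op))
        if not candidates:
            result.orphans.append(site)
            continue
        candidates.sort(key=lambda t: abs(t[0]))
        best = abs(candidates[0][0])
        tied = [op for d, op in candidates if abs(d) == best]
        if len(tied) > 1:
            result.ambiguous.append((site, sorted(op.operon_id for op in tied)))
            continue
        d, op = candidates[0]
        hits[(site.motif_id, op.operon_id)].append((site, d))

    for (motif_id, operon_id), pairs in sorted(hits.items()):
        pairs.sort(key=lambda t: (abs(t[1]), t[0].site_id))
        result.regulated_operons.append(
            RegulatedOperon(
                operon=operon_by_id[operon_id],
                motif_id=motif_id,
                sites=[s for s, _ in pairs],
                site_to_start_distance=pairs[0][1],
            )
        )
    return result


def build_regulons(assignments: list[RegulatedOperon]) -> list[Regulon]:
    """Group regulated operons into per-(motif, genome) regulons."""
    grouped: dict[tuple[str, str], list[RegulatedOperon]] = defaultdict(list)
    for ro in assignments:
        grouped[(ro.motif_id, ro.genome_id)].append(ro)
    return [
        Regulon(motif_id=motif_id, genome_id=genome_id, regulated_operons=ros)
        for (motif_id, genome_id), ros in sorted(grouped.items())
    ]
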