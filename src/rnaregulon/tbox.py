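"""T-box amino acid specificity from specifier codons.

A T-box leader senses uncharged tRNA: its specifier codon pairs with
the tRNA anticodon and thereby fixes which amino acid the element
responds to.  Given a multiple alignment of T-box sequences with one
declared reference row whose specifier codon position is known, the
codon of every other row is read off the same alignment columns and
translated with the standard genetic code, replacing the visual
inspection a curator would perform on the alignment.

T-box regulogs built at the lineage level are then split into amino
acid-specific regulogs, one per specificity group present.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

from Bio import AlignIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .model import Cron, Regulog, ValidationError

logger = logging.getLogger(__name__)

UNRESOLVED = "unresolved"
UNASSIGNED = "unassigned"

RNA_BASES = set("ACGU")


@dataclass
class TBoxAlignment:
    """A gapped T-box alignment with a reference specifier-codon span.

    ``reference_codon_span`` gives the three 1-based *ungapped* positions
    of the specifier codon in the reference sequence; gaps in the
    reference row are accounted for when mapping to alignment columns.
    """

    rows: dict[str, str]
    reference_id: str
    reference_codon_span: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.reference_id not in self.rows:
            raise ValidationError(
                f"reference {self.reference_id!r} absent from alignment"
            )
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError("alignment rows have unequal lengths")
        a, b, c = self.reference_codon_span
        if not (1 <= a < b < c):
            raise ValidationError(
                f"codon span {self.reference_codon_span} not strictly increasing"
            )


def read_alignment(
    path: str | Path,
    reference_id: str,
    reference_codon_span: tuple[int, int, int],
    format: str = "stockholm",
) -> TBoxAlignment:
    """Load a Stockholm or aligned-FASTA T-box alignment."""
    aln = AlignIO.read(str(path), format)
    rows = {rec.id: str(rec.seq).upper().replace("T", "U") for rec in aln}
    return TBoxAlignment(
        rows=rows, reference_id=reference_id, reference_codon_span=reference_codon_span
    )


def map_anchor_columns(alignment: TBoxAlignment) -> tuple[int, int, int]:
    """Alignment columns (1-based) of the reference's specifier codon.

    Walks the reference row mapping each ungapped position to its
    column; errors if the span exceeds the reference's ungapped length.
    """
    ref = alignment.rows[alignment.reference_id]
    span = alignment.reference_codon_span
    ungapped_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref, start=1):
        if ch != "-":
            pos += 1
            ungapped_to_col[pos] = col
    missing = [p for p in span if p not in ungapped_to_col]
    if missing:
        raise ValidationError(
            f"codon span {span} exceeds reference ungapped length {pos}"
        )
    return tuple(ungapped_to_col[p] for p in span)  # type: ignore[return-value]


@dataclass(frozen=True)
class SpecificityCall:
    site_id: str
    codon: str
    amino_acid: str
    specificity_group: str


def call_specificity(
    alignment: TBoxAlignment,
    group_merges: dict[str, str] | None = None,
) -> list[SpecificityCall]:
    """Read each row's specifier codon and translate it.

    A codon containing a gap or non-ACGU character, or translating to a
    stop, is reported as unresolved/unassigned.  ``group_merges``
    optionally renames amino-acid groups (e.g. pooling Ile/Met into a
    branched readout); by default the specificity group is the amino
    acid's three-letter code.
    """
    cols = map_anchor_columns(alignment)
    merges = group_merges or {}
    calls = []
    for site_id, row in alignment.rows.items():
        codon = "".join(row[c - 1] for c in cols)
        if any(ch not in RNA_BASES for ch in codon):
            calls.append(SpecificityCall(site_id, UNRESOLVED, UNASSIGNED, UNASSIGNED))
            continue
        aa1 = str(Seq(codon).translate())
        if aa1 == "*":
            calls.append(SpecificityCall(site_id, codon, UNASSIGNED, UNASSIGNED))
            continue
        aa3 = seq3(aa1)
        group = merges.get(aa3, aa3)
        calls.append(SpecificityCall(site_id, codon, aa3, group))
    return calls


def split_tbox_regulogs(
    tbox_regulogs: list[Regulog],
    calls: list[SpecificityCall],
) -> tuple[list[Regulog], list[str]]:
    """Split lineage-level T-box regulogs by amino acid specificity.

    Every T-box site must have a SpecificityCall.  Each lineage regulog
    is replaced by one regulog per specificity group present; operons
    whose sites are all unresolved go to an unassigned bucket that is
    excluded from regulog counts.  Returns ``(specificity_regulogs,
    unassigned_site_ids)``.  CRON structure is preserved by splitting
    each CRON into per-specificity sub-CRONs.
    """
    call_by_site = {c.site_id: c for c in calls}
    specific: list[Regulog] = []
    unassigned_sites: list[str] = []

    for regulog in tbox_regulogs:
        by_group: dict[str, list[Cron]] = defaultdict(list)
        for cron in regulog.crons:
            sub_members: dict[str, dict[str, list]] = defaultdict(dict)
            for genome_id, ros in cron.members.items():
                for ro in ros:
                    group = _operon_specificity(ro, call_by_site)
                    if group == UNASSIGNED:
                        unassigned_sites.extend(s.site_id for s in ro.sites)
                        continue
                    sub_members[group].setdefault(genome_id, []).append(ro)
            for group, members in sorted(sub_members.items()):
                by_group[group].append(
                    Cron(
                        cron_id=f"{cron.cron_id}:{group}",
                        motif_id=cron.motif_id,
                        taxgroup_id=cron.taxgroup_id,
                        anchor_group=cron.anchor_group,
                        members=members,
                        conservation=cron.conservation,
                        accepted=cron.accepted,
                    )
                )
        if not by_group:
            logger.warning(
                "T-box regulog %s/%s: all sites unresolved, regulog dropped",
                regulog.motif_id,
                regulog.taxgroup_id,
            )
        for group, crons in sorted(by_group.items()):
            specific.append(
                Regulog(
                    motif_id=regulog.motif_id,
                    taxgroup_id=regulog.taxgroup_id,
                    crons=crons,
                    specificity_group=group,
                )
            )
    return specific, unassigned_sites


def _operon_specificity(ro, call_by_site: dict[str, SpecificityCall]) -> str:
    """Majority specificity over an operon's sites; unresolved ignored."""
    votes = Counter()
    for s in ro.sites:
        call = call_by_site.get(s.site_id)
        if call is None:
            raise ValidationError(f"T-box site {s.site_id} has no specificity call")
        if call.specificity_group != UNASSIGNED:
            votes[call.specificity_group] += 1
    if not votes:
        return UNASSIGNED
    top = max(votes.values())
    return min(g for g, n in votes.items() if n == top)
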