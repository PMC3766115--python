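"""Core data model for RNA-motif regulon reconstruction.

The objects here mirror the entities of a comparative reconstruction of
cis-regulatory RNA regulons in bacteria: annotated genes grouped into
genomes, candidate RNA regulatory sites from covariance-model scans,
operons inferred from gene layout, regulated operons and per-genome
regulons, cross-genome clusters of co-regulated orthologous operons
(CRONs), and lineage-level regulogs.

Coordinates are 1-based and inclusive throughout (GFF3 convention);
``start <= end`` always holds and the strand is stored separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input record violates a data-model invariant."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive coordinates."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str = ""
    functional_role: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def start_codon(self) -> int:
        """Genomic coordinate of the translation start (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """One annotated genome belonging to a taxonomic group.

    Genes are kept sorted by (contig_id, start); ``(genome_id, gene_id)``
    is unique within the genome.
    """

    genome_id: str
    taxgroup_id: str
    contig_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.taxgroup_id:
            raise ValidationError(f"genome {self.genome_id}: empty taxgroup_id")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(
                    f"genome {self.genome_id}: duplicate gene_id {g.gene_id}"
                )
            seen.add(g.gene_id)
            if g.contig_id not in self.contig_lengths:
                raise ValidationError(
                    f"gene {g.gene_id}: contig {g.contig_id} has no recorded length"
                )
            if g.end > self.contig_lengths[g.contig_id]:
                raise ValidationError(
                    f"gene {g.gene_id}: end {g.end} exceeds contig length "
                    f"{self.contig_lengths[g.contig_id]}"
                )
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.end))

    def genes_on(self, contig_id: str) -> list[Gene]:
        return [g for g in self.genes if g.contig_id == contig_id]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class RnaSite:
    """A candidate cis-regulatory RNA element from a genome scan.

    ``score`` is the covariance-model bit score of the hit.  Coordinates
    are normalised so that ``start <= end``; the hit orientation lives in
    ``strand``.
    """

    site_id: str
    motif_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"site {self.site_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"site {self.site_id}: bad strand {self.strand!r}")
        if not math.isfinite(self.score):
            raise ValidationError(f"site {self.site_id}: non-finite score")

    def overlaps(self, other: "RnaSite") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.end
            and other.start <= self.end
        )


MOTIF_CLASSES = ("riboswitch", "pyrR", "ribosomal_leader", "aa_leader", "tbox")


@dataclass(frozen=True)
class MotifInfo:
    """One RNA motif family: Rfam accession, name, mechanistic class."""

    motif_id: str
    name: str
    motif_class: str
    effector: str = "unknown"
    score_threshold: float = 0.0
    high_conf_threshold: float = float("inf")

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValidationError(
                f"motif {self.motif_id}: unknown class {self.motif_class!r}"
            )
        if not math.isfinite(self.score_threshold):
            raise ValidationError(f"motif {self.motif_id}: non-finite threshold")


class MotifRegistry:
    """Lookup of motif families keyed by Rfam accession."""

    def __init__(self, motifs: list[MotifInfo] | None = None):
        self._motifs: dict[str, MotifInfo] = {}
        for m in motifs or []:
            self.add(m)

    def add(self, motif: MotifInfo) -> None:
        if motif.motif_id in self._motifs:
            raise ValidationError(f"duplicate motif_id {motif.motif_id}")
        self._motifs[motif.motif_id] = motif

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self._motifs

    def __getitem__(self, motif_id: str) -> MotifInfo:
        return self._motifs[motif_id]

    def __iter__(self):
        return iter(self._motifs.values())

    def __len__(self) -> int:
        return len(self._motifs)


class OrthologyMap:
    """gene -> ortholog group mapping with an inverse index.

    Each gene maps to at most one ortholog group; the inverse index maps
    a group id to the set of ``(genome_id, gene_id)`` members.
    """

    def __init__(self):
        self._forward: dict[tuple[str, str], str] = {}
        self._inverse: dict[str, set[tuple[str, str]]] = {}

    def add(self, genome_id: str, gene_id: str, group_id: str) -> None:
        key = (genome_id, gene_id)
        existing = self._forward.get(key)
        if existing is not None and existing != group_id:
            raise ValidationError(
                f"gene {genome_id}/{gene_id} mapped to two ortholog groups "
                f"({existing}, {group_id})"
            )
        self._forward[key] = group_id
        self._inverse.setdefault(group_id, set()).add(key)

    def group_of(self, genome_id: str, gene_id: str) -> str | None:
        return self._forward.get((genome_id, gene_id))

    def members(self, group_id: str) -> set[tuple[str, str]]:
        return set(self._inverse.get(group_id, set()))

    def genomes_with_group(self, group_id: str) -> set[str]:
        return {gid for gid, _ in self._inverse.get(group_id, set())}

    def __len__(self) -> int:
        return len(self._forward)

    def items(self):
        return self._forward.items()


@dataclass
class Operon:
    """A run of co-transcribed adjacent same-strand genes.

    ``genes`` are ordered 5'->3' in transcription direction, so on the
    minus strand the genomic order is reversed.  ``leader_anchor`` is the
    first gene in transcription direction and carries the start codon
    against which upstream regulatory sites are positioned.
    """

    operon_id: str
    genome_id: str
    contig_id: str
    strand: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"operon {self.operon_id}: no genes")
        for g in self.genes:
            if g.contig_id != self.contig_id or g.strand != self.strand:
                raise ValidationError(
                    f"operon {self.operon_id}: gene {g.gene_id} on wrong "
                    "contig or strand"
                )

    @property
    def leader_anchor(self) -> Gene:
        return self.genes[0]

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RegulatedOperon:
    """An operon with one or more same-family RNA sites assigned to it.

    ``tandem`` is true when at least two sites of the family sit upstream
    of the same operon (the hallmark arrangement of glycine riboswitches).
    ``site_to_start_distance`` is the signed distance, in gene
    orientation, from the nearest site's gene-proximal end to the leader
    start codon (negative = upstream).
    """

    operon: Operon
    motif_id: str
    sites: list[RnaSite]
    site_to_start_distance: int

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValidationError("regulated operon with no sites")
        if any(s.motif_id != self.motif_id for s in self.sites):
            raise ValidationError("regulated operon mixes motif families")

    @property
    def tandem(self) -> bool:
        return len(self.sites) >= 2

    @property
    def genome_id(self) -> str:
        return self.operon.genome_id


@dataclass
class Regulon:
    """All genes of one genome controlled by sites of one motif family."""

    motif_id: str
    genome_id: str
    regulated_operons: list[RegulatedOperon]

    @property
    def gene_count(self) -> int:
        return sum(len(ro.operon) for ro in self.regulated_operons)

    @property
    def site_count(self) -> int:
        return sum(len(ro.sites) for ro in self.regulated_operons)


@dataclass
class Cron:
    """Cluster of co-Regulated Orthologous operoNs.

    A cross-genome cluster, within one taxonomic group, of regulated
    operons whose leader genes are orthologous (share ``anchor_group``)
    or whose gene content strongly overlaps.  ``conservation`` is the
    fraction of anchor-bearing genomes of the group that carry a
    regulated member.
    """

    cron_id: str
    motif_id: str
    taxgroup_id: str
    anchor_group: str
    members: dict[str, list[RegulatedOperon]]
    conservation: float = float("nan")
    accepted: bool = False
    reject_reason: str = ""

    @property
    def regulated_genomes(self) -> set[str]:
        return set(self.members)

    @property
    def operons(self) -> list[RegulatedOperon]:
        return [ro for ros in self.members.values() for ro in ros]

    @property
    def site_count(self) -> int:
        return sum(len(ro.sites) for ro in self.operons)

    @property
    def gene_count(self) -> int:
        return sum(len(ro.operon) for ro in self.operons)


@dataclass
class Regulog:
    """Accepted regulons of one motif family across one taxonomic group."""

    motif_id: str
    taxgroup_id: str
    crons: list[Cron]
    specificity_group: str = ""

    @property
    def total_sites(self) -> int:
        return sum(c.site_count for c in self.crons)

    @property
    def total_genes(self) -> int:
        return sum(c.gene_count for c in self.crons)

    @property
    def genome_count(self) -> int:
        genomes: set[str] = set()
        for c in self.crons:
            genomes |= c.regulated_genomes
        return len(genomes)

    @property
    def regulated_operons(self) -> list[RegulatedOperon]:
        return [ro for c in self.crons for ro in c.operons]
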