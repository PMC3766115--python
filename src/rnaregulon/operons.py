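"""Operon inference from gene layout.

Bacterial operons are approximated by chaining adjacent same-strand
genes whose intergenic gap does not exceed a maximum distance (default
200 nt), with overlapping coding regions also merged.  The gap between
consecutive genes is the number of nucleotides strictly between their
coding regions, ``next.start - prev.end - 1``, so a gap of exactly
``max_gap`` still merges and ``max_gap + 1`` breaks the operon.  A gene
nested inside another (same strand) is treated as a coding overlap.
"""

from __future__ import annotations

from itertools import groupby

from .model import Gene, Genome, Operon


def intergenic_gap(prev: Gene, nxt: Gene) -> int:
    """Nucleotides strictly between two genes (negative on overlap)."""
    return nxt.start - prev.end - 1


def infer_operons(
    genome: Genome, max_gap: int = 200, merge_overlaps: bool = True
) -> list[Operon]:
    """Partition a genome's genes into operons.

    Consecutive genes on one contig are merged into the growing operon
    when they share its strand and either their gap to the operon's
    rightmost end is within ``max_gap``, or their coding regions overlap
    and ``merge_overlaps`` is on.  Strand changes always break.  Within
    each operon genes are ordered 5'->3' in transcription direction
    (reversed genomic order on the minus strand).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    operons: list[Operon] = []
    counter = 0
    for contig_id, contig_genes in groupby(genome.genes, key=lambda g: g.contig_id):
        runs: list[list[Gene]] = []
        right_end = 0  # rightmost coding end of the current run
        for gene in contig_genes:
            if runs:
                current = runs[-1]
                gap = gene.start - right_end - 1
                same_strand = gene.strand == current[-1].strand
                merge = same_strand and (
                    (0 <= gap <= max_gap) or (gap < 0 and merge_overlaps)
                )
            else:
                merge = False
            if merge:
                runs[-1].append(gene)
                right_end = max(right_end, gene.end)
            else:
                runs.append([gene])
                right_end = gene.end
        for run in runs:
            counter += 1
            ordered = run if run[0].strand == "+" else list(reversed(run))
            operons.append(
                Operon(
                    operon_id=f"{genome.genome_id}.op{counter}",
                    genome_id=genome.genome_id,
                    contig_id=contig_id,
                    strand=run[0].strand,
                    genes=ordered,
                )
            )
    return operons
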