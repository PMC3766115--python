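"""Shared builders for small hand-laid genomes, sites and registries."""

from __future__ import annotations

import pytest

from rnaregulon.model import (
    Gene,
    Genome,
    MotifInfo,
    MotifRegistry,
    OrthologyMap,
    RnaSite,
)


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    genome_id: str = "G1",
    contig_id: str = "c1",
    role: str = "",
) -> Gene:
    return Gene(
        gene_id=gene_id,
        genome_id=genome_id,
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        locus_tag=gene_id,
        functional_role=role,
    )


def make_genome(
    genes: list[Gene],
    genome_id: str = "G1",
    taxgroup_id: str = "tax1",
    contig_len: int = 100_000,
) -> Genome:
    contigs = {g.contig_id for g in genes} or {"c1"}
    return Genome(
        genome_id=genome_id,
        taxgroup_id=taxgroup_id,
        contig_lengths={c: contig_len for c in contigs},
        genes=list(genes),
    )


def make_site(
    site_id: str,
    start: int,
    end: int,
    strand: str = "+",
    motif_id: str = "RF00059",
    genome_id: str = "G1",
    contig_id: str = "c1",
    score: float = 50.0,
) -> RnaSite:
    return RnaSite(
        site_id=site_id,
        motif_id=motif_id,
        genome_id=genome_id,
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        score=score,
    )


@pytest.fixture
def registry() -> MotifRegistry:
    return MotifRegistry(
        [
            MotifInfo("RF00059", "TPP", "riboswitch", "thiamin pyrophosphate", 30.0, 70.0),
            MotifInfo("RF00504", "Glycine", "riboswitch", "glycine", 30.0, 70.0),
            MotifInfo("RF00230", "T-box", "tbox", "unknown", 30.0, 70.0),
        ]
    )


@pytest.fixture
def orthology() -> OrthologyMap:
    return OrthologyMap()
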