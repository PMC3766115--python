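"""Synthetic multi-genome communities with planted RNA regulons.

The generator emulates the statistical structure the reconstruction
pipeline assumes in real data: taxonomic groups of related genomes that
share ortholog groups in conserved gene order, operon-structured gene
layouts (short intra-operon gaps, long inter-operon gaps), regulatory
sites planted in the upstream window of orthologous operon leaders at a
controlled conservation level, tandem arrangements of glycine-style
riboswitches, spurious sites in positions where no operon leader window
can claim them, and T-box alignments whose specifier codons encode
known amino acid specificities.

Every pipeline input format is emitted together with a ground-truth
manifest, so recovery can be scored exactly.  All randomness flows from
one seed; identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .classify import default_functional_map
from .model import Gene, Genome, MotifInfo, MotifRegistry, OrthologyMap, RnaSite
from .operons import infer_operons
from .tbox import TBoxAlignment

MARGIN = 600  # bare nucleotides before the first and after the last gene


@dataclass
class PlantedRegulonSpec:
    """One regulon to plant: a motif family regulating one orthologous
    operon across a conservation-fraction of a taxonomic group."""

    motif_id: str
    taxgroup_id: str
    n_operon_genes: int = 3
    conservation: float = 1.0
    tandem_prob: float = 0.0
    roles: tuple[str, ...] = ()
    specificity: str = ""  # 3-letter amino acid code, T-box motifs only

    def __post_init__(self) -> None:
        if not 0.0 <= self.conservation <= 1.0:
            raise ValueError("conservation must be in [0, 1]")
        if not 0.0 <= self.tandem_prob <= 1.0:
            raise ValueError("tandem_prob must be in [0, 1]")
        if self.n_operon_genes < 1:
            raise ValueError("planted operon needs at least one gene")


@dataclass
class SimConfig:
    """Study conditions for one synthetic community."""

    seed: int = 0
    n_taxgroups: int = 2
    genomes_per_group: int = 4
    genes_per_genome: int = 60
    gene_length: tuple[int, int] = (300, 1500)
    intra_operon_gap: tuple[int, int] = (20, 150)
    inter_operon_gap: tuple[int, int] = (300, 600)
    mean_operon_length: float = 2.5
    presence_prob: float = 0.9
    planted_regulons: list[PlantedRegulonSpec] = field(default_factory=list)
    spurious_sites_per_genome: int = 1
    true_score: tuple[float, float] = (60.0, 8.0)
    spurious_score: tuple[float, float] = (45.0, 6.0)
    score_threshold: float = 30.0
    high_conf_threshold: float = 70.0
    site_length: tuple[int, int] = (60, 140)
    upstream_placement: tuple[int, int] = (-400, -20)

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValueError("presence_prob must be in [0, 1]")
        if self.mean_operon_length < 1:
            raise ValueError("mean_operon_length must be >= 1")

    def taxgroup_ids(self) -> list[str]:
        return [f"tax{i + 1}" for i in range(self.n_taxgroups)]


def default_config(seed: int = 0) -> SimConfig:
    """The default planted-community layout used throughout the tests.

    Each taxonomic group carries a cobalamin-like riboswitch regulon
    over a three-gene biosynthetic operon, a glycine-like regulon with
    tandem riboswitch pairs over a two-gene operon, and two T-box
    regulons of different amino acid specificity; conservation 0.8 and
    one spurious site per genome (roughly 20% of true sites).
    """
    planted = []
    specs = ["Ile", "Met"]
    for t in range(2):
        tax = f"tax{t + 1}"
        planted += [
            PlantedRegulonSpec(
                motif_id="RF00174",
                taxgroup_id=tax,
                n_operon_genes=3,
                conservation=0.8,
                roles=("B12 biosynthesis", "B12 biosynthesis", "Cobalt transporters"),
            ),
            PlantedRegulonSpec(
                motif_id="RF00504",
                taxgroup_id=tax,
                n_operon_genes=2,
                conservation=0.8,
                tandem_prob=0.8,
                roles=("Glycine metabolism", "Glycine transporters"),
            ),
            PlantedRegulonSpec(
                motif_id="RF00230",
                taxgroup_id=tax,
                n_operon_genes=2,
                conservation=0.8,
                roles=("Amino acyl-tRNA synthetases", "Amino acid transporters"),
                specificity=specs[t],
            ),
        ]
    return SimConfig(seed=seed, planted_regulons=planted)


# ---------------------------------------------------------------------------
# internal template structures


@dataclass
class _TemplateGene:
    index: int  # position in taxgroup template; defines the ortholog group
    og: str
    role: str = ""
    forced: bool = False  # presence not subject to dropout


@dataclass
class _TemplateBlock:
    strand: str
    genes: list[_TemplateGene]
    planted: PlantedRegulonSpec | None = None

    @property
    def leader(self) -> _TemplateGene:
        """First gene in transcription direction."""
        return self.genes[0] if self.strand == "+" else self.genes[-1]


@dataclass
class Community:
    """A generated community plus everything needed to plant sites."""

    config: SimConfig
    genomes: dict[str, Genome]
    orthology: OrthologyMap
    registry: MotifRegistry
    functional_map: object
    templates: dict[str, list[_TemplateBlock]]
    rng: np.random.Generator
    sites: list[RnaSite] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# community generation


def _build_template(
    config: SimConfig, taxgroup_id: str, rng: np.random.Generator
) -> list[_TemplateBlock]:
    blocks: list[_TemplateBlock] = []
    planted_here = [p for p in config.planted_regulons if p.taxgroup_id == taxgroup_id]
    total = 0
    index = 0
    p_stop = 1.0 / config.mean_operon_length
    while total < config.genes_per_genome:
        size = int(min(rng.geometric(p_stop), 6))
        strand = "+" if rng.random() < 0.5 else "-"
        genes = []
        for _ in range(size):
            genes.append(_TemplateGene(index=index, og=f"{taxgroup_id}:OG{index:04d}"))
            index += 1
        blocks.append(_TemplateBlock(strand=strand, genes=genes))
        total += size
    # overwrite evenly spaced blocks with the planted operons
    if planted_here:
        if len(planted_here) > len(blocks):
            raise ValueError("more planted regulons than operon blocks")
        positions = list(np.linspace(0, len(blocks) - 1, len(planted_here)).astype(int))
        for i in range(1, len(positions)):  # force distinct block indices
            if positions[i] <= positions[i - 1]:
                positions[i] = positions[i - 1] + 1
        if positions and positions[-1] >= len(blocks):
            raise ValueError("more planted regulons than operon blocks")
        for spec, pos in zip(planted_here, positions):
            block = blocks[pos]
            block.planted = spec
            strand = block.strand
            genes = []
            for j in range(spec.n_operon_genes):
                genes.append(
                    _TemplateGene(
                        index=index,
                        og=f"{taxgroup_id}:OG{index:04d}",
                        forced=True,
                    )
                )
                index += 1
            block.genes = genes
            # roles follow transcription order: leader first
            order = genes if strand == "+" else list(reversed(genes))
            for j, tg in enumerate(order):
                if spec.roles:
                    tg.role = spec.roles[j % len(spec.roles)]
    return blocks


def _default_registry(config: SimConfig) -> MotifRegistry:
    from importlib import resources

    import pandas as pd

    ref = resources.files("rnaregulon.data").joinpath("rna_motif_families.tsv")
    with resources.as_file(ref) as path:
        fam = pd.read_csv(path, sep="\t", dtype=str)
    classes = dict(zip(fam.motif_id, fam.motif_class))
    names = dict(zip(fam.motif_id, fam.name))
    registry = MotifRegistry()
    for motif_id in sorted({p.motif_id for p in config.planted_regulons}):
        registry.add(
            MotifInfo(
                motif_id=motif_id,
                name=names.get(motif_id, motif_id),
                motif_class=classes.get(motif_id, "riboswitch"),
                score_threshold=config.score_threshold,
                high_conf_threshold=config.high_conf_threshold,
            )
        )
    return registry


def generate_community(config: SimConfig) -> Community:
    """Lay out genomes gene-by-gene from per-taxgroup templates.

    Genomes of one group share gene order and operon structure; gene
    lengths and gaps are redrawn per genome, and non-planted genes are
    present with ``presence_prob`` (gene loss).  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    templates = {
        tax: _build_template(config, tax, rng) for tax in config.taxgroup_ids()
    }
    genomes: dict[str, Genome] = {}
    orthology = OrthologyMap()
    for tax in config.taxgroup_ids():
        blocks = templates[tax]
        for k in range(config.genomes_per_group):
            genome_id = f"{tax}_g{k + 1}"
            genes: list[Gene] = []
            pos = MARGIN + 1
            prev_block_id: int | None = None
            for bi, block in enumerate(blocks):
                for tg in block.genes:
                    present = tg.forced or rng.random() < config.presence_prob
                    if not present:
                        continue
                    if genes:
                        lo, hi = (
                            config.intra_operon_gap
                            if prev_block_id == bi
                            else config.inter_operon_gap
                        )
                        pos = genes[-1].end + 1 + int(rng.integers(lo, hi + 1))
                    length = int(rng.integers(*config.gene_length, endpoint=True))
                    gene = Gene(
                        gene_id=f"{genome_id}_t{tg.index:04d}",
                        genome_id=genome_id,
                        contig_id="chr",
                        start=pos,
                        end=pos + length - 1,
                        strand=block.strand,
                        locus_tag=f"{genome_id}_t{tg.index:04d}",
                        functional_role=tg.role,
                    )
                    genes.append(gene)
                    orthology.add(genome_id, gene.gene_id, tg.og)
                    prev_block_id = bi
            contig_len = (genes[-1].end if genes else MARGIN) + MARGIN
            if genes and genes[-1].end + MARGIN > contig_len:
                raise ValueError(f"{genome_id}: layout exceeds contig")
            genomes[genome_id] = Genome(
                genome_id=genome_id,
                taxgroup_id=tax,
                contig_lengths={"chr": contig_len},
                genes=genes,
            )
    return Community(
        config=config,
        genomes=genomes,
        orthology=orthology,
        registry=_default_registry(config),
        functional_map=default_functional_map(),
        templates=templates,
        rng=rng,
        ground_truth={
            "seed": config.seed,
            "planted_regulons": [],
            "spurious_site_ids": [],
            "tbox_specificities": {},
        },
    )


# ---------------------------------------------------------------------------
# site planting


def _place_true_site(
    genome: Genome,
    leader: Gene,
    motif_id: str,
    site_id: str,
    distance_range: tuple[int, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> RnaSite:
    """A site whose gene-proximal end lands ``d`` nt upstream of the
    leader start codon, strand-matched."""
    d = int(rng.integers(distance_range[0], distance_range[1] + 1))
    length = int(rng.integers(*config.site_length, endpoint=True))
    score = float(rng.normal(*config.true_score))
    if leader.strand == "+":
        end = leader.start + d
        start = end - length + 1
    else:
        start = leader.end - d
        end = start + length - 1
    if start < 1 or end > genome.contig_lengths[leader.contig_id]:
        raise ValueError(f"site {site_id}: placement outside contig")
    return RnaSite(
        site_id=site_id,
        motif_id=motif_id,
        genome_id=genome.genome_id,
        contig_id=leader.contig_id,
        start=start,
        end=end,
        strand=leader.strand,
        score=score,
    )


def plant_regulons(community: Community) -> list[RnaSite]:
    """Plant true regulatory sites and spurious background hits.

    For each planted regulon, a conservation-fraction subset of the
    anchor-bearing genomes receives a site in the upstream window of the
    anchor operon's leader; tandem pairs are placed with the configured
    probability in disjoint upstream strata.  Spurious sites are then
    placed so that the whole site avoids, on its own strand, the
    assignment window of every operon leader — they survive score
    filtering but cannot produce a regulated operon.
    """
    config = community.config
    rng = community.rng
    sites: list[RnaSite] = []
    counter = 0

    for spec in config.planted_regulons:
        blocks = community.templates[spec.taxgroup_id]
        block = next(b for b in blocks if b.planted is spec)
        leader_tmpl = block.leader
        group_genomes = [
            g
            for g in sorted(community.genomes)
            if community.genomes[g].taxgroup_id == spec.taxgroup_id
        ]
        n_pick = int(round(spec.conservation * len(group_genomes)))
        picked = sorted(
            rng.choice(group_genomes, size=n_pick, replace=False).tolist()
        )
        truth_entry = {
            "motif_id": spec.motif_id,
            "taxgroup_id": spec.taxgroup_id,
            "anchor_group": leader_tmpl.og,
            "conservation": spec.conservation,
            "specificity": spec.specificity,
            "genomes": picked,
            "operons": {},
            "site_ids": [],
        }
        for genome_id in picked:
            genome = community.genomes[genome_id]
            leader = next(
                g
                for g in genome.genes
                if g.gene_id == f"{genome_id}_t{leader_tmpl.index:04d}"
            )
            tandem = rng.random() < spec.tandem_prob
            strata = [(-150, -20), (-400, -310)] if tandem else [
                config.upstream_placement
            ]
            for stratum in strata:
                counter += 1
                site = _place_true_site(
                    genome,
                    leader,
                    spec.motif_id,
                    f"{genome_id}_s{counter:04d}",
                    stratum,
                    config,
                    rng,
                )
                sites.append(site)
                truth_entry["site_ids"].append(site.site_id)
            operon_gene_ids = [
                f"{genome_id}_t{tg.index:04d}"
                for tg in (
                    block.genes if block.strand == "+" else reversed(block.genes)
                )
            ]
            truth_entry["operons"][genome_id] = operon_gene_ids
        community.ground_truth["planted_regulons"].append(truth_entry)
        if spec.specificity:
            for sid in truth_entry["site_ids"]:
                community.ground_truth["tbox_specificities"][sid] = spec.specificity

    sites.extend(_plant_spurious(community, sites))
    community.sites = sites
    return sites


def _leader_windows(genome: Genome, pad: int) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals, per strand, in which a site could be claimed
    by some operon leader (padded by the maximum site length)."""
    windows: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for op in infer_operons(genome):
        anchor = op.leader_anchor.start_codon
        if op.strand == "+":
            windows["+"].append((anchor - 500 - pad, anchor + 100 + pad))
        else:
            windows["-"].append((anchor - 100 - pad, anchor + 500 + pad))
    return windows


def _plant_spurious(community: Community, existing: list[RnaSite]) -> list[RnaSite]:
    config = community.config
    rng = community.rng
    motifs = sorted({p.motif_id for p in config.planted_regulons})
    out: list[RnaSite] = []
    counter = 0
    for genome_id in sorted(community.genomes):
        genome = community.genomes[genome_id]
        pad = config.site_length[1]
        windows = _leader_windows(genome, pad)
        occupied = [
            (s.start, s.end)
            for s in existing
            if s.genome_id == genome_id
        ]
        contig_len = genome.contig_lengths["chr"]
        for _ in range(config.spurious_sites_per_genome):
            placed = False
            for _attempt in range(2000):
                length = int(rng.integers(*config.site_length, endpoint=True))
                start = int(rng.integers(1, contig_len - length + 1))
                end = start + length - 1
                strand = "+" if rng.random() < 0.5 else "-"
                if any(start <= hi and lo <= end for lo, hi in windows[strand]):
                    continue
                if any(start <= hi and lo <= end for lo, hi in occupied):
                    continue
                counter += 1
                site = RnaSite(
                    site_id=f"{genome_id}_n{counter:04d}",
                    motif_id=str(rng.choice(motifs)) if motifs else "RF00059",
                    genome_id=genome_id,
                    contig_id="chr",
                    start=start,
                    end=end,
                    strand=strand,
                    score=float(rng.normal(*config.spurious_score)),
                )
                out.append(site)
                occupied.append((start, end))
                community.ground_truth["spurious_site_ids"].append(site.site_id)
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"{genome_id}: could not place a spurious site outside "
                    "all leader windows"
                )
    return out


# ---------------------------------------------------------------------------
# T-box alignments

# 90-nt stem of a T-box leader template; the specifier codon occupies
# ungapped positions 31-33 (here written as NNN before substitution).
_TBOX_TEMPLATE = (
    "GGAGCAUCGC"
    "UUGAGAGAUG"
    "GUGGUAACGC"
    "NNNGCAGAGA"
    "GGCUUCCGGC"
    "AAGGUGGUAC"
    "CGCGAUAGGA"
    "AGUCCUUGAG"
    "CGCAUGGAGC"
)
TBOX_CODON_SPAN = (31, 32, 33)
TBOX_REFERENCE_ID = "tbox_ref"

# representative codon per amino acid (RNA alphabet)
CODON_BY_AA = {
    "Ala": "GCA", "Arg": "CGU", "Asn": "AAC", "Asp": "GAC", "Cys": "UGC",
    "Gln": "CAA", "Glu": "GAA", "Gly": "GGC", "His": "CAC", "Ile": "AUC",
    "Leu": "CUC", "Lys": "AAA", "Met": "AUG", "Phe": "UUC", "Pro": "CCA",
    "Ser": "UCA", "Thr": "ACA", "Trp": "UGG", "Tyr": "UAC", "Val": "GUA",
}


def generate_tbox_alignments(
    community: Community,
    mutation_rate: float = 0.03,
    n_gap_columns: int = 3,
) -> TBoxAlignment | None:
    """Build a gapped alignment over all planted T-box sites.

    Each site's row is the template with the specifier codon replaced
    according to its planted specificity, plus background mutations and
    occasional single-base deletions away from the codon; a handful of
    all-gap columns are inserted outside the anchor region.  Returns
    ``None`` when no T-box was planted.
    """
    rng = community.rng
    truth = community.ground_truth["tbox_specificities"]
    if not truth:
        return None
    bases = "ACGU"
    anchor_lo, anchor_hi = TBOX_CODON_SPAN[0] - 1, TBOX_CODON_SPAN[2] - 1
    rows = {TBOX_REFERENCE_ID: _TBOX_TEMPLATE.replace("NNN", "GGC")}
    for site_id in sorted(truth):
        aa = truth[site_id]
        seq = list(_TBOX_TEMPLATE.replace("NNN", CODON_BY_AA[aa]))
        for i in range(len(seq)):
            if anchor_lo <= i <= anchor_hi:
                continue
            if rng.random() < mutation_rate:
                seq[i] = bases[int(rng.integers(0, 4))]
        # rare single-base deletion away from the anchor
        if rng.random() < 0.2:
            j = int(rng.integers(0, len(seq)))
            if not anchor_lo - 1 <= j <= anchor_hi + 1:
                seq[j] = "-"
        rows[site_id] = "".join(seq)
    # all-gap columns inserted outside the anchor region
    width = len(_TBOX_TEMPLATE)
    candidates = [c for c in range(width) if not anchor_lo - 2 <= c <= anchor_hi + 2]
    gap_cols = sorted(
        rng.choice(candidates, size=min(n_gap_columns, len(candidates)), replace=False).tolist(),
        reverse=True,
    )
    for col in gap_cols:
        rows = {k: v[:col] + "-" + v[col:] for k, v in rows.items()}
    return TBoxAlignment(
        rows=rows,
        reference_id=TBOX_REFERENCE_ID,
        reference_codon_span=TBOX_CODON_SPAN,
    )


# ---------------------------------------------------------------------------
# bundle emission


def write_bundle(community: Community, outdir: str | Path) -> dict[str, Path]:
    """Emit the community in the exact formats the readers consume.

    Writes one annotation TSV per genome, one site TSV, the orthology
    and registry TSVs, the functional map, the T-box alignment (when
    planted) and ``ground_truth.json``.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    genome_meta = {}
    for genome_id in sorted(community.genomes):
        genome = community.genomes[genome_id]
        p = outdir / f"{genome_id}.genes.tsv"
        rio.write_annotations(genome, p)
        paths[f"genes:{genome_id}"] = p
        genome_meta[genome_id] = {
            "taxgroup_id": genome.taxgroup_id,
            "contig_lengths": genome.contig_lengths,
        }
    import pandas as pd

    manifest_rows = [
        {
            "genome_id": gid,
            "taxgroup_id": community.genomes[gid].taxgroup_id,
            "path": f"{gid}.genes.tsv",
            "format": "tsv",
        }
        for gid in sorted(community.genomes)
    ]
    paths["genomes_manifest"] = outdir / "genomes.tsv"
    pd.DataFrame(manifest_rows).to_csv(paths["genomes_manifest"], sep="\t", index=False)
    paths["sites"] = outdir / "sites.tsv"
    rio.write_sites(community.sites, paths["sites"])
    paths["orthology"] = outdir / "orthology.tsv"
    rio.write_orthology(community.orthology, paths["orthology"])
    paths["registry"] = outdir / "registry.tsv"
    rio.write_registry(community.registry, paths["registry"])
    from importlib import resources
    import shutil

    ref = resources.files("rnaregulon.data").joinpath("functional_categories.tsv")
    paths["functional_map"] = outdir / "functional_map.tsv"
    with resources.as_file(ref) as src:
        shutil.copy(src, paths["functional_map"])
    alignment = generate_tbox_alignments(community)
    if alignment is not None:
        paths["tbox_alignment"] = outdir / "tbox_alignment.afa"
        with open(paths["tbox_alignment"], "w") as fh:
            for sid, row in alignment.rows.items():
                fh.write(f">{sid}\n{row}\n")
        community.ground_truth["tbox_reference"] = {
            "reference_id": alignment.reference_id,
            "codon_span": list(alignment.reference_codon_span),
        }
    community.ground_truth["genomes"] = genome_meta
    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(community.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = dataclasses.asdict(community.config)
    paths["sim_config"] = outdir / "sim_config.json"
    with open(paths["sim_config"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=list)
        fh.write("\n")
    return paths


def simulate(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a community, plant sites and alignments, write the bundle."""
    community = generate_community(config)
    plant_regulons(community)
    return write_bundle(community, outdir)
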