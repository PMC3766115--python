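"""Readers and writers for the pipeline's tabular formats.

Inputs
------
* gene annotations: GFF3 (``gene``/``CDS`` features) or a simplified TSV
  with columns ``gene_id  contig  start  end  strand  locus_tag
  functional_role``;
* RNA motif hits: Infernal ``--tblout``-style whitespace tables or a TSV
  with columns ``motif_id  contig  start  end  strand  score``;
* orthology: TSV ``genome_id  gene_id  ortholog_group_id``;
* motif registry: TSV ``motif_id  name  motif_class  effector
  score_threshold  [high_conf_threshold]``;
* functional categories: TSV ``functional_role  sfc  ofc``.

All coordinates are read and written 1-based inclusive.  Minus-strand
tblout rows (seq-from > seq-to) are normalised so that start <= end.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .classify import FunctionalMap
from .model import (
    Gene,
    Genome,
    MotifInfo,
    MotifRegistry,
    OrthologyMap,
    RnaSite,
    ValidationError,
)

logger = logging.getLogger(__name__)

GENE_TSV_COLUMNS = [
    "gene_id",
    "contig",
    "start",
    "end",
    "strand",
    "locus_tag",
    "functional_role",
]


# ---------------------------------------------------------------------------
# annotations


def read_annotations(
    path: str | Path,
    format: str = "tsv",
    genome_id: str = "",
    taxgroup_id: str = "",
    contig_lengths: dict[str, int] | None = None,
) -> Genome:
    """Read one genome's protein-coding gene annotation.

    ``contig_lengths`` may be supplied explicitly; otherwise lengths are
    taken from GFF3 ``##sequence-region`` directives or, as a fallback,
    from the maximum annotated end per contig.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome_id = genome_id or path.stem
    if format == "tsv":
        genes = _genes_from_tsv(path, genome_id)
        lengths = dict(contig_lengths or {})
    elif format == "gff3":
        genes, lengths = _genes_from_gff3(path, genome_id)
        if contig_lengths:
            lengths.update(contig_lengths)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    for g in genes:
        lengths.setdefault(g.contig_id, 0)
        lengths[g.contig_id] = max(lengths[g.contig_id], g.end)
    return Genome(
        genome_id=genome_id,
        taxgroup_id=taxgroup_id or "unknown",
        contig_lengths=lengths,
        genes=genes,
    )


def _genes_from_tsv(path: Path, genome_id: str) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: gene {row.gene_id}: non-integer coordinates"
            ) from exc
        genes.append(
            Gene(
                gene_id=row.gene_id,
                genome_id=genome_id,
                contig_id=row.contig,
                start=start,
                end=end,
                strand=row.strand,
                locus_tag=getattr(row, "locus_tag", "") or "",
                functional_role=getattr(row, "functional_role", "") or "",
            )
        )
    return genes


def _genes_from_gff3(path: Path, genome_id: str) -> tuple[list[Gene], dict[str, int]]:
    """Parse gene/CDS features from a GFF3 file.

    ``gene`` features are preferred; ``CDS`` features are used for loci
    without a gene record.  Other feature types are ignored.
    """
    lengths: dict[str, int] = {}
    records: dict[str, Gene] = {}
    cds_records: dict[str, Gene] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            contig, _, ftype, start_s, end_s, _, strand, _, attrs_s = fields[:9]
            if ftype not in ("gene", "CDS"):
                continue
            attrs = _parse_gff_attrs(attrs_s)
            gid = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Parent")
            if not gid:
                raise ValidationError(f"{path}: feature without ID: {line[:80]}")
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValidationError(f"{path}: record {gid}: end {end} < start {start}")
            gene = Gene(
                gene_id=gid,
                genome_id=genome_id,
                contig_id=contig,
                start=start,
                end=end,
                strand=strand,
                locus_tag=attrs.get("locus_tag", ""),
                functional_role=attrs.get("product", attrs.get("function", "")),
            )
            target = records if ftype == "gene" else cds_records
            if gid in target:
                raise ValidationError(f"{path}: duplicate gene_id {gid}")
            target[gid] = gene
    for gid, gene in cds_records.items():
        base = gid.removeprefix("cds-")
        if gid not in records and base not in records:
            records[gid] = gene
    return list(records.values()), lengths


def _parse_gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for item in s.split(";"):
        item = item.strip()
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_annotations(genome: Genome, path: str | Path) -> None:
    """Write a Genome back to the simplified TSV dialect (round-trips)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "locus_tag": g.locus_tag,
            "functional_role": g.functional_role,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RNA sites


def read_sites(
    path: str | Path,
    registry: MotifRegistry,
    genome_id: str = "",
) -> list[RnaSite]:
    """Read RNA motif hits and apply the per-family score thresholds.

    Accepts either an Infernal tblout table (``#``-commented,
    whitespace-delimited; query accession in column 4, coordinates in
    columns 8-9, strand in column 10, bit score in column 15) or a TSV
    with an explicit header.  Hits scoring below their family's
    registry threshold are dropped; the drop count is logged.
    """
    path = Path(path)
    raw = _read_site_rows(path, genome_id)
    sites: list[RnaSite] = []
    dropped = 0
    for rec in raw:
        if rec["motif_id"] not in registry:
            raise ValidationError(
                f"{path}: motif {rec['motif_id']} absent from registry"
            )
        if rec["score"] < registry[rec["motif_id"]].score_threshold:
            dropped += 1
            continue
        start, end = rec["start"], rec["end"]
        if start > end:  # tblout reverses coordinates on the minus strand
            start, end = end, start
        sites.append(
            RnaSite(
                site_id=rec["site_id"],
                motif_id=rec["motif_id"],
                genome_id=rec["genome_id"],
                contig_id=rec["contig"],
                start=start,
                end=end,
                strand=rec["strand"],
                score=rec["score"],
            )
        )
    if dropped:
        logger.info("%s: dropped %d sub-threshold hits", path.name, dropped)
    return sites


def _read_site_rows(path: Path, genome_id: str) -> list[dict]:
    with open(path) as fh:
        first = fh.readline()
    header = first.rstrip("\n").split("\t")
    if first.startswith("#") or not {"motif_id", "contig", "score"} <= set(header):
        return _parse_tblout(path, genome_id)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for i, row in enumerate(df.itertuples(index=False)):
        rows.append(
            {
                "site_id": getattr(row, "site_id", "") or f"{path.stem}.{i + 1}",
                "motif_id": row.motif_id,
                "genome_id": getattr(row, "genome_id", "") or genome_id or path.stem,
                "contig": row.contig,
                "start": int(row.start),
                "end": int(row.end),
                "strand": row.strand,
                "score": _parse_score(row.score, path, i),
            }
        )
    return rows


def _parse_tblout(path: Path, genome_id: str) -> list[dict]:
    rows = []
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 15:
                raise ValidationError(f"{path}: short tblout row: {line[:80]}")
            n += 1
            rows.append(
                {
                    "site_id": f"{path.stem}.{n}",
                    "motif_id": f[3],
                    "genome_id": genome_id or path.stem,
                    "contig": f[0],
                    "start": int(f[7]),
                    "end": int(f[8]),
                    "strand": f[9],
                    "score": _parse_score(f[14], path, n),
                }
            )
    return rows


def _parse_score(value: str, path: Path, row: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"{path}: row {row}: unparsable score {value!r}") from exc


def write_sites(sites: list[RnaSite], path: str | Path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "motif_id": s.motif_id,
            "genome_id": s.genome_id,
            "contig": s.contig_id,
            "start": s.start,
            "end": s.end,
            "strand": s.strand,
            "score": s.score,
        }
        for s in sites
    ]
    pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "motif_id",
            "genome_id",
            "contig",
            "start",
            "end",
            "strand",
            "score",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthology / registry / functional map


def read_orthology(
    path: str | Path, genomes: dict[str, Genome] | None = None
) -> OrthologyMap:
    """Read the gene -> ortholog-group TSV.

    A gene appearing under two different groups is a hard error; genes
    listed for genomes not loaded (when ``genomes`` is given) only warn.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    omap = OrthologyMap()
    known: set[tuple[str, str]] | None = None
    if genomes is not None:
        known = {
            (gen.genome_id, g.gene_id) for gen in genomes.values() for g in gen.genes
        }
    unknown = 0
    for row in df.itertuples(index=False):
        omap.add(row.genome_id, row.gene_id, row.ortholog_group_id)
        if known is not None and (row.genome_id, row.gene_id) not in known:
            unknown += 1
    if unknown:
        logger.warning(
            "%s: %d orthology rows refer to genes absent from loaded genomes",
            Path(path).name,
            unknown,
        )
    return omap


def write_orthology(omap: OrthologyMap, path: str | Path) -> None:
    rows = [
        {"genome_id": gid, "gene_id": gene, "ortholog_group_id": og}
        for (gid, gene), og in sorted(omap.items())
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "gene_id", "ortholog_group_id"]
    ).to_csv(path, sep="\t", index=False)


def read_registry(path: str | Path) -> MotifRegistry:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    registry = MotifRegistry()
    for row in df.itertuples(index=False):
        high = getattr(row, "high_conf_threshold", "")
        registry.add(
            MotifInfo(
                motif_id=row.motif_id,
                name=row.name,
                motif_class=row.motif_class,
                effector=getattr(row, "effector", "") or "unknown",
                score_threshold=float(row.score_threshold),
                high_conf_threshold=float(high) if high else float("inf"),
            )
        )
    return registry


def write_registry(registry: MotifRegistry, path: str | Path) -> None:
    rows = [
        {
            "motif_id": m.motif_id,
            "name": m.name,
            "motif_class": m.motif_class,
            "effector": m.effector,
            "score_threshold": m.score_threshold,
            "high_conf_threshold": m.high_conf_threshold,
        }
        for m in registry
    ]
    pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "name",
            "motif_class",
            "effector",
            "score_threshold",
            "high_conf_threshold",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_functional_map(path: str | Path) -> FunctionalMap:
    """Read the role -> SFC -> OFC classification table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fmap = FunctionalMap()
    for row in df.itertuples(index=False):
        fmap.add(row.functional_role, row.sfc, row.ofc)
    fmap.validate()
    return fmap
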