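"""Distribution and composition statistics of RNA-motif regulogs.

Covers the summary layer of the reconstruction: the motif x lineage
presence matrix with the A-F distribution classes, per-lineage and
per-motif site/gene aggregates with their per-genome ratios, OFC
proportion tables, tandem-riboswitch statistics, and the regulog
accounting that replaces lineage-level T-box regulogs by amino
acid-specific ones.

Formatting of per-genome ratios follows the reporting convention of
the regulog collection: values of 10 and above are printed as integers
(half-up rounding), smaller values with one decimal.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import MotifRegistry, Regulog

DISTRIBUTION_WIDE_FRACTION = 0.75  # strict lower bound for class A
DISTRIBUTION_RESTRICTED_MAX = 3  # at most this many lineages for class C

CLASS_BY_MOTIF_CLASS = {
    "ribosomal_leader": "D",
    "aa_leader": "E",
    "tbox": "F",
}


def round_half_up(value: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_per_genome(value: float) -> str:
    """Integer at >= 10 (half-up), one decimal below 10."""
    if value >= 10:
        return str(int(round_half_up(value)))
    return f"{round_half_up(value, 1):.1f}"


# ---------------------------------------------------------------------------
# distribution classes


def classify_distribution_group(
    motif_class: str,
    n_present: int,
    n_groups: int = 24,
) -> str:
    """Assign a motif its A-F distribution class.

    Ribosomal leaders, amino acid attenuator leaders, and T-boxes are
    fixed to D, E, and F by mechanism.  Riboswitches (and the PyrR
    motif) are A when present in more than 75% of lineages, C when
    restricted to at most three lineages, and B otherwise.
    """
    fixed = CLASS_BY_MOTIF_CLASS.get(motif_class)
    if fixed is not None:
        return fixed
    if n_present > DISTRIBUTION_WIDE_FRACTION * n_groups:
        return "A"
    if n_present <= DISTRIBUTION_RESTRICTED_MAX:
        return "C"
    return "B"


@dataclass
class DistributionMatrix:
    """Boolean motif x lineage presence with per-motif class letters."""

    presence: pd.DataFrame  # index: motif_id, columns: taxgroup_id, bool
    groups: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_regulogs(
        cls,
        regulogs: list[Regulog],
        registry: MotifRegistry,
        taxgroups: list[str],
    ) -> "DistributionMatrix":
        motifs = sorted({r.motif_id for r in regulogs})
        presence = pd.DataFrame(False, index=motifs, columns=sorted(set(taxgroups)))
        for r in regulogs:
            presence.loc[r.motif_id, r.taxgroup_id] = True
        groups = {}
        for motif_id in motifs:
            n_present = int(presence.loc[motif_id].sum())
            groups[motif_id] = classify_distribution_group(
                registry[motif_id].motif_class, n_present, n_groups=len(presence.columns)
            )
        return cls(presence=presence, groups=groups)


# ---------------------------------------------------------------------------
# lineage and motif aggregates


def lineage_stats(
    totals: pd.DataFrame,
    sites_per_genome_grand: str = "weighted",
) -> pd.DataFrame:
    """Per-lineage ratios and a grand-total row from lineage totals.

    ``totals`` needs columns ``taxgroup, genomes, sites, regulogs,
    target_genes``.  Adds formatted ``sites_per_genome`` and
    ``genes_per_genome`` columns plus a TOTAL row.  Two grand-average
    conventions are emitted explicitly: the grand sites-per-genome is
    weighted (total sites over total genomes) while the grand
    genes-per-genome is the unweighted mean of the lineage per-genome
    ratios; both are recorded in the column metadata of the output.
    """
    df = totals.copy()
    ratios_sites = df["sites"] / df["genomes"].where(df["genomes"] > 0, other=pd.NA)
    ratios_genes = df["target_genes"] / df["genomes"].where(df["genomes"] > 0, other=pd.NA)
    df["sites_per_genome"] = [
        format_per_genome(v) if pd.notna(v) else "0" for v in ratios_sites
    ]
    df["genes_per_genome"] = [
        format_per_genome(v) if pd.notna(v) else "0" for v in ratios_genes
    ]
    grand_genomes = int(df["genomes"].sum())
    grand = {
        "taxgroup": "TOTAL",
        "genomes": grand_genomes,
        "sites": int(df["sites"].sum()),
        "regulogs": int(df["regulogs"].sum()),
        "target_genes": int(df["target_genes"].sum()),
        "sites_per_genome": format_per_genome(df["sites"].sum() / grand_genomes)
        if grand_genomes
        else "0",
        # unweighted mean over lineage per-genome ratios
        "genes_per_genome": format_per_genome(float(ratios_genes.dropna().mean()))
        if ratios_genes.notna().any()
        else "0",
    }
    out = pd.concat([df, pd.DataFrame([grand])], ignore_index=True)
    out.attrs["sites_per_genome_grand"] = "weighted: total sites / total genomes"
    out.attrs["genes_per_genome_grand"] = "unweighted mean of lineage per-genome values"
    return out


def lineage_totals_from_regulogs(
    regulogs: list[Regulog], genomes_per_taxgroup: dict[str, int]
) -> pd.DataFrame:
    """Aggregate assembled regulogs into the lineage-totals table."""
    rows = []
    by_tax: dict[str, list[Regulog]] = defaultdict(list)
    for r in regulogs:
        by_tax[r.taxgroup_id].append(r)
    for tax, n_genomes in sorted(genomes_per_taxgroup.items()):
        rs = by_tax.get(tax, [])
        rows.append(
            {
                "taxgroup": tax,
                "genomes": n_genomes,
                "sites": sum(r.total_sites for r in rs),
                "regulogs": len(rs),
                "target_genes": sum(r.total_genes for r in rs),
            }
        )
    return pd.DataFrame(rows)


def motif_stats(regulogs: list[Regulog]) -> pd.DataFrame:
    """Per-motif aggregates: sites, genes, genomes, and the two ratios.

    ``genes_per_genome`` divides by genomes carrying at least one site;
    ``genes_per_riboswitch`` divides genes by sites.  Motifs with zero
    sites get undefined (NA) ratios and are flagged.
    """
    by_motif: dict[str, list[Regulog]] = defaultdict(list)
    for r in regulogs:
        by_motif[r.motif_id].append(r)
    rows = []
    for motif_id, rs in sorted(by_motif.items()):
        sites = sum(r.total_sites for r in rs)
        genes = sum(r.total_genes for r in rs)
        genomes = sum(r.genome_count for r in rs)
        rows.append(_motif_row(motif_id, sites, genes, genomes))
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "sites",
            "genes",
            "genomes_with_site",
            "genes_per_genome",
            "genes_per_riboswitch",
            "undefined",
        ],
    )


def _motif_row(motif_id: str, sites: int, genes: int, genomes: int) -> dict:
    undefined = sites == 0 or genomes == 0
    return {
        "motif_id": motif_id,
        "sites": sites,
        "genes": genes,
        "genomes_with_site": genomes,
        "genes_per_genome": format_per_genome(genes / genomes) if genomes else "NA",
        "genes_per_riboswitch": format_per_genome(genes / sites) if sites else "NA",
        "undefined": undefined,
    }


def motif_stats_from_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """Same ratios computed from a pre-aggregated per-motif table
    (columns ``motif_id, sites, genes, genomes_with_site``)."""
    rows = [
        _motif_row(
            row.motif_id, int(row.sites), int(row.genes), int(row.genomes_with_site)
        )
        for row in totals.itertuples(index=False)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# OFC proportions


def ofc_proportions(
    sfc_counts: dict[tuple[str, str], Counter],
    fmap,
    scope: str = "motif",
) -> dict[str, dict[str, float] | str]:
    """Relative OFC contributions per motif or per lineage.

    Counts are first aggregated through the SFC -> OFC map; genes in the
    unknown-role SFC are excluded, matching the convention that
    proportion tables cover only functionally assigned genes.  Scopes
    with no classified gene are labelled ``"N/A"``.
    """
    from .classify import UNKNOWN_SFC

    if scope not in ("motif", "taxgroup"):
        raise ValueError(f"scope must be motif or taxgroup, got {scope!r}")
    idx = 0 if scope == "motif" else 1
    pooled: dict[str, Counter] = defaultdict(Counter)
    for key, counts in sfc_counts.items():
        for sfc, n in counts.items():
            if sfc == UNKNOWN_SFC:
                continue
            pooled[key[idx]][fmap.ofc_of_sfc(sfc)] += n
    out: dict[str, dict[str, float] | str] = {}
    for scope_key in sorted({k[idx] for k in sfc_counts}):
        counts = pooled.get(scope_key)
        total = sum(counts.values()) if counts else 0
        if total == 0:
            out[scope_key] = "N/A"
        else:
            out[scope_key] = {ofc: n / total for ofc, n in sorted(counts.items())}
    return out


# ---------------------------------------------------------------------------
# tandem arrangements


def tandem_stats(regulated_operons: list) -> tuple[float, float]:
    """(tandem fraction, mean operon size) over one motif's operons.

    A tandem-regulated operon counts once in the mean size.  With no
    regulated operons both values are NaN.
    """
    n = len(regulated_operons)
    if n == 0:
        return float("nan"), float("nan")
    tandem = sum(1 for ro in regulated_operons if ro.tandem)
    mean_size = sum(len(ro.operon) for ro in regulated_operons) / n
    return tandem / n, mean_size


# ---------------------------------------------------------------------------
# regulog accounting


def regulog_accounting(
    n_initial: int, n_lineage_tbox: int, n_specificity: int
) -> int:
    """Total regulog count after the T-box split.

    Lineage-level T-box regulogs are removed and replaced by the amino
    acid-specific regulogs derived from them.
    """
    if n_lineage_tbox > n_initial:
        raise ValueError("more T-box regulogs than regulogs overall")
    return n_initial - n_lineage_tbox + n_specificity
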