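"""Infer operons and assign riboswitch sites to target operons.

A small hand-laid genome: the thiamin operon thiC-thiE sits 480 nt
downstream of a TPP riboswitch; a second gene pair on the minus strand
is out of reach.  The gap rule (<= 200 nt merges) and the assignment
window (500 nt upstream to 100 nt downstream of the start codon)
produce one regulated operon.
"""

from rnaregulon import Gene, Genome, RnaSite, assign_sites, deduplicate_hits, infer_operons

genes = [
    Gene("thiC", "G1", "c1", 1000, 1900, "+", "thiC", "Thiamin biosynthesis"),
    Gene("thiE", "G1", "c1", 2050, 2800, "+", "thiE", "Thiamin biosynthesis"),
    Gene("yxyA", "G1", "c1", 6000, 6900, "-", "yxyA", ""),
]
genome = Genome("G1", "tax1", {"c1": 10_000}, genes)

operons = infer_operons(genome, max_gap=200)
print(f"{len(operons)} operons inferred:")
for op in operons:
    print(f"  {op.operon_id}: {[g.gene_id for g in op.genes]} ({op.strand})")

sites = deduplicate_hits(
    [
        RnaSite("tpp1", "RF00059", "G1", "c1", 440, 520, "+", 55.0),
        RnaSite("tpp1b", "RF00059", "G1", "c1", 470, 540, "+", 48.0),  # overlap
        RnaSite("noise", "RF00059", "G1", "c1", 8000, 8100, "+", 42.0),
    ]
)
result = assign_sites(sites, operons, upstream=500, downstream=100)
for ro in result.regulated_operons:
    print(
        f"site(s) {[s.site_id for s in ro.sites]} -> operon "
        f"{[g.gene_id for g in ro.operon.genes]}, "
        f"{-ro.site_to_start_distance} nt upstream of the start codon"
    )
print(f"orphans (no operon window claims them): {[s.site_id for s in result.orphans]}")
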