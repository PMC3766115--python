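"""Cluster regulated operons across genomes into CRONs and score their
regulatory conservation.

Four genomes of one lineage regulate an orthologous operon (leader in
ortholog group OG_thiC); a fifth genome carries the gene but no site.
Conservation is regulated genomes over anchor-bearing genomes: 4/5.
"""

from rnaregulon import accept_crons, assemble_regulogs, build_crons
from rnaregulon.model import Gene, Genome, Operon, OrthologyMap, RegulatedOperon, Regulon, RnaSite

orthology = OrthologyMap()
regulons = []
genomes = []
for i in range(5):
    gid = f"G{i}"
    gene = Gene(f"{gid}_thiC", gid, "c1", 1000, 1900, "+", "", "Thiamin biosynthesis")
    orthology.add(gid, gene.gene_id, "OG_thiC")
    genomes.append(Genome(gid, "tax1", {"c1": 10_000}, [gene]))
    if i == 4:
        continue  # anchor-bearing but unregulated
    operon = Operon(f"{gid}:op1", gid, "c1", "+", [gene])
    site = RnaSite(f"{gid}_s1", "RF00059", gid, "c1", 440, 520, "+", 55.0)
    ro = RegulatedOperon(operon, "RF00059", [site], -480)
    regulons.append(Regulon("RF00059", gid, [ro]))

crons = build_crons(regulons, orthology, "tax1")
accept_crons(crons, genomes, orthology, min_conservation=0.5, min_genomes=2)
for cron in crons:
    print(
        f"{cron.cron_id}: anchor={cron.anchor_group} "
        f"conservation={cron.conservation:.2f} accepted={cron.accepted}"
    )

regulogs = assemble_regulogs(crons)
for r in regulogs:
    print(
        f"regulog {r.motif_id}/{r.taxgroup_id}: "
        f"{r.total_sites} sites, {r.total_genes} genes, {r.genome_count} genomes"
    )
print("conservation 0.80 means 4 of the 5 thiC-bearing genomes keep the site.")
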