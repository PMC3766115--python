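"""CRON clustering, conservation scoring, acceptance, operon extension,
and regulog assembly — including a brute-force clustering oracle."""

import numpy as np
import pytest

from rnaregulon.crons import (
    accept_crons,
    assemble_regulogs,
    build_crons,
    extend_operons,
    jaccard,
    score_conservation,
)
from rnaregulon.model import (
    MotifInfo,
    MotifRegistry,
    Operon,
    OrthologyMap,
    RegulatedOperon,
    Regulon,
)

from conftest import make_gene, make_genome, make_site


def make_regulated_operon(
    genome_id: str,
    gene_ids: list[str],
    orthology: OrthologyMap,
    ogs: list[str],
    motif_id: str = "RF00059",
    score: float = 50.0,
    op_id: str | None = None,
):
    genes = [
        make_gene(g, 1000 + i * 600, 1400 + i * 600, genome_id=genome_id)
        for i, g in enumerate(gene_ids)
    ]
    for g, og in zip(gene_ids, ogs):
        orthology.add(genome_id, g, og)
    operon = Operon(
        operon_id=op_id or f"{genome_id}:{gene_ids[0]}",
        genome_id=genome_id,
        contig_id="c1",
        strand="+",
        genes=genes,
    )
    site = make_site(
        f"s:{operon.operon_id}", 700, 800, motif_id=motif_id,
        genome_id=genome_id, score=score,
    )
    return RegulatedOperon(
        operon=operon, motif_id=motif_id, sites=[site], site_to_start_distance=-200
    )


def regulons_of(ros):
    grouped = {}
    for ro in ros:
        grouped.setdefault(ro.genome_id, []).append(ro)
    return [
        Regulon(motif_id=ros[0].motif_id, genome_id=gid, regulated_operons=lst)
        for gid, lst in grouped.items()
    ]


class TestBuildCrons:
    def test_shared_anchor_one_cron(self, orthology):
        ros = [
            make_regulated_operon(f"G{i}", [f"G{i}_a"], orthology, ["OG7"])
            for i in range(1, 4)
        ]
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        assert len(crons) == 1
        assert crons[0].anchor_group == "OG7"
        assert len(crons[0].operons) == 3

    def test_high_jaccard_merges(self, orthology):
        # anchors differ but gene content overlaps at Jaccard 2/3 >= 0.5
        a = make_regulated_operon("G1", ["G1_a", "G1_b", "G1_c"], orthology,
                                  ["OG1", "OG2", "OG3"])
        b = make_regulated_operon("G2", ["G2_b", "G2_c"], orthology,
                                  ["OG2", "OG3"])
        crons = build_crons(regulons_of([a, b]), orthology, "tax1")
        assert len(crons) == 1

    def test_disjoint_content_stays_separate(self, orthology):
        a = make_regulated_operon("G1", ["G1_a"], orthology, ["OG1"])
        b = make_regulated_operon("G2", ["G2_x"], orthology, ["OG9"])
        crons = build_crons(regulons_of([a, b]), orthology, "tax1")
        assert len(crons) == 2

    def test_unmapped_leader_becomes_singleton(self, orthology):
        ro = make_regulated_operon("G1", ["G1_a"], orthology, ["OG1"])
        orphan_genes = [make_gene("G2_z", 1000, 1400, genome_id="G2")]
        operon = Operon("G2:z", "G2", "c1", "+", orphan_genes)
        orphan = RegulatedOperon(
            operon=operon, motif_id="RF00059",
            sites=[make_site("sz", 700, 800, genome_id="G2")],
            site_to_start_distance=-200,
        )
        crons = build_crons(regulons_of([ro, orphan]), orthology, "tax1")
        anchors = {c.anchor_group for c in crons}
        assert "unassigned:G2_z" in anchors


def brute_force_components(seeds: dict, orthology: OrthologyMap, threshold=0.5):
    """Independent clustering oracle: exhaustive pairwise merge to a
    fixed point over member operons' ortholog-group sets."""

    def ogs(ros):
        out = set()
        for ro in ros:
            for g in ro.operon.genes:
                og = orthology.group_of(ro.genome_id, g.gene_id)
                if og is not None:
                    out.add(og)
        return out

    clusters = [set([a]) for a in seeds]
    content = {a: ogs(seeds[a]) for a in seeds}
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                # merge when ANY seed pair across the clusters meets the bound
                if any(
                    jaccard(content[a], content[b]) >= threshold
                    for a in clusters[i]
                    for b in clusters[j]
                ):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in clusters}


@pytest.mark.parametrize("seed", range(10))
def test_clustering_matches_brute_force_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    orthology = OrthologyMap()
    ros = []
    n_genomes = int(rng.integers(2, 6))
    og_pool = [f"OG{i}" for i in range(6)]
    for g in range(n_genomes):
        for k in range(int(rng.integers(1, 4))):
            size = int(rng.integers(1, 4))
            ogs = list(rng.choice(og_pool, size=size, replace=False))
            gene_ids = [f"G{g}_o{k}_{i}" for i in range(size)]
            ros.append(
                make_regulated_operon(
                    f"G{g}", gene_ids, orthology, ogs, op_id=f"G{g}:o{k}"
                )
            )
    crons = build_crons(regulons_of(ros), orthology, "tax1")
    got = {
        frozenset(ro.operon.operon_id for ro in c.operons) for c in crons
    }
    # oracle works on the same leader-anchored seeds
    seeds = {}
    for ro in ros:
        og = orthology.group_of(ro.genome_id, ro.operon.leader_anchor.gene_id)
        seeds.setdefault(og, []).append(ro)
    expected_anchor_sets = brute_force_components(seeds, orthology)
    expected = {
        frozenset(
            ro.operon.operon_id for a in anchor_set for ro in seeds[a]
        )
        for anchor_set in expected_anchor_sets
    }
    assert got == expected


class TestConservation:
    def _cron_with_anchor(self, orthology, n_regulated, n_bearing):
        ros = [
            make_regulated_operon(f"G{i}", [f"G{i}_a"], orthology, ["OG1"])
            for i in range(n_regulated)
        ]
        genomes = []
        for i in range(n_bearing):
            gid = f"G{i}"
            if i >= n_regulated:  # anchor-bearing but unregulated genome
                orthology.add(gid, f"{gid}_a", "OG1")
            genomes.append(make_genome([], genome_id=gid))
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        return crons[0], genomes

    def test_four_of_five(self, orthology):
        cron, genomes = self._cron_with_anchor(orthology, 4, 5)
        assert score_conservation(cron, genomes, orthology) == pytest.approx(0.8)

    def test_all_regulated_is_one(self, orthology):
        cron, genomes = self._cron_with_anchor(orthology, 5, 5)
        assert score_conservation(cron, genomes, orthology) == pytest.approx(1.0)

    def test_one_of_ten(self, orthology):
        cron, genomes = self._cron_with_anchor(orthology, 1, 10)
        assert score_conservation(cron, genomes, orthology) == pytest.approx(0.1)

    def test_bounds_and_monotonicity(self, orthology):
        for n_reg in range(1, 6):
            omap = OrthologyMap()
            cron, genomes = TestConservation._cron_with_anchor(
                self, omap, n_reg, 6
            )
            c = score_conservation(cron, genomes, omap)
            assert 0.0 <= c <= 1.0
            if n_reg > 1:
                omap_prev = OrthologyMap()
                prev, genomes_prev = TestConservation._cron_with_anchor(
                    self, omap_prev, n_reg - 1, 6
                )
                assert c >= score_conservation(prev, genomes_prev, omap_prev)


class TestAcceptance:
    def test_conserved_multi_genome_accepted(self, orthology, registry):
        ros = [
            make_regulated_operon(f"G{i}", [f"G{i}_a"], orthology, ["OG1"])
            for i in range(4)
        ]
        genomes = [make_genome([], genome_id=f"G{i}") for i in range(5)]
        orthology.add("G4", "G4_a", "OG1")
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        accept_crons(crons, genomes, orthology, registry)
        assert crons[0].accepted

    def test_low_conservation_low_score_rejected(self, orthology, registry):
        ros = [make_regulated_operon("G0", ["G0_a"], orthology, ["OG1"], score=40.0)]
        genomes = [make_genome([], genome_id=f"G{i}") for i in range(5)]
        for i in range(1, 5):
            orthology.add(f"G{i}", f"G{i}_a", "OG1")
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        accept_crons(crons, genomes, orthology, registry)
        assert not crons[0].accepted
        assert crons[0].reject_reason

    def test_single_genome_rescued_by_high_confidence_site(
        self, orthology, registry
    ):
        ros = [make_regulated_operon("G0", ["G0_a"], orthology, ["OG1"], score=85.0)]
        genomes = [make_genome([], genome_id="G0")]
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        accept_crons(crons, genomes, orthology, registry, min_genomes=2)
        assert crons[0].accepted


class TestExtension:
    def _community(self, support_count):
        """Four member genomes; G0 has a downstream gene at gap 250 whose
        ortholog group appears in ``support_count`` of the other three."""
        orthology = OrthologyMap()
        genomes = {}
        ros = []
        for i in range(4):
            gid = f"G{i}"
            genes = [make_gene(f"{gid}_a", 1000, 1400, genome_id=gid)]
            orthology.add(gid, f"{gid}_a", "OG_A")
            if i == 0:
                genes.append(make_gene(f"{gid}_x", 1651, 2000, genome_id=gid))
                orthology.add(gid, f"{gid}_x", "OG_X")
            elif i <= support_count:
                genes.append(make_gene(f"{gid}_x", 2401, 2800, genome_id=gid))
                orthology.add(gid, f"{gid}_x", "OG_X")
            genomes[gid] = make_genome(genes, genome_id=gid)
            member_genes = genomes[gid].genes_on("c1")
            member = [g for g in member_genes if g.gene_id != f"{gid}_a"]
            op_genes = [g for g in member_genes if g.gene_id == f"{gid}_a"]
            if i > 0 and member:
                op_genes = op_genes + member  # others already include OG_X
            operon = Operon(f"{gid}:op", gid, "c1", "+", op_genes)
            ros.append(
                RegulatedOperon(
                    operon=operon,
                    motif_id="RF00059",
                    sites=[make_site(f"s{gid}", 700, 800, genome_id=gid)],
                    site_to_start_distance=-200,
                )
            )
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        return crons[0], genomes, orthology

    def test_supported_downstream_gene_appended(self):
        cron, genomes, orthology = self._community(support_count=3)
        events = extend_operons(cron, genomes, orthology, extension_cap=300)
        g0 = next(ro for ro in cron.operons if ro.genome_id == "G0")
        assert [g.gene_id for g in g0.operon.genes] == ["G0_a", "G0_x"]
        assert events

    def test_unsupported_gene_not_appended(self):
        cron, genomes, orthology = self._community(support_count=1)
        extend_operons(cron, genomes, orthology, extension_cap=300)
        g0 = next(ro for ro in cron.operons if ro.genome_id == "G0")
        assert [g.gene_id for g in g0.operon.genes] == ["G0_a"]

    def test_cap_blocks_distant_gene(self):
        cron, genomes, orthology = self._community(support_count=3)
        extend_operons(cron, genomes, orthology, extension_cap=200)
        g0 = next(ro for ro in cron.operons if ro.genome_id == "G0")
        assert [g.gene_id for g in g0.operon.genes] == ["G0_a"]


class TestRegulogs:
    def test_totals(self, orthology):
        ros = []
        for i in range(3):
            ros.append(
                make_regulated_operon(
                    f"G{i}", [f"G{i}_a", f"G{i}_b"], orthology, ["OG1", "OG2"]
                )
            )
        for i in range(2):
            ros.append(
                make_regulated_operon(
                    f"G{i}", [f"G{i}_c"], orthology, ["OG3"], op_id=f"G{i}:c"
                )
            )
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        for c in crons:
            c.accepted = True
        regulogs = assemble_regulogs(crons)
        assert len(regulogs) == 1
        assert regulogs[0].total_genes == 3 * 2 + 2 * 1
        assert regulogs[0].total_sites == 5
        assert regulogs[0].genome_count == 3

    def test_rejected_crons_yield_no_regulog(self, orthology):
        ros = [make_regulated_operon("G0", ["G0_a"], orthology, ["OG1"])]
        crons = build_crons(regulons_of(ros), orthology, "tax1")
        for c in crons:
            c.accepted = False
        assert assemble_regulogs(crons) == []

    def test_tandem_counts_sites_individually_operon_once(self, orthology):
        ro = make_regulated_operon("G0", ["G0_a"], orthology, ["OG1"])
        ro.sites.append(
            make_site("s2", 550, 650, motif_id="RF00059", genome_id="G0")
        )
        crons = build_crons(regulons_of([ro]), orthology, "tax1")
        crons[0].accepted = True
        (regulog,) = assemble_regulogs(crons)
        assert regulog.total_sites == 2
        assert len(regulog.regulated_operons) == 1
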