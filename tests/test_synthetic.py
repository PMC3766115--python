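"""The synthetic community generator: determinism, planted-site
placement contracts, spurious-site safety, and T-box round trips."""

import json
import pathlib

import numpy as np
import pytest

from rnaregulon.assignment import assign_sites, deduplicate_hits
from rnaregulon.operons import infer_operons
from rnaregulon.simulate import (
    CODON_BY_AA,
    PlantedRegulonSpec,
    SimConfig,
    default_config,
    generate_community,
    generate_tbox_alignments,
    plant_regulons,
    simulate,
)
from rnaregulon.tbox import call_specificity


def small_config(seed=0, **overrides):
    base = dict(
        seed=seed,
        n_taxgroups=1,
        genomes_per_group=4,
        genes_per_genome=40,
        planted_regulons=[
            PlantedRegulonSpec(
                motif_id="RF00174", taxgroup_id="tax1", conservation=1.0,
                roles=("B12 biosynthesis",),
            )
        ],
        spurious_sites_per_genome=2,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestDeterminism:
    def test_identical_seed_byte_identical_bundle(self, tmp_path):
        simulate(default_config(11), tmp_path / "a")
        simulate(default_config(11), tmp_path / "b")
        for pa in sorted((tmp_path / "a").iterdir()):
            pb = tmp_path / "b" / pa.name
            assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_different_seed_differs(self, tmp_path):
        simulate(default_config(1), tmp_path / "a")
        simulate(default_config(2), tmp_path / "b")
        assert (tmp_path / "a" / "sites.tsv").read_text() != (
            tmp_path / "b" / "sites.tsv"
        ).read_text()


class TestCommunityLayout:
    def test_presence_probability_one_gives_full_orthologs(self):
        com = generate_community(small_config(presence_prob=1.0))
        sizes = {len(g.genes) for g in com.genomes.values()}
        assert len(sizes) == 1  # every genome realises the full template

    def test_genomes_share_ortholog_groups(self):
        com = generate_community(small_config())
        shared = set.intersection(
            *(
                {
                    com.orthology.group_of(gid, g.gene_id)
                    for g in com.genomes[gid].genes
                }
                for gid in com.genomes
            )
        )
        assert len(shared) > 10

    def test_small_gaps_force_single_operons(self):
        cfg = small_config(
            inter_operon_gap=(50, 150), planted_regulons=[], presence_prob=1.0
        )
        com = generate_community(cfg)
        for genome in com.genomes.values():
            ops = infer_operons(genome)
            strand_changes = sum(
                1
                for a, b in zip(genome.genes, genome.genes[1:])
                if a.strand != b.strand
            )
            assert len(ops) == strand_changes + 1


class TestPlantedSites:
    def test_full_conservation_sites_in_every_genome(self):
        com = generate_community(small_config())
        sites = plant_regulons(com)
        true_ids = set(com.ground_truth["planted_regulons"][0]["site_ids"])
        genomes_with_true = {
            s.genome_id for s in sites if s.site_id in true_ids
        }
        assert genomes_with_true == set(com.genomes)

    def test_planted_conservation_fraction(self):
        cfg = small_config()
        cfg.planted_regulons[0] = PlantedRegulonSpec(
            motif_id="RF00174", taxgroup_id="tax1", conservation=0.75,
        )
        com = generate_community(cfg)
        plant_regulons(com)
        truth = com.ground_truth["planted_regulons"][0]
        assert len(truth["genomes"]) == 3  # round(0.75 * 4)

    def test_tandem_probability_one_pairs_every_operon(self):
        cfg = small_config()
        cfg.planted_regulons[0] = PlantedRegulonSpec(
            motif_id="RF00504", taxgroup_id="tax1", conservation=1.0,
            tandem_prob=1.0,
        )
        com = generate_community(cfg)
        sites = plant_regulons(com)
        truth = com.ground_truth["planted_regulons"][0]
        assert len(truth["site_ids"]) == 2 * len(truth["genomes"])

    def test_true_sites_assign_to_planted_operon(self):
        com = generate_community(small_config())
        sites = plant_regulons(com)
        truth = com.ground_truth["planted_regulons"][0]
        for genome_id in truth["genomes"]:
            genome = com.genomes[genome_id]
            ops = infer_operons(genome)
            genome_sites = [
                s for s in sites
                if s.genome_id == genome_id and s.site_id in set(truth["site_ids"])
            ]
            res = assign_sites(deduplicate_hits(genome_sites), ops)
            leaders = {
                ro.operon.leader_anchor.gene_id for ro in res.regulated_operons
            }
            assert leaders == {truth["operons"][genome_id][0]}

    def test_spurious_sites_never_assigned(self):
        # noise-only configuration: every emitted site must be an orphan
        cfg = small_config(planted_regulons=[], spurious_sites_per_genome=4)
        cfg2 = SimConfig(**{**cfg.__dict__, "planted_regulons": [
            PlantedRegulonSpec(motif_id="RF00174", taxgroup_id="tax1",
                               conservation=0.0)
        ]})
        com = generate_community(cfg2)
        sites = plant_regulons(com)
        assert sites  # spurious sites exist
        assert all(s.site_id in set(com.ground_truth["spurious_site_ids"])
                   for s in sites)
        for genome_id, genome in com.genomes.items():
            ops = infer_operons(genome)
            res = assign_sites(
                deduplicate_hits([s for s in sites if s.genome_id == genome_id]),
                ops,
            )
            assert res.regulated_operons == []

    def test_true_and_spurious_ids_disjoint(self):
        com = generate_community(small_config())
        plant_regulons(com)
        true_ids = {
            sid
            for reg in com.ground_truth["planted_regulons"]
            for sid in reg["site_ids"]
        }
        assert true_ids.isdisjoint(com.ground_truth["spurious_site_ids"])


class TestTboxAlignments:
    def _community_with_tboxes(self, specificities):
        planted = [
            PlantedRegulonSpec(
                motif_id="RF00230", taxgroup_id="tax1", conservation=1.0,
                specificity=aa,
            )
            for aa in specificities
        ]
        cfg = small_config(
            planted_regulons=planted,
            genes_per_genome=max(60, 4 * len(planted)),
            genomes_per_group=2,
        )
        com = generate_community(cfg)
        plant_regulons(com)
        return com

    def test_planted_codon_round_trip(self):
        com = self._community_with_tboxes(["Met"])
        aln = generate_tbox_alignments(com)
        calls = {c.site_id: c for c in call_specificity(aln)}
        for sid, aa in com.ground_truth["tbox_specificities"].items():
            assert calls[sid].codon == "AUG"
            assert calls[sid].specificity_group == "Met"

    def test_all_twenty_specificities_recovered(self):
        groups = sorted(CODON_BY_AA)
        com = self._community_with_tboxes(groups)
        aln = generate_tbox_alignments(com)
        calls = {c.site_id: c for c in call_specificity(aln)}
        recovered = {
            calls[sid].specificity_group
            for sid in com.ground_truth["tbox_specificities"]
        }
        assert recovered == set(groups)

    def test_statistical_conservation_matches_configuration(self):
        # empirical planted conservation over many seeds stays inside
        # binomial 95% bounds around the configured value
        from scipy import stats as sps

        conservation, n_genomes, n_seeds = 0.75, 4, 40
        hits = 0
        for seed in range(n_seeds):
            cfg = small_config(seed=seed)
            cfg.planted_regulons[0] = PlantedRegulonSpec(
                motif_id="RF00174", taxgroup_id="tax1",
                conservation=conservation,
            )
            com = generate_community(cfg)
            plant_regulons(com)
            hits += len(com.ground_truth["planted_regulons"][0]["genomes"])
        total = n_seeds * n_genomes
        lo, hi = sps.binom.interval(0.95, total, conservation)
        assert lo <= hits <= hi
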