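"""Conserved regions, candidate calling, curation, class assignment, stats."""

import itertools

import pytest

from conftest import make_genome
from viramg import amg as vamg
from viramg.io import PUTATIVE
from viramg.pipeline import analyze_community
from viramg.simulate import SimulationConfig, simulate_community

V = "viral_like"
H = "viral_hallmark"
N = "nonviral"


def categories(genome):
    return [g.gene_category for g in genome.genes()]


class TestConservedRegions:
    @pytest.mark.parametrize(
        "cats,expected",
        [
            ([V, N, V], [(0, 2)]),
            ([N, V, V], [(1, 2)]),
            ([N, N], []),
            ([V, N, N], []),            # single viral gene: no region
            ([N, V, N, V, N, H], [(1, 5)]),  # maximal span, hallmark counts
        ],
    )
    def test_region_extent_per_contig(self, cats, expected):
        genome = make_genome([(c, "x") for c in cats])
        regions = vamg.find_conserved_regions(genome)
        assert [(r.first_gene_index, r.last_gene_index) for r in regions] == expected


class TestCandidateCalling:
    def oracle(self, cats, labels):
        """Enumerate candidates by the written rule, independently."""
        viral = [i for i, c in enumerate(cats) if c in (V, H)]
        if len(viral) < 2:
            return []
        lo, hi = viral[0], viral[-1]
        return [
            i
            for i in range(lo + 1, hi)
            if cats[i] == N and labels[i] != PUTATIVE
        ]

    @pytest.mark.parametrize(
        "cats,labels,n_expected",
        [
            ([V, N, V], ["x", "enolase", "x"], 1),
            ([V, N, V], ["x", PUTATIVE, "x"], 0),
            ([N, V, V], ["enolase", "x", "x"], 0),  # outside the region
        ],
    )
    def test_spec_examples(self, cats, labels, n_expected):
        genome = make_genome(list(zip(cats, labels)))
        regions = vamg.find_conserved_regions(genome)
        assert len(vamg.call_candidate_amgs(genome, regions)) == n_expected

    def test_exhaustive_three_gene_enumeration_matches_oracle(self):
        labels_pool = ["enolase", PUTATIVE]
        for cats in itertools.product([V, N], repeat=3):
            for labels in itertools.product(labels_pool, repeat=3):
                genome = make_genome(list(zip(cats, labels)))
                regions = vamg.find_conserved_regions(genome)
                got = vamg.call_candidate_amgs(genome, regions)
                want = self.oracle(list(cats), list(labels))
                assert [c.gene_id for c in got] == [
                    f"vOTU_T_g{i:03d}" for i in want
                ], (cats, labels)

    def test_immediate_flanking_mode_is_stricter(self):
        genome = make_genome(
            [(V, "x"), (N, "enolase"), (N, "hexokinase"), (V, "x")]
        )
        regions = vamg.find_conserved_regions(genome)
        span = vamg.call_candidate_amgs(genome, regions, flanking="span")
        immediate = vamg.call_candidate_amgs(genome, regions, flanking="immediate")
        assert len(span) == 2
        assert immediate == []  # neither interior gene has viral genes on both sides


class TestCuration:
    def _call(self, label, ko=""):
        return vamg.AMGCall(gene_id="g", votu_id="v", ko_id=ko, functional_label=label)

    @pytest.mark.parametrize(
        "label,ko,reason",
        [
            ("uncharacterized protein", "K00560", "nucleotide_metabolism"),  # KO arm
            ("ribosomal protein L31", "", "ribosomal_proteins"),
            ("DNA polymerase I", "", "dna_related_reactions"),
            ("glycosyltransferase family 2 protein", "", "viral_component_modification"),
        ],
    )
    def test_blacklisted_candidates_removed_with_first_matching_reason(
        self, label, ko, reason
    ):
        out = vamg.curate_amgs([self._call(label, ko)])
        assert out[0].curation_status == "removed"
        assert out[0].removal_reason == reason

    def test_legitimate_amgs_retained(self):
        for label, ko in [("glutamine synthetase", "K01915"),
                          ("chaperonin GroEL", "K04077")]:
            out = vamg.curate_amgs([self._call(label, ko)])
            assert out[0].curation_status == "retained"
            assert out[0].removal_reason == ""

    def test_idempotent_and_partition_preserving(self):
        calls = [
            self._call("glutamine synthetase", "K01915"),
            self._call("DNA polymerase I"),
            self._call("enolase", "K01689"),
        ]
        once = vamg.curate_amgs(calls)
        assert vamg.curate_amgs(once) == once
        assert [c.gene_id for c in once] == [c.gene_id for c in calls]
        n_ret = sum(c.curation_status == "retained" for c in once)
        n_rem = sum(c.curation_status == "removed" for c in once)
        assert n_ret + n_rem == len(calls)


class TestClassAssignment:
    def test_metabolism_pathway_gives_class_one(self):
        pmap = vamg.PathwayMap.default()
        call = vamg.AMGCall("g", "v", "K01915", "glutamine synthetase")
        assert vamg.assign_amg_class(call, pmap).amg_class == "I"

    def test_non_metabolism_and_unmapped_default_to_class_two(self):
        pmap = vamg.PathwayMap.default()
        tcs = vamg.AMGCall("g", "v", "K07636", "sensor kinase PhoR")
        assert vamg.assign_amg_class(tcs, pmap).amg_class == "II"
        unmapped = vamg.AMGCall("g", "v", "K99999", "mystery enzyme")
        assigned = vamg.assign_amg_class(unmapped, pmap)
        assert assigned.amg_class == "II" and assigned.pathways == frozenset()

    def test_multi_pathway_ko_with_any_metabolism_is_class_one(self):
        pmap = vamg.PathwayMap(
            ko_to_pathways={"K1": frozenset({"p_met", "p_env"})},
            pathway_top_category={"p_met": "Metabolism",
                                  "p_env": "Environmental Information Processing"},
        )
        call = vamg.AMGCall("g", "v", "K1", "x")
        assert vamg.assign_amg_class(call, pmap).amg_class == "I"

    def test_every_retained_amg_gets_a_class(self, golden_community):
        genomes, _ = golden_community
        analysis = analyze_community(genomes)
        retained = analysis.retained_amgs
        assert retained
        assert all(c.amg_class in ("I", "II") for c in retained)
        n_one = sum(c.amg_class == "I" for c in retained)
        n_two = sum(c.amg_class == "II" for c in retained)
        assert n_one + n_two == len(retained)


class TestGenomeStats:
    def test_direct_formulas(self):
        genome = make_genome(
            [(N, "enolase")] * 5 + [(N, PUTATIVE)] * 10, length_bp=10_000
        )
        stats = vamg.genome_stats(genome, [])
        assert stats.gene_density == pytest.approx(1.5)
        assert stats.annotation_rate == pytest.approx(5 / 15)
        amgs = [vamg.AMGCall(f"vOTU_T_g{i:03d}", "vOTU_T", "", "enolase")
                for i in range(2)]
        assert vamg.genome_stats(genome, amgs).amg_ratio == pytest.approx(2 / 15)

    def test_all_putative_genome_has_zero_annotation_rate(self):
        genome = make_genome([(N, PUTATIVE)] * 4)
        assert vamg.genome_stats(genome, []).annotation_rate == 0.0

    def test_annotation_rate_filter_is_inclusive_at_threshold(self):
        half = make_genome([(N, "enolase"), (N, PUTATIVE)], votu="half")
        above = make_genome([(N, "enolase"), (N, "hexokinase"), (N, PUTATIVE)],
                            votu="above")
        stats = [vamg.genome_stats(half, []), vamg.genome_stats(above, [])]
        kept = vamg.filter_by_annotation_rate(stats, [half, above])
        assert [g.votu_id for g in kept] == ["above"]
        assert vamg.filter_by_annotation_rate([], [], 0.5) == []


class TestPlantedRecovery:
    def test_perfect_precision_and_recall_on_undegraded_community(self):
        genomes, truth = simulate_community(
            SimulationConfig(n_lytic=25, n_temperate=8, seed=41)
        )
        analysis = analyze_community(genomes)
        called = {c.gene_id for c in analysis.retained_amgs}
        planted = set(truth.amg_genes)
        assert called == planted

    def test_no_retained_amg_is_viral_or_outside_a_region(self, golden_community):
        genomes, _ = golden_community
        analysis = analyze_community(genomes)
        genes = {g.gene_id: g for genome in genomes for g in genome.genes()}
        regions = {
            genome.votu_id: {
                r.contig_id: (r.first_gene_index, r.last_gene_index)
                for r in vamg.find_conserved_regions(genome)
            }
            for genome in genomes
        }
        index_of = {
            g.gene_id: i
            for genome in genomes
            for contig in genome.contigs.values()
            for i, g in enumerate(contig)
        }
        for call in analysis.retained_amgs:
            gene = genes[call.gene_id]
            assert gene.gene_category == "nonviral"
            lo, hi = regions[call.votu_id][gene.contig_id]
            assert lo < index_of[call.gene_id] < hi
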