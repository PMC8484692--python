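"""Similarity edges, the two clustering strategies, KO labels, localization."""

import numpy as np
import pytest
from _oracles import sw_score
from conftest import partition_of, truth_partition

from strainspec.orthology import (
    Gene,
    SimilarityEdge,
    StrainGeneSet,
    align_stats,
    assign_ko,
    classify_localization,
    cluster_orthologs,
    make_aligner,
    pairwise_similarity,
)
from strainspec.simulate import PanGenomeSpec, PlantedDirective, simulate_pangenome

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_gene(seed: int, n_codons: int = 40) -> tuple[str, str]:
    rng = np.random.default_rng(seed)
    nt = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_codons * 3)])
    prot = "".join(np.array(list(AA))[rng.integers(0, 20, n_codons)])
    return nt, prot


def _stub_sets(n: int) -> list[StrainGeneSet]:
    nt, prot = _random_gene(42)
    return [
        StrainGeneSet(s, [Gene(1, f"{s}:g00001", nt, prot)])
        for s in [chr(ord("a") + i) for i in range(n)]
    ]


class TestAlignStats:
    def test_identical_proteins_full_identity_and_coverage(self):
        aligner = make_aligner()
        seq = "MKLVINSGQWPAYERTMKLVINSGQWPAYERT"
        ident, score, qcov, scov = align_stats(aligner, seq, seq)
        assert ident == 100.0 and qcov == 100.0 and scov == 100.0
        assert score == len(seq)

    def test_half_protein_coverage(self):
        aligner = make_aligner()
        rng = np.random.default_rng(2)
        full = "".join(np.array(list(AA))[rng.integers(0, 20, 100)])
        half = full[:50]
        _, _, qcov, scov = align_stats(aligner, full, half)
        assert qcov == 50.0 and scov == 100.0

    def test_random_proteins_low_identity(self):
        rng = np.random.default_rng(1)
        a = "".join(np.array(list(AA))[rng.integers(0, 20, 100)])
        b = "".join(np.array(list(AA))[rng.integers(0, 20, 100)])
        aligner = make_aligner()
        ident, score, _, _ = align_stats(aligner, a, b)
        assert ident < 40.0
        # the aligner's local score matches a plain Smith-Waterman oracle
        assert score == pytest.approx(sw_score(a, b))


class TestPairwiseSimilarity:
    def test_requires_two_nonempty_strains(self):
        with pytest.raises(ValueError):
            pairwise_similarity(_stub_sets(1))
        sets = _stub_sets(2)
        sets[0].genes = []
        with pytest.raises(ValueError):
            pairwise_similarity(sets)

    def test_self_pairs_excluded(self, small_edges):
        assert all(e.query[0] != e.subject[0] for e in small_edges)

    def test_homologs_found_across_strains(self, small_pangenome, small_edges):
        _, truth = small_pangenome
        found = {frozenset((e.query, e.subject)) for e in small_edges}
        for members in truth.og_membership.values():
            members = sorted(members)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    if members[i][0] != members[j][0]:
                        key_i = (members[i][0], members[i][1])
                        key_j = (members[j][0], members[j][1])
                        assert frozenset((key_i, key_j)) in found


class TestClustering:
    def test_identical_copies_cluster_together_both_methods(self):
        sets = _stub_sets(3)
        edges = pairwise_similarity(sets)
        for method in "AB":
            clus = cluster_orthologs(edges, sets, method)
            assert len(clus.groups) == 1
            assert len(next(iter(clus.groups.values()))) == 3

    def test_chain_merging_differs_between_methods(self):
        # a-b 97%, b-c 97%, a-c 60%: single linkage merges all three,
        # BBH keeps only mutual best pairs (a-b and b-c, a's best is b)
        sets = _stub_sets(3)
        universe = [(gs.strain_id, gs.genes[0].gene_id) for gs in sets]
        a, b, c = universe
        edges = [
            SimilarityEdge(a, b, 97.0, 97.0, 100.0, 100.0),
            SimilarityEdge(b, c, 97.0, 97.0, 100.0, 100.0),
            SimilarityEdge(a, c, 60.0, 60.0, 100.0, 100.0),
        ]
        clus_a = cluster_orthologs(edges, sets, "A", identity_threshold=95.0)
        assert len(clus_a.groups) == 1
        clus_b = cluster_orthologs(edges, sets, "B")
        # b's best is its first-considered top scorer; both a-b and b-c are
        # mutual best hits, so B also yields one component here — but the
        # low a-c edge is never a BBH edge
        merged = max(clus_b.groups.values(), key=len)
        assert frozenset((a, c)) not in {
            frozenset(p) for p in zip(sorted(merged), sorted(merged)[1:])
        }

    def test_disjoint_cliques_stay_separate(self):
        nt1, prot1 = _random_gene(7)
        nt2, prot2 = _random_gene(8)
        sets = [
            StrainGeneSet(s, [
                Gene(1, f"{s}:g00001", nt1, prot1),
                Gene(2, f"{s}:g00002", nt2, prot2),
            ])
            for s in ("a", "b")
        ]
        edges = pairwise_similarity(sets)
        for method in "AB":
            clus = cluster_orthologs(edges, sets, method)
            parts = {frozenset(m) for m in clus.groups.values()}
            assert parts == {
                frozenset({("a", "a:g00001"), ("b", "b:g00001")}),
                frozenset({("a", "a:g00002"), ("b", "b:g00002")}),
            }

    def test_unknown_method_rejected(self, small_pangenome, small_edges):
        genomes, _ = small_pangenome
        with pytest.raises(ValueError):
            cluster_orthologs(small_edges, genomes, "C")

    @pytest.mark.parametrize("method", ["A", "B"])
    def test_partition_property(self, small_pangenome, small_edges, method):
        genomes, _ = small_pangenome
        clus = cluster_orthologs(small_edges, genomes, method)
        assert clus.n_genes() == sum(len(g.genes) for g in genomes)

    @pytest.mark.parametrize("rate", [0.0, 0.005, 0.01])
    @pytest.mark.parametrize("method", ["A", "B"])
    def test_perfect_recovery_low_mutation(self, rate, method):
        spec = PanGenomeSpec(
            n_strains=4, core_size=6, accessory_size=5,
            planted_specific=[PlantedDirective(("Fp01", "Fp03"), 2)],
            mutation_rate=rate, seed=17,
        )
        genomes, truth = simulate_pangenome(spec)
        edges = pairwise_similarity(genomes)
        clus = cluster_orthologs(edges, genomes, method)
        assert partition_of(clus) == truth_partition(truth)

    def test_partition_invariant_under_strain_order(self, small_pangenome):
        genomes, _ = small_pangenome
        edges_fwd = pairwise_similarity(genomes)
        edges_rev = pairwise_similarity(genomes[::-1])
        for method in "AB":
            p1 = partition_of(cluster_orthologs(edges_fwd, genomes, method))
            p2 = partition_of(cluster_orthologs(edges_rev, genomes[::-1], method))
            assert p1 == p2

    def test_bbh_edges_subset_of_single_linkage_components(self, small_pangenome, small_edges):
        # at equal thresholds B never merges what A separates
        genomes, _ = small_pangenome
        clus_a = cluster_orthologs(small_edges, genomes, "A", identity_threshold=90.0)
        clus_b = cluster_orthologs(small_edges, genomes, "B")
        to_a = clus_a.gene_to_group()
        for members in clus_b.groups.values():
            assert len({to_a[m] for m in members}) == 1


class TestAssignKO:
    def test_best_hit_above_thresholds_assigned(self, small_pangenome):
        genomes, truth = small_pangenome
        from strainspec.simulate import truth_ko_reference
        ref = truth_ko_reference(genomes, truth)
        ann = assign_ko(genomes, ref)
        for key, true_ko in truth.ko_truth.items():
            assert ann.labels[key] == true_ko

    def test_identity_threshold_is_strict(self):
        # identity is matches over the shorter sequence: 40 matching
        # residues in a 100-mer is exactly 40.0 -> rejected (strict >),
        # 41 matches -> accepted
        ref = {"K00001": "M" * 100}
        gene40 = StrainGeneSet("a", [Gene(1, "a:g00001", "ATG" * 100, "M" * 40 + "D" * 60)])
        gene41 = StrainGeneSet("a", [Gene(1, "a:g00001", "ATG" * 100, "M" * 41 + "D" * 59)])
        kw = dict(min_score=10.0, min_coverage=30.0, min_shared_kmers=1)
        assert assign_ko([gene40], ref, **kw).labels[("a", "a:g00001")] is None
        assert assign_ko([gene41], ref, **kw).labels[("a", "a:g00001")] == "K00001"

    def test_dissimilar_reference_gives_no_label(self):
        rng = np.random.default_rng(3)
        prot = "".join(np.array(list(AA))[rng.integers(0, 20, 120)])
        other = "".join(np.array(list(AA))[rng.integers(0, 20, 120)])
        sets = [StrainGeneSet("a", [Gene(1, "a:g00001", "ATG" * 120, prot)])]
        ann = assign_ko(sets, {"K99999": other})
        assert ann.labels[("a", "a:g00001")] is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            assign_ko(_stub_sets(2), {})


class TestLocalization:
    def test_hydrophobic_window_in_charged_context_is_transmembrane(self):
        call = classify_localization("K" * 20 + "L" * 19 + "K" * 20)
        assert call.category == "transmembrane"
        assert call.n_predicted_helices == 1

    def test_all_lysine_is_intracellular(self):
        call = classify_localization("K" * 60)
        assert call.category == "intracellular"
        assert call.n_predicted_helices == 0

    def test_hydrophobic_n_terminus_without_helix_is_extracellular(self):
        # 10 hydrophobic residues up front, then a long charged tail, with no
        # 19-residue window clearing the cutoff
        call = classify_localization("L" * 10 + "K" * 50)
        assert call.category == "extracellular"

    def test_helix_count_matches_window_scan_oracle(self):
        from strainspec.orthology import KYTE_DOOLITTLE
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(np.array(list(AA))[rng.integers(0, 20, 150)])
            call = classify_localization(seq)
            vals = [KYTE_DOOLITTLE[a] for a in seq]
            hits = [np.mean(vals[i:i + 19]) > 1.6 for i in range(len(vals) - 18)]
            n = sum(1 for i, h in enumerate(hits) if h and (i == 0 or not hits[i - 1]))
            assert call.n_predicted_helices == n

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            classify_localization("MKL*")
        with pytest.raises(ValueError):
            classify_localization("")
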