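import math

import dendropy
import numpy as np
import pytest

from gatescan.coevolution import (
    DistanceMatrix,
    fitch_parsimony,
    mantel_congruence,
    nj_tree,
    patristic_matrix,
    poisson_distance,
    robinson_foulds,
    transfer_signal,
)
from gatescan.errors import InputError
from gatescan.evaluation import exhaustive_fitch, random_additive_matrix
from gatescan.io_formats import ProteinRecord, read_newick
from gatescan.synthetic_data import (
    EvolutionConfig,
    apply_transfers,
    child_rng,
    random_protein,
    simulate_gene_family,
)


def _tree(newick):
    return read_newick(newick, from_string=True)


class TestPoissonDistance:
    def test_identical_pair_is_zero(self):
        dm = poisson_distance(["MKLAV", "MKLAV"])
        assert dm.d[0, 1] == 0.0

    def test_closed_form_at_p_tenth(self):
        # 1 mismatch out of 10 -> d = -ln(0.9)
        a = "MKLAVWYHED"
        b = "MKLAVWYHEE"
        dm = poisson_distance([a, b])
        assert dm.d[0, 1] == pytest.approx(-math.log(0.9), abs=1e-12)

    def test_gapped_columns_excluded(self):
        dm = poisson_distance(["MK-AV", "MKLAV"])
        assert dm.d[0, 1] == 0.0

    def test_saturated_pair_capped_and_flagged(self):
        a = "A" * 20
        b = "C" * 20
        dm = poisson_distance([a, b])
        assert dm.d[0, 1] == pytest.approx(-math.log(0.05))
        assert dm.saturated[0, 1]

    def test_no_comparable_columns_error(self):
        with pytest.raises(InputError):
            poisson_distance(["M----", "-KLAV"])

    def test_zero_rate_family_all_zero(self):
        cfg = EvolutionConfig(n_taxa=6, sub_rate=0.0, seed=4)
        recs, _ = simulate_gene_family(cfg, "MKLAVWYHED" * 10)
        dm = poisson_distance(recs)
        assert np.all(dm.d == 0.0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["a", "b", "c"]
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, d))
        _, D = patristic_matrix(tree, labels)
        # (a+b-c)/2 style closed forms: la=3, lb=2, lc=6
        assert np.allclose(D, d)

    def test_additive_matrix_recovered_exactly(self):
        truth, dm = random_additive_matrix(6, seed=9)
        inferred = nj_tree(dm)
        rf, _ = robinson_foulds(inferred, truth)
        assert rf == 0
        _, D = patristic_matrix(inferred, dm.labels)
        assert np.allclose(D, dm.d, atol=1e-8)

    def test_label_order_invariance(self):
        truth, dm = random_additive_matrix(7, seed=12)
        perm = [3, 0, 6, 2, 5, 1, 4]
        labels2 = [dm.labels[i] for i in perm]
        d2 = dm.d[np.ix_(perm, perm)]
        t1 = nj_tree(dm)
        t2 = nj_tree(DistanceMatrix(labels2, d2))
        rf, _ = robinson_foulds(t1, t2)
        assert rf == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(InputError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))

    def test_recovers_topology_from_simulated_sequences(self):
        # NJ on Poisson-corrected distances recovers the generating
        # topology (RF = 0) in >= 95% of replicates at 16 taxa and
        # root-to-tip divergence 0.3 on a fixed balanced tree
        def balanced_newick(n, el):
            labels = [f"t{i:02d}" for i in range(n)]

            def build(ls):
                if len(ls) == 1:
                    return f"{ls[0]}:{el}"
                h = len(ls) // 2
                return f"({build(ls[:h])},{build(ls[h:])}):{el}"

            s = build(labels)
            return "(" + s[1: s.rfind(")") + 1] + ";"

        nwk = balanced_newick(16, 0.075)  # depth 4 * 0.075 = 0.3 subs/site
        recovered = 0
        for rep in range(100):
            cfg = EvolutionConfig(
                n_taxa=16, sub_rate=0.3, tree_newick=nwk, seed=3000 + rep
            )
            recs, truth = simulate_gene_family(
                cfg, random_protein(child_rng(rep, "njrec"), 300)
            )
            inferred = nj_tree(poisson_distance(recs))
            rf, _ = robinson_foulds(inferred, truth)
            recovered += rf == 0
        assert recovered >= 95

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        truth, dm = random_additive_matrix(8, seed=33)
        noisy = dm.d + 0.01 * np.abs(
            np.random.default_rng(0).normal(size=dm.d.shape)
        )
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        mine = nj_tree(DistanceMatrix(dm.labels, noisy))
        ref = skbio.tree.nj(
            skbio.DistanceMatrix(noisy, ids=dm.labels)
        )
        ref_dp = read_newick(str(ref).strip(), from_string=True)
        rf, _ = robinson_foulds(mine, ref_dp)
        assert rf == 0


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = _tree("((A,B),(C,D),E);")
        assert robinson_foulds(t, _tree("((A,B),(C,D),E);")) == (0, 0.0)

    def test_single_nni_distance_two(self):
        t1 = _tree("(((A,B),C),D,E);")
        t2 = _tree("(((A,C),B),D,E);")
        rf, _ = robinson_foulds(t1, t2)
        assert rf == 2

    def test_star_vs_binary(self):
        n = 6
        star = _tree("(A,B,C,D,E,F);")
        binary = _tree("((((A,B),C),(D,E)),F);")
        rf, rf_norm = robinson_foulds(star, binary)
        assert rf == n - 3
        assert rf_norm == 1.0

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(InputError):
            robinson_foulds(_tree("((A,B),C);"), _tree("((A,B),D);"))

    def test_metric_properties_on_random_trees(self):
        trees = [random_additive_matrix(7, seed=s)[0] for s in range(5)]
        # relabel all to a shared leaf set
        for i in range(5):
            for j in range(5):
                dij, _ = robinson_foulds(trees[i], trees[j])
                dji, _ = robinson_foulds(trees[j], trees[i])
                assert dij == dji
                assert (dij == 0) == (i == j) or dij >= 0
        for i, j, k in [(0, 1, 2), (1, 3, 4), (0, 2, 4)]:
            dij, _ = robinson_foulds(trees[i], trees[j])
            djk, _ = robinson_foulds(trees[j], trees[k])
            dik, _ = robinson_foulds(trees[i], trees[k])
            assert dik <= dij + djk

    def test_agrees_with_dendropy(self):
        import dendropy.calculate.treecompare as tc

        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data="(((A,B),C),(D,E),F);", schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data="(((A,C),B),(D,F),E);", schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        expected = tc.symmetric_difference(t1, t2)
        mine, _ = robinson_foulds(
            _tree("(((A,B),C),(D,E),F);"), _tree("(((A,C),B),(D,F),E);")
        )
        assert mine == expected


class TestMantel:
    def test_relabeled_copy_gives_r_one(self):
        truth, dm = random_additive_matrix(6, seed=2)
        t1 = nj_tree(dm)
        labels2 = [f"p_{l}" for l in dm.labels]
        t2 = nj_tree(DistanceMatrix(labels2, dm.d))
        pairs = list(zip(dm.labels, labels2))
        res = mantel_congruence(t1, t2, pairs, n_perm=99, seed=0)
        assert res.mantel_r == pytest.approx(1.0)
        assert res.rf == 0

    def test_constant_matrix_flagged(self):
        star = _tree("(A:1,B:1,C:1,D:1);")
        star2 = _tree("(pA:1,pB:1,pC:1,pD:1);")
        pairs = [("A", "pA"), ("B", "pB"), ("C", "pC"), ("D", "pD")]
        res = mantel_congruence(star, star2, pairs, n_perm=99, seed=0)
        assert res.degenerate
        assert res.p_mantel == 1.0

    def test_too_few_pairs_rejected(self):
        t = _tree("((A,B),C);")
        with pytest.raises(InputError):
            mantel_congruence(t, t, [("A", "A"), ("B", "B"), ("C", "C")])

    def test_p_value_resolution(self):
        truth, dm = random_additive_matrix(8, seed=5)
        t1 = nj_tree(dm)
        labels2 = [f"p_{l}" for l in dm.labels]
        t2 = nj_tree(DistanceMatrix(labels2, dm.d))
        pairs = list(zip(dm.labels, labels2))
        res = mantel_congruence(t1, t2, pairs, n_perm=999, seed=1)
        assert res.p_mantel >= 1.0 / 1000
        assert res.n_permutations == 999


class TestFitchParsimony:
    def test_uniform_labels_zero_changes(self):
        t = _tree("((a,b),(c,d));")
        assert fitch_parsimony(t, {k: "X" for k in "abcd"}) == 0

    def test_four_leaf_alternating(self):
        t = _tree("((a1,b1),(a2,b2));")
        labels = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        assert fitch_parsimony(t, labels) == 2

    def test_monophyletic_gives_vertical_minimum(self):
        t = _tree("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        labels = {l: l[0].upper() for l in ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"]}
        assert fitch_parsimony(t, labels) == 3  # k - 1 with k = 4

    def test_unlabeled_leaf_rejected(self):
        t = _tree("((a,b),c);")
        with pytest.raises(InputError):
            fitch_parsimony(t, {"a": "A", "b": "B"})

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        for s in range(15):
            truth, dm = random_additive_matrix(int(rng.integers(4, 8)), seed=100 + s)
            leaves = dm.labels
            labels = {l: f"L{int(rng.integers(0, 3))}" for l in leaves}
            labels[leaves[0]] = "L0"
            labels[leaves[1]] = "L1"
            assert fitch_parsimony(truth, labels) == exhaustive_fitch(truth, labels)


class TestTransferSignal:
    def test_monophyletic_labels_zero_excess(self):
        t = _tree("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        labels = {l: l[0].upper() for l in ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"]}
        sig = transfer_signal(t, labels, n_perm=99, seed=0)
        assert sig.excess == 0
        assert sig.observed_changes == sig.vertical_minimum == 3

    def test_single_label_degenerate(self):
        t = _tree("((a,b),c);")
        sig = transfer_signal(t, {k: "X" for k in "abc"}, n_perm=99, seed=0)
        assert sig.excess == 0 and sig.p_perm == 1.0

    def test_forced_cross_label_transfers_detected(self):
        # a label-monophyletic species tree; three cross-label leaf moves
        # should each add at least one extra label change
        detected = 0
        for rep in range(20):
            cfg = EvolutionConfig(n_taxa=16, sub_rate=0.2, seed=500 + rep)
            from gatescan.synthetic_data import sample_species_tree

            tree = sample_species_tree(cfg)
            leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
            labels = {l: f"S{i // 4}" for i, l in enumerate(leaves)}
            rng = child_rng(rep, "force")
            apply_transfers(tree, 3, rng, leaf_labels=labels, cross_label=True)
            sig = transfer_signal(tree, labels, n_perm=49, seed=rep)
            detected += sig.excess >= 3
        assert detected >= 18  # >= 90 percent

    def test_shuffled_labels_give_large_p(self):
        # after full label shuffling the observed count is typical of the
        # permutation null, so p should not be extreme
        ps = []
        for rep in range(20):
            truth, dm = random_additive_matrix(10, seed=900 + rep)
            rng = child_rng(rep, "shuffle")
            labs = list("AABBCCDDEE")
            rng.shuffle(labs)
            labels = dict(zip(dm.labels, labs))
            sig = transfer_signal(truth, labels, n_perm=99, seed=rep)
            ps.append(sig.p_perm)
        assert np.mean(ps) > 0.2
        assert min(ps) > 0.01
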