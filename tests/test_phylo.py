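import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from brute_oracles import exhaustive_loglik, exhaustive_posterior, random_additive_tree
from paleocds.phylo import (
    BASES,
    K2PModel,
    RootingError,
    SaturationError,
    SiteAlignment,
    ancestral_states,
    bootstrap_support,
    distance_matrix,
    estimate_kappa,
    k2p_distance,
    nj_tree,
    pruning_loglik,
    root_at_outgroup,
    tree_bipartitions,
)
from paleocds.simulate import evolve_on_tree, simulate_root_cds


def _seq_with_counts(n, ts, tv):
    """Pair of sequences of length n with exactly ts transitions and tv
    transversions (rest identical)."""
    a = ["A"] * n
    b = ["A"] * n
    for i in range(ts):
        b[i] = "G"  # A->G transition
    for i in range(ts, ts + tv):
        b[i] = "C"  # A->C transversion
    return "".join(a), "".join(b)


class TestK2PDistance:
    def test_identical_is_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_value(self):
        # P = 0.1, Q = 0.05 over 20 sites
        a, b = _seq_with_counts(20, 2, 1)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.9)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_saturation_error(self):
        a, b = _seq_with_counts(10, 0, 5)  # Q = 0.5
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_n_excluded_pairwise(self):
        assert k2p_distance("ACGTN", "ACGTA") == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_reduces_to_jukes_cantor_at_one_third_transitions(self, k):
        # with P = p/3 and Q = 2p/3 the K2P distance equals the JC distance
        n = 60
        a, b = _seq_with_counts(n, k, 2 * k)
        p = 3 * k / n
        d_jc = -0.75 * math.log(1 - 4 * p / 3)
        assert k2p_distance(a, b) == pytest.approx(d_jc, rel=1e-12)


class TestTransitionMatrix:
    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 8.0])
    @pytest.mark.parametrize("t", [0.0, 0.01, 0.3, 2.0])
    def test_rows_sum_to_one(self, kappa, t):
        P = K2PModel(kappa).transition_matrix(t)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert (P >= 0).all()

    def test_zero_time_is_identity(self):
        assert np.allclose(K2PModel(3.0).transition_matrix(0.0), np.eye(4))

    def test_matches_matrix_exponential(self):
        kappa, t = 3.5, 0.27
        beta = 1 / (kappa + 2)
        Q = np.full((4, 4), beta)
        for i, partner in enumerate([2, 3, 0, 1]):  # A<->G, C<->T
            Q[i, partner] = kappa * beta
            Q[i, i] = 0
            Q[i, i] = -Q[i].sum()
        assert np.allclose(K2PModel(kappa).transition_matrix(t), expm(Q * t))

    def test_branch_length_is_expected_substitutions(self):
        # 1 - p_same(t) ~ t for small t under the normalized rates
        P = K2PModel(4.0).transition_matrix(1e-6)
        assert 1 - P[0, 0] == pytest.approx(1e-6, rel=1e-3)

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            K2PModel(0.0)


class TestNeighborJoining:
    def test_exact_recovery_of_additive_four_taxon_tree(self):
        # distances from ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = nj_tree(D)
        assert tree_bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=labels, columns=labels, dtype=float
        )
        tree = nj_tree(D)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        # l_A = (3+4-5)/2 = 1, l_B = (3+5-4)/2 = 2, l_C = (4+5-3)/2 = 3
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3})

    def test_non_symmetric_rejected(self):
        D = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D)

    @pytest.mark.parametrize("n_taxa", [5, 6, 7])
    def test_recovers_random_additive_trees(self, n_taxa):
        for rep in range(5):
            rng = np.random.default_rng(100 * n_taxa + rep)
            true_tree, D = random_additive_tree(n_taxa, rng)
            est = nj_tree(D)
            assert tree_bipartitions(est) == tree_bipartitions(true_tree)

    def test_agrees_with_dendropy_nj_topology(self):
        rng = np.random.default_rng(42)
        _, D = random_additive_tree(6, rng)
        est = nj_tree(D)
        csv = "," + ",".join(D.columns) + "\n" + "\n".join(
            label + "," + ",".join(str(v) for v in D.loc[label]) for label in D.index
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        ref = pdm.nj_tree()
        ref_bips = {
            frozenset(side)
            for side in (
                frozenset(t.label for t in b.leafset_taxa(ref.taxon_namespace))
                for b in ref.encode_bipartitions()
            )
        }
        anchor = min(D.index)
        all_taxa = frozenset(D.index)
        canon = {
            frozenset(all_taxa - s) if anchor in s else s
            for s in ref_bips
            if 1 < len(s) < len(all_taxa) - 1
        }
        canon = {s for s in canon if 1 < len(s) < len(all_taxa) - 1}
        assert tree_bipartitions(est) == canon


class TestBootstrap:
    def test_diagnostic_sites_force_full_support(self):
        # two 2-taxon clades separated by 40 diagnostic columns out of 1000,
        # plus a private variant per clade member to keep terminal edges real
        base = ["A"] * 1000
        def variant(positions, alt):
            row = base.copy()
            for p in positions:
                row[p] = alt
            return "".join(row)

        rows = {
            "A": variant(range(40), "C"),
            "B": variant(list(range(40)) + [100], "C"),
            "C": variant([200], "G"),
            "D": variant([300], "G"),
        }
        aln = SiteAlignment.from_sequences(rows)
        res = bootstrap_support(aln, n_reps=50, seed=7)
        assert res.supports[frozenset({"C", "D"})] == 100.0

    def test_single_replicate_supports_binary(self):
        rows = {"A": "ACGTAC", "B": "ACGTAT", "C": "GCGAAC", "D": "GCGAAT"}
        res = bootstrap_support(SiteAlignment.from_sequences(rows), n_reps=1, seed=0)
        assert all(v in (0.0, 100.0) for v in res.supports.values())

    def test_identical_sequences_flagged_degenerate(self):
        rows = {"A": "ACGT", "B": "ACGT", "C": "ACGT"}
        res = bootstrap_support(SiteAlignment.from_sequences(rows), n_reps=2, seed=0)
        assert res.degenerate

    def test_reproducible_for_fixed_seed(self):
        rows = {
            "A": "ACGTACGTAA" * 10,
            "B": "ACTTACGTAA" * 10,
            "C": "ACGAACGTAA" * 10,
            "D": "ACGAACTTAA" * 10,
        }
        aln = SiteAlignment.from_sequences(rows)
        r1 = bootstrap_support(aln, n_reps=20, seed=3)
        r2 = bootstrap_support(aln, n_reps=20, seed=3)
        assert r1.supports == r2.supports


class TestPruningLikelihood:
    def test_two_leaves_same_base_closed_form(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.2);", schema="newick")
        aln = SiteAlignment(ids=("A", "B"), rows=("A", "A"))
        model = K2PModel(2.0)
        # by reversibility: 0.25 * p_same(t1 + t2)
        expected = math.log(0.25 * model.transition_matrix(0.3)[0, 0])
        assert pruning_loglik(tree, aln, model) == pytest.approx(expected, rel=1e-12)

    def test_zero_length_star_identical_leaves(self):
        tree = dendropy.Tree.get(data="(A:0,B:0,C:0);", schema="newick")
        aln = SiteAlignment(ids=("A", "B", "C"), rows=("ACG", "ACG", "ACG"))
        ll = pruning_loglik(tree, aln, K2PModel(2.0))
        assert ll == pytest.approx(3 * math.log(0.25), rel=1e-12)

    def test_matches_exhaustive_enumeration(self, four_leaf_tree, four_leaf_alignment):
        model = K2PModel(2.5)
        assert pruning_loglik(four_leaf_tree, four_leaf_alignment, model) == pytest.approx(
            exhaustive_loglik(four_leaf_tree, four_leaf_alignment, model), rel=1e-12
        )

    def test_matches_exhaustive_on_random_trees(self):
        rng = np.random.default_rng(5)
        for rep in range(10):
            nwk = "((A:{:.3f},B:{:.3f}):{:.3f},(C:{:.3f},D:{:.3f}):{:.3f});".format(
                *rng.uniform(0.01, 0.5, 6)
            )
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            rows = tuple(
                "".join(rng.choice(list("ACGTN"), p=[0.23] * 4 + [0.08], size=6))
                for _ in range(4)
            )
            aln = SiteAlignment(ids=("A", "B", "C", "D"), rows=rows)
            model = K2PModel(float(rng.uniform(0.5, 8)))
            assert pruning_loglik(tree, aln, model) == pytest.approx(
                exhaustive_loglik(tree, aln, model), rel=1e-10
            )

    def test_negative_branch_rejected(self):
        tree = dendropy.Tree.get(data="(A:-0.1,B:0.2);", schema="newick")
        aln = SiteAlignment(ids=("A", "B"), rows=("A", "A"))
        with pytest.raises(ValueError, match="negative"):
            pruning_loglik(tree, aln, K2PModel(2.0))


class TestAncestralStates:
    def test_posteriors_match_exhaustive_bayes(self, four_leaf_tree, four_leaf_alignment):
        model = K2PModel(2.5)
        rec = ancestral_states(four_leaf_tree, four_leaf_alignment, model)
        internal_nodes = [
            n for n in four_leaf_tree.preorder_node_iter() if not n.is_leaf()
        ]
        for node in internal_nodes:
            for site in range(four_leaf_alignment.n_sites):
                expected = exhaustive_posterior(
                    four_leaf_tree, four_leaf_alignment, model, node, site
                )
                assert np.allclose(rec.posteriors[node.label][site], expected)

    def test_posterior_sums_to_one(self, four_leaf_tree, four_leaf_alignment):
        rec = ancestral_states(four_leaf_tree, four_leaf_alignment, K2PModel(1.5))
        for post in rec.posteriors.values():
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_leaves_short_branches(self):
        tree = dendropy.Tree.get(
            data="((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);", schema="newick"
        )
        aln = SiteAlignment(ids=tuple("ABCD"), rows=("G",) * 4)
        rec = ancestral_states(tree, aln, K2PModel(2.0))
        for lbl, seq in rec.sequences.items():
            assert seq == "G"
            assert rec.posteriors[lbl][0, BASES.index("G")] >= 0.99

    def test_zero_length_branches_exact(self):
        tree = dendropy.Tree.get(data="((A:0,B:0):0,(C:0,D:0):0);", schema="newick")
        aln = SiteAlignment(ids=tuple("ABCD"), rows=("T",) * 4)
        rec = ancestral_states(tree, aln, K2PModel(2.0))
        assert all(seq == "T" for seq in rec.sequences.values())

    def test_unrooted_input_rejected(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1,C:0.1);", schema="newick")
        aln = SiteAlignment(ids=tuple("ABC"), rows=("A", "C", "G"))
        with pytest.raises(RootingError):
            ancestral_states(tree, aln, K2PModel(2.0))

    def test_ties_flagged_not_silent(self):
        # two leaves with different bases at zero distance: symmetric tie
        tree = dendropy.Tree.get(data="(A:0.0,B:0.0);", schema="newick")
        aln = SiteAlignment(ids=("A", "B"), rows=("N", "N"))
        rec = ancestral_states(tree, aln, K2PModel(2.0))
        (tie,) = rec.ties.values()
        assert tie[0]  # all-missing site: flat posterior, tie flagged


class TestRooting:
    def test_outgroup_rooting_bisects_terminal_edge(self):
        labels = ["A", "B", "C", "chimp"]
        D = pd.DataFrame(
            [[0, 2, 4, 8], [2, 0, 4, 8], [4, 4, 0, 8], [8, 8, 8, 0]],
            index=labels, columns=labels, dtype=float,
        )
        tree = root_at_outgroup(nj_tree(D), "chimp")
        root_children = tree.seed_node.child_nodes()
        assert len(root_children) == 2
        sides = [
            {l.taxon.label for l in c.leaf_iter()} for c in root_children
        ]
        assert {"chimp"} in sides

    def test_missing_outgroup(self):
        D = pd.DataFrame(
            [[0, 1, 2], [1, 0, 2], [2, 2, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError, match="gorilla"):
            root_at_outgroup(nj_tree(D), "gorilla")


class TestEstimateKappa:
    def test_degenerate_alignment_returns_default_with_warning(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        aln = SiteAlignment(ids=("A", "B"), rows=("ACGT", "ACGT"))
        with pytest.warns(UserWarning, match="no variation"):
            assert estimate_kappa(aln, tree) == 2.0

    def test_no_transversions_hits_upper_bound_flagged(self):
        tree = dendropy.Tree.get(data="(A:0.05,B:0.05);", schema="newick")
        rows = ("A" * 50 + "C" * 50, "G" * 5 + "A" * 45 + "T" * 5 + "C" * 45)
        aln = SiteAlignment(ids=("A", "B"), rows=rows)
        with pytest.warns(UserWarning, match="upper search bound"):
            estimate_kappa(aln, tree)

    def test_recovers_kappa_one(self):
        tree = dendropy.Tree.get(
            data="((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05);", schema="newick"
        )
        root = simulate_root_cds(1000, seed=8)
        leaves, _ = evolve_on_tree(root, tree, K2PModel(1.0), seed=9)
        est = estimate_kappa(SiteAlignment.from_sequences(leaves), tree)
        assert 0.7 <= est <= 1.4
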