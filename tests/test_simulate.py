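import dendropy
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from paleocds import seqio
from paleocds.consensus import apply_variants
from paleocds.phylo import K2PModel, SiteAlignment
from paleocds.simulate import (
    apply_catalog,
    apply_damage,
    emit_vcf,
    evolve_on_tree,
    make_glud1_like_cds,
    make_glud2_like_cds,
    simulate_expression,
    simulate_root_cds,
)
from paleocds.substitutions import (
    annotate_consequences,
    classify_transition,
    enumerate_substitutions,
    parse_c_notation,
)
from paleocds.tables import GLUD1_DENISOVAN, GLUD2_DENISOVAN, make_paper_fixture


class TestSimulateRootCds:
    def test_gdh_scale_translates_cleanly(self):
        cds = simulate_root_cds(559, seed=1)
        assert len(cds) == 1677
        protein = str(Seq(cds.seq).translate())
        assert protein.startswith("M") and protein.endswith("*")
        assert "*" not in protein[:-1]

    def test_fixed_seed_deterministic(self):
        assert simulate_root_cds(50, seed=9).seq == simulate_root_cds(50, seed=9).seq

    def test_minimal_length(self):
        cds = simulate_root_cds(2, seed=0)
        assert cds.seq.startswith("ATG") and len(cds) == 6
        assert cds.seq[3:] in ("TAA", "TAG", "TGA")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_root_cds(1, seed=0)


class TestEvolveOnTree:
    def test_zero_length_branches_copy_root(self):
        tree = dendropy.Tree.get(data="(A:0,B:0,C:0);", schema="newick")
        root = simulate_root_cds(100, seed=2)
        leaves, internals = evolve_on_tree(root, tree, K2PModel(2.0), seed=3)
        assert all(seq == root.seq for seq in leaves.values())
        assert internals["root"] == root.seq

    def test_divergence_matches_closed_form(self):
        t = 0.08
        tree = dendropy.Tree.get(data=f"(A:{t},B:0);", schema="newick")
        root = simulate_root_cds(3400, seed=4)  # ~10 kb
        model = K2PModel(4.0)
        leaves, _ = evolve_on_tree(root, tree, model, seed=5)
        p_diff = np.mean([a != b for a, b in zip(leaves["A"], root.seq)])
        expected = 1.0 - model.transition_matrix(t)[0, 0]
        n = len(root)
        assert abs(p_diff - expected) < 4 * np.sqrt(expected * (1 - expected) / n)

    def test_ts_tv_ratio_reflects_kappa(self):
        kappa = 6.0
        tree = dendropy.Tree.get(data="(A:0.05,B:0);", schema="newick")
        root = simulate_root_cds(5000, seed=6)
        leaves, _ = evolve_on_tree(root, tree, K2PModel(kappa), seed=7)
        scan = enumerate_substitutions(
            seqio.CodingSequence(id="A", seq=leaves["A"], is_cds=True),
            root,
        )
        ts = sum(1 for r in scan if r.transition_type != "NONE")
        tv = len(scan) - ts
        # per-site transition:transversion probability ratio is kappa/2
        assert 0.5 * kappa * 0.6 < ts / tv < 0.5 * kappa * 1.5


class TestApplyDamage:
    def test_zero_rates_unchanged(self):
        cds = simulate_root_cds(100, seed=8)
        damaged, truth = apply_damage(cds, 0.0, 0.0, seed=9)
        assert damaged.seq == cds.seq and truth == []

    def test_forced_ts1(self):
        cds = seqio.CodingSequence(id="x", seq="AT", is_cds=False)
        damaged, truth = apply_damage(cds, 0.999999, 0.0, seed=10)
        assert damaged.seq == "GC"
        assert [t.transition_type for t in truth] == ["TS1", "TS1"]

    def test_truth_events_classify_back_to_their_type(self):
        cds = simulate_root_cds(300, seed=11)
        _, truth = apply_damage(cds, 0.05, 0.05, seed=12)
        assert truth  # rates high enough to fire at this length
        for event in truth:
            assert classify_transition(event.ref_base, event.alt_base) == event.transition_type

    def test_invalid_rate(self):
        cds = simulate_root_cds(10, seed=0)
        with pytest.raises(ValueError):
            apply_damage(cds, 1.0, 0.0, seed=0)


class TestEmitVcf:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_through_consensus(self, strand, tmp_path):
        root = simulate_root_cds(120, seed=13)
        model = seqio.ExonModel("chr7", ((51, 170), (301, 540)), strand)
        assert model.exonic_length == len(root)
        damaged, truth = apply_damage(root, 0.02, 0.02, seed=14)
        path = tmp_path / "sample.vcf"
        emit_vcf(root, damaged, model, path, sample="den")
        calls = seqio.read_vcf(path)
        rebuilt = apply_variants(root, model, calls)
        assert rebuilt.seq == damaged.seq

    def test_identical_sequences_give_headers_only(self, tmp_path):
        root = simulate_root_cds(50, seed=15)
        model = seqio.ExonModel("chr7", ((1, 150),), "+")
        path = tmp_path / "empty.vcf"
        emit_vcf(root, root, model, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []


class TestSimulateExpression:
    def test_fixed_seed_deterministic(self):
        rho = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        m1 = simulate_expression(10, rho, seed=16)
        m2 = simulate_expression(10, rho, seed=16)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_non_psd_rejected(self):
        rho = pd.DataFrame(
            [[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_expression(10, rho, seed=17)

    def test_identity_target_gives_near_zero_rho(self):
        from paleocds.expression import spearman

        rho = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        m = simulate_expression(500, rho, seed=18)
        r, _ = spearman(m.values.loc["a"], m.values.loc["b"])
        assert abs(r) < 0.15

    def test_strong_pair_recovered(self):
        from paleocds.expression import spearman

        rho = pd.DataFrame(
            [[1, 0.99], [0.99, 1]], index=["a", "b"], columns=["a", "b"], dtype=float
        )
        m = simulate_expression(100, rho, seed=19)
        r, _ = spearman(m.values.loc["a"], m.values.loc["b"])
        assert r > 0.9

    def test_values_non_negative_tpm_like(self):
        rho = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        m = simulate_expression(20, rho, seed=20, n_samples_per_tissue=3)
        assert (m.values.values >= 0).all()
        assert len(m.tissues) == 60


class TestSurrogateCds:
    def test_glud2_catalog_consequences_reproduced(self, glud2_cds):
        records = [parse_c_notation(n) for n, _ in GLUD2_DENISOVAN]
        annotated = annotate_consequences(records, glud2_cds)
        got = {
            r.c_notation: r.consequence.p_notation for r in annotated
        }
        expected = {n: c for n, c in GLUD2_DENISOVAN}
        assert got == expected

    def test_glud1_transversion_synonymous(self, glud1_cds):
        rec = parse_c_notation("c.909A>C")
        (annotated,) = annotate_consequences([rec], glud1_cds)
        assert annotated.consequence.synonymous
        assert annotated.consequence.residue_index == 303
        assert annotated.consequence.ref_aa == "T"  # Thr303

    def test_catalog_applies_cleanly_to_both(self, glud1_cds, glud2_cds):
        den1 = apply_catalog(glud1_cds, GLUD1_DENISOVAN, "denisovan_glud1")
        den2 = apply_catalog(glud2_cds, GLUD2_DENISOVAN, "denisovan_glud2")
        assert len(enumerate_substitutions(den1, glud1_cds)) == 10
        assert len(enumerate_substitutions(den2, glud2_cds)) == 13

    def test_surrogates_translate_without_internal_stops(self, glud1_cds, glud2_cds):
        for cds, catalog in ((glud1_cds, GLUD1_DENISOVAN), (glud2_cds, GLUD2_DENISOVAN)):
            derived = apply_catalog(cds, catalog, "derived")
            for s in (cds, derived):
                protein = str(Seq(s.seq).translate())
                assert "*" not in protein[:-1] and protein.endswith("*")


class TestPaperFixture:
    def test_fixture_rows_and_signature_entries(self, tmp_path):
        paths = make_paper_fixture(tmp_path)
        t1 = seqio.read_tsv_substitutions(paths["glud1_denisovan"])
        t2 = seqio.read_tsv_substitutions(paths["glud2_denisovan"])
        assert len(t1) == 10 and len(t2) == 13
        assert any(r["substitution"] == "c.909A>C" for r in t1)
        assert any(r["substitution"] == "c.1492T>G" for r in t2)
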