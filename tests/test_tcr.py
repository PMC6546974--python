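"""TCR repertoire operations: UMI consensus, clones, sharing, clonality,
overlap, Jaccard trees and tree concordance."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mima import tcr
from mima.tcr import (
    Repertoire,
    classify_tcr_sharing,
    cd3_tcr_correlation,
    define_clones,
    gini_index,
    jaccard_matrix,
    jaccard_tree,
    overlap_coefficient,
    permutation_organ_test,
    remove_public,
    repertoires_from_frame,
    subsampled_clonality,
    umi_consensus,
)
from mima.trees import SampleTree, robinson_foulds, tree_concordance


def _rep(sample_id, clones):
    """clones: list of (v, j, cdr3_nt, count)."""
    rows = [
        {
            "chain": "beta",
            "v_call": v,
            "j_call": j,
            "cdr3_nt": nt,
            "cdr3_aa": nt[:3],
            "duplicate_count": n,
        }
        for v, j, nt, n in clones
    ]
    return Repertoire(sample_id, pd.DataFrame(rows))


class TestUmiConsensus:
    UMI = "TACGATGCATTGCAT"  # invalid length on purpose for negative test

    def test_identical_reads_collapse(self):
        umi = "TACGATGCATTGCATT"[:16]
        umi = "T" + "ACGA" + "T" + "GCAT" + "T" + "GCAT" + "T"
        out = umi_consensus([(umi, "AAACCC")] * 3)
        assert out == ["AAACCC"]

    def test_low_identity_group_discarded(self):
        umi = "T" + "ACGA" + "T" + "GCAT" + "T" + "GCAT" + "T"
        out = umi_consensus([(umi, "AAAAAAAAAA"), (umi, "AAATTTTTTT")])
        assert out == []  # 30% identity <= 80% certainty rule

    def test_template_violation_discarded(self):
        bad = "A" + "ACGA" + "T" + "GCAT" + "T" + "GCAT" + "T"
        assert umi_consensus([(bad, "AAAA")]) == []

    def test_majority_vote(self):
        umi = "T" + "ACGA" + "T" + "GCAT" + "T" + "GCAT" + "T"
        out = umi_consensus([(umi, "AAAA"), (umi, "AAAA"), (umi, "AAAT")])
        assert out == ["AAAA"]

    def test_empty_input(self):
        assert umi_consensus([]) == []


class TestDefineClones:
    def test_same_key_merges_counts(self):
        rep = _rep("s", [("V1", "J1", "TGTGCA", 3), ("V1", "J1", "TGTGCA", 2)])
        table = define_clones(rep)
        assert len(table) == 1 and table["size"].iloc[0] == 5

    def test_different_v_splits(self):
        rep = _rep("s", [("V1", "J1", "TGTGCA", 3), ("V2", "J1", "TGTGCA", 2)])
        assert len(define_clones(rep)) == 2

    def test_partition_conserves_reads(self, rng):
        clones = [
            (f"V{rng.integers(1, 4)}", f"J{rng.integers(1, 3)}",
             "TGT" + "".join(rng.choice(list("ACGT"), 9)), int(rng.integers(1, 50)))
            for _ in range(100)
        ]
        rep = _rep("s", clones)
        assert define_clones(rep)["size"].sum() == rep.total_reads


class TestRemovePublic:
    def _cohort(self):
        shared = ("V1", "J1", "TGTAAA", 5)
        return {
            "p1": {"p1-a": _rep("p1-a", [shared, ("V2", "J1", "TGTCCC", 3)])},
            "p2": {"p2-a": _rep("p2-a", [shared, ("V3", "J2", "TGTGGG", 4)])},
        }

    def test_cross_patient_clone_removed(self):
        out = remove_public(self._cohort())
        for patient in out.values():
            for rep in patient.values():
                assert "TGTAAA" not in set(rep.clonotypes["cdr3_nt"])

    def test_external_db_clone_removed(self):
        out = remove_public(self._cohort(), external_db=["beta|V2|J1|TGTCCC"])
        assert "TGTCCC" not in set(out["p1"]["p1-a"].clonotypes["cdr3_nt"])

    def test_patient_unique_clone_kept(self):
        out = remove_public(self._cohort())
        assert "TGTGGG" in set(out["p2"]["p2-a"].clonotypes["cdr3_nt"])


class TestSharing:
    def test_labels_by_presence(self):
        sites = {
            f"s{i}": _rep(f"s{i}", [("V1", "J1", "TGTAAA", 5)]) for i in range(6)
        }
        sites["s0"] = _rep("s0", [("V1", "J1", "TGTAAA", 5), ("V1", "J1", "TGTCCC", 2)])
        labels, fractions = classify_tcr_sharing(sites)
        by_nt = {k.split("|")[-1]: v for k, v in labels.items()}
        assert by_nt["TGTAAA"] == "stem"
        assert by_nt["TGTCCC"] == "private"
        assert np.allclose(fractions.sum(axis=1), 1.0)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            classify_tcr_sharing({"s": _rep("s", [("V1", "J1", "TGTAAA", 1)])})

    def test_ground_truth_recovered_on_cohort(self, small_cohort):
        for case in small_cohort.cases.values():
            for chain in ("alpha", "beta"):
                frame = case.clonotypes[case.clonotypes["chain"] == chain]
                reps = repertoires_from_frame(frame)
                labels, _ = classify_tcr_sharing(reps)
                truth = {k: v for k, v in case.tcr_truth.items() if k.startswith(chain)}
                assert labels == truth

    def test_stem_read_fraction_tracks_config(self, small_cohort):
        case = next(iter(small_cohort.cases.values()))
        frame = case.clonotypes[case.clonotypes["chain"] == "beta"]
        _, fractions = classify_tcr_sharing(repertoires_from_frame(frame))
        # stem clones are boosted in size, so their read share exceeds the
        # configured clone-count share
        assert fractions["stem"].mean() >= small_cohort.config.tcr_stem_fraction


class TestGini:
    def test_uniform_sizes_zero(self):
        assert gini_index([5, 5, 5, 5]) == pytest.approx(0.0)

    @pytest.mark.parametrize("sizes", [[999, 1], [1, 2, 3, 10], [7]])
    def test_matches_mean_absolute_difference_oracle(self, sizes):
        x = np.asarray(sizes, dtype=float)
        n, mean = len(x), x.mean()
        brute = sum(abs(a - b) for a in x for b in x) / (2 * n * n * mean)
        assert gini_index(sizes) == pytest.approx(brute)

    def test_random_oracle(self, rng):
        for _ in range(50):
            x = rng.integers(1, 500, size=rng.integers(2, 40)).astype(float)
            brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * len(x) ** 2 * x.mean())
            assert gini_index(x) == pytest.approx(brute)


class TestSubsampledClonality:
    def test_even_clones_have_zero_gini(self):
        rep = _rep("s", [("V1", "J1", f"TGT{i:03d}".replace("0", "A"), 10) for i in range(100)])
        # make cdr3s unique
        rep = _rep("s", [("V1", "J1", "TGT" + format(i, "09b").replace("0", "A").replace("1", "C"), 10)
                         for i in range(100)])
        out = subsampled_clonality(rep, depth=1000, repeats=5, seed=1)
        assert out["gini_vertex"] == pytest.approx(0.0)

    def test_lcs_read_percentage_dialect(self):
        clones = [("V1", "J1", "TGTAAAAAA", 150)]
        clones += [("V1", "J1", "TGT" + format(i, "09b").replace("0", "A").replace("1", "C"), 10)
                   for i in range(85)]
        rep = _rep("s", clones)  # exactly 1000 reads; depth == total -> exhaustive
        out = subsampled_clonality(rep, depth=1000, repeats=3, seed=1)
        assert out["lcs"] == pytest.approx(15.0)
        assert out["lcs_per_cluster"] == pytest.approx(100.0 * 150 / 86)

    def test_below_depth_rejected(self):
        rep = _rep("s", [("V1", "J1", "TGTAAA", 50)])
        with pytest.raises(ValueError, match="below|<|reads"):
            subsampled_clonality(rep, depth=1000)

    def test_stability_under_more_repeats(self, small_cohort):
        case = next(iter(small_cohort.cases.values()))
        frame = case.clonotypes[case.clonotypes["chain"] == "beta"]
        rep = repertoires_from_frame(frame)[case.sample_ids[0]]
        a = subsampled_clonality(rep, depth=100, repeats=20, seed=1)
        b = subsampled_clonality(rep, depth=100, repeats=40, seed=2)
        assert abs(a["gini_cluster"] - b["gini_cluster"]) < 0.05


class TestOverlap:
    def test_identical_repertoires(self):
        rep = _rep("a", [("V1", "J1", "TGTAAA", 10), ("V2", "J1", "TGTCCC", 5)])
        assert overlap_coefficient(rep, rep, depth=None) == pytest.approx(1.0)

    def test_disjoint_repertoires(self):
        a = _rep("a", [("V1", "J1", "TGTAAA", 10)])
        b = _rep("b", [("V2", "J2", "TGTCCC", 10)])
        assert overlap_coefficient(a, b, depth=None) == 0.0

    def test_printed_formula(self):
        # C_i = 10, C_j = 30, C_ij = 5 -> O = 5 / 20 = 0.25
        def clones(n, prefix, start=0):
            return [(f"V{prefix}{i}", "J1", f"TGT{prefix}{i}", 2) for i in range(start, start + n)]

        shared = [(f"VS{i}", "J1", f"TGTS{i}", 2) for i in range(5)]
        a = _rep("a", shared + clones(5, "A"))
        b = _rep("b", shared + clones(25, "B"))
        assert overlap_coefficient(a, b, depth=None) == pytest.approx(0.25)

    def test_symmetric_and_bounded(self, small_cohort):
        case = next(iter(small_cohort.cases.values()))
        frame = case.clonotypes[case.clonotypes["chain"] == "beta"]
        reps = repertoires_from_frame(frame)
        ids = case.sample_ids[:3]
        for a, b in combinations(ids, 2):
            o_ab = overlap_coefficient(reps[a], reps[b], depth=100, repeats=5, seed=3)
            o_ba = overlap_coefficient(reps[b], reps[a], depth=100, repeats=5, seed=3)
            assert 0.0 <= o_ab <= 1.0
            assert abs(o_ab - o_ba) < 0.1  # same seed, independent draws


class TestJaccard:
    def _reps(self, sets):
        out = {}
        for sid, aas in sets.items():
            rows = [
                {"chain": "beta", "v_call": "V1", "j_call": "J1",
                 "cdr3_nt": "TGT" + aa, "cdr3_aa": aa, "duplicate_count": 2}
                for aa in aas
            ]
            out[sid] = Repertoire(sid, pd.DataFrame(rows))
        return out

    def test_identical_sets(self):
        reps = self._reps({"a": ["CAS"], "b": ["CAS"]})
        assert jaccard_matrix(reps).at["a", "b"] == 1.0

    def test_half_overlap(self):
        reps = self._reps({"a": ["A", "B", "C"], "b": ["B", "C", "D"]})
        assert jaccard_matrix(reps).at["a", "b"] == pytest.approx(0.5)

    def test_triangle_inequality_of_distance(self, rng):
        universe = [f"A{i}" for i in range(30)]
        sets = {
            f"s{k}": list(rng.choice(universe, size=rng.integers(5, 20), replace=False))
            for k in range(5)
        }
        mat = jaccard_matrix(self._reps(sets))
        d = 1.0 - mat
        ids = list(d.index)
        for a, b, c in combinations(ids, 3):
            assert d.at[a, c] <= d.at[a, b] + d.at[b, c] + 1e-12

    def test_identical_repertoires_tree_has_zero_cophenetic_distances(self):
        reps = self._reps({f"s{i}": ["X", "Y", "Z"] for i in range(4)})
        _, tree = jaccard_tree(reps)
        dist = tree.path_distances()
        assert np.allclose(dist.to_numpy(), 0.0)

    def test_fewer_than_three_samples_matrix_only(self):
        reps = self._reps({"a": ["X"], "b": ["Y"]})
        mat, tree = jaccard_tree(reps)
        assert tree is None and mat.shape == (2, 2)


class TestTreeConcordance:
    NEWICK = "((a:1,b:2):3,(c:1,(d:2,e:1):2):1);"

    def test_self_concordance(self):
        t = SampleTree.from_newick(self.NEWICK)
        res = tree_concordance(t, t, n_perm=50, seed=1)
        assert res.cophenetic_r == pytest.approx(1.0)
        assert res.rf_distance == 0
        assert res.p_value < 0.05

    def test_path_sums_match_networkx_shortest_paths(self):
        t = SampleTree.from_newick(self.NEWICK)
        g = nx.Graph()
        for edge in t.tree.preorder_edge_iter():
            if edge.head_node is None or edge.tail_node is None:
                continue
            g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0)
        leaf_node = {leaf.taxon.label: id(leaf) for leaf in t.tree.leaf_node_iter()}
        dist = t.path_distances()
        for a, b in combinations(sorted(leaf_node), 2):
            sp = nx.shortest_path_length(g, leaf_node[a], leaf_node[b], weight="weight")
            assert dist.at[a, b] == pytest.approx(sp)

    def test_rf_matches_bipartition_enumeration(self):
        caterpillar = SampleTree.from_newick("(((((a:1,b:1):1,c:1):1,d:1):1,e:1):1,f:1);")
        balanced = SampleTree.from_newick("((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);")

        def splits(tree):
            leaves = frozenset(tree.leaves)
            out = set()
            for node in tree.tree.preorder_node_iter():
                if node.parent_node is None or node.is_leaf():
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 1 < len(side) < len(leaves) - 1:
                    out.add(min(side, leaves - side, key=sorted))
            return out

        expected = len(splits(caterpillar) ^ splits(balanced))
        assert robinson_foulds(caterpillar, balanced) == expected == 2

    def test_too_few_shared_leaves_rejected(self):
        a = SampleTree.from_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            tree_concordance(a, a, n_perm=10)


class TestOrganTest:
    def test_structured_cohort_is_significant(self, small_cohort):
        case = max(small_cohort.cases.values(), key=lambda c: len(c.sample_ids))
        frame = case.clonotypes[case.clonotypes["chain"] == "beta"]
        reps = repertoires_from_frame(frame)
        res = permutation_organ_test(reps, case.organs, n_perm=50, seed=4)
        assert len(res.null_cophenetic) == 50
        assert res.p_cophenetic <= 0.05

    def test_requires_two_organs(self, small_cohort):
        case = next(iter(small_cohort.cases.values()))
        frame = case.clonotypes[case.clonotypes["chain"] == "beta"]
        reps = repertoires_from_frame(frame)
        with pytest.raises(ValueError):
            permutation_organ_test(reps, {s: "liver" for s in case.sample_ids}, n_perm=5)


class TestCd3Correlation:
    def test_perfectly_proportional(self):
        reads = [100, 1000, 10000, 300]
        reps = {
            f"s{i}": _rep(f"s{i}", [("V1", "J1", f"TGTA{i}", r)]) for i, r in enumerate(reads)
        }
        expr = pd.DataFrame(
            {f"s{i}": [r / 40.0] * 4 for i, r in enumerate(reads)},
            index=["CD3D", "CD3G", "CD3E", "CD247"],
        )
        r, p = cd3_tcr_correlation(expr, reps)
        assert r == pytest.approx(1.0)

    def test_independent_data_uncorrelated(self, rng):
        n = 100
        reps = {
            f"s{i}": _rep(f"s{i}", [("V1", "J1", f"TGTA{i}", int(rng.integers(50, 5000)))])
            for i in range(n)
        }
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(4, n)),
            index=["CD3D", "CD3G", "CD3E", "CD247"],
            columns=[f"s{i}" for i in range(n)],
        )
        r, _ = cd3_tcr_correlation(expr, reps)
        assert abs(r) < 0.3

    def test_sample_order_invariant(self, small_cohort):
        case = next(iter(small_cohort.cases.values()))
        reps = {
            s: Repertoire(s, g.drop(columns="sample_id"))
            for s, g in case.clonotypes.groupby("sample_id")
        }
        r1, _ = cd3_tcr_correlation(small_cohort.expression, reps)
        reversed_reps = dict(reversed(list(reps.items())))
        r2, _ = cd3_tcr_correlation(small_cohort.expression, reversed_reps)
        assert r1 == pytest.approx(r2)
        assert r1 > 0.5  # generator couples CD3 TPM to repertoire size
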