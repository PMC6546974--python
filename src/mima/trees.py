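"""Edge-weighted sample trees and tree-comparison statistics.

Trees over sample labels (genomic phylogenies, TCR-similarity dendrograms)
are compared by (i) the edge-weighted cophenetic statistic — the distance
between two leaves is the sum of edge weights along the path connecting them
— and (ii) the Robinson-Foulds bipartition distance on the shared-leaf
topologies, with permutation p-values from leaf-label randomization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage


class SampleTree:
    """An edge-weighted tree whose leaves are sample labels."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("edge weights must be non-negative")
        self.leaves = sorted(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "SampleTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_linkage(cls, Z: np.ndarray, labels: list[str]) -> "SampleTree":
        """Build a tree from a scipy linkage matrix; edge weights are merge-height
        differences, so leaf-pair path sums equal twice the cophenetic height."""
        n = len(labels)
        height = {i: 0.0 for i in range(n)}
        newick = {i: _quote(labels[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(Z):
            a, b = int(a), int(b)
            node = n + k
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
            height[node] = h
        return cls.from_newick(newick[n + len(Z) - 1] + ";")

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def path_distances(self, leaves: list[str] | None = None) -> pd.DataFrame:
        """All-pairs path-sum (patristic) distances over the given leaves."""
        leaves = sorted(leaves) if leaves is not None else self.leaves
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        out = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for a, b in combinations(leaves, 2):
            d = pdm.patristic_distance(taxa[a], taxa[b])
            out.at[a, b] = out.at[b, a] = d
        return out


def _quote(label: str) -> str:
    return f"'{label}'" if any(c in label for c in " (),:;") else label


def pair_vector(dist: pd.DataFrame, leaves: list[str]) -> np.ndarray:
    return np.array([dist.at[a, b] for a, b in combinations(sorted(leaves), 2)])


def cophenetic_correlation(tree_a: SampleTree, tree_b: SampleTree) -> float:
    """Pearson correlation of leaf-pair path-sum distance vectors (shared leaves)."""
    shared = sorted(set(tree_a.leaves) & set(tree_b.leaves))
    va = pair_vector(tree_a.path_distances(shared), shared)
    vb = pair_vector(tree_b.path_distances(shared), shared)
    return float(stats.pearsonr(va, vb).statistic)


def robinson_foulds(tree_a: SampleTree, tree_b: SampleTree) -> int:
    """Unrooted symmetric bipartition difference on the shared-leaf topologies."""
    shared = set(tree_a.leaves) & set(tree_b.leaves)
    if len(shared) < 4:
        raise ValueError("Robinson-Foulds needs >= 4 shared leaves")
    ns = dendropy.TaxonNamespace()
    pruned = []
    for t in (tree_a, tree_b):
        clone = dendropy.Tree.get(data=t.to_newick(), schema="newick", taxon_namespace=ns)
        clone.retain_taxa_with_labels(sorted(shared))
        clone.encode_bipartitions()
        pruned.append(clone)
    return int(dendropy.calculate.treecompare.symmetric_difference(*pruned))


@dataclass
class TreeConcordance:
    cophenetic_r: float
    rf_distance: int
    p_value: float
    null_r: np.ndarray


def tree_concordance(
    tree_a: SampleTree,
    tree_b: SampleTree,
    n_perm: int = 1000,
    seed: int = 0,
) -> TreeConcordance:
    """Concordance of two sample trees on their shared leaves.

    The p-value permutes the leaf labels of one tree's distance matrix and
    counts null cophenetic correlations at least as large as the observed
    one (pseudo-counted).
    """
    shared = sorted(set(tree_a.leaves) & set(tree_b.leaves))
    if len(shared) < 4:
        raise ValueError("tree concordance needs >= 4 shared leaves")
    da = tree_a.path_distances(shared)
    db = tree_b.path_distances(shared)
    va = pair_vector(da, shared)
    vb = pair_vector(db, shared)
    observed = float(stats.pearsonr(va, vb).statistic)
    rf = robinson_foulds(tree_a, tree_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    mat_b = db.loc[shared, shared].to_numpy()
    for i in range(n_perm):
        perm = rng.permutation(len(shared))
        permuted = mat_b[np.ix_(perm, perm)]
        vp = permuted[np.triu_indices(len(shared), k=1)]
        null[i] = stats.pearsonr(va, vp).statistic
    p = (np.sum(null >= observed) + 1) / (n_perm + 1)
    return TreeConcordance(observed, rf, float(p), null)


def organ_reference_tree(organs: dict[str, str]) -> SampleTree:
    """A polytomy tree grouping samples by organ (unit edge weights)."""
    groups: dict[str, list[str]] = {}
    for sid, organ in organs.items():
        groups.setdefault(organ, []).append(sid)
    parts = []
    for organ in sorted(groups):
        members = sorted(groups[organ])
        if len(members) == 1:
            parts.append(f"{_quote(members[0])}:2")
        else:
            parts.append("(" + ",".join(f"{_quote(s)}:1" for s in members) + "):1")
    return SampleTree.from_newick("(" + ",".join(parts) + ");")


def complete_linkage_tree(distance: pd.DataFrame) -> SampleTree:
    """Agglomerative complete-linkage tree from a symmetric distance matrix.

    Labels are sorted lexicographically first so that merge tie-breaking is
    reproducible.
    """
    labels = sorted(distance.index)
    mat = distance.loc[labels, labels].to_numpy()
    condensed = mat[np.triu_indices(len(labels), k=1)]
    Z = linkage(condensed, method="complete")
    return SampleTree.from_linkage(Z, labels)
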