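"""TCR repertoire analysis: UMI consensus, clone definition, public-TCR
removal, stem/clade/private sharing, subsampled clonality metrics, overlap
coefficients, CDR3 Jaccard trees and organ/genomic-tree concordance."""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import (
    SampleTree,
    complete_linkage_tree,
    cophenetic_correlation,
    organ_reference_tree,
    pair_vector,
    robinson_foulds,
)

log = logging.getLogger(__name__)

UMI_TEMPLATE = "TNNNNTNNNNTNNNNT"
UMI_MIN_IDENTITY = 0.80
CLONOTYPE_COLUMNS = [
    "sample_id",
    "chain",
    "v_call",
    "j_call",
    "cdr3_nt",
    "cdr3_aa",
    "duplicate_count",
]
CD3_COMPLEX_GENES = ("CD3D", "CD3G", "CD3E", "CD247")


@dataclass
class Repertoire:
    """One sample's clonotype table (AIRR-style columns)."""

    sample_id: str
    clonotypes: pd.DataFrame

    def __post_init__(self):
        missing = set(CLONOTYPE_COLUMNS) - {"sample_id"} - set(self.clonotypes.columns)
        if missing:
            raise ValueError(f"clonotype table lacks columns {sorted(missing)}")
        if (self.clonotypes["duplicate_count"] < 1).any():
            raise ValueError("clonotype counts must be >= 1")

    @property
    def total_reads(self) -> int:
        return int(self.clonotypes["duplicate_count"].sum())

    def subset(self, chain: str) -> "Repertoire":
        return Repertoire(self.sample_id, self.clonotypes[self.clonotypes["chain"] == chain])


def repertoires_from_frame(frame: pd.DataFrame) -> dict[str, Repertoire]:
    return {
        sid: Repertoire(sid, grp.drop(columns="sample_id"))
        for sid, grp in frame.groupby("sample_id", sort=True)
    }


# ---------------------------------------------------------------------------
# UMI consensus
# ---------------------------------------------------------------------------


def _umi_valid(umi: str) -> bool:
    if len(umi) != len(UMI_TEMPLATE):
        return False
    return all(b == "T" for b, t in zip(umi, UMI_TEMPLATE) if t == "T")


def _pair_identity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    n = max(len(a), len(b))
    matches = sum(x == y for x, y in zip(a, b))
    return matches / n


def umi_consensus(reads: Sequence[tuple[str, str]]) -> list[str]:
    """Collapse reads sharing a molecular barcode to consensus sequences.

    UMIs must match the TNNNNTNNNNTNNNNT template (conserved T positions);
    a barcode group is kept only when mean pairwise sequence identity
    exceeds 80%, in which case a positionwise majority-vote consensus is
    emitted.
    """
    groups: dict[str, list[str]] = {}
    for umi, seq in reads:
        if _umi_valid(umi):
            groups.setdefault(umi, []).append(seq)
    out = []
    for umi in sorted(groups):
        seqs = groups[umi]
        if len(seqs) > 1:
            idents = [
                _pair_identity(seqs[i], seqs[j])
                for i in range(len(seqs))
                for j in range(i + 1, len(seqs))
            ]
            if np.mean(idents) <= UMI_MIN_IDENTITY:
                continue
        length = max(len(s) for s in seqs)
        consensus = "".join(
            Counter(s[i] for s in seqs if i < len(s)).most_common(1)[0][0]
            for i in range(length)
        )
        out.append(consensus)
    return out


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------


def _clone_keys(frame: pd.DataFrame, clone_key: str = "vj") -> pd.Series:
    """Clone identity: identical CDR3 nucleotide sequence + V gene (+ J gene)."""
    if clone_key == "vj":
        return frame["chain"] + "|" + frame["v_call"] + "|" + frame["j_call"] + "|" + frame["cdr3_nt"]
    if clone_key == "v":
        return frame["chain"] + "|" + frame["v_call"] + "||" + frame["cdr3_nt"]
    raise ValueError(f"unknown clone_key {clone_key!r}")


def define_clones(repertoire: Repertoire, clone_key: str = "vj") -> pd.DataFrame:
    """Partition a repertoire into clones; clone size sums member read counts."""
    frame = repertoire.clonotypes.copy()
    frame["clone_id"] = _clone_keys(frame, clone_key)
    table = (
        frame.groupby("clone_id", sort=True)
        .agg(
            chain=("chain", "first"),
            v_call=("v_call", "first"),
            j_call=("j_call", "first"),
            cdr3_nt=("cdr3_nt", "first"),
            cdr3_aa=("cdr3_aa", "first"),
            size=("duplicate_count", "sum"),
        )
        .reset_index()
    )
    assert table["size"].sum() == repertoire.total_reads
    return table


def remove_public(
    repertoires_by_patient: Mapping[str, Mapping[str, Repertoire]],
    external_db: Sequence[str] = (),
    clone_key: str = "vj",
) -> dict[str, dict[str, Repertoire]]:
    """Drop public clones: present in the external database or in >= 2 patients."""
    patient_clones: dict[str, set[str]] = {}
    for patient, reps in repertoires_by_patient.items():
        keys: set[str] = set()
        for rep in reps.values():
            keys |= set(_clone_keys(rep.clonotypes, clone_key))
        patient_clones[patient] = keys
    counts = Counter(k for keys in patient_clones.values() for k in keys)
    public = {k for k, c in counts.items() if c >= 2} | set(external_db)
    out: dict[str, dict[str, Repertoire]] = {}
    for patient, reps in repertoires_by_patient.items():
        out[patient] = {}
        for sid, rep in reps.items():
            keys = _clone_keys(rep.clonotypes, clone_key)
            out[patient][sid] = Repertoire(sid, rep.clonotypes[~keys.isin(public)])
    return out


def classify_tcr_sharing(
    site_repertoires: Mapping[str, Repertoire], clone_key: str = "vj"
) -> tuple[dict[str, str], pd.DataFrame]:
    """Label clones stem/clade/private by cross-site sharing within a case.

    Stem: in every metastatic site; clade: in some but not all; private: in
    one.  Also returns the per-site fraction of reads in each class (rows
    sum to 1) — the repertoire-composition quantity.
    """
    sites = sorted(site_repertoires)
    if len(sites) < 2:
        raise ValueError("sharing undefined for a single site")
    site_tables = {s: define_clones(site_repertoires[s], clone_key) for s in sites}
    presence = Counter()
    for s in sites:
        presence.update(set(site_tables[s]["clone_id"]))
    labels = {
        cid: "stem" if n == len(sites) else ("private" if n == 1 else "clade")
        for cid, n in presence.items()
    }
    fractions = pd.DataFrame(0.0, index=sites, columns=["stem", "clade", "private"])
    for s in sites:
        t = site_tables[s]
        total = t["size"].sum()
        for lab in fractions.columns:
            fractions.at[s, lab] = t.loc[t["clone_id"].map(labels) == lab, "size"].sum() / total
    return labels, fractions


# ---------------------------------------------------------------------------
# clonality metrics
# ---------------------------------------------------------------------------


def gini_index(sizes: Sequence[float]) -> float:
    """Gini inequality of a size distribution: sum |xi-xj| / (2 n^2 mean)."""
    x = np.sort(np.asarray(sizes, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty size distribution")
    total = x.sum()
    if total == 0:
        raise ValueError("all sizes are zero")
    i = np.arange(1, n + 1)
    return float((2 * np.sum(i * x) - (n + 1) * total) / (n * total))


def _subsample_counts(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``depth`` reads without replacement from per-row read counts."""
    reads = np.repeat(np.arange(len(counts)), counts)
    chosen = rng.choice(len(reads), size=depth, replace=False)
    return np.bincount(reads[chosen], minlength=len(counts))


def subsampled_clonality(
    repertoire: Repertoire,
    depth: int = 1000,
    repeats: int = 20,
    seed: int = 0,
    clone_key: str = "vj",
) -> dict[str, float]:
    """Depth-normalized clonality metrics, averaged over subsampling repeats.

    Per repeat, ``depth`` reads are drawn without replacement; we report the
    vertex Gini (reads per unique sequence), cluster Gini (reads per clone),
    and mean/largest cluster size in two dialects: as a percentage of
    subsampled reads (``mcs``/``lcs``, default) and divided by the number of
    clusters x 100 (``mcs_per_cluster``/``lcs_per_cluster``, the printed
    form).
    """
    if depth < 10:
        raise ValueError("subsampling depth must be >= 10")
    if repertoire.total_reads < depth:
        raise ValueError(
            f"sample {repertoire.sample_id} has {repertoire.total_reads} reads < depth {depth}"
        )
    rng = np.random.default_rng(seed)
    frame = repertoire.clonotypes.reset_index(drop=True)
    vertex_counts = frame["duplicate_count"].to_numpy()
    clone_ids = _clone_keys(frame, clone_key)
    clone_codes = pd.factorize(clone_ids)[0]
    acc: dict[str, list[float]] = {k: [] for k in (
        "gini_vertex", "gini_cluster", "mcs", "lcs", "mcs_per_cluster", "lcs_per_cluster"
    )}
    for _ in range(repeats):
        sub_vertex = _subsample_counts(vertex_counts, depth, rng)
        sub_cluster = np.bincount(clone_codes, weights=sub_vertex)
        v = sub_vertex[sub_vertex > 0]
        c = sub_cluster[sub_cluster > 0]
        acc["gini_vertex"].append(gini_index(v))
        acc["gini_cluster"].append(gini_index(c))
        acc["mcs"].append(100.0 * c.mean() / depth)
        acc["lcs"].append(100.0 * c.max() / depth)
        acc["mcs_per_cluster"].append(100.0 * depth / len(c))
        acc["lcs_per_cluster"].append(100.0 * c.max() / len(c))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def overlap_coefficient(
    rep_i: Repertoire,
    rep_j: Repertoire,
    depth: int | None = 1000,
    repeats: int = 20,
    seed: int = 0,
    clone_key: str = "vj",
) -> float:
    """Mean clonal overlap O(i,j) = C_ij / (0.5 (C_i + C_j)) over subsamples.

    ``depth=None`` computes the coefficient once on the full clone sets.
    Symmetric in its arguments by construction.
    """

    def overlap(set_i: set, set_j: set) -> float:
        ci, cj = len(set_i), len(set_j)
        if ci + cj == 0:
            return 0.0
        return len(set_i & set_j) / (0.5 * (ci + cj))

    if depth is None:
        return overlap(
            set(define_clones(rep_i, clone_key)["clone_id"]),
            set(define_clones(rep_j, clone_key)["clone_id"]),
        )
    for rep in (rep_i, rep_j):
        if rep.total_reads < depth:
            raise ValueError(f"sample {rep.sample_id} below subsampling depth {depth}")
    rng = np.random.default_rng(seed)
    vals = []
    frames = []
    for rep in (rep_i, rep_j):
        f = rep.clonotypes.reset_index(drop=True)
        frames.append((f["duplicate_count"].to_numpy(), _clone_keys(f, clone_key).to_numpy()))
    for _ in range(repeats):
        sets = []
        for counts, keys in frames:
            sub = _subsample_counts(counts, depth, rng)
            sets.append(set(keys[sub > 0]))
        vals.append(overlap(*sets))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Jaccard similarity trees
# ---------------------------------------------------------------------------


def jaccard_matrix(
    repertoires: Mapping[str, Repertoire], chain: str = "beta"
) -> pd.DataFrame:
    """Pairwise Jaccard index on unique CDR3 amino-acid sets."""
    sets = {
        sid: set(rep.subset(chain).clonotypes["cdr3_aa"]) for sid, rep in repertoires.items()
    }
    ids = sorted(sets)
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = sets[ids[a_i]], sets[ids[b_i]]
            union = len(a | b)
            j = len(a & b) / union if union else 0.0
            mat.iat[a_i, b_i] = mat.iat[b_i, a_i] = j
    return mat


def jaccard_tree(
    repertoires: Mapping[str, Repertoire], chain: str = "beta"
) -> tuple[pd.DataFrame, SampleTree | None]:
    """Jaccard similarity matrix plus a complete-linkage tree on 1 - J.

    With fewer than three repertoires only the matrix is returned.
    """
    sim = jaccard_matrix(repertoires, chain)
    if len(sim) < 3:
        return sim, None
    return sim, complete_linkage_tree(1.0 - sim)


# ---------------------------------------------------------------------------
# organ permutation test
# ---------------------------------------------------------------------------


@dataclass
class OrganTestResult:
    cophenetic_statistic: float
    rf_statistic: int
    p_cophenetic: float
    p_rf: float
    null_cophenetic: np.ndarray
    null_rf: np.ndarray


def _organ_cophenetic_stat(tree: SampleTree, organs: Mapping[str, str]) -> float:
    """Correlation between tree distances and the different-organ indicator."""
    leaves = sorted(tree.leaves)
    d = pair_vector(tree.path_distances(leaves), leaves)
    from itertools import combinations

    indicator = np.array(
        [0.0 if organs[a] == organs[b] else 1.0 for a, b in combinations(leaves, 2)]
    )
    if indicator.std() == 0 or d.std() == 0:
        return 0.0
    return float(stats.pearsonr(d, indicator).statistic)


def permutation_organ_test(
    repertoires: Mapping[str, Repertoire],
    organs: Mapping[str, str],
    chain: str = "beta",
    n_perm: int = 100,
    seed: int = 0,
) -> OrganTestResult:
    """Does the CDR3 Jaccard tree cluster metastases by target organ?

    TCR reads are reshuffled uniformly across metastases (preserving
    per-sample read totals), the Jaccard tree is rebuilt per randomization,
    and the observed organ concordance — cophenetic correlation with the
    different-organ indicator, and Robinson-Foulds distance to the organ
    reference tree — is compared against the null trees (pseudo-counted,
    one-sided toward concordance).
    """
    ids = sorted(repertoires)
    if len(ids) < 4:
        raise ValueError("organ test needs >= 4 samples")
    if len(set(organs[s] for s in ids)) < 2:
        raise ValueError("organ test needs >= 2 organs")
    subs = {sid: repertoires[sid].subset(chain) for sid in ids}
    _, observed_tree = jaccard_tree(subs, chain)
    organ_tree = organ_reference_tree({s: organs[s] for s in ids})
    obs_coph = _organ_cophenetic_stat(observed_tree, organs)
    obs_rf = robinson_foulds(observed_tree, organ_tree)

    # expand reads: each read carries its clonotype's CDR3 aa
    all_aa, totals = [], []
    for sid in ids:
        f = subs[sid].clonotypes
        all_aa.append(np.repeat(f["cdr3_aa"].to_numpy(), f["duplicate_count"].to_numpy()))
        totals.append(int(f["duplicate_count"].sum()))
    pool = np.concatenate(all_aa)
    bounds = np.cumsum(totals)[:-1]
    rng = np.random.default_rng(seed)
    null_coph = np.empty(n_perm)
    null_rf = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        shuffled = pool[rng.permutation(len(pool))]
        pieces = np.split(shuffled, bounds)
        sets = {sid: set(p.tolist()) for sid, p in zip(ids, pieces)}
        sim = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a, b = sets[ids[a_i]], sets[ids[b_i]]
                u = len(a | b)
                j = len(a & b) / u if u else 0.0
                sim.iat[a_i, b_i] = sim.iat[b_i, a_i] = j
        tree = complete_linkage_tree(1.0 - sim)
        null_coph[i] = _organ_cophenetic_stat(tree, organs)
        null_rf[i] = robinson_foulds(tree, organ_tree)
    p_coph = (np.sum(null_coph >= obs_coph) + 1) / (n_perm + 1)
    p_rf = (np.sum(null_rf <= obs_rf) + 1) / (n_perm + 1)
    return OrganTestResult(obs_coph, obs_rf, float(p_coph), float(p_rf), null_coph, null_rf)


# ---------------------------------------------------------------------------
# CD3 expression vs TCR reads
# ---------------------------------------------------------------------------


def cd3_tcr_correlation(
    expression: pd.DataFrame, repertoires: Mapping[str, Repertoire]
) -> tuple[float, float]:
    """Pearson correlation of log10 CD3-complex TPM vs log10 total TCR reads.

    x sums TPM of CD3D/CD3G/CD3E/CD247 per sample; y sums alpha- plus
    beta-chain reads; samples with non-positive sums are dropped with a
    warning.
    """
    xs, ys = [], []
    for sid, rep in sorted(repertoires.items()):
        if sid not in expression.columns:
            continue
        tpm = expression.loc[[g for g in CD3_COMPLEX_GENES if g in expression.index], sid].sum()
        reads = rep.total_reads
        if tpm <= 0 or reads <= 0:
            log.warning("sample %s dropped (non-positive CD3 TPM or read sum)", sid)
            continue
        xs.append(np.log10(tpm))
        ys.append(np.log10(reads))
    if len(xs) < 3:
        raise ValueError("need >= 3 samples with both data types")
    r = stats.pearsonr(xs, ys)
    return float(r.statistic), float(r.pvalue)
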