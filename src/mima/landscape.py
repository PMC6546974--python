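"""Mutation-landscape analyses: metastatic lineage classification, targeted-
sequencing detection/QC rules, WES-vs-TS validation metrics, mutant-allele
expression Z scores, germline concordance, and the posterior/cluster filters
that prepare tree-inference inputs."""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MutationRecord, PresenceMatrix

log = logging.getLogger(__name__)

LINEAGES = ("stem", "clade", "private")

TS_MIN_DEPTH = 500
TS_CONTROL_SD = 3.0
TS_MIN_AF = 0.01
TS_QC_AF = 0.05
TS_QC_FRACTION = 0.90
CONCORDANCE_RELATED = 0.90
POSTERIOR_PRESENT = 0.5
CLUSTER_MIN_PREVALENCE = 0.1
CLUSTER_PRESENT_FRACTION = 0.40
CLUSTER_PRESENT_VAF = 0.01


# ---------------------------------------------------------------------------
# lineage classification
# ---------------------------------------------------------------------------


def classify_lineage(presence: PresenceMatrix | pd.DataFrame) -> tuple[dict[str, str], dict[str, int]]:
    """Label each mutation stem / clade / private from its presence pattern.

    Stem: present in every metastasis of the case; private: in exactly one;
    clade: in at least two but not all.  Returns the per-mutation labels and
    the per-label counts.
    """
    matrix = presence.presence if isinstance(presence, PresenceMatrix) else presence.astype(bool)
    n_samples = matrix.shape[1]
    if n_samples < 2:
        raise ValueError("lineage undefined for <2 samples")
    n_present = matrix.sum(axis=1)
    if (n_present == 0).any():
        raise ValueError("presence matrix contains mutations present in no sample")
    labels = {}
    for mid, n in n_present.items():
        labels[mid] = "stem" if n == n_samples else ("private" if n == 1 else "clade")
    counts = {lab: sum(v == lab for v in labels.values()) for lab in LINEAGES}
    return labels, counts


# ---------------------------------------------------------------------------
# targeted-sequencing detection & validation
# ---------------------------------------------------------------------------


def ts_detect(
    sample_afs: Mapping[str, tuple[float, float]],
    control_afs: Mapping[str, Sequence[float]],
) -> tuple[dict[str, str], bool]:
    """Targeted-sequencing detection calls for one sample.

    A mutation is detected iff depth >= 500x, its AF is at least 3 control
    standard deviations above the control mean, and AF >= 1%.  Loci with
    fewer than two control AFs are returned as "uncallable".  The sample is
    flagged failed-QC when over 90% of its mutations have AF below 5%.
    """
    calls = {}
    afs = []
    for mid, (af, depth) in sample_afs.items():
        controls = np.asarray(control_afs.get(mid, ()), dtype=float)
        afs.append(af)
        if controls.size < 2:
            calls[mid] = "uncallable"
            continue
        threshold = controls.mean() + TS_CONTROL_SD * controls.std(ddof=1)
        ok = depth >= TS_MIN_DEPTH and af >= threshold and af >= TS_MIN_AF
        calls[mid] = "detected" if ok else "not_detected"
    qc_failed = bool(afs) and np.mean(np.asarray(afs) < TS_QC_AF) > TS_QC_FRACTION
    return calls, qc_failed


def validation_metrics(wes_calls: set, ts_calls: set, universe: set) -> dict[str, float]:
    """Sensitivity/specificity/accuracy/precision of WES against TS truth.

    TP = WES∩TS, FP = WES\\TS, FN = TS\\WES, TN = universe minus the union;
    sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
    accuracy (TP+TN)/all.  An empty denominator means there were no cases of
    that kind to get wrong; the metric is vacuously 1.0 (never 0).
    """
    if not universe:
        raise ValueError("empty universe")
    if not wes_calls <= universe or not ts_calls <= universe:
        raise ValueError("calls must be subsets of the universe")
    tp = len(wes_calls & ts_calls)
    fp = len(wes_calls - ts_calls)
    fn = len(ts_calls - wes_calls)
    tn = len(universe - (wes_calls | ts_calls))

    def safe(num, den):
        return num / den if den else 1.0

    return {
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "precision": safe(tp, tp + fp),
        "accuracy": safe(tp + tn, tp + fp + fn + tn),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


# ---------------------------------------------------------------------------
# mutant-allele expression
# ---------------------------------------------------------------------------


@dataclass
class MutantExpressionResult:
    values: pd.DataFrame  # mutation_id, sample_id, lineage, expression, z
    by_lineage: dict[str, np.ndarray]
    rank_sum_p: dict[tuple[str, str], float]


def mutant_expression_zscores(
    mutations: Sequence[MutationRecord] | Sequence[str],
    gene_tpm: pd.DataFrame,
    rna_vaf: pd.DataFrame,
    lineage: Mapping[str, str],
    gene_of: Mapping[str, str] | None = None,
) -> MutantExpressionResult:
    """Z-scored mutant-allele expression per (mutation, sample), by lineage.

    Mutant expression is log2(gene TPM x RNA VAF + 1) wherever the mutant
    allele is seen in RNA (VAF > 0); Z scores are taken across all such
    values within the case.  A degenerate spread (single value, or all values
    equal) yields Z = 0.  Pairwise lineage differences are scored with the
    Wilcoxon rank-sum test.
    """
    if gene_of is None:
        gene_of = {m.mutation_id: m.gene for m in mutations}
        mut_ids = [m.mutation_id for m in mutations]
    else:
        mut_ids = list(mutations)
    rows = []
    for mid in mut_ids:
        gene = gene_of[mid]
        if gene not in gene_tpm.index or mid not in rna_vaf.index:
            continue
        for sid in rna_vaf.columns:
            v = rna_vaf.at[mid, sid]
            if v > 0 and sid in gene_tpm.columns:
                expr = float(np.log2(gene_tpm.at[gene, sid] * v + 1.0))
                rows.append((mid, sid, lineage[mid], expr))
    if not rows:
        log.warning("no expressed mutations; empty mutant-expression result")
        empty = pd.DataFrame(columns=["mutation_id", "sample_id", "lineage", "expression", "z"])
        return MutantExpressionResult(empty, {}, {})
    values = pd.DataFrame(rows, columns=["mutation_id", "sample_id", "lineage", "expression"])
    sd = values["expression"].std(ddof=0)
    if sd == 0 or len(values) == 1:
        values["z"] = 0.0
    else:
        values["z"] = (values["expression"] - values["expression"].mean()) / sd
    by_lineage = {
        lab: grp["z"].to_numpy() for lab, grp in values.groupby("lineage", sort=False)
    }
    rank_sum_p = {}
    for a, b in (("stem", "clade"), ("clade", "private"), ("stem", "private")):
        if a in by_lineage and b in by_lineage and len(by_lineage[a]) and len(by_lineage[b]):
            rank_sum_p[(a, b)] = float(stats.ranksums(by_lineage[a], by_lineage[b]).pvalue)
    return MutantExpressionResult(values, by_lineage, rank_sum_p)


# ---------------------------------------------------------------------------
# germline concordance
# ---------------------------------------------------------------------------


def genotype_concordance(
    germline_a: set, germline_b: set, denominator: str = "jaccard"
) -> dict[str, float | bool]:
    """Fraction of shared germline variants; related iff strictly above 90%.

    The shared-fraction base is Jaccard (|A∩B| / |A∪B|) by default, or the
    smaller set (``denominator="min"``).
    """
    if not germline_a or not germline_b:
        raise ValueError("germline variant sets must be non-empty")
    inter = len(germline_a & germline_b)
    if denominator == "jaccard":
        frac = inter / len(germline_a | germline_b)
    elif denominator == "min":
        frac = inter / min(len(germline_a), len(germline_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return {"fraction_shared": frac, "related": frac > CONCORDANCE_RELATED}


# ---------------------------------------------------------------------------
# tree-input preparation
# ---------------------------------------------------------------------------


def posteriors_to_binary(posterior: pd.DataFrame) -> pd.DataFrame:
    """Binarize a mutation x sample posterior matrix at 0.5.

    Rows whose posteriors are below 0.5 in every sample are removed (likely
    false positives); remaining entries map to 1 iff p >= 0.5 (the quoted
    rule zeroes only entries strictly smaller than 0.5).
    """
    vals = posterior.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ValueError("posterior entries must lie in [0, 1]")
    keep = (vals >= POSTERIOR_PRESENT).any(axis=1)
    return (posterior.loc[keep] >= POSTERIOR_PRESENT).astype(int)


@dataclass
class ClusterPrevalence:
    """A mutation cluster with per-sample mean cellular prevalence."""

    cluster_id: str
    prevalence: pd.Series  # per sample
    members: list[str]

    def __post_init__(self):
        if ((self.prevalence < 0) | (self.prevalence > 1)).any():
            raise ValueError(f"cluster {self.cluster_id}: prevalences must be in [0, 1]")


def filter_prevalence_clusters(
    clusters: Sequence[ClusterPrevalence], vaf: pd.DataFrame
) -> tuple[list[ClusterPrevalence], pd.DataFrame]:
    """Prepare clone-tree input: prevalence filters plus binary presence patterns.

    In order: (1) clusters whose cellular prevalence never exceeds 0.1 in any
    sample are removed; (2) if several clusters are present (prevalence
    > 0.1) in all samples, only the one with the highest prevalence survives;
    (3) a surviving cluster is called present in a sample iff at least 40% of
    its member mutations have VAF > 0.01 there.
    """
    if not clusters:
        raise ValueError("empty cluster set")
    kept = [c for c in clusters if (c.prevalence > CLUSTER_MIN_PREVALENCE).any()]
    ubiquitous = [c for c in kept if (c.prevalence > CLUSTER_MIN_PREVALENCE).all()]
    if len(ubiquitous) > 1:
        winner = max(ubiquitous, key=lambda c: c.prevalence.max())
        drop = {c.cluster_id for c in ubiquitous if c is not winner}
        kept = [c for c in kept if c.cluster_id not in drop]
    patterns = {}
    for c in kept:
        members = [m for m in c.members if m in vaf.index]
        frac = (vaf.loc[members] > CLUSTER_PRESENT_VAF).mean(axis=0)
        patterns[c.cluster_id] = frac >= CLUSTER_PRESENT_FRACTION
    return kept, pd.DataFrame(patterns).T.astype(bool)
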