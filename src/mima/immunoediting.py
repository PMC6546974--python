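"""Neo-epitope enumeration and the simulation-based immunoediting test.

The test asks whether a metastasis carries fewer neo-epitopes than expected
given its mutation spectrum.  For each replicate, every observed mutation is
re-placed at a random genomic position with the *same* trinucleotide context
(gene chosen proportionally to a background per-gene mutation rate, position
within the gene proportionally to a coverage weight), the identical
neo-epitope counting pipeline is run on the simulated set, and the
observed-to-expected ratio is recorded.  The empirical p-value is the
(pseudo-counted) fraction of replicates whose ratio reaches 1.

MHC binding itself is behind a pluggable ``(peptide, allele) -> IC50``
predicate; the default is a deterministic hash surrogate with a configurable
binder rate, so the whole pipeline is reproducible without an external
predictor.  An adapter for a real predictor only needs to supply the same
callable.
"""

from __future__ import annotations

import hashlib
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MutationRecord

IC50_BINDING_NM = 500.0
MIN_RPKM = 1.0
COVERED_MIN_READS = 14  # a base counts as covered in >=14-read panel samples

BinderPredicate = Callable[[str, str], float]


# ---------------------------------------------------------------------------
# gene rates and coverage
# ---------------------------------------------------------------------------


@dataclass
class GeneRateTable:
    """Relative background mutation rate per gene (counts normalized to 1)."""

    rates: pd.Series
    source_counts: pd.Series

    def __post_init__(self):
        if (self.rates < 0).any():
            raise ValueError("gene rates must be non-negative")
        if abs(self.rates.sum() - 1.0) > 1e-9:
            raise ValueError("gene rates must sum to 1")


def build_gene_rates(catalog: pd.Series | Mapping[str, int]) -> GeneRateTable:
    """Normalize a gene -> mutation-count catalog into relative rates."""
    counts = pd.Series(catalog, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("catalog has no mutations")
    return GeneRateTable(rates=counts / total, source_counts=counts)


@dataclass
class NeoEpitopeTest:
    """Observed vs simulation-expected neo-epitope counts for one sample."""

    sample_id: str
    observed_count: int
    expected_counts: list[int]
    ratios: list[float]
    empirical_p: float
    n_replicates: int = 100

    def __post_init__(self):
        if len(self.ratios) != self.n_replicates:
            raise ValueError("one ratio required per replicate")
        if not (0.0 < self.empirical_p <= 1.0):
            raise ValueError("empirical p must be in (0, 1]")


@dataclass
class HlaLohCall:
    allele: str
    copy_number: float
    p_value: float
    lost: bool

    def __post_init__(self):
        if self.lost and not (self.copy_number < 0.5 and self.p_value < 0.05):
            raise ValueError("lost requires copy number < 0.5 and p < 0.05")


# ---------------------------------------------------------------------------
# binder predicate
# ---------------------------------------------------------------------------


def hash_binder_predicate(binder_rate: float = 0.02, seed: int = 0) -> BinderPredicate:
    """Deterministic IC50 surrogate: a seeded hash of (peptide, allele).

    A fraction ``binder_rate`` of peptide/allele pairs falls at or below the
    500 nM binding threshold; the rest is spread over (500, 50000] nM.
    """
    if not 0.0 <= binder_rate <= 1.0:
        raise ValueError("binder_rate must be in [0, 1]")

    def predicate(peptide: str, allele: str) -> float:
        digest = hashlib.blake2b(
            f"{peptide}|{allele}|{seed}".encode(), digest_size=8
        ).digest()
        u = int.from_bytes(digest, "big") / 2**64
        if binder_rate > 0 and u < binder_rate:
            return IC50_BINDING_NM * u / binder_rate
        if binder_rate >= 1.0:
            return IC50_BINDING_NM * u
        return IC50_BINDING_NM + (u - binder_rate) / (1 - binder_rate) * 49500.0

    return predicate


# ---------------------------------------------------------------------------
# peptide enumeration
# ---------------------------------------------------------------------------


def enumerate_candidate_peptides(
    mutation: MutationRecord, protein: str, window: int = 17
) -> list[tuple[str, str]]:
    """All mutant 9-mers covering a missense substitution, paired with wild type.

    The mutant residue is placed centrally in a ``window``-long stretch
    (truncated at the protein termini) and a sliding 9-mer window is applied;
    only 9-mers containing the mutant position are emitted.
    """
    if mutation.effect != "missense":
        raise ValueError(f"{mutation.mutation_id}: peptide enumeration requires missense")
    if not 17 <= window <= 21:
        raise ValueError("window must be between 17 and 21 residues")
    if mutation.protein_pos is None or mutation.aa_alt is None:
        raise ValueError(f"{mutation.mutation_id}: missing protein annotation")
    pos0 = mutation.protein_pos - 1
    if pos0 >= len(protein):
        raise ValueError(f"{mutation.mutation_id}: protein position beyond sequence")
    half = window // 2
    lo = max(0, pos0 - half)
    hi = min(len(protein), pos0 + half + 1)
    wt_window = protein[lo:hi]
    mut_window = wt_window[: pos0 - lo] + mutation.aa_alt + wt_window[pos0 - lo + 1 :]
    out = []
    for start in range(0, len(mut_window) - 8):
        if start <= pos0 - lo <= start + 8:
            out.append((mut_window[start : start + 9], wt_window[start : start + 9]))
    return out


@dataclass
class NeoEpitopeCounter:
    """Per-sample neo-epitope counting machinery (binding + expression filters).

    A mutation contributes one neo-epitope if at least one of its mutant
    9-mers binds at least one patient HLA allele (IC50 <= 500 nM under the
    predicate) and its gene and transcript RPKM both exceed 1 — the highly
    similar peptides arising from one mutation are counted as one.
    Binding decisions are memoized by (gene, position, alt) since simulated
    replicates revisit the same context-bearing positions.
    """

    proteins: Mapping[str, str]
    alleles: Sequence[str]
    predicate: BinderPredicate
    gene_rpkm: pd.Series | None = None
    transcript_rpkm: pd.Series | None = None
    window: int = 17
    _bind_cache: dict = field(default_factory=dict, repr=False)

    def binds(self, mutation: MutationRecord) -> bool:
        if mutation.effect != "missense":
            return False
        key = (mutation.gene, mutation.pos, mutation.alt, self.window)
        hit = self._bind_cache.get(key)
        if hit is None:
            peptides = enumerate_candidate_peptides(
                mutation, self.proteins[mutation.gene], self.window
            )
            hit = any(
                self.predicate(mut9, allele) <= IC50_BINDING_NM
                for mut9, _ in peptides
                for allele in self.alleles
            )
            self._bind_cache[key] = hit
        return hit

    def expressed(self, mutation: MutationRecord) -> bool | None:
        """True/False under the RPKM > 1 rule; None when expression is missing."""
        if self.gene_rpkm is None:
            return True  # no expression data supplied: filter disabled
        if mutation.gene not in self.gene_rpkm.index:
            return None
        if self.gene_rpkm[mutation.gene] <= MIN_RPKM:
            return False
        if self.transcript_rpkm is not None:
            if mutation.gene not in self.transcript_rpkm.index:
                return None
            if self.transcript_rpkm[mutation.gene] <= MIN_RPKM:
                return False
        return True

    def is_neoepitope(self, mutation: MutationRecord) -> bool:
        expressed = self.expressed(mutation)
        if expressed is None or not expressed:
            return False
        return self.binds(mutation)

    def count(self, mutations: Sequence[MutationRecord]) -> int:
        return sum(self.is_neoepitope(m) for m in mutations)

    def presenting_alleles(self, mutation: MutationRecord) -> list[str]:
        """HLA alleles with at least one binding mutant 9-mer for this mutation."""
        if mutation.effect != "missense":
            return []
        peptides = enumerate_candidate_peptides(
            mutation, self.proteins[mutation.gene], self.window
        )
        return [
            allele
            for allele in self.alleles
            if any(self.predicate(m9, allele) <= IC50_BINDING_NM for m9, _ in peptides)
        ]


def count_neoepitopes(
    mutations: Sequence[MutationRecord],
    proteins: Mapping[str, str],
    hla_alleles: Sequence[str],
    binder: BinderPredicate,
    gene_rpkm: pd.Series | None = None,
    transcript_rpkm: pd.Series | None = None,
    window: int = 17,
) -> int:
    counter = NeoEpitopeCounter(proteins, hla_alleles, binder, gene_rpkm, transcript_rpkm, window)
    return counter.count(mutations)


# ---------------------------------------------------------------------------
# context-preserving mutation simulation
# ---------------------------------------------------------------------------


def simulate_mutation_set(
    observed: Sequence[MutationRecord],
    rates: GeneRateTable,
    genome,
    rng: np.random.Generator | int,
) -> list[MutationRecord]:
    """Re-place every observed substitution at a random context-matched position.

    ``genome`` bundles the per-gene position-by-context index, coverage
    weights and coding sequences (see
    :class:`mima.synthetic.genome.SyntheticGenome`); gene choice is
    proportional to ``rates`` restricted to genes carrying the context.  The
    simulated set preserves the observed trinucleotide-context multiset
    exactly (asserted).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rate_dict = rates.rates.to_dict()
    simulated = []
    for i, rec in enumerate(observed):
        if not rec.is_substitution:
            raise ValueError(f"{rec.mutation_id}: simulation requires substitutions")
        channel = genome.channel_of(rec)
        sim = genome.place_mutation(
            channel,
            rate_dict,
            rng,
            case_id=rec.case_id,
            mutation_id=f"sim_{i}_{rec.mutation_id}",
        )
        assert genome.channel_of(sim) == channel
        simulated.append(sim)
    return simulated


# ---------------------------------------------------------------------------
# observed / expected test
# ---------------------------------------------------------------------------


def _ratio(observed: int, expected: int) -> float:
    if expected > 0:
        return observed / expected
    # expected 0: conservative conventions — both zero counts as a tie at 1,
    # observed > 0 counts as a ratio above 1
    return 1.0 if observed == 0 else np.inf


def observed_expected_test(
    mutations: Sequence[MutationRecord],
    counter: NeoEpitopeCounter,
    rates: GeneRateTable,
    genome,
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
) -> NeoEpitopeTest:
    """Per-sample immunoediting test: observed vs context-matched simulated counts.

    ``empirical_p = (k + 1) / (n + 1)`` with k the number of replicates whose
    observed-to-expected ratio is >= 1 (ties included); a sample in which all
    replicates exceed the observed count therefore gets p = 1/(n+1) ≈ 0.01 at
    the default 100 replicates.
    """
    if n_replicates < 10:
        raise ValueError("n_replicates must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subs = [m for m in mutations if m.is_substitution]
    observed = counter.count(subs)
    expected, ratios = [], []
    for _ in range(n_replicates):
        sim = simulate_mutation_set(subs, rates, genome, rng)
        e = counter.count(sim)
        expected.append(e)
        ratios.append(_ratio(observed, e))
    k = sum(r >= 1.0 for r in ratios)
    p = (k + 1) / (n_replicates + 1)
    return NeoEpitopeTest(
        sample_id=sample_id,
        observed_count=observed,
        expected_counts=expected,
        ratios=ratios,
        empirical_p=p,
        n_replicates=n_replicates,
    )


@dataclass
class GroupedRatioTest:
    group_id: str
    observed_mean_ratio: float
    null_means: list[float]
    p_value: float


def grouped_mean_ratio_null(
    samples: Sequence[tuple[Sequence[MutationRecord], NeoEpitopeCounter]],
    rates: GeneRateTable,
    genome,
    n_outer: int = 20,
    n_inner: int = 100,
    seed: int = 0,
    group_id: str = "",
) -> GroupedRatioTest:
    """Group-level immunoediting test on the mean observed/expected ratio.

    The null distribution replaces each sample's observed set with one
    simulated "pseudo-observed" set and scores it against ``n_inner`` further
    simulations; ``n_outer`` such replicates give the null means.  p is the
    pseudo-counted fraction of null means at or below the observed mean
    (one-sided toward depletion).
    """
    if len(samples) < 1:
        raise ValueError("empty group")
    rng = np.random.default_rng(seed)
    if len(samples) == 1:
        muts, counter = samples[0]
        single = observed_expected_test(
            muts, counter, rates, genome, n_replicates=n_inner, seed=rng, sample_id=group_id
        )
        return GroupedRatioTest(
            group_id=group_id,
            observed_mean_ratio=float(np.mean(np.clip(single.ratios, 0, 10))),
            null_means=[],
            p_value=single.empirical_p,
        )

    def mean_ratio(obs_count: int, expected: list[int]) -> float:
        return float(np.mean([np.clip(_ratio(obs_count, e), 0, 10) for e in expected]))

    per_sample = []
    for muts, counter in samples:
        subs = [m for m in muts if m.is_substitution]
        obs = counter.count(subs)
        exp = [
            counter.count(simulate_mutation_set(subs, rates, genome, rng))
            for _ in range(n_inner)
        ]
        per_sample.append((subs, counter, obs, mean_ratio(obs, exp)))
    observed_mean = float(np.mean([m for *_, m in per_sample]))

    null_means = []
    for _ in range(n_outer):
        vals = []
        for subs, counter, _, _ in per_sample:
            pseudo = simulate_mutation_set(subs, rates, genome, rng)
            pseudo_obs = counter.count(pseudo)
            exp = [
                counter.count(simulate_mutation_set(subs, rates, genome, rng))
                for _ in range(n_inner)
            ]
            vals.append(mean_ratio(pseudo_obs, exp))
        null_means.append(float(np.mean(vals)))
    k = sum(nm <= observed_mean for nm in null_means)
    p = (k + 1) / (n_outer + 1)
    return GroupedRatioTest(group_id, observed_mean, null_means, p)


# ---------------------------------------------------------------------------
# HLA LOH
# ---------------------------------------------------------------------------


def hla_loh_assess(
    allele_table: pd.DataFrame,
    neoepitope_alleles: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[HlaLohCall], float | None]:
    """Call HLA LOH per allele and the fraction of neo-epitopes restricted to lost alleles.

    ``allele_table`` needs columns allele / copy_number / p_value.  An allele
    is lost iff copy number < 0.5 and p < 0.05.  A neo-epitope associates with
    loss iff *every* allele it binds is lost; the second return value is that
    fraction (None when no neo-epitope mapping is given).
    """
    calls = []
    for row in allele_table.itertuples(index=False):
        lost = (row.copy_number < 0.5) and (row.p_value < 0.05)
        calls.append(HlaLohCall(row.allele, float(row.copy_number), float(row.p_value), lost))
    if neoepitope_alleles is None:
        return calls, None
    lost_set = {c.allele for c in calls if c.lost}
    fractions = []
    for _, alleles in neoepitope_alleles.items():
        alleles = list(alleles)
        if not alleles:
            continue
        fractions.append(all(a in lost_set for a in alleles))
    frac = float(np.mean(fractions)) if fractions else None
    return calls, frac
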