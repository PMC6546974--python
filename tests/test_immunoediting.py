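"""Neo-epitope enumeration/counting rules and the simulation-based
observed/expected depletion test."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mima.datatypes import MutationRecord
from mima.immunoediting import (
    GeneRateTable,
    NeoEpitopeCounter,
    _ratio,
    build_gene_rates,
    enumerate_candidate_peptides,
    grouped_mean_ratio_null,
    hash_binder_predicate,
    hla_loh_assess,
    observed_expected_test,
    simulate_mutation_set,
)
from mima.synthetic.genome import GeneModel, SyntheticGenome, _index_contexts


class TestGeneRates:
    def test_normalization(self):
        rates = build_gene_rates(pd.Series({"A": 2, "B": 8}))
        assert rates.rates["A"] == pytest.approx(0.2)
        assert rates.rates["B"] == pytest.approx(0.8)

    def test_single_gene(self):
        assert build_gene_rates(pd.Series({"A": 5})).rates["A"] == 1.0

    def test_zero_catalog_rejected(self):
        with pytest.raises(ValueError):
            build_gene_rates(pd.Series({"A": 0}))

    def test_rates_sum_to_one(self, rng):
        counts = pd.Series(rng.integers(1, 100, size=30), index=[f"g{i}" for i in range(30)])
        assert build_gene_rates(counts).rates.sum() == pytest.approx(1.0)


class TestBinderPredicate:
    def test_deterministic(self):
        p = hash_binder_predicate(0.05, seed=3)
        assert p("ACDEFGHIK", "HLA-A*01:01") == p("ACDEFGHIK", "HLA-A*01:01")

    def test_binder_fraction_close_to_rate(self, rng):
        p = hash_binder_predicate(0.1, seed=1)
        peptides = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 9)) for _ in range(5000)]
        frac = np.mean([p(pep, "HLA-B*07:02") <= 500 for pep in peptides])
        assert abs(frac - 0.1) < 0.02

    def test_zero_rate_binds_nothing(self):
        p = hash_binder_predicate(0.0)
        assert p("ACDEFGHIK", "X") > 500


class TestPeptideEnumeration:
    def _missense(self, protein_pos):
        return MutationRecord(
            case_id="c", mutation_id="m", chrom="G", pos=3 * protein_pos - 1,
            ref="C", alt="T", gene="G", effect="missense",
            trinucleotide_context="ACA", protein_pos=protein_pos, aa_ref="A", aa_alt="V",
        )

    def test_central_mutation_yields_nine_windows(self):
        protein = "L" * 200
        pairs = enumerate_candidate_peptides(self._missense(50), protein, window=17)
        assert len(pairs) == 9

    def test_terminal_mutation_truncated_to_one_window(self):
        protein = "L" * 200
        pairs = enumerate_candidate_peptides(self._missense(1), protein, window=17)
        assert len(pairs) == 1

    def test_mutant_differs_from_wildtype_at_one_residue(self):
        protein = "LMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        for mut9, wt9 in enumerate_candidate_peptides(self._missense(12), protein, window=17):
            assert sum(a != b for a, b in zip(mut9, wt9)) == 1

    def test_non_missense_rejected(self):
        rec = MutationRecord(
            case_id="c", mutation_id="m", chrom="G", pos=5, ref="C", alt="T",
            gene="G", effect="silent", trinucleotide_context="ACA",
        )
        with pytest.raises(ValueError):
            enumerate_candidate_peptides(rec, "L" * 50)


def _toy_genome(cds_by_gene, coverage=None):
    genes = {}
    for name, cds in cds_by_gene.items():
        cov = np.ones(len(cds)) if coverage is None else coverage[name]
        genes[name] = GeneModel(name, cds, cov, _index_contexts(cds))
    return SyntheticGenome(genes)


class TestSimulation:
    def test_context_multiset_preserved(self, small_cohort, small_rates):
        case = next(iter(small_cohort.cases.values()))
        observed = case.mutations[:100]
        sim = simulate_mutation_set(observed, small_rates, small_cohort.genome, 5)
        assert len(sim) == len(observed)
        obs_channels = Counter(small_cohort.genome.channel_of(m) for m in observed)
        sim_channels = Counter(small_cohort.genome.channel_of(m) for m in sim)
        assert obs_channels == sim_channels

    def test_unique_context_position_is_forced(self):
        # ACA occurs exactly once (position 4 of gene A); elsewhere never
        genome = _toy_genome({"A": "TTGACAGGTGGTGGT", "B": "GGTGGTGGTGGTGGT"})
        rec = genome._record_at(genome.genes["A"], 5, "A", "c", "m0")
        assert rec.trinucleotide_context == "ACA"
        rates = build_gene_rates(pd.Series({"A": 1, "B": 9}))
        for seed in range(10):
            (sim,) = simulate_mutation_set([rec], rates, genome, seed)
            assert (sim.gene, sim.pos) == ("A", 5)

    def test_gene_choice_proportional_to_rates(self):
        cds = "ATGACATCACCAGGA" * 4
        genome = _toy_genome({"A": cds, "B": cds})  # identical contexts and coverage
        rates = build_gene_rates(pd.Series({"A": 2, "B": 8}))
        rec = genome._record_at(genome.genes["A"], 5, "A", "c", "m0")
        rng = np.random.default_rng(0)
        sims = simulate_mutation_set([rec] * 10000, rates, genome, rng)
        frac_b = np.mean([s.gene == "B" for s in sims])
        assert abs(frac_b - 0.8) < 0.02

    def test_missing_context_rejected(self):
        genome = _toy_genome({"A": "GGTGGTGGTGGTGGT"})
        rec = MutationRecord(
            case_id="c", mutation_id="m", chrom="A", pos=5, ref="C", alt="A",
            gene="A", effect="missense", trinucleotide_context="ACA",
        )
        rates = build_gene_rates(pd.Series({"A": 1}))
        with pytest.raises(ValueError, match="context"):
            simulate_mutation_set([rec], rates, genome, 0)


class TestCountingRules:
    def _counter(self, cohort, binder_rate=None, **kw):
        case = next(iter(cohort.cases.values()))
        rate = cohort.config.binder_rate if binder_rate is None else binder_rate
        return case, NeoEpitopeCounter(
            proteins=cohort.proteins(),
            alleles=case.hla_alleles,
            predicate=hash_binder_predicate(rate, seed=cohort.config.seed),
            **kw,
        )

    def test_nothing_binds_gives_zero(self, small_cohort):
        case, counter = self._counter(small_cohort, binder_rate=0.0)
        assert counter.count(case.mutations[:50]) == 0

    def test_mutation_with_several_binding_peptides_counts_once(self, small_cohort):
        case, counter = self._counter(small_cohort, binder_rate=1.0)
        missense = [m for m in case.mutations if m.effect == "missense"][:20]
        assert counter.count(missense) == len(missense)

    def test_low_rpkm_excluded(self, small_cohort):
        case, _ = self._counter(small_cohort)
        missense = next(m for m in case.mutations if m.effect == "missense")
        low = pd.Series(0.5, index=[missense.gene])
        counter = NeoEpitopeCounter(
            small_cohort.proteins(), case.hla_alleles,
            hash_binder_predicate(1.0), gene_rpkm=low,
        )
        assert counter.count([missense]) == 0


class TestObservedExpectedTest:
    def test_ratio_conventions(self):
        assert _ratio(0, 0) == 1.0  # tie counts toward k
        assert _ratio(3, 0) == np.inf
        assert _ratio(3, 6) == 0.5

    def test_accept_nothing_predicate_gives_p_one(self, small_cohort, small_rates):
        case = next(iter(small_cohort.cases.values()))
        counter = NeoEpitopeCounter(
            small_cohort.proteins(), case.hla_alleles, hash_binder_predicate(0.0)
        )
        res = observed_expected_test(
            case.mutations[:40], counter, small_rates, small_cohort.genome,
            n_replicates=20, seed=1,
        )
        assert res.observed_count == 0
        assert all(e == 0 for e in res.expected_counts)
        assert all(r == 1.0 for r in res.ratios)
        assert res.empirical_p == 1.0

    def test_empirical_p_formula(self):
        # (k + 1) / (n + 1): k = 0 -> ~0.0099, k = n -> 1, k = n/2 -> ~0.505
        for k, n, expected in [(0, 100, 1 / 101), (100, 100, 1.0), (50, 100, 51 / 101)]:
            assert (k + 1) / (n + 1) == pytest.approx(expected)

    def test_lower_observed_count_weakly_decreases_p(self, small_cohort, small_rates):
        case = next(iter(small_cohort.cases.values()))
        sid = case.sample_ids[0]
        counter = small_cohort.neoepitope_counter(case.case_id, sid)
        res = observed_expected_test(
            case.mutations_in_sample(sid), counter, small_rates, small_cohort.genome,
            n_replicates=30, seed=2, sample_id=sid,
        )

        def p_for(observed):
            k = sum(_ratio(observed, e) >= 1.0 for e in res.expected_counts)
            return (k + 1) / (len(res.expected_counts) + 1)

        ps = [p_for(o) for o in range(res.observed_count + 1)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_too_few_replicates_rejected(self, small_cohort, small_rates):
        case = next(iter(small_cohort.cases.values()))
        counter = NeoEpitopeCounter(
            small_cohort.proteins(), case.hla_alleles, hash_binder_predicate(0.0)
        )
        with pytest.raises(ValueError):
            observed_expected_test(
                case.mutations[:5], counter, small_rates, small_cohort.genome,
                n_replicates=5,
            )


class TestGroupedTest:
    def test_null_distribution_structure(self, small_cohort, small_rates):
        case = next(iter(small_cohort.cases.values()))
        inputs = [
            (
                case.mutations_in_sample(sid)[:30],
                small_cohort.neoepitope_counter(case.case_id, sid),
            )
            for sid in case.sample_ids[:2]
        ]
        res = grouped_mean_ratio_null(
            inputs, small_rates, small_cohort.genome,
            n_outer=20, n_inner=10, seed=3, group_id="case",
        )
        assert len(res.null_means) == 20
        assert 0 < res.p_value <= 1

    def test_single_sample_delegates(self, small_cohort, small_rates):
        case = next(iter(small_cohort.cases.values()))
        sid = case.sample_ids[0]
        inputs = [(case.mutations_in_sample(sid)[:20],
                   small_cohort.neoepitope_counter(case.case_id, sid))]
        res = grouped_mean_ratio_null(
            inputs, small_rates, small_cohort.genome, n_inner=15, seed=1, group_id=sid
        )
        assert res.null_means == []


class TestHlaLoh:
    TABLE = pd.DataFrame(
        {
            "allele": ["HLA-A*01", "HLA-B*07", "HLA-C*04"],
            "copy_number": [0.4, 0.6, 0.3],
            "p_value": [0.01, 0.01, 0.2],
        }
    )

    def test_loss_rule(self):
        calls, _ = hla_loh_assess(self.TABLE)
        lost = {c.allele: c.lost for c in calls}
        assert lost == {"HLA-A*01": True, "HLA-B*07": False, "HLA-C*04": False}

    def test_fraction_restricted_to_lost(self):
        neo = {
            "n1": ["HLA-A*01"],
            "n2": ["HLA-A*01"],
            "n3": ["HLA-B*07"],
            "n4": ["HLA-A*01", "HLA-B*07"],
        }
        _, frac = hla_loh_assess(self.TABLE, neo)
        assert frac == pytest.approx(0.5)

    def test_invariant_enforced(self):
        from mima.immunoediting import HlaLohCall

        with pytest.raises(ValueError):
            HlaLohCall("x", 0.8, 0.01, lost=True)


def test_hash_predicate_exchangeable_between_observed_and_simulated(small_cohort, small_rates):
    """The generator and the simulator share one placement kernel, so under
    the null the observed neo-epitope count sits inside the simulated range."""
    case = next(iter(small_cohort.cases.values()))
    sid = case.sample_ids[0]
    counter = small_cohort.neoepitope_counter(case.case_id, sid)
    res = observed_expected_test(
        case.mutations_in_sample(sid), counter, small_rates, small_cohort.genome,
        n_replicates=50, seed=9, sample_id=sid,
    )
    lo, hi = np.quantile(res.expected_counts, [0.0, 1.0])
    assert lo - 5 <= res.observed_count <= hi + 5
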