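"""Seeded generator for synthetic multi-metastasis cohorts.

Each case gets a random clade tree over its metastases; mutations live on the
root edge (stem), clade edges, or leaf edges (private), with substitution
channels drawn from a configured signature mixture and genomic positions
placed by the same rate/coverage/context kernel the immunoediting simulator
uses.  Read counts, lineage-graded mutant-allele expression, TCR repertoires
with shared expanded clones, HLA LOH events, clade-structured immune
expression, and clustered cell centroids complete the cohort; every latent
truth is recorded in a manifest so downstream recovery can be verified.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .._channels import CHANNELS
from ..datatypes import MutationRecord, PresenceMatrix
from ..immunoediting import NeoEpitopeCounter, build_gene_rates, hash_binder_predicate
from ..tme import CYTOLYTIC_GENES, load_panel
from .catalog import synthetic_signature_catalog
from .genome import SyntheticGenome
from .pointset import generate_pointset

CD3_GENES = ("CD3D", "CD3G", "CD3E", "CD247")
ORGANS = ("bone", "liver", "lung", "brain", "lymph_node", "pleura")
_CODONS_NOSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in {"TAA", "TAG", "TGA"}
]


@dataclass
class CohortConfig:
    """Study conditions for a generated cohort.

    Mutation-count means and repertoire sizes are desk-scale versions of a
    multi-region autopsy series (several metastases per case, stem/clade/
    private architecture, a small number of clades per case).
    """

    n_cases: int = 10
    metastases_per_case: tuple[int, int] = (5, 20)
    n_clades: int = 3
    stem_mutations_mean: float = 120.0
    clade_mutations_mean: float = 60.0
    private_mutations_mean: float = 30.0
    signature_mixture: dict[str, float] = field(
        default_factory=lambda: {"SIG1": 0.4, "SIG2": 0.2, "SIG13": 0.2, "SIG17": 0.2}
    )
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 80.0
    subclonal_fraction: float = 0.2
    expression_gradient: tuple[float, float, float] = (0.5, 0.25, 0.08)
    tcr_clones_per_site: int = 150
    clone_size_exponent: float = 2.0
    tcr_stem_fraction: float = 0.22
    tcr_clade_fraction: float = 0.5
    depletion_strength: float = 1.0
    binder_rate: float = 0.02
    hla_loh_cases: int = 2
    n_genes: int = 300
    cells_per_sample: int = 600
    organ_by_clade: bool = True
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        def bad(name, why):
            raise ValueError(f"invalid CohortConfig.{name}: {why}")

        for name in ("n_cases", "n_clades", "tcr_clones_per_site", "n_genes", "cells_per_sample"):
            if getattr(self, name) < 1:
                bad(name, "must be a positive count")
        lo, hi = self.metastases_per_case
        if not (2 <= lo <= hi):
            bad("metastases_per_case", "need 2 <= low <= high")
        for name in ("stem_mutations_mean", "clade_mutations_mean", "private_mutations_mean"):
            if getattr(self, name) < 0:
                bad(name, "must be non-negative")
        w = np.array(list(self.signature_mixture.values()), dtype=float)
        if (w < 0).any():
            bad("signature_mixture", "weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            bad("signature_mixture", f"weights must sum to 1, got {w.sum()}")
        plo, phi = self.purity_range
        if not (0.0 <= plo <= phi <= 1.0):
            bad("purity_range", "must be an ordered pair of fractions")
        for name in (
            "subclonal_fraction",
            "tcr_stem_fraction",
            "tcr_clade_fraction",
            "depletion_strength",
            "binder_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, f"must be a fraction in [0, 1], got {v}")
        if self.tcr_stem_fraction + self.tcr_clade_fraction > 1.0:
            bad("tcr_clade_fraction", "stem + clade TCR fractions exceed 1")
        g = self.expression_gradient
        if not (g[0] > g[1] > g[2] >= 0):
            bad("expression_gradient", "means must be ordered stem > clade > private")
        if self.clone_size_exponent <= 1.0:
            bad("clone_size_exponent", "power-law exponent must exceed 1")
        if self.depth_mean <= 0:
            bad("depth_mean", "must be positive")
        if self.hla_loh_cases < 0:
            bad("hla_loh_cases", "must be a non-negative count")


@dataclass
class CaseData:
    case_id: str
    sample_ids: list[str]
    organs: dict[str, str]
    clade_of_sample: dict[str, int]
    purity: dict[str, float]
    mutations: list[MutationRecord]
    lineage_truth: dict[str, str]
    signature_truth: dict[str, str]
    ccf: dict[str, float]
    presence_true: pd.DataFrame
    alt_reads: pd.DataFrame
    depth: pd.DataFrame
    rna_vaf: pd.DataFrame
    tree_newick: str
    clonotypes: pd.DataFrame
    tcr_truth: dict[str, str]
    hla_alleles: list[str]
    hla_table: pd.DataFrame
    depleted: bool

    def presence_matrix(self, from_reads: bool = False) -> PresenceMatrix:
        if from_reads:
            return PresenceMatrix.from_reads(self.alt_reads, self.depth)
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = (self.alt_reads / self.depth).where(self.depth > 0, 0.0)
        return PresenceMatrix(
            presence=self.presence_true, vaf=vaf, depth=self.depth, alt=self.alt_reads
        )

    def mutations_in_sample(self, sample_id: str) -> list[MutationRecord]:
        present = self.presence_true[sample_id]
        return [m for m in self.mutations if present[m.mutation_id]]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genome: SyntheticGenome
    reference_catalog: pd.Series
    signature_catalog: pd.DataFrame
    cases: dict[str, CaseData]
    expression: pd.DataFrame
    transcript_rpkm: pd.DataFrame
    pointsets: dict[str, pd.DataFrame]

    @property
    def all_sample_ids(self) -> list[str]:
        return [s for c in self.cases.values() for s in c.sample_ids]

    def proteins(self) -> dict[str, str]:
        return {name: g.protein for name, g in self.genome.genes.items()}

    def true_exposures(self, case_id: str) -> pd.DataFrame:
        """Per-sample mutation counts by generating signature (samples x signatures)."""
        case = self.cases[case_id]
        sigs = list(self.signature_catalog.columns)
        out = pd.DataFrame(0, index=case.sample_ids, columns=sigs)
        for m in case.mutations:
            sig = case.signature_truth[m.mutation_id]
            present = case.presence_true.loc[m.mutation_id]
            out.loc[present[present].index, sig] += 1
        return out

    def neoepitope_counter(self, case_id: str, sample_id: str) -> NeoEpitopeCounter:
        case = self.cases[case_id]
        return NeoEpitopeCounter(
            proteins=self.proteins(),
            alleles=case.hla_alleles,
            predicate=hash_binder_predicate(self.config.binder_rate, seed=self.config.seed),
            gene_rpkm=self.expression[sample_id],
            transcript_rpkm=self.transcript_rpkm[sample_id],
        )

    def manifest(self) -> dict:
        """JSON-serializable ground truth sufficient for downstream recovery checks."""
        cfg = asdict(self.config)
        cfg["metastases_per_case"] = list(cfg["metastases_per_case"])
        cfg["purity_range"] = list(cfg["purity_range"])
        cfg["expression_gradient"] = list(cfg["expression_gradient"])
        cases = {}
        for cid, case in self.cases.items():
            cases[cid] = {
                "samples": case.sample_ids,
                "organs": case.organs,
                "clade_of_sample": {s: int(c) for s, c in case.clade_of_sample.items()},
                "purity": {s: float(p) for s, p in case.purity.items()},
                "lineage": case.lineage_truth,
                "signature": case.signature_truth,
                "ccf": {m: float(v) for m, v in case.ccf.items()},
                "tcr_sharing": case.tcr_truth,
                "tree_newick": case.tree_newick,
                "hla_alleles": case.hla_alleles,
                "hla_table": case.hla_table.to_dict(orient="records"),
                "depleted": case.depleted,
            }
        return {
            "config": cfg,
            "reference_catalog": {g: int(c) for g, c in self.reference_catalog.items()},
            "cases": cases,
        }


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_reference_catalog(
    n_genes: int, seed: int, gene_names: list[str] | None = None
) -> pd.Series:
    """Synthetic gene -> mutation-count background catalog (heavy-tailed counts)."""
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    counts = np.minimum(rng.zipf(1.5, size=n_genes), 5000)
    return pd.Series(counts, index=gene_names, name="mutation_count").astype(int)


def _random_partition(items: list, k: int, rng: np.random.Generator) -> list[list]:
    """Uniform random recursive bipartition of ``items`` into k non-empty groups."""
    groups = [list(items)]
    while len(groups) < k:
        splittable = [i for i, g in enumerate(groups) if len(g) > 1]
        g = groups.pop(splittable[int(rng.integers(len(splittable)))])
        order = rng.permutation(len(g))
        cut = int(rng.integers(1, len(g)))
        groups.append(sorted(g[i] for i in order[:cut]))
        groups.append(sorted(g[i] for i in order[cut:]))
    return groups


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        n_codons = int(rng.integers(10, 14))
        body = "".join(rng.choice(_CODONS_NOSTOP, size=n_codons))
        nt = "TGT" + body + ("TTT" if rng.random() < 0.5 else "TTC")
        if nt not in existing:
            existing.add(nt)
            return nt


def _translate(nt: str) -> str:
    from .genome import CODON_TABLE

    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


def clone_key(chain: str, v_call: str, j_call: str, cdr3_nt: str) -> str:
    return f"{chain}|{v_call}|{j_call}|{cdr3_nt}"


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_genome, ss_catalog, ss_sig, ss_cases, ss_expr, ss_points = root.spawn(6)

    genome = SyntheticGenome.generate(
        n_genes=config.n_genes, seed=ss_genome.generate_state(1)[0] % 2**31
    )
    ref_catalog = generate_reference_catalog(
        config.n_genes, seed=ss_catalog.generate_state(1)[0] % 2**31, gene_names=genome.gene_names
    )
    rates = build_gene_rates(ref_catalog)
    sig_labels = tuple(config.signature_mixture)
    sig_catalog = synthetic_signature_catalog(
        len(sig_labels), seed=ss_sig.generate_state(1)[0] % 2**31, labels=sig_labels
    )
    predicate = hash_binder_predicate(config.binder_rate, seed=config.seed)
    proteins = {name: g.protein for name, g in genome.genes.items()}
    thinning_counter = NeoEpitopeCounter(proteins, [], predicate)  # alleles set per case

    cases = {}
    case_seeds = ss_cases.spawn(config.n_cases)
    for ci in range(config.n_cases):
        case_id = f"case{ci + 1:02d}"
        deplete = config.depletion_strength < 1.0
        cases[case_id] = _generate_case(
            case_id,
            config,
            genome,
            rates,
            sig_catalog,
            predicate,
            proteins,
            deplete=deplete,
            apply_loh=ci < config.hla_loh_cases,
            rng=np.random.default_rng(case_seeds[ci]),
        )

    expression, transcript_rpkm = _generate_expression(
        config, genome, cases, rng=np.random.default_rng(ss_expr)
    )
    point_seeds = ss_points.spawn(len(cases))
    pointsets = {}
    for case, css in zip(cases.values(), point_seeds):
        sample_rngs = css.spawn(len(case.sample_ids))
        for sid, srs in zip(case.sample_ids, sample_rngs):
            pointsets[sid] = generate_pointset(
                config.cells_per_sample, seed=int(srs.generate_state(1)[0] % 2**31)
            )
    return SyntheticCohort(
        config=config,
        genome=genome,
        reference_catalog=ref_catalog,
        signature_catalog=sig_catalog,
        cases=cases,
        expression=expression,
        transcript_rpkm=transcript_rpkm,
        pointsets=pointsets,
    )


def _generate_case(
    case_id,
    cfg: CohortConfig,
    genome: SyntheticGenome,
    rates,
    sig_catalog: pd.DataFrame,
    predicate,
    proteins,
    deplete: bool,
    apply_loh: bool,
    rng: np.random.Generator,
) -> CaseData:
    lo, hi = cfg.metastases_per_case
    n_samples = int(rng.integers(lo, hi + 1))
    sample_ids = [f"{case_id}-{i + 1:03d}" for i in range(n_samples)]
    k = min(cfg.n_clades, n_samples)
    clades = _random_partition(list(range(n_samples)), k, rng)
    clade_of_sample = {sample_ids[i]: ci for ci, grp in enumerate(clades) for i in grp}
    if cfg.organ_by_clade:
        organs = {s: ORGANS[c % len(ORGANS)] for s, c in clade_of_sample.items()}
    else:
        organs = {s: ORGANS[int(rng.integers(len(ORGANS)))] for s in sample_ids}
    purity = {s: float(rng.uniform(*cfg.purity_range)) for s in sample_ids}

    hla_alleles = [
        f"HLA-{locus}*{int(rng.integers(1, 80)):02d}:0{copy}"
        for locus in "ABC"
        for copy in (1, 2)
    ]

    mixture = np.array([cfg.signature_mixture[s] for s in sig_catalog.columns])
    sig_cols = [sig_catalog[c].to_numpy() for c in sig_catalog.columns]
    rate_dict = rates.rates.to_dict()
    counter = NeoEpitopeCounter(proteins, hla_alleles, predicate)

    mut_counter = [0]

    def draw_mutations(n: int) -> list[tuple[MutationRecord, str]]:
        out = []
        for _ in range(n):
            si = int(rng.choice(len(mixture), p=mixture))
            channel = CHANNELS[int(rng.choice(96, p=sig_cols[si]))]
            mut_counter[0] += 1
            mid = f"{case_id}_m{mut_counter[0]:05d}"
            rec = genome.place_mutation(channel, rate_dict, rng, case_id, mid)
            if deplete and counter.binds(rec) and rng.random() > cfg.depletion_strength:
                for _ in range(50):  # swap for a context-matched non-binder position
                    cand = genome.place_mutation(channel, rate_dict, rng, case_id, mid)
                    if not counter.binds(cand):
                        rec = cand
                        break
            out.append((rec, sig_catalog.columns[si]))
        return out

    mutations: list[MutationRecord] = []
    signature_truth: dict[str, str] = {}
    ccf: dict[str, float] = {}
    presence_rows: dict[str, np.ndarray] = {}

    def add(records, present_mask, subclonal_eligible):
        for rec, sig in records:
            mutations.append(rec)
            signature_truth[rec.mutation_id] = sig
            if subclonal_eligible and rng.random() < cfg.subclonal_fraction:
                ccf[rec.mutation_id] = float(rng.uniform(0.3, 0.9))
            else:
                ccf[rec.mutation_id] = 1.0
            presence_rows[rec.mutation_id] = present_mask

    all_mask = np.ones(n_samples, dtype=bool)
    add(draw_mutations(int(rng.poisson(cfg.stem_mutations_mean))), all_mask, True)
    clade_counts = []
    for grp in clades:
        mask = np.zeros(n_samples, dtype=bool)
        mask[grp] = True
        # a clade edge to a single leaf coincides with the leaf edge: its
        # distinguishing mutations are the sample's private ones
        n_c = int(rng.poisson(cfg.clade_mutations_mean)) if len(grp) > 1 else 0
        clade_counts.append(n_c)
        add(draw_mutations(n_c), mask, True)
    private_counts = []
    for i in range(n_samples):
        mask = np.zeros(n_samples, dtype=bool)
        mask[i] = True
        n_p = int(rng.poisson(cfg.private_mutations_mean))
        private_counts.append(n_p)
        add(draw_mutations(n_p), mask, False)

    mut_ids = [m.mutation_id for m in mutations]
    presence_true = pd.DataFrame(
        np.vstack([presence_rows[m] for m in mut_ids]), index=mut_ids, columns=sample_ids
    )
    lineage_truth = {}
    n_present = presence_true.sum(axis=1)
    for mid in mut_ids:
        if n_present[mid] == n_samples:
            lineage_truth[mid] = "stem"
        elif n_present[mid] == 1:
            lineage_truth[mid] = "private"
        else:
            lineage_truth[mid] = "clade"

    depth = pd.DataFrame(
        rng.poisson(cfg.depth_mean, size=(len(mut_ids), n_samples)),
        index=mut_ids,
        columns=sample_ids,
    )
    pur = np.array([purity[s] for s in sample_ids])
    ccf_vec = np.array([ccf[m] for m in mut_ids])
    p_alt = np.clip(np.outer(ccf_vec, pur) / 2.0, 0, 1)
    alt = pd.DataFrame(
        rng.binomial(depth.to_numpy(), p_alt) * presence_true.to_numpy(),
        index=mut_ids,
        columns=sample_ids,
    )

    gradient = dict(zip(("stem", "clade", "private"), cfg.expression_gradient))
    kappa = 20.0
    rna = np.zeros((len(mut_ids), n_samples))
    for i, mid in enumerate(mut_ids):
        mean = max(gradient[lineage_truth[mid]], 1e-3)
        present = presence_true.iloc[i].to_numpy()
        rna[i, present] = rng.beta(mean * kappa, (1 - mean) * kappa, size=present.sum())
    rna_vaf = pd.DataFrame(rna, index=mut_ids, columns=sample_ids)

    tree_newick = _case_newick(sample_ids, clades, clade_counts, private_counts)

    clonotypes, tcr_truth = _generate_repertoires(cfg, sample_ids, clades, rng)

    hla_rows = []
    n_lost = int(rng.integers(1, 4)) if apply_loh else 0
    lost_idx = set(rng.choice(6, size=n_lost, replace=False).tolist()) if n_lost else set()
    for ai, allele in enumerate(hla_alleles):
        if ai in lost_idx:
            cn, p = float(rng.uniform(0.1, 0.45)), float(rng.uniform(0.001, 0.02))
        else:
            cn, p = float(rng.uniform(0.8, 1.6)), float(rng.uniform(0.1, 0.95))
        hla_rows.append({"allele": allele, "copy_number": cn, "p_value": p})

    return CaseData(
        case_id=case_id,
        sample_ids=sample_ids,
        organs=organs,
        clade_of_sample=clade_of_sample,
        purity=purity,
        mutations=mutations,
        lineage_truth=lineage_truth,
        signature_truth=signature_truth,
        ccf=ccf,
        presence_true=presence_true,
        alt_reads=alt,
        depth=depth,
        rna_vaf=rna_vaf,
        tree_newick=tree_newick,
        clonotypes=clonotypes,
        tcr_truth=tcr_truth,
        hla_alleles=hla_alleles,
        hla_table=pd.DataFrame(hla_rows),
        depleted=deplete,
    )


def _case_newick(sample_ids, clades, clade_counts, private_counts) -> str:
    parts = []
    for ci, grp in enumerate(clades):
        leaves = [f"{sample_ids[i]}:{private_counts[i] + 1}" for i in grp]
        if len(grp) == 1:
            parts.append(f"{sample_ids[grp[0]]}:{private_counts[grp[0]] + clade_counts[ci] + 1}")
        else:
            parts.append(f"({','.join(leaves)}):{clade_counts[ci] + 1}")
    return f"({','.join(parts)});"


def _generate_repertoires(cfg: CohortConfig, sample_ids, clades, rng):
    n = cfg.tcr_clones_per_site
    n_stem = max(1, round(cfg.tcr_stem_fraction * n))
    n_clade = max(1, round(cfg.tcr_clade_fraction * n))
    n_private = max(0, n - n_stem - n_clade)

    rows = []
    truth: dict[str, str] = {}
    for chain, v_prefix, j_prefix, nv, nj in (
        ("alpha", "TRAV", "TRAJ", 40, 50),
        ("beta", "TRBV", "TRBJ", 30, 13),
    ):
        seen: set[str] = set()

        def new_clone():
            v = f"{v_prefix}{int(rng.integers(1, nv + 1))}"
            j = f"{j_prefix}{int(rng.integers(1, nj + 1))}"
            nt = _random_cdr3(rng, seen)
            return (chain, v, j, nt, _translate(nt))

        def size(boost):
            return int(min(rng.zipf(cfg.clone_size_exponent), 5000)) + boost

        stem_pool = [new_clone() for _ in range(n_stem)]
        clade_pools = [[new_clone() for _ in range(n_clade)] for _ in clades]
        presence_count = {}
        for clone in stem_pool:
            presence_count[clone] = len(sample_ids)
        for grp, pool in zip(clades, clade_pools):
            for clone in pool:
                presence_count[clone] = len(grp)
        for si, sid in enumerate(sample_ids):
            my_clade = next(ci for ci, grp in enumerate(clades) if si in grp)
            for clone in stem_pool:
                rows.append((sid, *clone, size(4)))
            for clone in clade_pools[my_clade]:
                rows.append((sid, *clone, size(2)))
            for _ in range(n_private):
                clone = new_clone()
                presence_count[clone] = 1
                rows.append((sid, *clone, size(0)))
        for clone, cnt in presence_count.items():
            label = "stem" if cnt == len(sample_ids) else ("private" if cnt == 1 else "clade")
            truth[clone_key(clone[0], clone[1], clone[2], clone[3])] = label

    clonotypes = pd.DataFrame(
        rows,
        columns=["sample_id", "chain", "v_call", "j_call", "cdr3_nt", "cdr3_aa", "duplicate_count"],
    )
    return clonotypes, truth


def _generate_expression(cfg: CohortConfig, genome, cases, rng):
    panel = load_panel()
    immune_genes = list(dict.fromkeys(list(panel["gene"]) + list(CYTOLYTIC_GENES)))
    sample_ids = [s for c in cases.values() for s in c.sample_ids]
    genes = genome.gene_names + immune_genes + list(CD3_GENES)

    expr = pd.DataFrame(0.0, index=genes, columns=sample_ids)
    expr.loc[genome.gene_names] = np.exp(
        rng.normal(0.7, 1.2, size=(len(genome.gene_names), len(sample_ids)))
    )
    # clade-structured immune expression: one shared effect per (case, clade)
    for case in cases.values():
        effects = {c: rng.normal(0.0, 0.7) for c in set(case.clade_of_sample.values())}
        for sid in case.sample_ids:
            eff = effects[case.clade_of_sample[sid]]
            expr.loc[immune_genes, sid] = np.exp(
                rng.normal(2.0 + eff, 0.5, size=len(immune_genes))
            )
    # CD3-complex genes track total TCR reads
    for case in cases.values():
        reads = case.clonotypes.groupby("sample_id")["duplicate_count"].sum()
        for sid in case.sample_ids:
            total = float(reads.get(sid, 0))
            expr.loc[list(CD3_GENES), sid] = (
                total / 400.0 * np.exp(rng.normal(0, 0.15, size=len(CD3_GENES)))
            )
    transcript = expr * np.exp(rng.normal(0.0, 0.2, size=expr.shape))
    return expr, transcript
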