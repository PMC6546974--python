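"""Synthetic gene set underlying generated cohorts.

Each gene is a random intron-less coding sequence.  From the sequence we
derive everything the downstream stages need: trinucleotide contexts, protein
translations for neo-epitope enumeration, per-position coverage weights, and
an index of positions by pyrimidine-centred context.  Mutations are placed on
this gene set by one shared kernel — gene chosen proportionally to a
reference-catalog rate (restricted to genes carrying the required context),
position within the gene proportionally to its coverage weight — used both
when generating "observed" mutations and when simulating context-matched
expected mutations, so that under the null the two are exchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .._channels import COMPLEMENT, PYRIMIDINES, canonical_channel, channel_parts, revcomp
from ..datatypes import MutationRecord

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
CODON_TABLE = {c: str(Seq(c).translate()) for c in _CODONS}
CODON_TABLE.update({c: "*" for c in _STOPS})


@dataclass
class GeneModel:
    name: str
    cds: str
    coverage: np.ndarray  # per-base fraction of panel samples covered >= 14 reads
    context_positions: dict[str, np.ndarray]  # canonical 3-mer -> 1-based positions

    @property
    def protein(self) -> str:
        return "".join(CODON_TABLE[self.cds[i : i + 3]] for i in range(0, len(self.cds), 3))

    def __len__(self) -> int:
        return len(self.cds)


def _index_contexts(cds: str) -> dict[str, np.ndarray]:
    idx: dict[str, list[int]] = {}
    for p in range(2, len(cds)):  # 1-based positions 2..L-1
        ctx = cds[p - 2 : p + 1]
        canon = ctx if ctx[1] in PYRIMIDINES else revcomp(ctx)
        idx.setdefault(canon, []).append(p)
    return {k: np.asarray(v, dtype=np.int64) for k, v in idx.items()}


class SyntheticGenome:
    """A seeded collection of :class:`GeneModel` with a context lookup."""

    def __init__(self, genes: dict[str, GeneModel]):
        self.genes = genes
        self.gene_names = list(genes)
        # canonical context -> list of gene names carrying it
        self.context_genes: dict[str, list[str]] = {}
        for name, g in genes.items():
            for ctx in g.context_positions:
                self.context_genes.setdefault(ctx, []).append(name)

    @classmethod
    def generate(
        cls,
        n_genes: int = 300,
        seed: int = 0,
        codon_range: tuple[int, int] = (120, 400),
        coverage_beta: tuple[float, float] = (10.0, 2.0),
    ) -> "SyntheticGenome":
        if n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        rng = np.random.default_rng(seed)
        genes = {}
        for i in range(n_genes):
            name = f"GENE{i + 1:04d}"
            n_codons = int(rng.integers(codon_range[0], codon_range[1] + 1))
            codons = rng.choice(_CODONS, size=n_codons)
            cds = "".join(codons)
            coverage = rng.beta(*coverage_beta, size=len(cds))
            genes[name] = GeneModel(name, cds, coverage, _index_contexts(cds))
        genome = cls(genes)
        missing = [c for c in _all_canonical_contexts() if c not in genome.context_genes]
        if missing:  # astronomically unlikely at realistic sizes
            raise RuntimeError(f"generated genome lacks contexts: {missing}")
        return genome

    def place_mutation(
        self,
        channel: str,
        gene_rates: "np.ndarray | dict[str, float]",
        rng: np.random.Generator,
        case_id: str = "",
        mutation_id: str = "",
    ) -> MutationRecord:
        """Draw a genomic location for a substitution of the given 96-channel class.

        The trinucleotide context is preserved exactly: only positions whose
        (strand-collapsed) context matches the channel are eligible.  Gene is
        chosen proportionally to ``gene_rates`` over context-bearing genes;
        position within the gene proportionally to its coverage weight.
        """
        ref_c, alt_c, ctx_c = channel_parts(channel)
        candidates = self.context_genes.get(ctx_c)
        if not candidates:
            raise ValueError(f"no gene carries context {ctx_c!r}")
        if isinstance(gene_rates, dict):
            w = np.array([gene_rates.get(g, 0.0) for g in candidates], dtype=float)
        else:
            w = np.asarray(gene_rates, dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(candidates))
        gene_name = candidates[rng.choice(len(candidates), p=w / w.sum())]
        gene = self.genes[gene_name]
        positions = gene.context_positions[ctx_c]
        cov = gene.coverage[positions - 1]
        pos = int(positions[rng.choice(len(positions), p=cov / cov.sum())])
        return self._record_at(gene, pos, alt_c, case_id, mutation_id)

    def _record_at(
        self, gene: GeneModel, pos: int, alt_canonical: str, case_id: str, mutation_id: str
    ) -> MutationRecord:
        ref = gene.cds[pos - 1]
        alt = alt_canonical if ref in PYRIMIDINES else COMPLEMENT[alt_canonical]
        context = gene.cds[pos - 2 : pos + 1]
        ci = (pos - 1) // 3
        codon = gene.cds[3 * ci : 3 * ci + 3]
        off = (pos - 1) % 3
        new_codon = codon[:off] + alt + codon[off + 1 :]
        aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[new_codon]
        if aa_alt == aa_ref:
            effect = "silent"
        elif aa_alt == "*":
            effect = "truncating"
        elif aa_ref == "*":
            effect = "nonstop"
        else:
            effect = "missense"
        return MutationRecord(
            case_id=case_id,
            mutation_id=mutation_id,
            chrom=gene.name,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene.name,
            effect=effect,
            trinucleotide_context=context,
            protein_pos=ci + 1,
            aa_ref=aa_ref,
            aa_alt=aa_alt,
        )

    def channel_of(self, record: MutationRecord) -> str:
        return canonical_channel(record.ref, record.alt, record.trinucleotide_context)

    def coverage_index(self) -> dict[tuple[str, int], float]:
        """Flat (gene, 1-based position) -> covered-fraction mapping."""
        return {
            (name, p + 1): float(f)
            for name, g in self.genes.items()
            for p, f in enumerate(g.coverage)
        }


def _all_canonical_contexts() -> list[str]:
    return [five + mid + three for mid in PYRIMIDINES for five in "ACGT" for three in "ACGT"]
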