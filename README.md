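# mima — multi-region immuno-metastasis analysis

`mima` implements the bespoke computational procedures used to analyse
multi-region autopsy cohorts of metastatic breast cancer, where several
metastases per patient are profiled by WES, RNA-seq, TCR sequencing and
digital pathology. It is aimed at cancer-genomics and tumor-immunology
analysts who want these procedures as tested, reusable library code, and it
ships a seeded synthetic multi-metastasis cohort generator so the entire
pipeline can be exercised — and its statistical behaviour verified — without
access to controlled patient data.

## What it computes

**Lineage classification.** Within a case, a mutation (or TCR clone) is
*metastatic stem* when present in all metastases, *clade* when present in at
least two but not all, and *private* when found in a single metastasis.
Around this sit the targeted-sequencing detection rules (depth ≥ 500×,
AF ≥ mean + 3 SD of controls, AF ≥ 1%, sample QC at >90% of AFs < 5%),
WES-vs-TS validation metrics (TP/(TP+FN) etc.), mutant-allele expression
Z scores, germline concordance (> 90% ⇒ related), and the posterior/cluster
filters that prepare clone-tree inputs.

**Mutational signatures.** Profiles are 96-channel pyrimidine-centred
spectra m. Extraction is multiplicative-update NMF under generalized KL
divergence with bootstrap consensus; refitting solves
min‖m − S·e‖², e ≥ 0 (NNLS) against a catalog S, attributing a signature
only when its exposure reaches max(0.03·total, 10) mutations. Diagnostics:
residual RMSE, Shannon entropy of the normalized profile, and a 10,000×
bootstrap cosine-similarity test with a label-swap null.

**Immunoediting test.** Neo-epitopes are missense mutations with ≥ 1 mutant
9-mer (sliding window over a mutant-centred 17–21-aa stretch) binding ≥ 1
patient HLA allele at IC50 ≤ 500 nM — behind a pluggable predicate, with a
deterministic hash surrogate as default — and gene/transcript RPKM > 1.
Each replicate re-places every observed mutation at a random position with
the identical trinucleotide context (gene ∝ background rate, position ∝
coverage weight ≥ 14 reads), and the empirical p is the pseudo-counted
fraction of replicates whose observed/expected ratio reaches 1:
p = (k+1)/(n+1). Group-level means use a 20×100 nested simulation null.
HLA LOH is called at copy number < 0.5 with p < 0.05.

**TCR repertoire.** UMI consensus (TNNNNTNNNNTNNNNT barcodes, > 80%
within-barcode identity), clones as identical CDR3 nucleotide sequence +
V(/J) gene, public-TCR removal, stem/clade/private sharing, subsampled
(depth 1000, 20 repeats) vertex/cluster Gini and cluster-size metrics,
clonal overlap O(i,j) = C_ij / ½(C_i + C_j), CDR3 amino-acid Jaccard
matrices with complete-linkage trees, read-reshuffling organ permutation
tests, and edge-weighted cophenetic / Robinson–Foulds concordance between
TCR trees and genomic trees.

**Microenvironment.** Cytolytic activity = geometric mean of GZMA and PRF1
TPM (pseudocount 0.01); immunophenogram category Z scores with
IPS ∈ {0..10} (aggregate Z ≥ 3 → 10, ≤ 0 → 0); kNN cell density
Σ_N = N/(π·d_N²) with N = 50 on digitized-slide centroids.

## Worked example

```python
from mima.synthetic import CohortConfig, generate_cohort
from mima import landscape, signatures

cohort = generate_cohort(CohortConfig(n_cases=2, seed=1))
case = cohort.cases["case01"]

labels, counts = landscape.classify_lineage(case.presence_matrix())
print(counts)

profile = signatures.build_profile96(case.mutations)
fit = signatures.fit_exposures(profile, cohort.signature_catalog)
print(fit.exposures.round(0).to_dict(), round(fit.rmse, 2))
```

prints

```
{'stem': 112, 'clade': 179, 'private': 349}
{'SIG1': 266.0, 'SIG2': 134.0, 'SIG13': 95.0, 'SIG17': 137.0} 2.51
```

The first line is the case's mutation-lineage census (every mutation is
present in all / some / one of its 11 metastases). The second line refits
per-signature exposures in mutation units against the cohort's (synthetic)
signature catalog — the case was generated with mixture 0.4/0.2/0.2/0.2
over 640 mutations, and the refit recovers those contributions with a small
channel-level RMSE.

A full orchestrated run (cohort → landscape → signatures → immunoediting →
TCR → TME) is available as `mima run --config run.yaml`, and
`mima synth --seed 1 --out cohort/` writes per-sample VCFs, AIRR-style
clonotype TSVs, expression CSV, newick trees and a ground-truth manifest.

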