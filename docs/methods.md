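# Methods

This note records the models behind `mima`, the defaults that matter, what
the synthetic cohort generator does and does not emulate, and the numerical
choices made where the underlying procedures left the design open.

## Synthetic cohort model

Each case receives a random number of metastases (default 5–20) partitioned
into up to `n_clades` (default 3) clades by uniform random recursive
bipartition; singleton clades draw no clade-level mutations, since a clade
edge ending in one leaf coincides with that leaf's edge. Mutations live on
the root edge (stem), clade edges, or leaf edges (private), with Poisson
counts around configurable means (defaults 120/60/30 — a desk-scale version
of exome burdens in heavily pretreated metastatic disease).

Mutations are substitutions on a small synthetic gene set: each gene is a
random intron-less CDS (120–400 codons drawn from the 61 sense codons), so
trinucleotide contexts, protein translations and protein effects all derive
from actual sequence. A mutation's 96-channel class is drawn from the
configured signature mixture (default 0.4/0.2/0.2/0.2 over four synthetic
catalog signatures); its genomic position is then drawn by the *placement
kernel*: gene proportional to a background per-gene rate (heavy-tailed
synthetic reference catalog) restricted to genes carrying the required
context, position within the gene proportional to a per-base coverage
weight (Beta(10,2), emulating the fraction of panel samples covered at
≥ 14 reads). The immunoediting simulator uses the identical kernel, which
makes observed and simulated mutation sets exchangeable under the null —
the property that calibrates the empirical p-values.

Read counts are Binomial(depth, purity·CCF/2) with depth ~ Poisson(80) and
purity ~ U(0.3, 0.9) (diploid assumption); a configurable fraction (0.2) of
stem/clade mutations is subclonal with CCF ~ U(0.3, 0.9). The
`expression_gradient` is implemented as the lineage-specific mean RNA
variant-allele fraction (defaults 0.50/0.25/0.08 for stem/clade/private,
Beta-distributed with concentration 20), while gene-level TPM is drawn
independently of mutation status (log-normal). Two things follow: the
mutant-allele expression Z-score gradient stem > clade > private is
recoverable through the RNA-VAF term, and the neo-epitope expression filter
(gene/transcript RPKM > 1) treats observed and simulated mutations
identically, preserving null exchangeability.

TCR repertoires per site hold `tcr_clones_per_site` (default 150) clones:
a stem pool included in every site (fraction 0.22), per-clade pools
included in every site of the clade (0.50), and site-private clones. Clone
sizes are truncated Zipf draws (exponent 2.0) with additive boosts (+4
stem, +2 clade) so shared clones are more expanded, drawn independently per
site so clonal representation varies between sites. CDR3s are random
in-frame nucleotide sequences (Cys...Phe); both α and β chains are
generated. Immune-panel gene expression carries a shared per-(case, clade)
log-normal effect (clade-structured immune expression); CD3D/G/E/CD247 TPM
tracks each sample's total TCR reads. HLA tables give six alleles per case;
the first `hla_loh_cases` cases get 1–3 alleles with copy number
U(0.1, 0.45) and p U(0.001, 0.02). Cell centroids are Gaussian blobs (70%
of cells in 5 clusters, SD 60 px on a 2000×2000 px field) over a uniform
background.

Peptide "binding" ground truth is a deterministic seeded hash of
(peptide, allele): a configurable fraction (default 0.02) of pairs falls at
or below 500 nM. `depletion_strength` d thins binders in the *observed*
mutations only: a generated mutation with a binding peptide is kept with
probability d, otherwise swapped for a context-matched non-binder position,
leaving the mutation count and spectrum unchanged. d = 1 is the null.

**What the generator does not emulate:** real COSMIC signature profiles
(the catalog is synthetic), copy-number variation and its effect on VAF/CCF,
indels and structural variants, read-level sequencing error, genuine MHC
binding affinity landscapes, V(D)J recombination statistics, or spatial
interaction between cell classes. Passing recovery tests therefore shows
the *procedures* are correct and calibrated under their stated assumptions,
not that those assumptions hold in any particular patient cohort.

## Analysis procedures and conventions

**Lineage.** Stem iff present in all samples of the case, private iff in
exactly one, clade otherwise; presence calls from reads use alt ≥ 3 AND
VAF ≥ 0.02 (configurable). Classification accepts any variant type.

**TS detection.** detected iff depth ≥ 500 AND AF ≥ mean + 3·SD of ≥ 2
controls (sample SD, ddof 1) AND AF ≥ 0.01; loci with < 2 controls are
"uncallable"; a sample fails QC when > 90% of its mutations have AF < 0.05.

**Validation metrics.** TP/FP/FN/TN from the WES/TS set algebra over a
stated universe. An empty denominator means there were no cases of that
kind to get wrong; the metric is reported as vacuously 1.0 (its numerator
is necessarily 0, so no information is lost).

**Genotype concordance.** Shared fraction defaults to Jaccard
|A∩B|/|A∪B| for symmetry (the alternative |A∩B|/min(|A|,|B|) is selectable);
"related" is strict > 0.90.

**Tree-input filters.** Posterior binarization keeps entries ≥ 0.5 (the
boundary 0.5 maps to present) after removing rows below 0.5 everywhere.
Cluster filtering applies, in order: drop clusters never exceeding
prevalence 0.1; among clusters present (prevalence > 0.1) in all samples
keep only the highest; call a surviving cluster present in a sample iff
≥ 40% of members have VAF > 0.01. "Present in all samples" in the middle
step is prevalence-based (> 0.1), consistent with the first step's
threshold, since the binary patterns are only produced afterwards.

**Signatures.** Channel order is substitution-class major (C>A … T>G),
flanking-context minor, both alphabetical. KL-NMF uses multiplicative
updates, 200 iterations max, relative tolerance 1e-6, U(0,1) seeded
initialization; bootstrap consensus pools per-bootstrap signatures and
greedily clusters at cosine ≥ 0.8. Exposure refitting is plain NNLS on raw
counts (no sum constraint; catalog columns are normalized so exposures come
out in mutation units); the attribution threshold max(0.03·total, 10) is
applied iteratively — drop, refit, repeat until stable — with a `min()`
switch. If no signature survives, exposures are all zero with
rmse = rms(m) and a flag. The similarity bootstrap resamples each profile
multinomially; its null pools both profiles and resplits at the observed
totals; p is the pseudo-counted fraction of null cosines ≥ observed, so
high similarity gives small p.

**Immunoediting.** Per-mutation counting: ≥ 1 mutant 9-mer from the
mutant-centred window (default 17 aa, truncated at termini) binding ≥ 1
allele at ≤ 500 nM, with gene and transcript RPKM > 1; several binding
peptides from one mutation count once. Ratio conventions for expected = 0:
observed = 0 ties at 1 (counts toward k), observed > 0 counts as above 1 —
both conservative against false depletion claims. Empirical
p = (k+1)/(n+1) with k the replicates at ratio ≥ 1; at n = 100 a fully
depleted sample (k = 0) gets p = 1/101 ≈ 0.0099. Tie inclusion makes the
test conservative when counts are small; calibration is checked at
realistic per-sample burdens where ties are rare (~4% of replicates). The
grouped test compares the group's mean ratio with 20 nested pseudo-observed
means (100 inner simulations each), one-sided toward depletion. Genes
lacking a required context are excluded and rates renormalized.

**TCR.** UMI groups need the conserved-T template and > 80% mean pairwise
identity (positionwise majority consensus). Clones are keyed on chain +
CDR3 nucleotide + V + J by default (`clone_key="v"` drops J). Subsampling
draws reads without replacement; samples under the depth are excluded, not
exhausted. Gini uses the mean-absolute-difference estimator with no
small-sample correction. MCS/LCS are reported in two dialects because the
printed formulas (÷ number of clusters × 100) cannot yield percentages of
reads: the default dialect is 100 × cluster reads / subsample reads
(mean / max), the as-printed dialect is also emitted. Complete-linkage
merges break ties lexicographically by sample id (labels are sorted before
linkage). The organ permutation test reshuffles reads across metastases
preserving per-sample totals; organ concordance is measured two ways —
Pearson correlation between tree path-sum distances and the
different-organ indicator, and RF distance to an organ-polytomy reference
tree — each with its own one-sided pseudo-counted p. Tree concordance uses
path-sum (patristic) distances on shared leaves, RF on shared-leaf
topologies, and a leaf-label permutation null on one tree's distance
matrix.

**TME.** Gene Z scores use population SD across samples (constant genes →
Z 0); parameter scores average member genes with equal weights (absent
genes are logged and skipped); categories average parameters; the
aggregate averages ±1-weighted parameter scores. IPS interpolates linearly
between the anchors (0 → 0, 3 → 10) with half-up rounding and clipping —
the anchors are exact, interior values are an interpretation. Cytolytic
pseudocount is 0.01. kNN density excludes the query point from its own
population and breaks distance ties by point index.

## Problem sizes

Tests and the acceptance script run on scaled cohorts chosen to exercise
the statistics at meaningful counts: signature/NMF recovery uses 80
samples × 300–600 mutations; the immunoediting null calibration uses 200
metastases at ~100 mutations each with 100 replicates (ties ~6% of
replicates, rejection rate at 0.05 inside [0.02, 0.10]); organ-test
calibration and power use single cases of 8–12 metastases × 60 clones per
site with 60 permutations. The pipeline orchestrator bounds the
immunoediting stage (`immuno_replicates`, `immuno_max_samples`) because it
dominates runtime; per-sample analyses at the full defaults use
`observed_expected_test` directly.

## Known limitations

The binder surrogate has no sequence structure (hash-uniform over
peptide/allele pairs), so neo-epitope *counts* are realistic but binding
*motifs* are not. The organ permutation null destroys all repertoire
structure, not only organ structure, which can make the cophenetic organ
statistic mildly anti-conservative when strong non-organ structure exists;
the RF statistic against the organ reference tree is less sensitive to
this. LCS/MCS printed-formula dialects are retained verbatim for
comparability but are not percentages of reads. The NNLS refit assumes the
catalog is correct up to the attribution threshold; systematically missing
processes surface as positive residual excess, which is the intended
diagnostic use of the RMSE and entropy outputs.
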