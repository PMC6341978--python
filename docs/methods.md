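# Methods

This note documents the models, parameter choices and numerical
decisions behind `holoseq`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Host/symbiont partitioning

A holobiont assembly mixes transcripts from the coral animal and its
dinoflagellate symbionts. After two prefilters — summed FPKM < 0.5
across samples, and absence of any open reading frame of ≥ 100 codons —
transcripts are classified by a fixed precedence: (1) ortholog evidence
against a coral reference → host; (2) ortholog evidence against a
symbiont reference → symbiont; (3) reciprocal best BLAST hit to a
cnidarian database → host; (4) otherwise the GC rule: GC ≤ 0.47
(inclusive) → host, else discarded. Evidence against *both* references
is treated as conflicting and the transcript discarded; the precedence
order follows the order in which the evidence classes are usually
trusted (direct orthology over RBH over composition). Ortholog
detection itself (InParanoid/BLAST) is consumed from hit tables — only
the RBH logic (mutual best score, ties broken toward the
lexicographically smaller id) is implemented here.

GC is computed over unambiguous bases only; an all-ambiguous sequence
is an error, not 0. ORFs are ATG→stop on both strands in all frames,
with every in-frame ATG reported (nested ORFs share a stop) and
coordinates always given on the forward strand.

Accuracy accounting: the GC rule only admits transcripts *into* the
host set, so a transcript discarded as `gc_fail` counts as a symbiont
decision when scoring against ground truth, while prefilter and
conflict discards are excluded from the denominator.

## Synthetic data

The generator emulates the statistical structure each stage assumes,
with one deterministic RNG stream per stage (seeded from the config
seed plus a CRC of the stage name, so outputs are byte-identical across
runs and stages are insensitive to each other's draw counts).

* **Transcripts.** Per-transcript GC targets are normal around the pool
  mean (host 0.40, symbiont 0.55, sd 0.04, truncated to [0,1]); these
  defaults put the 0.47 cutoff near the optimal decision boundary so
  tests exercise real misclassification (≈ 2% at defaults, Φ(1.75)
  each side). Sequences carry exactly ⌊GC·L⌉ G/C bases: one engineered
  stop-free ORF (100–300 codons) is GC-budgeted by a base-flip repair
  walk and embedded in composition-matched flanks. Lengths are uniform
  on [400, 2000] bp.
* **ITS2 reads.** The clade C/D references are 400 bp at 15%
  divergence — far enough apart that a 75 bp read within 10% edit
  distance of one reference cannot also match the other. Read pairs
  are drawn FR from fragments of 150–250 bp with uniform substitution
  errors (default 0.003/base); indels are not simulated, which at
  75 bp changes nothing downstream of the edit-distance mapper.
* **Counts.** Gamma-Poisson (negative binomial, dispersion 0.1) around
  mean = library size × relative abundance × 2^(effects). Planted DEGs
  shift ±lfc/2 per group (half up, half down); module genes share a
  latent standard-normal factor scaled by the module loading, optionally
  tied to a trait (0.9 trait + residual noise). FPKM is computed from
  counts, lengths and realized library sizes. Note an interaction that
  mirrors real data: latent module factors can correlate with a
  contrast by chance at n = 24, so contrasts run on data with large
  planted modules can call module genes as DEGs — calibration tests
  therefore use module-free configurations.
* **Genotypes.** Balding–Nichols: ancestral p ~ U(0.1, 0.9), group
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), diploid genotypes binomial,
  depth Poisson(40). Each SNP sits at a controlled position of a
  four-fold degenerate codon (GCT→GCC synonymous at position 3,
  GCT→GAT nonsynonymous at position 2) inside a generated full-length
  ORF, so synonymous annotation is testable exactly.
* **Annotations.** A pfam2go-syntax mapping with one planted term whose
  genes are sampled with configurable weight on a DEG set; weight 1
  means no enrichment (null calibration).

What passing these tests shows: the estimators are correct and
calibrated under the generative models they assume. What they do not
show: robustness to isoform-level quantification error, mapping bias,
GC- or length-dependent artefacts, batch effects, or indel/structural
error modes — none of which the generator produces.

## Symbiont typing

Reads are aligned to both clade references by banded semi-global edit
distance (edlib), each mate on both strands, with a mate accepted
within 10% of its length. The pair score is Σ(L − 3d) over mapped
mates (+1 match / −2 difference); a pair counts once, for the
reference with the strictly best pair score — equal-best pairs count
nowhere. This makes "uniquely mapped" deterministic and
mapper-independent. A SAM path (pair scores from AS, falling back to
−NM) feeds the same counter. Marker discovery seeds candidate
transcript/query pairs on shared 11-mers before alignment, and scores
hits with a Karlin–Altschul e-value using generic ungapped parameters
(λ = 1.28, K = 0.46); the 10⁻³ cutoff sits so many orders of magnitude
from the exact-copy regime that parameter precision is immaterial.
Phylogenetic type placement is simplified to nearest global-alignment
identity against a type panel, with ties reported together.
Mismatched-read profiling (fraction with ≥ 1 difference, edit-distance
histogram) uses the same alignments' NM-equivalent counts.

## Differential expression

The stack mirrors the standard count pipeline: genes need count ≥ 1 in
≥ 3 samples; TMM factors are computed exactly as in the canonical
description (75th-percentile reference selection; M/A over genes
positive in both libraries; 30%/5% double trim by rank; inverse
approximate-binomial-variance weights; geometric-mean-1 scaling) and
are verified against edgeR's `calcNormFactors` to 10⁻⁶ in the test
suite. logCPM uses prior count 0.5. MDS distances are leading log-fold
changes: the RMS of the 500 largest squared logCPM differences per
sample pair, embedded by classical (Torgerson) scaling.

voom weights come from an unweighted first pass: per-gene √(residual
sd) is lowess-smoothed (span 0.5) against average log₂ count, the trend
is evaluated at each observation's fitted log count (clipped to the
trend's range) and inverted to the fourth power. Moderation estimates
(d₀, s₀²) by matching the mean and variance of log s² through
digamma/trigamma identities, with the trigamma inverse solved by
Newton iteration; d₀ = ∞ (all variances equal) degenerates to a normal
reference, a single gene degenerates to the ordinary t (d₀ = 0). The
whole path is cross-checked against limma's voom+eBayes on a shared
fixture (log-fold changes to 0.02, t correlation > 0.999, prior df
within 10% — the residual difference is the lowess implementation).
Contrasts are three separate binary comparisons (site, clade, disease)
rather than one multi-factor model; "GA-diseased" pools lesioned and
unaffected tissue of diseased colonies. The two samples per diseased
colony are modeled as independent, a deliberate simplification and a
known statistical caveat. Sample outliers are only ever *flagged*
(mean Euclidean logCPM distance > 2 sd above average); exclusion is an
explicit config input.

## Coexpression networks

Unsigned adjacency |cor|^β on log₂(FPKM+1) after requiring FPKM ≥ 1 in
≥ 3 samples. The scale-free fit index bins connectivity into 10
equal-width bins and takes the R² of log₁₀(frequency) on log₁₀(mean k)
over non-empty bins, signed by −sign(slope); β is the smallest
candidate reaching 0.8, else the argmax with a warning. (Equal-width
bins are the canonical choice; equal-occupancy bins would make the
response constant and the fit undefined.) TOM follows the standard
formula with unit diagonal.

Module detection clusters 1−TOM by average linkage. When expression is
available, a simplified dynamic cut walks the dendrogram from the root
and splits a cluster whenever its two children's eigengenes correlate
below the merge threshold (0.85) — i.e. while the children carry
distinct signals — keeping clusters of ≥ 30 genes; unassigned genes
with module membership |kME| ≥ 0.6 are then adopted by their best
module, and modules with eigengene correlation > 0.85 are merged. A
static cut at 0.998 of the maximum merge height is the fallback when
only the TOM is available. The eigengene-guided traversal was chosen
after the static cut proved brittle: two planted modules whose latent
factors correlate by chance at 24 samples merge below any fixed
height. Eigengenes are the first right singular vector of the
standardized module matrix, sign-fixed to correlate positively with
mean module expression; module–trait association is per-module OLS of
the eigengene on the trait with BH correction across modules.

## Population genetics

Filters run in the documented order — depth < 20 → missing call,
call rate ≥ 0.95 ("max missing 0.95" read vcftools-style), MAF ≥ 0.1,
biallelic only — then synonymous selection against ORFs (standard
code; SNPs outside any ORF are undetermined and excluded), then
thinning to the first SNP on each gene's longest isoform (ties toward
the lexicographically smaller isoform id). WC84 variance components
a/b/c are computed per locus from sample sizes, allele frequencies and
observed heterozygosities, with loci lacking two callable diploids in
either group or with zero denominator skipped; θ = Σa/Σ(a+b+c), and
negative estimates are kept (standard for this estimator). CIs are
percentile bootstrap over loci (default 1,000 replicates). The 2×2
association test defaults to the uncorrected Pearson statistic, which
is what the reported statistics correspond to; the Yates-corrected
variant is available and verified against `scipy.stats.chi2_contingency`.

### Island-model recovery

The acceptance experiments model two demes of N = 1,000 diploids
exchanging migrants symmetrically at rate m, using the equilibrium
relation F = 1/(1 + 4Nm·(d/(d−1))²) = 1/(1+16Nm) for d = 2 and
realizing allele frequencies through the Balding–Nichols beta
approximation, drawing SNPs until 2,524 pass the MAF filter. This is a
deliberate choice between the two available routes: a literal
structured-coalescent simulation at the same (N, m) yields a *larger*
WC84 θ (≈ 1/(1+8Nm) for two sampled demes — for m = 1.30·10⁻³,
θ ≈ 0.09 versus 0.046 from the island formula), because the classic
island-model F refers to differentiation relative to the migrant pool
of many demes. The beta approximation directly targets the F scale the
reported estimates live on, is exact in expectation, and runs in
milliseconds. The coalescent route remains in the test suite as an
independent genotype source for cross-checking the WC84 estimator
against a Hudson-style estimator. The MAF filter introduces a small
upward bias at small sample sizes (≈ +0.002 at 6/6 sampling),
quantified by the recovery tests and well inside the stated
tolerances.

## Enrichment

GO terms are transferred flatly from Pfam domains via the pfam2go
mapping — no GO-graph ancestor propagation, so term sizes are those of
the direct transfer (matching how domain-based annotations are usually
tabulated for non-model organisms). The universe defaults to genes
carrying ≥ 1 annotation. Overrepresentation is the hypergeometric
upper tail P(X ≥ count) (verified against exhaustive enumeration for
small universes); the odds ratio uses the standard 2×2 layout with ∞
when a complementary cell is empty. Reporting keeps p < 0.05 and
count ≥ ⌈0.02·n⌉ of the gene set (ceiling chosen so "at least 2%"
is never undershot). Semantic-similarity redundancy reduction
(REVIGO-style) is out of scope: it requires an external GO graph and
information-content corpus.

## Datasets and orchestration

The bundled 27-sample design (two sites, dominant clade per sample from
ITS2 proportions, GA status, colony pairing) drives four named subsets:
`all`; `default` = all minus the expression-clustering outlier (WA8,
supplied as an explicit, logged exclusion — never inferred silently)
and minus mixed-composition samples (two clades ≥ 0.25: WH8, WA12);
`waiopae`; and `hu` (no lesioned tissue). Colony-level 2×2 tables
(site × clade, health × clade) are recomputed from the metadata at run
time. `run_pipeline` executes every stage on one synthetic holobiont,
writes one TSV per stage plus a JSON manifest with the seed and all
thresholds applied (0.47, 0.25, 0.05, 0.1, 20, 0.95, 1000), and fails
with a stage-tagged error while retaining earlier outputs.

## Problem sizes

Desk-scale defaults keep every stage seconds-fast: 2,000+2,000
transcripts for partitioning; 2,000 ITS2 pairs per sample in the
pipeline (10,000 in the composition round-trip experiments); 24-sample
count matrices with up to 2,000 genes; networks of ~800 genes; 2,500
SNPs with 1,000 bootstrap replicates; 50-seed island-model recovery.
These sizes were chosen so Monte-Carlo error is comfortably below each
test's tolerance while the whole suite stays interactive.

## Known limitations

* Naive FPKM arithmetic stands in for RSEM's EM quantification; no
  isoform-level expression.
* Nearest-identity ITS2 type assignment replaces phylogenetic
  placement; intragenomic ITS2 variants are not distinguished from
  distinct symbiont genotypes.
* Colony-level pseudo-replication (two tissues per diseased colony) is
  not modeled in the linear models.
* Two groups only for F<sub>ST</sub>; no haplotype phasing; variant
  calling is consumed, not performed.
* The enrichment universe behind published domain-annotation tables is
  rarely stated; absolute p-values therefore depend on that choice and
  only the machinery, not any published table, is reproduced exactly.
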