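# Methods

## The problem and the model

A kleptokaryon-bearing ciliate yields a single "host" RNA-seq library that
mixes transcripts of two genomes: the ciliate's own and that of the stolen
cryptophyte nucleus (KN). With no reference genome for either partner, the
only practical deconvolution signal is homology: a gene whose best hit in a
broad eukaryotic reference database is a cryptophyte protein, at e-value
≤ t, is attributed to the KN; everything else — non-cryptophyte best hit,
hit above threshold, or no hit — is attributed to the host. The default
t = 10⁻⁴ is deliberately permissive (rapidly evolving host proteins rarely
hit cryptophytes by chance at this level, while true KN genes with partial
alignments are retained); the sweep to 10⁻³⁰ bounds how much of the KN call
rests on marginal alignments. Attribution to host is explicitly a *default*,
not a positive identification, which is why the strict mode separately counts
genes confirmed as host by a ciliate best hit. "Best hit" is the minimal
e-value, with ties broken by maximal bitscore and then lexicographically
smallest subject id, so results are independent of hit-table row order; the
tie-break chain is a package choice (recorded in run metadata) because
top-hit ties have no canonical resolution. Self-hits (query id = subject id)
are removed before selection, since the reference database may embed the
query library's own proteins.

## Category statistics

Two complementary engines compare the KN gene set against the free-living
prey library (GC) at the level of functional units (KEGG-style KO → pathway
→ subcategory → category; only the four broad categories Metabolism, Genetic
Information Processing, Environmental Information Processing and Cellular
Processes are analyzed).

**Protein counts.** Per unit, the 2×2 table (in-unit vs out-of-unit
annotated proteins, per library) is tested with Pearson's chi-square, 1 df,
Yates continuity correction on by default (the conventional default for 2×2
tables in mainstream statistics environments; a flag disables it).
Out-of-unit denominators are, by default, the *sum of unit counts over all
analyzed units* ("category_sum"): a gene sitting in several units counts
once per unit, and the published percentage arithmetic for this system is
consistent with that convention. The alternative "annotated_total"
denominator (all KO-annotated proteins per library) is selectable. A gene
contributes once to each distinct unit reachable through any of its KOs —
never twice to the same unit through two KOs — which prevents double
counting inside a unit while preserving genuine multi-pathway membership.
The one-gene-per-KO deduplication variant keeps, per library and KO, the
gene with the highest read count (ties: smallest gene id); the choice of
representative does not affect count-based tests, but a deterministic rule
makes runs reproducible. Deduplication is idempotent.

**Expression.** Each gene's expression proxy is reads per base pair
(count/length). Per unit, the GC and KN gene-level vectors are compared with
a two-sided Mann–Whitney U test: exact enumeration when the smaller sample
has ≤ 8 observations and no ties, otherwise the normal approximation with
midrank tie correction and continuity correction (scipy's implementation
behind this method-selection rule). Genes with zero reads are included by
default (a flag drops them); no library-size scaling is applied before the
test — the proxy is length-normalized only, matching the upstream method
this engine mirrors — and an optional counts-per-million pre-scaling flag
exists for users whose libraries differ grossly in depth. Benjamini–Hochberg
correction runs within each analysis family separately (the subcategory
protein tests; the subcategory expression tests; the pathway expression
tests), and units empty in either library are reported with p = NA and
excluded from correction. KO-level summaries pool reads of all transcripts
sharing a KO and divide by their summed length; a KO with no transcript in a
library is rendered "NP", which is deliberately distinct from a present but
silent KO (reads-per-bp 0). Displayed log values use log10; raw values are
always emitted.

## No-replicate differential expression

Orthologs are paired by reciprocal best hits (RBBH) at the same e-value
threshold and tie-break chain as partitioning; the pairing is a partial
matching by construction. With one library per condition there is no
replication, so dispersion cannot be estimated; the package follows the
fixed-dispersion route with φ = 0.3, a deliberate biological-variability
allowance between the commonly recommended bounds for this design. Two
normalization backends feed one exact-test engine:

* **TMM** — weighted trimmed mean of M-values, implemented to match the
  canonical definition: genes zero in either library excluded, 30 % of the
  M (log-ratio) tails and 5 % of the A (abundance) tails trimmed by
  midranks, remaining M averaged with inverse asymptotic binomial-variance
  weights, reference library the one whose upper-quartile/library-size
  ratio is nearer the two-library mean, factors rescaled to geometric mean
  1, effective size = library size × factor. The implementation agrees
  with edgeR's `calcNormFactors` to ~10⁻¹⁰ (cross-checked in the test
  suite). Note that trimming by midranks makes the trim window sensitive
  to exact count ties at the boundary; M is therefore computed in quotient
  form, log2((y₁/N₁)/(y₂/N₂)), so equal count pairs stay exactly tied.
* **Median-of-ratios** — per library, the median over genes of
  count / per-gene geometric mean, genes with zero geometric mean excluded,
  normalized to geometric mean 1.

The **exact test** conditions on the sum: counts are rescaled to the
geometric mean of the effective sizes and rounded (a documented
approximation in place of quantile-adjusted pseudo-counts — it preserves
the conditional structure and stays brute-forceable), and under the null
the probability of a split k + (s−k) is proportional to f(k)·f(s−k) with f
the NB pmf of mean s/2 and dispersion φ (variance μ + φμ²). The two-sided
p-value sums the probabilities of all splits at most as likely as the
observation (relative tolerance 10⁻¹⁰ guards float noise in tied splits),
capped at 1. As φ → 0 the test converges to the conditional binomial
(Poisson-limit) exact test, which the suite verifies against
`scipy.stats.binomtest`.

Fold changes are log2((y_KN + ½)/S_KN ÷ (y_GC + ½)/S_GC); the prior count
½ keeps zeros finite and is a package choice (no canonical value exists for
this design). `klass` reflects the |log2FC| ≥ 1 boundary alone — the
fold-change-focused reading appropriate when significance is underpowered —
while `significant` records BH-adjusted p < α, so callers can intersect the
two; the intersection is what the null-rate simulations constrain, because
at φ = 0.3 the null spread of log2FC alone (sd ≈ 1.1) makes a pure
fold-change cut fire on roughly a third of unchanged genes.

## The synthetic-data generator

The generator emulates the statistical shape of the study system, not its
sequences: a chimeric library of n genes with true KN origin ~
Bernoulli(π = 0.615); lognormal coding-sequence lengths targeting mean
850, sd 648 bp; a 4-category / 21-subcategory / 89-pathway hierarchy with a
fixed KO block per pathway and a 30 % annotation rate (one KO per annotated
gene, so read totals are conserved under KO rollup); gamma-Poisson (NB)
counts at dispersion 0.3; and per-pathway Δlog2 shifts applied to KN genes.
Expected coverage is parameterized *per gene* (default 400 reads) with a
deterministic normalizer E[e^baseline]·E[length], so a gene's expected rate
does not depend on how many other genes share its library — this is what
makes an effect-free dataset a genuine null for the expression comparison
(an earlier total-depth parameterization coupled coverage to the decoy count
and produced spurious global shifts). Gene-to-gene expression spread is
lognormal with σ = 1 (natural log), a typical transcriptome-wide dynamic
range. Every KN gene has a same-identity GC ortholog (so RBBH recovery is
well-defined), the GC library carries 3× decoy genes by default (the prey
library is several-fold larger than the chimeric one), and misassignment of
best-hit taxa is controlled by ε (default 0); true-hit e-values are drawn
log-uniform between 10⁻⁵⁰ and 10⁻⁵. Decoy forward hits whose reverse best
points elsewhere exercise RBBH mutuality failures. Everything is
reproducible byte-for-byte from the seed.

What the generator does *not* emulate: real sequence content (FASTA bases
are random), assembly redundancy (no multi-isoform KOs unless configured),
annotation bias between libraries, and correlated expression within
pathways beyond the shared mean shift. Passing recovery tests therefore
demonstrate the statistical machinery under the stated model, not
robustness to assembly artifacts or annotation error.

## Problem sizes and numerical choices

Simulation-based tests use 10,000 genes for mixture-fraction recovery
(three-binomial-SD criterion) and 24,000 genes for the pathway-effect power
runs, sized so the affected pathway holds ≈ 50 kleptokaryon genes — the
regime in which a +2 log2 shift is detected in ≥ 18/20 seeds at FDR 0.05,
with null runs flagging ~0 % of units. Fold-change recovery embeds 50
shifted pairs among 1,000 unchanged ones so the trimmed-mean normalization
is anchored by the majority; with a heavily contaminated pair set (≳ 15 %
shifted) TMM partially absorbs the effect and estimates shrink — a known
property of trimmed normalization, not a defect of the estimator here.
Result TSVs render floats at 6 significant digits (round-trip guaranteed at
that precision); raw hit tables use shortest round-trip float repr so
write-then-read is the identity. Chi-square requires all four margins
positive; Mann–Whitney requires both samples non-empty; TMM and
median-of-ratios require at least one gene positive in both libraries.

## Known limitations

* Host attribution is a default, so the KN fraction is a lower bound only
  in the direction the strict-ciliate mode quantifies; genes without hits
  are invisible to the method.
* The fixed dispersion of the exact test is an assumption, not an estimate;
  p-values are calibrated only insofar as φ = 0.3 is realistic.
* Percentages and enrichment depend on the denominator convention; both
  conventions are exposed because the field's reporting is inconsistent.
* The expression comparison inherits the length-normalized-only proxy: it
  conflates depth with expression if libraries differ grossly in per-gene
  coverage (the CPM flag exists for that case).
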