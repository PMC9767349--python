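# Methods

This note documents the statistical procedures, the synthetic-data
generators, and the design decisions behind `hifburden`.

## Qualifying variants

A variant observation qualifies when its annotated functional
consequence is in the allowed set and its population minor allele
frequency is strictly below the threshold (default 1%). Two presets are
shipped:

* `PRIORITIZATION` — discovery filtering: missense, nonsense,
  stop-loss, splice-site SNVs and coding indels;
* `BURDEN` — burden testing: the same classes restricted to single
  nucleotide variants (`len(ref) == len(alt) == 1`).

A missing MAF annotation means "absent from the population reference"
and is treated as 0, so novel variants always pass the frequency
filter. The MAF is a single annotated column; no attempt is made to
combine multiple frequency resources. Splice-site membership is taken
from the annotation; no distance-to-exon recomputation is done.
Coordinates follow the VCF convention (1-based, explicit REF/ALT) on
one declared genome build, and inputs are assumed normalized
(left-aligned); variant identity for "distinct variant" counting is
the genomic tuple (chrom, pos, ref, alt).

## Burden testing

Individuals collapse to one boolean per gene (carrier = at least one
qualifying variant; compound heterozygotes count once). For gene *g*
with `a` case carriers, `b` control carriers, `c` case non-carriers and
`d` control non-carriers:

* **p-value** — two-sided Fisher exact test under the minimum-likelihood
  convention: the sum of hypergeometric point probabilities, over all
  tables with the observed margins, that do not exceed the observed
  table's probability (with a ~1e-7 relative tie tolerance). A zero
  margin carries no information and yields p = 1 by convention. The
  implementation delegates to `scipy.stats.fisher_exact`, which
  implements exactly this definition; the test suite verifies equality
  against an exhaustive rational-arithmetic enumeration for every table
  with margins ≤ 12.
* **Effect size** — the unconditional cross-product odds ratio
  OR = ad/bc (+∞ if bc = 0 with ad > 0; undefined if both products are
  0).
* **Confidence interval** — Woolf's log-normal interval
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). Tables with a zero cell receive
  the Haldane–Anscombe +0.5 correction in every cell for the OR/CI
  only, never for the exact p, and are flagged.
* **Significance** — nominal two-sided p < 0.05. No multiplicity
  correction drives the flag (the scan covers a handful of candidate
  genes); a Benjamini–Hochberg column is emitted alongside for
  transparency.

This estimator combination reproduces the published table for the
reference cohort (94 cases vs 2,054 controls) at the printed rounding:
VHL p = 1.36e-05, OR 17.4 (5.9–51.3); HIF1A p = 0.002, CI 1.9–10.1;
IDH1 p = 0.02, OR 6.1. Two printed values differ in the last digit
from the cross-product/Woolf computation (HIF1A OR prints 4.3 vs
computed 4.39; IDH1 CI low prints 1.6 vs computed 1.68) — possibly a
conditional-MLE point estimate or rounding in the original report; the
package reports the computed values.

Report rendering is centralized: p to 3 significant figures
(scientific below 1e-3), ratios to one decimal with round-half-up,
fractions as one-decimal percentages.

## Mosaicism and variant origin

VAF = alt reads / total reads. A constitutional heterozygote is
expected at VAF ≈ 0.5; an early post-zygotic (mosaic) variant sits
lower. The mosaic flag is deliberately rule-based, since the original
analysis reported mosaicism qualitatively from ~37–39% VAFs:

* depth < 20 (or no read support) → `insufficient_data`;
* VAF < 0.45 **and** exact two-sided binomial test vs 0.5 rejecting at
  α = 0.01 → `mosaic_candidate`;
* otherwise `consistent_het`.

At depth 54 a VAF of 37% gives binomial p ≈ 0.076, i.e. the rule
refuses to call mosaicism from depth alone at that coverage — it
requires either deeper data or stronger deviation, which is the
conservative behaviour we want from a screening flag.

Variant origin per (individual, variant): present only in tumor DNA →
`somatic_tumor_only`; present in blood/saliva with a mosaic-candidate
flag → `post_zygotic_mosaic`; otherwise `germline`. Candidate
summaries (gene / distinct-variant / carrier counts) exclude tumor-only
records.

Trio classification works on allele-presence indicators: any missing
parent → `unknown`; both parents negative → `de_novo`; both parents
positive → the ambiguous inherited label `maternal+paternal`.

## Expression analysis

FPKM(g, s) = (count + 0.0001) · 1e9 / (length(g) · libsize(s)), with
the library size the raw column total. The pseudo-count keeps zero
counts finite on the log scale.

The analysis requires significance by two *independent* algorithms and
intersects their calls — that two-method design is the point, not the
identity of any external engine, so both tests are implemented here:

* **Welch test** (method A): per-gene Welch two-sample t on log2 FPKM;
  the log2 fold change is the difference of group means. Genes with
  zero variance on both sides report p = 1.
* **NB Wald test** (method B): raw counts, median-of-ratios size
  factors (over genes positive in every sample), per-gene
  method-of-moments dispersion pooled across the two groups and floored
  at 1e-8, delta-method standard error
  √((1/μ₁+α)/n₁ + (1/μ₀+α)/n₀) on the log mean ratio. Because the
  moment dispersion is noisy at n = 3, the Wald statistic is referred
  to a t distribution with the pooled residual df, which keeps the
  empirical size ≤ 0.07 at nominal 0.05 in null simulations (and
  converges to the exact Poisson comparison for large, equi-dispersed
  counts). All-zero genes are excluded and reported p = 1.

The intersection keeps genes passing α = 0.05 under both methods —
BH-adjusted p by default, with a raw-p switch since published
per-comparison counts are ambiguous about correction — and requires
direction concordance (discordant genes are dropped and counted in a
diagnostics field); the up/down split follows method B's sign.

**Regulon fraction**: for a DE list D and regulon R within tested
universe U, the fraction |D∩R|/|D| with a hypergeometric upper-tail
enrichment p. `compare_fractions` reports the proband/control fraction
ratio with a two-proportion z test on the overlap counts. The
high-fold filter selects genes with fold change strictly above a
threshold (default 3) in a stated direction.

**Technical replicates.** `HypoxiaResponseModel` collapses technical
replicates to per-individual samples by default. Treating the 12
proband technical replicates as independent samples pseudo-replicates
the 4 biological units: the detection threshold then saturates and the
regulon-fraction ratio stops responding to the attenuation parameter at
all (we measured ratio ≈ 1.2 at attenuation 0.5 *and* 1.0 under that
mode). The independent-samples mode remains available
(`collapse_technical=False`) for comparability with analyses that made
that choice.

The curated 836-gene HIF-1 regulon used in the original study is not
published in reusable form; fractions against it require a
user-supplied GMT. The package ships a small illustrative list of
HIF-1 regulated genes and the synthetic generator emits a labelled
synthetic regulon.

## Synthetic cohort generator

`simulate_cohort` draws, for each gene, independent carrier indicators:
controls at the gene's carrier probability, cases at that probability
times an enrichment factor ≥ 1. Defaults mirror the reference study
regime: 94 cases (71:23 OD:MS) vs 2,054 controls, three genes at the
published carrier-count regimes (HIF1A, VHL, IDH1) and three without a
detectable excess. Carrier variants are rare functional SNVs with MAF
log-uniform on [1e-5, 5e-3]; each carrier receives a unique locus
within its gene. Case variants are assigned de novo (10%), mosaic (5%,
saliva source, alternate reads binomial at the configured VAF 0.37 and
depth 54), or tumor-only (2%); the rest segregate from a random parent
when a trio exists (72% of cases). Background records are
*non-qualifying by construction* — synonymous, or functional at common
(≥ 2%) MAF — so the qualifying-filtered carrier matrix equals the truth
table exactly, which the tests assert. The generative assumptions for
control carrier rates are a modelling choice (the underlying cohort
data are not public), selected to reproduce the published count
regimes, not estimated from data.

All randomness flows from one `numpy.random.Generator`; identical
configs give bit-identical outputs, and written VCFs are byte-stable.

## Synthetic expression generator

`simulate_expression` emits negative-binomial counts (common dispersion
0.05) for 8,000 genes × 30 samples: 3 control individuals (biological
replicates) and 4 probands × 3 technical replicates, each cultured at
normoxia and hypoxia. Baseline means are log-normal (log-mean 5, sd
1.3, median ~150 counts); gene lengths uniform on
[300, 10 kb]; library sizes uniform on [8e6, 1.2e7].

A regulon of 836 genes responds to hypoxia with log2 fold changes ~
N(1.3, 1.0); 30% of non-regulon genes respond with the *same* signed
effect distribution. That symmetry is deliberate: detection power
depends on effect size and direction (strong down-regulation is easier
to call through log-FPKM dropout), so giving both pools identical
effect distributions makes the expected regulon fraction equal the pool
ratio 836/(836 + 0.30·7164) ≈ 0.28 — the published control regime —
independent of per-group power. In proband samples regulon effects are
multiplied by the attenuation parameter (default 0.5); the truth table
records per-group true effects, and proband regulon truth equals
control truth times the attenuation exactly, by construction.

Each individual (cell line) realizes its own biological state: a
per-gene baseline multiplier 2^N(0, 0.1) and a per-gene response
deviation N(0, 0.1) added to the group effect. Technical replicates
share that state and differ only by counting noise — which is why
treating them as independent samples overstates replication. The noise
scales are small (cultured fibroblast lines under a controlled
exposure), chosen so a 3-replicate design retains power, consistent
with such experiments clustering cleanly by condition.

What the generator does *not* model: read-level effects (FASTQ,
alignment, positional bias), correlated gene modules, isoform-level
variation, batch effects, and compositional library artifacts beyond
simple size scaling. Published absolute DE counts are therefore not
reproduction targets — the raw data are controlled-access and the
original DE engines are external; what the pipeline is tested to
recover is the *relative* structure: fraction ratio ≈ attenuation
(0.45 ± 0.03 across 20 seeds at attenuation 0.5; ≈ 1 at attenuation 1;
≈ 0 at attenuation 0), calibrated null behaviour, and exact agreement
of all deterministic statistics with brute-force oracles.

## Numerical and interface choices

* Fisher p, binomial test, hypergeometric tail: scipy; BH and the
  two-proportion z test: statsmodels; VCF I/O: pysam/htslib.
* MAF/CADD annotations round-trip VCF at 6 significant digits (htslib
  stores INFO floats in single precision), matching how annotation
  pipelines print frequencies.
* Problem sizes in the stochastic checks — 2,000 genes for the null
  burden calibration, 20 seeds × 8,000 genes for attenuation
  recovery — are chosen so the whole suite runs in well under a minute
  while leaving the binomial/Monte-Carlo error comfortably inside the
  asserted bands.
* Degenerate inputs are explicit: zero library size, empty gene panel,
  unlabeled individuals, unknown consequence strings and malformed GMT
  lines raise with the offending file/locus named; empty DE lists give
  an undefined fraction (NaN) with p = 1 rather than an error.

## Known limitations

* The burden model ignores population stratification and relatedness;
  it assumes cases and controls share the annotation and capture
  pipeline.
* The mosaic rule is a screening heuristic; at common exome depths it
  has little power below VAF deviations of ~15 points.
* The NB Wald test is approximate (moment dispersion, no shrinkage);
  it is deliberately simple and is always used jointly with the Welch
  test through the intersection.
* Technical-replicate collapsing averages counts and rounds, which
  discards a small amount of information relative to a mixed model;
  a random-effects DE model is out of scope.
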