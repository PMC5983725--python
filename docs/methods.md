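# Methods

This note documents the models, the defaults and the reasoning behind the
design choices; it is the companion to the API documentation in the module
docstrings.

## Methylcytosine calling

Bisulfite treatment converts unmethylated cytosines to uracil (read as T)
while 5-methylcytosine resists conversion, so a methylated fraction *m* at
a site with coverage *n* yields methylated-read counts
k ~ Binomial(n, m + (1−m)·e), where *e* is the probability that a truly
unmethylated cytosine nevertheless reads as C — chemistry failure plus
sequencing error. *e* is not knowable from the genome itself, so it is
estimated from an unmethylated lambda phage spike-in as the pooled ratio
Σk/Σn over all spike-in cytosines. Pooling (rather than averaging
per-site ratios) weights every read equally and is the maximum-likelihood
estimate under a shared *e*. The spike-in is identified by chromosome
name (`lambda` by default) and excluded from every genome-wide statistic.

Each genomic cytosine is then tested against the null "this site is
unmethylated": p = P(X ≥ k | n, e), the exact binomial upper tail.
Multiple testing is controlled with Benjamini–Hochberg **per context** —
CG, CHG and CHH sites form separate families because their null fractions
and site counts differ by an order of magnitude and a pooled correction
would let the abundant CHH family dominate the threshold. A site is
called methylated at q < 0.01 (default).

Two related guarantees are distinguished deliberately: BH at 0.01 is the
*call rule*; the *diagnostic* `expected_false_positive_fraction` (the sum
of called sites' p-values divided by the call count, an upper bound on the
expected FP fraction under the error model) is reported separately and
flagged when it exceeds 1%. The two usually agree in intent, and keeping
the diagnostic explicit makes the calibration inspectable.

The two strands of a CpG dyad are treated as independent sites by
default; `merge_symmetric_cg` pools them on request. Sites within 2 bp of
their strand's 3' end have undefined context and are excluded.

### Replicate merging

A site survives the merge of two biological replicates only when (a) it is
covered at ≥ 10 reads in both, and (b) the methylated/unmethylated
determination agrees. Surviving counts are summed and the level
recomputed; the larger (more conservative) p and q are carried. The rule
is symmetric in the replicates.

A consequence worth knowing: sites whose true level puts them near the
calling boundary (roughly k ∈ {2, 3} at 30×, i.e. levels around 5–10%)
have call status that genuinely flickers between replicates, and the
consistency rule removes them. This thins coverage in *lowly* methylated
regions — visible downstream as reduced sensitivity for hypo-DMRs whose
treatment level lands in that zone (see below).

## DMR detection

Windows are non-overlapping 200-bp tiles by default. The window geometry
is configurable (`window_size`, `step`; overlapping windows replicate
sites into every covering tile; `window_size < step` requires an explicit
gaps opt-in). Within a window, methylated/unmethylated read counts of one
context are pooled over the cytosines covered in **both** samples —
pooling counts (not averaging site levels) matches the single 2×2 Fisher
test applied per window. A window is eligible with ≥ 5 context sites.

The two-tailed Fisher exact p-value is computed from the hypergeometric
pmf over the whole support at fixed margins: the p-value of cell *a* is
the sum of probabilities of all tables no more probable than the observed
one, with a 1e-7 relative tie tolerance absorbing float rounding (the
convention of R's `fisher.test`). Computing the full support vector at
once makes both genome scans and exhaustive enumeration cheap; the
implementation is verified against `scipy.stats.fisher_exact` on random
tables and against exact integer-rational enumeration on *all* tables
with total ≤ 60 (maximal relative deviation observed: ~7e-16).

A DMR is an eligible window with fold change ≥ 2 between pooled levels
(ratio of the larger to the smaller; infinite when exactly one level is
zero, 1 when both are zero) and raw p < 1e-20. BH q-values over the
eligible windows are reported alongside, but the default filter applies to
the raw p — at a threshold twenty orders of magnitude below any
conventional level, the distinction is immaterial in practice, and both
columns are emitted so either convention can be audited. Direction is
`hyper` when the treatment level is higher. Adjacent or overlapping
passing windows of the same direction are merged into maximal runs
(pooled counts summed, levels and fold recomputed, minimal p kept); both
merged and unmerged counts are reported since region counts depend on the
merge convention.

## Genomic categories

Two schemes coexist because methylation is conventionally reported against
gene models in two ways:

* **mC-site scheme** (point queries): exon > intron > promoter (1 kb
  upstream of the TSS, strand-aware) > intergenic. TE positions fall
  through to intergenic here.
* **DMR scheme** (interval queries): gene_body, upstream (2 kb), downstream
  (2 kb), transposon, intergenic. Each base of the query interval is
  claimed by the highest-precedence category covering it; the category
  claiming the most bases wins, ties broken by precedence
  (gene_body > upstream > downstream > transposon). Defining overlap via
  the per-base partition (rather than raw per-category overlap) makes the
  assignment a true partition and lets a naive per-base scan serve as an
  exact oracle.

Both precedence orders are constructor arguments. Promoter and
upstream/downstream windows are clipped at chromosome boundaries. TSS/TES
are strand-aware (the TSS of a minus-strand gene is its larger
coordinate); introns are derived as the gene span minus exons.
Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
inclusive, and BED output 0-based half-open.

## Profiles

`global_levels` reports, per context, the unweighted mean of per-site
levels over called mC sites — and the read-weighted pooled ratio as a
secondary column, since the two differ under uneven coverage and the
field uses both conventions. A context without mC sites reports NaN, not
zero. Proportion reports round half-up via exact decimal arithmetic at
the requested precision (binary-float rounding produces occasional
off-by-one-ulp surprises at two decimals).

Metaplots tile the 2-kb flanks into fixed 50-bp bins (40 per flank) and
length-normalise gene/TE bodies into 40 proportional bins (configurable);
minus-strand features are mirrored so profiles read 5'→3'. Every covered
cytosine contributes its level k/n by default (`mc_only` restricts to
called sites). Features shorter than the body bin count are skipped and
counted. Bin values are unweighted means over contributing sites pooled
across features.

## Expression association

The DEG filter is boundary-inclusive as printed: linear fold change ≥ 2
in either direction (equivalently |log2FC| ≥ 1) and Q ≤ 0.01. DEG
statistics are consumed from the input table, not recomputed — the
upstream differential-expression model is routine and out of scope; the
generator supplies consistent Q-values. Expression groups follow the
conventional RPKM boundaries (≥ 10 highest; 1 < medium < 10;
0 < lowest ≤ 1; silent = 0). Methylation terciles are rank-based with
ties broken by gene id; when the count is not divisible by 3 the lower
groups absorb the extras (documented and fixed, so group membership is
reproducible). Gene-region methylation levels are unweighted means over
covered cytosines of the region and context.

A methDEG record links a DEG to a DMR overlapping (≥ 1 bp) its 2-kb
upstream window (Pro-methDEG) or gene body (Gb-methDEG) in the same
comparison; one gene can hold both. The upstream width is configurable
(the 2-kb DMR-scheme window is the default; the 1-kb promoter is an
alternative some analyses prefer).

## The synthetic generator

The generator emulates the study conditions the analysis chain is built
for: ~30× Poisson coverage, 0.5% conversion error, context mean levels
CG 0.393 / CHG 0.1538 / CHH 0.0524, two replicates per condition, a
lambda-sized spike-in (48,502 bp), two-fold-or-greater planted effects
(default 4).

Per-site true levels are drawn from Beta(μκ, (1−μ)κ) with concentration
κ = 0.5, giving the bimodal level distribution (mass near 0 and near 1)
seen in real plant methylomes; a single shared level per context would
make FDR and DMR tests degenerate. Levels are drawn **once per site and
shared** across conditions and replicates; the treatment condition
differs from control only inside planted DMR windows. Independent
per-condition draws would plant unlabelled true differences everywhere
and no false-positive statement could be made.

Planted DMR windows are aligned to the caller's default 200-bp tiling
(recovery is then well-defined at window resolution), require ≥ 8 sites
of the planted context, are never adjacent, and half are drawn from tiles
overlapping gene bodies or 2-kb upstream windows so DMR-to-gene links
exist. Inside a planted window the control level is drawn tightly around
the context mean (Beta with κ = 50) and the treatment level is the
control level × effect (hyper) or ÷ effect (hypo), clamped to [0, 1].
Planted DEGs receive |log2FC| ≥ 2 and Q ∈ [1e-8, 1e-3]; all other genes
are constructed to fail the DEG filter; ~10% of genes are silent.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level artefacts (M-bias, PCR
duplicates, mapping bias), strand-asymmetric methylation, spatial
autocorrelation of levels outside planted windows, overdispersion between
biological replicates (replicates share true levels here), context
misassignment from genetic variation, and annotation errors. Results on
real libraries depend on upstream alignment and extraction quality, which
are out of scope.

## Numerical choices and degenerate inputs

* Binomial tails via `scipy.stats.binom.sf(k−1, n, e)` (exact for integer
  k); k = 0 gives p = 1 exactly.
* BH via `statsmodels.stats.multitest.multipletests`; ties share q-values;
  q is monotone in p-rank by construction.
* Fisher p of a table whose tail covers the whole support is exactly 1.
* All-zero 2×2 tables: p = 1, fold = 1. Empty chromosomes yield zero
  windows; empty contexts are reported as missing.
* Error-rate estimation fails loudly on an empty or zero-coverage
  spike-in — calling never proceeds uncalibrated.
* Determinism: every stochastic step derives its generator from the
  config seed plus a fixed stage code (and condition/replicate codes), so
  a config reproduces its outputs byte for byte; the pipeline manifest
  records SHA-256 of every output.

## Problem sizes used in the shipped checks

The test-suite and acceptance studies run at toy scale chosen to keep the
statistical properties measurable while the whole suite stays fast: 1–2
chromosomes of 50–100 kb (a few ×10⁴ cytosines per sample), 10⁵-site null
samples for FDR control over ten seeds, ten simulated studies of eight
planted hyper-DMRs each for recovery, and exhaustive Fisher enumeration
to table total 60 (635,375 tables). At these sizes the end-to-end
pipeline completes in ~15 s and the full acceptance script in ~40 s.

## Known limitations

* The replicate-consistency merge systematically under-covers lowly
  methylated regions; hypo-DMRs whose treatment level falls near the
  calling boundary can drop below the 5-site minimum and be missed. This
  is a property of the published rule, reproduced faithfully, and is the
  reason the recovery benchmark plants hyper windows.
* Pooled-count Fisher testing ignores biological dispersion between
  replicates (no methylKit/DSS-style variance model); with only two
  replicates merged by consistency this matches the original chain but
  will be anti-conservative on noisy real data.
* CHH effects at realistic plant levels (~5%) rarely clear the 2-fold +
  p < 1e-20 bar at 30× — few or no CHH DMRs is the expected behaviour,
  not a bug.
* Transcript isoforms, UTRs and nested TEs are not modelled; one gene
  model per gene id.
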