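# Methods

`dmrkit` identifies differentially methylated regions (DMRs) from
bisulfite-sequencing alignments in three stages: per-CpG count
extraction, distance-based clustering of CpG sites into regions, and
beta-binomial Wald tests of group methylation differences. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## Count extraction

Input is Bismark-dialect SAM/BAM: each primary mapped read carries a
methylation-call string (`XM`, one character per query base, `z`/`Z` for
un/methylated CpG context) and a conversion-strand tag (`XG`, `CT` or
`GA`). Calls are mapped to reference coordinates by walking the CIGAR:
M/=/X consume query and reference, I/S consume query only (their CpG
calls have no reference coordinate and are dropped, with a counter),
D/N consume reference only. Because coordinates come from the alignment
rather than a reference CpG catalogue, CpG sites created by sample
variants or indels ("novel" sites) are counted at their reference
positions — a reference-restricted extractor would silently skip them.

The two strands of a CpG are merged at the forward-strand cytosine:
`CT`-strand calls already sit on the C; `GA`-strand calls sit on the
guanine one base to the right and are shifted by −1. For properly paired
reads the overlapping portion of the second-in-pair mate contributes no
calls, so one sequenced fragment is counted once per covered site
(toggle `--no-dedup-overlap`). Mates are matched by query name, so file
order does not matter. There is no mapping-quality filter by default
(`--min-mapq` exists). Output is a tab-delimited table — chrom, 1-based
position, total, methylated, unmethylated — sorted by header chromosome
order, then position.

Per-read joint methylation patterns ("methylation linkage") over
user-supplied intervals are reported as strings over `M`/`u`/`-`
(methylated / unmethylated / not covered), one column per CpG position
observed in the interval, tallied over reads. Only pattern extraction is
provided; downstream tests on pattern nonrandomness are out of scope.

## Clustering

Per-sample tables are outer-joined on (chrom, pos). A site is *valid*
when at least `min_samples` (`-s`, default 1) samples cover it with at
least `min_reads` (`-r`, default 3) reads. Valid sites are grouped by
single-linkage clustering: adjacent sites at most `max_dist` (`-d`,
default 100) bp apart share a region. Single linkage chains, so any
cluster spanning more than `max_len` (`-x`, default 500) bp is split
recursively at its largest internal gap (leftmost on ties) until every
piece fits; largest-gap bisection respects the spatial structure and
guarantees the span bound. Clusters with fewer than `min_cpg` (`-c`,
default 3) sites are dropped. Per-sample methylated (X) and total (N)
counts are summed over member sites — missing cells contribute zero —
and regions where any sample's N falls below `min_total` (`-m`, default
20) are dropped, so downstream tests have adequate counts. Region
coordinates are the first and last member CpG (1-based inclusive).

The whole stage sees only positions and coverage, never the
methylated/unmethylated split, so region construction cannot bias the
differential tests. `--preset biseq` (r=1, s=1, m=1, x=1e9, c=5)
reproduces plain 100-bp single-linkage clustering with a 5-site minimum,
the clustering used by BiSeq-style workflows.

## Differential testing

For each region and group g with replicate counts X_gi of N_gi, the
group mean is the coverage-weighted fraction mu_g = ΣX_gi/ΣN_gi (never a
mean of per-replicate ratios). Replicate-level variation is
beta-binomial with dispersion phi, the intra-class correlation of calls
within a replicate:

    Var(X_gi/N_gi) = mu (1 − mu) [1 + (N_gi − 1) phi] / N_gi.

**Dispersion estimation.** The raw per-region phi solves the
coverage-weighted residual variance identity
E[Σ w_i (p_i − mu)²] = Σ w_i (1 − w_i) Var(p_i) with w_i = N_i/ΣN_i,
clamped to [0, 1). With one informative replicate (or mu at 0/1) the raw
estimate is undefined. Raw estimates from a handful of replicates are
extremely noisy, so they are shrunk toward an empirical prior on the log
scale, fitted per group across all regions of a comparison:

* prior location m̂ = log of the mean *unclamped* moment estimate
  (averaging on the natural scale avoids the downward Jensen bias of
  averaging logs; using unclamped values avoids upward bias when the
  true dispersion is near zero);
* prior scale τ̂² = variance of log phi over the strictly positive
  estimates minus the sampling noise of a (k−1)-df variance estimate,
  trigamma((k−1)/2), floored at 1e-3 (zero-clamped estimates carry no
  log-scale spread and would spuriously inflate τ̂);
* each region's log phi* is the precision-weighted blend of its own
  estimate (precision 1/trigamma((k−1)/2)) and m̂ (precision 1/τ̂²);
  undefined raw estimates take exp(m̂); with fewer than two defined
  estimates a fixed fallback prior (location log 0.01, scale 1) is used.

When regions share a common dispersion, τ̂² collapses to its floor and
every region is pulled to the ensemble mean, which is what a 1-df
per-region estimate deserves; genuinely heterogeneous dispersions keep
τ̂² positive and retain per-region information.

**Wald test.** Var(mu_g) = mu_g(1 − mu_g) · Σ w_i²(1 + (N_gi − 1)phi*_g)/N_gi,
with mu_g clamped into [1/(2ΣN), 1 − 1/(2ΣN)] so boundary estimates
cannot zero the variance (any small constant works; this one scales with
the information available). The statistic is
(mu_A − mu_B)/√(Var_A + Var_B) with a two-sided normal p-value. With
phi = 0 and single replicates this is exactly the classical
two-proportion z statistic. p-values are Benjamini–Hochberg adjusted
within each pairwise comparison (not pooled across comparisons). With
three or more groups, every unordered pair is tested; regions untestable
for a comparison (a group with zero coverage) carry missing statistics
rather than being dropped, so row sets align across comparisons.

A region is a DMR for a comparison when |mu_A − mu_B| ≥ `--min-diff`
(default 0.10), p ≤ `--max-p` (default 0.05) and q ≤ `--max-q` (default
0.05; set 1 to disable). The FDR gate is part of the defaults because
without it a well-calibrated test necessarily flags ~5% of null regions
that also clear the effect-size gate whenever between-replicate
dispersion is appreciable; the q threshold is what makes a
replicate-vs-replicate contrast come out empty.

**Known limitation.** The Wald variance plugs the estimated mu_g into
mu_g(1 − mu_g). When dispersion is large (phi ≈ 0.2) and replication
minimal (2 per group), a group whose replicates both draw extreme means
gets an understated variance, inflating the far tail of the statistic:
null simulations at phi = 0.2 show a p < 0.05 rate of ~0.07 (nominal
0.05) and occasional clusters of very small p-values that survive BH.
Bias-correcting the plug-in would break the exact two-proportion closed
form at phi = 0, which is kept deliberately. At phi ≤ 0.05 —
representative of replicate variation in typical targeted bisulfite
data — calibration is accurate (~0.05 observed). Single-factor designs
only: no covariates, batch effects, or quantitative traits; no
smoothing.

## Synthetic data

The generators exist to exercise the pipeline's contracts with exact
bookkeeping, not to imitate sequencing artifacts.

*Reads.* A toy chromosome (default 20 kb) is drawn with no accidental CG
dinucleotides, then CG sites are planted with geometric gaps (default
density 0.02/bp, i.e. one CpG per ~50 bp, RRBS-like); the recorded site
list therefore equals a CG scan of the sequence. Reads (default 80 bp,
half paired with overlapping mates, half on the GA strand) carry XM/XG
tags; each fragment draws one Bernoulli methylation state per covered
site from the per-sample probability, both mates report it, and the
truth table records exactly the calls a deduplicating extractor should
count. Optional loci are planted as C-A-G and covered by reads carrying
a 1-bp deletion of the A, creating a novel CpG present in the alignments
but absent from the reference. Bisulfite-conversion failure and
sequencing error are absorbed into the per-site probabilities; there are
no quality-score or adapter models, so passing tests certify coordinate
arithmetic and bookkeeping, not robustness to base-calling noise.

*Region counts.* X_gi ~ BetaBinomial(N_gi, mu_g, phi) via
Beta-then-Binomial composition (phi = 0 degenerates to binomial),
N_gi ~ 1 + Poisson(mean − 1). Null calibration uses 5,000 regions, 2
replicates per group, mu = 0.5, coverage ~30 per replicate, phi in
{0, 0.05, 0.2}. The recovery experiment uses 3v3 replicates, a
hypomethylated baseline mu = 0.05 (unmethylated-island background at
the bisulfite non-conversion floor) with +0.30 injected on 10% of
regions — the classic promoter-hypermethylation contrast — and
replicate totals of ~150 (five CpG sites at ~30× each). Everything is
deterministic under the seed.

## Numerical and degenerate-input choices

* Empty inputs produce empty (header-only) outputs, exit 0.
* Chromosome order follows the alignment header, not lexicographic sort.
* BED input/output is 0-based half-open; all internal and tabular
  coordinates are 1-based inclusive; conversion happens only at the BED
  boundary.
* Ties in the largest-gap split go to the leftmost gap; splitting a
  cluster never reorders or drops sites.
* phi is clamped to [0, 1 − 1e-8]; logs of raw dispersions are floored
  at 1e-4.
* BH q-values: step-up with a running minimum from the largest p; NaN
  p-values pass through and are excluded from the multiplicity count.
* `--threads` affects BAM decompression only; outputs are identical for
  any value, and running stages separately or via `all` is byte-identical.
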