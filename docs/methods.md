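# Methods

## Model

Given D studies of the same case/control contrast, each contributing a list
of up-regulated genes, the combined universe ψ is the union of the lists and
the contingency matrix M ∈ {0,1}^(N×D) has m_ij = 1 when gene i is on study
j's list. For a gene set G, its submatrix M^G keeps the rows of G ∩ ψ.

The counting score of M^G sums joint up-regulation over strict study pairs,
S_cs = Σ_{a>b} Σ_i m_ia m_ib = Σ_i C(k_i, 2) with k_i the row sum. Its
chance expectation under independent Bernoulli(p̂_j) calls is
S̄ = N^G Σ_{a>b} p̂_a p̂_b, where p̂_j is estimated from the **overall**
matrix (column sum / N), never from the submatrix. With
S_max = N^G D(D−1)/2 the chance-corrected score is
(S_cs − S̄)/(S_max − S̄), the same normalization the adjusted Rand index
applies to the Rand index. It is ≈0 on random input (exactly 0 in
expectation, with variance shrinking as 1/N^G), 1 at perfect consensus, and
may be negative.

### Triangle convention

Summation notation for the counting score is sometimes written with a bound
that would include the diagonal (b ≤ a); the diagonal contributes Σ_i k_i,
which is inconsistent with the stated maximum N^G D(D−1)/2 and with the
cancellation that makes the corrected score vanish on random input. The
strict lower triangle (a > b) is used everywhere in this package. All three
of S_cs, S̄ and S_max use the same convention, so the normalization is
internally consistent.

### Assumptions

* Study calls are treated as exchangeable Bernoulli draws per column; the
  null ignores within-study gene–gene correlation (co-regulation), so null
  p-values are anti-conservative for strongly co-regulated sets. The score
  itself is a descriptive effect size and unaffected.
* The universe is the union of up-regulated lists, not of platform contents.
  A gene unmeasured on one platform counts as "not up-regulated" there. This
  makes the construction reproducible from lists alone, at the cost of a
  conservative bias against genes on minority platforms.
* The expectation S̄ plugs in estimated probabilities; no finite-sample
  correction is applied (the plug-in error is O(1/N) on a universe of
  thousands of genes).

## Exact p-value

The null distribution of S_cs is computed without permutation. One gene's
row sum K is Poisson-binomial over (p̂_1 … p̂_D), obtained by the standard
polynomial product; mapping K → C(K, 2) gives the per-gene pair-count pmf on
the integer grid 0 … D(D−1)/2. The N^G-fold convolution (binary
exponentiation, O(log N) convolutions) yields the exact pmf of S_cs; the
p-value is the upper tail at the observed score, summed from the small end
to limit cancellation. Arithmetic is float64 on the integer grid: double
precision resolves tail masses down to ~1e-308, far finer than any
reportable p-value. For D > 25 (per-gene support > 300) the exact route is
replaced by a normal approximation with the exact per-gene mean and
variance, continuity-corrected, and the output records which method was
used.

Because S_cs is discrete, the p-value is exactly valid but super-uniform at
the granularity of the point masses; uniformity diagnostics (KS) are run at
N^G = 1000, where the point mass near the mode is ~1e-3 and discreteness is
negligible against 2000-replicate sampling noise.

## Gene-set collections

GMT is the interchange format (set id, description, members per line; round
trips are lossless for membership and order). GO-derived collections follow
the MSigDB C5 recipe: annotations restricted to a namespace
(biological_process by default), a taxon (human, 9606) and an evidence-code
whitelist (IDA, IPI, IMP, IGI, IEP, ISS, TAS — electronic IEA annotations
excluded); NOT-qualified annotations dropped; each gene propagated to every
ancestor reachable over is_a and part_of edges (regulates-type edges
excluded); obsolete terms skipped; and finally an inclusive 15–500 size gate
applied **after** propagation. Qualifiers other than NOT (e.g.
contributes_to) are kept. OBO parsing uses obonet, GAF parsing uses
biopython's GAF iterator, and the ancestor closure uses networkx; the
collection construction logic, filters and provenance tracking are this
package's.

Reproducing any specific published collection byte-for-byte requires the
archived ontology and annotation releases it was built from; collection
provenance records the source file names so this is checkable.

## Simulation suite and synthetic data

The generator draws independent Bernoulli(p_j) entries. Per-study rates are
either fixed or drawn from a Beta distribution parameterized by mean and
variance (method of moments; the variance must respect the p(1−p) bound),
which is how "random data with different levels of variance across studies"
is emulated. Defaults reflect the motivating study conditions: D = 20 for
the size-sweep experiments, D = 7 and a background call rate of 0.2
(roughly the per-study list sizes relative to a ~9000–10000-gene union) for
multi-study fixtures. A single root seed is expanded into named substreams
so each experiment is independently reproducible.

The planted-signal fixture emits D study lists, a GMT of planted plus decoy
sets and a truth table. Each planted gene's row is all-ones with the
configured joint probability (0.8 by default in the acceptance conditions)
and a background draw otherwise; decoys are random samples of background
genes (sizes 15–50). What passing these tests shows: the score separates
planted consensus structure from independent noise at realistic sizes. What
they do not show: robustness to correlated backgrounds, platform-specific
missingness, or errors in gene-identifier harmonization, none of which the
generator emulates.

### Experiment sizes

Chosen so every experiment completes in seconds while estimator noise stays
well inside the acceptance bands: randomness detection uses 1000 replicates
of 1000×7 matrices; the size sweep uses sizes 15…500 in steps of 5 with 50
replicates per size (a sparse 9-point grid leaves the size–score Pearson
correlation with a sampling sd of ~0.05, too coarse to test a ±0.1 band;
the dense grid brings it to ~0.015); expectation agreement uses 2000
replicates per (N, D, p) setting; p-value calibration uses 2000 replicates
at N^G = 1000.

## Numerical and design choices

* Deterministic ordering everywhere: genes lexicographic, studies in input
  order; ranked outputs are tie-broken by p-value then set id, so reruns
  are byte-identical.
* Scores are reported to 6 decimal places; internal computation is full
  precision.
* Sets with empty universe intersection, and the degenerate case S̄ = S_max
  (every p̂_j = 1), yield sentinels and a side report, never exceptions
  mid-pipeline.
* Fold-change derivation of a study list from an expression table uses the
  ratio of linear-scale group means with an inclusive threshold; log2 input
  is exponentiated first; genes with zero control mean are excluded with a
  warning count. No other differential-expression statistic is computed —
  published lists are taken as given.
* Identifier harmonization is deliberately offline: upper-casing,
  whitespace stripping and an optional user-supplied alias map. No remote
  symbol lookup, so results are reproducible but cross-platform synonym
  resolution is only as good as the supplied map.
* Per-study enrichment flags from external methods (e.g. GSEA run on full
  matrices) are merged into ranked output as pass-through annotation
  columns; this package never runs GSEA.
* No multiple-testing correction is applied to the ranked p-values by
  default; an FDR column is a possible extension.

## Known limitations

* The independence null understates tail probabilities for co-regulated
  gene sets; p-values are best read as a ranking aid next to the score.
* Whether published p-values from other implementations of this score family
  derive from the same null is not always documented; systematic deviations
  are recorded rather than calibrated away.
* Gene-level consensus counts depend on the harmonization map; with only
  symbol-level lists, platform probes that map to no official symbol are
  silently absent.
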