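"""Chance-corrected consensus scoring of gene sets across studies.

The counting score (CS) of a gene-set submatrix sums, over all strict study
pairs (a > b), the number of genes jointly up-regulated in both studies.
Equivalently, each gene with row sum k contributes C(k, 2) pairs.  CS grows
with both set size and chance co-occurrence, so it is normalized the way the
adjusted Rand index corrects the Rand index:

    S_CSSCMP = (S_cs - S_bar) / (S_max - S_bar)

where S_bar = N * sum_{a>b} p_a p_b is the expectation of CS under
independent Bernoulli(p_j) calls with the study probabilities p_j estimated
from the overall matrix (column sum / universe size), and
S_max = N * D (D - 1) / 2 is the all-ones maximum.  The score is ~0 for
random input, 1 at perfect consensus, and may go negative for below-chance
co-association.

A permutation-free p-value accompanies the score: under the independence
null the distribution of one gene's pair-count contribution follows from the
Poisson-binomial distribution of its row sum; convolving it N times gives the
exact null distribution of CS, whose upper tail at the observed CS is the
p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contingency import (ConfigurationError, ContingencyMatrix,
                          GeneSetSubmatrix)

#: studies beyond which the exact convolution null is replaced by a normal
#: approximation (per-gene support D(D-1)/2 stays tractable up to here)
MAX_EXACT_STUDIES = 25


@dataclass(frozen=True)
class StudyProbabilities:
    """Per-study up-regulation probabilities p_j, from the overall matrix."""

    p_hat: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p_hat",
                           np.asarray(self.p_hat, dtype=float))
        if ((self.p_hat < 0) | (self.p_hat > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_studies(self) -> int:
        return self.p_hat.size

    def pair_sum(self) -> float:
        """sum_{a>b} p_a p_b over strict study pairs."""
        s = self.p_hat.sum()
        return float((s * s - (self.p_hat ** 2).sum()) / 2.0)


@dataclass
class ScoreResult:
    """Scores for one gene set: CS, expectation, maximum, CSSCMP, p-value."""

    set_id: str
    n_genes: int
    cs: int
    expected: float
    s_max: int
    csscmp: float
    p_value: float
    rank: int | None = None
    name: str = ""
    pvalue_method: str = "exact"


def counting_score(sub: GeneSetSubmatrix | np.ndarray) -> int:
    """Counting score: joint up-regulation count over strict study pairs.

    Computed per gene as C(row sum, 2), summed over genes; identical to the
    strict-lower-triangle sum of (M^T M) but linear in the matrix size.
    Returns None (unscorable) for an empty submatrix.
    """
    entries = sub.entries if isinstance(sub, GeneSetSubmatrix) else np.asarray(sub)
    if entries.shape[0] == 0:
        return None
    k = entries.sum(axis=1).astype(np.int64)
    return int((k * (k - 1) // 2).sum())


def upregulation_probabilities(M: ContingencyMatrix) -> StudyProbabilities:
    """p_j = (column-j sum) / N over the overall matrix."""
    if M.n_genes < 1:
        raise ConfigurationError("empty contingency matrix")
    return StudyProbabilities(M.column_sums() / M.n_genes)


def expected_counting_score(n_genes: int,
                            probs: StudyProbabilities) -> float:
    """Expected CS for n_genes independent Bernoulli(p_j) rows."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    return n_genes * probs.pair_sum()


def max_counting_score(n_genes: int, n_studies: int) -> int:
    """Maximum attainable CS: N * D (D - 1) / 2 (all-ones matrix)."""
    if n_studies < 2:
        raise ConfigurationError("need >= 2 studies")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    return n_genes * n_studies * (n_studies - 1) // 2


def csscmp_score(sub: GeneSetSubmatrix,
                 probs: StudyProbabilities) -> float:
    """Chance-corrected score (S_cs - S_bar) / (S_max - S_bar).

    Returns None (undefined sentinel) when S_max == S_bar, which happens only
    when every study probability is 1; negative values indicate below-chance
    co-association.
    """
    if not sub.scorable:
        return None
    cs = counting_score(sub)
    s_bar = expected_counting_score(sub.n_genes, probs)
    s_max = max_counting_score(sub.n_genes, probs.n_studies)
    if s_max <= s_bar:
        return None
    return (cs - s_bar) / (s_max - s_bar)


def _row_sum_pmf(p_hat: np.ndarray) -> np.ndarray:
    """Poisson-binomial pmf of one gene's row sum over D studies.

    Standard polynomial construction: product of (1 - p_j + p_j x).
    """
    pmf = np.array([1.0])
    for p in p_hat:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def pair_count_pmf(probs: StudyProbabilities) -> np.ndarray:
    """Null pmf of one gene's pair-count contribution C(k, 2).

    Support is 0 .. D(D-1)/2 on the integer grid; mass sits only at
    triangular numbers.
    """
    d = probs.n_studies
    row_pmf = _row_sum_pmf(probs.p_hat)
    out = np.zeros(d * (d - 1) // 2 + 1)
    for k, mass in enumerate(row_pmf):
        out[k * (k - 1) // 2] += mass
    return out


def null_cs_distribution(n_genes: int,
                         probs: StudyProbabilities) -> np.ndarray:
    """Exact null pmf of CS for n_genes independent rows, by convolution.

    Binary exponentiation keeps the number of convolutions at O(log N).
    """
    base = pair_count_pmf(probs)
    result = np.array([1.0])
    power = base
    n = n_genes
    while n:
        if n & 1:
            result = np.convolve(result, power)
        n >>= 1
        if n:
            power = np.convolve(power, power)
    return result


def csscmp_pvalue(sub: GeneSetSubmatrix, probs: StudyProbabilities,
                  observed_cs: int | None = None) -> tuple:
    """Upper-tail P(CS >= observed) under the independence null.

    Exact for D <= 25 via per-gene pattern distribution + convolution (no
    permutation trials).  For larger D a normal approximation with the exact
    per-gene mean and variance is used; the method is reported alongside the
    value.

    Returns
    -------
    (p_value, method) : (float, str)
        method is ``"exact"`` or ``"normal_approx"``.
    """
    if not sub.scorable:
        return None, "unscorable"
    cs = counting_score(sub) if observed_cs is None else observed_cs
    d = probs.n_studies
    n = sub.n_genes
    if d <= MAX_EXACT_STUDIES:
        pmf = null_cs_distribution(n, probs)
        # sum the small tail to limit cancellation
        p = float(pmf[cs:].sum())
        return min(max(p, 0.0), 1.0), "exact"
    per_gene = pair_count_pmf(probs)
    support = np.arange(per_gene.size)
    mu1 = float(support @ per_gene)
    var1 = float((support ** 2) @ per_gene) - mu1 ** 2
    mean, sd = n * mu1, math.sqrt(max(n * var1, 1e-300))
    from scipy.stats import norm
    # continuity-corrected upper tail
    return float(norm.sf((cs - 0.5 - mean) / sd)), "normal_approx"


def score_collection(M: ContingencyMatrix, collection,
                     compute_pvalues: bool = True):
    """Score every gene set in a collection against the overall matrix.

    Returns
    -------
    (results, unscorable) : (list of ScoreResult, list of set ids)
        Results sorted by CSSCMP descending, ties by p-value ascending then
        set id; ranks assigned 1..K.  Sets with empty intersection (or
        undefined score) are listed separately.
    """
    from .contingency import extract_submatrix

    probs = upregulation_probabilities(M)
    results, unscorable = [], []
    for gs in collection:
        sub = extract_submatrix(M, gs.genes, set_id=gs.set_id)
        score = csscmp_score(sub, probs)
        if score is None:
            unscorable.append(gs.set_id)
            continue
        cs = counting_score(sub)
        if compute_pvalues:
            p, method = csscmp_pvalue(sub, probs, observed_cs=cs)
        else:
            p, method = float("nan"), "skipped"
        results.append(ScoreResult(
            set_id=gs.set_id, name=getattr(gs, "name", ""),
            n_genes=sub.n_genes, cs=cs,
            expected=expected_counting_score(sub.n_genes, probs),
            s_max=max_counting_score(sub.n_genes, probs.n_studies),
            csscmp=score, p_value=p, pvalue_method=method,
        ))
    results.sort(key=lambda r: (-r.csscmp,
                                r.p_value if compute_pvalues else 0.0,
                                r.set_id))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results, unscorable


def results_to_frame(results, annotations=None):
    """Tidy DataFrame of ranked results, scores rounded to 6 decimals.

    ``annotations`` may be a DataFrame indexed by set_id with per-study 0/1
    enrichment flags from an external method; it is merged as pass-through
    metadata, never computed here.
    """
    import pandas as pd

    df = pd.DataFrame(
        [{"set_id": r.set_id, "set_name": r.name, "n_genes": r.n_genes,
          "cs": r.cs, "expected": round(r.expected, 6),
          "s_max": r.s_max, "csscmp": round(r.csscmp, 6),
          "p_value": r.p_value, "rank": r.rank} for r in results]
    )
    if annotations is not None and not df.empty:
        df = df.merge(annotations, how="left", left_on="set_id",
                      right_index=True)
    return df
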