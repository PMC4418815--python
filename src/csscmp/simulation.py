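"""Random contingency matrices and synthetic multi-study fixtures.

Three experiment families validate the score's advertised properties:

* randomness detection — on matrices of independent Bernoulli calls the
  chance-corrected score concentrates at 0 while the raw counting score does
  not;
* size insensitivity — sweeping the gene-set size shows the counting score
  growing linearly with size while the corrected score stays flat;
* variance robustness — drawing per-study call rates from a Beta
  distribution with fixed mean and increasing variance leaves the top-set
  score summary of random data near 0, far below real consensus data.

All randomness flows from a single seed expanded into per-experiment
substreams, so each experiment is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import (ConfigurationError, ContingencyMatrix,
                          GeneSetSubmatrix, StudyGeneList, build_contingency)
from .genesets import GeneSet, GeneSetCollection
from .scoring import (StudyProbabilities, counting_score, csscmp_score,
                      score_collection, upregulation_probabilities)


@dataclass
class SimulationConfig:
    """Conditions for the random-matrix experiments.

    Parameters
    ----------
    n_studies : int
        Number of study columns D.
    probabilities : sequence of float, optional
        Fixed per-study Bernoulli call rates; mutually exclusive with the
        Beta model below.
    prob_mean, prob_variance : float, optional
        Beta model: per-study rates drawn with this mean and variance
        (variance must satisfy the Bernoulli bound v < m(1-m)).
    set_sizes : list of int
        Gene-set sizes N to sweep.
    n_replicates : int
        Replicates per condition.
    seed : int
        Root seed; every experiment derives its own substream.
    """

    n_studies: int = 20
    probabilities: Sequence[float] | None = None
    prob_mean: float = 0.3
    prob_variance: float = 0.0
    set_sizes: list = field(default_factory=lambda: [15, 50, 100, 200, 500])
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if ((p < 0) | (p > 1)).any():
                raise ConfigurationError("probabilities must lie in [0, 1]")
            if p.size != self.n_studies:
                raise ConfigurationError(
                    "probabilities length must equal n_studies")
        else:
            m, v = self.prob_mean, self.prob_variance
            if not 0 < m < 1:
                raise ConfigurationError("prob_mean must lie in (0, 1)")
            if v < 0 or v >= m * (1 - m):
                raise ConfigurationError(
                    f"prob_variance must lie in [0, {m * (1 - m):.4f}) "
                    f"for mean {m}")

    def draw_probabilities(self, rng: np.random.Generator) -> np.ndarray:
        """Per-study call rates: fixed vector, or Beta(mean, variance)."""
        if self.probabilities is not None:
            return np.asarray(self.probabilities, dtype=float)
        m, v = self.prob_mean, self.prob_variance
        if v == 0:
            return np.full(self.n_studies, m)
        # method-of-moments Beta parameters
        common = m * (1 - m) / v - 1
        return rng.beta(m * common, (1 - m) * common, size=self.n_studies)


def _spawn(seed: int, label: str) -> np.random.Generator:
    """Named substream so experiments don't share random state."""
    digest = sum(ord(c) * 131 ** i for i, c in enumerate(label)) % (2 ** 20)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


def random_entries(n_genes: int, p: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """n_genes x D matrix of independent Bernoulli(p_j) calls."""
    return (rng.random((n_genes, p.size)) < p).astype(np.int8)


def random_contingency(cfg: SimulationConfig,
                       n_genes: int,
                       rng: np.random.Generator | None = None,
                       prefix: str = "G") -> ContingencyMatrix:
    """Random contingency matrix with synthetic gene names.

    Genes whose row is all zeros are kept (the matrix is a simulation
    object, not the union of lists), so column means converge to p_j.
    """
    rng = rng if rng is not None else _spawn(cfg.seed, "random_contingency")
    p = cfg.draw_probabilities(rng)
    width = max(6, len(str(n_genes)))
    genes = [f"{prefix}{i:0{width}d}" for i in range(n_genes)]
    return ContingencyMatrix(genes, [f"S{j+1}" for j in range(cfg.n_studies)],
                             random_entries(n_genes, p, rng))


def random_score_sample(cfg: SimulationConfig, n_genes: int,
                        n_replicates: int | None = None) -> np.ndarray:
    """CSSCMP scores of independent random matrices (randomness check).

    Each replicate draws its own matrix and scores it against the call
    rates estimated from that same matrix, mirroring how a whole random
    universe would be scored.
    """
    rng = _spawn(cfg.seed, "random_scores")
    reps = n_replicates if n_replicates is not None else cfg.n_replicates
    out = np.empty(reps)
    for r in range(reps):
        p = cfg.draw_probabilities(rng)
        entries = random_entries(n_genes, p, rng)
        probs = StudyProbabilities(entries.mean(axis=0))
        sub = GeneSetSubmatrix("random", list(range(n_genes)), entries)
        score = csscmp_score(sub, probs)
        out[r] = np.nan if score is None else score
    return out


def size_sweep_experiment(cfg: SimulationConfig) -> dict:
    """Score random matrices across gene-set sizes; CS vs CSSCMP.

    Returns
    -------
    dict with keys ``points`` (tidy DataFrame: size, replicate, cs,
    csscmp), ``per_size`` (mean per size) and ``correlations``
    (Pearson r of size with each score over all points).
    """
    if len(set(cfg.set_sizes)) < 2:
        raise ConfigurationError("need >= 2 distinct set sizes")
    rng = _spawn(cfg.seed, "size_sweep")
    rows = []
    for size in cfg.set_sizes:
        for rep in range(cfg.n_replicates):
            p = cfg.draw_probabilities(rng)
            entries = random_entries(size, p, rng)
            probs = StudyProbabilities(entries.mean(axis=0))
            sub = GeneSetSubmatrix("sweep", list(range(size)), entries)
            score = csscmp_score(sub, probs)
            rows.append({"size": size, "replicate": rep,
                         "cs": counting_score(sub),
                         "csscmp": np.nan if score is None else score})
    points = pd.DataFrame(rows)
    per_size = points.groupby("size")[["cs", "csscmp"]].mean().reset_index()
    corr_cs = stats.pearsonr(points["size"], points["cs"]).statistic
    corr_cc = stats.pearsonr(points["size"], points["csscmp"]).statistic
    return {"points": points, "per_size": per_size,
            "correlations": {"cs": float(corr_cs), "csscmp": float(corr_cc)}}


def variance_robustness_experiment(
    cfg: SimulationConfig,
    collection: GeneSetCollection,
    variance_levels: Sequence[float] = (0.0, 0.005, 0.01, 0.02),
    top_fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    real_matrix: ContingencyMatrix | None = None,
) -> pd.DataFrame:
    """Mean CSSCMP of the top score fractions, random data vs (optionally) real.

    For each variance level, per-study call rates are drawn from a Beta with
    the configured mean, a random matrix is generated over the collection's
    gene universe, and the collection is scored against it.  The summary for
    real data uses the supplied matrix unchanged.
    """
    rng = _spawn(cfg.seed, "variance_robustness")
    universe = sorted(set().union(*(gs.genes for gs in collection)))
    rows = []

    def summarize(results, source, variance):
        scores = np.array([r.csscmp for r in results])  # already sorted desc
        for frac in top_fractions:
            k = max(1, int(round(frac * scores.size)))
            rows.append({"source": source, "variance": variance,
                         "top_fraction": frac,
                         "mean_csscmp": float(scores[:k].mean()),
                         "n_sets": scores.size})

    for v in variance_levels:
        level_cfg = SimulationConfig(
            n_studies=cfg.n_studies, prob_mean=cfg.prob_mean,
            prob_variance=v, seed=cfg.seed)
        p = level_cfg.draw_probabilities(rng)
        entries = random_entries(len(universe), p, rng)
        M = ContingencyMatrix(universe,
                              [f"S{j+1}" for j in range(cfg.n_studies)],
                              entries)
        results, _ = score_collection(M, collection, compute_pvalues=False)
        summarize(results, "random", v)
    if real_matrix is not None:
        results, _ = score_collection(real_matrix, collection,
                                      compute_pvalues=False)
        summarize(results, "real", np.nan)
    return pd.DataFrame(rows)


def make_fixture(
    planted: Sequence[tuple],
    n_studies: int = 7,
    n_background_genes: int = 2000,
    background_prob: float = 0.2,
    n_decoys: int = 95,
    decoy_size_range: tuple = (15, 50),
    seed: int = 0,
):
    """Synthetic multi-study fixture with planted consensus gene sets.

    Planted sets receive genes whose rows are all-ones with the stated joint
    probability (background Bernoulli draws otherwise), so their consensus
    score exceeds the decoys drawn purely from background.

    Parameters
    ----------
    planted : sequence of (set_size, joint_probability)
        One entry per planted set; planted genes are disjoint from the
        background pool.

    Returns
    -------
    (study_lists, collection, truth) where ``truth`` is a DataFrame with
    columns set_id, planted, size, joint_probability.
    """
    rng = _spawn(seed, "fixture")
    study_ids = [f"S{j+1}" for j in range(n_studies)]
    bg_genes = [f"BG{i:05d}" for i in range(n_background_genes)]
    p = np.full(n_studies, background_prob)
    bg_entries = random_entries(n_background_genes, p, rng)

    gene_rows = {}
    for g, row in zip(bg_genes, bg_entries):
        gene_rows[g] = row
    sets, truth_rows = [], []
    counter = 0
    for idx, (size, joint_prob) in enumerate(planted):
        members = []
        for _ in range(size):
            g = f"PL{counter:05d}"
            counter += 1
            if rng.random() < joint_prob:
                gene_rows[g] = np.ones(n_studies, dtype=np.int8)
            else:
                gene_rows[g] = random_entries(1, p, rng)[0]
            members.append(g)
        sid = f"PLANTED_{idx+1:02d}"
        sets.append(GeneSet(sid, f"planted joint p={joint_prob}",
                            set(members)))
        truth_rows.append({"set_id": sid, "planted": True, "size": size,
                           "joint_probability": joint_prob})
    for idx in range(n_decoys):
        size = int(rng.integers(decoy_size_range[0],
                                decoy_size_range[1] + 1))
        members = rng.choice(bg_genes, size=size, replace=False)
        sid = f"DECOY_{idx+1:03d}"
        sets.append(GeneSet(sid, "background sample", set(members.tolist())))
        truth_rows.append({"set_id": sid, "planted": False, "size": size,
                           "joint_probability": np.nan})

    study_lists = []
    for j, sid in enumerate(study_ids):
        genes = frozenset(g for g, row in gene_rows.items() if row[j])
        study_lists.append(StudyGeneList(study_id=sid, genes=genes,
                                         source_note="synthetic fixture"))
    collection = GeneSetCollection(
        label="fixture", sets=sets,
        provenance={"generator": "make_fixture", "seed": str(seed)})
    truth = pd.DataFrame(truth_rows)
    return study_lists, collection, truth
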