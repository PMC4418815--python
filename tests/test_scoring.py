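import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csscmp import (ConfigurationError, ContingencyMatrix, GeneSet,
                    GeneSetCollection, GeneSetSubmatrix, StudyProbabilities,
                    counting_score, csscmp_pvalue, csscmp_score,
                    expected_counting_score, max_counting_score,
                    null_cs_distribution, score_collection,
                    upregulation_probabilities)
from csscmp.scoring import pair_count_pmf


def brute_force_counting_score(entries) -> int:
    """Independent oracle: explicit triple loop over strict study pairs."""
    entries = np.asarray(entries)
    n, d = entries.shape
    total = 0
    for a in range(d):
        for b in range(a):
            for i in range(n):
                total += int(entries[i, a]) * int(entries[i, b])
    return total


class TestCountingScore:
    def test_all_ones_reaches_maximum(self):
        sub = GeneSetSubmatrix("x", list(range(10)), np.ones((10, 3)))
        assert counting_score(sub) == 30 == max_counting_score(10, 3)

    def test_all_zeros_scores_zero(self):
        sub = GeneSetSubmatrix("x", list(range(5)), np.zeros((5, 4)))
        assert counting_score(sub) == 0

    def test_worked_example(self, worked_submatrix):
        assert counting_score(worked_submatrix) == 4
        assert brute_force_counting_score(worked_submatrix.entries) == 4

    def test_empty_submatrix_unscorable(self):
        sub = GeneSetSubmatrix("x", [], np.empty((0, 3)))
        assert counting_score(sub) is None

    @settings(max_examples=500, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 20),
           st.integers(2, 6))
    def test_matches_triple_loop_oracle(self, seed, n, d):
        entries = np.random.default_rng(seed).integers(0, 2, (n, d))
        sub = GeneSetSubmatrix("r", list(range(n)), entries)
        assert counting_score(sub) == brute_force_counting_score(entries)


class TestProbabilitiesAndExpectation:
    def test_probabilities_are_column_means(self, toy_matrix):
        probs = upregulation_probabilities(toy_matrix)
        assert np.allclose(probs.p_hat, [0.75, 0.75, 0.25])

    def test_constant_columns_give_zero_or_one(self):
        M = ContingencyMatrix(["A", "B"], ["S1", "S2"],
                              np.array([[1, 1], [1, 0]]))
        probs = upregulation_probabilities(M)
        assert probs.p_hat[0] == 1.0 and probs.p_hat[1] == 0.5

    def test_expected_score_hand_value(self):
        probs = StudyProbabilities([0.75, 0.75, 0.25])
        # 2 * (0.75*0.75 + 0.75*0.25 + 0.75*0.25)
        assert expected_counting_score(2, probs) == pytest.approx(1.875)

    def test_expectation_degenerate_bounds(self):
        zero = StudyProbabilities([0.0, 0.0, 0.0])
        ones = StudyProbabilities([1.0] * 5)
        assert expected_counting_score(100, zero) == 0.0
        assert expected_counting_score(7, ones) == max_counting_score(7, 5)

    def test_max_score_formula(self):
        assert max_counting_score(2, 3) == 6
        assert max_counting_score(0, 4) == 0
        assert max_counting_score(54, 7) == 1134
        with pytest.raises(ConfigurationError):
            max_counting_score(5, 1)


class TestChanceCorrectedScore:
    def test_worked_example(self, worked_submatrix):
        probs = StudyProbabilities([0.75, 0.75, 0.25])
        score = csscmp_score(worked_submatrix, probs)
        assert score == pytest.approx((4 - 1.875) / (6 - 1.875))
        assert score == pytest.approx(0.515151515)

    @pytest.mark.parametrize("n,d", [(1, 2), (5, 3), (40, 7)])
    def test_perfect_consensus_scores_one(self, n, d):
        sub = GeneSetSubmatrix("x", list(range(n)), np.ones((n, d)))
        probs = StudyProbabilities(np.full(d, 0.4))
        assert csscmp_score(sub, probs) == pytest.approx(1.0)

    def test_all_prob_one_is_undefined(self):
        sub = GeneSetSubmatrix("x", [0], np.ones((1, 3)))
        assert csscmp_score(sub, StudyProbabilities([1, 1, 1])) is None

    def test_random_input_scores_near_zero(self):
        rng = np.random.default_rng(11)
        p = np.array([0.2, 0.35, 0.3, 0.25, 0.4])
        entries = (rng.random((5000, 5)) < p).astype(np.int8)
        probs = StudyProbabilities(entries.mean(axis=0))
        sub = GeneSetSubmatrix("r", list(range(5000)), entries)
        assert abs(csscmp_score(sub, probs)) < 0.01

    def test_appending_all_ones_row_never_decreases_score(self):
        rng = np.random.default_rng(5)
        probs = StudyProbabilities([0.3, 0.4, 0.2, 0.5])
        for _ in range(50):
            n = int(rng.integers(1, 30))
            entries = rng.integers(0, 2, (n, 4))
            before = csscmp_score(
                GeneSetSubmatrix("a", list(range(n)), entries), probs)
            grown = np.vstack([entries, np.ones((1, 4), dtype=int)])
            after = csscmp_score(
                GeneSetSubmatrix("a", list(range(n + 1)), grown), probs)
            assert after >= before - 1e-12


class TestExactPValue:
    def test_observed_zero_gives_one(self, worked_submatrix):
        probs = StudyProbabilities([0.75, 0.75, 0.25])
        p, method = csscmp_pvalue(worked_submatrix, probs, observed_cs=0)
        assert p == 1.0 and method == "exact"

    def test_single_gene_two_studies(self):
        probs = StudyProbabilities([0.5, 0.5])
        sub = GeneSetSubmatrix("x", [0], np.array([[1, 1]]))
        p, _ = csscmp_pvalue(sub, probs, observed_cs=1)
        assert p == pytest.approx(0.25)

    def test_two_genes_convolution(self):
        probs = StudyProbabilities([0.5, 0.5])
        sub = GeneSetSubmatrix("x", [0, 1], np.array([[1, 1], [1, 1]]))
        p, _ = csscmp_pvalue(sub, probs, observed_cs=2)
        assert p == pytest.approx(0.0625)

    def test_null_distribution_matches_enumeration(self):
        # D=3: enumerate all 8 patterns per gene, 2 genes -> 64 outcomes
        import itertools

        probs = StudyProbabilities([0.3, 0.6, 0.5])
        p = probs.p_hat
        dist = {}
        for rows in itertools.product(itertools.product([0, 1], repeat=3),
                                      repeat=2):
            prob = 1.0
            score = 0
            for row in rows:
                for j, v in enumerate(row):
                    prob *= p[j] if v else 1 - p[j]
                k = sum(row)
                score += k * (k - 1) // 2
            dist[score] = dist.get(score, 0.0) + prob
        pmf = null_cs_distribution(2, probs)
        for s, mass in dist.items():
            assert pmf[s] == pytest.approx(mass, abs=1e-12)

    def test_pmf_sums_to_one_and_mean_matches_expectation(self):
        probs = StudyProbabilities([0.2, 0.5, 0.3, 0.4, 0.25, 0.1, 0.35])
        pmf = null_cs_distribution(30, probs)
        assert pmf.sum() == pytest.approx(1.0)
        mean = (np.arange(pmf.size) * pmf).sum()
        assert mean == pytest.approx(expected_counting_score(30, probs))

    def test_normal_fallback_for_many_studies(self):
        d = 30
        probs = StudyProbabilities(np.full(d, 0.3))
        rng = np.random.default_rng(2)
        entries = rng.integers(0, 2, (20, d))
        sub = GeneSetSubmatrix("x", list(range(20)), entries)
        p, method = csscmp_pvalue(sub, probs)
        assert method == "normal_approx" and 0 <= p <= 1


class TestScoreCollection:
    def test_perfect_set_ranks_first(self, toy_matrix):
        coll = GeneSetCollection("toy", [
            GeneSet("ALLSTUDIES", "only g1", {"G1"}),
            GeneSet("MIXED", "g2..g4", {"G2", "G3", "G4"}),
        ])
        results, unscorable = score_collection(toy_matrix, coll)
        assert results[0].set_id == "ALLSTUDIES"
        assert results[0].rank == 1 and results[1].rank == 2
        assert unscorable == []

    def test_empty_intersection_reported_separately(self, toy_matrix):
        coll = GeneSetCollection("toy", [
            GeneSet("GHOST", "", {"Z1"}),
            GeneSet("REAL", "", {"G1", "G2"}),
        ])
        results, unscorable = score_collection(toy_matrix, coll)
        assert unscorable == ["GHOST"]
        assert [r.set_id for r in results] == ["REAL"]

    def test_single_set_gets_rank_one(self, toy_matrix):
        coll = GeneSetCollection("toy", [GeneSet("ONLY", "", {"G3"})])
        results, _ = score_collection(toy_matrix, coll)
        assert results[0].rank == 1

    def test_result_invariants(self, toy_matrix):
        coll = GeneSetCollection("toy", [
            GeneSet(f"S{i}", "", set(np.random.default_rng(i).choice(
                toy_matrix.gene_ids, 2, replace=False)))
            for i in range(5)
        ])
        results, _ = score_collection(toy_matrix, coll)
        for r in results:
            assert 0 <= r.cs <= r.s_max
            assert r.s_max == r.n_genes * 3 * 2 // 2
            assert r.csscmp <= 1
            assert 0 < r.p_value <= 1
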