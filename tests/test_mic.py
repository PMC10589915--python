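"""Mutual-information and MIC estimator tests.

The exhaustive-path results are checked against ``brute_force_mic``, an
independent oracle that enumerates every admissible cut-point placement
using explicit midpoint cut values and a plain-Python MI computation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnfusion.mic import MicConfig, mic, mic_matrix, mutual_information


def plain_mi_bits(counts):
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    px = counts.sum(axis=1) / total
    py = counts.sum(axis=0) / total
    s = 0.0
    for a in range(counts.shape[0]):
        for b in range(counts.shape[1]):
            p = counts[a, b] / total
            if p > 0:
                s += p * np.log2(p / (px[a] * py[b]))
    return s


def brute_force_mic(x, y, alpha=0.6):
    """Exhaustive maximization over all admissible grids, independent route."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    N = len(x)
    bound = N ** alpha

    def midpoints(v):
        sv = np.sort(np.unique(v))
        return (sv[:-1] + sv[1:]) / 2

    cx, cy = midpoints(x), midpoints(y)
    best = 0.0
    m = 2
    while m * 2 < bound:
        n = 2
        while m * n < bound:
            for gx in itertools.combinations(cx, m - 1):
                xb = np.searchsorted(gx, x)
                for gy in itertools.combinations(cy, n - 1):
                    yb = np.searchsorted(gy, y)
                    cnt = np.zeros((m, n))
                    for a, b in zip(xb, yb):
                        cnt[a, b] += 1
                    val = plain_mi_bits(cnt) / np.log2(min(m, n))
                    best = max(best, val)
            n += 1
        m += 1
    return best


class TestMutualInformation:
    def test_perfect_diagonal_dependence_is_one_bit(self):
        assert mutual_information([[2, 0], [0, 2]]) == pytest.approx(1.0)

    def test_exact_independence_is_zero(self):
        assert mutual_information([[1, 1], [1, 1]]) == pytest.approx(0.0, abs=1e-15)

    def test_skewed_table_term_by_term(self):
        # 0.5 log2(4/3) + 0.25 log2(2/3) + 0.25 log2(2)
        assert mutual_information([[2, 1], [0, 1]]) == pytest.approx(0.311278, abs=1e-6)

    def test_single_nonempty_row_is_zero(self):
        assert mutual_information([[3, 2, 1], [0, 0, 0]]) == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([[0, 0], [0, 0]])

    @given(st.lists(st.integers(0, 8), min_size=4, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_information_inequality(self, flat):
        if sum(flat) == 0:
            flat[0] = 1
        side = 2 if len(flat) % 2 == 0 else 3
        counts = np.resize(flat, (len(flat) // side, side))
        assert mutual_information(counts) >= 0.0

    def test_agrees_with_sklearn_contingency_route(self, rng):
        from sklearn.metrics import mutual_info_score
        counts = rng.integers(0, 10, size=(4, 3))
        counts[0, 0] += 1
        expected = mutual_info_score(None, None, contingency=counts) / np.log(2)
        assert mutual_information(counts) == pytest.approx(expected, abs=1e-12)


class TestMic:
    def test_identity_n16_is_exactly_one(self):
        x = np.arange(1, 17, dtype=float)
        assert mic(x, x) == pytest.approx(1.0, abs=1e-15)

    def test_constant_vector_scores_zero(self, rng):
        assert mic(np.ones(100), rng.normal(size=100)) == 0.0

    def test_too_small_sample_defined_zero_with_warning(self, rng):
        with pytest.warns(UserWarning, match="no admissible grid"):
            assert mic(rng.normal(size=8), rng.normal(size=8)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mic(np.arange(10), np.arange(11))

    def test_matches_exhaustive_oracle_on_seeded_cases(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            N = int(rng.integers(11, 21))
            x = rng.normal(size=N)
            y = x ** 2 + rng.normal(size=N)
            assert mic(x, y) == pytest.approx(brute_force_mic(x, y), abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        for N in (15, 60):
            x = rng.normal(size=N)
            y = np.sin(x) + rng.normal(size=N) * 0.3
            assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-15)

    def test_bounded_in_unit_interval(self, rng):
        for N in (12, 18, 40, 120):
            x, y = rng.normal(size=N), rng.normal(size=N)
            assert 0.0 <= mic(x, y) <= 1.0

    @pytest.mark.parametrize("N", [14, 20, 60])
    def test_invariant_under_strictly_increasing_transforms(self, N):
        rng = np.random.default_rng(N)
        x = rng.normal(size=N)
        y = x + rng.normal(size=N)
        base = mic(x, y)
        assert mic(np.exp(x), y) == pytest.approx(base, abs=1e-15)
        assert mic(x, y ** 3) == pytest.approx(base, abs=1e-15)

    def test_self_mic_is_one_when_half_split_exists(self, rng):
        # a 2x2 grid with an even split puts all mass on the diagonal
        for N in (12, 16, 30):
            x = rng.normal(size=N)
            assert mic(x, x) == pytest.approx(1.0, abs=1e-15)

    def test_approximate_path_lower_bounds_exhaustive(self, rng):
        x = rng.normal(size=24)
        y = x + 0.5 * rng.normal(size=24)
        exact = mic(x, y, config=MicConfig(exhaustive_cutoff=25))
        approx = mic(x, y, config=MicConfig(exhaustive_cutoff=10))
        assert approx <= exact + 1e-12


class TestMicMatrix:
    def test_duplicated_gene_scores_one(self, small_dataset):
        ds = small_dataset
        ds.steady.values[:, 1] = ds.steady.values[:, 0]
        for exp in ds.ts_experiments:
            exp.values[:, 1] = exp.values[:, 0]
        m = mic_matrix(ds)
        assert m[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_symmetric_with_nan_diagonal(self, small_dataset):
        m = mic_matrix(small_dataset)
        np.testing.assert_array_equal(m.scores, m.scores.T)
        assert np.all(np.isnan(np.diag(m.scores)))

    def test_entries_equal_pairwise_calls_on_pooled_vectors(self, small_dataset):
        m = mic_matrix(small_dataset)
        pooled = small_dataset.pooled_matrix()
        for i in range(5):
            for j in range(i + 1, 5):
                assert m[i, j] == pytest.approx(mic(pooled[:, i], pooled[:, j]),
                                                abs=1e-15)

    def test_candidate_restriction_skips_uninvolved_pairs(self, small_dataset):
        m = mic_matrix(small_dataset, candidate_regulators=["G1"])
        assert not np.isnan(m[0, 3])
        assert np.isnan(m[2, 3])  # neither gene is a candidate regulator

    def test_tsv_roundtrip(self, tmp_path, small_dataset):
        m = mic_matrix(small_dataset)
        path = tmp_path / "mic.tsv"
        m.to_tsv(path)
        from grnfusion.mic import MicMatrix
        back = MicMatrix.from_tsv(path)
        np.testing.assert_allclose(back.scores, m.scores, rtol=1e-9)
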