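"""Null-model contracts and distributional checks.

The Patefield uniformity check uses instances whose feasible tables are
all 0/1-valued; on those the fixed-margin hypergeometric table
distribution is provably uniform, so a chi-square test against the
enumerated feasible set is exact.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from woodweb import (
    InteractionMatrix,
    ValidationError,
    null_ensemble,
    patefield_null,
    patefield_table_null,
    shannon_entries,
    shuffle_null,
    to_integer_matrix,
    vazquez_null,
)


def enumerate_tables(row_sums, col_sums):
    """Brute-force oracle: all non-negative integer tables with the margins."""
    nr, nc = len(row_sums), len(col_sums)
    tables = []

    def rows(i, remaining_cols, acc):
        if i == nr:
            if all(c == 0 for c in remaining_cols):
                tables.append(tuple(acc))
            return
        for row in itertools.product(*(range(min(row_sums[i], c) + 1) for c in remaining_cols)):
            if sum(row) == row_sums[i]:
                rows(i + 1, [c - r for c, r in zip(remaining_cols, row)], acc + [row])

    rows(0, list(col_sums), [])
    return tables


class TestPatefield:
    def test_marginals_exact(self):
        rng = np.random.default_rng(0)
        W = rng.integers(0, 9, size=(5, 7)).astype(float)
        W[0, 0] += 1
        M = InteractionMatrix(W)
        for seed in range(20):
            N = patefield_null(M, seed)
            assert np.array_equal(N.row_totals, M.row_totals)
            assert np.array_equal(N.col_totals, M.col_totals)

    def test_one_by_one_identity(self):
        M = InteractionMatrix(np.array([[4.0]]))
        assert patefield_null(M, 0).weights[0, 0] == 4.0

    def test_non_integer_input_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            patefield_null(InteractionMatrix(np.array([[0.5, 0.5]])), 0)

    @pytest.mark.parametrize(
        "matrix",
        [
            [[1, 0], [0, 1]],             # margins (1,1)/(1,1): 2 tables
            [[1, 1, 0], [0, 0, 1]],       # margins (2,1)/(1,1,1): 3 tables
            [[1, 0, 0], [0, 1, 1]],       # same family, different observed
        ],
    )
    def test_uniform_over_feasible_set_on_01_instances(self, matrix):
        M = InteractionMatrix(np.asarray(matrix, dtype=float))
        feasible = enumerate_tables(
            [int(x) for x in M.row_totals], [int(x) for x in M.col_totals]
        )
        assert len(feasible) > 1
        counts = dict.fromkeys(feasible, 0)
        n = 10_000
        for seed in range(n):
            t = tuple(
                tuple(int(x) for x in row) for row in patefield_null(M, seed).weights
            )
            counts[t] += 1
        observed = np.array([counts[f] for f in feasible])
        assert observed.min() > 0
        chi = sps.chisquare(observed)
        assert chi.pvalue > 0.01

    def test_independence_structure_gives_near_zero_h2prime(self):
        from woodweb import h2prime

        M = InteractionMatrix(np.outer([10, 20, 30], [1, 2, 3, 4]).astype(float))
        assert h2prime(M) == 0.0
        nulls = [h2prime(patefield_null(M, s)) for s in range(50)]
        assert np.mean(nulls) < 0.05

    def test_table_null_preserves_table_margins(self, small_table):
        null = patefield_table_null(small_table, 3)
        assert (null.sample_totals() == small_table.sample_totals()).all()
        assert (null.otu_totals() == small_table.otu_totals()).all()


class TestVazquez:
    def test_full_matrix_support_forced(self):
        M = InteractionMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        N = vazquez_null(M, 0)
        assert (N.weights > 0).all()

    def test_total_and_link_count_exact_no_empty_margins(self):
        rng = np.random.default_rng(1)
        W = rng.random((4, 6)) * (rng.random((4, 6)) > 0.4)
        W[np.arange(4), np.arange(4)] += 0.5  # every row linked
        W[0, 4] += 0.3
        W[1, 5] += 0.3
        M = InteractionMatrix(W)
        for seed in range(20):
            N = vazquez_null(M, seed)
            assert N.links == M.links
            assert N.m == pytest.approx(M.m, abs=1e-9)
            assert (N.row_totals > 0).all() and (N.col_totals > 0).all()

    def test_mean_weight_tracks_marginal_product(self):
        M = InteractionMatrix(np.outer([8, 4, 2, 1], [8, 4, 2, 1]).astype(float))
        mean_w = np.zeros(M.shape)
        n = 300
        for seed in range(n):
            mean_w += vazquez_null(M, seed).weights
        mean_w /= n
        prod = np.outer(M.r, M.c).ravel()
        r = sps.pearsonr(prod, mean_w.ravel()).statistic
        assert r > 0.5

    def test_infeasible_link_count_rejected(self):
        # 3 links cannot cover 4 rows
        W = np.zeros((4, 2))
        W[0, 0] = W[1, 1] = W[2, 0] = 1.0
        with pytest.raises(ValidationError):
            vazquez_null(InteractionMatrix(W), 0)


class TestShuffle:
    def test_one_by_one_unchanged(self):
        M = InteractionMatrix(np.array([[2.5]]))
        assert shuffle_null(M, 0).weights[0, 0] == 2.5

    def test_value_multiset_and_link_count_preserved(self):
        rng = np.random.default_rng(2)
        W = rng.random((5, 6)) * (rng.random((5, 6)) > 0.5)
        W[0, 0] += 0.7
        M = InteractionMatrix(W)
        for seed in range(20):
            N = shuffle_null(M, seed)
            assert N.links == M.links
            assert np.allclose(
                np.sort(N.weights[N.weights > 0]), np.sort(M.weights[M.weights > 0])
            )

    def test_shannon_invariant_under_shuffle(self):
        # diversity depends only on the value multiset, which shuffle keeps:
        # the behavior behind the diversity-index exception in null testing
        rng = np.random.default_rng(3)
        W = rng.random((6, 9)) * (rng.random((6, 9)) > 0.4)
        W[0, 0] += 0.3
        M = InteractionMatrix(W)
        H = shannon_entries(M)
        for seed in range(10):
            assert shannon_entries(shuffle_null(M, seed)) == pytest.approx(H, abs=1e-12)


class TestEnsemble:
    def test_patefield_ensemble_contract(self):
        rng = np.random.default_rng(4)
        M = InteractionMatrix(rng.integers(0, 6, size=(4, 4)).astype(float) + 1)
        ens = null_ensemble(M, "patefield", n=50, seed=9)
        assert ens.n == 50 and len(ens.matrices) == 50
        assert ens.index_distributions.shape[0] == 50
        for N in ens.matrices:
            assert np.array_equal(N.row_totals, M.row_totals)

    def test_shuffle_ensemble_constant_shannon(self):
        rng = np.random.default_rng(5)
        M = InteractionMatrix(rng.random((4, 5)) + 0.01)
        ens = null_ensemble(M, "shuffle", n=20, seed=0)
        H = ens.index_distributions["shannon"]
        assert H.std() == pytest.approx(0.0, abs=1e-12)

    def test_planted_structure_exceeds_null_percentiles(self):
        # strongly modular network: observed specialization and modularity
        # sit above the 97.5th percentile of patefield and vazquez nulls
        from woodweb import h2prime, optimize_modules

        # heavy diagonal blocks plus sparse weak background links, so the
        # link count exceeds both dimensions and connectance-preserving
        # nulls can genuinely despecialize the matrix
        rng = np.random.default_rng(6)
        W = np.kron(np.eye(4), np.ones((1, 3))) * 15 + (rng.random((4, 12)) < 0.4)
        M = InteractionMatrix(W)
        obs_h2 = h2prime(M)
        obs_q = optimize_modules(M, seed=0).Q
        for method in ("patefield", "vazquez"):
            ens = null_ensemble(M, method, n=40, seed=1, compute_indices=False)
            null_h2 = [h2prime(N) for N in ens.matrices]
            null_q = [optimize_modules(N, n_starts=5, seed=2).Q for N in ens.matrices]
            assert obs_h2 > np.percentile(null_h2, 97.5)
            assert obs_q > np.percentile(null_q, 97.5)
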