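import numpy as np
import pytest

from woodweb import (
    InteractionMatrix,
    dprime,
    effective_partners,
    generality,
    h2_bounds,
    h2prime,
    interaction_evenness,
    network_level,
    shannon_entries,
)


def M(w):
    return InteractionMatrix(np.asarray(w, dtype=float))


class TestShannonAndEvenness:
    def test_uniform_cells(self):
        assert shannon_entries(M([[1, 1], [1, 1]])) == pytest.approx(np.log(4))

    def test_single_cell_zero_entropy(self):
        assert shannon_entries(M([[5, 0], [0, 0]])) == 0.0

    def test_hand_evaluated_three_cell(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        assert shannon_entries(M([[2, 1], [1, 0]])) == pytest.approx(1.0397, abs=1e-4)

    def test_evenness_uniform_is_one(self):
        assert interaction_evenness(M([[1, 1], [1, 1]])) == pytest.approx(1.0)

    def test_evenness_single_cell_is_zero(self):
        assert interaction_evenness(M([[5, 0], [0, 0]])) == 0.0

    def test_evenness_hand_value_and_sum_mode(self):
        m = M([[2, 1], [1, 0]])
        assert interaction_evenness(m, "prod") == pytest.approx(0.75, abs=1e-4)
        assert interaction_evenness(m, "sum") == pytest.approx(1.0397 / np.log(3), abs=1e-4)


class TestEffectivePartnersAndGenerality:
    def test_uniform_vector(self):
        assert effective_partners([1, 1, 1, 1]) == pytest.approx(4.0)

    def test_concentrated_vector(self):
        assert effective_partners([5, 0, 0]) == pytest.approx(1.0)

    def test_hand_value(self):
        assert effective_partners([2, 1, 1]) == pytest.approx(2.8284, abs=1e-4)

    def test_all_ones_rows(self):
        assert generality(M(np.ones((2, 4))), "rows") == pytest.approx(4.0)

    def test_equal_diagonal_is_one(self):
        assert generality(M(np.eye(3)), "rows") == pytest.approx(1.0)

    def test_weighted_mean_hand_value(self):
        val = generality(M([[2, 1, 1], [0, 0, 4]]), "rows")
        assert val == pytest.approx(0.5 * 2.8284 + 0.5, abs=1e-4)

    def test_bounds_and_uniform_attainment(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            W = rng.random((3, 5)) + 0.01
            g = generality(InteractionMatrix(W), "rows")
            assert 1.0 - 1e-9 <= g <= 5.0 + 1e-9
        assert generality(M(np.ones((3, 5))), "rows") == pytest.approx(5.0)

    def test_exp_mean_entropy_variant(self):
        m = M([[2, 1, 1], [0, 0, 4]])
        # exp(0.5 * H(row1) + 0.5 * 0)
        assert generality(m, "rows", method="exp_mean_entropy") == pytest.approx(
            np.exp(0.5 * 1.0397), abs=1e-3
        )


class TestH2:
    def test_equal_diagonal_fully_specialized(self):
        assert h2prime(M(np.eye(5))) == pytest.approx(1.0)

    def test_outer_product_no_specialization(self):
        # [[4,2],[2,1]] is the outer product of its own marginals
        m = M([[4, 2], [2, 1]])
        h2_min, h2_max = h2_bounds(m)
        assert shannon_entries(m) == pytest.approx(h2_max)
        assert h2prime(m) == 0.0

    def test_diagonal_h2min_equals_own_entropy(self):
        m = M(np.eye(4) * 2)
        h2_min, _ = h2_bounds(m)
        assert h2_min == pytest.approx(shannon_entries(m))

    def test_greedy_h2min_lower_bounds_random_tables(self):
        # greedy packing must not exceed the entropy of any
        # marginal-preserving table (Monte-Carlo oracle)
        from woodweb import patefield_null

        rng = np.random.default_rng(5)
        W = rng.integers(1, 20, size=(4, 4)).astype(float)
        m = InteractionMatrix(W)
        h2_min, h2_max = h2_bounds(m)
        for seed in range(200):
            ent = shannon_entries(patefield_null(m, seed))
            assert h2_min <= ent + 1e-9
            # independence maximizes entropy among fixed-margin tables
            assert ent <= h2_max + 1e-9

    def test_h2prime_monotone_along_packing_interpolation(self):
        # from uniform outer product (no structure) to equal diagonal
        outer = np.ones((4, 4)) / 16
        diag = np.eye(4) / 4
        vals = [h2prime(M((1 - t) * outer + t * diag)) for t in (0, 0.25, 0.5, 0.75, 1)]
        assert vals[0] == 0.0 and vals[-1] == pytest.approx(1.0)
        assert np.all(np.diff(vals) > 0)


class TestDprime:
    def test_all_ones_row_is_generalist(self):
        sp = dprime(M(np.ones((3, 4))), "rows")
        assert sp.dprime[0] == 0.0

    def test_exclusive_column_is_perfect_specialist(self):
        # row 0 concentrated on a column used by nobody else
        sp = dprime(M([[3, 0, 0], [0, 2, 1]]), "rows")
        assert sp.dprime[0] == pytest.approx(1.0)

    def test_hand_kl_evaluation(self):
        sp = dprime(M([[2, 1], [1, 2]]), "rows")
        assert sp.d[0] == pytest.approx(0.0566, abs=1e-4)
        assert sp.dprime[0] == pytest.approx(0.0817, abs=1e-4)

    def test_mean_dprime_monotone_along_interpolation(self):
        outer = np.ones((4, 4)) / 16
        diag = np.eye(4) / 4
        vals = [
            dprime(M((1 - t) * outer + t * diag), "rows").dprime.mean()
            for t in (0, 0.3, 0.6, 0.9)
        ]
        assert np.all(np.diff(vals) > 0)


class TestInvariances:
    @pytest.mark.parametrize("kappa", [0.01, 3.7, 1000.0])
    def test_scale_invariance(self, kappa):
        rng = np.random.default_rng(2)
        W = rng.random((4, 6)) * (rng.random((4, 6)) > 0.3)
        W[0, 0] += 0.5
        a, b = network_level(InteractionMatrix(W)), network_level(InteractionMatrix(W * kappa))
        for f in ("shannon", "interaction_evenness", "generality_rows",
                  "generality_cols", "h2prime", "connectance"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        W = rng.random((4, 5)) + 0.05
        pr, pc = rng.permutation(4), rng.permutation(5)
        a = network_level(InteractionMatrix(W))
        b = network_level(InteractionMatrix(W[np.ix_(pr, pc)]))
        for f in ("shannon", "h2prime", "generality_rows", "generality_cols"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-9)

    def test_network_level_deterministic(self):
        rng = np.random.default_rng(4)
        W = rng.random((5, 8))
        r1 = network_level(InteractionMatrix(W)).as_series()
        r2 = network_level(InteractionMatrix(W)).as_series()
        assert (r1.fillna(-1) == r2.fillna(-1)).all()

    def test_network_level_record_consistency(self):
        m = M(np.eye(4))
        rec = network_level(m)
        assert rec.h2prime == pytest.approx(1.0)
        assert rec.generality_rows == pytest.approx(1.0)
        assert rec.links == 4 and rec.connectance == pytest.approx(0.25)
        assert rec.h2_min - 1e-9 <= rec.h2 <= rec.h2_max + 1e-9
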