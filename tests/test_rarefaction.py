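import numpy as np
import pytest

from woodweb import (
    RarefactionConfig,
    SyntheticConfig,
    UndefinedEstimatorError,
    ValidationError,
    ace_richness,
    coverage_ratio,
    generate_dataset,
    rarefaction_ensemble,
    rarefy,
)


class TestAce:
    def test_no_rare_species_reduces_to_observed_richness(self):
        res = ace_richness([11, 12, 13])
        assert res.s_ace == 3.0
        assert res.s_rare == 0 and res.s_abund == 3

    def test_hand_evaluated_mixed_community(self):
        # S_abund=1, rare {1,1,2,3}: N_rare=7, F1=2,F2=1,F3=1, C=5/7,
        # gamma^2 = max(4*8/((5/7)*42) - 1, 0) = 1/15
        # S_ace = 1 + 4/(5/7) + (2/(5/7))/15 = 6.7866...
        res = ace_richness([1, 1, 2, 3, 15])
        assert res.s_ace == pytest.approx(6.78667, abs=1e-4)
        assert res.c_ace == pytest.approx(5 / 7)
        assert res.gamma_sq == pytest.approx(1 / 15)

    def test_all_singletons_undefined(self):
        with pytest.raises(UndefinedEstimatorError):
            ace_richness([1, 1, 1])

    def test_estimate_not_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(1, 40, size=30)
            try:
                res = ace_richness(a)
            except UndefinedEstimatorError:
                continue
            assert res.s_ace >= np.sum(a > 0) - 1e-9
            assert 0 < res.c_ace <= 1


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self, small_table):
        depth = int(small_table.sample_totals().min())
        sub = small_table.with_counts(small_table.counts.iloc[:1])
        full = int(sub.sample_totals().iloc[0])
        out = rarefy(sub, full, seed=3)
        assert (out.counts == sub.counts).all().all()

    def test_all_sample_sums_equal_depth(self, small_table):
        for seed in (0, 1, 99):
            out = rarefy(small_table, 10, seed)
            assert (out.sample_totals() == 10).all()

    def test_zero_category_never_drawn(self, small_table):
        import pandas as pd

        counts = pd.DataFrame([[1000, 0]], index=["oakA"], columns=["a", "b"])
        t = small_table.with_counts(counts.reindex(["oakA"]))
        out = rarefy(t, 10, seed=5)
        assert out.counts.loc["oakA", "a"] == 10
        assert out.counts.loc["oakA", "b"] == 0

    def test_depth_above_total_lists_offenders(self, small_table):
        with pytest.raises(ValidationError, match="oak"):
            rarefy(small_table, 10_000, seed=0)

    def test_expected_counts_match_hypergeometric_mean(self):
        # mean rarefied count of OTU j ~ depth * count_j / total over many draws
        import pandas as pd

        counts = pd.DataFrame([[60, 30, 10]], index=["s"], columns=list("abc"))
        meta = pd.DataFrame(
            {"resource": ["X"], "compartment": ["sapwood"], "replicate": ["p1"]},
            index=["s"],
        )
        from woodweb import OtuTable

        t = OtuTable(counts, meta)
        draws = np.array(
            [rarefy(t, 50, seed).counts.to_numpy()[0] for seed in range(1000)]
        )
        expect = 50 * np.array([60, 30, 10]) / 100
        # hypergeometric sd per draw is < 3.5; 1000 draws -> se < 0.11
        assert np.abs(draws.mean(axis=0) - expect).max() < 0.4


class TestEnsemble:
    def test_versions_distinct_but_reproducible(self, small_table):
        cfg = RarefactionConfig(depth=10, n_versions=3, base_seed=5)
        a = [t.counts for t in rarefaction_ensemble(small_table, cfg)]
        b = [t.counts for t in rarefaction_ensemble(small_table, cfg)]
        assert len(a) == 3
        for x, y in zip(a, b):
            assert (x == y).all().all()
        assert not (a[0] == a[1]).all().all()

    def test_single_version_equals_direct_rarefy(self, small_table):
        cfg = RarefactionConfig(depth=12, n_versions=1, base_seed=9)
        (only,) = list(rarefaction_ensemble(small_table, cfg))
        direct = rarefy(small_table, 12, 9)
        assert (only.counts == direct.counts).all().all()

    def test_depth_at_min_total_is_valid(self, small_table):
        depth = int(small_table.sample_totals().min())
        cfg = RarefactionConfig(depth=depth, n_versions=2, base_seed=0)
        for t in rarefaction_ensemble(small_table, cfg):
            assert (t.sample_totals() == depth).all()


class TestCoverageRatio:
    def test_full_depth_fully_observed_community_is_one(self, small_table):
        # all OTU totals > 10: ACE reduces to observed richness, and a
        # full-depth rarefaction observes everything
        t = small_table.with_counts(small_table.counts * 3)
        depth = int(t.sample_totals().min())
        assert coverage_ratio(t, depth, seed=0) == pytest.approx(1.0)

    def test_nondecreasing_in_depth(self):
        cfg = SyntheticConfig(n_otus=500, abundance_sigma=2.0, depth=300, seed=3)
        table, _ = generate_dataset(cfg)
        ratios = [
            np.mean([coverage_ratio(table, d, seed=s) for s in range(3)])
            for d in (5, 20, 80)
        ]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_calibrated_community_reports_29_percent(self):
        # community tuned (pilot calibration) so shallow rarefaction covers
        # ~29% of the ACE-estimated richness
        cfg = SyntheticConfig(n_otus=2000, abundance_sigma=2.0, depth=500, seed=42)
        table, _ = generate_dataset(cfg)
        ratio = np.mean([coverage_ratio(table, 36, seed=s) for s in range(3)])
        assert ratio == pytest.approx(0.29, abs=0.04)
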