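"""Cross-validation protocol, rank-test oracles, and reporting."""

import numpy as np
import pytest
import scipy.stats

from mtsimg import (
    Condition,
    ExperimentResult,
    SynthConfig,
    TrainConfig,
    compare_architectures,
    compare_encoders,
    compare_orders,
    dunn_test,
    encode_dataset,
    generate_synthetic,
    kfold_split,
    report,
    run_condition,
)
from mtsimg.errors import InvalidArgumentError, InvalidInputError


class TestKfold:
    def test_exact_division(self):
        y = np.tile([0, 1], 5)
        folds = kfold_split(y, 5, seed=3)
        assert [len(f) for f in folds] == [2] * 5
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_remainder_distribution(self):
        y = np.array([0, 1] * 5 + [0])
        folds = kfold_split(y, 5, seed=3)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 3]
        assert sorted(np.concatenate(folds)) == list(range(11))

    def test_stratification(self):
        y = np.tile([0, 1], 10)
        for fold in kfold_split(y, 5, seed=0):
            assert set(y[fold]) == {0, 1}

    def test_determinism(self):
        y = np.tile([0, 1], 8)
        a = kfold_split(y, 4, seed=9)
        b = kfold_split(y, 4, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kfold_split([0, 1, 0], 4, seed=0)


def make_result(errors, encoder="GASF", order=None):
    cond = Condition(encoder, image_size=8, order=order)
    return ExperimentResult(cond, np.asarray(errors, dtype=float), base_seed=0)


class TestDunn:
    def test_identical_samples_give_unit_p(self):
        out = dunn_test([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        np.testing.assert_allclose(out["p"], 1.0)
        np.testing.assert_allclose(np.diag(out["p"]), 1.0)

    def test_matches_independent_rank_computation(self):
        # fixed 3-group toy samples; oracle computed from first principles
        groups = [[0.0, 0.0, 0.0, 0.0], [10.0, 10.0, 10.0, 10.0],
                  [20.0, 20.0, 20.0, 20.0]]
        pooled = np.concatenate(groups)
        ranks = scipy.stats.rankdata(pooled)
        n_tot = pooled.size
        mean_r = [ranks[4 * i : 4 * (i + 1)].mean() for i in range(3)]
        _, t = np.unique(pooled, return_counts=True)
        var = n_tot * (n_tot + 1) / 12 - (t**3 - t).sum() / (12 * (n_tot - 1))
        z02 = (mean_r[0] - mean_r[2]) / np.sqrt(var * (1 / 4 + 1 / 4))
        p02 = 2 * scipy.stats.norm.sf(abs(z02))
        out = dunn_test(groups)
        np.testing.assert_allclose(out["z"][0, 2], z02, atol=1e-12)
        np.testing.assert_allclose(out["p"][0, 2], p02, atol=1e-12)
        # extreme pair has the smallest p; rank sums strictly ordered
        assert out["p"][0, 2] <= out["p"][0, 1]
        assert out["p"][0, 2] <= out["p"][1, 2]
        assert np.all(np.diff(out["mean_ranks"]) > 0)

    def test_holm_adjustment_never_smaller(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc, 1, 8) for loc in (0, 0.5, 2.0)]
        out = dunn_test(groups)
        iu = np.triu_indices(3, 1)
        assert np.all(out["p_holm"][iu] >= out["p"][iu] - 1e-15)

    def test_compare_encoders_wrapper(self):
        results = [
            make_result([[1, 2, 3, 4, 5]], encoder=e)
            for e in ("GASF", "GADF", "MTF")
        ]
        out = compare_encoders(results)
        assert out["encoders"] == ["GASF", "GADF", "MTF"]
        np.testing.assert_allclose(out["p"], 1.0)


class TestWilcoxonOrders:
    def test_self_pair_is_degenerate(self):
        r = make_result([[1.0, 2.0, 3.0, 4.0, 5.0]], order=(0, 1))
        out = compare_orders([r, r])
        assert out["degenerate"][0, 1]
        assert out["p"][0, 1] == 1.0

    def test_constant_shift_matches_hand_ranks(self):
        a = make_result([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]], order=(0, 1))
        b = make_result([[11.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0]],
                        order=(1, 0))
        out = compare_orders([a, b])
        # all 8 differences share one sign -> minimal statistic, exact p = 2/2^8 * 2
        stat = scipy.stats.wilcoxon(
            a.error_rates.ravel(), b.error_rates.ravel(), zero_method="wilcox"
        )
        assert out["p"][0, 1] == pytest.approx(float(stat.pvalue))
        assert out["p"][0, 1] < 0.05

    def test_unpaired_shapes_rejected(self):
        a = make_result([[1.0, 2.0]])
        b = make_result([[1.0, 2.0, 3.0]])
        with pytest.raises(InvalidInputError):
            compare_orders([a, b])

    def test_null_calibration_on_simulated_errors(self):
        # paired samples from one error distribution: ~5% rejections at 5%
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = make_result(rng.normal(10, 2, (4, 5)), order=(0, 1))
            b = make_result(rng.normal(10, 2, (4, 5)), order=(1, 0))
            out = compare_orders([a, b])
            rejections += out["p"][0, 1] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestKruskal:
    def test_identical_groups(self):
        out = compare_architectures([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["H"] == 0.0 and out["p"] == 1.0
        out3 = compare_architectures([5.0, 5.0], [5.0, 5.0], [5.0, 5.0])
        assert out3["p"] == 1.0

    def test_separated_groups_significant(self):
        out = compare_architectures([1.0, 2.0, 3.0], [100.0, 101.0, 102.0])
        assert out["p"] < 0.05

    def test_matches_closed_form_rank_formula(self):
        g1, g2, g3 = [1.0, 5.0, 8.0], [2.0, 6.0, 9.0], [3.0, 7.0, 30.0]
        pooled = np.array(g1 + g2 + g3)
        ranks = scipy.stats.rankdata(pooled)
        n_tot = pooled.size
        h = 12 / (n_tot * (n_tot + 1)) * sum(
            3 * (ranks[3 * i : 3 * (i + 1)].mean() - (n_tot + 1) / 2) ** 2
            for i in range(3)
        )
        out = compare_architectures(g1, g2, g3)
        assert out["H"] == pytest.approx(h, abs=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_architectures([1.0], [2.0])


@pytest.fixture(scope="module")
def mini_dataset():
    return generate_synthetic(
        SynthConfig(n_instances=16, m=2, length_range=(30, 40), seed=21)
    )


class TestRunCondition:
    def test_bookkeeping_and_determinism(self, mini_dataset):
        cond = Condition("GASF", image_size=8)
        cfg = TrainConfig(max_epochs=3, patience=3, batch_size=4,
                          validation_fraction=0.25)
        res1 = run_condition(mini_dataset, cond, cfg, repeats=1, folds=2, base_seed=5)
        assert res1.error_rates.shape == (1, 2)
        assert np.all((0 <= res1.error_rates) & (res1.error_rates <= 100))
        assert res1.mean_error == pytest.approx(res1.repeat_means.mean())
        res2 = run_condition(mini_dataset, cond, cfg, repeats=1, folds=2, base_seed=5)
        np.testing.assert_array_equal(res1.error_rates, res2.error_rates)

    def test_encoded_batch_geometry(self, mini_dataset):
        imgs = encode_dataset(mini_dataset, "GADF", 8, 4)
        assert imgs.shape == (16, 3, 16, 8)
        assert imgs.min() >= 0 and imgs.max() <= 1


class TestReport:
    def test_row_count_and_reproducibility(self, tmp_path):
        rng = np.random.default_rng(0)
        results = [
            make_result(rng.uniform(0, 10, (20, 5)), encoder=e)
            for e in ("GASF", "GADF", "MTF")
        ]
        comp = {"dunn_encoders": compare_encoders(results)}
        paths = report(results, comp, tmp_path / "out")
        lines = open(paths["csv"]).read().splitlines()
        assert len(lines) == 1 + 3 * 20 * 5
        first = open(paths["csv"], "rb").read()
        report(results, comp, tmp_path / "out")
        assert open(paths["csv"], "rb").read() == first
        summary = open(paths["summary"]).read()
        assert "GASF" in summary and "dunn_encoders" in summary

    def test_empty_results_header_only(self, tmp_path):
        paths = report([], None, tmp_path / "out")
        lines = open(paths["csv"]).read().splitlines()
        assert len(lines) == 1
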