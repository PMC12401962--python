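"""Splits, the training loop, evaluation metrics, CV, and power analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lcen
from lcen.data import FeatureMatrix, standardize_features
from lcen.decoder import DecoderSpec
from lcen.encoder import EncoderSpec
from lcen.model import ModelConfig
from lcen.training import evaluate, paired_ttest_power, split_dataset, train


def small_config(hierarchy, **kw):
    defaults = dict(
        encoder=EncoderSpec(
            layer_widths=(16, 8), dropout_rate=0.0, dropout_after=(), batch_norm=False
        ),
        decoder=DecoderSpec(hidden_widths=(8, 8)),
        hierarchy=hierarchy,
        lambdas={"kl": 0.001},
        max_epochs=3,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestSplitDataset:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (3000, (2100, 450, 450)),
            (10300, (7210, 1545, 1545)),
            (10, (7, 2, 1)),
        ],
    )
    def test_split_sizes_largest_remainder(self, n, expected):
        parts = split_dataset(n, (0.7, 0.15, 0.15), seed=0)
        assert tuple(len(p) for p in parts) == expected

    def test_disjoint_and_exhaustive(self):
        parts = split_dataset(101, seed=5)
        allidx = np.concatenate(parts)
        assert len(allidx) == 101
        assert len(np.unique(allidx)) == 101

    def test_seeded_reproducibility(self):
        a = split_dataset(50, seed=9)
        b = split_dataset(50, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_stratified_preserves_sizes_and_balance(self):
        labels = np.array([0] * 80 + [1] * 20)
        parts = split_dataset(100, seed=1, stratify=labels)
        assert tuple(len(p) for p in parts) == (70, 15, 15)
        # each split keeps roughly the 80/20 class ratio
        for p in parts:
            frac = labels[p].mean()
            assert 0.05 <= frac <= 0.4

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2)
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.4, 0.2))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=3, max_value=5000), st.integers(min_value=0, max_value=99))
    def test_partition_property(self, n, seed):
        parts = split_dataset(n, seed=seed)
        assert sum(len(p) for p in parts) == n
        assert len(set(np.concatenate(parts).tolist())) == n


class TestTrainLoop:
    def test_history_rows_and_columns(self, small_cohort):
        f, p, g, t = small_cohort
        fs = FeatureMatrix(standardize_features(f.values), f.modality_blocks,
                           f.subject_ids, f.column_names)
        cfg = small_config(t.level_map)
        params, hist, _ = train(fs, p, graph=g, config=cfg, seed=0)
        assert len(hist) == 3
        for col in ("train_total", "val_total", "train_reconstruction", "val_kl",
                    "alpha_1", "alpha_2", "alpha_3"):
            assert col in hist.columns

    def test_zero_learning_rate_leaves_parameters_unchanged(self, small_cohort):
        f, p, g, t = small_cohort
        fs = FeatureMatrix(standardize_features(f.values), f.modality_blocks,
                           f.subject_ids, f.column_names)
        cfg = small_config(t.level_map, lr=0.0, max_epochs=1)
        rng = np.random.default_rng(0)
        init = lcen.init_model(rng, fs.d_x, p.d_y, cfg)
        import copy

        before = copy.deepcopy(init)
        params, _, _ = train(fs, p, graph=g, config=cfg, seed=0, init_params=init)
        assert np.array_equal(params["decoder"]["out"]["W"], before["decoder"]["out"]["W"])
        assert np.array_equal(params["encoder"]["mu"]["W"], before["encoder"]["mu"]["W"])

    def test_logged_components_sum_to_total(self, small_cohort):
        f, p, g, t = small_cohort
        fs = FeatureMatrix(standardize_features(f.values), f.modality_blocks,
                           f.subject_ids, f.column_names)
        cfg = small_config(t.level_map, max_epochs=2)
        _, hist, _ = train(fs, p, graph=g, config=cfg, seed=0)
        comp_cols = [c for c in hist.columns if c.startswith("val_") and c != "val_total"]
        sums = hist[comp_cols].sum(axis=1)
        assert np.allclose(sums, hist["val_total"], atol=1e-9)

    def test_noiseless_linear_cohort_reaches_low_rmse(self):
        f, p, g, t = lcen.simulate_cohort(n=400, noise_sd_y=0.0, noise_sd_x=0.0, seed=2)
        fs = FeatureMatrix(standardize_features(f.values), f.modality_blocks,
                           f.subject_ids, f.column_names)
        cfg = ModelConfig(
            encoder=EncoderSpec(layer_widths=(5,), dropout_rate=0.0, dropout_after=(),
                                batch_norm=False),
            decoder=DecoderSpec(hidden_widths=(5, 8), residual_block=False),
            use_attention=False, deterministic_latent=True,
            lambdas={"kl": 0.0}, lr=0.01, max_epochs=200, patience=200,
        )
        params, hist, bn = train(fs, p, graph=g, config=cfg, seed=0)
        idx_val = split_dataset(400, seed=0)[1]
        m = evaluate(params, fs, p, cfg, graph=g, split=idx_val, bn_state=bn)
        # oracle: affine least squares on the noiseless cohort achieves ~0
        X1 = np.column_stack([fs.values, np.ones(len(fs.values))])
        coef, *_ = np.linalg.lstsq(X1, p.values, rcond=None)
        lsq_rmse = np.sqrt(np.mean((X1 @ coef - p.values) ** 2))
        assert lsq_rmse < 1e-6
        assert m["aggregate"]["rmse_pooled"] < 0.05


class TestEvaluate:
    def _constant_predictor(self, y):
        cfg = ModelConfig(
            encoder=EncoderSpec(layer_widths=(2,), dropout_rate=0, dropout_after=(),
                                batch_norm=False),
            decoder=DecoderSpec(hidden_widths=(2, 4), residual_block=False),
            use_attention=False, deterministic_latent=True,
        )
        return cfg

    def test_perfect_continuous_predictions(self, rng):
        # craft a model that is exactly the identity on 1 latent = phenotype
        from lcen.model import init_model, predict

        cfg = self._constant_predictor(None)
        x = rng.normal(size=(10, 2))
        params = init_model(np.random.default_rng(0), 2, 2, cfg)
        params["encoder"]["mu"]["W"] = np.eye(2)
        params["encoder"]["mu"]["b"][:] = 0
        params["decoder"]["pre"]["W"] = np.eye(2)
        params["decoder"]["pre"]["b"][:] = 0
        params["decoder"]["out"]["W"] = np.eye(2)
        params["decoder"]["out"]["b"][:] = 0
        from lcen.data import PhenotypeMatrix

        y = PhenotypeMatrix(values=x.copy())
        m = evaluate(params, x, y, cfg, graph=np.zeros((2, 2)))
        assert m["aggregate"]["mae"] == pytest.approx(0.0, abs=1e-12)
        assert m["aggregate"]["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_auroc_perfect_ranking_and_ties(self):
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert roc_auc_score([1, 0, 1, 0], [0.6, 0.6, 0.6, 0.6]) == 0.5

    def test_auroc_equals_rank_statistic(self, rng):
        from scipy.stats import rankdata
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            y = rng.integers(0, 2, size=40)
            if y.min() == y.max():
                continue
            s = rng.normal(size=40)
            n1, n0 = y.sum(), (1 - y).sum()
            ranks = rankdata(s)
            u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
            assert roc_auc_score(y, s) == pytest.approx(u / (n0 * n1), abs=1e-12)

    def test_single_class_auroc_missing_with_warning(self, rng):
        from lcen.data import PhenotypeMatrix
        from lcen.model import init_model

        cfg = self._constant_predictor(None)
        x = rng.normal(size=(8, 2))
        params = init_model(np.random.default_rng(0), 2, 1, cfg)
        y = PhenotypeMatrix(values=np.ones((8, 1)), column_kind=["binary"])
        with pytest.warns(UserWarning, match="single-class"):
            m = evaluate(params, x, y, cfg, graph=np.zeros((1, 1)))
        assert m["per_column"]["y0"]["auroc"] is None


class TestCrossvalidate:
    def test_folds_disjoint_exhaustive_and_reproducible(self, small_cohort):
        f, p, g, t = small_cohort
        fs = FeatureMatrix(standardize_features(f.values), f.modality_blocks,
                           f.subject_ids, f.column_names)
        cfg = small_config(t.level_map, max_epochs=1)
        res = lcen.crossvalidate(fs, p, graph=g, config=cfg, k=5, seed=0)
        assert len(res["folds"]) == 5
        res2 = lcen.crossvalidate(fs, p, graph=g, config=cfg, k=5, seed=0)
        assert res["mean"] == res2["mean"]
        assert set(res["sd"]) == set(res["mean"])

    def test_k_larger_than_n_rejected(self, small_cohort):
        f, p, g, t = small_cohort
        cfg = small_config(t.level_map)
        with pytest.raises(ValueError):
            lcen.crossvalidate(f, p, graph=g, config=cfg, k=10**6, seed=0)


class TestPowerAnalysis:
    def test_medium_effect_standard_design_returns_34(self):
        assert paired_ttest_power(0.5, 0.05, 0.80, two_tailed=True) == 34

    def test_huge_effect_saturates_at_two(self):
        assert paired_ttest_power(100.0) == 2

    def test_matches_statsmodels_solver(self):
        from statsmodels.stats.power import TTestPower

        for d, power in [(0.3, 0.8), (0.5, 0.9), (0.8, 0.8)]:
            sm_n = int(np.ceil(TTestPower().solve_power(effect_size=d, alpha=0.05,
                                                        power=power, alternative="two-sided")))
            assert abs(paired_ttest_power(d, 0.05, power) - sm_n) <= 1

    def test_matches_monte_carlo_simulation(self):
        # simulate paired differences with effect d: power at n and n-1
        d, alpha, target = 0.5, 0.05, 0.8
        n_star = paired_ttest_power(d, alpha, target)
        rng = np.random.default_rng(0)

        def mc_power(n, reps=10_000):
            x = rng.normal(loc=d, size=(reps, n))
            tstat = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
            from scipy.stats import t as tdist

            crit = tdist.ppf(1 - alpha / 2, n - 1)
            return np.mean(np.abs(tstat) > crit)

        assert mc_power(n_star) >= target - 0.02
        assert mc_power(n_star - 2) < target

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest_power(-1.0)
        with pytest.raises(ValueError):
            paired_ttest_power(0.5, alpha=1.5)
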