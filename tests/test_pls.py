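"""NIPALS PLS1, grouped validation and the metric suite."""

import numpy as np
import pandas as pd
import pytest

from cocoahsi.errors import DegenerateInputError, RankError
from cocoahsi.pls import (as_is_to_dmb, cross_validate, evaluate, fit_pls,
                          paired_ttest, select_lv, split_holdout)
from cocoahsi.spectra import SpectraTable


def random_table(rng, n_beans=20, sides=2, p=30):
    X = rng.normal(size=(n_beans * sides, p))
    meta = pd.DataFrame({
        "bean_id": np.repeat(np.arange(1, n_beans + 1), sides),
        "batch": 1, "side": np.tile(np.arange(1, sides + 1), n_beans),
        "fat_as_is": rng.uniform(45, 65, n_beans * sides),
        "fat_dmb": 55.0, "moisture": 6.5,
    })
    return SpectraTable(X, np.linspace(1000, 1300, p), meta)


class TestSplit:
    def test_printed_study_counts(self, shelled_table):
        cal, val = split_holdout(shelled_table, 0.7, seed=0)
        assert len(cal) == 238
        assert len(val) == 102

    def test_beans_never_straddle(self, shelled_table):
        cal, val = split_holdout(shelled_table, 0.7, seed=5)
        cal_beans = set(shelled_table.bean_ids[cal])
        val_beans = set(shelled_table.bean_ids[val])
        assert not (cal_beans & val_beans)

    def test_same_seed_same_split(self, shelled_table):
        assert np.array_equal(split_holdout(shelled_table, 0.7, 3)[0],
                              split_holdout(shelled_table, 0.7, 3)[0])

    def test_round_half_up(self, rng):
        # 5 beans at 0.7 -> 3.5 -> 4 beans in calibration
        table = random_table(rng, n_beans=5)
        cal, _ = split_holdout(table, 0.7, seed=0)
        assert np.unique(table.bean_ids[cal]).size == 4

    def test_invalid_ratio(self, shelled_table):
        with pytest.raises(ValueError):
            split_holdout(shelled_table, 1.2)


class TestFitPLS:
    def test_single_informative_band(self, rng):
        # only band 7 varies, so one latent variable suffices exactly
        X = np.full((25, 12), 0.5)
        X[:, 7] = rng.normal(size=25)
        y = 2.0 * X[:, 7]
        model = fit_pls(X, y, 1)
        assert evaluate(y, model.predict(X))["rmse"] < 1e-8
        assert np.argmax(np.abs(model.beta)) == 7

    def test_matches_independent_pls_oracle(self, rng):
        """NIPALS vs the SVD-based reference implementation, 50 problems."""
        from sklearn.cross_decomposition import PLSRegression
        for _ in range(50):
            X = rng.normal(size=(20, 50))
            y = X @ rng.normal(size=50) * 0.2 + rng.normal(size=20)
            model = fit_pls(X, y, 5)
            oracle = PLSRegression(n_components=5, scale=False).fit(X, y)
            assert np.abs(model.predict(X) - oracle.predict(X).ravel()).max() < 1e-8

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(30, 10))
        y = X @ rng.normal(size=10) + 3.0
        model = fit_pls(X, y, 10)
        G = np.column_stack([np.ones(30), X])
        coef, *_ = np.linalg.lstsq(G, y, rcond=None)
        assert np.abs(model.predict(X) - G @ coef).max() < 1e-8

    def test_beta_equals_score_recursion(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        model = fit_pls(X, y, 6)
        Xnew = rng.normal(size=(10, 40))
        assert np.abs(model.predict(Xnew) - model.predict_scores(Xnew)).max() < 1e-8

    def test_rmsec_nonincreasing_in_lv(self, rng):
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        rmses = [evaluate(y, fit_pls(X, y, k).predict(X))["rmse"]
                 for k in range(1, 11)]
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_rank_error_reports_components(self):
        X = np.outer(np.arange(10.0), np.ones(5))  # rank 1
        y = np.arange(10.0)
        with pytest.raises(RankError) as err:
            fit_pls(X, y, 3)
        assert err.value.n_extracted >= 1
        model = fit_pls(X, y, 3, strict=False)
        assert model.n_lv < 3

    def test_yaml_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        model = fit_pls(X, y, 4, wavelengths=np.linspace(1000, 1140, 15))
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        from cocoahsi.pls import PLSModel
        back = PLSModel.from_yaml(path)
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)


class TestCrossValidation:
    def test_noiseless_single_band(self, rng):
        table = random_table(rng, n_beans=20)
        X = np.zeros_like(table.X)
        X[:, 4] = table.X[:, 4]
        y = 3.0 * X[:, 4]
        rmsecv, _ = cross_validate(X, y, table.bean_ids, max_lv=1, folds=5)
        assert rmsecv[0] < 1e-8

    def test_rmsec_below_rmsecv(self, rng):
        """Training error never exceeds out-of-fold error (50 random sets)."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            table = random_table(r, n_beans=15, p=10)
            y = table.X @ r.normal(size=10) + r.normal(size=30) * 0.5
            rmsecv, _ = cross_validate(table.X, y, table.bean_ids,
                                       max_lv=4, folds=5, seed=seed)
            for lv in range(1, 5):
                model = fit_pls(table.X, y, lv)
                rmsec = evaluate(y, model.predict(table.X))["rmse"]
                assert rmsec <= rmsecv[lv - 1] + 1e-12

    def test_leave_one_bean_out(self, rng):
        table = random_table(rng, n_beans=8)
        y = table.y("as_is")
        rmsecv, _ = cross_validate(table.X, y, table.bean_ids, max_lv=2, folds=8)
        assert np.isfinite(rmsecv).all()

    def test_groups_respected(self, rng):
        from cocoahsi.pls import group_kfold
        ids = np.repeat(np.arange(10), 2)
        for train, test in group_kfold(ids, 5, seed=1):
            assert not (set(ids[train]) & set(ids[test]))

    def test_max_lv_too_large(self, rng):
        table = random_table(rng, n_beans=6, p=40)
        with pytest.raises(ValueError):
            cross_validate(table.X, table.y("as_is"), table.bean_ids,
                           max_lv=30, folds=3)


class TestSelectLV:
    def test_parsimony_rule_hand_case(self):
        assert select_lv([3.0, 2.0, 1.99, 1.98], parsimony=0.02) == 2

    def test_strictly_decreasing_zero_parsimony(self):
        assert select_lv([5.0, 4.0, 3.0, 2.0], parsimony=0.0) == 4

    def test_single_element(self):
        assert select_lv([1.7]) == 1


class TestMetrics:
    def test_perfect_prediction(self):
        out = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["r2"] == pytest.approx(1.0)
        assert out["rmse"] == 0.0
        assert out["rpd"] == np.inf

    def test_hand_computed_case(self):
        """y=[50,55,60], yhat=[51,54,61]: SSE=3, SST=50, sd=5, RMSE=1."""
        out = evaluate([50.0, 55.0, 60.0], [51.0, 54.0, 61.0])
        assert out["rmse"] == pytest.approx(1.0)
        assert out["rpd"] == pytest.approx(5.0)
        assert out["r2"] == pytest.approx(1 - 3 / 50)

    def test_rpd_definition(self, rng):
        y = rng.normal(50, 4, 200)
        yhat = y + rng.normal(0, 2, 200)
        out = evaluate(y, yhat)
        assert out["rpd"] * out["rmse"] == pytest.approx(np.std(y, ddof=1),
                                                         abs=1e-9)


class TestPairedTTest:
    def test_symmetric_differences_not_significant(self):
        """Null-centred differences rarely reject at the 5% level."""
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.normal(50, 3, 100)
            yhat = y + r.normal(0, 1, 100)
            if paired_ttest(y, yhat)["p"] < 0.05:
                rejections += 1
        assert rejections <= 3

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(DegenerateInputError):
            paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_ci_half_width_scales_inverse_sqrt_n(self, rng):
        d = rng.normal(0, 1, 50)
        y = np.zeros(50)
        small = paired_ttest(y[:10], d[:10])
        # analytic check on the formula itself
        from scipy import stats
        expect = stats.t.ppf(0.975, 9) * d[:10].std(ddof=1) / np.sqrt(10)
        assert small["ci_half_width"] == pytest.approx(expect)


class TestBasisConversion:
    def test_zero_moisture_identity(self):
        assert as_is_to_dmb(54.0, 0.0) == 54.0

    def test_hand_value(self):
        assert as_is_to_dmb(54.0, 7.0) == pytest.approx(5400 / 93)

    def test_monotone_in_moisture(self):
        vals = [float(as_is_to_dmb(54.0, m)) for m in (0, 5, 10, 20)]
        assert vals == sorted(vals)

    def test_invalid_moisture(self):
        with pytest.raises(ValueError):
            as_is_to_dmb(54.0, 100.0)
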