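"""Accuracy-weighted ensembling and calibration."""

import numpy as np
import pandas as pd
import pytest

from sdmens import AccuracyWeightedEnsemble, substitute_and_average


class TestSubstituteAndAverage:
    def test_two_model_substitution(self):
        # one high-precision positive call (PPV 0.85) and one high-NPV
        # negative call (1-0.89 = 0.11) average to 0.48
        calls = pd.DataFrame({"chr": [1.0], "mon": [0.0]})
        raw = substitute_and_average(calls, {"chr": (0.85, 0.77), "mon": (0.63, 0.89)})
        assert raw.iloc[0] == pytest.approx(0.48)

    def test_unanimous_perfect_precision(self):
        calls = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]})
        raw = substitute_and_average(
            calls, {"a": (1.0, 0.5), "b": (1.0, 0.6), "c": (1.0, 0.7)}
        )
        assert raw.iloc[0] == pytest.approx(1.0)

    def test_single_model_negative_call(self):
        raw = substitute_and_average(pd.DataFrame({"m": [0.0]}), {"m": (0.5, 0.92)})
        assert raw.iloc[0] == pytest.approx(0.08)

    def test_undefined_weight_excluded_with_warning(self):
        calls = pd.DataFrame({"good": [1.0, 0.0], "bad": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="undefined PPV or NPV"):
            raw = substitute_and_average(
                calls, {"good": (0.8, 0.9), "bad": (None, 0.9)}
            )
        assert raw.tolist() == pytest.approx([0.8, 0.1])

    def test_missing_calls_average_over_available(self):
        calls = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, np.nan]})
        raw = substitute_and_average(calls, {"a": (0.7, 0.8), "b": (0.6, 0.9)})
        assert raw.iloc[0] == pytest.approx(0.7)
        assert np.isnan(raw.iloc[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        calls = pd.DataFrame(rng.integers(0, 2, (50, 4)).astype(float),
                             columns=list("abcd"))
        w = {m: (rng.uniform(0.3, 1), rng.uniform(0.3, 1)) for m in "abcd"}
        raw = substitute_and_average(calls, w)
        lo = min(1 - npv for _, npv in w.values())
        hi = max(ppv for ppv, _ in w.values())
        assert (raw >= lo - 1e-12).all() and (raw <= hi + 1e-12).all()
        perm = calls[["c", "a", "d", "b"]]
        assert np.allclose(substitute_and_average(perm, w).to_numpy(), raw.to_numpy())


def _simulate_calls(rng, occupancy, specs):
    cols = {}
    for j, (se, sp) in enumerate(specs):
        u = rng.random(occupancy.size)
        cols[f"m{j}"] = np.where(occupancy == 1, u < se, u < 1 - sp).astype(float)
    return pd.DataFrame(cols)


class TestAccuracyWeightedEnsemble:
    def test_weights_match_confusion_counts(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 400)
        X = _simulate_calls(rng, y, [(0.8, 0.85), (0.7, 0.9)])
        ens = AccuracyWeightedEnsemble().fit(X, y)
        for j, name in enumerate(X.columns):
            c = X[name].to_numpy()
            tp = np.sum((c == 1) & (y == 1))
            fp = np.sum((c == 1) & (y == 0))
            tn = np.sum((c == 0) & (y == 0))
            fn = np.sum((c == 0) & (y == 1))
            assert ens.ppv_[j] == pytest.approx(tp / (tp + fp))
            assert ens.npv_[j] == pytest.approx(tn / (tn + fn))

    def test_calibration_recovers_identity(self):
        # when the raw score IS the true probability, the fitted map should
        # be close to the identity away from the boundaries
        rng = np.random.default_rng(42)
        n = 3000
        p_true = rng.uniform(0.01, 0.99, n)
        y = (rng.random(n) < p_true).astype(int)
        ens = AccuracyWeightedEnsemble()
        ens.weights_ = {"m": (1.0, 1.0)}
        cal = ens._fit_calibration(p_true, y)
        grid = np.linspace(0.05, 0.95, 19)
        fitted = cal.predict(grid)
        assert np.max(np.abs(fitted - grid)) < 0.05

    def test_near_separable_predictions_clamped(self):
        y = np.array([0] * 50 + [1] * 50)
        X = pd.DataFrame({"m": y.astype(float)})
        ens = AccuracyWeightedEnsemble().fit(X, y)
        p = ens.predict_proba(X)[:, 1]
        assert np.all(p[y == 1] >= 0.99)
        assert np.all(p[y == 0] <= 0.01)
        assert np.all((p >= 0) & (p <= 1))

    def test_constant_raw_score_falls_back_to_class_rate(self):
        # two complementary models whose calls carry no signal about y make
        # every county's substituted average identical
        z = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        y = np.array([1, 0, 0, 0, 1, 0, 0, 0])
        X = pd.DataFrame({"m1": z, "m2": 1 - z})
        with pytest.warns(UserWarning, match="constant raw score"):
            ens = AccuracyWeightedEnsemble().fit(X, y)
        p = ens.predict_proba(X)[:, 1]
        assert p == pytest.approx(np.full(8, y.mean()))

    def test_all_models_undefined_is_error(self):
        y = np.array([1, 0, 0, 1])
        X = pd.DataFrame({"m": np.ones(4)})  # never calls absent: NPV undefined
        with pytest.raises(ValueError, match="defined PPV and NPV"):
            with pytest.warns(UserWarning, match="undefined PPV or NPV"):
                AccuracyWeightedEnsemble().fit(X, y)

    def test_calibration_in_the_large(self):
        rng = np.random.default_rng(3)
        cfg_specs = [(0.85, 0.8), (0.7, 0.9), (0.9, 0.7), (0.65, 0.95), (0.8, 0.85)]
        y = (rng.random(2000) < 0.3).astype(int)
        X = _simulate_calls(rng, y, cfg_specs)
        ens = AccuracyWeightedEnsemble().fit(X, y)
        p = ens.predict_proba(X)[:, 1]
        assert p.mean() == pytest.approx(y.mean(), abs=0.01)

    def test_out_of_range_raw_scores_predicted_at_boundary(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 300)
        X = _simulate_calls(rng, y, [(0.8, 0.8), (0.75, 0.85)])
        ens = AccuracyWeightedEnsemble().fit(X, y)
        lo = ens.calibration_.predict(np.array([ens.calibration_.x_min]))
        below = ens.calibration_.predict(np.array([ens.calibration_.x_min - 0.5]))
        assert below == pytest.approx(lo)

    def test_monotone_fit_reported_on_training_range(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 800)
        X = _simulate_calls(rng, y, [(0.85, 0.85), (0.7, 0.9), (0.9, 0.75)])
        ens = AccuracyWeightedEnsemble().fit(X, y)
        grid = np.linspace(ens.calibration_.x_min, ens.calibration_.x_max, 101)
        fitted = ens.calibration_.predict(grid)
        # the smooth should be monotone on the bulk of the training range
        assert np.sum(np.diff(fitted) < -1e-6) <= 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            AccuracyWeightedEnsemble().fit(pd.DataFrame({"m": [1.0, 0.0]}), [1, 1])

    def test_json_roundtrip_reproduces_predictions(self):
        rng = np.random.default_rng(19)
        y = rng.integers(0, 2, 500)
        X = _simulate_calls(rng, y, [(0.8, 0.85), (0.7, 0.9), (0.9, 0.8)])
        ens = AccuracyWeightedEnsemble().fit(X, y)
        clone = AccuracyWeightedEnsemble.from_json(ens.to_json())
        p1 = ens.predict_proba(X)[:, 1]
        p2 = clone.predict_proba(X)[:, 1]
        assert np.max(np.abs(p1 - p2)) < 1e-6

    def test_edf_within_plausible_spline_range(self):
        rng = np.random.default_rng(23)
        y = rng.integers(0, 2, 1000)
        X = _simulate_calls(rng, y, [(0.85, 0.8), (0.7, 0.9), (0.9, 0.7), (0.8, 0.85)])
        ens = AccuracyWeightedEnsemble().fit(X, y)
        assert 1.0 <= ens.edf_ <= 11.0

    def test_mgcv_cross_check(self, tmp_path):
        """Calibration curve agrees with an independent mgcv binomial GAM."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the independent calibration check")
        rng = np.random.default_rng(31)
        n = 1500
        x = rng.uniform(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(5 * x - 2.5)))).astype(int)
        ens = AccuracyWeightedEnsemble()
        cal = ens._fit_calibration(x, y)
        grid = np.linspace(0.05, 0.95, 19)
        mine = cal.predict(grid)

        df = pd.DataFrame({"x": x, "y": y})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'd <- read.csv("%s")\n'
            "library(mgcv)\n"
            "fit <- gam(y ~ s(x, k = 10), family = binomial, data = d)\n"
            "g <- data.frame(x = seq(0.05, 0.95, length.out = 19))\n"
            'write.csv(data.frame(p = predict(fit, g, type = "response")), "%s", row.names = FALSE)\n'
            % (tmp_path / "d.csv", tmp_path / "out.csv")
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv")["p"].to_numpy()
        assert np.max(np.abs(mine - theirs)) < 0.05
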