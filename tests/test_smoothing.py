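"""Penalized-spline trend models with lake random intercepts."""

import subprocess
import textwrap

import numpy as np
import pytest

from trophont.exceptions import ValidationError
from trophont.smoothing import SplineGAMM, fit_smooth, permutation_test_smooth


def _linear_dataset(seed, n=300, slope=0.002, noise=0.1):
    rng = np.random.default_rng(seed)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    lake = np.repeat(["A", "B", "C"], sizes)
    x = rng.uniform(100.0, 500.0, n)
    # centered offsets: the population-level line is identifiable only up
    # to the mean lake effect
    raw = rng.normal(0.0, 0.08, 3)
    offsets = dict(zip("ABC", raw - raw.mean()))
    y = 2.0 + slope * x + np.array([offsets[l] for l in lake])
    y = y + rng.normal(0.0, noise, n)
    return x, y, lake


class TestRecovery:
    def test_linear_truth_recovered(self):
        x, y, lake = _linear_dataset(seed=2)
        fit = fit_smooth(y, x, lake)
        truth = 2.0 + 0.002 * x
        rmse = np.sqrt(np.mean((fit.predict(x) - truth) ** 2))
        assert rmse < 0.05
        assert fit.edf_smooth_ <= 1.3

    def test_constant_response_flat(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 1.0, 60)
        fit = fit_smooth(np.full(60, 3.0), x)
        assert fit.edf_smooth_ == pytest.approx(1.0, abs=1e-3)
        assert fit.f_stat_ == pytest.approx(0.0, abs=1e-8)
        assert fit.p_value_ == pytest.approx(1.0, abs=1e-6)

    def test_infinite_smoothing_limit_is_linear(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.0, 1.0, 150)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.2, 150)
        fit = SplineGAMM(k=5, lam=(1e9, 1.0)).fit(x, y)
        # the heavily penalized curve must have (numerically) no curvature
        grid = np.linspace(x.min(), x.max(), 30)
        pred = fit.predict(grid)
        second = np.diff(pred, 2)
        assert np.max(np.abs(second)) < 1e-5
        assert fit.edf_smooth_ == pytest.approx(1.0, abs=1e-3)

    def test_row_order_invariance(self):
        x, y, lake = _linear_dataset(seed=8, n=120)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(x))
        f1 = fit_smooth(y, x, lake)
        f2 = fit_smooth(y[perm], x[perm], lake[perm])
        assert f2.edf_smooth_ == pytest.approx(f1.edf_smooth_, abs=1e-6)
        assert f2.f_stat_ == pytest.approx(f1.f_stat_, rel=1e-5)
        np.testing.assert_allclose(
            f2.predict(np.linspace(150, 450, 7)),
            f1.predict(np.linspace(150, 450, 7)),
            atol=1e-7,
        )


class TestValidation:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            fit_smooth(np.random.default_rng(0).normal(size=30), np.full(30, 5.0))

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            fit_smooth(np.arange(5.0), np.arange(5.0), k=3)

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            fit_smooth(np.arange(30.0), np.arange(30.0), method="wiggle")

    def test_prediction_outside_range_rejected(self):
        x, y, lake = _linear_dataset(seed=3, n=90)
        fit = fit_smooth(y, x, lake)
        with pytest.raises(ValidationError):
            fit.predict([x.max() + 50.0])


class TestInference:
    def test_strong_signal_significant(self):
        x, y, lake = _linear_dataset(seed=5, n=220)
        fit = fit_smooth(y, x, lake)
        assert fit.p_value_ < 1e-6

    def test_gcv_also_recovers_linear(self):
        x, y, lake = _linear_dataset(seed=6)
        fit = fit_smooth(y, x, lake, method="GCV")
        truth = 2.0 + 0.002 * x
        assert np.sqrt(np.mean((fit.predict(x) - truth) ** 2)) < 0.05

    def test_permutation_test_agrees_on_strong_signal(self):
        x, y, lake = _linear_dataset(seed=7, n=90)
        res = permutation_test_smooth(y, x, lake, n_perm=99, seed=0)
        assert res["p_permutation"] == pytest.approx(0.01, abs=1e-9)  # 1/(99+1)

    def test_permutation_test_null_not_significant(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 90)
        y = rng.normal(0, 1, 90)
        res = permutation_test_smooth(y, x, n_perm=99, seed=1)
        assert res["p_permutation"] > 0.05


class TestAgainstMgcv:
    def test_matches_mgcv_reml_fit(self, tmp_path):
        """Independent oracle: mgcv's cr-spline + random-effect GAMM."""
        rng = np.random.default_rng(3)
        n = 240
        lake = np.repeat([1, 2, 3], n // 3)
        x = rng.uniform(100, 500, n)
        y = (
            2.0
            + 0.002 * x
            + 0.3 * np.sin((x - 100) / 400 * np.pi)
            + np.repeat(rng.normal(0, 0.1, 3), n // 3)
            + rng.normal(0, 0.15, n)
        )
        fit = fit_smooth(y, x, lake)
        grid = np.linspace(x.min(), x.max(), 40)

        data_path = tmp_path / "d.csv"
        np.savetxt(
            data_path,
            np.column_stack([x, y, lake]),
            delimiter=",",
            header="x,y,lake",
            comments="",
        )
        out_path = tmp_path / "out.csv"
        script = textwrap.dedent(
            f"""
            d <- read.csv('{data_path}'); d$lake <- factor(d$lake)
            suppressMessages(library(mgcv))
            m <- gam(y ~ s(x, k=3, bs='cr') + s(lake, bs='re'),
                     data=d, method='REML')
            s <- summary(m)
            xg <- seq(min(d$x), max(d$x), length=40)
            pr <- predict(m, newdata=data.frame(x=xg,
                          lake=factor(1, levels=levels(d$lake))), type='terms')
            write.csv(data.frame(fit=coef(m)[1] + pr[, 's(x)'],
                                 edf=s$s.table[1,1]),
                      '{out_path}', row.names=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = np.loadtxt(out_path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(fit.predict(grid), ref[:, 0], atol=1e-4)
        assert fit.edf_smooth_ == pytest.approx(ref[0, 1], abs=1e-3)
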