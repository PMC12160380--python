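"""Regression of ln median diameter on cultivation parameters:
transforms, fitting, diagnostics, VIF, elimination, prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from pelletmorph import regress, synthgen

S6_B0_GRID = [
    (5e6, a, t, False) for a in (150.0, 250.0) for t in (0.0, 1.0, 5.0, 10.0)
]


def make_dataset(noise=0.0, seed=0, replicates=3, conditions=None, **kw):
    df = synthgen.gen_regression_dataset(
        conditions=conditions or S6_B0_GRID,
        replicates=replicates,
        noise_sd_ln=noise,
        seed=seed,
        **kw,
    )
    return regress.build_dataset(df)


class TestBuildDataset:
    def test_ln_transform_range_bounds(self):
        df = synthgen.gen_regression_dataset(
            conditions=[(5e6, 250.0, 0.0, False), (5e4, 150.0, 0.0, False)],
            replicates=1,
            noise_sd_ln=0.0,
        )
        ds = regress.build_dataset(df)
        assert round(ds.frame["ln_spore"].max(), 2) == 15.42
        assert round(ds.frame["ln_agitation"].max(), 2) == 5.52
        assert round(ds.frame["ln_spore"].min(), 2) == 10.82
        assert round(ds.frame["ln_agitation"].min(), 2) == 5.01

    def test_multimodal_and_small_rows_dropped(self):
        df = synthgen.gen_regression_dataset(
            conditions=S6_B0_GRID, replicates=1, noise_sd_ln=0.0
        )
        df.loc[0, "modality"] = "multimodal"
        df.loc[1, "n_pellets"] = 20
        ds = regress.build_dataset(df)
        assert ds.n == len(df) - 2

    def test_all_rows_excluded_raises(self):
        df = synthgen.gen_regression_dataset(conditions=S6_B0_GRID, replicates=1)
        df["n_pellets"] = 5
        with pytest.raises(ValueError):
            regress.build_dataset(df)


class TestFitOLS:
    def test_noiseless_recovery_to_machine_precision(self):
        ds = make_dataset(noise=0.0)
        model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)
        b0, ba, bt = synthgen.PREDICTION_COEFFICIENTS
        assert model.params["const"] == pytest.approx(b0, rel=1e-8)
        assert model.params["ln_agitation"] == pytest.approx(ba, rel=1e-8)
        assert model.params["talc"] == pytest.approx(bt, rel=1e-8)

    def test_constant_response_zero_slopes(self):
        ds = make_dataset(noise=0.0)
        ds.frame["ln_pd"] = 5.0
        model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)
        assert model.params["ln_agitation"] == pytest.approx(0.0, abs=1e-10)
        assert model.params["talc"] == pytest.approx(0.0, abs=1e-10)
        assert model.r2 == pytest.approx(0.0, abs=1e-12)

    def test_residuals_orthogonal_to_design(self):
        ds = make_dataset(noise=0.15, seed=3)
        model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)
        x = ds.frame[list(model.predictors)].to_numpy()
        scale = np.abs(x).max() * len(x)
        assert np.abs(x.T @ model.residuals).max() <= 1e-8 * scale
        assert abs(model.residuals.sum()) <= 1e-8 * scale

    def test_adjusted_r2_below_r2(self):
        ds = make_dataset(noise=0.2, seed=4)
        model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)
        assert model.adjusted_r2 < model.r2

    def test_rank_deficiency_names_columns(self):
        ds = make_dataset(noise=0.1, seed=5)
        ds.frame["dup"] = ds.frame["talc"]
        with pytest.raises(ValueError, match="talc"):
            regress.fit_ols(ds, predictors=("talc", "dup"))

    def test_ci_coverage_at_noise_0p1(self):
        # 95% CIs from 24-point fits should cover the generating
        # coefficients in at least 93% of repetitions
        b0, ba, bt = synthgen.PREDICTION_COEFFICIENTS
        truth = {"const": b0, "ln_agitation": ba, "talc": bt}
        n_rep = 500
        covered = {k: 0 for k in truth}
        for rep in range(n_rep):
            ds = make_dataset(noise=0.1, seed=10_000 + rep)
            model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)
            for k, v in truth.items():
                lo, hi = model.conf_int.loc[k]
                covered[k] += int(lo <= v <= hi)
        for k, c in covered.items():
            assert c / n_rep >= 0.93, k


class TestVIF:
    def test_orthogonal_centred_predictors_vif_exactly_one(self):
        x1 = np.tile([-1.0, 1.0], 8)
        x2 = np.repeat([-1.0, 1.0], 8)
        design = pd.DataFrame({"x1": x1, "x2": x2})
        out = regress.vif(design)
        assert out["x1"] == pytest.approx(1.0, abs=1e-12)
        assert out["x2"] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_predictor_infinite(self):
        x = np.arange(10.0)
        design = pd.DataFrame({"a": x, "b": x})
        with pytest.warns(UserWarning, match="collinear"):
            out = regress.vif(design)
        assert np.isinf(out["a"])

    def test_near_collinear_exceeds_threshold(self, rng):
        x = rng.normal(size=200)
        design = pd.DataFrame({"a": x, "b": x + 0.01 * rng.normal(size=200)})
        assert (regress.vif(design) > regress.VIF_CRITICAL).all()

    def test_invariant_to_affine_rescaling(self, rng):
        a = rng.normal(size=100)
        b = 0.6 * a + rng.normal(size=100)
        d1 = pd.DataFrame({"a": a, "b": b})
        d2 = pd.DataFrame({"a": 3.0 * a - 7.0, "b": 0.1 * b + 2.0})
        assert regress.vif(d1).to_numpy() == pytest.approx(regress.vif(d2).to_numpy())


class TestDiagnostics:
    def test_standard_normal_residuals_score_near_zero(self, rng):
        n = 1000
        fitted = rng.uniform(5, 7, n)
        model = regress.RegressionModel(
            predictors=(), params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            tvalues=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
            r2=0.5, adjusted_r2=0.5, residuals=rng.standard_normal(n),
            fitted=fitted, vif=pd.Series(dtype=float),
            correlation_matrix=pd.DataFrame(), conf_int=pd.DataFrame(), nobs=n,
        )
        out = regress.diagnostics(model)
        assert abs(out["heteroscedasticity_score"]) <= 0.08
        assert out["normality_ppcc"] > 0.99

    def test_funnel_residuals_flagged(self, rng):
        n = 400
        fitted = np.linspace(1, 10, n)
        resid = fitted * rng.standard_normal(n) * 0.3
        model = regress.RegressionModel(
            predictors=(), params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            tvalues=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
            r2=0.5, adjusted_r2=0.5, residuals=resid, fitted=fitted,
            vif=pd.Series(dtype=float), correlation_matrix=pd.DataFrame(),
            conf_int=pd.DataFrame(), nobs=n,
        )
        assert regress.diagnostics(model)["heteroscedasticity_score"] > 0.5

    def test_perfect_fit_degenerate(self):
        ds = make_dataset(noise=0.0)
        model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)
        out = regress.diagnostics(model)
        assert out["degenerate"]


class TestElimination:
    def test_null_baffle_eliminated_in_most_runs(self):
        # baffle has true coefficient 0; spore carries signal so only the
        # baffle indicator should drop in the vast majority of runs
        grid = [
            (s, a, t, b)
            for s in synthgen.SPORE_LEVELS
            for a in synthgen.AGITATION_LEVELS
            for t in (0.0, 5.0)
            for b in (False, True)
        ]
        eliminated = 0
        n_runs = 200
        for rep in range(n_runs):
            ds = make_dataset(
                noise=0.1, seed=20_000 + rep, replicates=2, conditions=grid,
                spore_coefficient=-0.15,
            )
            model = regress.eliminate_nonsignificant(ds)
            eliminated += int("baffled" not in model.predictors)
        assert eliminated / n_runs >= 0.90

    def test_strong_signal_keeps_all_predictors(self):
        grid = [
            (s, a, t, b)
            for s in synthgen.SPORE_LEVELS
            for a in synthgen.AGITATION_LEVELS
            for t in (0.0, 5.0)
            for b in (False, True)
        ]
        ds = make_dataset(
            noise=0.02, seed=1, replicates=3, conditions=grid,
            spore_coefficient=-0.2, baffle_coefficient=0.5,
        )
        model = regress.eliminate_nonsignificant(ds)
        assert set(model.predictors) == set(regress.FULL_PREDICTORS)
        assert model.elimination_trace == []

    def test_alpha_one_keeps_full_model(self):
        grid = [
            (s, a, t, b)
            for s in synthgen.SPORE_LEVELS
            for a in synthgen.AGITATION_LEVELS
            for t in (0.0, 5.0)
            for b in (False, True)
        ]
        ds = make_dataset(noise=0.3, seed=2, replicates=2, conditions=grid)
        model = regress.eliminate_nonsignificant(ds, alpha=1.0)
        assert set(model.predictors) == set(regress.FULL_PREDICTORS)


class TestPredictDiameter:
    def test_closed_form(self):
        expected = math.exp(15.863 - 1.7769 * math.log(150.0))
        assert regress.predict_diameter(150.0, 0.0) == pytest.approx(expected)

    def test_talc_multiplier(self):
        base = regress.predict_diameter(250.0, 2.0)
        plus = regress.predict_diameter(250.0, 3.0)
        assert plus / base == pytest.approx(math.exp(-0.10856))

    def test_agitation_power_law(self):
        with pytest.warns(UserWarning):
            low = regress.predict_diameter(125.0, 0.0)
        base = regress.predict_diameter(250.0, 0.0)
        assert base / low == pytest.approx(2.0 ** (-1.7769))

    def test_monotone_decreasing(self):
        a = [regress.predict_diameter(x, 1.0) for x in (160.0, 200.0, 250.0)]
        t = [regress.predict_diameter(250.0, x) for x in (0.0, 2.0, 4.0)]
        assert a == sorted(a, reverse=True)
        assert t == sorted(t, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            regress.predict_diameter(0.0, 0.0)
        with pytest.raises(ValueError):
            regress.predict_diameter(250.0, -1.0)

    def test_out_of_validity_range_warns(self):
        with pytest.warns(UserWarning, match="outside the validated range"):
            regress.predict_diameter(150.0, 25.0)  # far below 150 µm


class TestSuppliedReplicateTable:
    """A user-supplied replicate table in the documented schema feeds the
    same reduced-model machinery; results are cross-checked against an
    independent least-squares oracle."""

    def test_reduced_model_matches_lstsq_oracle(self, tmp_path):
        df = synthgen.gen_regression_dataset(
            conditions=S6_B0_GRID, replicates=3, noise_sd_ln=0.08, seed=77
        )
        path = tmp_path / "replicates.csv"
        df.to_csv(path, index=False)
        loaded = regress.load_replicate_table(path)
        ds = regress.build_dataset(loaded)
        model = regress.fit_ols(ds, predictors=regress.REDUCED_PREDICTORS)

        # independent oracle: raw lstsq + closed-form R² / adjusted R²
        x = np.column_stack([
            np.ones(len(ds.frame)),
            np.log(loaded["agitation_rpm"].to_numpy()),
            loaded["talc_g_per_l"].to_numpy(),
        ])
        y = np.log(loaded["median_ed_um"].to_numpy())
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
        n, p = len(y), 2
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        assert model.params.to_numpy() == pytest.approx(beta)
        assert model.adjusted_r2 == pytest.approx(adj)
        # balanced factorial design: agitation and talc are orthogonal
        assert model.vif.to_numpy() == pytest.approx(1.0, abs=1e-9)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"agitation_rpm": [150.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            regress.load_replicate_table(path)
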