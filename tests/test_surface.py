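"""Weighted quadratic fitting, stepwise AIC selection and prediction."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import ecmopt as e
from ecmopt.errors import AlignmentError, SingularFitError, UndefinedFitError
from ecmopt.normalize import ExpressionMatrix
from ecmopt.surface import (
    adjusted_r2,
    fit_weighted,
    quadratic_basis,
    stepwise_aic,
)


class TestQuadraticBasis:
    def test_center_and_corner(self):
        assert np.allclose(quadratic_basis([0, 0, 0]), [1] + [0] * 9)
        assert np.allclose(quadratic_basis([1, 1, 1]), np.ones(10))

    def test_raw_point_hand_computed(self):
        c, f, l = 0.75, 0.15, 0.375
        expected = [1, c, f, l, c * f, c * l, f * l, c * c, f * f, l * l]
        assert np.allclose(quadratic_basis([c, f, l]), expected)

    def test_vectorized_matches_per_point(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, size=(20, 3))
        B = quadratic_basis(X)
        for i in range(20):
            assert np.allclose(B[i], quadratic_basis(X[i]))


class TestWeightedFit:
    def test_design_matrix_full_rank(self, coded_basis):
        assert np.linalg.matrix_rank(coded_basis) == 10

    def test_exact_recovery_on_noiseless_ccd(self, coded_basis, ccd_weights):
        beta = np.array([3.0, 2.0, -1.5, 0, 0, 0, 0, 0, 0, 0])
        y = coded_basis @ beta
        model = fit_weighted(y, coded_basis, ccd_weights)
        assert np.max(np.abs(model.coef - beta)) <= 1e-10
        assert model.adjusted_r2 == pytest.approx(1.0)

    def test_equal_weights_reduce_to_ols(self, coded_basis):
        rng = np.random.default_rng(1)
        y = rng.normal(size=23)
        wls = fit_weighted(y, coded_basis, np.full(23, 0.37))
        ols, *_ = np.linalg.lstsq(coded_basis, y, rcond=None)
        assert np.allclose(wls.coef, ols)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_and_statsmodels(self, coded_basis, ccd_weights, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        y = rng.normal(size=23)
        model = fit_weighted(y, coded_basis, ccd_weights)
        W = np.diag(ccd_weights)
        oracle = np.linalg.solve(
            coded_basis.T @ W @ coded_basis, coded_basis.T @ W @ y
        )
        assert np.allclose(model.coef, oracle, atol=1e-9)
        smfit = sm.WLS(y, coded_basis, weights=ccd_weights).fit()
        assert np.allclose(model.coef, smfit.params, atol=1e-9)

    def test_rank_deficiency_names_collinear_terms(self, ccd):
        X = ccd.coded_values().copy()
        X[:, 2] = X[:, 1]  # L duplicates F
        B = quadratic_basis(X)
        with pytest.raises(SingularFitError) as exc:
            fit_weighted(np.ones(23), B, np.ones(23))
        assert len(exc.value.collinear_terms) > 0

    def test_center_replicates_at_fractional_weight_equal_one_averaged_row(self):
        """9 center rows at weight 1/9 give the same normal equations as the
        averaged center row once at weight 1."""
        rng = np.random.default_rng(7)
        bounds = e.default_bounds()
        full = e.build_ccd(bounds, 9)
        collapsed = e.build_ccd(bounds, 1)
        y_named = {
            rid: rng.normal() for rid in full.runs["run_id"][full.runs["role"] != "center"]
        }
        y_center = rng.normal(size=9)
        yf, yc = [], []
        for _, row in full.runs.iterrows():
            yf.append(y_center.mean() if row["role"] == "center" else y_named[row["run_id"]])
        for _, row in collapsed.runs.iterrows():
            yc.append(y_center.mean() if row["role"] == "center" else y_named[row["run_id"]])
        mf = fit_weighted(np.array(yf), quadratic_basis(full.coded_values()),
                          e.run_weights(full).to_numpy())
        mc = fit_weighted(np.array(yc), quadratic_basis(collapsed.coded_values()),
                          e.run_weights(collapsed).to_numpy())
        assert np.allclose(mf.coef, mc.coef, atol=1e-10)


class TestAdjustedR2:
    def test_perfect_and_intercept_only(self):
        assert adjusted_r2(0.0, 5.0, 23, 10) == pytest.approx(1.0)
        # intercept-only: RSS equals TSS by construction
        assert adjusted_r2(5.0, 5.0, 23, 1) == pytest.approx(0.0)

    def test_formula_oracle(self):
        rss, tss, n, p = 2.0, 10.0, 23, 4
        r2 = 1 - rss / tss
        assert adjusted_r2(rss, tss, n, p) == pytest.approx(
            1 - (1 - r2) * (n - 1) / (n - p)
        )

    def test_undefined_when_saturated(self):
        with pytest.raises(UndefinedFitError):
            adjusted_r2(0.0, 1.0, 10, 10)


class TestStepwise:
    def test_aic_never_above_full_model(self, coded_basis, ccd_weights):
        rng = np.random.default_rng(11)
        for _ in range(30):
            y = rng.normal(size=23)
            full = fit_weighted(y, coded_basis, ccd_weights)
            reduced = stepwise_aic(y, coded_basis, ccd_weights, full=full)
            assert reduced.aic <= full.aic + 1e-9

    def test_pure_noise_models_are_pruned(self, coded_basis, ccd_weights):
        rng = np.random.default_rng(13)
        smaller = sum(
            len(stepwise_aic(rng.normal(size=23), coded_basis, ccd_weights).terms) < 10
            for _ in range(50)
        )
        assert smaller >= 40

    def test_matches_r_stepaic_oracle(self, ccd, coded_basis, ccd_weights, tmp_path):
        """Selected term sets agree exactly with MASS::stepAIC on identical data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(123)
        Xc = ccd.coded_values()
        ys = [3 + 2 * Xc[:, 0] - 1.5 * Xc[:, 1] + rng.normal(0, 0.05, 23) for _ in range(8)]
        ys += [rng.normal(size=23) for _ in range(4)]
        mine = [
            sorted(t for t in stepwise_aic(y, coded_basis, ccd_weights).terms if t != "1")
            for y in ys
        ]
        np.savetxt(tmp_path / "ys.tsv", np.array(ys), delimiter="\t")
        np.savetxt(tmp_path / "X.tsv", Xc, delimiter="\t")
        np.savetxt(tmp_path / "w.tsv", ccd_weights, delimiter="\t")
        script = textwrap.dedent("""
            suppressMessages(library(MASS))
            Y <- as.matrix(read.table('%(d)s/ys.tsv'))
            X <- as.matrix(read.table('%(d)s/X.tsv')); colnames(X) <- c('C','F','L')
            w <- scan('%(d)s/w.tsv', quiet=TRUE)
            df <- as.data.frame(X)
            form <- y ~ C + F + L + C:F + C:L + F:L + I(C^2) + I(F^2) + I(L^2)
            map <- c('C'='C','F'='F','L'='L','C:F'='C:F','C:L'='C:L','F:L'='F:L',
                     'I(C^2)'='C^2','I(F^2)'='F^2','I(L^2)'='L^2')
            for (i in 1:nrow(Y)) {
              df$y <- Y[i,]
              m <- stepAIC(lm(form, data=df, weights=w), direction='backward', trace=0)
              tt <- attr(terms(m), 'term.labels')
              cat(paste(sort(unname(map[tt])), collapse=','), sep='\\n')
            }
        """) % {"d": tmp_path}
        (tmp_path / "oracle.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R")], capture_output=True, text=True,
            timeout=120,
        )
        assert out.returncode == 0, out.stderr
        r_sets = [sorted(x for x in line.split(",") if x) for line in out.stdout.splitlines()]
        assert r_sets == mine

    def test_linear_truth_rarely_keeps_all_quadratics(self, ccd, coded_basis, ccd_weights):
        rng = np.random.default_rng(17)
        Xc = ccd.coded_values()
        allq = sum(
            all(t in stepwise_aic(
                3 + 2 * Xc[:, 0] - 1.5 * Xc[:, 1] + rng.normal(0, 0.05, 23),
                coded_basis, ccd_weights,
            ).terms for t in ("C^2", "F^2", "L^2"))
            for _ in range(60)
        )
        assert allq / 60 < 0.3

    def test_marginality_protects_main_effects(self, coded_basis, ccd_weights):
        rng = np.random.default_rng(19)
        for _ in range(20):
            y = rng.normal(size=23)
            m = stepwise_aic(y, coded_basis, ccd_weights, hierarchy="marginality")
            for t in m.terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in m.terms and b in m.terms


class TestPredict:
    def test_training_points_and_constants(self, coded_basis, ccd_weights, ccd):
        beta = np.zeros(10)
        beta[[0, 1, 4]] = [2.0, 1.0, -0.5]
        y = coded_basis @ beta
        model = fit_weighted(y, coded_basis, ccd_weights)
        assert np.allclose(model.predict_basis(coded_basis), y, atol=1e-10)
        const = e.GeneResponseModel("g", ("1",), np.array([4.2]), 0.0, 0.0, 23, 0.0)
        assert const.predict([0.3, -0.2, 0.9]) == pytest.approx(4.2)

    def test_grid_matches_per_point_oracle(self, coded_basis, ccd_weights):
        rng = np.random.default_rng(23)
        y = rng.normal(size=23)
        model = fit_weighted(y, coded_basis, ccd_weights)
        pts = rng.uniform(-1, 1, size=(50, 3))
        grid_pred = model.predict(pts)
        for i in range(50):
            x = pts[i]
            manual = sum(
                c * v for c, v in zip(
                    model.coef,
                    [1, x[0], x[1], x[2], x[0] * x[1], x[0] * x[2], x[1] * x[2],
                     x[0] ** 2, x[1] ** 2, x[2] ** 2],
                )
            )
            assert grid_pred[i] == pytest.approx(manual)

    def test_raw_coefficients_reproduce_coded_predictions(self, bounds, ccd, ccd_weights):
        rng = np.random.default_rng(29)
        y = rng.normal(size=23)
        model = fit_weighted(y, quadratic_basis(ccd.coded_values()), ccd_weights)
        raw_beta = model.raw_coefficients(bounds)
        pts = np.column_stack([rng.uniform(fb.low, fb.high, 20) for fb in bounds])
        coded_pts = np.column_stack([fb.code(pts[:, i]) for i, fb in enumerate(bounds)])
        assert np.allclose(
            quadratic_basis(pts) @ raw_beta, model.predict(coded_pts), atol=1e-8
        )


class TestFitAllGenes:
    def test_bookkeeping_and_noiseless_r2(self, bounds, ccd):
        truth = e.simulate_ground_truth(
            50, bounds,
            e.SimulationConfig(n_emt_up=5, n_emt_down=5, n_basal=5, n_classical=5,
                               n_housekeeping=2),
            seed=31,
        )
        eta = truth.expected_log2_expression(ccd)
        expr = ExpressionMatrix(eta, "condition_averaged")
        models = e.fit_all_genes(expr, ccd)
        assert len(models) == 50
        for g in truth.program_genes("emt_up"):
            assert models[g].adjusted_r2 == pytest.approx(1.0)

    def test_column_mismatch_raises(self, bounds, ccd):
        expr = ExpressionMatrix(
            pd.DataFrame(np.ones((3, 4)), index=list("abc"), columns=list("wxyz")),
            "condition_averaged",
        )
        with pytest.raises(AlignmentError):
            e.fit_all_genes(expr, ccd)


class TestValidateConfirmation:
    def test_noiseless_r2_one_rmse_zero(self, bounds, ccd):
        truth = e.simulate_ground_truth(
            30, bounds,
            e.SimulationConfig(n_emt_up=4, n_emt_down=4, n_basal=3, n_classical=3,
                               n_housekeeping=1),
            seed=37,
        )
        conf = e.confirmation_design(bounds, 5, seed=41)
        models = e.fit_all_genes(
            ExpressionMatrix(truth.expected_log2_expression(ccd), "condition_averaged"),
            ccd,
        )
        observed = truth.expected_log2_expression(conf)
        table, summary = e.validate_confirmation(models, observed, conf)
        assert summary["r2"] == pytest.approx(1.0)
        assert summary["rmse"] == pytest.approx(0.0, abs=1e-8)
        assert len(table) == 30 * 5

    def test_constant_predictions_score_nonpositive(self, bounds):
        conf = e.confirmation_design(bounds, 4, seed=43)
        const = e.GeneResponseModel("g0", ("1",), np.array([1.0]), 0.0, 0.0, 23, 0.0)
        observed = pd.DataFrame(
            [[0.0, 1.0, 2.0, 3.0]], index=["g0"], columns=conf.runs["run_id"]
        )
        _, summary = e.validate_confirmation({"g0": const}, observed, conf)
        assert summary["r2"] <= 0

    def test_summary_matches_formula_oracle(self, bounds):
        rng = np.random.default_rng(47)
        conf = e.confirmation_design(bounds, 5, seed=53)
        model = fit_weighted(
            rng.normal(size=23),
            quadratic_basis(e.build_ccd(bounds, 9).coded_values()),
            np.ones(23),
        )
        observed = pd.DataFrame(
            rng.normal(size=(1, 5)), index=["g"], columns=conf.runs["run_id"]
        )
        model.gene = "g"
        table, summary = e.validate_confirmation({"g": model}, observed, conf)
        resid = table["observed"] - table["predicted"]
        ss_tot = ((table["observed"] - table["observed"].mean()) ** 2).sum()
        assert summary["rmse"] == pytest.approx(np.sqrt((resid**2).mean()))
        assert summary["r2"] == pytest.approx(1 - (resid**2).sum() / ss_tot)


def test_run_weights_center_ninth(ccd):
    w = e.run_weights(ccd)
    centers = ccd.runs.loc[ccd.runs["role"] == "center", "run_id"]
    assert np.allclose(w.loc[centers], 1 / 9)
    others = ccd.runs.loc[ccd.runs["role"] != "center", "run_id"]
    assert np.allclose(w.loc[others], 1.0)
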