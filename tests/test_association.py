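"""Reliability, design assembly, LASSO selection, OLS and influence filtering."""

import json

import numpy as np
import pandas as pd
import pytest

from netrait import (
    AssociationConfig,
    GeneratorConfig,
    cronbach_alpha,
    generate_cohort,
    run_association,
    write_results,
)
from netrait.association import (
    DesignMatrix,
    assemble_design,
    cooks_distances,
    cooks_filter,
    lasso_select,
    ols_fit,
)
from netrait.metrics import SubjectMetrics


def fake_metrics(cohort, rng):
    """SubjectMetrics with random but fixed values (design-stage tests
    don't need real graph measures)."""
    n = len(cohort.regions)
    return [SubjectMetrics(subject_id=sid, cpl=float(rng.uniform(2, 3)),
                           gcc=float(rng.uniform(0, 1)),
                           smw=float(rng.uniform(0.8, 2)),
                           bet=rng.uniform(0, 50, size=n),
                           gcc_method="average_local", n_random_used=1)
            for sid in cohort.subject_ids]


@pytest.fixture(scope="module")
def small_cohort():
    cfg = GeneratorConfig(n_subjects=12, seed=42)
    cohort, _ = generate_cohort(cfg)
    return cohort


class TestCronbachAlpha:
    def test_identical_items_give_one(self):
        items = np.tile([[1.0], [2.0], [4.0], [3.0]], (1, 5))
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_zero_total_variance_is_error(self):
        items = np.array([[1, 2], [2, 1]])  # sums constant
        with pytest.raises(ValueError):
            cronbach_alpha(items)

    def test_matches_hand_computed_formula(self):
        items = np.array([[1.0, 2.0, 3.0],
                          [2.0, 3.0, 3.0],
                          [0.0, 1.0, 2.0],
                          [3.0, 4.0, 4.0]])
        k = 3
        item_vars = items.var(axis=0, ddof=1).sum()
        total_var = items.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - item_vars / total_var)
        assert cronbach_alpha(items) == pytest.approx(expected, abs=1e-12)
        # hand: item vars 5/3 + 5/3 + 2/3 = 4; var of sums 34/3
        assert cronbach_alpha(items) == pytest.approx(1.5 * (1 - 4 / (34 / 3)))
        assert cronbach_alpha(items) == pytest.approx(0.9705882352941176)


class TestAssembleDesign:
    def test_predictor_count_and_order(self, small_cohort, rng):
        design = assemble_design(fake_metrics(small_cohort, rng),
                                 small_cohort)
        assert len(design.predictor_names) == 88  # 2 + 3 + 83
        assert design.predictor_names[:5] == ["age", "sex", "cpl", "gcc",
                                              "smw"]
        assert design.predictor_names[5] == \
            "bet_" + small_cohort.regions.names[0]

    def test_standardization_contract(self, small_cohort, rng):
        design = assemble_design(fake_metrics(small_cohort, rng),
                                 small_cohort)
        assert np.allclose(design.X.mean(), 0, atol=1e-12)
        assert np.allclose(design.X.std(ddof=1), 1, atol=1e-12)
        assert design.y.mean() == pytest.approx(0, abs=1e-12)
        assert design.y.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_zero_variance_column_dropped_with_warning(self, small_cohort,
                                                       rng):
        ms = fake_metrics(small_cohort, rng)
        for m in ms:
            m.bet[0] = 7.0  # isolated-node column, constant across subjects
        with pytest.warns(UserWarning, match="zero-variance"):
            design = assemble_design(ms, small_cohort)
        dropped = "bet_" + small_cohort.regions.names[0]
        assert design.dropped_columns == [dropped]
        assert dropped not in design.X.columns

    def test_subject_mismatch_rejected(self, small_cohort, rng):
        ms = fake_metrics(small_cohort, rng)[:-1]
        with pytest.raises(ValueError, match="subjects"):
            assemble_design(ms, small_cohort)


def toy_design(n, p, rng, beta=None, noise=1.0):
    """Standardized design with an optional planted linear signal."""
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n) * noise
    if beta is not None:
        y = y + X @ beta
    Xz = (X - X.mean(0)) / X.std(0, ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    cols = [f"x{i}" for i in range(p)]
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    return DesignMatrix(
        X=pd.DataFrame(Xz, columns=cols, index=idx),
        y=pd.Series(yz, index=idx, name="trait_score"),
        standardization=pd.DataFrame(), dropped_columns=[])


class TestLassoSelect:
    def test_pure_noise_gives_empty_or_tiny_selection(self, rng):
        design = toy_design(60, 30, rng)
        sel = lasso_select(design, cv_folds=5, seed=0)
        assert len(sel.selected) <= 2

    def test_full_shrinkage_at_max_penalty(self, rng):
        # at the largest penalty on the path all coefficients vanish
        from sklearn.linear_model import Lasso
        design = toy_design(60, 30, rng)
        sel = lasso_select(design, cv_folds=5, seed=0)
        alpha_max = sel.cv_mse_path["alpha"].max()
        refit = Lasso(alpha=alpha_max * 1.01).fit(design.X, design.y)
        assert np.all(refit.coef_ == 0)

    def test_support_recovery_monte_carlo(self):
        # y = 0.8 x_j + noise at SNR ~ 4: x_j should be picked essentially
        # always at n = 200, p = 88
        hits = 0
        n_runs = 50
        for run in range(n_runs):
            rng = np.random.default_rng(1000 + run)
            beta = np.zeros(88)
            j = int(rng.integers(88))
            beta[j] = 0.8
            design = toy_design(200, 88, rng, beta=beta, noise=0.4)
            sel = lasso_select(design, cv_folds=5, seed=run, n_alphas=50)
            hits += f"x{j}" in sel.selected
        assert hits >= 45  # >= 90%

    def test_kkt_conditions_at_selected_penalty(self, rng):
        from sklearn.linear_model import Lasso
        design = toy_design(80, 20, rng,
                            beta=np.r_[0.9, -0.7, np.zeros(18)], noise=0.5)
        sel = lasso_select(design, cv_folds=5, seed=3)
        X = design.X.to_numpy()
        y = design.y.to_numpy()
        n = len(y)
        refit = Lasso(alpha=sel.penalty, max_iter=10**6, tol=1e-12).fit(X, y)
        b = refit.coef_
        grad = X.T @ (y - y.mean() - (X @ b - (X @ b).mean())) / n
        active = b != 0
        # subgradient: grad_j = alpha * sign(b_j) on the active set,
        # |grad_j| <= alpha elsewhere
        assert np.allclose(grad[active], sel.penalty * np.sign(b[active]),
                           atol=1e-6)
        assert np.all(np.abs(grad[~active]) <= sel.penalty + 1e-6)

    def test_near_zero_penalty_matches_ols(self, rng):
        from sklearn.linear_model import Lasso
        design = toy_design(100, 5, rng,
                            beta=np.r_[1.0, -0.5, 0.2, 0.0, 0.0], noise=0.5)
        X = design.X.to_numpy()
        y = design.y.to_numpy()
        lasso = Lasso(alpha=1e-10, max_iter=10**6, tol=1e-14).fit(X, y)
        Xc = np.c_[np.ones(len(y)), X]
        ols = np.linalg.lstsq(Xc, y, rcond=None)[0]
        assert np.allclose(lasso.coef_, ols[1:], atol=1e-6)


class TestOLSFit:
    def test_perfect_fit(self, rng):
        design = toy_design(30, 3, rng, beta=np.array([1.0, 0, 0]),
                            noise=1e-15)
        model, _ = ols_fit(design, ["x0"])
        assert model.fit["r_squared"] == pytest.approx(1.0)
        assert model.fit["residual_se"] == pytest.approx(0.0, abs=1e-6)

    def test_study_degrees_of_freedom(self, rng):
        # 50 retained subjects and 24 predictors leave 25 residual df
        design = toy_design(50, 30, rng)
        model, _ = ols_fit(design, [f"x{i}" for i in range(24)])
        assert model.fit["residual_df"] == 25
        assert model.fit["f_df1"] == 24

    def test_matches_normal_equations(self, rng):
        design = toy_design(40, 6, rng, beta=rng.standard_normal(6))
        names = design.predictor_names
        model, _ = ols_fit(design, names)
        Xc = np.c_[np.ones(40), design.X.to_numpy()]
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ design.y.to_numpy())
        got = np.r_[model.coef["(Intercept)"],
                    [model.coef[n] for n in names]]
        assert np.allclose(got, beta, atol=1e-10)

    def test_rank_deficiency_rejected(self, rng):
        design = toy_design(30, 4, rng)
        design.X["x3"] = design.X["x2"]
        with pytest.raises(ValueError, match="rank"):
            ols_fit(design, design.predictor_names)


class TestCooksFilter:
    def test_planted_outlier_removed_and_slope_recovered(self, rng):
        n = 60
        design = toy_design(n, 2, rng, beta=np.array([0.9, 0.0]), noise=0.2)
        clean_model, _ = ols_fit(design, ["x0", "x1"])
        # displace one response by 10 SD
        design.y.iloc[7] += 10.0
        _, res = ols_fit(design, ["x0", "x1"])
        removed = cooks_filter(res, list(design.y.index), multiplier=3.0)
        assert removed == ["s7"]
        refit, _ = ols_fit(design, ["x0", "x1"],
                           subjects=[s for s in design.y.index
                                     if s != "s7"])
        assert refit.coef["x0"] == pytest.approx(clean_model.coef["x0"],
                                                 rel=0.05)

    def test_cooks_distance_matches_leave_one_out(self, rng):
        design = toy_design(15, 2, rng, beta=np.array([0.8, -0.3]),
                            noise=0.5)
        names = ["x0", "x1"]
        _, res = ols_fit(design, names)
        d = cooks_distances(res)
        Xc = np.c_[np.ones(15), design.X.to_numpy()]
        y = design.y.to_numpy()
        p = Xc.shape[1]
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        fitted = Xc @ beta
        s2 = ((y - fitted) ** 2).sum() / (15 - p)
        for i in range(15):
            keep = np.arange(15) != i
            bi = np.linalg.solve(Xc[keep].T @ Xc[keep], Xc[keep].T @ y[keep])
            d_loo = ((Xc @ beta - Xc @ bi) ** 2).sum() / (p * s2)
            assert d[i] == pytest.approx(d_loo, abs=1e-10)


class TestRunAssociation:
    def test_deterministic_and_serializable(self, small_cohort, rng,
                                            tmp_path):
        ms = fake_metrics(small_cohort, np.random.default_rng(0))
        cfg = AssociationConfig(cv_folds=4, seed=5)
        a = run_association(ms, small_cohort, cfg)
        b = run_association(ms, small_cohort, cfg)
        assert a.to_dict() == b.to_dict()
        files = write_results(a, None, None, tmp_path)
        with open(files["association_json"]) as fh:
            back = json.load(fh)
        from netrait.association import AssociationModel
        assert AssociationModel.from_dict(back).to_dict() == a.to_dict()

    def test_significance_flag_threshold_semantics(self, small_cohort):
        ms = fake_metrics(small_cohort, np.random.default_rng(0))
        model = run_association(ms, small_cohort,
                                AssociationConfig(cv_folds=4, seed=5))
        for name, p in model.p_values.items():
            assert model.significant[name] == (p < model.alpha_level)

    def test_forced_covariates_always_reported(self, small_cohort):
        ms = fake_metrics(small_cohort, np.random.default_rng(1))
        model = run_association(ms, small_cohort,
                                AssociationConfig(cv_folds=4, seed=6))
        assert model.predictors[:2] == ["age", "sex"]
        table = model.coefficient_table()
        assert list(table["predictor"][:3]) == ["(Intercept)", "age", "sex"]

    def test_scale_invariance_of_standardized_betas(self, small_cohort):
        ms1 = fake_metrics(small_cohort, np.random.default_rng(2))
        ms2 = [SubjectMetrics(m.subject_id, m.cpl, m.gcc, m.smw,
                              m.bet * 1000.0, m.gcc_method, m.n_random_used)
               for m in ms1]
        cfg = AssociationConfig(cv_folds=4, seed=7)
        a = run_association(ms1, small_cohort, cfg)
        b = run_association(ms2, small_cohort, cfg)
        assert a.predictors == b.predictors
        for name in a.coef:
            assert a.coef[name] == pytest.approx(b.coef[name], abs=1e-8)
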