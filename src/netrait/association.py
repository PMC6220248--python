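"""Trait association: LASSO selection, OLS refit, influence filtering.

The design holds 2 + 3 + N candidate predictors per subject — age, sex
(male = 1, female = 0), the three global network measures (CPL, GCC, SMW)
and one betweenness column per region (88 columns for the 83-node
parcellation). A direct regression on all of them is hopeless at cohort
sample sizes (multicollinearity among network measures, combinatorial model
selection), so predictors are first screened by L1-penalized least squares
with a cross-validated penalty; the surviving predictors — with age and sex
always forced back in — go into an ordinary least-squares fit. Subjects
whose Cook's distance exceeds 3x the mean are removed in a single pass and
the model refit. Coefficients are standardized betas (both X and y are
z-scored); associations are flagged at p < 0.01, with no multiplicity
correction.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .io import Cohort
from .metrics import SubjectMetrics

FORCED_PREDICTORS = ("age", "sex")
GLOBAL_PREDICTORS = ("cpl", "gcc", "smw")


def cronbach_alpha(items: np.ndarray) -> float:
    """Internal-consistency reliability of a subjects x k item matrix:
    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    sample variances (denominator n-1)."""
    items = np.asarray(items, dtype=float)
    n, k = items.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 items and >= 2 subjects")
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    item_vars = items.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_vars / total_var)


@dataclass
class DesignMatrix:
    """Standardized predictors and response, with the scaling record."""

    X: pd.DataFrame               # z-scored predictors, subject-indexed
    y: pd.Series                  # z-scored trait score
    standardization: pd.DataFrame  # per-column mean and sd (raw scale)
    dropped_columns: list[str]     # zero-variance predictors excluded

    @property
    def predictor_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class AssociationModel:
    """Final fit: standardized coefficients with inference and provenance."""

    predictors: list[str]          # model terms in report order (no intercept)
    coef: dict[str, float]         # includes "(Intercept)"
    se: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    significant: dict[str, bool]
    alpha_level: float
    removed_subjects: list[str]
    retained_subjects: list[str]
    fit: dict[str, float]          # residual_se, residual_df, r_squared,
                                   # adj_r_squared, f_statistic, f_df1,
                                   # f_df2, f_pvalue
    provenance: dict = field(default_factory=dict)

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for name in ["(Intercept)"] + self.predictors:
            rows.append({
                "predictor": name,
                "standardized_beta": self.coef[name],
                "se_beta": self.se[name],
                "t_value": self.t_values[name],
                "p_value": self.p_values[name],
                "significant": self.significant[name],
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "coef": self.coef, "se": self.se,
            "t_values": self.t_values, "p_values": self.p_values,
            "significant": self.significant,
            "alpha_level": self.alpha_level,
            "removed_subjects": self.removed_subjects,
            "retained_subjects": self.retained_subjects,
            "fit": self.fit, "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssociationModel":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class AssociationConfig:
    cv_folds: int = 10
    cooks_multiplier: float = 3.0
    alpha_level: float = 0.01
    penalty_rule: str = "1se"      # "1se" (default) or "min"
    n_alphas: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 3:
            raise ValueError("cv_folds must be >= 3")
        if self.cooks_multiplier <= 0:
            raise ValueError("cooks_multiplier must be > 0")
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must be in (0, 1)")
        if self.penalty_rule not in ("min", "1se"):
            raise ValueError("penalty_rule must be 'min' or '1se'")


def assemble_design(metrics: list[SubjectMetrics], cohort: Cohort,
                    ) -> DesignMatrix:
    """Build the standardized design: age, sex, cpl, gcc, smw, then one
    betweenness column per region (region-table order). Both predictors and
    response are centered and scaled to unit SD (sample SD, n-1); columns
    with zero variance are excluded with a warning."""
    by_id = {m.subject_id: m for m in metrics}
    ids = cohort.subject_ids
    if set(by_id) != set(ids):
        raise ValueError("metrics and cohort cover different subjects")
    names = cohort.regions.names
    rows = []
    for sid in ids:
        m = by_id[sid]
        cov = cohort.covariates.loc[sid]
        row = {"age": float(cov["age"]),
               "sex": 1.0 if cov["sex"] == "male" else 0.0,
               "cpl": m.cpl, "gcc": m.gcc, "smw": m.smw}
        row.update({f"bet_{nm}": float(b) for nm, b in zip(names, m.bet)})
        rows.append(row)
    X = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    y = cohort.covariates["trait_score"].astype(float).loc[ids]

    means = X.mean()
    sds = X.std(ddof=1)
    dropped = list(X.columns[sds == 0])
    if dropped:
        warnings.warn(f"excluding zero-variance predictors: {dropped}")
    keep = [c for c in X.columns if c not in dropped]
    Xz = (X[keep] - means[keep]) / sds[keep]
    y_sd = y.std(ddof=1)
    if y_sd == 0:
        raise ValueError("response has zero variance")
    yz = (y - y.mean()) / y_sd
    record = pd.DataFrame({"mean": pd.concat([means, pd.Series({"trait_score": y.mean()})]),
                           "sd": pd.concat([sds, pd.Series({"trait_score": y_sd})])})
    return DesignMatrix(X=Xz, y=yz, standardization=record,
                        dropped_columns=dropped)


@dataclass
class LassoSelection:
    selected: list[str]
    penalty: float
    coef: pd.Series
    cv_mse_path: pd.DataFrame     # columns: alpha, mean_mse, se_mse


def lasso_select(design: DesignMatrix, cv_folds: int = 10,
                 seed: int = 0, penalty_rule: str = "min",
                 n_alphas: int = 100) -> LassoSelection:
    """L1-penalized least squares over a log-spaced penalty path, penalty
    chosen by seeded K-fold cross-validated MSE (at its minimum, or by the
    one-SE rule); returns the predictors with non-zero coefficients."""
    X = design.X.to_numpy()
    y = design.y.to_numpy()
    if np.var(y) == 0:
        raise ValueError("degenerate response (zero variance)")
    if len(y) < cv_folds:
        raise ValueError("fewer subjects than CV folds")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=n_alphas, cv=cv, max_iter=200_000, tol=1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter at tiny alphas
        model.fit(X, y)
    mse = model.mse_path_.mean(axis=1)
    se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    alphas = model.alphas_
    if penalty_rule == "min":
        best = float(model.alpha_)
        coefs = model.coef_
    else:  # one-SE rule: largest penalty within one SE of the minimum MSE
        i_min = int(np.argmin(mse))
        ok = np.flatnonzero(mse <= mse[i_min] + se[i_min])
        i_best = int(ok[np.argmax(alphas[ok])])
        best = float(alphas[i_best])
        from sklearn.linear_model import Lasso
        refit = Lasso(alpha=best, max_iter=200_000, tol=1e-7).fit(X, y)
        coefs = refit.coef_
    coef = pd.Series(coefs, index=design.predictor_names)
    selected = list(coef.index[coef != 0])
    path = pd.DataFrame({"alpha": alphas, "mean_mse": mse, "se_mse": se})
    return LassoSelection(selected=selected, penalty=best, coef=coef,
                          cv_mse_path=path)


def _inference_from_fit(res, predictors: list[str], alpha_level: float,
                        removed: list[str], retained: list[str],
                        provenance: dict) -> AssociationModel:
    names = ["(Intercept)"] + predictors
    coef = dict(zip(names, (float(v) for v in res.params)))
    se = dict(zip(names, (float(v) for v in res.bse)))
    tv = dict(zip(names, (float(v) for v in res.tvalues)))
    pv = dict(zip(names, (float(v) for v in res.pvalues)))
    sig = {k: bool(v < alpha_level) for k, v in pv.items()}
    n_ret = len(retained)
    p = len(predictors)
    resid_df = int(res.df_resid)
    assert resid_df == n_ret - p - 1, "residual df bookkeeping"
    fit = {
        "residual_se": float(np.sqrt(res.mse_resid)) if resid_df > 0 else 0.0,
        "residual_df": resid_df,
        "r_squared": float(res.rsquared),
        "adj_r_squared": float(res.rsquared_adj),
        "f_statistic": float(res.fvalue) if p > 0 else float("nan"),
        "f_df1": int(res.df_model),
        "f_df2": resid_df,
        "f_pvalue": float(res.f_pvalue) if p > 0 else float("nan"),
    }
    return AssociationModel(predictors=predictors, coef=coef, se=se,
                            t_values=tv, p_values=pv, significant=sig,
                            alpha_level=alpha_level, removed_subjects=removed,
                            retained_subjects=retained, fit=fit,
                            provenance=provenance)


def ols_fit(design: DesignMatrix, predictors: list[str],
            subjects: list[str] | None = None,
            alpha_level: float = 0.01,
            removed: list[str] | None = None,
            provenance: dict | None = None):
    """OLS with intercept on the standardized design restricted to
    ``predictors`` (and to ``subjects``, if given). Returns
    (AssociationModel, statsmodels results)."""
    X = design.X[predictors]
    y = design.y
    if subjects is not None:
        X = X.loc[subjects]
        y = y.loc[subjects]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    Xc = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design")
    res = sm.OLS(y.to_numpy(), Xc).fit()
    model = _inference_from_fit(res, predictors, alpha_level,
                                removed or [], list(X.index),
                                provenance or {})
    return model, res


def cooks_distances(res) -> np.ndarray:
    """Cook's distance per observation of a fitted OLS."""
    return res.get_influence().cooks_distance[0]


def cooks_filter(res, subjects: list[str],
                 multiplier: float = 3.0) -> list[str]:
    """Subjects whose Cook's distance exceeds ``multiplier`` times the mean
    distance (single pass; the caller refits once on the survivors)."""
    d = cooks_distances(res)
    mean_d = d.mean()
    return [sid for sid, di in zip(subjects, d) if di > multiplier * mean_d]


def run_association(metrics: list[SubjectMetrics], cohort: Cohort,
                    config: AssociationConfig | None = None,
                    ) -> AssociationModel:
    """Full association stage.

    Order: assemble design -> LASSO selection on all subjects -> OLS on all
    subjects (selected terms, age and sex forced) -> one Cook's-distance
    pass -> refit on retained subjects -> flag p < alpha_level.
    """
    config = config or AssociationConfig()
    design = assemble_design(metrics, cohort)
    sel = lasso_select(design, cv_folds=config.cv_folds, seed=config.seed,
                       penalty_rule=config.penalty_rule,
                       n_alphas=config.n_alphas)
    forced = [p for p in FORCED_PREDICTORS if p in design.X.columns]
    predictors = forced + [p for p in sel.selected if p not in forced]
    provenance = {
        "seed": config.seed, "cv_folds": config.cv_folds,
        "penalty": sel.penalty, "penalty_rule": config.penalty_rule,
        "lasso_selected": sel.selected,
        "cooks_multiplier": config.cooks_multiplier,
        "dropped_zero_variance": design.dropped_columns,
    }
    all_ids = list(design.X.index)
    _, res0 = ols_fit(design, predictors, alpha_level=config.alpha_level,
                      provenance=provenance)
    removed = cooks_filter(res0, all_ids, config.cooks_multiplier)
    retained = [s for s in all_ids if s not in removed]
    provenance["removed_subjects"] = removed
    model, _ = ols_fit(design, predictors, subjects=retained,
                       alpha_level=config.alpha_level, removed=removed,
                       provenance=provenance)
    return model
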