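"""Drug-screening cascade: univariate logistic screen, cross-validated
LASSO selection, covariate-adjusted multivariate logistic regression, and
ROC/AUC assessment.

The outcome is a binary per-report indicator of the target adverse event.
Predictors are per-drug primary-suspect indicators plus demographic
covariates coded as in the source analysis: sex (female reference), age
in five classes (<18 reference; 18-40, 41-60, 61-80, >80), and body
weight dichotomized as inside vs outside 50-100 kg (inside reference).
Reports missing any covariate are excluded (complete-case analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

AGE_CLASS_EDGES = ((18, 40), (41, 60), (61, 80))  # plus <18 ref and >80
COVARIATE_COLUMNS = ("sex_male", "age_18_40", "age_41_60", "age_61_80",
                     "age_gt80", "weight_out_of_range")


@dataclass
class DesignMatrix:
    """Complete-case design matrix for the screening cascade."""

    X: pd.DataFrame          # drug indicators (alphabetical) then covariates
    y: pd.Series             # binary target-event outcome
    drug_columns: list[str]
    primaryids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)


def _age_class_columns(age_years: pd.Series) -> pd.DataFrame:
    out = pd.DataFrame(index=age_years.index)
    out["age_18_40"] = ((age_years >= 18) & (age_years <= 40)).astype(int)
    out["age_41_60"] = ((age_years > 40) & (age_years <= 60)).astype(int)
    out["age_61_80"] = ((age_years > 60) & (age_years <= 80)).astype(int)
    out["age_gt80"] = (age_years > 80).astype(int)
    return out


def build_design_matrix(store, drug_list, target_pts) -> DesignMatrix:
    """Assemble the complete-case design matrix from a case store.

    Rows with missing sex, age, or weight are dropped.  Drug columns are
    alphabetical; covariates follow in a fixed order.  Raises
    ``ValueError`` when no complete case remains.
    """
    demo = store.demo
    complete = (demo["sex"].isin(["male", "female"])
                & demo["age_years"].notna() & demo["weight_kg"].notna())
    demo = demo[complete]
    if demo.empty:
        raise ValueError("no complete cases: every report misses a covariate")
    pids = demo["primaryid"].to_numpy()
    index = pd.Index(pids, name="primaryid")

    X = pd.DataFrame(index=index)
    drugs = sorted(set(drug_list))
    ps = store.ps_drugs()
    ps = ps[ps["generic_name"].isin(drugs) & ps["primaryid"].isin(index)]
    hit = ps.drop_duplicates(["primaryid", "generic_name"]).assign(v=1)
    wide = hit.pivot(index="primaryid", columns="generic_name", values="v")
    for drug in drugs:
        col = wide[drug] if drug in wide.columns else pd.Series(dtype=float)
        X[drug] = col.reindex(index).fillna(0).astype(int)

    X["sex_male"] = (demo["sex"].to_numpy() == "male").astype(int)
    age = pd.Series(demo["age_years"].to_numpy(), index=index)
    X = pd.concat([X, _age_class_columns(age)], axis=1)
    wt = demo["weight_kg"].to_numpy()
    X["weight_out_of_range"] = ((wt < 50) | (wt > 100)).astype(int)

    event_pids = pd.Index(store.event_primaryids(target_pts))
    y = pd.Series(index.isin(event_pids).astype(int), index=index, name="event")
    return DesignMatrix(X=X, y=y, drug_columns=drugs, primaryids=pids)


# ---------------------------------------------------------------------------
# univariate screen

@dataclass
class ScreenResult:
    retained: list[str]
    per_drug: pd.DataFrame      # a, or_, p, p_adj, ror, ror_lo, excluded_reason
    separation_failures: list[str] = field(default_factory=list)


def univariate_screen(
    dm: DesignMatrix,
    ror_frame: pd.DataFrame,
    min_a: int = 100,
    alpha: float = 0.01,
    ror_rule: str = "ci_lower",
) -> ScreenResult:
    """Single-predictor logistic screen with the published inclusion rules.

    A drug is retained when (i) its case count a exceeds ``min_a``, (ii)
    its ROR is disproportionate — the 95% CI lower bound above 1 by
    default (``ror_rule="point"`` uses the point estimate instead) — and
    (iii) its Benjamini-Hochberg-adjusted univariate p-value is below
    ``alpha``.  The BH family is the set of drugs passing the count gate.
    ``ror_frame`` must be indexed by drug with ``a``, ``ror``, ``ror_lo``
    columns (as produced by :func:`faerspv.signals.signal_table`).
    """
    if ror_rule not in ("ci_lower", "point"):
        raise ValueError(f"unknown ror_rule {ror_rule!r}")
    rows = []
    separation = []
    gated = [d for d in dm.drug_columns
             if d in ror_frame.index and ror_frame.loc[d, "a"] > min_a]
    pvals = {}
    for drug in gated:
        x = sm.add_constant(dm.X[[drug]].to_numpy(dtype=float))
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(dm.y.to_numpy(), x).fit(disp=0, maxiter=100)
            if not np.all(np.isfinite(fit.bse)):
                raise PerfectSeparationError("infinite standard errors")
            pvals[drug] = float(fit.pvalues[1])
            or_ = float(np.exp(fit.params[1]))
        except (PerfectSeparationError, np.linalg.LinAlgError) as err:
            logger.warning("univariate separation for %s: %s", drug, err)
            separation.append(drug)
            pvals[drug] = np.nan
            or_ = np.nan
        rows.append({"drug": drug, "or_": or_, "p": pvals[drug]})

    per_drug = pd.DataFrame(rows).set_index("drug") if rows else pd.DataFrame(
        columns=["or_", "p"])
    per_drug["a"] = ror_frame["a"].reindex(per_drug.index)
    per_drug["ror"] = ror_frame["ror"].reindex(per_drug.index)
    per_drug["ror_lo"] = ror_frame["ror_lo"].reindex(per_drug.index)

    if len(per_drug):
        ok = per_drug["p"].notna()
        adj = pd.Series(np.nan, index=per_drug.index)
        if ok.any():
            adj[ok] = multipletests(per_drug.loc[ok, "p"], method="fdr_bh")[1]
        per_drug["p_adj"] = adj
    else:
        per_drug["p_adj"] = []

    retained = []
    for drug, row in per_drug.iterrows():
        if drug in separation:
            continue
        ror_ok = (row["ror_lo"] > 1.0) if ror_rule == "ci_lower" else (row["ror"] > 1.0)
        if ror_ok and np.isfinite(row["p_adj"]) and row["p_adj"] < alpha:
            retained.append(drug)
    return ScreenResult(retained=retained, per_drug=per_drug,
                        separation_failures=separation)


# ---------------------------------------------------------------------------
# LASSO selection

@dataclass
class LassoResult:
    selected: list[str]
    lambda_chosen: float
    lambda_min: float
    lambda_1se: float
    rule: str
    path: pd.DataFrame          # lambda, mean_deviance, se_deviance, n_nonzero
    coefficients: pd.Series     # at the chosen lambda, original scale


#: Covariate columns are multiplied by this factor before the L1 fit: the
#: fitted coefficient shrinks by the same factor, so its penalty
#: contribution becomes negligible - the per-column penalty-factor trick
#: for solvers without one.
_COVARIATE_INFLATION = 1e2


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def lasso_select(
    dm: DesignMatrix,
    retained: list[str],
    n_folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
    n_lambdas: int = 20,
    lambda_min_ratio: float = 1e-3,
    penalize_covariates: bool = False,
) -> LassoResult:
    """L1-penalized logistic selection over the retained drugs.

    Ten-fold (stratified, seeded) cross-validation of binomial deviance
    over a log-spaced lambda path; the chosen lambda is the largest within
    one standard error of the minimum (``rule="1se"``, the default) or the
    minimizer itself (``rule="min"``).  Demographic covariates are kept in
    the model but unpenalized unless ``penalize_covariates`` is set.
    Returns the drugs with nonzero coefficients at the chosen lambda; an
    empty selection is a warning, not an error.
    """
    if rule not in ("1se", "min"):
        raise ValueError(f"unknown lambda rule {rule!r}")
    if len(retained) < 1:
        raise ValueError("lasso_select needs at least one retained drug")
    cols = list(retained) + list(COVARIATE_COLUMNS)
    X = dm.X[cols].to_numpy(dtype=float).copy()
    y = dm.y.to_numpy(dtype=float)
    n, _ = X.shape
    n_drugs = len(retained)

    scale = np.ones(X.shape[1])
    if not penalize_covariates:
        scale[n_drugs:] = _COVARIATE_INFLATION
        X[:, n_drugs:] = X[:, n_drugs:] * _COVARIATE_INFLATION

    # glmnet-style lambda path from the gradient at the null model
    resid = y - y.mean()
    lam_max = np.max(np.abs(X[:, :n_drugs].T @ resid)) / n
    lam_max = max(lam_max, 1e-6)
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.zeros((n_folds, n_lambdas))
    for i, (train, test) in enumerate(skf.split(X, y)):
        for j, lam in enumerate(lambdas):
            model = _l1_fit(X[train], y[train], lam)
            p = model.predict_proba(X[test])[:, 1]
            fold_dev[i, j] = _binomial_deviance(y[test], p)
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)

    j_min = int(np.argmin(mean_dev))
    lambda_min = float(lambdas[j_min])
    within = mean_dev <= mean_dev[j_min] + se_dev[j_min]
    j_1se = int(np.flatnonzero(within)[0])  # lambdas descend: first = largest
    lambda_1se = float(lambdas[j_1se])
    lam_chosen = lambda_1se if rule == "1se" else lambda_min

    final = _l1_fit(X, y, lam_chosen)
    # column j was multiplied by scale[j], so beta_original = beta_fit*scale[j]
    coefs = final.coef_.ravel() * scale
    coef_series = pd.Series(coefs, index=cols)
    selected = [d for d in retained if abs(coef_series[d]) > 1e-8]
    if not selected:
        logger.warning("LASSO selected no drugs at lambda=%.5g", lam_chosen)

    n_nonzero = []
    for lam in lambdas:
        m = _l1_fit(X, y, lam)
        n_nonzero.append(int(np.sum(np.abs(m.coef_.ravel()[:n_drugs]) > 1e-8)))
    path = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev,
                         "se_deviance": se_dev, "n_nonzero": n_nonzero})
    return LassoResult(selected=selected, lambda_chosen=float(lam_chosen),
                       lambda_min=lambda_min, lambda_1se=lambda_1se, rule=rule,
                       path=path, coefficients=coef_series)


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # sklearn minimizes sum(loss) + (1/C)||w||_1; glmnet mean-loss lambda
    # therefore maps to C = 1/(n*lambda).
    C = 1.0 / (len(y) * lam)
    model = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                               max_iter=1000, tol=1e-5, random_state=0)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# multivariate fit

@dataclass
class RegressionResult:
    terms: pd.DataFrame          # coef, or_, ci_lo, ci_hi, p, p_adj, significant
    loglik: float
    n: int
    significant_drugs: list[str]


def multivariate_fit(
    dm: DesignMatrix,
    selected: list[str],
    alpha: float = 0.01,
    include_covariates: bool = True,
) -> RegressionResult:
    """Covariate-adjusted multivariate logistic model over selected drugs.

    Wald odds ratios, 95% CIs, and p-values per term; BH-adjusted drug
    p-values are reported alongside, and drugs with p < ``alpha`` are
    labeled significant.  Raises ``RuntimeError`` naming offending terms
    on non-convergence or separation.
    """
    cols = list(selected) + (list(COVARIATE_COLUMNS) if include_covariates else [])
    X = sm.add_constant(dm.X[cols].to_numpy(dtype=float))
    y = dm.y.to_numpy(dtype=float)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # convergence is verified below via the score vector
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise RuntimeError(f"multivariate fit failed: {err}") from err
    if not fit.mle_retvals.get("converged", True):
        # Newton's step-halving flag can oscillate at the optimum; a
        # vanishing score still certifies the MLE
        score = np.asarray(fit.model.score(fit.params))
        if np.max(np.abs(score)) > 1e-3:
            raise RuntimeError("multivariate fit did not converge")
    bse = np.asarray(fit.bse)
    if not np.all(np.isfinite(bse)):
        bad = [cols[i - 1] for i in range(1, len(bse)) if not np.isfinite(bse[i])]
        raise RuntimeError(f"separation in multivariate fit: terms {bad}")

    names = ["const"] + cols
    coef = np.asarray(fit.params)
    z = 1.959963984540054
    terms = pd.DataFrame({
        "term": names, "coef": coef, "or_": np.exp(coef),
        "ci_lo": np.exp(coef - z * bse), "ci_hi": np.exp(coef + z * bse),
        "p": np.asarray(fit.pvalues),
    }).set_index("term")
    drug_mask = terms.index.isin(selected)
    terms["p_adj"] = np.nan
    if drug_mask.any():
        terms.loc[drug_mask, "p_adj"] = multipletests(
            terms.loc[drug_mask, "p"], method="fdr_bh")[1]
    terms["significant"] = drug_mask & (terms["p"] < alpha)
    sig = [t for t in selected if terms.loc[t, "significant"]]
    return RegressionResult(terms=terms, loglik=float(fit.llf), n=dm.n,
                            significant_drugs=sig)


def predicted_probabilities(dm: DesignMatrix, result: RegressionResult,
                            selected: list[str]) -> np.ndarray:
    """In-sample fitted event probabilities of a multivariate model."""
    cols = list(selected) + list(COVARIATE_COLUMNS)
    X = sm.add_constant(dm.X[cols].to_numpy(dtype=float))
    coef = result.terms["coef"].to_numpy()
    eta = X @ coef
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(probabilities, outcome) -> tuple[float, pd.DataFrame]:
    """AUC by the tie-corrected Mann-Whitney rank statistic, plus ROC points.

    Raises ``ValueError`` when the outcome has a single class.  The ROC
    frame has columns ``fpr``/``tpr``/``threshold`` suitable for plotting.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcome must align")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: outcome has a single class")
    ranks = rankdata(p)  # average ranks handle ties
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-p, kind="mergesort")
    ps, ys = p[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(ps)), len(ps) - 1]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(1 - ys)[distinct]
    roc = pd.DataFrame({
        "threshold": np.r_[np.inf, ps[distinct]],
        "tpr": np.r_[0.0, tp / n1],
        "fpr": np.r_[0.0, fp / n0],
    })
    return float(auc), roc
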