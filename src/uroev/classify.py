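"""Confounder-adjusted logistic diagnostic models and their evaluation.

Case/control status is modelled by a binomial GLM (logit link) on the
log-scale qPCR predictors, always adjusted for age and gender, optionally
with the clinical risk factors obesity and hypertension. Reported per
model: ROC/AUC (Mann-Whitney form, ties counted half), sensitivity /
specificity / accuracy at a probability threshold, per-gene odds ratios
scaled to the gene's interquartile range (exp(beta * IQR)), a Wald p per
gene and a one-tailed chi-squared deviance test against the intercept-only
null. Robustness is assessed by stratified repeated k-fold
cross-validation with class-balanced round-robin fold assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "DiagnosticReport",
    "CVReport",
    "fit_logistic",
    "roc_auc",
    "classification_metrics",
    "youden_threshold",
    "odds_ratio_iqr",
    "deviance_test",
    "cross_validate",
    "diagnostic_report",
]

_RISK_FACTORS = {"obesity", "hypertension"}


@dataclass(frozen=True)
class ModelSpec:
    """Which gene predictors and risk factors enter a diagnostic model.

    Age and gender are always included as adjusters.
    """

    gene_predictors: tuple[str, ...]
    risk_factors: tuple[str, ...] = ()

    def __post_init__(self):
        genes = tuple(self.gene_predictors)
        object.__setattr__(self, "gene_predictors", genes)
        object.__setattr__(self, "risk_factors", tuple(self.risk_factors))
        if not 1 <= len(genes) <= 4:
            raise ValueError("1-4 gene predictors required")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene predictors")
        bad = set(self.risk_factors) - _RISK_FACTORS
        if bad:
            raise ValueError(f"unknown risk factor(s): {sorted(bad)}")
        if len(set(self.risk_factors)) != len(self.risk_factors):
            raise ValueError("duplicate risk factors")

    @property
    def terms(self) -> list[str]:
        return list(self.gene_predictors) + list(self.risk_factors) + \
            ["age", "gender"]


@dataclass
class ModelFit:
    """A fitted binomial GLM with everything evaluation needs."""

    spec: ModelSpec | None
    params: pd.Series
    bse: pd.Series
    null_deviance: float
    deviance: float
    fitted: pd.Series          # probabilities, indexed by sample_id
    y: pd.Series               # observed labels (case=1)
    X: pd.DataFrame            # design actually used (complete cases)
    converged: bool

    def __post_init__(self):
        if self.converged:
            if self.deviance > self.null_deviance + 1e-8:
                raise ValueError("residual deviance exceeds null deviance")

    def predict(self, X_new: pd.DataFrame) -> pd.Series:
        eta = X_new[self.params.index].to_numpy() @ self.params.to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X_new.index)


def _model_frame(spec: ModelSpec, predictors: pd.DataFrame, sheet
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the design (complete cases) and response for a spec."""
    rows = sheet.rows if hasattr(sheet, "rows") else sheet
    df = rows.set_index("sample_id") if "sample_id" in rows else rows
    missing_genes = [g for g in spec.gene_predictors
                     if g not in predictors.columns]
    if missing_genes:
        raise KeyError(f"predictor column(s) absent: {missing_genes}")
    frame = pd.DataFrame(index=df.index)
    frame["intercept"] = 1.0
    for g in spec.gene_predictors:
        frame[g] = predictors.reindex(df.index)[g]
    for rf in spec.risk_factors:
        frame[rf] = df[rf].astype(float)
    frame["age"] = df["age"].astype(float) - df["age"].astype(float).mean()
    frame["gender"] = (df["gender"] == "male").astype(float)
    y = (df["group"] == "case").astype(float)
    complete = frame.notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("dropping %d sample(s) with incomplete model variables",
                    n_drop)
    return frame[complete], y[complete]


def _glm_binomial(y: np.ndarray, X: pd.DataFrame):
    """statsmodels binomial GLM fit, with separation handled as a flag."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError, PerfectSeparationWarning)

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except PerfectSeparationError:
            return None, False
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            converged = False
    if not res.converged or not np.isfinite(res.params).all() \
            or np.abs(res.params).max() > 1e3:
        converged = False
    return res, converged


def fit_logistic(spec: ModelSpec, predictors: pd.DataFrame, sheet
                 ) -> ModelFit:
    """Fit the diagnostic logistic model (case=1) by IRLS.

    ``predictors`` is a samples x genes table of log relative expression;
    covariates come from the sample sheet. Samples with any missing model
    variable are dropped (logged). Perfect separation is reported as a
    non-converged fit rather than an exception; a singular design raises.
    """
    X, y = _model_frame(spec, predictors, sheet)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    res, converged = _glm_binomial(y.to_numpy(), X)
    if res is None:
        nan = pd.Series(np.nan, index=X.columns)
        return ModelFit(spec=spec, params=nan, bse=nan,
                        null_deviance=np.nan, deviance=np.nan,
                        fitted=pd.Series(np.nan, index=X.index), y=y, X=X,
                        converged=False)
    if not converged:
        logger.warning("logistic fit flagged non-converged "
                       "(possible separation)")
    return ModelFit(
        spec=spec,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        null_deviance=float(res.null_deviance),
        deviance=float(res.deviance),
        fitted=pd.Series(np.clip(res.fittedvalues, 1e-12, 1 - 1e-12),
                         index=X.index),
        y=y, X=X, converged=converged)


def intercept_only_fit(fit: ModelFit) -> ModelFit:
    """The null model (intercept only) on the same samples."""
    X0 = fit.X[["intercept"]]
    res, converged = _glm_binomial(fit.y.to_numpy(), X0)
    return ModelFit(spec=None, params=pd.Series(res.params, index=X0.columns),
                    bse=pd.Series(res.bse, index=X0.columns),
                    null_deviance=float(res.null_deviance),
                    deviance=float(res.deviance),
                    fitted=pd.Series(res.fittedvalues, index=X0.index),
                    y=fit.y, X=X0, converged=converged)


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC.

    AUC is the Mann-Whitney statistic U/(n1*n0) with ties counted one half
    (the probability a random case outscores a random control). ROC points
    are emitted at every unique score threshold, anchored at (0,0) and
    (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep the last point of each tied-score block
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    thr = np.r_[np.inf, s_sorted[distinct]]
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, float(auc)


def classification_metrics(probabilities, labels, threshold: float = 0.5
                           ) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at ``p >= threshold`` = case."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    pred = (p >= threshold).astype(float)
    tp = float(((pred == 1) & (y == 1)).sum())
    tn = float(((pred == 0) & (y == 0)).sum())
    fp = float(((pred == 1) & (y == 0)).sum())
    fn = float(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y)
    return sens, spec, acc


def youden_threshold(probabilities, labels) -> float:
    """Probability cut maximizing sensitivity + specificity - 1."""
    points, _ = roc_auc(probabilities, labels)
    j = points["tpr"] - points["fpr"]
    best = points.loc[j.idxmax(), "threshold"]
    return float(best if np.isfinite(best) else 1.0)


def odds_ratio_iqr(fit: ModelFit, genes=None) -> pd.DataFrame:
    """Odds ratio per gene for an IQR-sized change in its predictor.

    OR_IQR = exp(beta_gene * IQR), IQR = Q3 - Q1 of the gene's predictor
    over the modelled samples (linear-interpolation quantiles). A negative
    coefficient (lower expression in cases) gives OR < 1. Zero IQR yields
    OR = 1 with a warning.
    """
    if not fit.converged:
        raise ValueError("odds ratios require a converged fit")
    genes = list(genes) if genes is not None else \
        list(fit.spec.gene_predictors)
    rows = []
    for g in genes:
        x = fit.X[g].to_numpy(dtype=float)
        q1, q3 = np.percentile(x, [25, 75])  # linear interpolation
        iqr = q3 - q1
        if iqr == 0:
            logger.warning("gene %s: zero IQR, OR set to 1", g)
            or_ = 1.0
        else:
            or_ = float(np.exp(fit.params[g] * iqr))
        z = fit.params[g] / fit.bse[g]
        rows.append({"gene": g, "beta": float(fit.params[g]),
                     "iqr": float(iqr), "or_iqr": or_,
                     "p_wald": float(2 * stats.norm.sf(abs(z)))})
    return pd.DataFrame(rows).set_index("gene")


def deviance_test(fit: ModelFit, null_fit: ModelFit | None = None) -> float:
    """One-tailed chi-squared test of the model against the null.

    By default the null is intercept-only on the same samples, so the test
    measures the joint contribution of genes and covariates. D =
    D_null - D_model is referred to chi-squared with df = number of
    non-intercept parameters difference.
    """
    if null_fit is None:
        null_fit = intercept_only_fit(fit)
    if len(null_fit.y) != len(fit.y):
        raise ValueError("null model fitted on different samples")
    D = null_fit.deviance - fit.deviance
    df = len(fit.params) - len(null_fit.params)
    if D < -1e-8:
        raise ValueError("negative deviance difference: models not nested "
                         "or fit did not converge")
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(max(D, 0.0), df))


@dataclass
class DiagnosticReport:
    """Full-data evaluation of one diagnostic model."""

    spec: ModelSpec
    fit: ModelFit
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    roc_points: pd.DataFrame
    or_iqr: pd.DataFrame
    p_model: float
    threshold: float

    @property
    def p_gene(self) -> pd.Series:
        return self.or_iqr["p_wald"]


def diagnostic_report(spec: ModelSpec, predictors: pd.DataFrame, sheet,
                      threshold: float | str = 0.5) -> DiagnosticReport:
    """Fit a model and compute the full metric panel.

    ``threshold`` is the probability cut for sensitivity/specificity/
    accuracy: a float (default 0.5) or "youden" for the Youden-optimal cut
    on the fitted probabilities.
    """
    fit = fit_logistic(spec, predictors, sheet)
    if not fit.converged:
        raise ValueError("model did not converge; no report")
    probs = fit.fitted.to_numpy()
    y = fit.y.to_numpy()
    points, auc = roc_auc(probs, y)
    thr = youden_threshold(probs, y) if threshold == "youden" \
        else float(threshold)
    sens, spec_, acc = classification_metrics(probs, y, threshold=thr)
    return DiagnosticReport(
        spec=spec, fit=fit, sensitivity=sens, specificity=spec_,
        accuracy=acc, auc=auc, roc_points=points,
        or_iqr=odds_ratio_iqr(fit), p_model=deviance_test(fit),
        threshold=thr)


@dataclass
class CVReport:
    """Stratified repeated k-fold cross-validation summary."""

    per_eval: pd.DataFrame      # repeat, fold, auc, sens, spec, acc
    summary: pd.DataFrame       # mean and sd per metric over all evals
    n_repeats: int
    n_folds: int
    n_nonconverged: int
    fold_composition: pd.DataFrame
    seed: int


def _deal_folds(rng: np.random.Generator, ids: np.ndarray, n_folds: int
                ) -> list[np.ndarray]:
    """Shuffle one class and deal round-robin; fold sizes differ by <= 1."""
    perm = rng.permutation(ids)
    return [perm[k::n_folds] for k in range(n_folds)]


def cross_validate(spec: ModelSpec, predictors: pd.DataFrame, sheet,
                   n_folds: int = 5, n_repeats: int = 1000,
                   min_per_fold: dict[str, int] | None = None,
                   threshold: float = 0.5, seed: int = 0) -> CVReport:
    """Stratified repeated k-fold CV of a diagnostic model.

    Each repeat shuffles cases and controls separately and deals each
    class round-robin into ``n_folds`` bins, so per-class fold sizes
    differ by at most one and every test fold contains both classes. The
    model is trained on k-1 bins and evaluated (AUC, sensitivity,
    specificity, accuracy at ``threshold``) on the held-out bin; metrics
    are pooled over all repeat x fold evaluations for the mean/SD summary.
    Non-converged training fits are excluded from the pool and counted.

    ``min_per_fold`` (e.g. ``{"case": 10, "control": 4}``) asserts the
    smallest admissible per-class fold size; an error lists any shortfall
    before any work is done.
    """
    X_all, y_all = _model_frame(spec, predictors, sheet)
    ids = X_all.index.to_numpy()
    case_ids = ids[y_all.to_numpy() == 1]
    ctrl_ids = ids[y_all.to_numpy() == 0]
    if min_per_fold:
        shortfall = {}
        for cls, ids_cls in (("case", case_ids), ("control", ctrl_ids)):
            need = min_per_fold.get(cls, 0)
            have = len(ids_cls) // n_folds
            if have < need:
                shortfall[cls] = (have, need)
        if shortfall:
            raise ValueError(f"cohort too small for fold minima: "
                             f"{shortfall} (have, required) per fold")
    rng = np.random.default_rng(seed)
    evals, comp_rows = [], []
    n_fail = 0
    for rep in range(n_repeats):
        case_folds = _deal_folds(rng, case_ids, n_folds)
        ctrl_folds = _deal_folds(rng, ctrl_ids, n_folds)
        for k in range(n_folds):
            test_ids = np.concatenate([case_folds[k], ctrl_folds[k]])
            train_mask = ~X_all.index.isin(test_ids)
            X_tr, y_tr = X_all[train_mask], y_all[train_mask]
            X_te, y_te = X_all.loc[test_ids], y_all.loc[test_ids]
            comp_rows.append({"repeat": rep, "fold": k,
                              "n_case": len(case_folds[k]),
                              "n_control": len(ctrl_folds[k])})
            res, converged = _glm_binomial(y_tr.to_numpy(), X_tr)
            if res is None or not converged:
                n_fail += 1
                continue
            eta = X_te.to_numpy() @ np.asarray(res.params)
            probs = 1.0 / (1.0 + np.exp(-eta))
            _, auc = roc_auc(probs, y_te.to_numpy())
            sens, spec_, acc = classification_metrics(
                probs, y_te.to_numpy(), threshold=threshold)
            evals.append({"repeat": rep, "fold": k, "auc": auc,
                          "sensitivity": sens, "specificity": spec_,
                          "accuracy": acc})
    per_eval = pd.DataFrame(evals)
    metrics = ["auc", "sensitivity", "specificity", "accuracy"]
    if len(per_eval):
        summary = pd.DataFrame({"mean": per_eval[metrics].mean(),
                                "sd": per_eval[metrics].std(ddof=1)})
    else:
        summary = pd.DataFrame({"mean": pd.Series(np.nan, index=metrics),
                                "sd": pd.Series(np.nan, index=metrics)})
    if n_fail:
        logger.warning("%d of %d fold fits non-converged and excluded",
                       n_fail, n_repeats * n_folds)
    return CVReport(per_eval=per_eval, summary=summary, n_repeats=n_repeats,
                    n_folds=n_folds, n_nonconverged=n_fail,
                    fold_composition=pd.DataFrame(comp_rows), seed=seed)
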