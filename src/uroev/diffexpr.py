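"""Covariate-adjusted negative-binomial differential region expression.

The model follows the DESeq-style parameterization: counts K_ij for region
i and sample j are NB with mean mu_ij = s_j * q_ij and variance
mu + alpha_i * mu^2, where s_j is a median-of-ratios size factor and
log q_ij = x_j' beta_i with design columns (intercept, status, gender,
age-centered). The status coefficient, reported on the log2 scale, is the
case-vs-control fold change adjusted for gender and age; inference is a
Wald z-test with Benjamini-Hochberg correction across regions.

Dispersion estimation is a deliberately simple two-step scheme: a per-region
method-of-moments estimate on normalized counts with design effects removed,
shrunk toward a 1/mu + constant trend fitted robustly across regions
(geometric-mean averaging). There is no Cox-Reid adjustment, outlier
handling, independent filtering or fold-change shrinkage; the contract is
simulation calibration (type-I error, FDR), not numeric identity with any
particular reference tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "build_design",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "adjust_bh",
    "log_transform",
    "pca",
    "hierarchical_cluster",
    "differential_expression",
]

_LN2 = np.log(2.0)
_ALPHA_FLOOR = 1e-8


def build_design(sheet) -> pd.DataFrame:
    """Design matrix: intercept, status (case=1), gender (male=1), age centered.

    Control and female are the reference levels, so a negative status
    coefficient means lower expression in cases.
    """
    df = sheet.rows if hasattr(sheet, "rows") else sheet
    index = pd.Index(df["sample_id"]) if "sample_id" in df else df.index
    X = pd.DataFrame({
        "intercept": np.ones(len(df)),
        "status": (df["group"] == "case").to_numpy(dtype=float),
        "gender": (df["gender"] == "male").to_numpy(dtype=float),
        "age": (df["age"].astype(float)
                - df["age"].astype(float).mean()).to_numpy(),
    }, index=index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only regions with nonzero counts in every sample enter the geometric
    reference (the standard median-of-ratios restriction).
    """
    c = np.asarray(counts.counts if hasattr(counts, "counts") else counts,
                   dtype=float)
    all_pos = (c > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no region with nonzero counts in all samples; "
                         "apply the expression filter first")
    ref = c[all_pos]
    log_geo = np.mean(np.log(ref), axis=1)
    s = np.exp(np.median(np.log(ref) - log_geo[:, None], axis=0))
    return s / np.exp(np.mean(np.log(s)))


def estimate_dispersion(counts, s: np.ndarray, design: pd.DataFrame,
                        ) -> np.ndarray:
    """Per-region NB dispersion alpha_i (variance = mu + alpha mu^2).

    Method-of-moments on size-factor-normalized counts with design effects
    removed by OLS, then geometric-mean shrinkage toward a robustly fitted
    a1/mu + a0 trend. With fewer than 10 regions the trend fit is refused
    and the raw estimates are used with a warning.
    """
    c = np.asarray(counts.counts if hasattr(counts, "counts") else counts,
                   dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    norm = c / s[None, :]
    mu_bar = norm.mean(axis=1)
    # hat matrix for removing design-explained variation
    H = X @ np.linalg.solve(X.T @ X, X.T)
    resid = norm - norm @ H.T
    var = (resid ** 2).sum(axis=1) / max(n - p, 1)
    xim = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (var - xim * mu_bar) / mu_bar ** 2
    alpha_hat = np.where(np.isfinite(alpha_hat), alpha_hat, 0.0)
    alpha_hat = np.maximum(alpha_hat, 0.0)
    alpha_pos = np.maximum(alpha_hat, _ALPHA_FLOOR)

    R = len(mu_bar)
    if R < 10:
        logger.warning("only %d regions: dispersion trend fit refused, "
                       "using raw method-of-moments estimates", R)
        return alpha_pos

    usable = (mu_bar > 0) & (alpha_hat > _ALPHA_FLOOR)
    if usable.sum() >= 10:
        import statsmodels.api as sm
        Z = np.column_stack([np.ones(usable.sum()), 1.0 / mu_bar[usable]])
        rlm = sm.RLM(alpha_hat[usable], Z, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = rlm.params
    else:
        a0, a1 = float(np.median(alpha_pos)), 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu_bar > 0, mu_bar, np.inf)
    trend = np.maximum(trend, _ALPHA_FLOOR)
    final = np.exp(0.5 * np.log(alpha_pos) + 0.5 * np.log(trend))
    return np.maximum(final, _ALPHA_FLOOR)


def _nb_deviance(y, mu, alpha):
    """Unit NB deviance summed over samples (rows = regions)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        a = np.where(alpha > 1e-12, alpha, 1e-12)[:, None]
        term2 = (y + 1.0 / a) * np.log((1.0 + a * mu) / (1.0 + a * y))
    return 2.0 * (term1 + term2).sum(axis=1)


def _fit_nb_glm_batch(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                      alpha: np.ndarray, max_iter: int = 100,
                      tol: float = 1e-8):
    """Vectorized IRLS over regions sharing one design matrix.

    y: (R, n) counts; X: (n, p); offset: (n,) log size factors;
    alpha: (R,) dispersions. Returns (beta (R,p), se (R,p),
    converged (R,) bool, mu (R,n)).
    """
    R, n = y.shape
    p = X.shape[1]
    # initial working response: log of normalized counts
    z0 = np.log(y + 0.5) - offset[None, :]
    pinv = np.linalg.pinv(X)
    beta = z0 @ pinv.T
    converged = np.zeros(R, dtype=bool)
    active = np.ones(R, dtype=bool)
    dev_old = np.full(R, np.inf)
    mu_full = np.empty_like(z0)
    a = alpha
    for _ in range(max_iter):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        mu_full[idx] = mu
        W = mu / (1.0 + a[idx][:, None] * mu)
        z = (eta - offset[None, :]) + (y[idx] - mu) / mu
        XtWX = np.einsum("rn,np,nq->rpq", W, X, X, optimize=True)
        XtWz = np.einsum("rn,np->rp", W * z, X, optimize=True)
        # ridge jitter for numerically singular systems
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.einsum("rpq,rq->rp", np.linalg.pinv(XtWX), XtWz)
        bad = ~np.isfinite(new_beta).all(axis=1)
        new_beta[bad] = beta[idx][bad]
        beta[idx] = new_beta
        dev = _nb_deviance(y[idx], np.exp(np.clip(new_beta @ X.T
                                                  + offset[None, :],
                                                  -30, 30)), a[idx])
        rel = np.abs(dev - dev_old[idx]) / (np.abs(dev) + 0.1)
        done = rel < tol
        converged[idx[done]] = True
        dev_old[idx] = dev
        active[idx[done]] = False
    # final mu and standard errors from the expected information X'WX
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu_full = np.exp(eta)
    W = mu_full / (1.0 + a[:, None] * mu_full)
    XtWX = np.einsum("rn,np,nq->rpq", W, X, X, optimize=True)
    XtWX += 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.maximum(np.einsum("rpp->rp", cov), 0.0))
    return beta, se, converged, mu_full


def nb_wald_test(counts, s: np.ndarray, alpha: np.ndarray,
                 design: pd.DataFrame, coef: str = "status",
                 max_iter: int = 100, tol: float = 1e-8) -> pd.DataFrame:
    """Per-region NB GLM Wald test for the given design coefficient.

    Returns a DataFrame (index = region keys when available) with columns
    base_mean, log2fc, se_log2fc, wald_z, p_value, p_adjusted and
    converged. Non-converged regions get missing p-values and are excluded
    from the BH correction.
    """
    c = counts.counts if hasattr(counts, "counts") else counts
    index = c.index if isinstance(c, pd.DataFrame) else pd.RangeIndex(len(c))
    y = np.asarray(c, dtype=float)
    X = np.asarray(design, dtype=float)
    cols = list(design.columns)
    if coef not in cols:
        raise ValueError(f"coefficient {coef!r} not in design columns {cols}")
    j = cols.index(coef)
    offset = np.log(np.asarray(s, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    if (alpha < 0).any():
        raise ValueError("dispersions must be non-negative")
    beta, se, converged, mu = _fit_nb_glm_batch(
        y, X, offset, np.maximum(alpha, _ALPHA_FLOOR),
        max_iter=max_iter, tol=tol)
    n_fail = int((~converged).sum())
    if n_fail:
        logger.warning("%d region fit(s) did not converge; their p-values "
                       "are set missing", n_fail)
    log2fc = beta[:, j] / _LN2
    se2 = se[:, j] / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, j] / se[:, j]
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(converged & np.isfinite(z), p, np.nan)
    out = pd.DataFrame({
        "base_mean": (y / s[None, :]).mean(axis=1),
        "log2fc": log2fc,
        "se_log2fc": se2,
        "wald_z": z,
        "p_value": p,
        "p_adjusted": adjust_bh(p),
        "converged": converged,
    }, index=index)
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing p excluded from m."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def log_transform(tpm, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(tpm + pseudocount); errors on negative input."""
    from .regions import TPMMatrix

    if isinstance(tpm, TPMMatrix):
        df = tpm.values
    elif isinstance(tpm, pd.DataFrame):
        df = tpm
    else:
        df = pd.DataFrame(np.asarray(tpm, dtype=float))
    if (df.to_numpy() < 0).any():
        raise ValueError("log_transform requires non-negative input")
    return np.log2(df + pseudocount)


def pca(matrix: pd.DataFrame, n_components: int | None = None):
    """PCA with samples as observations and regions as features.

    ``matrix`` is regions x samples (the orientation of the expression
    tables here); it is transposed internally. Columns are centered, not
    scaled. Component signs follow the largest-absolute-loading-positive
    convention so results are reproducible across SVD implementations.

    Returns (scores, loadings, variance_explained): scores is samples x
    PCs, loadings regions x PCs, and variance_explained fractions of total
    variance (sums to <= 1 over returned components).
    """
    X = matrix.T  # samples x regions
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    obs_index, feat_index = X.index, X.columns
    A = X.to_numpy(dtype=float)
    means = A.mean(axis=0)
    A = A - means[None, :]
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    k = n_components or min(A.shape)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest |loading| positive per component
    for i in range(k):
        jmax = np.argmax(np.abs(Vt[i]))
        if Vt[i, jmax] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total_var = (A ** 2).sum()
    var_exp = (S ** 2) / total_var if total_var > 0 else np.zeros(k)
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * S[None, :], index=obs_index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=feat_index, columns=pcs)
    return scores, loadings, var_exp


def hierarchical_cluster(matrix: pd.DataFrame):
    """Complete-linkage agglomerative clustering on Euclidean sample distance.

    ``matrix`` is regions x samples; returns (linkage, sample_ids) where
    linkage is the scipy (n-1) x 4 merge-tree encoding. Deterministic for a
    given sample order (ties resolved by scipy's ordering).
    """
    X = matrix.T.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    Z = sch.linkage(X, method="complete", metric="euclidean")
    return Z, list(matrix.columns)


@dataclass
class DEOutput:
    """Full differential-expression stage output."""

    result: pd.DataFrame          # per-region DE table (sorted by p)
    size_factors: np.ndarray
    dispersions: np.ndarray
    design: pd.DataFrame


def differential_expression(counts, sheet, annotation=None,
                            coef: str = "status") -> DEOutput:
    """End-to-end DE stage: size factors, dispersion, Wald test, BH, labels."""
    from .regions import annotate_regions

    design = build_design(sheet)
    # align design rows to count columns
    design = design.loc[counts.sample_ids]
    s = size_factors(counts)
    alpha = estimate_dispersion(counts, s, design)
    res = nb_wald_test(counts, s, alpha, design, coef=coef)
    if annotation is not None:
        labels = annotate_regions(counts.regions, annotation)
        res = res.join(labels.rename("genes"))
    res = res.sort_values("p_value", kind="stable")
    return DEOutput(result=res, size_factors=s, dispersions=alpha,
                    design=design)
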