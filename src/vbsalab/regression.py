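"""Per-view linear models WBSA ~ VBSA (+ measurements) and their validation.

The core model is ordinary least squares for, per camera angle (theta, phi),

    WBSA_i = c1 * VBSA_i(theta, phi) + c0            (single predictor)
    WBSA_i = c1 * VBSA_i + c2 * stature_i + ... + c0 (multi predictor)

validated by seeded k-fold cross-validation (k = 10 by default) with pooled
prediction errors: RMSE and MSPE in dm^2 / dm^4, MAPE in percent.  Variable
association is summarised with Spearman rank correlations (average ranks on
ties) and residuals are checked for normality / homoscedasticity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.diagnostic import het_breuschpagan

logger = logging.getLogger(__name__)

__all__ = [
    "AngleFit",
    "CorrelationMatrix",
    "fit_linear",
    "cross_validate",
    "spearman_matrix",
    "fit_by_group",
    "residual_diagnostics",
]


@dataclass
class AngleFit:
    """Per-(theta, phi) regression coefficients and CV error metrics."""

    theta: float
    phi: float
    coefficients: dict[str, float]   # {"c0": intercept, "c1": vbsa, ...}
    residual_se: float               # dm^2
    cv_rmse: float                   # dm^2
    cv_mspe: float                   # dm^4
    cv_mape: float                   # percent
    n: int
    group: str = "all"
    t_values: dict[str, float] = field(default_factory=dict)


@dataclass
class CorrelationMatrix:
    names: list[str]
    rho: np.ndarray                   # pairwise Spearman rho
    undefined: list[str] = field(default_factory=list)  # constant columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.names, columns=self.names)


def _design(vbsa: np.ndarray, extra: dict[str, np.ndarray] | None
            ) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(vbsa), vbsa]
    names = ["c0", "c1"]
    if extra:
        for k, (name, vals) in enumerate(extra.items(), start=2):
            cols.append(np.asarray(vals, dtype=float))
            names.append(f"c{k}_{name}")
    return np.stack(cols, axis=1), names


def fit_linear(vbsa, wbsa, extra_predictors: dict | None = None
               ) -> dict[str, float]:
    """OLS coefficients for WBSA = c1*VBSA (+ extras) + c0.

    Solved by orthogonal decomposition (SVD least squares), not the normal
    equations, for conditioning.  A rank-deficient design raises, naming the
    collinear columns.
    """
    vbsa = np.asarray(vbsa, dtype=float)
    wbsa = np.asarray(wbsa, dtype=float)
    X, names = _design(vbsa, extra_predictors)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(wbsa))):
        raise ValueError("non-finite values in the regression inputs")
    if len(wbsa) <= X.shape[1] - 1:
        raise ValueError("need more observations than predictors")
    coef, _, rank, _ = np.linalg.lstsq(X, wbsa, rcond=None)
    if rank < X.shape[1]:
        # identify offending columns from the pivoted QR diagonal
        _, Rq = np.linalg.qr(X)
        diag = np.abs(np.diag(Rq))
        bad = [names[i] for i in range(len(names))
               if diag[i] < 1e-10 * max(diag.max(), 1.0)]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (collinear columns: {bad or names})")
    return dict(zip(names, coef))


def _predict(X: np.ndarray, coef: np.ndarray) -> np.ndarray:
    return X @ coef


def cross_validate(vbsa, wbsa, extra_predictors: dict | None = None,
                   k: int = 10, seed: int = 0, theta: float = 0.0,
                   phi: float = 0.0, group: str = "all") -> AngleFit:
    """Seeded k-fold CV of the linear model; pooled prediction errors.

    Folds are a uniform random permutation split into k near-equal parts.
    RMSE = sqrt(mean squared held-out error), MSPE = mean squared error,
    MAPE = mean(|err| / truth) * 100, all pooled over the k held-out sets.
    """
    vbsa = np.asarray(vbsa, dtype=float)
    wbsa = np.asarray(wbsa, dtype=float)
    n = len(wbsa)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must not exceed the number of subjects")
    X, names = _design(vbsa, extra_predictors)
    p = X.shape[1]

    coef_all = fit_linear(vbsa, wbsa, extra_predictors)
    c = np.array([coef_all[nm] for nm in names])
    resid = wbsa - _predict(X, c)
    dof = max(n - p, 1)
    residual_se = float(np.sqrt(resid @ resid / dof))
    # classical OLS t-values
    XtX_inv = np.linalg.pinv(X.T @ X)
    se_coef = residual_se * np.sqrt(np.maximum(np.diag(XtX_inv), 0.0))
    t_values = {nm: float(c[i] / se_coef[i]) if se_coef[i] > 0 else np.inf
                for i, nm in enumerate(names)}

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    sq_err = np.empty(n)
    abs_rel = np.empty(n)
    for train, test in kf.split(X):
        cf, _, _, _ = np.linalg.lstsq(X[train], wbsa[train], rcond=None)
        pred = _predict(X[test], cf)
        err = wbsa[test] - pred
        sq_err[test] = err ** 2
        abs_rel[test] = np.abs(err) / np.abs(wbsa[test])
    mspe = float(np.mean(sq_err))
    return AngleFit(
        theta=theta, phi=phi, coefficients=coef_all,
        residual_se=residual_se,
        cv_rmse=float(np.sqrt(mspe)), cv_mspe=mspe,
        cv_mape=float(np.mean(abs_rel) * 100.0),
        n=n, group=group, t_values=t_values,
    )


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman rank correlations (average ranks on ties).

    Constant columns have no defined rank correlation: they are flagged in
    ``undefined`` and their entries set to NaN rather than silently zeroed.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows")
    names = list(num.columns)
    constant = [c for c in names if np.ptp(num[c].to_numpy()) == 0]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(num.to_numpy(), axis=0).statistic
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:  # scipy collapses the two-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    for c in constant:
        i = names.index(c)
        rho[i, :] = np.nan
        rho[:, i] = np.nan
        rho[i, i] = np.nan
    return CorrelationMatrix(names, rho, undefined=constant)


def fit_by_group(frame: pd.DataFrame, grouping: str,
                 vbsa_col: str = "vbsa_gt", wbsa_col: str = "wbsa",
                 extra_cols: list[str] | None = None, k: int = 10,
                 seed: int = 0, theta: float = 0.0, phi: float = 0.0,
                 min_margin: int = 2) -> list[AngleFit]:
    """Independent fit + CV per partition of the subjects.

    Groups smaller than (number of coefficients + ``min_margin``) are skipped
    with a logged warning rather than producing a meaningless fit.
    """
    if grouping not in frame.columns:
        raise ValueError(f"grouping column {grouping!r} not in table")
    if frame[grouping].nunique() == 0:
        raise ValueError("empty grouping")
    fits = []
    p = 2 + (len(extra_cols) if extra_cols else 0)
    for label, sub in frame.groupby(grouping, sort=True):
        if len(sub) < p + min_margin:
            logger.warning("group %r skipped: n=%d < %d", label, len(sub),
                           p + min_margin)
            continue
        extra = ({c: sub[c].to_numpy() for c in extra_cols}
                 if extra_cols else None)
        n_eff = min(k, len(sub))
        fits.append(cross_validate(sub[vbsa_col].to_numpy(),
                                   sub[wbsa_col].to_numpy(), extra,
                                   k=n_eff, seed=seed, theta=theta, phi=phi,
                                   group=str(label)))
    return fits


def residual_diagnostics(fit: AngleFit, vbsa, wbsa,
                         extra_predictors: dict | None = None
                         ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Residual table for QQ / scale plots plus a heteroscedasticity test.

    Returns (table, stats) where the table holds residuals, standardized
    residuals and theoretical normal quantiles, and stats carries the
    Breusch-Pagan LM statistic and p-value for a variance trend in the
    fitted values.
    """
    vbsa = np.asarray(vbsa, dtype=float)
    wbsa = np.asarray(wbsa, dtype=float)
    X, names = _design(vbsa, extra_predictors)
    c = np.array([fit.coefficients[nm] for nm in names])
    fitted = _predict(X, c)
    resid = wbsa - fitted
    sd = resid.std(ddof=X.shape[1]) or 1.0
    std_resid = resid / sd
    n = len(resid)
    order = np.argsort(np.argsort(resid))
    theo_q = stats.norm.ppf((order + 1 - 0.375) / (n + 0.25))
    table = pd.DataFrame({
        "fitted": fitted,
        "residual": resid,
        "std_residual": std_resid,
        "theoretical_quantile": theo_q,
    })
    if np.allclose(resid, 0.0, atol=1e-12):
        bp = {"bp_stat": 0.0, "bp_pvalue": 1.0}
    else:
        lm, lm_p, _, _ = het_breuschpagan(resid, X)
        bp = {"bp_stat": float(lm), "bp_pvalue": float(lm_p)}
    return table, bp


def fits_to_frame(fits: list[AngleFit]) -> pd.DataFrame:
    """Machine-readable fit table: one row per (group, theta, phi)."""
    rows = []
    for f in fits:
        row = {"theta": f.theta, "phi": f.phi, "group": f.group, "n": f.n}
        row.update(f.coefficients)
        row.update({f"t_{k}": v for k, v in f.t_values.items()})
        row.update({"se": f.residual_se, "cv_rmse": f.cv_rmse,
                    "cv_mspe": f.cv_mspe, "cv_mape": f.cv_mape})
        rows.append(row)
    return pd.DataFrame(rows)
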