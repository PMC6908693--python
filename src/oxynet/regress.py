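"""Log-log regression machinery for density dependence.

Simple OLS, variance-inflation screening, backward elimination and the
environmental-covariate models, all on log10-transformed data.  Fits are
performed with statsmodels OLS; results are repackaged into a compact
:class:`RegressionResult` that carries slope(s), intercept, adjusted R²,
F, degrees of freedom and the labels of excluded observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    slopes: dict[str, float]
    intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    df_model: int
    df_resid: int
    p_value: float
    n: int
    coef_p: dict[str, float] = field(default_factory=dict)
    excluded: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        """Single slope, for simple regressions."""
        if len(self.slopes) != 1:
            raise ValueError("multiple slopes; use .slopes")
        return next(iter(self.slopes.values()))

    def slope_ci(self, name: str | None = None, level: float = 0.95) -> tuple[float, float]:
        name = name if name is not None else next(iter(self.slopes))
        se = self.diagnostics["bse"][name]
        t = stats.t.ppf(0.5 + level / 2.0, self.df_resid)
        b = self.slopes[name]
        return (b - t * se, b + t * se)


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)  # (step, dropped, p, adj_r2_after)


def log10_series(raw: pd.Series, label: str = "") -> pd.Series:
    """log10 transform dropping non-positive values with a warning."""
    s = pd.Series(raw).astype(float)
    bad = s.index[(s <= 0) | s.isna()]
    if len(bad):
        log.warning("dropping %d non-positive/missing values from %s", len(bad), label)
    return np.log10(s.drop(bad))


def ln_series(raw: pd.Series, label: str = "") -> pd.Series:
    """Natural-log transform dropping non-positive values with a warning.

    The density-dependence fits use the natural-log scale so their
    intercepts are directly comparable with the planted values; the slope,
    R², F and df are identical in any log base.
    """
    s = pd.Series(raw).astype(float)
    bad = s.index[(s <= 0) | s.isna()]
    if len(bad):
        log.warning("dropping %d non-positive/missing values from %s", len(bad), label)
    return np.log(s.drop(bad))


def _fit(y: pd.Series, X: pd.DataFrame) -> tuple[sm.regression.linear_model.RegressionResultsWrapper, pd.DataFrame]:
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.OLS(y, Xc).fit()
    return model, Xc


def _package(model, X: pd.DataFrame, excluded: list) -> RegressionResult:
    names = [c for c in model.params.index if c != "const"]
    resid = model.resid
    diag = {
        "bse": {k: float(model.bse[k]) for k in model.params.index},
        "shapiro_p": float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan,
    }
    if names:
        try:
            bp = sm.stats.diagnostic.het_breuschpagan(resid, sm.add_constant(X, has_constant="add"))
            diag["breusch_pagan_p"] = float(bp[1])
        except Exception:  # degenerate designs
            diag["breusch_pagan_p"] = np.nan
    return RegressionResult(
        slopes={k: float(model.params[k]) for k in names},
        intercept=float(model.params.get("const", np.nan)),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        f_stat=float(model.fvalue) if names else 0.0,
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        p_value=float(model.f_pvalue) if names else 1.0,
        n=int(model.nobs),
        coef_p={k: float(model.pvalues[k]) for k in names},
        excluded=list(excluded),
        diagnostics=diag,
    )


def fit_simple(x: pd.Series, y: pd.Series, excluded: list | None = None) -> RegressionResult:
    """OLS of y on a single predictor (both already log-transformed).

    Reports adjusted R² = 1 - (1-R²)(N-1)/(N-2), the F statistic with
    (1, N-2) degrees of freedom and its two-tailed p.
    """
    x, y = pd.Series(x).astype(float), pd.Series(y).astype(float)
    common = x.index.intersection(y.index)
    x, y = x.loc[common].dropna(), y.loc[common]
    common = x.index.intersection(y.dropna().index)
    x, y = x.loc[common], y.loc[common]
    if len(x) < 3:
        raise DataError("simple regression needs N >= 3")
    if np.isclose(x.std(ddof=0), 0):
        raise DataError("constant predictor")
    name = x.name if x.name is not None else "x"
    model, _ = _fit(y, x.to_frame(name))
    return _package(model, x.to_frame(name), excluded or [])


def exclude_outliers(x: pd.Series, y: pd.Series, bound: float = 1.96) -> tuple[pd.Index, pd.DataFrame]:
    """Drop observations outside the 95% residual interval of a first-pass fit.

    A preliminary simple OLS is fitted; observations whose internally
    studentized residual magnitude exceeds ``bound`` (two-tailed 95% normal
    bound by default) are excluded.  Returns (retained index, table of
    dropped observations with their studentized residuals).
    """
    x, y = pd.Series(x).astype(float), pd.Series(y).astype(float)
    common = x.dropna().index.intersection(y.dropna().index)
    x, y = x.loc[common], y.loc[common]
    if len(x) < 5:
        raise DataError("outlier screen needs N >= 5")
    model, Xc = _fit(y, x.to_frame(x.name or "x"))
    if model.ssr <= 1e-12 * max(1.0, float((y ** 2).sum())):
        return x.index, pd.DataFrame(columns=["studentized_residual", "reason"])
    infl = model.get_influence()
    student = pd.Series(infl.resid_studentized_internal, index=x.index)
    dropped = student.index[student.abs() > bound]
    table = pd.DataFrame(
        {"studentized_residual": student.loc[dropped],
         "reason": [f"|t|={abs(v):.2f} > {bound}" for v in student.loc[dropped]]}
    )
    return x.index.difference(dropped), table


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_k = 1 / (1 - R²_k).

    R²_k comes from regressing predictor k on all the others (with
    intercept).  Perfect collinearity yields +inf.
    """
    X = pd.DataFrame(predictors).astype(float).dropna()
    if X.shape[1] < 2:
        raise DataError("VIF needs >= 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise DataError("VIF needs N > number of predictors")
    out = {}
    for k in X.columns:
        others = X.drop(columns=k)
        model, _ = _fit(X[k], others)
        r2 = min(model.rsquared, 1.0)
        out[k] = np.inf if np.isclose(r2, 1.0, atol=1e-12) else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_screen(predictors: pd.DataFrame, limit: float = 10.0) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the max-VIF predictor while any VIF exceeds ``limit``."""
    X = pd.DataFrame(predictors).astype(float)
    removed: list[str] = []
    while X.shape[1] >= 2:
        v = vif(X)
        worst = v.sort_values(ascending=False, kind="stable")
        if worst.iloc[0] <= limit:
            break
        # ties: larger VIF first, then alphabetical
        top = worst[np.isclose(worst, worst.iloc[0]) | (worst == worst.iloc[0])]
        drop = sorted(top.index)[0]
        removed.append(drop)
        X = X.drop(columns=drop)
    return X, removed


def backward_select(
    y: pd.Series, predictors: pd.DataFrame, alpha: float = 0.05
) -> tuple[RegressionResult, SelectionTrace]:
    """Backward elimination: drop the least significant predictor until all
    surviving coefficients have p <= alpha.

    Ties break by larger p then alphabetical label.  If everything is
    dropped an intercept-only model is returned with a warning.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(predictors).astype(float)
    keep = y.dropna().index.intersection(X.dropna().index)
    y, X = y.loc[keep], X.loc[keep]
    if len(y) <= X.shape[1] + 1:
        raise DataError("backward selection needs N > predictors + 1")
    trace = SelectionTrace()
    step = 0
    while X.shape[1] > 0:
        model, _ = _fit(y, X)
        pvals = model.pvalues.drop("const", errors="ignore")
        worst_p = pvals.max()
        if worst_p <= alpha:
            return _package(model, X, []), trace
        candidates = sorted(pvals.index[np.isclose(pvals, worst_p) | (pvals == worst_p)])
        drop = candidates[0]
        X = X.drop(columns=drop)
        step += 1
        if X.shape[1] > 0:
            after, _ = _fit(y, X)
            adj = float(after.rsquared_adj)
        else:
            adj = 0.0
        trace.steps.append((step, drop, float(worst_p), adj))
    warnings.warn("all predictors eliminated; returning intercept-only model", stacklevel=2)
    model, _ = _fit(y, pd.DataFrame(index=y.index))
    return _package(model, pd.DataFrame(index=y.index), []), trace


def fit_environment(
    y: pd.Series,
    env: pd.DataFrame,
    density: pd.Series,
    alpha: float = 0.05,
    vif_limit: float = 10.0,
) -> tuple[RegressionResult, SelectionTrace, list[str]]:
    """Environmental-covariate model: VIF screen then backward selection.

    ``density`` is appended to the environmental predictors; all series
    must already be on their analysis scale (log10 where appropriate).
    """
    X = pd.DataFrame(env).copy()
    X["density"] = pd.Series(density)
    keep = pd.Series(y).dropna().index.intersection(X.dropna().index)
    X = X.loc[keep]
    screened, removed = vif_screen(X, vif_limit)
    result, trace = backward_select(pd.Series(y).loc[keep], screened, alpha)
    return result, trace, removed
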