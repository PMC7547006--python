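"""Linear feature-selection models on the standardized covariate table.

Four fits are supported, mirroring common variable-screening practice for
ecological regressions: an ordinary Gaussian GLM, ridge and lasso regression
(penalty chosen by tenfold cross-validation), and bidirectional stepwise
search minimising the AIC.  Variable importance is the per-covariate
absolute t-statistic normalised to sum to 100%; for the penalized fits the
t-statistics come from an OLS refit on the active set, since penalized
estimators carry no canonical t-statistic.

All estimators are scikit-learn compatible (``get_params``/``set_params``,
fitted attributes with trailing underscores) and accept a DataFrame or array
design that is assumed pre-standardised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "GLMSelector",
    "RidgeSelector",
    "LassoSelector",
    "StepwiseAICSelector",
    "fit_ols_glm",
    "fit_ridge",
    "fit_lasso",
    "fit_step_aic",
    "variable_importance",
    "importance_table",
]

#: AIC convention used throughout this module (recorded on every fit):
#: n * log(RSS / n) + 2 * (p + 1), where p counts slopes + intercept and the
#: +1 is the error variance.  Differences of AICs are what matter, so the
#: additive Gaussian constant is dropped.
AIC_CONVENTION = "n*log(RSS/n) + 2*(p+1), Gaussian constant dropped"


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if len(ya) != Xa.shape[0]:
        raise ValueError("X and y have incompatible lengths")
    return Xa, ya, names


def _ols_aic(rss: float, n: int, p_slopes: int) -> float:
    return n * np.log(rss / n) + 2 * (p_slopes + 1)


def _ols_fit(Xa, ya, cols):
    """OLS on the selected columns (with intercept); returns coef, se, t, rss."""
    design = sm.add_constant(Xa[:, cols], has_constant="add")
    res = sm.OLS(ya, design).fit()
    return res


class _BaseSelector(BaseEstimator, RegressorMixin):
    """Shared prediction/importance plumbing for the four linear fits."""

    method: str = ""

    def predict(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
        return self.intercept_ + Xa @ self.coef_

    def _finalize(self, names, coef, intercept, se, t, aic, selected):
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = float(intercept)
        self.standard_errors_ = np.asarray(se, dtype=float)
        self.t_statistics_ = np.asarray(t, dtype=float)
        self.aic_ = float(aic)
        self.selected_ = tuple(selected)
        self.aic_convention_ = AIC_CONVENTION
        return self

    def variable_importance(self) -> pd.Series:
        return variable_importance(self)


class GLMSelector(_BaseSelector):
    """Ordinary Gaussian GLM (least squares) with t-statistics and AIC."""

    method = "glm"

    def fit(self, X, y):
        Xa, ya, names = _as_xy(X, y)
        n, p = Xa.shape
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")
        design = sm.add_constant(Xa, has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # name a minimal set of columns dependent on the preceding ones
            _, r = np.linalg.qr(design)
            dep = [names[j - 1] for j in range(1, design.shape[1])
                   if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
            raise ValueError(f"design is rank deficient; collinear columns: {dep}")
        res = sm.OLS(ya, design).fit()
        aic = _ols_aic(float(res.ssr), n, p)
        return self._finalize(
            names, res.params[1:], res.params[0], res.bse[1:], res.tvalues[1:],
            aic, names,
        )


class RidgeSelector(_BaseSelector):
    """Ridge regression, intercept unpenalized, lambda by tenfold CV MSE.

    Solved in closed form on centred data: beta = (X'X + lam I)^-1 X'y.
    t-statistics for importance come from an OLS refit on all columns.
    """

    method = "ridge"

    def __init__(self, lambda_grid=None, cv=10, seed=0):
        self.lambda_grid = lambda_grid
        self.cv = cv
        self.seed = seed

    @staticmethod
    def _solve(Xc, yc, lam):
        p = Xc.shape[1]
        return np.linalg.solve(Xc.T @ Xc + lam * np.eye(p), Xc.T @ yc)

    def fit(self, X, y):
        Xa, ya, names = _as_xy(X, y)
        grid = self.lambda_grid
        if grid is None:
            grid = np.logspace(-3, 4, 50)
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise ValueError("lambda_grid is empty")
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
        mse = np.zeros(len(grid))
        for tr, te in kf.split(Xa):
            xm, ym = Xa[tr].mean(axis=0), ya[tr].mean()
            Xc, yc = Xa[tr] - xm, ya[tr] - ym
            Xt = Xa[te] - xm
            for gi, lam in enumerate(grid):
                beta = self._solve(Xc, yc, lam)
                mse[gi] += np.mean((ya[te] - ym - Xt @ beta) ** 2) * len(te)
        mse /= len(ya)
        best = int(np.argmin(mse))  # ties -> lowest index (smallest lambda first)
        lam = float(grid[best])
        xm, ym = Xa.mean(axis=0), ya.mean()
        beta = self._solve(Xa - xm, ya - ym, lam)
        intercept = ym - xm @ beta
        res = _ols_fit(Xa, ya, list(range(Xa.shape[1])))
        rss = float(np.sum((ya - intercept - Xa @ beta) ** 2))
        aic = _ols_aic(rss, len(ya), Xa.shape[1])
        self.penalty_ = lam
        self.cv_mse_ = mse
        return self._finalize(
            names, beta, intercept, res.bse[1:], res.tvalues[1:], aic, names
        )


class LassoSelector(_BaseSelector):
    """Lasso (coordinate descent, objective RSS/(2n) + lambda * ||b||_1),
    lambda by tenfold CV with the one-standard-error rule on a 100-point log
    grid descending four decades from lambda_max = max|X'(y - ybar)|/n."""

    method = "lasso"

    def __init__(self, lambda_grid=None, cv=10, one_se=True, seed=0, max_iter=50_000):
        self.lambda_grid = lambda_grid
        self.cv = cv
        self.one_se = one_se
        self.seed = seed
        self.max_iter = max_iter

    def _lasso(self, Xa, ya, lam):
        m = Lasso(alpha=lam, fit_intercept=True, max_iter=self.max_iter, tol=1e-10)
        m.fit(Xa, ya)
        if m.n_iter_ >= self.max_iter:
            gap = getattr(m, "dual_gap_", np.nan)
            raise RuntimeError(
                f"lasso failed to converge in {self.max_iter} iterations "
                f"(dual gap {gap:.3e}) at lambda={lam:.3e}"
            )
        return m

    def fit(self, X, y):
        Xa, ya, names = _as_xy(X, y)
        n, p = Xa.shape
        grid = self.lambda_grid
        if grid is None:
            lam_max = np.max(np.abs(Xa.T @ (ya - ya.mean()))) / n
            grid = np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, 100)
        grid = np.asarray(grid, dtype=float)
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
        fold_mse = np.zeros((self.cv, len(grid)))
        for fi, (tr, te) in enumerate(kf.split(Xa)):
            for gi, lam in enumerate(grid):
                m = self._lasso(Xa[tr], ya[tr], lam)
                fold_mse[fi, gi] = np.mean((ya[te] - m.predict(Xa[te])) ** 2)
        mean_mse = fold_mse.mean(axis=0)
        se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(self.cv)
        best = int(np.argmin(mean_mse))
        if self.one_se:
            cutoff = mean_mse[best] + se_mse[best]
            # grid descends from lambda_max, so the first admissible index is
            # the largest (most parsimonious) lambda within one SE
            best = int(np.nonzero(mean_mse <= cutoff)[0][0])
        lam = float(grid[best])
        m = self._lasso(Xa, ya, lam)
        coef = m.coef_.copy()
        active = [j for j in range(p) if coef[j] != 0.0]
        se = np.zeros(p)
        t = np.zeros(p)
        if active:
            res = _ols_fit(Xa, ya, active)
            se[active] = res.bse[1:]
            t[active] = res.tvalues[1:]
        rss = float(np.sum((ya - m.predict(Xa)) ** 2))
        aic = _ols_aic(rss, n, len(active))
        self.penalty_ = lam
        self.cv_mse_ = mean_mse
        return self._finalize(
            names, coef, m.intercept_, se, t, aic, [names[j] for j in active]
        )


class StepwiseAICSelector(_BaseSelector):
    """Bidirectional greedy stepwise search from the full model.

    At each step the single add/drop move that most reduces the AIC is
    applied; the search stops at a local minimum.  Ties break toward the
    lowest column index, so the path is deterministic given column order.
    """

    method = "step_aic"

    def __init__(self, direction="both", max_p=60):
        self.direction = direction
        self.max_p = max_p

    @staticmethod
    def _aic_for(Xa, ya, cols):
        if cols:
            design = sm.add_constant(Xa[:, cols], has_constant="add")
        else:
            design = np.ones((len(ya), 1))
        beta, rss_arr, *_ = np.linalg.lstsq(design, ya, rcond=None)
        resid = ya - design @ beta
        rss = float(resid @ resid)
        return _ols_aic(rss, len(ya), len(cols))

    def fit(self, X, y):
        Xa, ya, names = _as_xy(X, y)
        n, p = Xa.shape
        if p > self.max_p:
            raise ValueError(f"p={p} exceeds supported maximum {self.max_p}")
        current = list(range(p))
        current_aic = self._aic_for(Xa, ya, current)
        self.path_ = [(tuple(current), current_aic)]
        while True:
            best_move, best_aic = None, current_aic
            moves = [("drop", j) for j in current]
            if self.direction == "both":
                moves += [("add", j) for j in range(p) if j not in current]
            for kind, j in moves:  # scan order fixes the lowest-index tie-break
                cols = [c for c in current if c != j] if kind == "drop" else sorted(
                    current + [j]
                )
                aic = self._aic_for(Xa, ya, cols)
                if aic < best_aic - 1e-10:
                    best_move, best_aic = (kind, j), aic
            if best_move is None:
                break
            kind, j = best_move
            current = (
                [c for c in current if c != j] if kind == "drop" else sorted(current + [j])
            )
            current_aic = best_aic
            self.path_.append((tuple(current), current_aic))

        coef = np.zeros(p)
        se = np.zeros(p)
        t = np.zeros(p)
        if current:
            res = _ols_fit(Xa, ya, current)
            coef[current] = res.params[1:]
            se[current] = res.bse[1:]
            t[current] = res.tvalues[1:]
            intercept = res.params[0]
        else:
            intercept = ya.mean()
        return self._finalize(
            names, coef, intercept, se, t, current_aic, [names[j] for j in current]
        )


# ---------------------------------------------------------------------------
# functional wrappers and importance


def fit_ols_glm(X, y) -> GLMSelector:
    return GLMSelector().fit(X, y)


def fit_ridge(X, y, lambda_grid=None, cv=10, seed=0) -> RidgeSelector:
    return RidgeSelector(lambda_grid=lambda_grid, cv=cv, seed=seed).fit(X, y)


def fit_lasso(X, y, lambda_grid=None, cv=10, seed=0) -> LassoSelector:
    return LassoSelector(lambda_grid=lambda_grid, cv=cv, seed=seed).fit(X, y)


def fit_step_aic(X, y, direction="both") -> StepwiseAICSelector:
    return StepwiseAICSelector(direction=direction).fit(X, y)


def variable_importance(fit: _BaseSelector) -> pd.Series:
    """|t_j| / sum_k |t_k| * 100 per covariate; unselected covariates get 0."""
    t = np.abs(fit.t_statistics_)
    total = t.sum()
    if total == 0:
        raise ValueError("all t-statistics are zero; importance undefined")
    return pd.Series(t / total * 100.0, index=fit.feature_names_in_, name=fit.method)


def _significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def importance_table(fits: list[_BaseSelector]) -> pd.DataFrame:
    """Per-method coefficient / significance-code / VI% table (CSV-ready)."""
    from scipy import stats

    blocks = {}
    for fit in fits:
        vi = variable_importance(fit)
        dof = max(len(fit.feature_names_in_), 1)
        pvals = 2 * stats.norm.sf(np.abs(fit.t_statistics_))
        blocks[(fit.method, "coef")] = pd.Series(
            fit.coef_, index=fit.feature_names_in_
        )
        blocks[(fit.method, "sc")] = pd.Series(
            [_significance_code(p) for p in pvals], index=fit.feature_names_in_
        )
        blocks[(fit.method, "vi_pct")] = vi
    return pd.DataFrame(blocks)
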