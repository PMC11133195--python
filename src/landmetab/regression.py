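"""Statistical analyses: stepwise multiple regression and simple linear fits.

The composite disturbance index is regressed on the per-hexagon cover
proportions (one predictor per land-cover class) with bidirectional
stepwise selection, and on the hexagon ecosystem-service capacity with an
ordinary least-squares line. Selection is deterministic: candidates are
scanned in column order and the best single add/remove move is taken until
no move improves the criterion.

Cover proportions sum to one within each hexagon, so the full design with
an intercept is collinear by construction; no transformation is applied —
the intercept is kept and selection drops redundant terms, matching how
such compositional regressions are conventionally reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError

SIGNIFICANCE_LEVEL = 0.050  # flagged with '*' in the report


@dataclass
class RegressionResult:
    """Stepwise OLS fit in the layout of a published regression table."""

    coefficients: pd.DataFrame  # term, estimate, std_error, t_value, p_value, significant
    r_squared: float
    adj_r_squared: float
    resid_se: float
    f_statistic: float
    df_model: int
    df_resid: int
    f_pvalue: float
    residual_quantiles: dict[str, float]
    n: int
    selected: list[str]
    dropped: list[str] = field(default_factory=list)
    criterion: str = "aic"

    def significant_terms(self) -> list[str]:
        sel = self.coefficients
        return list(sel.loc[sel["significant"] & (sel["term"] != "Intercept"), "term"])

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "criterion": self.criterion,
            "n": self.n,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "resid_se": self.resid_se,
            "f_statistic": self.f_statistic,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "f_pvalue": self.f_pvalue,
            "residual_quantiles": self.residual_quantiles,
            "selected": self.selected,
            "dropped": self.dropped,
            "coefficients": self.coefficients.to_dict(orient="records"),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc

    def report(self) -> str:
        """Plain-text report: residual quantiles, coefficient block, fit stats."""
        q = self.residual_quantiles
        lines = [
            f"Step-wise multiple regression (criterion: {self.criterion})",
            "",
            "Residuals:",
            f"{'Min':>10}{'1Q':>10}{'Median':>10}{'3Q':>10}{'Max':>10}",
            "".join(f"{q[k]:>10.5f}" for k in ("min", "q1", "median", "q3", "max")),
            "",
            f"{'Variables/Coefficients':<40}{'Estimate':>12}{'Std. Error':>12}"
            f"{'t value':>10}{'Pr(>|t|)':>12}  Significance(<0.050)",
        ]
        for _, r in self.coefficients.iterrows():
            star = "*" if r["significant"] else ""
            lines.append(
                f"{r['term']:<40}{r['estimate']:>12.5f}{r['std_error']:>12.6f}"
                f"{r['t_value']:>10.3f}{r['p_value']:>12.3g}  {star}"
            )
        lines += [
            "",
            f"n: {self.n}. Multiple R-squared: {self.r_squared:.4f}. "
            f"Adjusted R-squared: {self.adj_r_squared:.4f}.",
            f"Residual standard error: {self.resid_se:.5f} on {self.df_resid} degrees "
            f"of freedom.",
            f"F-statistic: {self.f_statistic:.1f} on {self.df_model} and "
            f"{self.df_resid} DF. p-value: {self.f_pvalue:.3g}",
            "Significance codes: * < 0.050. "
            "p values are two-sided t tests; no multiple-testing correction.",
        ]
        if self.dropped:
            lines.append(f"Dropped (degenerate/collinear) terms: {', '.join(self.dropped)}")
        return "\n".join(lines)


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _criterion_value(res, criterion: str) -> float:
    return float(res.aic if criterion == "aic" else res.bic)


def stepwise_mrm(
    response: pd.Series,
    predictors: pd.DataFrame,
    criterion: str = "aic",
    enter_p: float = 0.05,
    remove_p: float = 0.10,
    max_steps: int = 200,
) -> RegressionResult:
    """Bidirectional stepwise OLS of ``response`` on ``predictors``.

    ``criterion`` is ``"aic"`` or ``"bic"`` (best single add/remove move per
    step) or ``"pvalue"`` (enter at ``enter_p``, remove at ``remove_p``).
    Constant (zero-variance) predictors are dropped up front and reported.
    """
    if criterion not in ("aic", "bic", "pvalue"):
        raise InvalidArgumentError(f"unknown stepwise criterion {criterion!r}")
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float).copy()
    X.columns = [str(c) for c in X.columns]
    n = len(y)
    if X.shape[0] != n:
        raise InvalidArgumentError("response and predictors have different lengths")
    if n < X.shape[1] + 2:
        raise InvalidArgumentError(
            f"need at least {X.shape[1] + 2} observations for {X.shape[1]} predictors"
        )
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X.to_numpy())):
        raise InvalidArgumentError("non-finite values in regression inputs")

    dropped = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0.0]
    candidates = [c for c in X.columns if c not in dropped]

    # once the fit is numerically perfect, further moves only chase rounding
    tss = float(np.sum((y - y.mean()) ** 2))
    perfect = lambda res: float(res.ssr) <= 1e-20 * max(1.0, tss)  # noqa: E731

    selected: list[str] = []
    if criterion in ("aic", "bic"):
        current = _criterion_value(_fit_ols(y, X[selected]), criterion)
        for _ in range(max_steps):
            if selected and perfect(_fit_ols(y, X[selected])):
                break
            best_move, best_val = None, current - 1e-9
            for c in candidates:  # deterministic column order
                if c in selected:
                    continue
                val = _criterion_value(_fit_ols(y, X[selected + [c]]), criterion)
                if val < best_val:
                    best_move, best_val = ("add", c), val
            for c in selected:
                trial = [s for s in selected if s != c]
                val = _criterion_value(_fit_ols(y, X[trial]), criterion)
                if val < best_val:
                    best_move, best_val = ("remove", c), val
            if best_move is None:
                break
            action, term = best_move
            if action == "add":
                selected.append(term)
            else:
                selected.remove(term)
            current = best_val
    else:  # p-value stepping: enter the smallest p < enter_p, remove p > remove_p
        for _ in range(max_steps):
            if selected and perfect(_fit_ols(y, X[selected])):
                break
            changed = False
            best_term, best_pv = None, enter_p
            for c in candidates:
                if c in selected:
                    continue
                res = _fit_ols(y, X[selected + [c]])
                pv = float(res.pvalues.iloc[-1])
                if pv < best_pv:
                    best_term, best_pv = c, pv
            if best_term is not None:
                selected.append(best_term)
                changed = True
            if selected:
                res = _fit_ols(y, X[selected])
                pvals = res.pvalues.drop("const")
                worst = pvals.idxmax()
                if float(pvals.max()) > remove_p:
                    selected.remove(str(worst))
                    changed = True
            if not changed:
                break

    res = _fit_ols(y, X[selected])
    # rank-deficiency after selection is reported, not silently absorbed
    exog_rank = np.linalg.matrix_rank(sm.add_constant(X[selected], has_constant="add"))
    rank_dropped: list[str] = []
    if exog_rank < len(selected) + 1:
        for c in list(selected):
            trial = [s for s in selected if s != c]
            if np.linalg.matrix_rank(
                sm.add_constant(X[trial], has_constant="add")
            ) == exog_rank:
                selected = trial
                rank_dropped.append(c)
        res = _fit_ols(y, X[selected])

    resid = np.asarray(res.resid, dtype=float)
    qs = np.quantile(resid, [0.0, 0.25, 0.5, 0.75, 1.0])
    names = ["Intercept"] + selected
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": np.asarray(res.params, dtype=float),
            "std_error": np.asarray(res.bse, dtype=float),
            "t_value": np.asarray(res.tvalues, dtype=float),
            "p_value": np.asarray(res.pvalues, dtype=float),
        }
    )
    coef["significant"] = coef["p_value"] < SIGNIFICANCE_LEVEL
    df_model = int(res.df_model)
    df_resid = int(res.df_resid)
    return RegressionResult(
        coefficients=coef,
        r_squared=float(res.rsquared) if selected else 0.0,
        adj_r_squared=float(res.rsquared_adj) if selected else 0.0,
        resid_se=float(np.sqrt(res.mse_resid)),
        f_statistic=float(res.fvalue) if selected else float("nan"),
        df_model=df_model,
        df_resid=df_resid,
        f_pvalue=float(res.f_pvalue) if selected else float("nan"),
        residual_quantiles={
            "min": float(qs[0]),
            "q1": float(qs[1]),
            "median": float(qs[2]),
            "q3": float(qs[3]),
            "max": float(qs[4]),
        },
        n=n,
        selected=selected,
        dropped=dropped + rank_dropped,
        criterion=criterion,
    )


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_fit(x, y) -> LinearFitResult:
    """Ordinary least-squares line y = slope·x + intercept; R² is the squared
    Pearson correlation."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D arrays of equal length")
    if len(xa) < 3:
        raise InvalidArgumentError("linear fit needs at least 3 points")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise InvalidArgumentError("non-finite values in linear fit inputs")
    if np.ptp(xa) == 0.0:
        raise DegenerateInputError("zero variance in x")
    fit = stats.linregress(xa, ya)
    return LinearFitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(xa),
    )
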