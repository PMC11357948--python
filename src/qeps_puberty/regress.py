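"""Milestone-wise regression modelling.

Association and outcome variables are standardized by their own cohort SD so
that standardized beta coefficients are comparable across variables.
Univariable scans are adjusted for multiplicity with the Holm step-down
procedure; multivariable models are built per clinical milestone (birth,
age 7, pubertal onset, midpuberty) with forward/backward stepwise selection
at p < 0.05, and report model R-squared plus per-variable partial R-squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .derive import MILESTONE_GROUPS

__all__ = [
    "RegressionReport",
    "standardize",
    "holm_adjust",
    "univariable_scan",
    "StepwiseOLS",
    "stepwise_select",
    "partial_r2",
    "milestone_models",
    "analyze_postmenarcheal_gain",
]

log = logging.getLogger(__name__)


@dataclass
class RegressionReport:
    """Per-variable effects and model fit for one outcome at one milestone."""

    outcome: str
    milestone: str
    kind: str  # "univariable" or "multivariable"
    table: pd.DataFrame  # one row per variable
    model_r2: float = float("nan")
    selected: list = field(default_factory=list)
    n: int = 0


def standardize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Center each numeric column and divide by its own cohort SD.

    A column with zero spread cannot be standardized and raises, naming the
    offending column.
    """
    out = table.copy()
    cols = columns if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    for c in cols:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {c!r} is constant (SD = 0); cannot standardize")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, order of the input preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def univariable_scan(
    table: pd.DataFrame, outcome: str, variables, min_n: int = 10
) -> RegressionReport:
    """Simple linear regression of the standardized outcome on each
    standardized variable, complete-case per pair, Holm-adjusted across the
    scanned set.

    On standardized data the slope equals the Pearson correlation and the
    univariable R-squared is its square.
    """
    rows = []
    for var in variables:
        sub = table[[outcome, var]].dropna()
        if len(sub) < min_n:
            log.warning("skipping %s: only %d complete pairs", var, len(sub))
            continue
        z = standardize(sub, [outcome, var])
        res = _fit_ols(z[outcome].to_numpy(), z[[var]])
        ci = res.conf_int().loc[var]
        rows.append(
            {
                "variable": var,
                "beta": res.params[var],
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p": res.pvalues[var],
                "r2": res.rsquared,
                "n": int(len(sub)),
            }
        )
    tab = pd.DataFrame(rows)
    if not tab.empty:
        tab["p_holm"] = holm_adjust(tab["p"].to_numpy())
    return RegressionReport(
        outcome=outcome,
        milestone="all",
        kind="univariable",
        table=tab,
        n=int(len(table)),
    )


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop later-named columns that are linearly dependent on earlier ones."""
    keep = []
    for c in X.columns:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(c)
        else:
            log.warning("dropping %s: perfectly collinear with earlier columns", c)
    return X[keep]


class StepwiseOLS(BaseEstimator):
    """Forward/backward stepwise OLS on standardized variables.

    A forward step adds the candidate with the smallest p-value below
    ``alpha_enter``; a backward step removes any included variable whose
    p-value exceeds ``alpha_remove``; steps alternate to a fixpoint.  Ties
    break on the larger |t| statistic, then alphabetically, so selection is
    deterministic.

    Attributes
    ----------
    selected_ : list of str
        Variables in the final model, in order of entry.
    results_ : statsmodels OLS results for the final model.
    r2_ : float
        Final model R-squared (0 for an empty model).
    partial_r2_ : dict
        Per-selected-variable partial R-squared.
    """

    def __init__(self, alpha_enter: float = 0.05, alpha_remove: float = 0.05):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        X = _drop_collinear(X.astype(float))
        selected: list[str] = []
        visited = set()
        while True:
            state = frozenset(selected)
            if state in visited:
                break
            visited.add(state)
            changed = False
            # forward
            remaining = [c for c in X.columns if c not in selected]
            best = None
            for c in remaining:
                res = _fit_ols(y, X[selected + [c]])
                p, t = res.pvalues[c], abs(res.tvalues[c])
                cand = (p, -t, c)
                if p < self.alpha_enter and (best is None or cand < best[0]):
                    best = (cand, c)
            if best is not None:
                selected.append(best[1])
                changed = True
            # backward
            while selected:
                res = _fit_ols(y, X[selected])
                pv = res.pvalues[selected]
                worst = pv.idxmax()
                if pv[worst] > self.alpha_remove:
                    selected.remove(worst)
                    changed = True
                else:
                    break
            if not changed:
                break

        self.selected_ = selected
        if selected:
            self.results_ = _fit_ols(y, X[selected])
            self.r2_ = float(self.results_.rsquared)
            sse_full = float(np.sum(self.results_.resid**2))
            self.partial_r2_ = {}
            for c in selected:
                others = [v for v in selected if v != c]
                if others:
                    sse_red = float(np.sum(_fit_ols(y, X[others]).resid**2))
                else:
                    sse_red = float(np.sum((y - y.mean()) ** 2))
                self.partial_r2_[c] = (sse_red - sse_full) / sse_red
        else:
            self.results_ = None
            self.r2_ = 0.0
            self.partial_r2_ = {}
        self._X_columns = list(X.columns)
        return self

    def report(self, outcome: str = "", milestone: str = "") -> RegressionReport:
        check_is_fitted(self, "selected_")
        rows = []
        for c in self.selected_:
            ci = self.results_.conf_int().loc[c]
            rows.append(
                {
                    "variable": c,
                    "beta": self.results_.params[c],
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p": self.results_.pvalues[c],
                    "partial_r2": self.partial_r2_[c],
                }
            )
        return RegressionReport(
            outcome=outcome,
            milestone=milestone,
            kind="multivariable",
            table=pd.DataFrame(rows),
            model_r2=self.r2_,
            selected=list(self.selected_),
            n=int(self.results_.nobs) if self.results_ is not None else 0,
        )


def stepwise_select(
    table: pd.DataFrame,
    outcome: str,
    candidates,
    alpha: float = 0.05,
) -> tuple[list, StepwiseOLS]:
    """Functional wrapper around :class:`StepwiseOLS`.

    Standardizes outcome and candidates on the complete cases, runs
    stepwise selection, and returns ``(selected variables, fitted estimator)``.
    """
    candidates = list(candidates)
    sub = table[[outcome] + candidates].dropna()
    if sub.empty or not candidates:
        est = StepwiseOLS(alpha, alpha)
        est.selected_ = []
        est.results_ = None
        est.r2_ = 0.0
        est.partial_r2_ = {}
        return [], est
    z = standardize(sub)
    est = StepwiseOLS(alpha_enter=alpha, alpha_remove=alpha)
    est.fit(z[candidates], z[outcome].to_numpy())
    return est.selected_, est


def partial_r2(table: pd.DataFrame, outcome: str, selected, variable: str) -> float:
    """Partial R-squared of one selected variable: the fraction of the
    reduced model's residual variance explained when the variable enters."""
    if variable not in selected:
        raise ValueError(f"{variable!r} is not in the selected set")
    sub = table[[outcome] + list(selected)].dropna()
    z = standardize(sub)
    y = z[outcome].to_numpy()
    full = _fit_ols(y, z[list(selected)])
    others = [v for v in selected if v != variable]
    sse_full = float(np.sum(full.resid**2))
    if others:
        sse_red = float(np.sum(_fit_ols(y, z[others]).resid**2))
    else:
        sse_red = float(np.sum((y - y.mean()) ** 2))
    return (sse_red - sse_full) / sse_red


def milestone_models(
    table: pd.DataFrame,
    outcome: str = "age_menarche",
    groups: dict | None = None,
    alpha: float = 0.05,
) -> list[RegressionReport]:
    """One multivariable model per clinical milestone.

    Candidate variables accumulate over milestones (everything observable up
    to that point is eligible), so explained variance is non-decreasing on
    a fixed complete-case cohort.  Reports are returned in milestone order.
    """
    groups = groups if groups is not None else MILESTONE_GROUPS
    missing = [g for g in groups if not groups[g]]
    if missing:
        raise ValueError(f"milestone groups without variables: {missing}")
    reports = []
    cumulative: list[str] = []
    for milestone, vars_ in groups.items():
        absent = [v for v in vars_ if v not in table.columns]
        if absent:
            raise ValueError(
                f"milestone {milestone!r} variables missing from table: {absent}"
            )
        cumulative = cumulative + [v for v in vars_ if v not in cumulative]
        selected, est = stepwise_select(table, outcome, cumulative, alpha)
        rep = est.report(outcome=outcome, milestone=milestone)
        reports.append(rep)
    return reports


def analyze_postmenarcheal_gain(
    table: pd.DataFrame,
    variables,
    outcome: str = "postmenarcheal_gain",
    alpha: float = 0.05,
) -> tuple[RegressionReport, RegressionReport | None]:
    """Secondary-outcome analysis.

    Runs the univariable scan; a multivariable model is only attempted when
    more than one variable survives the Holm adjustment (with at most one
    significant association there is nothing to model jointly).
    """
    uni = univariable_scan(table, outcome, variables)
    n_sig = (
        int((uni.table["p_holm"] < alpha).sum()) if not uni.table.empty else 0
    )
    if n_sig <= 1:
        return uni, None
    sig_vars = uni.table.loc[uni.table["p_holm"] < alpha, "variable"].tolist()
    _, est = stepwise_select(table, outcome, sig_vars, alpha)
    return uni, est.report(outcome=outcome, milestone="all")


def forest_plot(reports, path):
    """Basic forest plot of standardized betas with 95% CIs per milestone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = []
    for rep in reports:
        for _, r in rep.table.iterrows():
            rows.append((f"{rep.milestone}: {r['variable']}", r["beta"],
                         r["ci_low"], r["ci_high"]))
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(rows) + 1)))
    if rows:
        labels, betas, lo, hi = zip(*rows)
        ypos = np.arange(len(rows))[::-1]
        ax.errorbar(
            betas, ypos,
            xerr=[np.array(betas) - np.array(lo), np.array(hi) - np.array(betas)],
            fmt="o", capsize=3,
        )
        ax.set_yticks(ypos)
        ax.set_yticklabels(labels)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("standardized beta (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
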