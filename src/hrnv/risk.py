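"""Risk-stratification workflow for 30-day MACE prediction.

The pipeline mirrors standard clinical-model practice on a chest-pain
cohort: encode features, screen candidates with univariable logistic
regressions (keep p < 0.2), reduce with backward stepwise multivariable
logistic regression, estimate out-of-sample performance with leave-one-out
cross-validation (LOOCV), and compare models with ROC analysis (trapezoid
AUC, DeLong confidence interval, and operating-point metrics at the cut-off
nearest the upper-left corner).

Model fits go through statsmodels' ``Logit``; this module owns the
selection logic, the cross-validation loop and the ROC machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "encode_troponin",
    "univariable_screen",
    "stepwise_backward",
    "loocv_probabilities",
    "roc_analysis",
    "ModelResult",
    "ROCResult",
    "run_pipeline",
]


def encode_troponin(value: float, normal_limit: float = 0.03) -> int:
    """Code a high-sensitivity troponin-T value (ng/mL) into {0, 1, 2}.

    0 for values at or below the normal limit, 1 for values between one and
    three times the limit (inclusive of the 3x boundary), 2 above that.
    """
    if value < 0:
        raise ValueError("troponin cannot be negative")
    if value <= normal_limit:
        return 0
    if value <= 3 * normal_limit:
        return 1
    return 2


def _fit_model(model):
    # Newton handles poorly scaled designs (e.g. raw spectral powers) far
    # better than lbfgs; fall back to lbfgs if the Hessian degenerates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200, method="newton")
            if np.all(np.isfinite(fit.params)):
                return fit
        except Exception:
            pass
        return model.fit(disp=0, maxiter=500, method="lbfgs")


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    return _fit_model(sm.Logit(y, sm.add_constant(X, has_constant="add")))


@dataclass
class ModelResult:
    """A fitted multivariable logistic model: selected variables with
    adjusted ORs, Wald 95% CIs and p-values."""

    variables: list[str]
    table: pd.DataFrame  # index: variable; columns: or_, ci_lo, ci_hi, p
    converged: bool
    fit: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(
            self.fit.predict(sm.add_constant(X[self.variables], has_constant="add"))
        )


def _wald_table(fit, variables: list[str]) -> pd.DataFrame:
    params = fit.params[variables]
    se = fit.bse[variables]
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "or_": np.exp(params),
            "ci_lo": np.exp(params - z * se),
            "ci_hi": np.exp(params + z * se),
            "p": fit.pvalues[variables],
        }
    )


def univariable_screen(cohort: pd.DataFrame, candidates: list[str],
                       alpha_in: float = 0.2, outcome: str = "outcome"):
    """One single-predictor logistic fit per candidate.

    Returns ``(selected, table)``: the candidates with Wald p < ``alpha_in``
    and the per-variable OR/CI/p table.  Variables with (quasi-)separation
    or non-convergent fits are flagged in the table's ``separation`` column
    and excluded from selection.
    """
    rows, selected = {}, []
    for var in candidates:
        sub = cohort[[var, outcome]].dropna()
        if sub[var].nunique() < 2:
            raise ValueError(f"candidate {var!r} has fewer than 2 distinct values")
        fit = _fit_logit(sub[outcome].to_numpy(), sub[[var]])
        se = float(fit.bse[var])
        beta = float(fit.params[var])
        # (quasi-)separation heuristic: diverging coefficient or Wald SE
        sep = (not fit.mle_retvals.get("converged", True)) or se > 30 \
            or abs(beta) > 15 or not math.isfinite(se)
        row = _wald_table(fit, [var]).iloc[0].to_dict()
        row["separation"] = sep
        rows[var] = row
        if sep:
            warnings.warn(f"separation suspected for {var!r}; excluded", stacklevel=2)
        elif row["p"] < alpha_in:
            selected.append(var)
    return selected, pd.DataFrame(rows).T


def stepwise_backward(cohort: pd.DataFrame, candidates: list[str],
                      alpha_out: float = 0.05, criterion: str = "p",
                      forced: tuple[str, ...] = (),
                      outcome: str = "outcome") -> ModelResult:
    """Backward elimination from the full multivariable logistic model.

    ``criterion="p"`` (default) repeatedly drops the removable variable with
    the largest Wald p until all p <= ``alpha_out``; ``criterion="aic"``
    drops while any removal lowers the AIC.  ``forced`` variables are never
    dropped.  Deterministic given the data.  An empty candidate set returns
    the intercept-only model.
    """
    data = cohort[list(dict.fromkeys([*candidates, *forced, outcome]))].dropna()
    y = data[outcome].to_numpy()
    current = list(dict.fromkeys([*candidates, *forced]))

    def fit_current(varlist):
        if varlist:
            return _fit_logit(y, data[varlist])
        return _fit_model(sm.Logit(y, np.ones((y.size, 1))))

    fit = fit_current(current)
    while current:
        removable = [v for v in current if v not in forced]
        if not removable:
            break
        if criterion == "p":
            pvals = fit.pvalues[removable]
            worst = pvals.idxmax()
            if pvals.max() <= alpha_out:
                break
            current.remove(worst)
            fit = fit_current(current)
        elif criterion == "aic":
            best_aic, best_var = fit.aic, None
            for v in removable:
                trial = fit_current([w for w in current if w != v])
                if trial.aic < best_aic:
                    best_aic, best_var = trial.aic, v
            if best_var is None:
                break
            current.remove(best_var)
            fit = fit_current(current)
        else:
            raise ValueError("criterion must be 'p' or 'aic'")

    converged = bool(fit.mle_retvals.get("converged", True))
    if not converged:
        raise RuntimeError(
            f"stepwise model failed to converge with variables {current}"
        )
    table = _wald_table(fit, current) if current else pd.DataFrame(
        columns=["or_", "ci_lo", "ci_hi", "p"])
    return ModelResult(variables=current, table=table, converged=converged, fit=fit)


def loocv_probabilities(cohort: pd.DataFrame, variables: list[str],
                        outcome: str = "outcome") -> np.ndarray:
    """Leave-one-out out-of-fold predicted probabilities.

    The variable list is fixed (selection is done once on the full data);
    each patient is predicted by a model refit on the other N-1.  Folds that
    fail to converge are reported in a warning and predicted anyway.
    """
    data = cohort[[*variables, outcome]].dropna().reset_index(drop=True)
    y = data[outcome].to_numpy()
    X = sm.add_constant(data[variables], has_constant="add").to_numpy()
    n = y.size
    probs = np.empty(n)
    bad_folds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = _fit_model(sm.Logit(y[mask], X[mask]))
        if not fit.mle_retvals.get("converged", True):
            bad_folds.append(i)
        probs[i] = 1.0 / (1.0 + np.exp(-float(X[i] @ fit.params)))
    if bad_folds:
        warnings.warn(f"{len(bad_folds)} LOOCV fold(s) did not converge", stacklevel=2)
    return probs


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    optimal_cutoff: float
    metrics_at_optimal: dict
    _scores: np.ndarray = field(repr=False, default=None)
    _outcome: np.ndarray = field(repr=False, default=None)

    def metrics_at(self, cutoff: float) -> dict:
        """Sens/spec/PPV/NPV (with binomial CIs) at an arbitrary cut-off."""
        return _confusion_metrics(self._scores, self._outcome, cutoff)


def _delong_ci(scores: np.ndarray, outcome: np.ndarray, auc: float,
               level: float = 0.95) -> tuple[float, float]:
    """DeLong variance of the empirical AUC via placement values."""
    pos = scores[outcome == 1]
    neg = scores[outcome == 0]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (math.nan, math.nan)
    p = k / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def _confusion_metrics(scores, outcome, cutoff: float) -> dict:
    pred = scores >= cutoff
    tp = int(np.sum(pred & (outcome == 1)))
    fn = int(np.sum(~pred & (outcome == 1)))
    tn = int(np.sum(~pred & (outcome == 0)))
    fp = int(np.sum(pred & (outcome == 0)))
    out = {
        "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
        "specificity": tn / (tn + fp) if tn + fp else math.nan,
        "ppv": tp / (tp + fp) if tp + fp else math.nan,
        "npv": tn / (tn + fn) if tn + fn else math.nan,
    }
    out["sensitivity_ci"] = _binomial_ci(tp, tp + fn)
    out["specificity_ci"] = _binomial_ci(tn, tn + fp)
    out["ppv_ci"] = _binomial_ci(tp, tp + fp)
    out["npv_ci"] = _binomial_ci(tn, tn + fn)
    return out


def roc_analysis(scores, outcome) -> ROCResult:
    """Empirical ROC over all distinct thresholds.

    AUC is the trapezoidal area, identical to the Mann-Whitney concordance
    probability; its 95% CI uses DeLong's placement-value variance.  The
    optimal cut-off minimises the Euclidean distance to the perfect
    classifier corner (0, 1) in (1-specificity, sensitivity) space; the
    returned object can also report sens/spec/PPV/NPV (with normal-
    approximation binomial CIs) at any requested cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    if set(np.unique(outcome)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(outcome)) < 2:
        raise ValueError("both outcome classes must be present")

    thresholds = np.unique(scores)[::-1]
    thresholds = np.concatenate(([thresholds[0] + 1.0], thresholds))
    npos = int(np.sum(outcome == 1))
    nneg = int(np.sum(outcome == 0))
    sens = np.array([np.sum(scores[outcome == 1] >= t) / npos for t in thresholds])
    spec = np.array([np.sum(scores[outcome == 0] < t) / nneg for t in thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    ci = _delong_ci(scores, outcome, auc)

    dist = np.hypot(fpr, 1.0 - sens)
    opt = float(thresholds[int(np.argmin(dist))])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        optimal_cutoff=opt,
        metrics_at_optimal=_confusion_metrics(scores, outcome, opt),
        _scores=scores,
        _outcome=outcome,
    )


def run_pipeline(cohort: pd.DataFrame, candidates: list[str],
                 alpha_in: float = 0.2, alpha_out: float = 0.05,
                 strict_cv: bool = False, outcome: str = "outcome") -> dict:
    """Screen -> stepwise -> LOOCV -> ROC, end to end.

    Default mode selects variables once on the full data and uses LOOCV only
    for the coefficients (the optimistic but common procedure); with
    ``strict_cv`` the screening and stepwise selection are repeated inside
    every fold as well, and both AUCs are reported so the optimism gap is
    visible.
    """
    selected, uni_table = univariable_screen(cohort, candidates, alpha_in, outcome)
    model = stepwise_backward(cohort, selected, alpha_out, outcome=outcome)
    probs = loocv_probabilities(cohort, model.variables, outcome)
    data = cohort[[*model.variables, outcome]].dropna()
    roc = roc_analysis(probs, data[outcome].to_numpy())
    out = {
        "univariable": uni_table,
        "screened": selected,
        "model": model,
        "loocv_probs": probs,
        "roc": roc,
    }
    if strict_cv:
        y = cohort[outcome].to_numpy()
        n = len(cohort)
        strict_probs = np.empty(n)
        for i in range(n):
            rest = cohort.drop(index=cohort.index[i])
            sel_i, _ = univariable_screen(rest, candidates, alpha_in, outcome)
            model_i = stepwise_backward(rest, sel_i, alpha_out, outcome=outcome)
            strict_probs[i] = float(
                model_i.predict(cohort.iloc[[i]][model_i.variables])[0]
            ) if model_i.variables else y[rest.index].mean()
        out["strict_loocv_probs"] = strict_probs
        out["strict_roc"] = roc_analysis(strict_probs, y)
    return out
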