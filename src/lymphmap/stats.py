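"""Cohort-level statistics: dichotomization, 2x2 association measures and
logistic regression with forward stepwise selection.

Continuous predictors are dichotomized at the observed value maximizing the
Youden index J = sensitivity + specificity - 1 (classification rule
"positive iff value >= threshold").  Odds ratios use the Woolf log-normal
confidence interval, with the Haldane-Anscombe +0.5 correction available
for zero cells.  Logistic models are fitted by Newton/IRLS with monotone
likelihood (separation) detection; forward stepwise selection enters the
candidate with the smallest likelihood-ratio-test p-value at each step.

Fixed dichotomization cut-offs shipped as defaults: CA125 264.5 U/mL, HE4
148.5 (postmenopausal) / 122.2 (premenopausal), ascites 90 mL, age 50
years, tumour size 100 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CUTOFFS",
    "ContingencyTable2x2",
    "CutoffResult",
    "LogisticFit",
    "OddsRatioResult",
    "youden_cutoff",
    "dichotomize",
    "odds_ratio_2x2",
    "chi_square_2x2",
    "mann_whitney_u",
    "fit_logistic",
    "forward_stepwise",
    "YoudenBinarizer",
    "ForwardStepwiseLogistic",
]

#: Default clinical cut-offs (classification rule: positive iff >= cut-off).
DEFAULT_CUTOFFS = {
    "age": 50.0,
    "tumor_size_mm": 100.0,
    "ca125": 264.5,
    "he4_postmenopausal": 148.5,
    "he4_premenopausal": 122.2,
    "ascites_ml": 90.0,
}


# ---------------------------------------------------------------------------
# Youden-index dichotomization


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_cutoff(values, labels) -> CutoffResult:
    """Observed-value threshold maximizing J = sensitivity + specificity - 1.

    The rule is "positive iff value >= threshold"; candidate thresholds are
    the observed values, and ties in J are broken toward the smallest
    threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape or v.ndim != 1 or len(v) < 2:
        raise ValueError("values and labels must be equal-length 1-D with n >= 2")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "both label classes must be present: sensitivity/specificity undefined"
        )
    best: CutoffResult | None = None
    for t in np.unique(v):
        pred = v >= t
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(t), j, sens, spec)
    assert best is not None
    return best


def dichotomize(values, threshold: float) -> np.ndarray:
    """Binary indicator "value >= threshold" (the above-cutoff category)."""
    return (np.asarray(values, dtype=float) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# 2x2 tables


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts n[exposure][outcome]: first index exposure 0/1, second outcome 0/1."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        cells = (self.n00, self.n01, self.n10, self.n11)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")

    @classmethod
    def from_arrays(cls, exposure, outcome) -> "ContingencyTable2x2":
        e = np.asarray(exposure, dtype=int)
        o = np.asarray(outcome, dtype=int)
        return cls(
            int(((e == 0) & (o == 0)).sum()),
            int(((e == 0) & (o == 1)).sum()),
            int(((e == 1) & (o == 0)).sum()),
            int(((e == 1) & (o == 1)).sum()),
        )

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.n00, self.n01], [self.n10, self.n11]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


def odds_ratio_2x2(table: ContingencyTable2x2, correction: bool = False) -> OddsRatioResult:
    """Odds ratio with the Woolf log-normal 95% confidence interval.

    OR = (n11 * n00) / (n10 * n01); CI = exp(ln OR +/- 1.96 sqrt(sum 1/cell)).
    With ``correction`` and any zero cell, 0.5 is added to every cell
    (Haldane-Anscombe) and the result is flagged.
    """
    cells = np.array([table.n00, table.n01, table.n10, table.n11], dtype=float)
    corrected = False
    if (cells == 0).any():
        if not correction:
            names = ["n00", "n01", "n10", "n11"]
            zero = [names[i] for i in range(4) if cells[i] == 0]
            raise ValueError(
                f"zero cell(s) {zero}: odds ratio undefined without the "
                "Haldane-Anscombe correction"
            )
        cells = cells + 0.5
        corrected = True
    n00, n01, n10, n11 = cells
    or_ = (n11 * n00) / (n10 * n01)
    half = 1.96 * np.sqrt((1.0 / cells).sum())
    log_or = np.log(or_)
    return OddsRatioResult(
        float(or_), float(np.exp(log_or - half)), float(np.exp(log_or + half)), corrected
    )


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False):
    """Pearson chi-square for a 2x2 table (no continuity correction by default).

    Returns (statistic, p_value) with 1 degree of freedom.  A zero row or
    column marginal makes the test undefined and raises.
    """
    m = table.as_matrix()
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square test undefined")
    stat, p, dof, _ = sps.chi2_contingency(m, correction=yates)
    assert dof == 1
    return float(stat), float(p)


def mann_whitney_u(sample_a, sample_b):
    """Mann-Whitney U (for the first sample) with its two-sided p-value.

    Midrank tie handling; exact enumeration when both groups have n <= 8
    and there are no ties, normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Logistic regression (Newton / IRLS)


@dataclass
class LogisticFit:
    coefficients: np.ndarray          # intercept first
    standard_errors: np.ndarray
    converged: bool
    n_iterations: int
    separation_flag: bool
    log_likelihood: float
    term_names: list[str] = field(default_factory=list)
    iteration_trace: list[float] = field(default_factory=list)


def fit_logistic(design, outcome, add_intercept: bool = True,
                 tol: float = 1e-8, max_iter: int = 100,
                 separation_bound: float = 15.0) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Convergence is declared when the score (gradient) norm drops below
    ``tol``; monotone likelihood (separation) is flagged when any
    coefficient magnitude exceeds ``separation_bound`` and iteration stops.
    Raises on non-convergence without separation.
    """
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(outcome)) == X.shape[1]:
            X = X.T
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("design rows must match outcome length")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    # reject collinear constant columns beyond the intercept
    if add_intercept:
        for j in range(1, X.shape[1]):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"column {names[j]!r} is constant")

    beta = np.zeros(X.shape[1])
    trace: list[float] = []
    converged = False
    separation = False
    it = 0
    H = np.eye(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        gnorm = float(np.linalg.norm(grad))
        trace.append(gnorm)
        if gnorm < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.abs(beta).max() > separation_bound:
            separation = True
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(y * np.log(np.clip(p, 1e-300, None))
                          + (1 - y) * np.log(np.clip(1 - p, 1e-300, None))))
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
    if not converged and not separation:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations; "
            f"gradient-norm trace tail {trace[-3:]}"
        )
    return LogisticFit(beta, se, converged, it, separation, ll, names, trace)


def _lrt_pvalue(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(sps.chi2.sf(stat, df))


@dataclass
class StepwiseResult:
    selected: list[str]
    fit: LogisticFit | None
    entry_pvalues: dict[str, float]
    skipped: list[str] = field(default_factory=list)


def forward_stepwise(candidates: pd.DataFrame, outcome, alpha_in: float = 0.05) -> StepwiseResult:
    """Forward stepwise logistic selection by likelihood-ratio test.

    Starts from the intercept-only model; at each step the candidate with
    the smallest LRT p-value enters if p < ``alpha_in`` (entry only, no
    removal).  A candidate causing separation is, when binary, scored via
    the Haldane-corrected 2x2 odds ratio instead; otherwise it is skipped
    with a logged warning.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate set must be non-empty")
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    selected: list[str] = []
    skipped: list[str] = []
    entry_p: dict[str, float] = {}
    # intercept-only log-likelihood
    pbar = y.mean()
    ll_cur = float(n * (pbar * np.log(max(pbar, 1e-300))
                        + (1 - pbar) * np.log(max(1 - pbar, 1e-300)))) if 0 < pbar < 1 else 0.0
    cur_fit: LogisticFit | None = None
    remaining = [str(c) for c in candidates.columns]
    while remaining:
        best_name, best_p, best_fit, best_ll = None, None, None, None
        for name in list(remaining):
            X_try = candidates[selected + [name]]
            try:
                fit = fit_logistic(X_try, y)
            except (RuntimeError, ValueError) as exc:
                logger.warning("candidate %s skipped: %s", name, exc)
                remaining.remove(name)
                skipped.append(name)
                continue
            if fit.separation_flag:
                col = candidates[name].to_numpy()
                if set(np.unique(col)) <= {0, 1} and not selected:
                    tab = ContingencyTable2x2.from_arrays(col, y.astype(int))
                    res = odds_ratio_2x2(tab, correction=True)
                    # Wald z on the corrected log-OR as the entry p-value
                    se = (np.log(res.ci_high) - np.log(res.odds_ratio)) / 1.96
                    z = np.log(res.odds_ratio) / se
                    p_val = float(2 * sps.norm.sf(abs(z)))
                    logger.warning(
                        "candidate %s separated; Haldane-corrected 2x2 fallback used",
                        name,
                    )
                    fit = None
                    ll_try = None
                else:
                    logger.warning("candidate %s separated; skipped", name)
                    remaining.remove(name)
                    skipped.append(name)
                    continue
            else:
                ll_try = fit.log_likelihood
                p_val = _lrt_pvalue(ll_try, ll_cur)
            if best_p is None or p_val < best_p:
                best_name, best_p, best_fit, best_ll = name, p_val, fit, ll_try
        if best_name is None or best_p is None or best_p >= alpha_in:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        entry_p[best_name] = best_p
        if best_fit is not None and best_ll is not None:
            cur_fit = best_fit
            ll_cur = best_ll
    if selected and cur_fit is None:
        try:
            cur_fit = fit_logistic(candidates[selected], y)
        except RuntimeError:
            cur_fit = None
    return StepwiseResult(selected, cur_fit, entry_p, skipped)


# ---------------------------------------------------------------------------
# Estimators


class YoudenBinarizer(TransformerMixin, BaseEstimator):
    """Per-column dichotomizer at the Youden-optimal observed threshold.

    ``fit(X, y)`` learns one threshold per column against the binary
    outcome ``y``; ``transform`` maps values to the indicator
    "value >= threshold".
    """

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        self.cutoffs_ = {
            str(c): youden_cutoff(X[c].to_numpy(), y) for c in X.columns
        }
        self.thresholds_ = np.array(
            [self.cutoffs_[str(c)].threshold for c in X.columns]
        )
        return self

    def transform(self, X):
        if not hasattr(self, "thresholds_"):
            raise ValueError("estimator is not fitted")
        X = pd.DataFrame(X)
        return (X.to_numpy(dtype=float) >= self.thresholds_).astype(int)


class ForwardStepwiseLogistic(BaseEstimator):
    """Forward stepwise logistic regression (likelihood-ratio entry test).

    Parameters
    ----------
    alpha_in : float, default 0.05
        Entry significance level for the LRT.

    Attributes
    ----------
    selected_ : list of str
        Covariates entered, in entry order.
    fit_ : LogisticFit or None
        Final fitted model over the selected covariates.
    entry_pvalues_ : dict
        LRT p-value at the step each covariate entered.
    """

    def __init__(self, alpha_in: float = 0.05):
        self.alpha_in = alpha_in

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray([str(c) for c in X.columns], dtype=object)
        self.n_features_in_ = X.shape[1]
        res = forward_stepwise(X, y, alpha_in=self.alpha_in)
        self.selected_ = res.selected
        self.fit_ = res.fit
        self.entry_pvalues_ = res.entry_pvalues
        self.skipped_ = res.skipped
        return self

    def predict_proba(self, X):
        if not hasattr(self, "selected_"):
            raise ValueError("estimator is not fitted")
        X = pd.DataFrame(X)
        if not self.selected_ or self.fit_ is None:
            raise ValueError("no covariates selected; intercept-only model")
        Z = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in self.selected_]
        )
        p = 1.0 / (1.0 + np.exp(-(Z @ self.fit_.coefficients)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
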