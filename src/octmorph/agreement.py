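"""Repeatability and regression statistics.

Paired session comparisons (paired t or Wilcoxon chosen by a
Shapiro-Wilk normality check of the differences), two-way mixed-effects
absolute-agreement single-measures intraclass correlation ICC(A,1) with
F-distribution confidence limits, within-subject coefficient of
variation with a seeded bootstrap CI, Bland-Altman limits of agreement,
Spearman rank correlation, ordinary least squares with
forward/backward stepwise model selection scored by adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import CollinearityError, ConstantInputError, DegenerateDataError


@dataclass
class PairedMeasurements:
    """Two masked measurement sessions of one parameter across subjects."""

    subject_id: np.ndarray
    obs1: np.ndarray
    obs2: np.ndarray

    def __post_init__(self):
        self.subject_id = np.asarray(self.subject_id)
        self.obs1 = np.asarray(self.obs1, dtype=float)
        self.obs2 = np.asarray(self.obs2, dtype=float)
        if not (len(self.subject_id) == len(self.obs1) == len(self.obs2)):
            raise ValueError("mismatched lengths")
        if len(self.obs1) < 2:
            raise ValueError("need at least 2 subjects")
        if np.isnan(self.obs1).any() or np.isnan(self.obs2).any():
            raise ValueError("missing values within retained pairs")

    @property
    def n(self) -> int:
        return len(self.obs1)

    @property
    def differences(self) -> np.ndarray:
        return self.obs1 - self.obs2

    @classmethod
    def from_long(cls, df: pd.DataFrame, parameter: str) -> "PairedMeasurements":
        """Build from a long table (subject_id, session, parameter, value)."""
        sub = df[df["parameter"] == parameter]
        wide = sub.pivot(index="subject_id", columns="session", values="value")
        if wide.shape[1] != 2:
            raise ValueError(f"expected exactly 2 sessions, got {wide.shape[1]}")
        wide = wide.dropna()
        return cls(wide.index.to_numpy(), wide.iloc[:, 0].to_numpy(),
                   wide.iloc[:, 1].to_numpy())


@dataclass
class AgreementResult:
    """Row type of a repeatability table."""

    parameter: str
    n: int
    mean1: float
    mean2: float
    p_paired: float
    test_used: str
    mean_diff: float
    mean_diff_ci: tuple
    loa_lower: float
    loa_upper: float
    cov_percent: float
    cov_ci: tuple
    icc: float
    icc_ci: tuple

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("mean_diff_ci", "cov_ci", "icc_ci"):
            d[k] = list(d[k])
        return d


def paired_test(pairs: PairedMeasurements):
    """Paired t-test when the differences pass Shapiro-Wilk normality
    (p >= 0.05), Wilcoxon signed-rank otherwise.

    Returns ``(p_value, test_used)`` where ``test_used`` is
    ``'paired_t' | 'wilcoxon' | 'degenerate'`` (all differences zero gives
    p = 1)."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    d = pairs.differences
    if np.all(d == d[0]) and d[0] == 0:
        return 1.0, "degenerate"
    if np.all(d == d[0]):
        # constant non-zero shift: normality is vacuous, t-test degenerate
        return 0.0, "degenerate"
    sw_p = stats.shapiro(d).pvalue
    if sw_p >= 0.05:
        return float(stats.ttest_rel(pairs.obs1, pairs.obs2).pvalue), "paired_t"
    return float(stats.wilcoxon(pairs.obs1, pairs.obs2).pvalue), "wilcoxon"


def _anova_mean_squares(pairs: PairedMeasurements):
    """Two-way (subjects x sessions) ANOVA mean squares, k = 2 sessions."""
    data = np.column_stack([pairs.obs1, pairs.obs2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc(pairs: PairedMeasurements, alpha: float = 0.05):
    """ICC(A,1): two-way mixed-effects, absolute agreement, single measures.

    Computed from the ANOVA mean squares as
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` with k = 2
    sessions; the CI uses the F-distribution method with Satterthwaite
    degrees of freedom.  Raises :class:`DegenerateDataError` when there is
    no between-subject variance."""
    n, k, msr, msc, mse = _anova_mean_squares(pairs)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or msr <= 1e-30:
        raise DegenerateDataError("no between-subject variance; ICC undefined")
    value = (msr - mse) / denom
    if mse == 0 and msc == mse:
        return float(value), (float(value), float(value))
    a = (k * value) / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = value
    return float(value), (float(lower), float(upper))


def coefficient_of_variation(pairs: PairedMeasurements, *, n_boot: int = 2000,
                             seed: int = 0, alpha: float = 0.05):
    """Within-subject CoV (root-mean-square method), percent.

    ``CoV = sqrt( (1/2n) sum d_i^2 ) / grand_mean x 100`` with a seeded
    percentile-bootstrap CI over subjects."""
    d = pairs.differences
    grand = np.mean((pairs.obs1 + pairs.obs2) / 2)
    if grand <= 0:
        raise ValueError("grand mean must be positive for a CoV")
    value = 100.0 * np.sqrt(np.mean(d ** 2) / 2.0) / grand
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pairs.n, size=(n_boot, pairs.n))
    o1, o2 = pairs.obs1[idx], pairs.obs2[idx]
    boots = 100.0 * np.sqrt(np.mean((o1 - o2) ** 2, axis=1) / 2.0) \
        / np.mean((o1 + o2) / 2, axis=1)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(value), (float(lo), float(hi))


def bland_altman(pairs: PairedMeasurements, alpha: float = 0.05):
    """Mean difference, its t-based CI, and 1.96-SD limits of agreement."""
    if pairs.n < 3:
        raise ValueError("need at least 3 pairs")
    d = pairs.differences
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    se = sd / np.sqrt(pairs.n)
    tcrit = stats.t.ppf(1 - alpha / 2, pairs.n - 1)
    ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    return mean_diff, ci, (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)


def spearman_rho(x, y):
    """Spearman rank correlation (mid-ranks for ties) with a t-approximation
    p-value on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length sequences of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("Spearman rho undefined for a constant sequence")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_bootstrap_ci(x, y, *, n_boot: int = 1000, seed: int = 0,
                          alpha: float = 0.05):
    """Seeded percentile-bootstrap CI for Spearman's rho (vectorised)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    rhos = np.where(denom > 0, (rx * ry).sum(axis=1) / np.where(denom == 0, 1, denom),
                    np.nan)
    rhos = rhos[np.isfinite(rhos)]
    lo, hi = np.percentile(rhos, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# regression

@dataclass
class RegressionResult:
    dependent: str
    predictors: tuple
    coefficients: dict
    conf_int: dict
    p_values: dict
    r2: float
    adjusted_r2: float
    n: int
    selection_path: list = field(default_factory=list)

    def predict(self, values: dict) -> float:
        """Evaluate the linear model at the supplied predictor values."""
        y = self.coefficients.get("const", 0.0)
        for name in self.predictors:
            y += self.coefficients[name] * values[name]
        return float(y)

    def to_dict(self) -> dict:
        return {
            "dependent": self.dependent, "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "p_values": self.p_values, "r2": self.r2,
            "adjusted_r2": self.adjusted_r2, "n": self.n,
            "selection_path": self.selection_path,
        }


def _design_matrix(table: pd.DataFrame, predictors):
    X = pd.DataFrame(index=table.index)
    for name in predictors:
        col = table[name]
        if col.dtype == object or col.dtype.name in ("category", "bool"):
            codes, _ = pd.factorize(col)
            X[name] = codes.astype(float)
        else:
            X[name] = col.astype(float)
    return X


def fit_regression(table: pd.DataFrame, dependent: str, predictors) -> RegressionResult:
    """Ordinary least squares with intercept and t-based 95% CIs.

    Raises :class:`CollinearityError` naming the offending columns on a
    rank-deficient design, and ``ValueError`` for constant predictors or
    too few rows."""
    predictors = list(predictors)
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    X = _design_matrix(table, predictors)
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant predictors: {const_cols}")
    y = table[dependent].astype(float)
    if predictors:
        Xc = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            bad = []
            base_rank = np.linalg.matrix_rank(Xc.to_numpy())
            for c in X.columns:
                if np.linalg.matrix_rank(Xc.drop(columns=[c]).to_numpy()) == base_rank:
                    bad.append(c)
            raise CollinearityError(bad or list(X.columns))
        fit = sm.OLS(y, Xc).fit()
    else:
        fit = sm.OLS(y, np.ones((n, 1))).fit()
    ci = fit.conf_int(alpha=0.05)
    names = list(fit.params.index) if predictors else ["const"]
    coefficients = {k: float(v) for k, v in zip(names, np.atleast_1d(fit.params))}
    ci_arr = np.atleast_2d(np.asarray(ci))
    conf = {k: (float(lo), float(hi)) for k, (lo, hi) in zip(names, ci_arr)}
    pvals = {k: float(v) for k, v in zip(names, np.atleast_1d(fit.pvalues))}
    r2 = float(fit.rsquared) if predictors else 0.0
    adj = float(fit.rsquared_adj) if predictors else 0.0
    return RegressionResult(dependent, tuple(predictors), coefficients, conf,
                            pvals, r2, adj, n)


def select_model(table: pd.DataFrame, dependent: str, candidate_predictors, *,
                 enter_p: float = 0.05, remove_p: float = 0.05) -> RegressionResult:
    """Forward selection plus backward elimination; the winner is the model
    with the greatest adjusted R² among the two models the procedures end
    at (ties broken toward fewer predictors, then lexicographically).

    The selection path (ordered add/drop log) is attached to the result.
    """
    candidates = list(candidate_predictors)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    cache: dict = {}

    def fitted(preds):
        key = frozenset(preds)
        if key not in cache:
            cache[key] = fit_regression(table, dependent, sorted(preds))
        return cache[key]

    path = []
    fitted(())

    current: set = set()
    while True:
        remaining = [c for c in candidates if c not in current]
        if not remaining:
            break
        trials = [(fitted(current | {c}).p_values[c], c) for c in remaining]
        best_p, best_c = min(trials)
        if best_p < enter_p:
            current.add(best_c)
            path.append(("forward_add", best_c, best_p))
        else:
            break
    forward_terminal = frozenset(current)

    current = set(candidates)
    fitted(current)
    while current:
        fit = fitted(current)
        worst_c, worst_p = max(((c, fit.p_values[c]) for c in current),
                               key=lambda t: t[1])
        if worst_p >= remove_p:
            current.remove(worst_c)
            path.append(("backward_drop", worst_c, worst_p))
        else:
            break
    backward_terminal = frozenset(current)

    def sort_key(key):
        res = fitted(key)
        return (-res.adjusted_r2, len(key), tuple(sorted(key)))

    winner_key = min({forward_terminal, backward_terminal}, key=sort_key)
    winner = fitted(winner_key)
    winner.selection_path = path
    return winner
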