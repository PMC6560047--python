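"""Behavioral interference statistics, partial correlations, permutation and
group tests, and record-level exclusion filters.

Foil errors — choosing, on a memory-test trial, the option that is correct
only in the alternative context — are the behavioral index of memory
interference; normalized foil errors subtract the rate of never-correct
("other") errors on the same trials to control for lapses. Cross-subject
brain-behavior relationships are assessed with partial correlations
(each variable residualized on its own nuisance set by OLS), and the
difference between two correlations sharing an outcome is tested by
permuting the outcome's subject labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


@dataclass
class BehavioralRecord:
    """One memory-test (or training) response."""

    trial: object
    response: int
    correct: bool
    error_kind: str  # {"none", "foil", "other"}
    context: str
    rt: Optional[float] = None


@dataclass
class TestResult:
    statistic: float
    p_value: float
    tails: str  # {"one", "two"}
    n: int
    method: str


class FoilStats(NamedTuple):
    accuracy_pct: float
    foil_error_pct: float
    normalized_foil_error_pct: float


# --------------------------------------------------------------------------
# Behavioral summaries

def foil_statistics(records: Sequence[BehavioralRecord]) -> FoilStats:
    """Accuracy, foil-error %, and normalized foil-error % of a record set.

    The normalized measure is the percentage of foil choices on foil trials
    minus the percentage of other-error choices on foil trials. Raises if
    the set contains no foil trials (the statistic is undefined, not zero).
    """
    records = list(records)
    if not records:
        raise ValueError("no behavioral records")
    accuracy = 100.0 * np.mean([r.correct for r in records])
    foil_trials = [r for r in records if getattr(r.trial, "is_foil_trial", False)]
    if not foil_trials:
        raise ValueError("no foil trials: foil statistics are undefined")
    n = len(foil_trials)
    foil_pct = 100.0 * sum(r.error_kind == "foil" for r in foil_trials) / n
    other_pct = 100.0 * sum(r.error_kind == "other" for r in foil_trials) / n
    return FoilStats(float(accuracy), float(foil_pct), float(foil_pct - other_pct))


def learning_accuracy(block_accuracies: Sequence[float]) -> float:
    """Accuracy of the participant's best training block."""
    accs = list(block_accuracies)
    if not accs:
        raise ValueError("no training blocks")
    return float(max(accs))


# --------------------------------------------------------------------------
# Partial correlation

@dataclass
class PartialCorrInputs:
    yi: np.ndarray
    yj: np.ndarray
    xi: Optional[np.ndarray] = None  # nuisance for yi (1-D or 2-D)
    xj: Optional[np.ndarray] = None  # nuisance for yj


class PartialCorrResult(NamedTuple):
    r: float
    p: float
    plot_i: np.ndarray
    plot_j: np.ndarray


def _as_nuisance(x, n) -> np.ndarray:
    if x is None:
        return np.empty((n, 0))
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _residualize(y: np.ndarray, x: np.ndarray) -> Tuple[np.ndarray, float]:
    X = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    eps = y - X @ beta
    return eps, float(beta[0])


def partial_correlation(
    inputs: PartialCorrInputs, method: str = "pearson"
) -> PartialCorrResult:
    """Correlation between residuals of each outcome on its own nuisance set.

    Rows with missing values in any input are dropped (listwise deletion).
    The p-value uses a t reference with n - 2 - k degrees of freedom, where
    k is the larger of the two nuisance column counts. Residuals returned
    for plotting are shifted by intercept plus the outcome mean.
    """
    yi = np.asarray(inputs.yi, dtype=float)
    yj = np.asarray(inputs.yj, dtype=float)
    if yi.shape != yj.shape:
        raise ValueError("outcome vectors must have equal length")
    n0 = len(yi)
    xi = _as_nuisance(inputs.xi, n0)
    xj = _as_nuisance(inputs.xj, n0)
    keep = (
        np.isfinite(yi)
        & np.isfinite(yj)
        & np.isfinite(xi).all(axis=1)
        & np.isfinite(xj).all(axis=1)
    )
    yi, yj, xi, xj = yi[keep], yj[keep], xi[keep], xj[keep]
    n = len(yi)
    k = max(xi.shape[1], xj.shape[1])
    if n <= k + 2:
        raise ValueError("too few observations for the nuisance set")
    eps_i, b0_i = _residualize(yi, xi)
    eps_j, b0_j = _residualize(yj, xj)
    if np.std(eps_i) == 0 or np.std(eps_j) == 0:
        raise ValueError("constant residuals; partial correlation undefined")
    if method == "pearson":
        r = float(np.corrcoef(eps_i, eps_j)[0, 1])
    elif method == "spearman":
        r = float(sps.spearmanr(eps_i, eps_j).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    dof = n - 2 - k
    t = r * np.sqrt(dof / max(1.0 - r**2, 1e-300))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(
        r=r,
        p=min(p, 1.0),
        plot_i=eps_i + b0_i + yi.mean(),
        plot_j=eps_j + b0_j + yj.mean(),
    )


# --------------------------------------------------------------------------
# Permutation test for a difference between two correlations

def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("constant input vector")
    return (x - x.mean()) / s


def correlation_difference_permutation(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    method: str = "pearson",
    paired: bool = False,
) -> Tuple[float, float]:
    """Permutation test of corr(x1, y) - corr(x2, y).

    The null is built by permuting y's subject labels; by default
    independently for the two correlations within each iteration
    (``paired=True`` reuses one permutation for both). Two-sided p with the
    add-one estimator, so p is never zero.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x1) == len(x2) == len(y)):
        raise ValueError("input vectors must have equal length")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if method == "spearman":
        x1, x2, y = (sps.rankdata(v) for v in (x1, x2, y))
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    n = len(y)
    z1, z2, zy = _standardize(x1), _standardize(x2), _standardize(y)
    observed = float(np.dot(z1, zy) / n - np.dot(z2, zy) / n)

    rng = np.random.default_rng(seed)
    perms1 = np.argsort(rng.random((n_perm, n)), axis=1)
    yp1 = zy[perms1]
    r1 = yp1 @ z1 / n
    if paired:
        r2 = yp1 @ z2 / n
    else:
        perms2 = np.argsort(rng.random((n_perm, n)), axis=1)
        r2 = zy[perms2] @ z2 / n
    null = r1 - r2
    p = float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1))
    return observed, p


# --------------------------------------------------------------------------
# Group tests

def _tail_adjust(stat: float, p_two: float, tails: str) -> float:
    if tails == "two":
        return p_two
    # one-tailed in the direction of positive statistic
    return p_two / 2.0 if stat >= 0 else 1.0 - p_two / 2.0


def paired_ttest(a, b, tails: str = "two") -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.all(d == 0):
        return TestResult(0.0, 1.0, tails, len(d), "paired t")
    if np.std(d, ddof=1) == 0:
        raise ValueError("degenerate variance in paired differences")
    t, p = sps.ttest_rel(a, b)
    return TestResult(float(t), float(_tail_adjust(t, p, tails)), tails, len(d), "paired t")


def one_sample_ttest(a, popmean: float = 0.0, tails: str = "two") -> TestResult:
    a = np.asarray(a, dtype=float)
    if np.all(a == popmean):
        return TestResult(0.0, 1.0, tails, len(a), "one-sample t")
    if np.std(a, ddof=1) == 0:
        raise ValueError("degenerate variance")
    t, p = sps.ttest_1samp(a, popmean)
    return TestResult(float(t), float(_tail_adjust(t, p, tails)), tails, len(a), "one-sample t")


def two_sample_ttest(a, b, tails: str = "two") -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b):
        return TestResult(0.0, 1.0, tails, len(a) + len(b), "two-sample t")
    t, p = sps.ttest_ind(a, b)
    return TestResult(float(t), float(_tail_adjust(t, p, tails)), tails, len(a) + len(b), "two-sample t")


def one_way_anova(*groups) -> TestResult:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    f, p = sps.f_oneway(*groups)
    return TestResult(float(f), float(p), "two", sum(len(g) for g in groups), "one-way ANOVA")


def regression_with_covariates(
    y, indicator, covariates: Optional[pd.DataFrame] = None, tails: str = "two"
) -> TestResult:
    """Multiple regression of ``y`` on a group indicator plus covariates;
    the test is on the indicator's coefficient."""
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame({"indicator": np.asarray(indicator, dtype=float)})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    model = sm.OLS(y, sm.add_constant(X)).fit()
    t = float(model.tvalues["indicator"])
    p = float(model.pvalues["indicator"])
    return TestResult(t, float(_tail_adjust(t, p, tails)), tails, len(y), "OLS regression")


# --------------------------------------------------------------------------
# Exclusion filters

def mrs_quality_filter(measurements: Iterable, crlb_max: float = 50.0) -> list:
    """Keep metabolite records whose CRLB is at or below the threshold."""
    if crlb_max <= 0:
        raise ValueError("crlb_max must be positive")
    return [m for m in measurements if m.crlb <= crlb_max]


def subject_exclusions(
    subjects: Sequence, scan_accuracy_min: float = 0.80
) -> pd.DataFrame:
    """Per-subject exclusion table.

    A subject is excluded from fMRI analyses if any scan-task block falls
    below ``scan_accuracy_min`` (boundary inclusive: exactly 80% is
    retained), and from MRS-involving analyses if their GABA fit is
    flagged inestimable.
    """
    rows = []
    for s in subjects:
        accs = s.behavior.scan_accuracy if hasattr(s, "behavior") else s.scan_accuracy
        fmri_excluded = any(a < scan_accuracy_min for a in accs)
        mrs_excluded = bool(getattr(s, "gaba_inestimable", False))
        reasons = []
        if fmri_excluded:
            reasons.append(f"scan-task accuracy below {scan_accuracy_min:.0%}")
        if mrs_excluded:
            reasons.append("GABA inestimable")
        rows.append(
            {
                "subject_id": getattr(s, "subject_id", None),
                "fmri_excluded": fmri_excluded,
                "mrs_excluded": mrs_excluded,
                "reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows)
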