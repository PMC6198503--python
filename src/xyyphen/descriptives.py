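"""Normality-gated univariate cohort statistics and classification rules.

The testing machinery mirrors a SAS-style descriptive workflow: each
variable is screened with Shapiro-Wilk at alpha = .05; normal variables are
contrasted with independent-samples t tests (pooled vs Satterthwaite decided
by a folded-F test on the variances), non-normal variables with the
tie-corrected Wilcoxon rank-sum Z (exact enumeration at small combined n).
Categorical contrasts use the uncorrected Pearson chi-square or Fisher's
exact test.  One-sample t tests compare cohort means against instrument
population norms.  No multiplicity adjustment is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableSummary",
    "TestResult",
    "ClassificationRule",
    "summarize_variable",
    "one_sample_t",
    "two_sample_t",
    "wilcoxon_rank_sum",
    "pearson_chi_square",
    "fisher_exact",
    "gated_group_contrast",
    "classify_delays_and_sld",
    "iq_band",
]

ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Raised for inputs on which the requested statistic is undefined."""


@dataclass(frozen=True)
class VariableSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    shapiro_p: float
    is_normal: bool

    def __post_init__(self) -> None:
        if self.n < 1 or self.sd < 0:
            raise ValueError("invalid summary")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")

    def describe(self) -> str:
        """Table-1-style description: mean +/- SD if normal, else median [IQR]."""
        if self.is_normal:
            return f"{self.mean:.2f} ± {self.sd:.2f}"
        return f"{self.median:g} [{self.q1:g}–{self.q3:g}]"


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: float | None
    p: float
    alpha: float = ALPHA
    effect_direction: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p outside [0,1]: {self.p}")
        if self.df is not None and not (self.df > 0 or math.isnan(self.df)):
            raise ValueError(f"df must be positive, got {self.df}")

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[~np.isnan(x)]


def summarize_variable(values, alpha: float = ALPHA) -> VariableSummary:
    """Moment and quantile summaries plus the Shapiro-Wilk normality gate."""
    x = _clean(values)
    if x.size == 0:
        raise DegenerateInputError("all values missing")
    if x.size < 3:
        raise DegenerateInputError(f"need >= 3 non-missing values for the normality gate, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant column: normality and dispersion undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000; irrelevant here
        sw_p = float(stats.shapiro(x).pvalue)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return VariableSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        shapiro_p=sw_p,
        is_normal=sw_p >= alpha,
    )


def one_sample_t(mean: float, sd: float, n: int, mu0: float) -> TestResult:
    """One-sample t test from summary statistics against a norm ``mu0``."""
    if n < 2:
        raise DegenerateInputError("one-sample t needs n >= 2")
    if sd <= 0:
        raise DegenerateInputError("one-sample t needs sd > 0")
    t = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    return TestResult("one-sample t", float(t), float(df), float(p),
                      effect_direction=int(np.sign(mean - mu0)))


def _folded_f_unequal(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """SAS-style folded-F test of equal variances; True => use Satterthwaite."""
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if v1 == 0 and v2 == 0:
        raise DegenerateInputError("both groups have zero variance: folded-F undefined")
    if min(v1, v2) == 0:
        raise DegenerateInputError("a group has zero variance: variance ratio undefined")
    if v1 >= v2:
        f, d1, d2 = v1 / v2, a.size - 1, b.size - 1
    else:
        f, d1, d2 = v2 / v1, b.size - 1, a.size - 1
    p = 2 * stats.f.sf(f, d1, d2)
    return min(p, 1.0) < alpha


def two_sample_t(group_a, group_b, variance_rule: str = "folded_f",
                 alpha: float = ALPHA) -> TestResult:
    """Independent-samples t test.

    ``variance_rule``: ``"folded_f"`` (pooled unless the folded-F variance
    test rejects at ``alpha``, then Satterthwaite), ``"pooled"``, or
    ``"welch"`` (always Satterthwaite).  Satterthwaite df are fractional.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs n >= 2")
    n1, n2 = a.size, b.size
    m1, m2 = np.mean(a), np.mean(b)
    v1, v2 = np.var(a, ddof=1), np.var(b, ddof=1)

    if variance_rule == "folded_f":
        use_welch = _folded_f_unequal(a, b, alpha)
    elif variance_rule == "welch":
        use_welch = True
    elif variance_rule == "pooled":
        use_welch = False
    else:
        raise ValueError(f"unknown variance_rule {variance_rule!r}")

    if use_welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            t, df = 0.0, float(n1 + n2 - 2)
        else:
            t = (m1 - m2) / math.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        method = "Satterthwaite t"
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = float(n1 + n2 - 2)
        if sp2 == 0:
            t = 0.0
        else:
            t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        method = "pooled t"
    p = 2 * stats.t.sf(abs(t), df) if not math.isnan(t) else float("nan")
    return TestResult(method, float(t), float(df), float(min(p, 1.0)),
                      effect_direction=int(np.sign(m1 - m2)))


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, s_obs: float) -> float:
    """Two-sided exact p for the rank-sum statistic by full enumeration of
    all assignments of the pooled (mid-)ranks to group A."""
    idx = range(ranks.size)
    sums = np.array([ranks[list(c)].sum() for c in combinations(idx, n_a)])
    p_lo = np.mean(sums <= s_obs + 1e-12)
    p_hi = np.mean(sums >= s_obs - 1e-12)
    return float(min(1.0, 2 * min(p_lo, p_hi)))


def wilcoxon_rank_sum(group_a, group_b, continuity: bool = True,
                      exact_max_n: int = 10) -> TestResult:
    """Wilcoxon rank-sum test with mid-ranks and tie-corrected variance.

    Reports a normal-approximation Z (with continuity correction by
    default); when the combined sample size is <= ``exact_max_n`` the
    two-sided p comes from exact enumeration over all group assignments of
    the pooled ranks instead.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    N = n1 + n2
    ranks = stats.rankdata(pooled)
    s = ranks[:n1].sum()
    e = n1 * (N + 1) / 2.0
    # tie-corrected permutation variance of the rank sum
    var = n1 * n2 / (N * (N - 1)) * (np.sum(ranks**2) - N * (N + 1) ** 2 / 4.0)
    if var <= 0:
        warnings.warn("all values tied across both groups; Z = 0", stacklevel=2)
        return TestResult("Wilcoxon rank-sum Z", 0.0, None, 1.0, note="all tied")
    diff = s - e
    cc = 0.5 if (continuity and diff != 0) else 0.0
    z = (abs(diff) - cc) / math.sqrt(var) * (1 if diff >= 0 else -1)
    if N <= exact_max_n:
        p = _exact_rank_sum_p(ranks, n1, s)
        method = "Wilcoxon rank-sum (exact)"
    else:
        p = 2 * stats.norm.sf(abs(z))
        method = "Wilcoxon rank-sum Z"
    return TestResult(method, float(z), None, float(p),
                      effect_direction=int(np.sign(diff)))


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if t.sum() == 0:
        raise DegenerateInputError("empty table")
    return t.astype(float)


def pearson_chi_square(table) -> TestResult:
    """Uncorrected Pearson chi-square for a 2x2 table (df = 1)."""
    t = _as_2x2(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateInputError(
            "zero row/column margin: chi-square undefined; use fisher_exact"
        )
    expected = np.outer(rows, cols) / t.sum()
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    direction = int(np.sign(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]))
    return TestResult("Pearson chi-square", chi2, 1.0, p, effect_direction=direction)


def fisher_exact(table) -> TestResult:
    """Fisher's exact test, two-sided by summing hypergeometric
    probabilities no larger than the observed table's."""
    t = _as_2x2(table).astype(int)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return TestResult("Fisher exact", float("nan"), None, 1.0, note="degenerate margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    direction = int(np.sign(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]))
    return TestResult("Fisher exact", float("nan"), None, float(p), effect_direction=direction)


def gated_group_contrast(group_a, group_b, alpha: float = ALPHA,
                         variance_rule: str = "folded_f") -> tuple[TestResult, VariableSummary]:
    """Dispatch a two-group contrast through the normality gate.

    The variable (both groups pooled, as tabulated) is summarized first; a
    non-significant Shapiro-Wilk sends the contrast to the t test, a
    significant one to the Wilcoxon rank-sum.  Returns the chosen test's
    result (identical to calling it directly) and the gating summary.
    """
    a, b = _clean(group_a), _clean(group_b)
    summary = summarize_variable(np.concatenate([a, b]), alpha=alpha)
    if summary.is_normal:
        result = two_sample_t(a, b, variance_rule=variance_rule, alpha=alpha)
    else:
        result = wilcoxon_rank_sum(a, b)
    return result, summary


def iq_band(fsiq: float) -> str:
    """Conventional FSIQ bands: average >= 85, borderline 70-84, mild 55-69,
    moderate 40-54, severe below."""
    if np.isnan(fsiq):
        return "unknown"
    if fsiq >= 85:
        return "average"
    if fsiq >= 70:
        return "borderline"
    if fsiq >= 55:
        return "mild"
    if fsiq >= 40:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class ClassificationRule:
    """Milestone-delay and specific-learning-disability rules.

    A milestone is delayed when the age is *strictly greater* than the
    threshold (24 months exactly is on time).  SLD requires at least one
    achievement standard score below 78 (1.5 SD below the population mean)
    AND FSIQ above 70.
    """

    milestone_threshold: float = 24.0
    milestone_cols: tuple[str, ...] = ("age_first_words", "age_phrases", "age_walked")
    continence_thresholds: tuple[tuple[str, float], ...] = (
        ("daytime_continence", 36.0),
        ("nighttime_continence", 48.0),
        ("bowel_continence", 36.0),
    )
    achievement_cols: tuple[str, ...] = ("wj_reading", "wj_math", "wj_writing")
    sld_cutoff: float = 78.0
    fsiq_floor: float = 70.0
    fsiq_col: str = "fsiq"

    def __post_init__(self) -> None:
        if self.milestone_threshold <= 0 or self.sld_cutoff <= 0:
            raise ValueError("thresholds must be strictly positive")
        for _, thr in self.continence_thresholds:
            if thr <= 0:
                raise ValueError("thresholds must be strictly positive")


def _rate(k: int, n: int) -> str:
    return f"{k}/{n} ({0 if n == 0 else round(100 * k / n):.0f}%)"


def classify_delays_and_sld(
    data: pd.DataFrame, rule: ClassificationRule | None = None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-participant delay/SLD flags plus cohort rates with explicit
    denominators ("25/53 (47%)" style).

    Missing inputs yield missing flags (pd.NA), never False: a participant
    with no FSIQ has an undetermined SLD status and drops out of the
    denominator.
    """
    rule = rule or ClassificationRule()
    flags = pd.DataFrame(index=data.index)

    thresholds = [(c, rule.milestone_threshold) for c in rule.milestone_cols]
    thresholds += list(rule.continence_thresholds)
    for col, thr in thresholds:
        if col not in data.columns:
            continue
        x = data[col]
        flags[f"{col}_delayed"] = pd.array(
            np.where(x.isna(), pd.NA, x > thr), dtype="boolean"
        )

    ach = [c for c in rule.achievement_cols if c in data.columns]
    if ach and rule.fsiq_col in data.columns:
        below = data[ach] < rule.sld_cutoff
        any_below = pd.array(
            np.where(data[ach].isna().all(axis=1), pd.NA, below.any(axis=1)),
            dtype="boolean",
        )
        fsiq_ok = pd.array(
            np.where(data[rule.fsiq_col].isna(), pd.NA, data[rule.fsiq_col] > rule.fsiq_floor),
            dtype="boolean",
        )
        # A False on either side decides SLD=False even if the other is missing.
        flags["sld"] = any_below & fsiq_ok
        for c in ach:
            flags[f"sld_{c}"] = pd.array(
                np.where(data[c].isna(), pd.NA, data[c] < rule.sld_cutoff), dtype="boolean"
            ) & fsiq_ok

    rates = {}
    for col in flags.columns:
        f = flags[col]
        n = int(f.notna().sum())
        k = int((f == True).sum())  # noqa: E712 — boolean dtype with NA
        rates[col] = _rate(k, n)
    return flags, rates
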