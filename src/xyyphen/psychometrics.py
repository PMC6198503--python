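"""Diagnostic-instrument psychometrics against a reference ASD diagnosis.

Sensitivity and specificity of binary instrument calls, exact binomial
(Clopper-Pearson) confidence intervals, rank-based AUC with a stratified
bootstrap CI, and the whole battery stratified by co-occurring behavior
problems (CBCL internalizing/externalizing T >= 64) — the structure of a
diagnostic-accuracy table with full-sample and stratum rows per instrument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "PerformanceEstimate",
    "InstrumentSpec",
    "StratumSpec",
    "confusion_from_calls",
    "clopper_pearson_ci",
    "sensitivity_specificity",
    "auc",
    "stratified_performance",
]


class UndefinedMetricError(ValueError):
    """A performance metric whose denominator class is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class PerformanceEstimate:
    metric: str  # sensitivity | specificity | auc
    point: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_effective: int

    def __post_init__(self) -> None:
        for v in (self.point, self.ci_low, self.ci_high):
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"{self.metric}: value {v} outside [0,1]")
        if not math.isnan(self.point) and not (
            self.ci_low - 1e-12 <= self.point <= self.ci_high + 1e-12
        ):
            raise ValueError(f"{self.metric}: point outside CI")


def confusion_from_calls(instrument_positive, diagnosis) -> ConfusionCounts:
    """Cross-tabulate binary instrument calls against the reference
    diagnosis.  Pairs with a missing value on either side are dropped (the
    count of dropped pairs is warned when non-zero)."""
    call = np.asarray(instrument_positive, dtype=float)
    dx = np.asarray(diagnosis, dtype=float)
    if call.shape != dx.shape:
        raise ValueError("call and diagnosis vectors must align")
    keep = ~(np.isnan(call) | np.isnan(dx))
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} participant(s) with missing call/diagnosis", stacklevel=2)
    call, dx = call[keep].astype(bool), dx[keep].astype(bool)
    return ConfusionCounts(
        tp=int((call & dx).sum()),
        fp=int((call & ~dx).sum()),
        tn=int((~call & ~dx).sum()),
        fn=int((~call & dx).sum()),
    )


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI by inverting binomial tails (beta quantiles).

    ``x = 0`` pins the lower bound at exactly 0; ``x = n`` pins the upper
    bound at exactly 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    a = (1.0 - level) / 2.0
    lo = 0.0 if x == 0 else float(stats.beta.ppf(a, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1.0 - a, x + 1, n - x))
    return lo, hi


def sensitivity_specificity(
    counts: ConfusionCounts, level: float = 0.95
) -> dict[str, PerformanceEstimate]:
    """Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), each with a
    Clopper-Pearson CI.  An empty class raises ``UndefinedMetricError``."""
    out = {}
    for metric, x, n in [
        ("sensitivity", counts.tp, counts.n_cases),
        ("specificity", counts.tn, counts.n_controls),
    ]:
        if n == 0:
            raise UndefinedMetricError(f"{metric} undefined: empty denominator class")
        lo, hi = clopper_pearson_ci(x, n, level)
        out[metric] = PerformanceEstimate(metric, x / n, lo, hi, "Clopper-Pearson", n)
    return out


def _rank_auc(scores: np.ndarray, dx: np.ndarray) -> float:
    """P(random case outscores random control), ties counted 1/2."""
    ranks = stats.rankdata(scores)
    n_pos = int(dx.sum())
    n_neg = dx.size - n_pos
    u = ranks[dx].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc(
    scores,
    diagnosis,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> PerformanceEstimate:
    """Rank-based AUC of a continuous instrument score against diagnosis.

    The CI is a stratified bootstrap (cases and controls resampled
    separately, ``n_boot`` draws, percentile interval).  Constant scores
    give AUC = 0.5 with a warning.
    """
    s = np.asarray(scores, dtype=float)
    d = np.asarray(diagnosis, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(d))
    s, d = s[keep], d[keep].astype(bool)
    n_pos, n_neg = int(d.sum()), int((~d).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs at least one case and one control")
    if np.ptp(s) == 0:
        warnings.warn("constant scores: AUC = 0.5", stacklevel=2)
        return PerformanceEstimate("auc", 0.5, 0.5, 0.5, "degenerate", n_pos + n_neg)
    point = _rank_auc(s, d)
    rng = np.random.default_rng(seed)
    pos, neg = s[d], s[~d]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = pos[rng.integers(0, n_pos, n_pos)]
        bn = neg[rng.integers(0, n_neg, n_neg)]
        boots[i] = _rank_auc(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)]),
        )
    a = (1 - level) / 2
    lo, hi = np.quantile(boots, [a, 1 - a])
    lo, hi = min(lo, point), max(hi, point)
    return PerformanceEstimate("auc", point, float(lo), float(hi), "stratified bootstrap", n_pos + n_neg)


@dataclass(frozen=True)
class InstrumentSpec:
    """How one instrument enters the evaluation.

    ``call_col`` names an existing binary positivity column; alternatively
    ``score_col`` + ``cutoff`` derive the call (``score >= cutoff`` when
    ``higher_positive``).  ``score_col`` also feeds the AUC when
    ``auc_mode='score'``; with ``auc_mode='call'`` the binary call itself is
    scored (cut-off-level AUC).
    """

    name: str
    call_col: str | None = None
    score_col: str | None = None
    cutoff: float | None = None
    higher_positive: bool = True

    def __post_init__(self) -> None:
        if self.call_col is None and (self.score_col is None or self.cutoff is None):
            raise ValueError(f"instrument {self.name!r}: need call_col or score_col+cutoff")

    def calls(self, data: pd.DataFrame) -> pd.Series:
        if self.call_col is not None:
            return data[self.call_col]
        s = data[self.score_col]
        pos = s >= self.cutoff if self.higher_positive else s <= self.cutoff
        return pos.astype(float).where(s.notna())

    def scores(self, data: pd.DataFrame, auc_mode: str) -> pd.Series | None:
        if auc_mode == "call" or self.score_col is None:
            c = self.calls(data)
            return c if self.higher_positive else 1 - c
        s = data[self.score_col]
        return s if self.higher_positive else -s


@dataclass(frozen=True)
class StratumSpec:
    stratifier: str  # column name, e.g. cbcl_internalizing
    cutoff: float = 64.0

    def masks(self, data: pd.DataFrame) -> dict[str, pd.Series]:
        x = data[self.stratifier]
        return {
            f"{self.stratifier} < {self.cutoff:g}": x < self.cutoff,
            f"{self.stratifier} >= {self.cutoff:g}": x >= self.cutoff,
        }


def _row(
    data: pd.DataFrame,
    inst: InstrumentSpec,
    dx_col: str,
    label: str,
    auc_mode: str,
    level: float,
    seed: int,
) -> dict:
    dx = data[dx_col]
    row = {
        "instrument": inst.name,
        "stratum": label,
        "n_asd": int((dx == 1).sum()),
        "n_non_asd": int((dx == 0).sum()),
    }
    calls = inst.calls(data)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts = confusion_from_calls(calls, dx)
            perf = sensitivity_specificity(counts, level)
        for m in ("sensitivity", "specificity"):
            e = perf[m]
            row[m], row[f"{m}_lo"], row[f"{m}_hi"] = e.point, e.ci_low, e.ci_high
    except UndefinedMetricError:
        for m in ("sensitivity", "specificity"):
            row[m] = row[f"{m}_lo"] = row[f"{m}_hi"] = float("nan")
    scores = inst.scores(data, auc_mode)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e = auc(scores, dx, level=level, seed=seed)
        row["auc"], row["auc_lo"], row["auc_hi"] = e.point, e.ci_low, e.ci_high
    except UndefinedMetricError:
        row["auc"] = row["auc_lo"] = row["auc_hi"] = float("nan")
    return row


def stratified_performance(
    data: pd.DataFrame,
    instruments: list[InstrumentSpec],
    dx_col: str = "dsm5_asd",
    strata: list[StratumSpec] | None = None,
    auc_mode: str = "score",
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Full diagnostic-accuracy table: per instrument, a full-sample row and
    one row per stratum side (participants missing the stratifier fall out
    of both sides but stay in the full sample).  Rows with an empty class
    keep their place with NaN metrics."""
    if auc_mode not in ("score", "call"):
        raise ValueError("auc_mode must be 'score' or 'call'")
    if strata is None:
        strata = [
            StratumSpec(c) for c in ("cbcl_externalizing", "cbcl_internalizing")
            if c in data.columns
        ]
    usable = data[data[dx_col].notna()]
    rows = []
    for inst in instruments:
        rows.append(_row(usable, inst, dx_col, "full sample", auc_mode, level, seed))
        for spec in strata:
            for label, mask in spec.masks(usable).items():
                rows.append(_row(usable[mask], inst, dx_col, label, auc_mode, level, seed))
    return pd.DataFrame(rows)
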