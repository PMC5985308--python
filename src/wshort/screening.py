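"""Screening evaluation at a giftedness cutoff, plus group descriptives.

Classification calls a case positive when its score is at or above the
cutoff (ties count as positive).  AUC is the Mann-Whitney probability
that a random gifted case outscores a random typical case, with ties
credited 1/2 — equivalent to exhaustive concordant-pair counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ScreeningReport:
    """Confusion-matrix and ROC summary for one form at one cutoff."""

    form: str
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 1.0 - self.sensitivity

    def as_row(self) -> dict:
        return {
            "form": self.form, "cutoff": self.cutoff, "auc": self.auc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "fpr": self.fpr, "fnr": self.fnr,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def classify_and_summarize(
    scores: Sequence[float],
    labels: Sequence[bool],
    cutoff: float = 125.0,
    *,
    form: str = "",
) -> ScreeningReport:
    """Confusion counts and AUC of ``scores`` against binary ``labels``.

    ``labels`` is True for the gifted (positive) class.  With a single
    class present the confusion counts are still returned and AUC is NaN.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    pred = s >= cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos and n_neg:
        ranks = stats.rankdata(s)  # mid-ranks give ties 1/2 credit
        auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    else:
        auc = float("nan")
    return ScreeningReport(form, cutoff, tp, fp, tn, fn, float(auc))


@dataclass(frozen=True)
class ZouCIResult:
    """95% CI for the difference of two dependent, overlapping correlations."""

    r1: float
    r2: float
    r23: float
    n: int
    lower: float
    upper: float
    conf: float = 0.95

    @property
    def diff(self) -> float:
        return self.r1 - self.r2


def zou_ci_dependent_overlapping(
    r1: float, r2: float, r23: float, n: int, conf: float = 0.95
) -> ZouCIResult:
    """Zou's interval for r1 - r2 when both correlations share a variable.

    r1 = corr(X1, Y), r2 = corr(X2, Y), r23 = corr(X1, X2).  Individual
    Fisher-z confidence limits per correlation are combined through the
    asymptotic correlation between the two estimates.
    """
    for label, r in (("r1", r1), ("r2", r2), ("r23", r23)):
        if not abs(r) < 1:
            raise ValueError(f"{label} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    zc = stats.norm.ppf(0.5 + conf / 2.0)
    h = zc / np.sqrt(n - 3)

    def limits(r: float) -> tuple[float, float]:
        z = np.arctanh(r)
        return float(np.tanh(z - h)), float(np.tanh(z + h))

    l1, u1 = limits(r1)
    l2, u2 = limits(r2)
    c = ((r23 - r1 * r2 / 2.0) * (1 - r1**2 - r2**2 - r23**2) + r23**3) / (
        (1 - r1**2) * (1 - r2**2)
    )
    if not -1.0 <= c <= 1.0:
        raise ValueError(
            f"inconsistent correlation triple (implied estimator correlation {c:.3f})"
        )
    diff = r1 - r2
    lower = diff - np.sqrt(
        (r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2)
    )
    upper = diff + np.sqrt(
        (u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2)
    )
    return ZouCIResult(r1, r2, r23, n, float(lower), float(upper), conf)


def cohen_d_independent(
    a: Sequence[float] | tuple[float, float, int],
    b: Sequence[float] | tuple[float, float, int],
) -> float:
    """Pooled-SD standardised mean difference d_s between two groups.

    Each group is either a raw score vector or a ``(mean, sd, n)``
    summary triple (sample SD, n-1 denominator).
    """

    def summarise(g) -> tuple[float, float, int]:
        if isinstance(g, tuple) and len(g) == 3:
            return float(g[0]), float(g[1]), int(g[2])
        v = np.asarray(g, dtype=float)
        return float(v.mean()), float(v.std(ddof=1)), len(v)

    m_a, sd_a, n_a = summarise(a)
    m_b, sd_b, n_b = summarise(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((m_a - m_b) / pooled)


def sample_statistics(scores: Sequence[float]) -> dict:
    """Mean, sample SD, adjusted skewness and adjusted excess kurtosis.

    Uses the bias-adjusted Fisher-Pearson skewness and adjusted excess
    kurtosis, the usual reporting convention in descriptive tables.
    Higher moments of a constant vector are NaN.
    """
    x = np.asarray(scores, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return {"mean": float(x.mean()), "sd": 0.0,
                "skewness": float("nan"), "kurtosis": float("nan")}
    kurt = (float(stats.kurtosis(x, bias=False, fisher=True))
            if len(x) >= 4 else float("nan"))
    return {
        "mean": float(x.mean()),
        "sd": sd,
        "skewness": float(stats.skew(x, bias=False)),
        "kurtosis": kurt,
    }


def group_balance_tests(
    age_a: Sequence[float],
    age_b: Sequence[float],
    sex_counts_a: tuple[int, int],
    sex_counts_b: tuple[int, int],
) -> dict:
    """Welch t on age and 2x2 Pearson chi-square (no continuity) on sex.

    Satterthwaite degrees of freedom are reported fractionally.  Used to
    confirm that generated two-group samples are demographically matched.
    """
    a = np.asarray(age_a, dtype=float)
    b = np.asarray(age_b, dtype=float)
    t, p_t = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    table = np.array([sex_counts_a, sex_counts_b], dtype=float)
    chi2, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
    return {
        "t": float(t), "df": float(df), "p_age": float(p_t),
        "chi2": float(chi2), "p_sex": float(p_chi),
    }
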