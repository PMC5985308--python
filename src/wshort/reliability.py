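"""Reliability indices: composite reliability, SEM, hierarchical omega, ICC.

Composite reliability of a sum of p subtests with reliabilities r_jj and
pairwise correlations r_jk is the classical

    r_cc = (sum r_jj + 2 sum r_jk) / (p + 2 sum r_jk)

on the standardised metric.  Hierarchical omega is the share of the
composite's variance carried by the general factor of the *full*
battery:  omega_H = (sum of general loadings)^2 / (p + 2 sum r_jk).
General loadings come from a higher-order factor model (group factors =
index membership, one second-order factor) fitted by unweighted least
squares and collapsed by the Schmid-Leiman transformation; for 2-item
composites this is the only route, since a general factor is not
identifiable from 2 items alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateCompositeError, EstimationError


def composite_reliability(r_jj: Sequence[float], sum_r_jk: float) -> float:
    """r_cc of a composite from subtest reliabilities and correlation sum."""
    p = len(r_jj)
    if p < 1:
        raise ValueError("need at least one subtest reliability")
    denom = p + 2.0 * sum_r_jk
    if denom <= 0:
        raise DegenerateCompositeError(
            f"composite variance p + 2*sum_r_jk = {denom} is not positive"
        )
    return float((np.sum(r_jj) + 2.0 * sum_r_jk) / denom)


def sem(r_cc: float, composite_sd: float = 15.0) -> float:
    """Standard error of measurement: composite_sd * sqrt(1 - r_cc)."""
    if not 0.0 <= r_cc <= 1.0:
        raise ValueError(f"r_cc must lie in [0, 1], got {r_cc}")
    return float(composite_sd * np.sqrt(1.0 - r_cc))


@dataclass(frozen=True)
class GeneralLoadings:
    """Per-subtest general-factor loadings lambda_g, keyed by subtest name."""

    loadings: Mapping[str, float]
    method: str

    def subset(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.loadings]
        if missing:
            raise KeyError(f"no general loading for subtest(s) {missing}")
        return np.array([self.loadings[n] for n in names], dtype=float)


def estimate_general_loadings(
    battery,
    *,
    supplied: Mapping[str, float] | None = None,
) -> GeneralLoadings:
    """General-factor loadings of every subtest in ``battery``.

    Fits an independent-cluster higher-order model to the battery's
    correlation matrix: subtest i loads lambda_i on its index's group
    factor, group factor m loads gamma_m on a single second-order general
    factor, so the model correlation is

        R_ij = lambda_i lambda_j             (same index)
        R_ij = lambda_i lambda_j gamma_m gamma_m'   (different indices)

    minimised by unweighted least squares on the off-diagonal residuals.
    The Schmid-Leiman general loading is lambda_g,i = lambda_i * gamma_m.
    ``supplied`` bypasses estimation (method="supplied").
    """
    names = list(battery.subtest_names)
    if supplied is not None:
        return GeneralLoadings(dict(supplied), method="supplied")
    groups = [s.index for s in battery.subtests]
    group_labels = sorted(set(groups))
    if len(names) < 3 or len(group_labels) < 2:
        raise EstimationError(
            "need >= 3 subtests in >= 2 index groups to identify a general factor"
        )
    k = len(names)
    g_of = np.array([group_labels.index(g) for g in groups])
    r = battery.correlation
    iu, ju = np.triu_indices(k, 1)
    same = g_of[iu] == g_of[ju]
    obs = r[iu, ju]

    def model(theta: np.ndarray) -> np.ndarray:
        lam, gam = theta[:k], theta[k:]
        m = lam[iu] * lam[ju]
        return np.where(same, m, m * gam[g_of[iu]] * gam[g_of[ju]])

    # data-driven start: sqrt of mean absolute off-diagonal per row
    off = np.abs(r - np.eye(k))
    lam0 = np.sqrt(np.clip(off.sum(axis=1) / (k - 1), 0.01, 0.81))
    theta0 = np.concatenate([lam0, np.full(len(group_labels), 0.8)])
    lower = np.zeros(k + len(group_labels))
    upper = np.concatenate([np.full(k, 2.0), np.ones(len(group_labels))])
    fit = least_squares(
        lambda t: model(t) - obs, theta0, bounds=(lower, upper), xtol=1e-12
    )
    if fit.status <= 0:
        raise EstimationError(f"higher-order ULS fit did not converge: {fit.message}")
    lam, gam = fit.x[:k], fit.x[k:]
    lam_g = lam * gam[g_of]
    if (lam_g > 1.0).any():
        warnings.warn(
            "Heywood case: general loading(s) above 1 clipped to 1", stacklevel=2
        )
        lam_g = np.clip(lam_g, 0.0, 1.0)
    return GeneralLoadings(dict(zip(names, lam_g)), method="uls-schmid-leiman")


def omega_hierarchical(
    loadings: GeneralLoadings | Sequence[float], subset: Sequence[str] | None, sum_r_jk: float
) -> float:
    """omega_H of a composite: general variance over total sum-score variance.

    ``loadings`` may be a :class:`GeneralLoadings` (with ``subset`` naming
    the composite members) or a raw loading vector (``subset`` ignored).
    """
    if isinstance(loadings, GeneralLoadings):
        lam = loadings.subset(list(subset))
    else:
        lam = np.asarray(loadings, dtype=float)
    p = len(lam)
    denom = p + 2.0 * sum_r_jk
    if denom <= 0:
        raise DegenerateCompositeError("composite variance is not positive")
    return float(lam.sum() ** 2 / denom)


def icc_a1(x: Sequence[float], y: Sequence[float]) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares with rows = subjects and
    columns = the two scores being compared.  Unlike Pearson r it
    penalises mean shifts and scale changes.  Negative values are
    returned unfloored; zero total variance yields NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    sst = float(((data - grand) ** 2).sum())
    if sst == 0.0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return float("nan")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    )
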