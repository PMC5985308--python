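"""Validity indices of a short form against a full composite.

A short form built from a subset of the full scale shares measurement
error with it, which inflates the raw part-whole Pearson correlation
r_sf.  The corrected correlation subtracts that shared-error covariance:

    r' = r_sf - (1 - r_cc) * sqrt(p + 2 S_p) / sqrt(m + 2 S_m) * (SD_sf / SD_c)

with p, S_p the short form's size and correlation sum, m, S_m the
reference composite's, SD_sf the observed short-form SD and SD_c the
composite-metric SD (15).  On equated simulated populations the SD
ratio is ~1; a strategy switch drops it.

The panel for one form collects r_cc, omega_H, and {r', ICC, C_acc} per
reference scale, summarised by the agreement score R_c = the unweighted
mean of those eight values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .battery import ShortFormDef

REFERENCE_SCALES = ("FSIQ", "GAI")


def corrected_correlation(
    r_sf: float,
    r_cc: float,
    p: int,
    sum_r_jk: float,
    m: int,
    sum_r_lm: float,
    sd_sf: float,
    composite_sd: float = 15.0,
    *,
    sd_ratio: bool = True,
) -> float:
    """Part-whole correlation corrected for shared error variance."""
    denom = m + 2.0 * sum_r_lm
    if denom <= 0:
        raise ValueError("reference-composite variance is not positive")
    correction = (1.0 - r_cc) * np.sqrt((p + 2.0 * sum_r_jk) / denom)
    if sd_ratio:
        correction *= sd_sf / composite_sd
    return float(r_sf - correction)


@dataclass(frozen=True)
class DiscrepancyResult:
    """Paired comparison of short-form vs full-scale means."""

    mean_diff: float
    t: float
    df: int
    p_value: float
    d_rm: float
    degenerate: bool = False


def discrepancy_test(
    sf_scores: Sequence[float], full_scores: Sequence[float]
) -> DiscrepancyResult:
    """Two-tailed paired t-test of (short form - full scale) with d_rm.

    The repeated-measures effect size follows the correlation-adjusted
    convention:  d_rm = mean_diff / sqrt(sd1^2 + sd2^2 - 2 r sd1 sd2)
    * sqrt(2 (1 - r)).  A zero-variance difference vector is flagged
    rather than reported as an infinite t.
    """
    sf = np.asarray(sf_scores, dtype=float)
    full = np.asarray(full_scores, dtype=float)
    if sf.shape != full.shape or sf.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    n = len(sf)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    diff = sf - full
    sd_diff = diff.std(ddof=1)
    mean_diff = float(diff.mean())
    if sd_diff == 0.0:
        warnings.warn("zero-variance difference: t undefined", stacklevel=2)
        return DiscrepancyResult(mean_diff, float("nan"), n - 1, float("nan"),
                                 float("nan"), degenerate=True)
    t = mean_diff / (sd_diff / np.sqrt(n))
    p_value = 2.0 * stats.t.sf(abs(t), n - 1)
    r = float(np.corrcoef(sf, full)[0, 1])
    sd1, sd2 = sf.std(ddof=1), full.std(ddof=1)
    d_rm = mean_diff / np.sqrt(sd1**2 + sd2**2 - 2 * r * sd1 * sd2) * np.sqrt(
        2.0 * (1.0 - r)
    )
    return DiscrepancyResult(mean_diff, float(t), n - 1, float(p_value), float(d_rm))


def c_acc(
    sf_scores: Sequence[float],
    full_scores: Sequence[float],
    cutoff: float = 125.0,
    sem: float | None = None,
) -> float:
    """Identification-accuracy indicator.

    Among cases truly at/above the cutoff on the full scale, the share
    whose short-form score is also at/above the cutoff *and* within
    +/- 2 SEM of the full-scale score (the score-stability rule).
    Undefined (NaN, with warning) when no case reaches the cutoff.
    """
    if sem is None or sem <= 0:
        raise ValueError("a positive short-form SEM is required")
    sf = np.asarray(sf_scores, dtype=float)
    full = np.asarray(full_scores, dtype=float)
    if sf.shape != full.shape:
        raise ValueError("paired vectors of equal length required")
    truly = full >= cutoff
    denom = int(truly.sum())
    if denom == 0:
        warnings.warn("no case reaches the cutoff: C_acc undefined", stacklevel=2)
        return float("nan")
    hit = truly & (sf >= cutoff) & (np.abs(sf - full) <= 2.0 * sem)
    return float(hit.sum() / denom)


@dataclass(frozen=True)
class ScaleIndices:
    """Validity indices of one form against one reference scale."""

    r_sf: float
    r_prime: float
    icc: float
    c_acc: float


@dataclass(frozen=True)
class IndexPanel:
    """Full reliability/validity panel of one short form."""

    form: ShortFormDef
    r_cc: float
    omega_h: float
    scales: Mapping[str, ScaleIndices]
    extras: dict = field(default_factory=dict, compare=False)

    @property
    def name(self) -> str:
        return self.form.name

    @property
    def r_c(self) -> float:
        return r_c_composite(self)

    def constituents(self) -> list[float]:
        vals = [self.r_cc, self.omega_h]
        for scale in REFERENCE_SCALES:
            s = self.scales[scale]
            vals += [s.r_prime, s.icc, s.c_acc]
        return vals

    def as_row(self) -> dict:
        row = {"form": self.name, "p": self.form.p,
               "r_cc": self.r_cc, "omega_h": self.omega_h}
        for scale, s in self.scales.items():
            row[f"{scale}_r_sf"] = s.r_sf
            row[f"{scale}_r_prime"] = s.r_prime
            row[f"{scale}_icc"] = s.icc
            row[f"{scale}_c_acc"] = s.c_acc
        row["r_c"] = self.r_c
        return row


def r_c_composite(panel: IndexPanel) -> float:
    """Agreement score R_c: unweighted mean of the eight panel indices.

    The constituents are r_cc, omega_H, and {r', ICC, C_acc} for each of
    the two reference scales.  Any missing (NaN) constituent is an error.
    """
    vals = panel.constituents()
    labels = ["r_cc", "omega_h"] + [
        f"{s}_{i}" for s in REFERENCE_SCALES for i in ("r_prime", "icc", "c_acc")
    ]
    bad = [lab for lab, v in zip(labels, vals) if v is None or not np.isfinite(v)]
    if bad:
        raise ValueError(f"R_c undefined: missing constituent(s) {bad}")
    return float(np.mean(vals))


def r_c_from_values(values: Sequence[float]) -> float:
    """R_c straight from an 8-vector of panel indices (fixture path)."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (8,) or not np.isfinite(vals).all():
        raise ValueError("need 8 finite constituent indices")
    return float(vals.mean())


def rank_short_forms(
    panels: Sequence[IndexPanel], top: int | None = None
) -> list[IndexPanel]:
    """Panels in decreasing R_c, per size class; top-k per class if given.

    Ties break by higher r_cc, then lexicographic form name.
    """
    if not panels:
        raise ValueError("no panels to rank")
    out: list[IndexPanel] = []
    for size in sorted({p.form.p for p in panels}):
        group = [p for p in panels if p.form.p == size]
        group.sort(key=lambda p: (-p.r_c, -p.r_cc, p.name))
        out.extend(group if top is None else group[:top])
    return out


def compare_index_panels(
    panels_a: Sequence[IndexPanel], panels_b: Sequence[IndexPanel]
) -> pd.DataFrame:
    """Mean difference and Pearson r of each index across matched forms.

    Mirrors an empirical-vs-simulated agreement check: rows are the
    indices (per scale) plus R_c; columns ``difference`` (mean a-b) and
    ``r`` across the matched forms.
    """
    a_by = {p.name: p for p in panels_a}
    b_by = {p.name: p for p in panels_b}
    if set(a_by) != set(b_by):
        raise ValueError(
            f"form sets differ: {sorted(set(a_by) ^ set(b_by))}"
        )
    names = sorted(a_by)

    def col(getter) -> tuple[np.ndarray, np.ndarray]:
        va = np.array([getter(a_by[n]) for n in names])
        vb = np.array([getter(b_by[n]) for n in names])
        return va, vb

    rows = {}
    items: list[tuple[str, callable]] = [("r_cc", lambda p: p.r_cc),
                                         ("omega_h", lambda p: p.omega_h)]
    for scale in REFERENCE_SCALES:
        for ind in ("r_prime", "icc", "c_acc"):
            items.append(
                (f"{scale}_{ind}",
                 lambda p, s=scale, i=ind: getattr(p.scales[s], i))
            )
    items.append(("r_c", lambda p: p.r_c))
    for label, getter in items:
        va, vb = col(getter)
        r = float(np.corrcoef(va, vb)[0, 1]) if len(names) > 1 and va.std() > 0 and vb.std() > 0 else float("nan")
        rows[label] = {"difference": float((va - vb).mean()), "r": r}
    return pd.DataFrame(rows).T
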