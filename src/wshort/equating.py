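"""Linear equating of sums of scaled scores onto the deviation-IQ metric.

The equating line for a composite of p subtests with pairwise-correlation
sum S = sum r_jk follows from the variance of a sum of standardised
scores: the sum score has SD  sigma_sum = scaled_sd * sqrt(p + 2S), so

    slope     = composite_sd / sigma_sum
    intercept = composite_mean - slope * p * scaled_mean

which sends the population mean of the sum to the composite mean and its
SD to the composite SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCompositeError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Norms:
    """Score-metric constants: scaled subtests and standard composites."""

    scaled_mean: float = 10.0
    scaled_sd: float = 3.0
    composite_mean: float = 100.0
    composite_sd: float = 15.0


def composite_coefficients(
    p: int, sum_r_jk: float, norms: Norms = Norms()
) -> tuple[float, float]:
    """Equating slope and intercept for a p-subtest composite.

    Raises
    ------
    DegenerateCompositeError
        If the implied sum-score variance p + 2*sum_r_jk is not positive.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    var = p + 2.0 * sum_r_jk
    if var <= 0:
        raise DegenerateCompositeError(
            f"sum-score variance p + 2*sum_r_jk = {var} is not positive"
        )
    s_c = norms.scaled_sd * np.sqrt(var)
    slope = norms.composite_sd / s_c
    intercept = norms.composite_mean - slope * p * norms.scaled_mean
    return float(slope), float(intercept)


def score_composite(
    scores: pd.DataFrame,
    subset: Sequence[str],
    slope: float,
    intercept: float,
    *,
    round_coefficients: int | None = None,
) -> pd.Series:
    """Score a composite: slope * (sum of subset columns) + intercept.

    Rows with a missing subset value are dropped (complete-case policy)
    and their ids logged.  ``round_coefficients`` reproduces scoring with
    printed, rounded coefficients (e.g. 2 decimals) for cross-checks; the
    default full-precision path is the computational one.
    """
    missing_cols = [s for s in subset if s not in scores.columns]
    if missing_cols:
        raise KeyError(f"score table lacks subtest column(s) {missing_cols}")
    block = scores.loc[:, list(subset)]
    ok = block.notna().all(axis=1)
    if not ok.all():
        dropped = scores.index[~ok].tolist()
        log.warning("dropping %d incomplete row(s): %s", len(dropped), dropped)
        block = block.loc[ok]
    if round_coefficients is not None:
        slope = round(slope, round_coefficients)
        intercept = round(intercept, round_coefficients)
    return slope * block.sum(axis=1) + intercept


def full_composite_scores(
    scores: pd.DataFrame,
    battery,
    composite_name: str,
    *,
    prefer_column: bool = True,
) -> pd.Series:
    """Standard scores for a named full composite (FSIQ, GAI, ...).

    If the table already carries a column of that name — the empirical
    case, where composites come from norm tables — that column is
    returned verbatim when ``prefer_column`` is set; the equated version
    remains available by passing ``prefer_column=False``.
    """
    if composite_name not in battery.composites:
        raise KeyError(f"battery defines no composite {composite_name!r}")
    if prefer_column and composite_name in scores.columns:
        return scores[composite_name]
    members = battery.composites[composite_name]
    slope, intercept = composite_coefficients(
        len(members), battery.sum_r(members), battery.norms
    )
    return score_composite(scores, members, slope, intercept)
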