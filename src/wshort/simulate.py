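"""Monte-Carlo population simulation from a battery correlation matrix.

Scores are drawn multivariate normal via the lower Cholesky factor of
the target correlation matrix and rescaled to the scaled-score metric
(mean 10, SD 3).  An optional discretisation rounds half-away-from-zero
to integers and clips to the published scaled-score range [1, 19]; it
attenuates correlations slightly and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import BatteryValidationError

DEFAULT_N = 1_000_000
DEFAULT_SEED = 20180528

Provenance = Literal["simulated", "empirical", "synthetic-fixture"]


@dataclass
class PopulationSample:
    """A table of per-individual scaled scores, one column per subtest.

    Composite columns are appended by the scoring layer.  ``scores`` may
    also carry id/group/age/sex columns in empirical or synthetic mode.
    """

    scores: pd.DataFrame
    provenance: Provenance = "simulated"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.scores)

    def write_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path, index=False)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_population(
    battery,
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
    *,
    discretize: bool = False,
) -> PopulationSample:
    """Draw ``n`` cases of correlated scaled scores from ``battery``.

    Fully reproducible from ``seed``.  Raises a factorisation error if
    the matrix is indefinite (load the battery with ``repair_psd`` for
    marginally indefinite transcriptions).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    r = battery.correlation
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        # exactly singular but PSD matrices still admit a factor
        w, v = np.linalg.eigh(r)
        if w.min() < -1e-8:
            raise BatteryValidationError(
                f"correlation matrix is indefinite (min eigenvalue {w.min():.3e})"
            ) from None
        chol = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, r.shape[0]))
    x = battery.norms.scaled_mean + battery.norms.scaled_sd * (z @ chol.T)
    if discretize:
        x = np.clip(_round_half_away(x), 1, 19)
    frame = pd.DataFrame(x, columns=list(battery.subtest_names))
    return PopulationSample(frame, provenance="simulated", seed=seed)


def correlation_recovery(sample: PopulationSample, battery) -> float:
    """Max |sample correlation - target| over off-diagonal cells.

    A simulation health check; provenance-agnostic.
    """
    cols = list(battery.subtest_names)
    got = sample.scores[cols].corr().to_numpy()
    dev = np.abs(got - battery.correlation)
    np.fill_diagonal(dev, 0.0)
    return float(dev.max())
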