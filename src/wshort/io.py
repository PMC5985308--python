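"""Score-file I/O: one row per child, one column per subtest code.

Schema: ``id``, optional ``group`` / ``age_months`` / ``sex``, one
column per subtest, optional precomputed composite columns (FSIQ, GAI).
UTF-8 CSV, decimal point.  Rows missing any battery subtest are dropped
with their ids logged; extra annotation columns pass through untouched.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .simulate import PopulationSample

log = logging.getLogger(__name__)


def read_scores(path: str | Path, battery=None) -> PopulationSample:
    frame = pd.read_csv(path)
    provenance = "empirical"
    if battery is not None:
        missing = [s for s in battery.subtest_names if s not in frame.columns]
        if missing:
            raise KeyError(
                f"score file {path} lacks battery subtest column(s) {missing}"
            )
        ok = frame[list(battery.subtest_names)].notna().all(axis=1)
        if not ok.all():
            ids = (frame.loc[~ok, "id"].tolist()
                   if "id" in frame.columns else frame.index[~ok].tolist())
            log.warning("dropping %d incomplete row(s): %s", len(ids), ids)
            frame = frame.loc[ok].reset_index(drop=True)
    return PopulationSample(frame, provenance=provenance)


def write_scores(sample: PopulationSample, path: str | Path) -> None:
    sample.scores.to_csv(path, index=False)
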