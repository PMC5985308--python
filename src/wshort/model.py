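"""Model/Results orchestration of the short-form evaluation pipeline.

:class:`ShortFormModel` holds the design — a battery, the candidate form
sizes, the reference scales and the giftedness cutoff — plus optionally
an observed sample.  ``fit()`` scores every candidate form on the sample
(simulating one from the battery's correlation matrix when none is
given) and returns a :class:`ShortFormResults` carrying the per-form
reliability/validity panels, rankings, discrepancy tests and screening
reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .battery import BatterySpec, ShortFormDef, enumerate_short_forms, load_battery
from .equating import full_composite_scores, score_composite
from .reliability import GeneralLoadings, estimate_general_loadings, omega_hierarchical
from .screening import ScreeningReport, classify_and_summarize
from .simulate import DEFAULT_N, DEFAULT_SEED, PopulationSample, simulate_population
from .validity import (
    IndexPanel,
    ScaleIndices,
    c_acc,
    corrected_correlation,
    discrepancy_test,
    rank_short_forms,
)


class ShortFormModel:
    """Short-form evaluation design for one battery.

    Parameters
    ----------
    battery
        A validated :class:`~wshort.battery.BatterySpec`.
    sample
        Observed scores (empirical mode).  When ``None``, ``fit``
        simulates a population from the battery's correlation matrix.
    sizes
        Candidate short-form sizes drawn from the verbal/performance
        pools (2 and/or 4).
    scales
        Reference full composites the forms are validated against.
    cutoff
        Standard-score threshold defining giftedness (default 125, the
        95th percentile).
    """

    def __init__(
        self,
        battery: BatterySpec,
        sample: PopulationSample | None = None,
        *,
        sizes: Sequence[int] = (2, 4),
        scales: Sequence[str] = ("FSIQ", "GAI"),
        cutoff: float = 125.0,
    ) -> None:
        for scale in scales:
            if scale not in battery.composites:
                raise KeyError(f"battery defines no composite {scale!r}")
        self.battery = battery
        self.sample = sample
        self.sizes = tuple(sizes)
        self.scales = tuple(scales)
        self.cutoff = float(cutoff)
        self.forms: list[ShortFormDef] = enumerate_short_forms(battery, self.sizes)

    @classmethod
    def from_config(
        cls, battery_path: str | Path, scores_path: str | Path | None = None, **kwargs
    ) -> "ShortFormModel":
        from .io import read_scores

        battery = load_battery(battery_path)
        sample = read_scores(scores_path, battery) if scores_path else None
        return cls(battery, sample, **kwargs)

    def fit(
        self,
        n: int = DEFAULT_N,
        seed: int = DEFAULT_SEED,
        *,
        discretize: bool = False,
        sd_ratio: bool = True,
        loadings: GeneralLoadings | None = None,
    ) -> "ShortFormResults":
        """Score every candidate form and compute its index panel.

        ``n``/``seed``/``discretize`` control the simulated population
        and are ignored in empirical mode.  ``sd_ratio`` selects the
        corrected-correlation variant that scales the shared-error term
        by the observed short-form SD over the composite SD.
        """
        battery = self.battery
        if self.sample is not None:
            sample = self.sample
            n, seed = sample.n, sample.seed
        else:
            sample = simulate_population(battery, n=n, seed=seed,
                                         discretize=discretize)
        if loadings is None:
            loadings = estimate_general_loadings(battery)

        data = sample.scores.copy()
        full: dict[str, pd.Series] = {}
        for scale in self.scales:
            full[scale] = full_composite_scores(data, battery, scale)
            data[f"{scale}_equated"] = full_composite_scores(
                data, battery, scale, prefer_column=False
            )
            data[scale] = full[scale]

        panels: list[IndexPanel] = []
        for form in self.forms:
            sf = score_composite(data, form.subset, form.slope, form.intercept)
            data[form.name] = sf
            omega = omega_hierarchical(loadings, form.subset, form.sum_r_jk)
            per_scale: dict[str, ScaleIndices] = {}
            for scale in self.scales:
                ref = full[scale]
                members = battery.composites[scale]
                r_sf = float(np.corrcoef(sf, ref)[0, 1])
                r_prime = corrected_correlation(
                    r_sf, form.r_cc, form.p, form.sum_r_jk,
                    len(members), battery.sum_r(members),
                    sd_sf=float(sf.std(ddof=1)),
                    composite_sd=battery.norms.composite_sd,
                    sd_ratio=sd_ratio,
                )
                from .reliability import icc_a1

                per_scale[scale] = ScaleIndices(
                    r_sf=r_sf,
                    r_prime=r_prime,
                    icc=icc_a1(sf.to_numpy(), ref.to_numpy()),
                    c_acc=c_acc(sf, ref, cutoff=self.cutoff, sem=form.sem),
                )
            panels.append(
                IndexPanel(form=form, r_cc=form.r_cc, omega_h=omega,
                           scales=per_scale)
            )
        return ShortFormResults(
            model=self, sample=sample, scored=data, panels=panels,
            loadings=loadings, n=n, seed=seed,
        )


@dataclass
class ShortFormResults:
    """Fitted short-form evaluation: panels, rankings and reports."""

    model: ShortFormModel
    sample: PopulationSample
    scored: pd.DataFrame
    panels: list[IndexPanel]
    loadings: GeneralLoadings
    n: int
    seed: int | None
    _ranked: list[IndexPanel] | None = field(default=None, repr=False)

    # -- tables -------------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        """Per-form index panel table, ranked by R_c within size class."""
        rows = [p.as_row() for p in rank_short_forms(self.panels)]
        return pd.DataFrame(rows).set_index("form")

    def rank(self, top: int | None = None) -> list[IndexPanel]:
        return rank_short_forms(self.panels, top)

    def panel(self, name: str) -> IndexPanel:
        for p in self.panels:
            if p.name == name:
                return p
        raise KeyError(f"no panel for form {name!r}")

    # -- follow-up analyses -------------------------------------------

    def discrepancies(self, scale: str = "FSIQ",
                      bonferroni: bool = False) -> pd.DataFrame:
        """Paired t and d_rm of each form against one reference scale.

        With ``bonferroni`` the significance threshold 0.05 is divided
        by the number of forms tested and reported per row.
        """
        alpha = 0.05 / len(self.panels) if bonferroni else 0.05
        rows = []
        for p in self.panels:
            res = discrepancy_test(self.scored[p.name], self.scored[scale])
            rows.append({
                "form": p.name, "mean_diff": res.mean_diff, "t": res.t,
                "df": res.df, "p_value": res.p_value, "d_rm": res.d_rm,
                "significant": bool(res.p_value < alpha)
                if np.isfinite(res.p_value) else False,
            })
        return pd.DataFrame(rows).set_index("form")

    def screen(
        self,
        forms: Sequence[str] | None = None,
        *,
        reference_scale: str = "FSIQ",
        cutoff: float | None = None,
    ) -> pd.DataFrame:
        """Screening reports: confusion counts and AUC per form.

        The gold standard is the clinical ``group`` column when the
        sample carries one (empirical mode); otherwise the reference
        full scale at the cutoff (simulation mode).
        """
        cutoff = self.model.cutoff if cutoff is None else cutoff
        if forms is None:
            forms = [p.name for p in self.rank(3)]
        if "group" in self.scored.columns:
            labels = (self.scored["group"] == "gifted").to_numpy()
        else:
            labels = (self.scored[reference_scale] >= cutoff).to_numpy()
        rows = []
        for name in forms:
            rep: ScreeningReport = classify_and_summarize(
                self.scored[name], labels, cutoff, form=name
            )
            rows.append(rep.as_row())
        return pd.DataFrame(rows).set_index("form")

    def pooled_correlation(self, size: int, scale: str = "FSIQ") -> float:
        """Correlation between form and full scores stacked across all
        forms of one size class (each case contributes once per form)."""
        names = [p.name for p in self.panels if p.form.p == size]
        if not names:
            raise ValueError(f"no forms of size {size}")
        sf = np.concatenate([self.scored[n].to_numpy() for n in names])
        ref = np.tile(self.scored[scale].to_numpy(), len(names))
        return float(np.corrcoef(sf, ref)[0, 1])

    # -- reporting ----------------------------------------------------

    @property
    def manifest(self) -> dict:
        doc = json.dumps(self.model.battery.to_dict(), sort_keys=True)
        return {
            "battery": self.model.battery.name,
            "battery_sha256": hashlib.sha256(doc.encode()).hexdigest(),
            "provenance": self.sample.provenance,
            "n": int(self.n),
            "seed": self.seed,
            "sizes": list(self.model.sizes),
            "scales": list(self.model.scales),
            "cutoff": self.model.cutoff,
            "loadings_method": self.loadings.method,
        }

    def summary(self) -> str:
        """Human-readable evaluation summary (3-dp indices)."""
        lines = [
            "Short-form evaluation",
            "=" * 72,
            f"battery: {self.model.battery.name}   "
            f"sample: {self.sample.provenance} (n={self.n:,})",
            f"forms: {len(self.panels)}  sizes {self.model.sizes}  "
            f"cutoff {self.model.cutoff:g}  "
            f"loadings: {self.loadings.method}",
            "",
        ]
        tab = self.table.drop(columns=["p"]).round(3)
        lines.append(tab.to_string())
        lines.append("")
        for size in sorted(self.model.sizes):
            best = [p for p in self.rank(1) if p.form.p == size]
            if best:
                lines.append(
                    f"best {size}-subtest form: {best[0].name} "
                    f"(R_c = {best[0].r_c:.3f})"
                )
        return "\n".join(lines)
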