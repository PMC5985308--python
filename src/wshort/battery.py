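"""Battery specification: subtests, correlations, composites, and short forms.

A *battery* is a set of subtests reported on the scaled-score metric
(mean 10, SD 3) together with the published inter-subtest correlation
matrix and per-subtest reliabilities.  Composites (e.g. FSIQ, GAI) are
named subtest lists scored on the standard-score metric (mean 100,
SD 15).  Candidate short forms are drawn from two pools, conventionally
``verbal`` and ``performance``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .equating import Norms, composite_coefficients
from .errors import BatteryValidationError, SubtestReferenceError
from .reliability import composite_reliability, sem

PSD_TOL = -1e-8


@dataclass(frozen=True)
class SubtestInfo:
    """One subtest: short code, index membership, and reliability r_jj."""

    name: str
    index: str
    reliability: float
    long_name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.reliability <= 1.0:
            raise BatteryValidationError(
                f"subtest {self.name!r}: reliability must be in (0, 1], "
                f"got {self.reliability}"
            )


@dataclass(frozen=True)
class ShortFormDef:
    """A candidate subtest subset with its equating line and reliability.

    ``slope`` and ``intercept`` map the sum of scaled scores onto the
    standard-score metric; ``r_cc`` is the composite reliability and
    ``sem`` the standard error of measurement in standard-score points.
    """

    subset: tuple[str, ...]
    sum_r_jk: float
    slope: float
    intercept: float
    r_cc: float
    sem: float

    @property
    def p(self) -> int:
        return len(self.subset)

    @property
    def name(self) -> str:
        return "".join(self.subset)

    def __str__(self) -> str:  # e.g. "SiMr = 3.01 x (Si+Mr) + 39.81"
        terms = "+".join(self.subset)
        return f"{self.name} = {self.slope:.2f} x ({terms}) + {self.intercept:.2f}"


@dataclass(frozen=True)
class BatterySpec:
    """A validated test battery.

    Correlation row/column order follows ``subtests`` order.  ``meta`` is
    free-form provenance (e.g. the true loadings of a generated battery)
    and takes no part in equality or validation.
    """

    name: str
    subtests: tuple[SubtestInfo, ...]
    correlation: np.ndarray
    composites: Mapping[str, tuple[str, ...]]
    pools: Mapping[str, tuple[str, ...]]
    norms: Norms = field(default_factory=Norms)
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    # -- validation ---------------------------------------------------

    def __post_init__(self) -> None:
        names = [s.name for s in self.subtests]
        if len(set(names)) != len(names):
            raise BatteryValidationError("duplicate subtest names")
        r = np.asarray(self.correlation, dtype=float)
        object.__setattr__(self, "correlation", r)
        k = len(names)
        if r.shape != (k, k):
            raise BatteryValidationError(
                f"correlation matrix is {r.shape}, expected ({k}, {k})"
            )
        asym = np.abs(r - r.T)
        if asym.max(initial=0.0) > 1e-12:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise BatteryValidationError(
                f"correlation matrix not symmetric at cell ({i}, {j}): "
                f"{r[i, j]} vs {r[j, i]}"
            )
        if np.abs(np.diag(r) - 1.0).max() > 1e-12:
            raise BatteryValidationError("correlation diagonal must be 1")
        lo = float(np.linalg.eigvalsh(r).min())
        if lo < PSD_TOL:
            raise BatteryValidationError(
                f"correlation matrix not positive semi-definite: "
                f"smallest eigenvalue {lo:.3e}"
            )
        for label, members in {**self.composites, **self.pools}.items():
            if len(set(members)) != len(members):
                raise BatteryValidationError(f"duplicate subtest in {label!r}")
            missing = [m for m in members if m not in names]
            if missing:
                raise SubtestReferenceError(
                    f"{label!r} references unknown subtest(s) {missing}"
                )

    # -- lookups ------------------------------------------------------

    @property
    def subtest_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.subtests)

    def index_of(self, name: str) -> int:
        return self.subtest_names.index(name)

    def reliability_of(self, name: str) -> float:
        return self.subtests[self.index_of(name)].reliability

    def submatrix(self, subset: Sequence[str]) -> np.ndarray:
        idx = [self.index_of(s) for s in subset]
        return self.correlation[np.ix_(idx, idx)]

    def sum_r(self, subset: Sequence[str]) -> float:
        """Sum of the p(p-1)/2 pairwise correlations within ``subset``."""
        r = self.submatrix(subset)
        return float(r[np.triu_indices_from(r, k=1)].sum())

    def composite_correlation(self, a: Sequence[str], b: Sequence[str]) -> float:
        """Closed-form correlation between the sum scores of two subsets.

        Overlapping members contribute their unit self-correlation, which
        is what makes part-whole correlations exceed the cross-block mean.
        """
        ia = [self.index_of(s) for s in a]
        ib = [self.index_of(s) for s in b]
        cov = float(self.correlation[np.ix_(ia, ib)].sum())
        sa = np.sqrt(len(a) + 2.0 * self.sum_r(a))
        sb = np.sqrt(len(b) + 2.0 * self.sum_r(b))
        return cov / (sa * sb)

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "subtests": [
                {
                    "name": s.name,
                    "index": s.index,
                    "reliability": s.reliability,
                    **({"long_name": s.long_name} if s.long_name else {}),
                }
                for s in self.subtests
            ],
            "correlation": self.correlation.tolist(),
            "composites": {k: list(v) for k, v in self.composites.items()},
            "pools": {k: list(v) for k, v in self.pools.items()},
            "norms": {
                "scaled_mean": self.norms.scaled_mean,
                "scaled_sd": self.norms.scaled_sd,
                "composite_mean": self.norms.composite_mean,
                "composite_sd": self.norms.composite_sd,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PSD matrix.

    Negative eigenvalues are clipped to zero and the diagonal is rescaled
    back to one.  Intended for marginally indefinite, hand-transcribed
    matrices; never applied silently.
    """
    r = np.asarray(matrix, dtype=float)
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    r = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def battery_from_dict(doc: Mapping, *, repair_psd: bool = False) -> BatterySpec:
    subtests = tuple(
        SubtestInfo(
            name=s["name"],
            index=s.get("index", ""),
            reliability=float(s["reliability"]),
            long_name=s.get("long_name", ""),
        )
        for s in doc["subtests"]
    )
    corr = np.asarray(doc["correlation"], dtype=float)
    if repair_psd:
        corr = nearest_psd(corr)
    norms_doc = doc.get("norms", {})
    norms = Norms(
        scaled_mean=float(norms_doc.get("scaled_mean", 10.0)),
        scaled_sd=float(norms_doc.get("scaled_sd", 3.0)),
        composite_mean=float(norms_doc.get("composite_mean", 100.0)),
        composite_sd=float(norms_doc.get("composite_sd", 15.0)),
    )
    return BatterySpec(
        name=doc.get("name", "battery"),
        subtests=subtests,
        correlation=corr,
        composites={k: tuple(v) for k, v in doc.get("composites", {}).items()},
        pools={k: tuple(v) for k, v in doc.get("pools", {}).items()},
        norms=norms,
    )


def load_battery(path: str | Path, *, repair_psd: bool = False) -> BatterySpec:
    """Load and validate a battery config from JSON or YAML.

    ``repair_psd`` applies an explicit nearest-PSD projection before
    validation, for matrices transcribed at low precision.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)  # YAML is a JSON superset
    return battery_from_dict(doc, repair_psd=repair_psd)


def make_short_form(battery: BatterySpec, subset: Sequence[str]) -> ShortFormDef:
    """Build one short form: equating line, r_cc and SEM for ``subset``."""
    subset = tuple(subset)
    sum_r_jk = battery.sum_r(subset)
    slope, intercept = composite_coefficients(len(subset), sum_r_jk, battery.norms)
    r_jj = [battery.reliability_of(s) for s in subset]
    r_cc = composite_reliability(r_jj, sum_r_jk)
    return ShortFormDef(
        subset=subset,
        sum_r_jk=sum_r_jk,
        slope=slope,
        intercept=intercept,
        r_cc=r_cc,
        sem=sem(r_cc, battery.norms.composite_sd),
    )


def enumerate_short_forms(
    battery: BatterySpec, sizes: Iterable[int] = (2, 4)
) -> list[ShortFormDef]:
    """Enumerate candidate short forms from the verbal x performance pools.

    Size-2 forms take one subtest from each pool; size-4 forms take two
    from each.  Ordering is deterministic: by size, then lexicographic in
    the pool-order subset tuple.
    """
    from .errors import ConfigurationError

    for pool in ("verbal", "performance"):
        if not battery.pools.get(pool):
            raise ConfigurationError(f"battery defines no {pool!r} pool")
    verbal = battery.pools["verbal"]
    perf = battery.pools["performance"]
    sizes = sorted(set(sizes))
    bad = [s for s in sizes if s not in (2, 4)]
    if bad:
        raise ConfigurationError(f"unsupported short-form sizes {bad}")
    forms: list[ShortFormDef] = []
    for size in sizes:
        half = size // 2
        combos = [
            v + q
            for v in itertools.combinations(verbal, half)
            for q in itertools.combinations(perf, half)
        ]
        combos.sort()
        forms.extend(make_short_form(battery, c) for c in combos)
    return forms


def with_meta(battery: BatterySpec, **meta) -> BatterySpec:
    return replace(battery, meta={**battery.meta, **meta})
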