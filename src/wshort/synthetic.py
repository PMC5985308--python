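"""Synthetic study inputs: factor-structured batteries and two-group samples.

The published subtest correlation/reliability tables of real Wechsler
manuals are proprietary, so every pipeline input can instead be
generated here: a battery whose correlation matrix follows a
higher-order factor structure (general + index group factors), and a
two-group child sample that emulates the study design — a typical group
drawn at the population mean and a gifted group drawn mean-shifted and
then ascertained on the rule "FSIQ >= 125 or GAI >= 125".
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .battery import BatterySpec, SubtestInfo
from .equating import full_composite_scores
from .errors import ConfigurationError
from .simulate import PopulationSample, _round_half_away, simulate_population

Range = tuple[float, float]


def generate_battery_spec(
    pools: Mapping[str, Sequence[str]],
    *,
    general_range: Range | Mapping[str, Range] = (0.6, 0.8),
    group_range: Range | Mapping[str, Range] = (0.3, 0.45),
    reliability_range: Range = (0.82, 0.92),
    composites: Mapping[str, Sequence[str]] | None = None,
    enumeration_pools: Mapping[str, Sequence[str]] | None = None,
    name: str = "synthetic-battery",
    seed: int = 0,
) -> BatterySpec:
    """Generate a PSD, factor-structured battery specification.

    ``pools`` maps index labels (VCI, PRI, ...) to subtest names and
    must partition the battery.  Correlations are built as
    ``R_ij = g_i g_j + s_i s_j`` (the group term only within a pool)
    with general loadings g drawn from ``general_range`` and group
    increments s scaled per pool from ``group_range``; within a pool the
    ratio s_i/g_i is constant, so the matrix follows the exact
    independent-cluster higher-order model and the true general loadings
    (stored in ``meta["general_loadings"]``) are recoverable.
    Reliabilities are drawn uniformly, floored at each subtest's
    communality.  PSD holds by construction.
    """
    names = [s for members in pools.values() for s in members]
    if len(set(names)) != len(names):
        raise ConfigurationError("pools must partition the subtests")
    k = len(names)
    if k < 4:
        raise ConfigurationError("need at least 4 subtests")
    rng = np.random.default_rng(seed)

    def pool_range(spec: Range | Mapping[str, Range], label: str) -> Range:
        return spec[label] if isinstance(spec, Mapping) else spec

    g = np.empty(k)
    s = np.empty(k)
    pool_of: list[str] = []
    pos = 0
    for label, members in pools.items():
        m = len(members)
        lo, hi = pool_range(general_range, label)
        if not 0.0 <= lo <= hi < 1.0:
            raise ConfigurationError(f"infeasible general range for {label!r}")
        gm = rng.uniform(lo, hi, size=m)
        lo_s, hi_s = pool_range(group_range, label)
        target = rng.uniform(lo_s, hi_s)
        mean_g = gm.mean()
        sm = np.zeros(m) if mean_g == 0 else target * gm / mean_g
        # keep communalities bounded away from 1
        h2 = gm**2 + sm**2
        if (h2 >= 0.98).any():
            sm = sm * np.sqrt(np.clip((0.97 - gm**2) / np.maximum(sm**2, 1e-12), 0, 1))
        g[pos:pos + m] = gm
        s[pos:pos + m] = sm
        pool_of.extend([label] * m)
        pos += m

    corr = np.outer(g, g)
    for label in pools:
        idx = [i for i, p in enumerate(pool_of) if p == label]
        corr[np.ix_(idx, idx)] += np.outer(s[idx], s[idx])
    np.fill_diagonal(corr, 1.0)

    lo_r, hi_r = reliability_range
    if not 0.0 < lo_r <= hi_r <= 1.0:
        raise ConfigurationError("infeasible reliability range")
    h2 = g**2 + s**2
    rel = np.maximum(rng.uniform(lo_r, hi_r, size=k), h2)
    if (rel > 1.0).any():
        raise ConfigurationError("communality exceeds 1: loadings too large")

    subtests = tuple(
        SubtestInfo(name=n, index=p, reliability=float(r))
        for n, p, r in zip(names, pool_of, rel)
    )
    return BatterySpec(
        name=name,
        subtests=subtests,
        correlation=corr,
        composites={k_: tuple(v) for k_, v in (composites or {}).items()},
        pools={k_: tuple(v) for k_, v in (enumeration_pools or {}).items()},
        meta={"general_loadings": dict(zip(names, g)),
              "group_increments": dict(zip(names, s)),
              "seed": seed},
    )


def wisc_like_battery(version: str = "IV", seed: int = 0) -> BatterySpec:
    """A 10-subtest battery emulating a WISC-style structure.

    Four index pools (verbal comprehension, perceptual reasoning,
    working memory, processing speed), a 10-subtest FSIQ and a
    6-subtest GAI.  Loading ranges follow the usual ordering: the
    GAI subtests are the most g-saturated, processing speed the least.
    The correlation matrix is synthetic — generated, not transcribed
    from any manual.
    """
    if version not in ("IV", "V"):
        raise ConfigurationError("version must be 'IV' or 'V'")
    perf = ["Bd", "Pc", "Mr"] if version == "IV" else ["Bd", "Mr", "Fw"]
    pools = {
        "VCI": ["Si", "Vo", "Co"],
        "PRI": perf,
        "WMI": ["Ds", "Ln"],
        "PSI": ["Cd", "Sy"],
    }
    gai = pools["VCI"] + pools["PRI"]
    # canonical form-name order: verbal Si,Vo,Co; performance Mr,(Pc|Fw),Bd
    perf_order = ["Mr", "Pc", "Bd"] if version == "IV" else ["Mr", "Fw", "Bd"]
    return generate_battery_spec(
        pools,
        general_range={"VCI": (0.70, 0.78), "PRI": (0.64, 0.74),
                       "WMI": (0.56, 0.66), "PSI": (0.42, 0.52)},
        group_range={"VCI": (0.34, 0.44), "PRI": (0.30, 0.40),
                     "WMI": (0.36, 0.46), "PSI": (0.46, 0.56)},
        reliability_range=(0.82, 0.92),
        composites={"FSIQ": [s for m in pools.values() for s in m], "GAI": gai},
        enumeration_pools={"verbal": pools["VCI"], "performance": perf_order},
        name=f"wisc{version.lower()}-like-synthetic",
        seed=seed,
    )


# gifted-group mean shifts (scaled points above 10) emulating the
# published gifted-sample subtest means; unlisted subtests fall back to
# the mean shift of the listed ones
_GIFTED_OFFSETS = {
    name: fixtures.GROUP_DESCRIPTIVES[name]["gifted"][0] - 10.0
    for name in ("Si", "Vo", "Co", "Bd", "Pc", "Mr", "Ds", "Ln", "Cd", "Sy")
}

AGE_MOMENTS = {"gifted": (124.65, 12.34), "typical": (126.87, 31.88)}


def generate_two_group_sample(
    battery: BatterySpec,
    n_gifted: int = 117,
    n_typical: int = 52,
    *,
    offsets: Mapping[str, float] | None = None,
    cutoff: float = 125.0,
    seed: int = 0,
) -> PopulationSample:
    """A gifted + typical child sample with ascertained gifted cases.

    The typical group is drawn at the population mean.  Gifted cases are
    drawn from a mean-shifted population and kept only if their equated
    FSIQ or GAI reaches ``cutoff`` — mean shift plus ascertainment,
    because selection from an unshifted population cannot reproduce the
    published gifted subtest means.  Scores are rounded and clipped to
    [1, 19]; age and sex emulate the published group demographics.
    """
    rng = np.random.default_rng(seed)
    names = list(battery.subtest_names)
    if offsets is None:
        known = [_GIFTED_OFFSETS[n] for n in names if n in _GIFTED_OFFSETS]
        fallback = float(np.mean(known)) if known else 4.0
        offsets = {n: _GIFTED_OFFSETS.get(n, fallback) for n in names}
    shift = np.array([offsets.get(n, 0.0) for n in names])

    def draw(n: int, mean_shift: np.ndarray | float, sub_seed: int) -> pd.DataFrame:
        pop = simulate_population(battery, n=max(n, 2), seed=sub_seed)
        x = pop.scores.to_numpy()[:n] + mean_shift
        x = np.clip(_round_half_away(x), 1, 19)
        return pd.DataFrame(x, columns=names)

    # gifted: rejection-sample on the ascertainment rule
    kept: list[pd.DataFrame] = []
    total_drawn = 0
    n_kept = 0
    batch = max(4 * n_gifted, 200)
    for attempt in range(60):
        block = draw(batch, shift, int(rng.integers(2**31 - 1)))
        fsiq = full_composite_scores(block, battery, "FSIQ", prefer_column=False)
        gai = full_composite_scores(block, battery, "GAI", prefer_column=False)
        ok = (fsiq >= cutoff) | (gai >= cutoff)
        total_drawn += len(block)
        sel = block.loc[ok]
        kept.append(sel)
        n_kept += len(sel)
        if n_kept >= n_gifted:
            break
        if total_drawn >= 20 * batch and n_kept / total_drawn < 1e-4:
            raise ConfigurationError(
                "ascertainment acceptance rate below 1e-4: increase the "
                "gifted mean offsets"
            )
    if n_kept < n_gifted:
        raise ConfigurationError(
            f"could not ascertain {n_gifted} gifted cases "
            f"(acceptance rate {n_kept / max(total_drawn, 1):.2e})"
        )
    gifted = pd.concat(kept, ignore_index=True).iloc[:n_gifted]
    typical = draw(n_typical, 0.0, int(rng.integers(2**31 - 1)))

    frames = []
    for label, block, n in (("gifted", gifted, n_gifted),
                            ("typical", typical, n_typical)):
        mu, sd = AGE_MOMENTS[label]
        age = np.clip(rng.normal(mu, sd, size=n), 60, 200).round(1)
        sex = np.where(rng.random(n) < fixtures.MALE_PROP[label], "M", "F")
        out = block.reset_index(drop=True).copy()
        out.insert(0, "sex", sex)
        out.insert(0, "age_months", age)
        out.insert(0, "group", label)
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "id", [f"c{i + 1:04d}" for i in range(len(table))])
    for comp in ("FSIQ", "GAI"):
        if comp in battery.composites:
            table[comp] = full_composite_scores(
                table, battery, comp, prefer_column=False
            ).round(1)
    return PopulationSample(table, provenance="synthetic-fixture", seed=seed)


def packaged_fixtures() -> dict:
    """The published reference values as one machine-readable bundle."""
    return {
        "formulas": {"WISC-IV": dict(fixtures.WISC4_FORMULAS),
                     "WISC-V": dict(fixtures.WISC5_FORMULAS)},
        "panels": {"WISC-IV": dict(fixtures.WISC4_PANELS),
                   "WISC-V": dict(fixtures.WISC5_PANELS)},
        "panel_fields": fixtures.PANEL_FIELDS,
        "group_descriptives": dict(fixtures.GROUP_DESCRIPTIVES),
        "group_sizes": {"gifted": fixtures.N_GIFTED,
                        "typical": fixtures.N_TYPICAL},
        "screening": dict(fixtures.SCREENING_REFERENCE),
        "pooled_correlation_comparison": dict(
            fixtures.POOLED_CORRELATION_COMPARISON
        ),
        "headline_r_c": {f"{k[0]}:{k[1]}": v
                         for k, v in fixtures.HEADLINE_R_C.items()},
    }
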