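import math

import numpy as np
import pytest

import wshort as w
from wshort.fixtures import (
    HEADLINE_R_C,
    PANEL_FIELDS,
    WISC4_PANELS,
    WISC5_PANELS,
)
from wshort.validity import ScaleIndices


def _panel(name="Ab", p=2, r_cc=0.9, omega=0.6, fsiq=(0.8, 0.85, 0.8),
           gai=(0.82, 0.88, 0.9)):
    form = w.ShortFormDef(subset=(name, "Mr"), sum_r_jk=0.4, slope=3.0,
                          intercept=40.0, r_cc=r_cc,
                          sem=15 * math.sqrt(1 - r_cc))
    scales = {
        "FSIQ": ScaleIndices(r_sf=fsiq[0] + 0.02, r_prime=fsiq[0],
                             icc=fsiq[1], c_acc=fsiq[2]),
        "GAI": ScaleIndices(r_sf=gai[0] + 0.02, r_prime=gai[0],
                            icc=gai[1], c_acc=gai[2]),
    }
    return w.IndexPanel(form=form, r_cc=r_cc, omega_h=omega, scales=scales)


class TestCorrectedCorrelation:
    def test_perfect_reliability_no_correction(self):
        got = w.corrected_correlation(0.9, 1.0, 2, 0.4, 10, 15.0, sd_sf=14.0)
        assert got == pytest.approx(0.9)

    def test_unit_ratio_case(self):
        got = w.corrected_correlation(0.95, 0.9, 4, 2.0, 4, 2.0, sd_sf=15.0)
        assert got == pytest.approx(0.85)

    def test_arithmetic_example(self):
        got = w.corrected_correlation(0.90, 0.877, 2, 0.38, 10, 15.0,
                                      sd_sf=15.0)
        expect = 0.90 - 0.123 * math.sqrt(2.76) / math.sqrt(40.0)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(0.8677, abs=5e-4)

    def test_variant_without_sd_ratio(self):
        with_ratio = w.corrected_correlation(0.9, 0.877, 2, 0.38, 10, 15.0,
                                             sd_sf=12.0)
        without = w.corrected_correlation(0.9, 0.877, 2, 0.38, 10, 15.0,
                                          sd_sf=12.0, sd_ratio=False)
        assert with_ratio > without  # smaller SD shrinks the correction
        at_15 = w.corrected_correlation(0.9, 0.877, 2, 0.38, 10, 15.0,
                                        sd_sf=15.0)
        assert at_15 == pytest.approx(
            w.corrected_correlation(0.9, 0.877, 2, 0.38, 10, 15.0,
                                    sd_sf=15.0, sd_ratio=False)
        )

    @pytest.mark.parametrize("r_cc", [0.5, 0.8, 0.99, 1.0])
    def test_never_exceeds_raw_correlation(self, r_cc):
        got = w.corrected_correlation(0.9, r_cc, 2, 0.4, 10, 15.0, sd_sf=14.0)
        assert got <= 0.9 + 1e-15
        if r_cc == 1.0:
            assert got == pytest.approx(0.9)
        else:
            assert got < 0.9


class TestDiscrepancyTest:
    def test_identical_scores(self, rng):
        x = rng.normal(100, 15, size=30)
        res = w.discrepancy_test(x, x + rng.normal(0, 3, size=30))
        assert res.df == 29
        with pytest.warns(UserWarning):
            zero = w.discrepancy_test(x, x.copy() + 0.0)
        # identical vectors: flagged degenerate (zero-variance difference)
        assert zero.mean_diff == 0.0 and zero.degenerate

    def test_constant_shift_flagged(self, rng):
        x = rng.normal(100, 15, size=20)
        with pytest.warns(UserWarning):
            res = w.discrepancy_test(x + 5.0, x)
        assert res.degenerate
        assert res.mean_diff == pytest.approx(5.0)
        assert math.isnan(res.t)

    def test_matches_direct_formula_oracle(self, rng):
        sf = rng.normal(100, 15, size=20)
        full = 0.8 * sf + rng.normal(0, 8, size=20) + 20
        res = w.discrepancy_test(sf, full)
        d = sf - full
        t = d.mean() / (d.std(ddof=1) / math.sqrt(20))
        r = np.corrcoef(sf, full)[0, 1]
        s1, s2 = sf.std(ddof=1), full.std(ddof=1)
        d_rm = (d.mean() / math.sqrt(s1**2 + s2**2 - 2 * r * s1 * s2)
                * math.sqrt(2 * (1 - r)))
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.d_rm == pytest.approx(d_rm, abs=1e-10)
        assert res.df == 19


class TestCAcc:
    def test_perfect_agreement_above_cutoff(self):
        x = np.array([130.0, 140.0, 126.0])
        assert w.c_acc(x, x, 125, sem=5.0) == 1.0

    def test_no_gifted_reference_is_nan(self):
        full = np.array([110.0, 120.0])
        with pytest.warns(UserWarning):
            out = w.c_acc(full, full, 125, sem=5.0)
        assert math.isnan(out)

    def test_hand_enumerated_example(self):
        full = np.array([130.0, 126.0, 140.0, 120.0, 135.0])
        sf = np.array([128.0, 114.0, 131.0, 130.0, 133.0])
        assert w.c_acc(sf, full, 125, sem=5.0) == pytest.approx(0.75)

    def test_monotone_in_sem(self, rng):
        full = rng.normal(130, 10, size=500)
        sf = full + rng.normal(0, 8, size=500)
        vals = [w.c_acc(sf, full, 125, sem=s) for s in (2.0, 4.0, 6.0, 10.0)]
        assert vals == sorted(vals)


class TestRc:
    def test_all_ones(self):
        assert w.r_c_from_values([1.0] * 8) == 1.0

    @pytest.mark.parametrize("panels,scale_name", [
        (WISC4_PANELS, "WISC-IV"), (WISC5_PANELS, "WISC-V")
    ])
    def test_reproduces_all_printed_r_c(self, panels, scale_name):
        """The 8-constituent unweighted mean reproduces every published
        agreement score at 3 decimals."""
        assert len(panels) == 18
        for name, row in panels.items():
            got = w.r_c_from_values(row[:8])
            # constituents and R_c are each printed at 3 dp
            assert abs(got - row[8]) <= 0.001 + 1e-12, name

    def test_headline_values(self):
        for (scale, form), expect in HEADLINE_R_C.items():
            panels = WISC4_PANELS if scale == "WISC-IV" else WISC5_PANELS
            assert round(w.r_c_from_values(panels[form][:8]), 3) == expect

    def test_missing_constituent_named(self):
        p = _panel()
        broken = w.IndexPanel(
            form=p.form, r_cc=p.r_cc, omega_h=float("nan"), scales=p.scales
        )
        with pytest.raises(ValueError, match="omega_h"):
            w.r_c_composite(broken)

    def test_panel_fields_order(self):
        assert PANEL_FIELDS[:2] == ("r_cc", "omega_h")
        assert PANEL_FIELDS[-1] == "r_c"


class TestRanking:
    def test_descending_by_r_c(self):
        # mimic the published top-3 ordering 0.807 / 0.806 / 0.789
        def mk(name, bump):
            form = w.ShortFormDef(subset=(name[:2], name[2:]), sum_r_jk=0.4,
                                  slope=3.0, intercept=40.0, r_cc=0.85,
                                  sem=5.0)
            s = ScaleIndices(0.8, 0.78 + bump, 0.82 + bump, 0.8 + bump)
            return w.IndexPanel(form=form, r_cc=0.85, omega_h=0.55 + bump,
                                scales={"FSIQ": s, "GAI": s})

        panels = [mk("VoBd", 0.0), mk("SiMr", 0.02), mk("VoMr", 0.01)]
        ranked = w.rank_short_forms(panels)
        assert [p.name for p in ranked] == ["SiMr", "VoMr", "VoBd"]

    def test_tie_broken_by_r_cc_then_name(self):
        def mk(name, r_cc):
            form = w.ShortFormDef(subset=(name[:2], name[2:]), sum_r_jk=0.4,
                                  slope=3.0, intercept=40.0, r_cc=r_cc,
                                  sem=5.0)
            # keep the 8-value mean identical across panels
            s = ScaleIndices(0.8, 0.8, 0.8, 0.8)
            return w.IndexPanel(form=form, r_cc=0.8, omega_h=0.8,
                                scales={"FSIQ": s, "GAI": s})

        a, b = mk("SiMr", 0.9), mk("VoMr", 0.8)
        ranked = w.rank_short_forms([b, a])
        assert [p.form.r_cc for p in ranked] == [0.9, 0.8]
        c, d = mk("VoBd", 0.8), mk("SiBd", 0.8)
        assert [p.name for p in w.rank_short_forms([c, d])] == ["SiBd", "VoBd"]

    def test_single_panel(self):
        p = _panel()
        assert w.rank_short_forms([p]) == [p]


class TestComparePanels:
    def test_identical_sets(self, wisc4):
        res = w.ShortFormModel(wisc4).fit(n=20_000, seed=3)
        cmp = w.compare_index_panels(res.panels, res.panels)
        assert np.allclose(cmp["difference"], 0.0)
        assert np.allclose(cmp["r"].dropna(), 1.0)

    def test_mismatched_forms_error(self):
        a, b = _panel(), _panel()
        b2 = w.IndexPanel(
            form=w.ShortFormDef(("Vo", "Bd"), 0.4, 3.0, 40.0, 0.9, 4.7),
            r_cc=b.r_cc, omega_h=b.omega_h, scales=b.scales,
        )
        with pytest.raises(ValueError, match="differ"):
            w.compare_index_panels([a], [b2])

    def test_independent_simulations_agree(self, wisc4):
        """Monte-Carlo stability: two independently simulated panel sets
        from the same battery produce near-identical R_c orderings."""
        m = w.ShortFormModel(wisc4)
        r1 = m.fit(n=150_000, seed=101)
        r2 = m.fit(n=150_000, seed=202)
        cmp = w.compare_index_panels(r1.panels, r2.panels)
        assert abs(cmp.loc["r_c", "difference"]) < 0.01
        assert cmp.loc["r_c", "r"] > 0.99
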