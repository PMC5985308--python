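import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wshort as w
from wshort.battery import BatterySpec, SubtestInfo


class TestCompositeReliability:
    def test_perfect_subtests_give_one(self):
        assert w.composite_reliability([1.0, 1.0, 1.0], 1.2) == pytest.approx(1.0)

    def test_single_subtest_passthrough(self):
        assert w.composite_reliability([0.87], 0.0) == pytest.approx(0.87)

    def test_two_subtest_arithmetic(self):
        got = w.composite_reliability([0.90, 0.89], 0.38)
        assert got == pytest.approx(2.55 / 2.76)

    def test_degenerate_denominator(self):
        with pytest.raises(w.DegenerateCompositeError):
            w.composite_reliability([0.9, 0.9], -1.1)

    @given(
        r_jj=st.lists(st.floats(0.05, 1.0), min_size=1, max_size=6),
        sum_r=st.floats(0.0, 10.0),
        bump=st.floats(0.0, 0.2),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounded_and_increasing_in_reliabilities(self, r_jj, sum_r, bump):
        base = w.composite_reliability(r_jj, sum_r)
        assert base <= 1.0 + 1e-12
        bumped = list(r_jj)
        bumped[0] = min(1.0, bumped[0] + bump)
        assert w.composite_reliability(bumped, sum_r) >= base - 1e-12


class TestSem:
    @pytest.mark.parametrize(
        "r_cc,expect", [(1.0, 0.0), (0.91, 4.5), (0.877, 5.2607)]
    )
    def test_values(self, r_cc, expect):
        assert w.sem(r_cc, 15.0) == pytest.approx(expect, abs=5e-4)


class TestGeneralLoadings:
    def test_one_factor_battery_closed_form(self):
        # all pairwise r = lambda^2 with lambda = 0.8
        lam = 0.8
        r = np.full((6, 6), lam * lam)
        np.fill_diagonal(r, 1.0)
        b = BatterySpec(
            name="one-factor",
            subtests=tuple(
                SubtestInfo(f"S{i}", "A" if i < 3 else "B", 0.9)
                for i in range(6)
            ),
            correlation=r, composites={}, pools={},
        )
        got = w.estimate_general_loadings(b)
        assert got.method == "uls-schmid-leiman"
        for v in got.loadings.values():
            assert v == pytest.approx(lam, abs=0.01)

    def test_identity_matrix_zero_loadings(self):
        b = BatterySpec(
            name="iid",
            subtests=tuple(
                SubtestInfo(f"S{i}", "A" if i < 2 else "B", 0.9)
                for i in range(4)
            ),
            correlation=np.eye(4), composites={}, pools={},
        )
        got = w.estimate_general_loadings(b)
        assert all(abs(v) < 0.02 for v in got.loadings.values())

    def test_supplied_override_returned_verbatim(self, wisc4):
        sup = {s: 0.5 for s in wisc4.subtest_names}
        got = w.estimate_general_loadings(wisc4, supplied=sup)
        assert got.method == "supplied"
        assert got.loadings == sup

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_battery_loadings_recovered(self, seed):
        """Parameter recovery: known general loadings within 0.05 each."""
        b = w.generate_battery_spec(
            {"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"],
             "C": ["c1", "c2"]},
            seed=seed,
        )
        truth = b.meta["general_loadings"]
        got = w.estimate_general_loadings(b)
        for name, lam in truth.items():
            assert got.loadings[name] == pytest.approx(lam, abs=0.05)

    def test_too_few_groups_rejected(self):
        b = BatterySpec(
            name="onegroup",
            subtests=tuple(SubtestInfo(f"S{i}", "A", 0.9) for i in range(4)),
            correlation=np.eye(4), composites={}, pools={},
        )
        with pytest.raises(w.EstimationError):
            w.estimate_general_loadings(b)


class TestOmegaHierarchical:
    def test_perfect_general_factor(self):
        assert w.omega_hierarchical([1.0, 1.0], None, 1.0) == pytest.approx(1.0)

    def test_no_general_factor(self):
        assert w.omega_hierarchical([0.0, 0.0], None, 0.3) == 0.0

    def test_arithmetic_example(self):
        got = w.omega_hierarchical([0.7, 0.6], None, 0.38)
        assert got == pytest.approx(1.69 / 2.76)

    def test_within_unit_interval_on_battery(self, wisc4, loadings4):
        for form in w.enumerate_short_forms(wisc4):
            omega = w.omega_hierarchical(loadings4, form.subset, form.sum_r_jk)
            assert 0.0 <= omega <= 1.0


class TestIccA1:
    def test_identical_vectors(self, rng):
        x = rng.normal(size=20)
        assert w.icc_a1(x, x) == pytest.approx(1.0)

    def test_constant_shift_penalised_below_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 1.0
        got = w.icc_a1(x, y)
        assert got < 1.0  # Pearson r is exactly 1 here

    def test_matches_brute_force_anova(self, rng):
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(scale=0.5, size=10)
        # independent oracle: explicit two-way ANOVA sums over cells
        data = np.column_stack([x, y])
        n, k = data.shape
        grand = data.mean()
        ssr = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
        ssc = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
        sst = sum((v - grand) ** 2 for v in data.ravel())
        msr = ssr / (n - 1)
        msc = ssc / (k - 1)
        mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
        expect = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert w.icc_a1(x, y) == pytest.approx(expect, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(scale=0.6, size=30) + 0.3
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": np.tile(["a", "b"], 30),
            "scores": np.column_stack([x, y]).ravel(),
        })
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="scores")
        mask = ref.Type.isin(["ICC(A,1)", "ICC2"])
        icc_a1_ref = float(ref.loc[mask, "ICC"].iloc[0])
        assert w.icc_a1(x, y) == pytest.approx(icc_a1_ref, abs=1e-8)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert w.icc_a1(x, y) == pytest.approx(w.icc_a1(y, x), abs=1e-12)

    def test_zero_variance_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = w.icc_a1([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert np.isnan(out)


def test_half_composite_correlation_matches_closed_form(wisc4, pop200k):
    """Empirical correlation of two half-composites approaches the
    closed-form composite correlation at large n."""
    verbal = list(wisc4.pools["verbal"])
    perf = list(wisc4.pools["performance"])
    expect = wisc4.composite_correlation(verbal, perf)
    a = pop200k.scores[verbal].sum(axis=1)
    b = pop200k.scores[perf].sum(axis=1)
    got = float(np.corrcoef(a, b)[0, 1])
    assert got == pytest.approx(expect, abs=0.01)
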