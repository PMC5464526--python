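"""QC cascade: worked arithmetic examples, accounting invariants,
idempotence and batch orthogonality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltamed import BiomarkerQC, QcConfig
from deltamed.qc import (
    adjust_batch,
    normalize_and_standardize,
    reconcile_duplicates,
    remove_outliers,
    resolve_low,
)


def _panel(rows):
    """rows: (subject, analyte, rep1, rep2, low1, low2, ldd, batch)."""
    return pd.DataFrame(
        rows, columns=["subject_id", "analyte", "rep1", "rep2", "low1", "low2", "ldd", "batch"]
    )


class TestReconcileDuplicates:
    def test_within_tolerance_pair_keeps_mean(self):
        # |10.0-10.4| / 10.2 = 3.92% <= 5% -> retained as 10.2
        p = _panel([("s1", "a", 10.0, 10.4, False, False, 1.0, "B1")])
        values, *_ , counts = reconcile_duplicates(p)
        assert values.loc["s1", "a"] == pytest.approx(10.2)
        assert counts.loc["a", "n_discarded_duplicates"] == 0

    def test_discordant_pair_discarded(self):
        # |10-11| / 10.5 = 9.52% > 5% -> missing
        p = _panel([("s1", "a", 10.0, 11.0, False, False, 1.0, "B1")])
        values, *_, counts = reconcile_duplicates(p)
        assert np.isnan(values.loc["s1", "a"])
        assert counts.loc["a", "n_discarded_duplicates"] == 1

    def test_identical_pair_trivially_kept(self):
        p = _panel([("s1", "a", 5.0, 5.0, False, False, 1.0, "B1")])
        values, *_ = reconcile_duplicates(p)
        assert values.loc["s1", "a"] == 5.0

    def test_nonpositive_reading_rejected(self):
        p = _panel([("s1", "a", -1.0, 2.0, False, False, 1.0, "B1")])
        with pytest.raises(ValueError, match="positive"):
            reconcile_duplicates(p)

    def test_double_low_pair_bypasses_difference_rule(self):
        p = _panel([("s1", "a", 0.10, 0.30, True, True, 1.0, "B1")])
        values, lows, *_ = reconcile_duplicates(p)
        assert lows.loc["s1", "a"]
        assert not np.isnan(values.loc["s1", "a"])


class TestResolveLow:
    def _wide(self, n_low, n_total=10, ldd=2.0):
        values = pd.DataFrame({"a": np.full(n_total, 5.0)},
                              index=[f"s{i}" for i in range(n_total)])
        lows = pd.DataFrame({"a": [i < n_low for i in range(n_total)]}, index=values.index)
        return values, lows, pd.Series({"a": ldd})

    def test_majority_low_drops_analyte(self):
        values, lows, ldd = self._wide(6)  # 0.6 > 0.5
        out, dropped, _ = resolve_low(values, lows, ldd)
        assert "a" not in out.columns
        assert dropped["a"]

    def test_exactly_half_low_is_retained(self):
        values, lows, ldd = self._wide(5)  # 0.5 not > 0.5
        out, dropped, _ = resolve_low(values, lows, ldd)
        assert "a" in out.columns and not dropped["a"]

    def test_minority_low_imputed_at_half_ldd(self):
        values, lows, ldd = self._wide(4, ldd=2.0)
        out, *_ = resolve_low(values, lows, ldd)
        assert (out.loc[lows["a"], "a"] == 1.0).all()
        assert (out.loc[~lows["a"], "a"] == 5.0).all()

    def test_no_low_readings_unchanged(self):
        values, lows, ldd = self._wide(0)
        out, *_ = resolve_low(values, lows, ldd)
        pd.testing.assert_frame_equal(out, values)

    def test_nonpositive_ldd_rejected(self):
        values, lows, _ = self._wide(1)
        with pytest.raises(ValueError):
            resolve_low(values, lows, pd.Series({"a": 0.0}))


class TestRemoveOutliers:
    def test_single_extreme_among_constants(self):
        """99 zeros and one 100: mean 1, sample SD 10, z=9.9 -> only the
        extreme value is deleted."""
        x = pd.Series(np.r_[np.zeros(99), 100.0])
        out, n = remove_outliers(x)
        assert n.iloc[0] == 1
        assert np.isnan(out.iloc[-1])
        assert out.iloc[:99].notna().all()

    def test_constant_vector_untouched(self):
        x = pd.Series(np.ones(50))
        out, n = remove_outliers(x)
        assert n.iloc[0] == 0
        assert out.notna().all()

    def test_normal_tail_mass(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(size=10000))
        _, n = remove_outliers(x)
        expect = 10000 * 0.0027
        assert abs(n.iloc[0] - expect) <= 3 * np.sqrt(expect)

    def test_single_pass_no_reiteration(self):
        # after deleting the extreme, the remaining spread would flag
        # more points under re-screening; a single pass must not
        x = pd.Series(np.r_[np.zeros(99), 100.0])
        out, _ = remove_outliers(x)
        out2, n2 = remove_outliers(out.dropna())
        assert n2.iloc[0] == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(pd.Series([1.0, 2.0]))


class TestNormalizeStandardize:
    def test_simple_vector(self):
        out, flags = normalize_and_standardize(pd.Series([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.to_numpy(), [-1, 0, 1])
        assert not flags.iloc[0]

    def test_idempotent_on_symmetric_input(self):
        rng = np.random.default_rng(1)
        x = pd.Series(rng.normal(size=500))
        once, _ = normalize_and_standardize(x)
        twice, _ = normalize_and_standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_lognormal_gets_logged_and_deskewed(self):
        from scipy.stats import skew

        rng = np.random.default_rng(2)
        x = pd.Series(np.exp(rng.normal(size=2000) * 1.2))
        out, flags = normalize_and_standardize(x)
        assert flags.iloc[0]
        assert abs(skew(out)) < abs(skew(x))

    def test_nonpositive_under_log_names_analyte(self):
        x = pd.DataFrame({"bad_analyte": np.r_[np.exp(np.linspace(0, 6, 50)), -1.0]})
        with pytest.raises(ValueError, match="bad_analyte"):
            normalize_and_standardize(x)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_always_mean_zero_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        x = pd.Series(np.exp(rng.normal(size=60)))
        out, _ = normalize_and_standardize(x)
        assert out.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestAdjustBatch:
    def test_two_batch_means_zeroed(self):
        values = pd.Series(np.r_[np.random.default_rng(0).normal(1.0, 0.1, 30),
                                 np.random.default_rng(1).normal(3.0, 0.1, 30)])
        batch = pd.Series(["B1"] * 30 + ["B2"] * 30)
        out, _ = adjust_batch(values, batch)
        assert out[:30].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[30:].mean() == pytest.approx(0.0, abs=1e-10)

    def test_single_batch_equals_centered_input(self):
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(2.0, 1.0, 40))
        out, _ = adjust_batch(values, pd.Series(["B1"] * 40))
        centered = (values - values.mean())
        np.testing.assert_allclose(out, centered / centered.std(ddof=1), atol=1e-10)

    def test_known_shifts_recovered(self):
        rng = np.random.default_rng(4)
        n = 900
        batch = pd.Series(rng.choice(["B1", "B2", "B3"], size=n))
        noise = rng.normal(size=n)
        shift = batch.map({"B1": 0.0, "B2": 1.0, "B3": -2.0})
        values = pd.Series(noise + shift)
        out, coefs = adjust_batch(values, batch)
        se = 1.0 / np.sqrt(n / 3)
        assert coefs.loc[0, "B2"] == pytest.approx(1.0, abs=3 * se)
        assert coefs.loc[0, "B3"] == pytest.approx(-2.0, abs=3 * se)

    def test_residuals_orthogonal_to_dummies(self):
        rng = np.random.default_rng(5)
        batch = pd.Series(rng.choice(["B1", "B2", "B3", "B4"], size=200))
        values = pd.Series(rng.normal(size=200) + batch.map({"B1": 0, "B2": 1, "B3": 2, "B4": 3}))
        out, _ = adjust_batch(values, batch)
        for lvl in ["B1", "B2", "B3", "B4"]:
            assert out[batch == lvl].mean() == pytest.approx(0.0, abs=1e-10)

    def test_singleton_batch_warns_and_zeroes(self):
        values = pd.Series([1.0, 2.0, 3.0, 10.0])
        batch = pd.Series(["B1", "B1", "B1", "B2"])
        with pytest.warns(UserWarning, match="single observation"):
            out, _ = adjust_batch(values, batch)
        assert out.iloc[3] == pytest.approx(0.0, abs=1e-10)


class TestCascade:
    def test_report_reconciles_every_reading(self, small_cohort):
        qc = BiomarkerQC().fit(small_cohort.raw_panel)
        t = qc.report_.table
        assert ((t["n_retained"] + t["n_discarded_duplicates"]) == t["n_input"]).all()
        assert (t["n_input"] == len(small_cohort.observed)).all()

    def test_output_standardized_per_analyte(self, small_cohort):
        qc = BiomarkerQC().fit(small_cohort.raw_panel)
        panel = qc.panel_
        means = panel.mean()
        sds = panel.std(ddof=1)
        assert (means.abs() < 1e-8).all()
        np.testing.assert_allclose(sds, 1.0, atol=1e-8)

    def test_qc_recovers_true_levels_up_to_scale(self, small_cohort):
        """After the cascade, standardized analytes correlate strongly
        with the generating true levels."""
        qc = BiomarkerQC().fit(small_cohort.raw_panel)
        panel = qc.panel_.reindex(small_cohort.observed["subject_id"])
        for analyte in panel.columns:
            truth = small_cohort.observed.set_index("subject_id")[analyte]
            ok = panel[analyte].notna()
            r = np.corrcoef(panel.loc[ok, analyte], truth[ok])[0, 1]
            assert r > 0.95

    def test_saturated_analyte_dropped_downstream(self):
        from deltamed import SimConfig, simulate_cohort

        cfg = SimConfig(n_subjects=300, seed=6, n_proteins=2, ldd_quantile=0.6,
                        duplicate_cv=0.0, outlier_rate=0.0)
        coh = simulate_cohort(cfg)
        qc = BiomarkerQC().fit(coh.raw_panel)
        assert qc.report_.table["dropped"].all()
        assert qc.panel_.shape[1] == 0

    def test_report_round_trips_json(self, small_cohort):
        qc = BiomarkerQC().fit(small_cohort.raw_panel)
        from deltamed.qc import QcReport

        again = QcReport.from_json(qc.report_.to_json())
        assert list(again.table.index) == list(qc.report_.table.index)


def test_qcconfig_validation():
    with pytest.raises(ValueError):
        QcConfig(duplicate_tolerance=0.0)
    with pytest.raises(ValueError):
        QcConfig(outlier_sd=-1)
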