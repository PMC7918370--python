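import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsgc import (
    ARIMASettings,
    TimeAxis,
    combine,
    fit_all_residuals,
    fit_trend,
    pairwise_windows,
    timepoint_test,
)
from tsgc.errors import CompletenessError, ConfigurationError
from tsgc.inference import runs_to_windows


def pooled_t_oracle(a, b):
    a, b = np.asarray(a), np.asarray(b)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestTimepointTest:
    def test_identical_groups_null(self):
        t, p = timepoint_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups(self, rng):
        a = np.zeros(4) + rng.normal(0, 1e-9, 4)
        b = np.ones(4) + rng.normal(0, 1e-9, 4)
        _, p = timepoint_test(a, b)
        assert p < 1e-10

    def test_matches_textbook_pooled_formula(self):
        rng = np.random.default_rng(71)
        a = rng.normal(0, 1, 9)
        b = rng.normal(1, 1, 9)
        t, _ = timepoint_test(a, b)
        assert t == pytest.approx(pooled_t_oracle(a, b), abs=1e-10)

    def test_degenerate_equal_constants(self):
        t, p = timepoint_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_distinct_constants(self):
        t, p = timepoint_test([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0
        assert t == -np.inf

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ConfigurationError):
            timepoint_test([1.0], [2.0, 3.0])


def brute_force_runs(flags):
    """Run-length scan oracle: list of (start, end) 1-based index runs."""
    runs, start = [], None
    for i, f in enumerate(list(flags) + [False], start=1):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


@settings(max_examples=100, deadline=None)
@given(st.lists(st.booleans(), min_size=1, max_size=40))
def test_window_extraction_matches_run_scan(flags):
    """Windows are exactly the maximal runs of significant indices."""
    axis = TimeAxis(n_timepoints=len(flags), interval_minutes=2.0)
    windows = runs_to_windows(np.array(flags), ("A", "B"), axis)
    expected = brute_force_runs(flags)
    assert [(w.start_index, w.end_index) for w in windows] == expected
    for w in windows:
        assert w.start_minutes == 2.0 * (w.start_index - 1)
        assert w.end_minutes == 2.0 * (w.end_index - 1)
    flagged = {i for w in windows for i in range(w.start_index, w.end_index + 1)}
    assert flagged == {i for i, f in enumerate(flags, start=1) if f}


@pytest.fixture(scope="module")
def fitted_small_panel(request):
    panel, _ = request.getfixturevalue("small_ar_panel")
    lmm_fit = fit_trend(panel)
    models = fit_all_residuals(
        lmm_fit, ARIMASettings(min_d=1, p_max=1, q_max=1, drift=False)
    )
    return panel, lmm_fit, models


class TestCombine:
    def test_naive_mode_is_lmm_only(self, fitted_small_panel):
        _, lmm_fit, _ = fitted_small_panel
        cf = combine(lmm_fit, None, "naive")
        np.testing.assert_allclose(cf.frame["arima_fitted"], 0.0)
        np.testing.assert_allclose(
            cf.frame["final_fitted"], cf.frame["lmm_fitted"], atol=1e-12
        )
        np.testing.assert_allclose(
            cf.frame["final_residual"],
            lmm_fit.residuals.to_numpy(),
            atol=1e-12,
        )

    def test_corrected_mode_reconstructs_observed(self, fitted_small_panel):
        _, lmm_fit, models = fitted_small_panel
        cf = combine(lmm_fit, models, "corrected")
        recon = cf.frame["final_fitted"] + cf.frame["final_residual"]
        np.testing.assert_allclose(recon, cf.frame["observed"], atol=1e-10)

    def test_group_residual_means_near_zero(self, fitted_small_panel):
        _, lmm_fit, models = fitted_small_panel
        cf = combine(lmm_fit, models, "corrected")
        frame = cf.frame
        for g, sub in frame.groupby("group"):
            r = sub["final_residual"]
            se = r.std() / np.sqrt(len(r))
            assert abs(r.mean()) <= 2 * se

    def test_missing_arima_fit_rejected(self, fitted_small_panel):
        _, lmm_fit, models = fitted_small_panel
        partial = type(models)(
            fits={k: v for k, v in list(models.fits.items())[:-1]},
            whiteness=models.whiteness,
            settings=models.settings,
        )
        with pytest.raises(CompletenessError):
            combine(lmm_fit, partial, "corrected")


class TestPairwiseWindows:
    def test_bonferroni_threshold_for_three_groups(self, fitted_small_panel):
        _, lmm_fit, models = fitted_small_panel
        report = pairwise_windows(combine(lmm_fit, models, "corrected"), 0.05)
        assert report.n_comparisons_per_timepoint == 3
        assert report.threshold == pytest.approx(0.05 / 3)
        assert report.threshold == pytest.approx(0.01667, abs=5e-6)

    def test_every_flagged_index_in_exactly_one_window(self, fitted_small_panel):
        _, lmm_fit, models = fitted_small_panel
        report = pairwise_windows(combine(lmm_fit, models, "corrected"), 0.05)
        for (ga, gb), sub in report.results.groupby(["group_a", "group_b"]):
            flagged = set(sub.loc[sub["significant"], "time"])
            in_windows = [
                set(range(w.start_index, w.end_index + 1))
                for w in report.windows_for((ga, gb))
            ]
            union = set().union(*in_windows) if in_windows else set()
            assert union == flagged
            # non-overlapping
            assert sum(len(s) for s in in_windows) == len(union)

    def test_report_invariant_to_subject_order(self, fitted_small_panel):
        panel, lmm_fit, models = fitted_small_panel
        report = pairwise_windows(combine(lmm_fit, models, "corrected"), 0.05)
        import tsgc.panel as tp

        shuffled = tp.Panel.from_frame(
            panel.data.sample(frac=1.0, random_state=3),
            reference_group=panel.reference_group,
        )
        fit2 = fit_trend(shuffled)
        models2 = fit_all_residuals(
            fit2, ARIMASettings(min_d=1, p_max=1, q_max=1, drift=False)
        )
        report2 = pairwise_windows(combine(fit2, models2, "corrected"), 0.05)
        a = report.results.sort_values(["group_a", "group_b", "time"])
        b = report2.results.sort_values(["group_a", "group_b", "time"])
        np.testing.assert_allclose(
            a["p"].to_numpy(), b["p"].to_numpy(), atol=1e-6
        )

    def test_single_group_rejected(self, fitted_small_panel):
        _, lmm_fit, models = fitted_small_panel
        cf = combine(lmm_fit, models, "corrected")
        cf.frame = cf.frame[cf.frame["group"] == "G1"]
        with pytest.raises(ConfigurationError):
            pairwise_windows(cf, 0.05)
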