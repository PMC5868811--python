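"""Section statistics: summaries, distribution curves, group comparisons."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sarcoquant.published import (
    CONSISTENT_CV_ROWS,
    REPORTED_BMD_REDUCTION_PERCENT,
    WHOLE_SECTION_SUMMARIES,
    section_means,
)
from sarcoquant.stats import (
    compare_groups,
    cv_from_sem,
    distribution_curves,
    experiment_variability,
    membrane_normalised,
    summarize_section,
)


class TestSummarize:
    def test_closed_form(self):
        s = summarize_section([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.sd == pytest.approx(1.0)
        assert s.cv_percent == pytest.approx(50.0)
        assert s.sem == pytest.approx(1.0 / np.sqrt(3))
        assert (s.min, s.max) == (1.0, 3.0)

    def test_constant_values(self):
        s = summarize_section([7.0] * 10)
        assert s.sd == 0 and s.sem == 0 and s.cv_percent == 0

    def test_single_value_undefined_spread(self):
        s = summarize_section([5.0])
        assert s.n_fibres == 1 and s.mean == 5.0
        assert s.sd is None and s.sem is None and s.cv_percent is None

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_section([])

    @given(
        st.lists(st.floats(1.0, 1e5), min_size=2, max_size=200),
    )
    def test_cv_sem_identity(self, values):
        """CV% == 100 * SEM * sqrt(n) / mean, algebraically."""
        s = summarize_section(values)
        assert s.cv_percent == pytest.approx(
            cv_from_sem(s.mean, s.sem, s.n_fibres), rel=1e-9
        )

    def test_published_consistency_row(self):
        """mean 18109 +/- 29.58 over 14559 fibres gives CV 19.71%."""
        assert round(cv_from_sem(18109, 29.58, 14559), 2) == 19.71


class TestDistributionCurves:
    def test_single_bin(self):
        c = distribution_curves([3.0, 4.0, 5.0], bins=1)
        assert c.absolute_percent.tolist() == [100.0]
        assert c.cumulative_percent.tolist() == [100.0]

    def test_counting_oracle(self, rng):
        values = rng.uniform(0, 1000, 500)
        c = distribution_curves(values, bins=16)
        for i in range(16):
            lo, hi = c.bin_edges[i], c.bin_edges[i + 1]
            if i == 15:
                n = ((values >= lo) & (values <= hi)).sum()
            else:
                n = ((values >= lo) & (values < hi)).sum()
            assert c.absolute_percent[i] == pytest.approx(100.0 * n / 500)

    def test_uniform_midpoint(self, rng):
        """Cumulative curve of uniform draws reaches ~50% at the half-range."""
        values = rng.uniform(0, 1.0, 1000)
        c = distribution_curves(values, bins=64)
        assert c.cumulative_percent[31] == pytest.approx(50.0, abs=5.0)

    @given(st.lists(st.floats(0.0, 1e6), min_size=1, max_size=300))
    def test_cumulative_monotone_ends_at_100(self, values):
        c = distribution_curves(values, bins=32)
        assert c.absolute_percent.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(c.cumulative_percent) >= -1e-12)
        assert c.cumulative_percent[-1] == pytest.approx(100.0, abs=1e-9)

    def test_bad_bins(self):
        with pytest.raises(ValueError):
            distribution_curves([1.0], bins=0)


class TestGroupComparison:
    def test_identical_groups(self):
        c = compare_groups([10.0, 10.0], [10.0, 10.0])
        assert c.fold_change == 1.0 and c.percent_reduction == 0.0

    def test_doubled_group(self):
        c = compare_groups([20.0], [10.0])
        assert c.fold_change == 2.0
        assert c.percent_reduction == pytest.approx(-100.0)

    def test_fold_reduction_identity(self):
        c = compare_groups([13.0, 17.0], [21.0, 19.0])
        assert c.fold_change == pytest.approx(1 - c.percent_reduction / 100.0)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [0.0])

    def test_mann_whitney_identical_samples(self, rng):
        x = rng.normal(100, 10, 200)
        c = compare_groups([x.mean()], [x.mean()], x, x)
        assert c.mann_whitney_p >= 0.99

    def test_anova_three_groups(self, rng):
        a = rng.normal(10, 1, 50)
        b = rng.normal(10, 1, 50)
        d = rng.normal(30, 1, 50)
        c = compare_groups([a.mean()], [b.mean()], a, b, extra_groups_fibre_values=[d])
        assert c.anova_p < 1e-6

    def test_published_bmd_reductions(self):
        """Unweighted section-mean averaging reproduces the reported BMD
        reductions: 29% (ab15277) and 14% (MANDYS106) versus controls."""
        for antibody, expected in REPORTED_BMD_REDUCTION_PERCENT.items():
            c = compare_groups(
                section_means(antibody, "bmd"), section_means(antibody, "control")
            )
            assert c.percent_reduction_reported == expected


class TestExperimentVariability:
    def test_identical_repeats(self):
        assert experiment_variability([10.0, 10.0]) == 0.0

    def test_two_repeats_closed_form(self):
        means = [18109.0, 23271.0]
        cv = experiment_variability(means)
        expected = 100.0 * np.std(means, ddof=1) / np.mean(means)
        assert cv == pytest.approx(expected)

    def test_single_repeat_undefined(self):
        assert experiment_variability([10.0]) is None

    def test_mapping_form(self):
        out = experiment_variability({"control_1": [10.0, 12.0], "control_2": [5.0]})
        assert out["control_2"] is None
        assert out["control_1"] == pytest.approx(
            100.0 * np.std([10, 12], ddof=1) / 11.0
        )

    def test_published_rows_internally_consistent(self):
        """The printed CV of each self-consistent published row equals the
        SEM-derived value to two decimals."""
        for antibody, exp, sample in CONSISTENT_CV_ROWS:
            row = WHOLE_SECTION_SUMMARIES[antibody][exp][sample]
            assert round(cv_from_sem(row["mean"], row["sem"], row["n"]), 2) == row["cv"]


def test_membrane_normalised_flags_zero_division():
    out = membrane_normalised([10.0, 20.0], [5.0, 0.0])
    assert out[0] == 2.0
    assert np.isnan(out[1])
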