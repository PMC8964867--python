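import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrophybench import (ImpactRecord, benchmark_outliers, grubbs_critical,
                          grubbs_statistic, iterative_grubbs)


class TestStatistic:
    def test_symmetric_three_points(self):
        res = grubbs_statistic([-1.0, 0.0, 1.0])
        assert res.G == pytest.approx(1.0)       # s = 1, max |dev| = 1
        assert res.candidate_index in (0, 2)

    def test_single_extreme(self):
        res = grubbs_statistic([0.0, 0.0, 0.0, 10.0])
        # mean 2.5, sd 5 -> G = 7.5/5
        assert res.G == pytest.approx(1.5)
        assert res.candidate_index == 3

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="zero sample SD"):
            grubbs_statistic([2.0, 2.0, 2.0])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="n >= 3"):
            grubbs_statistic([1.0, 2.0])

    def test_tie_resolves_to_lowest_index(self):
        res = grubbs_statistic([5.0, 0.0, 0.0, 0.0, 5.0, 0.0])
        assert res.candidate_index == 0


class TestCritical:
    def test_three_points_five_percent(self):
        assert grubbs_critical(3, 0.05) == pytest.approx(1.1543, abs=1e-4)

    def test_alpha_monotonicity(self):
        assert grubbs_critical(10, 0.01) > grubbs_critical(10, 0.05)

    def test_n_monotonicity(self):
        assert grubbs_critical(10, 0.05) > grubbs_critical(3, 0.05)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            grubbs_critical(2, 0.05)
        with pytest.raises(ValueError):
            grubbs_critical(10, 0.0)

    def test_matches_independent_t_quantile_route(self):
        # independent evaluation of the two-sided critical value through R's qt
        ns = list(range(3, 31))
        script = (
            "for (n in 3:30) for (a in c(0.05, 0.01)) {"
            "t <- qt(a/(2*n), df=n-2, lower.tail=FALSE);"
            "cat(sprintf('%.10f\\n', (n-1)/sqrt(n)*sqrt(t^2/(n-2+t^2))))}"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        expected = iter(vals)
        for n in ns:
            for a in (0.05, 0.01):
                assert grubbs_critical(n, a) == pytest.approx(next(expected),
                                                              abs=1e-9)


class TestIterative:
    def test_plain_normal_sample_unflagged(self):
        # cross-checked against reference implementations of Grubbs's test:
        # this mild sample produces G below the n=8 critical value 2.126
        sample = [0.2, -0.4, 0.1, 0.6, -0.2, 0.3, -0.5, 0.0]
        report = iterative_grubbs(sample, alpha=0.05)
        assert report.flagged_ids == []
        assert report.n_total == 8

    def test_planted_contaminant_flagged_then_stops(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.2, 0.05, size=40)
        x[17] = 0.2 + 10 * 0.05
        report = iterative_grubbs(x, alpha=0.05)
        assert 17 in report.flagged_ids
        assert report.flagged_ids[0] == 17

    def test_idempotent_on_cleaned_sample(self):
        rng = np.random.default_rng(1)
        x = list(rng.normal(size=30))
        x[5] = 12.0
        report = iterative_grubbs(x, alpha=0.05)
        cleaned = [v for i, v in enumerate(x) if i not in report.flagged_ids]
        assert iterative_grubbs(cleaned, alpha=0.05).flagged_ids == []

    def test_small_sample_warns_instead_of_raising(self):
        report = iterative_grubbs([1.0, 2.0], alpha=0.05)
        assert report.flagged_ids == []
        assert "n=2" in report.warning

    def test_custom_ids_returned(self):
        x = [0.1, 0.2, 0.15, 9.0, 0.12]
        report = iterative_grubbs(x, ids=list("abcde"))
        assert report.flagged_ids[0] == "d"

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_location_scale_invariance(self, a, b):
        rng = np.random.default_rng(99)
        x = rng.normal(size=25)
        x[3] = 8.0
        base = iterative_grubbs(x, alpha=0.05).flagged_ids
        transformed = iterative_grubbs(a * x + b, alpha=0.05).flagged_ids
        assert base == transformed


class TestBenchmarkCriterion:
    def test_hand_computed_threshold_and_strictness(self):
        # 75th percentile of [1,2,3,4] under linear interpolation is 3.25
        report = benchmark_outliers([3.26, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert report.parameters["threshold"] == pytest.approx(3.25)
        assert report.n_flagged == 2

    def test_all_below_threshold(self):
        report = benchmark_outliers([0.1, 0.2], [1.0, 2.0, 3.0, 4.0])
        assert report.n_flagged == 0

    def test_exact_threshold_not_flagged(self):
        report = benchmark_outliers([3.25], [1.0, 2.0, 3.0, 4.0])
        assert report.n_flagged == 0

    def test_empty_benchmark_rejected(self):
        with pytest.raises(ValueError):
            benchmark_outliers([1.0], [])

    def test_failed_records_ignored(self):
        recs = [ImpactRecord("a", "x", "y", 9.0),
                ImpactRecord("b", "x", "y", status="failed:perturbation")]
        report = benchmark_outliers(recs, [1.0, 2.0, 3.0, 4.0])
        assert report.flagged_ids == ["a"]
        assert report.n_total == 1
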