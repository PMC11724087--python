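"""Percentile binning, event ratios, truncated C, bootstrap, KM, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.utils import concordance_index

from phenorisk.metrics import (
    EndpointEval,
    assign_percentiles,
    bootstrap_delta_c,
    harrell_c,
    incident_event_ratio,
    kaplan_meier,
    summarize_phenome,
)


class TestAssignPercentiles:
    def test_hundred_distinct_scores_bijection(self):
        rng = np.random.default_rng(0)
        s = rng.permutation(100).astype(float)
        bins = assign_percentiles(s)
        assert sorted(bins.tolist()) == list(range(1, 101))
        assert np.array_equal(np.argsort(s), np.argsort(bins, kind="stable"))

    def test_all_equal_scores_stable_order(self):
        s = np.zeros(200)
        bins = assign_percentiles(s)
        # stable tie-break: input order decides, first half low bins
        assert np.array_equal(bins, np.repeat(np.arange(1, 101), 2))

    def test_bin_means_monotone(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=1000)
        bins = assign_percentiles(s)
        means = [s[bins == b].mean() for b in range(1, 101)]
        assert np.all(np.diff(means) >= 0)

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=1037)
        counts = np.bincount(assign_percentiles(s))[1:]
        assert counts.max() - counts.min() <= 1

    def test_too_few_eligible_rejected(self):
        with pytest.raises(ValueError):
            assign_percentiles(np.arange(50.0))

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=500)
        assert np.array_equal(assign_percentiles(s), assign_percentiles(s + 7.5))


class TestIncidentEventRatio:
    def _bins_events(self, e_top, e_bot, band_n):
        bins = np.concatenate([np.repeat(5, band_n), np.repeat(95, band_n)])
        events = np.zeros(2 * band_n, dtype=bool)
        events[band_n : band_n + e_top] = True  # top band
        events[:e_bot] = True  # bottom band
        return events, bins

    def test_printed_cardiac_arrest_ratio(self):
        """1053 vs 59 events in equal decile bands gives 17.85."""
        events, bins = self._bins_events(1053, 59, 50249)
        r = incident_event_ratio(events, bins)
        assert round(r.ratio, 2) == 17.85

    def test_printed_heart_failure_ratio(self):
        events, bins = self._bins_events(6738, 146, 50249)
        assert round(incident_event_ratio(events, bins).ratio, 2) == 46.15

    def test_equal_counts_give_unity(self):
        events, bins = self._bins_events(40, 40, 500)
        assert incident_event_ratio(events, bins).ratio == 1.0

    def test_zero_bottom_events_reports_infinity(self):
        events, bins = self._bins_events(10, 0, 100)
        r = incident_event_ratio(events, bins)
        assert np.isinf(r.ratio) and r.events_bottom == 0

    def test_unequal_band_sizes_use_rates(self):
        bins = np.array([5] * 100 + [95] * 50)
        events = np.zeros(150, dtype=bool)
        events[:10] = True  # bottom rate 0.10
        events[100:105] = True  # top rate 0.10
        assert incident_event_ratio(events, bins).ratio == pytest.approx(1.0)


class TestHarrellC:
    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=bool)
        s = -t  # higher score, earlier event
        assert harrell_c(s, t, e, None) == 1.0

    def test_all_tied_scores_half(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2, 50) + 0.01
        e = rng.random(50) < 0.7
        assert harrell_c(np.zeros(50), t, e, None) == 0.5

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(1)
        n = 50
        s = rng.normal(size=n)
        t = rng.exponential(5, n) + 0.01
        e = rng.random(n) < 0.6
        conc = comp = 0.0
        tc = np.minimum(t, 10.0)
        ec = e & (t <= 10.0)
        for i in range(n):
            for k in range(n):
                if tc[i] < tc[k] and ec[i]:
                    comp += 1
                    conc += (s[i] > s[k]) + 0.5 * (s[i] == s[k])
        assert harrell_c(s, t, e, 10.0) == pytest.approx(conc / comp, rel=1e-12)

    def test_matches_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        n = 200
        s = rng.normal(size=n)
        t = rng.exponential(3, n) + 0.01
        e = rng.random(n) < 0.5
        assert harrell_c(s, t, e, None) == pytest.approx(
            concordance_index(t, -s, e), rel=1e-12
        )

    def test_truncation_censors_late_events(self):
        t = np.array([1.0, 12.0, 15.0])
        e = np.array([True, True, False])
        s = np.array([3.0, 2.0, 1.0])
        # after clipping at 10, only the first event remains
        assert harrell_c(s, t, e, 10.0) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        s = rng.normal(size=n)
        t = rng.exponential(4, n) + 0.01
        e = rng.random(n) < 0.6
        if not (e & (t <= 10)).any():
            return
        c1 = harrell_c(s, t, e, 10.0)
        c2 = harrell_c(np.exp(2 * s) + 5, t, e, 10.0)
        assert c1 == pytest.approx(c2, rel=1e-12)


class TestBootstrapDeltaC:
    def _data(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        eta = rng.normal(size=n)
        T = rng.exponential(1.0 / (0.08 * np.exp(eta)))
        C = rng.uniform(5, 15, n)
        return eta, np.minimum(T, C), T <= C

    def test_identical_scores_not_significant(self):
        eta, t, e = self._data()
        d, ci, sig = bootstrap_delta_c(eta, eta, t, e, n_boot=50, seed=1)
        assert d == 0.0 and not sig

    def test_bonferroni_widens_ci(self):
        eta, t, e = self._data(seed=3)
        rng = np.random.default_rng(4)
        noisy = eta + rng.normal(0, 1.0, len(eta))
        _, ci1, _ = bootstrap_delta_c(eta, noisy, t, e, n_boot=400, m_tests=1, seed=5)
        _, ci100, _ = bootstrap_delta_c(eta, noisy, t, e, n_boot=400, m_tests=100, seed=5)
        assert (ci100[1] - ci100[0]) > (ci1[1] - ci1[0])

    def test_informative_score_significant(self):
        eta, t, e = self._data(n=800, seed=6)
        rng = np.random.default_rng(7)
        junk = rng.normal(size=len(eta))
        d, ci, sig = bootstrap_delta_c(eta, junk, t, e, n_boot=300, seed=8)
        assert d > 0 and sig

    def test_type_one_error_under_null(self):
        """B = noisy copy of A adds no information: false-positive rate
        stays within binomial tolerance of the nominal level."""
        fp = 0
        n_trials = 40
        for trial in range(n_trials):
            eta, t, e = self._data(n=150, seed=100 + trial)
            rng = np.random.default_rng(500 + trial)
            b = eta + rng.normal(0, 1e-3 * eta.std(), len(eta))
            _, _, sig = bootstrap_delta_c(eta, b, t, e, n_boot=200, seed=trial)
            fp += sig
        rate = fp / n_trials
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_trials)

    def test_too_few_iterations_rejected(self):
        eta, t, e = self._data()
        with pytest.raises(ValueError):
            bootstrap_delta_c(eta, eta, t, e, n_boot=1)


class TestKaplanMeier:
    def test_no_events_flat_zero(self):
        km = kaplan_meier(np.array([2.0, 3.0]), np.zeros(2, bool), np.array(["g", "g"]))
        assert np.allclose(km["g"]["cum_event_rate"], 0.0)

    def test_hand_product_limit(self):
        """times (1,2,3), events (1,1,0): S(2) = (2/3)(1/2) = 1/3."""
        km = kaplan_meier(
            np.array([1.0, 2.0, 3.0]), np.array([True, True, False]),
            np.array(["g"] * 3),
        )
        rate_at_2 = km["g"].set_index("time")["cum_event_rate"].loc[2.0]
        assert rate_at_2 == pytest.approx(1 - 1 / 3)

    def test_reduces_to_ecdf_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(3, 100) + 0.01
        km = kaplan_meier(t, np.ones(100, bool), np.array(["g"] * 100))
        df = km["g"]
        for _, row in df.iloc[1::17].iterrows():
            assert row["cum_event_rate"] == pytest.approx(np.mean(t <= row["time"]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier(np.array([]), np.array([], dtype=bool),
                         np.array([], dtype=object))


class TestSummarizePhenome:
    def _evals(self, n_sig, n_total):
        out = []
        for k in range(n_total):
            out.append(
                EndpointEval(
                    endpoint_id=f"E{k}", c_baseline=0.6, c_full=0.7,
                    delta_c=0.1, ci_lower=0.05, ci_upper=0.15,
                    significant=k < n_sig,
                )
            )
        return out

    @pytest.mark.parametrize(
        "n_sig,n_total,expected",
        [(1546, 1741, 88.8), (1115, 1414, 78.9), (1171, 1519, 77.1),
         (207, 1741, 11.9), (0, 10, 0.0)],
    )
    def test_reported_percentages(self, n_sig, n_total, expected):
        s = summarize_phenome(self._evals(n_sig, n_total))
        assert s["pct_significant"] == expected

    def test_delta_c_quartiles(self):
        import pandas as pd

        df = pd.DataFrame(
            {"endpoint_id": [f"E{k}" for k in range(5)],
             "delta_c": [0.05, 0.08, 0.10, 0.15, 0.30],
             "significant": [True] * 5}
        )
        q = summarize_phenome(df)["delta_c_quartiles"]
        assert q["q50"] == pytest.approx(0.10)

    def test_ci_must_bracket_point(self):
        with pytest.raises(ValueError):
            EndpointEval("E", 0.6, 0.7, delta_c=0.2, ci_lower=0.25,
                         ci_upper=0.3, significant=True)
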