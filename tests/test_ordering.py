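"""Temporal-ordering statistics: dT arithmetic and antisymmetry, frame
ordering fractions, OLS invariances, the permutation null for R^2, and
the ATP-motility analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axocascade import (
    EventCalls,
    cohort_report,
    delta_t,
    linear_fit,
    ordering_fraction,
)
from axocascade.ordering import atp_motility_analysis


def calls_with(times_list):
    out = []
    for i, times in enumerate(times_list):
        c = EventCalls(axon_id=f"a{i}")
        c.times.update(times)
        out.append(c)
    return out


class TestDeltaT:
    def test_mean_and_sem_arithmetic(self):
        calls = calls_with(
            [
                {"mito_stop": 4.0, "ca_onset": 4.4},
                {"mito_stop": 5.0, "ca_onset": 5.44},
            ]
        )
        s = delta_t(calls, "mito_stop", "ca_onset")
        assert s.mean == pytest.approx(0.42)
        assert s.sem == pytest.approx(0.02)
        assert s.n == 2

    def test_identity_pair_is_zero(self):
        calls = calls_with([{"ca_onset": 4.4}, {"ca_onset": 5.1}])
        s = delta_t(calls, "ca_onset", "ca_onset")
        assert s.mean == 0.0 and s.sem == 0.0

    def test_missing_events_excluded_pairwise(self):
        calls = calls_with(
            [
                {"mito_stop": 4.0, "ca_onset": 4.5},
                {"mito_stop": 5.0, "ca_onset": None},
                {"ca_onset": 6.0},
            ]
        )
        s = delta_t(calls, "mito_stop", "ca_onset")
        assert s.n == 1 and s.n_excluded == 2

    def test_no_qualifying_axons_errors_with_names(self):
        calls = calls_with([{"mito_stop": 4.0}])
        with pytest.raises(ValueError, match="ca_onset"):
            delta_t(calls, "mito_stop", "ca_onset")

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=10.0),
                st.floats(min_value=0.1, max_value=10.0),
            ),
            min_size=2,
            max_size=12,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetry(self, data):
        calls = calls_with([{"A": a, "B": b} for a, b in data])
        fwd = delta_t(calls, "A", "B")
        rev = delta_t(calls, "B", "A")
        assert fwd.mean == pytest.approx(-rev.mean, abs=1e-12)
        assert fwd.sem == pytest.approx(rev.sem, abs=1e-12)


class TestOrderingFraction:
    def test_five_of_seven_strict(self):
        frame = 10.0 / 60.0
        times = []
        for i in range(5):  # strictly one frame earlier
            times.append({"tmrm_drop": 3.0 + i, "ca_onset": 3.0 + i + frame})
        for i in range(2):  # same frame
            times.append({"tmrm_drop": 6.0 + i, "ca_onset": 6.0 + i + 0.01})
        f = ordering_fraction(calls_with(times), "tmrm_drop", "ca_onset", frame)
        assert (f.n_strict_before, f.n_same_frame, f.n_after) == (5, 2, 0)
        assert f.fraction_strict == pytest.approx(5 / 7)
        assert 100 * f.fraction_strict == pytest.approx(71.43, abs=0.01)

    def test_large_gaps_all_strict(self):
        times = [{"A": t, "B": t + 2.0} for t in (1.0, 2.0, 3.0)]
        f = ordering_fraction(calls_with(times), "A", "B", 10 / 60)
        assert f.fraction_strict == 1.0

    def test_simultaneous_events_all_same_frame(self):
        times = [{"A": t, "B": t} for t in (1.0, 2.0, 3.0)]
        f = ordering_fraction(calls_with(times), "A", "B", 10 / 60)
        assert f.fraction_strict == 0.0 and f.n_same_frame == 3

    @given(shift=st.floats(min_value=-5.0, max_value=5.0))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_common_time_shift(self, shift):
        frame = 10.0 / 60.0
        base = [(1.0, 1.05), (2.0, 2.3), (3.0, 3.5), (0.5, 0.52)]
        f0 = ordering_fraction(
            calls_with([{"A": a, "B": b} for a, b in base]), "A", "B", frame
        )
        # shift both events by a whole number of frames plus the tested
        # arbitrary offset applied to the frame origin via whole frames
        k = round(shift / frame)
        f1 = ordering_fraction(
            calls_with([{"A": a + k * frame, "B": b + k * frame} for a, b in base]),
            "A",
            "B",
            frame,
        )
        assert (f0.n_strict_before, f0.n_same_frame, f0.n_after) == (
            f1.n_strict_before,
            f1.n_same_frame,
            f1.n_after,
        )


class TestLinearFit:
    def test_perfect_line(self):
        x = np.arange(5.0)
        r = linear_fit(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        r = linear_fit([1, 2, 3], [1, 2, 2])
        assert r.slope == pytest.approx(0.5)
        assert r.r_squared == pytest.approx(0.75)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit([2, 2, 2], [1, 2, 3])

    def test_constant_y_flagged(self):
        r = linear_fit([1, 2, 3], [4, 4, 4])
        assert r.r_squared == 0.0 and r.constant_y

    @given(
        a=st.floats(min_value=0.1, max_value=5.0),
        b=st.floats(min_value=-10.0, max_value=10.0),
        c=st.floats(min_value=0.1, max_value=5.0),
        d=st.floats(min_value=-10.0, max_value=10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_r_squared_invariant_under_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = 1.5 * x + rng.normal(size=12)
        r0 = linear_fit(x, y)
        r1 = linear_fit(a * x + b, c * y + d)
        assert r1.r_squared == pytest.approx(r0.r_squared, rel=1e-9)

    def test_permutation_null_matches_one_over_n_minus_one(self):
        """Under random shuffling of y, E[R^2] = 1/(n-1); checked by a
        1000-permutation Monte Carlo."""
        rng = np.random.default_rng(11)
        n = 9
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(size=n)
        r2 = []
        for _ in range(1000):
            r2.append(linear_fit(x, rng.permutation(y)).r_squared)
        assert np.mean(r2) == pytest.approx(1 / (n - 1), abs=0.03)


class TestAtpMotility:
    @staticmethod
    def axon(i, decline, f_at, arrest, base=0.3):
        return {
            "axon_id": f"a{i}",
            "perceval_decline": decline,
            "baseline_mobile_fraction": base,
            "mobile_fraction_at": f_at,
            "arrest_time": arrest,
        }

    def test_axons_without_arrest_excluded(self):
        axons = [self.axon(i, 40 + i, 0.2, 4.0 + 0.1 * i) for i in range(4)]
        axons.append(self.axon(9, 50, 0.2, None))
        res = atp_motility_analysis(axons)
        assert res.n_excluded == 1
        assert len(res.table) == 4

    def test_violation_counting(self):
        # motility dropped 50% while the sensor dropped 30% -> violation
        axons = [
            self.axon(0, 30.0, 0.15, 4.0),
            self.axon(1, 60.0, 0.15, 4.5),
            self.axon(2, 80.0, 0.06, 5.0),
        ]
        res = atp_motility_analysis(axons)
        assert res.n_violations == 1

    def test_too_few_axons_rejected(self):
        with pytest.raises(ValueError):
            atp_motility_analysis([self.axon(0, 40, 0.2, 4.0)])


class TestCohortReport:
    def test_report_contains_all_cascade_pairs(self):
        calls = calls_with(
            [
                {
                    "mito_stop": 4.0,
                    "tmrm_drop": 4.3,
                    "ca_onset": 4.42,
                    "ps_exposure": 4.93,
                    "degeneration": 6.09,
                }
                for _ in range(3)
            ]
        )
        rep = cohort_report(calls)
        assert set(rep["delta_t"]) == {
            "mito_arrest_to_calcium",
            "tmrm_drop_to_calcium",
            "calcium_to_ps_exposure",
            "calcium_to_degeneration",
        }
        assert all("mean_h" in v for v in rep["delta_t"].values())

    def test_event_free_cohort_marks_not_applicable(self):
        calls = calls_with([{"ca_onset": None, "mito_stop": None} for _ in range(3)])
        rep = cohort_report(calls)
        assert all(
            v == {"status": "not_applicable"} for v in rep["delta_t"].values()
        )
        assert rep["ordering"]["tmrm_before_calcium"] == {"status": "not_applicable"}

    def test_report_deterministic(self):
        calls = calls_with(
            [{"mito_stop": 4.0, "ca_onset": 4.4, "tmrm_drop": 4.2} for _ in range(4)]
        )
        assert cohort_report(calls) == cohort_report(calls)

    def test_second_peak_correlations(self):
        rng = np.random.default_rng(2)
        frag = rng.uniform(5, 9, 22)
        rows = [
            {
                "initiation": f - 1.6 + rng.normal(0, 0.05),
                "duration": 1.6 + rng.normal(0, 0.3),
                "intensity": 3.5 + rng.normal(0, 0.5),
                "fragmentation_time": f,
            }
            for f in frag
        ]
        rep = cohort_report(
            calls_with([{"ca_onset": 4.0, "tmrm_drop": 3.9}] * 3), second_peak=rows
        )
        sp = rep["second_peak"]
        assert sp["initiation_vs_fragmentation_r"] > 0.9
        assert abs(sp["intensity_vs_fragmentation_r"]) < 0.5
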