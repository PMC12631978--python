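"""Modified z-score active-fraction calling and peak grouping."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hteda import (
    ActiveFractionCall,
    DegenerateSpreadWarning,
    FractionScheme,
    HtedaError,
    Toxicogram,
    call_active,
    group_peaks,
    modified_z_scores,
)


def brute_force_z(values):
    """Independent oracle: plain-python median/MAD modified z-scores."""
    med = statistics.median(values)
    mad = statistics.median([abs(v - med) for v in values])
    if mad == 0:
        return [0.0] * len(values)
    return [(v - med) / mad for v in values]


class TestModifiedZ:
    def test_worked_vector(self):
        calls = modified_z_scores([1, 2, 3, 4, 100])
        assert calls[0].median == 3
        assert calls[0].mad == 1
        assert [c.z for c in calls] == pytest.approx([-2, -1, 0, 1, 97])
        assert [c.active for c in calls] == [False] * 4 + [True]

    def test_degenerate_spread(self):
        with pytest.warns(DegenerateSpreadWarning):
            calls = modified_z_scores([5.0, 5.0, 5.0, 5.0])
        assert all(c.z == 0.0 and not c.active for c in calls)

    def test_minimum_size(self):
        with pytest.raises(HtedaError):
            modified_z_scores([1.0, 2.0])

    def test_threshold_strictly_greater(self):
        # median 1, MAD 1: the outlier lands exactly on z = 10
        calls = modified_z_scores([0, 0, 1, 2, 11], threshold=10)
        assert calls[-1].z == pytest.approx(10.0)
        assert not calls[-1].active
        calls2 = modified_z_scores([0, 0, 1, 2, 12], threshold=10)
        assert calls2[-1].active

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=50,
        )
    )
    def test_matches_brute_force_oracle(self, values):
        expected = brute_force_z(values)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateSpreadWarning)
            calls = modified_z_scores(values)
        assert [c.z for c in calls] == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=4,
            max_size=30,
        ),
        st.floats(min_value=-50, max_value=50),
        st.floats(min_value=0.1, max_value=20),
    )
    def test_shift_invariance_and_scale_equivariance(self, values, shift, scale):
        import statistics
        import warnings

        from hypothesis import assume

        med = statistics.median(values)
        # a well-conditioned spread keeps the property out of float
        # cancellation territory
        assume(statistics.median([abs(v - med) for v in values]) > 1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateSpreadWarning)
            base = [c.z for c in modified_z_scores(values)]
            shifted = [c.z for c in modified_z_scores([v + shift for v in values])]
            scaled = [c.z for c in modified_z_scores([v * scale for v in values])]
        assert shifted == pytest.approx(base, abs=1e-6, rel=1e-6)
        assert scaled == pytest.approx(base, abs=1e-6, rel=1e-6)


class TestCallActive:
    def test_spiked_fractions_called(self, scheme):
        rng = np.random.default_rng(7)
        resp = rng.normal(0.0, 0.4, 80)
        spiked = [10, 11, 12, 40, 41]
        resp[spiked] = [60, 80, 55, 70, 90]
        tox = Toxicogram.from_responses(resp, scheme)
        calls = call_active(tox)
        assert sorted(c.fraction_index for c in calls if c.active) == [
            i + 1 for i in spiked
        ]

    def test_blank_toxicogram_no_calls(self, scheme):
        # noise-only blanks: no fraction should be called at z > 10
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tox = Toxicogram.from_responses(
                rng.normal(0.0, 0.5, 80), scheme, source="blank"
            )
            assert not any(c.active for c in call_active(tox))

    def test_infinite_threshold(self, scheme):
        rng = np.random.default_rng(0)
        tox = Toxicogram.from_responses(rng.normal(0, 1, 80), scheme)
        assert not any(c.active for c in call_active(tox, threshold=np.inf))

    def test_audit_fields_exposed(self, scheme):
        tox = Toxicogram.from_responses(np.arange(80, dtype=float), scheme)
        calls = call_active(tox)
        assert calls[0].median == pytest.approx(39.5)
        assert calls[0].mad == pytest.approx(20.0)


class TestGroupPeaks:
    def _calls(self, active, n=80):
        return [
            ActiveFractionCall(
                fraction_index=i,
                response=100.0 if i in active else 0.0,
                median=0.0,
                mad=1.0,
                z=100.0 if i in active else 0.0,
                active=i in active,
            )
            for i in range(1, n + 1)
        ]

    def test_two_runs(self, scheme):
        peaks = group_peaks(self._calls({51, 52, 53, 58, 59}), scheme)
        assert [p.fractions for p in peaks] == [(51, 52, 53), (58, 59)]
        assert peaks[0].rt_start_s == pytest.approx(50 * 18.0)
        assert peaks[0].rt_end_s == pytest.approx(53 * 18.0)

    def test_no_active(self, scheme):
        assert group_peaks(self._calls(set()), scheme) == []

    def test_all_active_single_peak(self, scheme):
        # uniform high activity minus a constant spread: force via threshold 0
        calls = modified_z_scores(np.linspace(1, 1000, 80), threshold=-1e9)
        peaks = group_peaks(calls, scheme)
        assert len(peaks) == 1
        assert peaks[0].rt_window == pytest.approx((0.0, 1440.0))

    def test_gap_tolerance(self, scheme):
        calls = self._calls({10, 12, 20})
        assert len(group_peaks(calls, scheme)) == 3
        assert len(group_peaks(calls, scheme, gap_tolerance=1)) == 2
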