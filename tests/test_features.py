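"""Feature-table operations: blank rule, matching, windows, fractions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hteda import (
    Feature,
    FeatureTable,
    FractionScheme,
    HtedaError,
    assign_fractions,
    blank_subtract,
    count_shared,
    filter_rt_window,
    match_features,
    read_feature_table,
)


def _table(rows, provenance="sample"):
    feats = [
        Feature(id=f"f{i}", mz=mz, rt_s=rt, intensity=inten, ion_source=src)
        for i, (mz, rt, inten, src) in enumerate(rows)
    ]
    return FeatureTable.from_features(feats, provenance=provenance)


class TestMatchFeatures:
    def test_ppm_boundary(self):
        a = Feature("a", 300.0000, 100.0, 1.0)
        assert match_features(a, Feature("b", 300.0014, 110.0, 1.0))  # 4.67 ppm
        assert not match_features(a, Feature("c", 300.0016, 110.0, 1.0))  # 5.33

    def test_rt_boundary(self):
        a = Feature("a", 300.0, 100.0, 1.0)
        assert match_features(a, Feature("b", 300.0, 130.0, 1.0))
        assert not match_features(a, Feature("c", 300.0, 130.1, 1.0))

    def test_reflexive(self):
        a = Feature("a", 451.1234, 777.0, 5.0)
        assert match_features(a, a)

    def test_zero_tolerance_is_equality(self):
        a = Feature("a", 300.0, 100.0, 1.0)
        assert match_features(a, a, mz_tol_ppm=0.0, rt_tol_s=0.0)
        assert not match_features(
            a, Feature("b", 300.0000001, 100.0, 1.0), mz_tol_ppm=0.0, rt_tol_s=0.0
        )


class TestBlankSubtract:
    def test_intensity_ratio_rule(self):
        sample = _table(
            [(300.0, 100.0, 400.0, "ESI_pos"), (350.0, 200.0, 250.0, "ESI_pos")]
        )
        blank = _table(
            [(300.0, 100.0, 100.0, "ESI_pos"), (350.0, 200.0, 100.0, "ESI_pos")],
            provenance="blank",
        )
        kept = blank_subtract(sample, blank, ratio=3.0)
        # 400 > 3*100 kept; 250 <= 3*100 removed
        assert kept.df["id"].tolist() == ["f0"]

    def test_no_blank_match_kept(self):
        sample = _table([(300.0, 100.0, 10.0, "ESI_pos")])
        blank = _table([(500.0, 100.0, 1e9, "ESI_pos")], provenance="blank")
        assert len(blank_subtract(sample, blank)) == 1

    def test_highest_intensity_blank_match_used(self):
        sample = _table([(300.0, 100.0, 250.0, "ESI_pos")])
        blank = _table(
            [(300.0, 95.0, 10.0, "ESI_pos"), (300.00001, 105.0, 100.0, "ESI_pos")],
            provenance="blank",
        )
        # against the 100-intensity blank the 250 fails the 3x rule
        assert len(blank_subtract(sample, blank)) == 0

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        sample = _table(
            [(100 + i, rng.uniform(0, 1000), rng.uniform(1, 1e5), "ESI_pos")
             for i in range(50)]
        )
        blank = _table(
            [(100 + i + rng.normal(0, 1e-5), rng.uniform(0, 1000),
              rng.uniform(1, 1e5), "ESI_pos") for i in range(30)],
            provenance="blank",
        )
        once = blank_subtract(sample, blank)
        twice = blank_subtract(once, blank)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_mixed_sources_rejected(self):
        sample = _table([(300.0, 1.0, 1.0, "ESI_pos")])
        blank = _table([(300.0, 1.0, 1.0, "APCI_pos")], provenance="blank")
        with pytest.raises(HtedaError):
            blank_subtract(sample, blank)


class TestRtWindowAndFractions:
    def test_half_open_window(self):
        t = _table(
            [(300.0, 1000.0, 1.0, "ESI_pos"), (301.0, 1110.0, 1.0, "ESI_pos")]
        )
        kept = filter_rt_window(t, (900.0, 1110.0))
        assert kept.df["rt_s"].tolist() == [1000.0]
        assert len(filter_rt_window(t.subset([False, False]), (0.0, 10.0))) == 0

    def test_empty_window_rejected(self):
        t = _table([(300.0, 1000.0, 1.0, "ESI_pos")])
        with pytest.raises(HtedaError):
            filter_rt_window(t, (100.0, 100.0))

    def test_assign_fractions(self, scheme):
        t = _table(
            [
                (300.0, 915.0, 1.0, "ESI_pos"),  # floor(915/18)=50 -> 51
                (301.0, 2000.0, 1.0, "ESI_pos"),  # beyond window
                (302.0, 18.0, 1.0, "ESI_pos"),  # boundary -> later fraction
            ]
        )
        m = assign_fractions(t, scheme)
        assert m["f0"] == 51
        assert m["f1"] is None
        assert m["f2"] == 2


class TestCountShared:
    def test_disjoint_and_identical(self):
        a = _table([(300.0, 10.0, 1.0, "ESI_pos"), (400.0, 20.0, 1.0, "ESI_pos")])
        b = _table([(500.0, 10.0, 1.0, "ESI_pos")])
        assert count_shared(a, b) == 0
        assert count_shared(a, a) == 2

    def test_one_to_one_pairing(self):
        a = _table([(300.0, 10.0, 1.0, "ESI_pos")])
        b = _table(
            [(300.0001, 10.0, 1.0, "ESI_pos"), (300.0002, 12.0, 1.0, "ESI_pos")]
        )
        assert count_shared(a, b) == 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetry_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        def rand_table(n):
            return _table(
                [
                    (rng.uniform(100, 110), rng.uniform(0, 100), 1.0, "ESI_pos")
                    for _ in range(n)
                ]
            )
        a, b = rand_table(rng.integers(1, 15)), rand_table(rng.integers(1, 15))
        assert count_shared(a, b) == count_shared(b, a)


class TestIo:
    def test_round_trip(self, tmp_path):
        t = _table([(300.1234, 100.0, 55.5, "ESI_pos")])
        p = tmp_path / "t.tsv"
        t.write(p)
        back = read_feature_table(p)
        assert back.df["mz"].iloc[0] == pytest.approx(300.1234)
        assert bool(back.df["has_ms2"].iloc[0]) is False

    def test_rt_minutes_converted(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,mz,rt_min,intensity,ion_source,has_ms2\nx,300.0,15.0,1.0,ESI_pos,True\n")
        t = read_feature_table(p)
        assert t.df["rt_s"].iloc[0] == pytest.approx(900.0)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {
                "id": ["a", "a"],
                "mz": [1.0, 2.0],
                "rt_s": [0.0, 0.0],
                "intensity": [1.0, 1.0],
                "ion_source": ["ESI_pos"] * 2,
                "has_ms2": [False, False],
            }
        )
        with pytest.raises(HtedaError):
            FeatureTable(df)
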