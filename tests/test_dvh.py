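"""DVH data model, text I/O, conversions and dose metrics."""

import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bnct_tcp import (
    DVH,
    DVHParseError,
    dose_at_volume,
    max_dose,
    mean_dose,
    min_dose,
    read_dvh,
    to_cumulative,
    to_differential,
    volume_fraction_below,
    write_dvh,
)

CUM = DVH(kind="cumulative", doses=[10, 20, 30], volumes=[1.0, 0.8, 0.3])


@st.composite
def dvh_strategy(draw):
    n = draw(st.integers(1, 10))
    doses = draw(
        st.lists(st.floats(1.0, 100.0), min_size=n, max_size=n, unique=True)
    )
    vols = draw(st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n))
    vols = np.asarray(vols)
    return DVH(kind="differential", doses=sorted(doses), volumes=vols / vols.sum())


class TestModel:
    def test_differential_volume_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            DVH(kind="differential", doses=[10, 20], volumes=[0.4, 0.5])

    def test_near_one_sum_renormalized(self):
        d = DVH(kind="differential", doses=[10, 20], volumes=[0.5, 0.495])
        assert d.volumes.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cumulative_must_be_non_increasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            DVH(kind="cumulative", doses=[10, 20], volumes=[0.8, 1.0])

    def test_doses_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            DVH(kind="differential", doses=[10, 10], volumes=[0.5, 0.5])


class TestConversion:
    def test_cumulative_to_differential_by_hand(self):
        diff = to_differential(CUM)
        np.testing.assert_allclose(diff.volumes, [0.2, 0.5, 0.3], atol=1e-12)

    def test_single_bin(self):
        d = DVH(kind="cumulative", doses=[15.0], volumes=[1.0])
        np.testing.assert_allclose(to_differential(d).volumes, [1.0])

    @given(dvh=dvh_strategy())
    def test_round_trip_identity(self, dvh):
        back = to_differential(to_cumulative(dvh))
        np.testing.assert_allclose(back.volumes, dvh.volumes, atol=1e-12)

    def test_same_kind_returns_copy(self):
        copy = to_cumulative(CUM)
        assert copy is not CUM
        np.testing.assert_allclose(copy.volumes, CUM.volumes)


class TestMetrics:
    def test_uniform(self):
        d = DVH(kind="differential", doses=[20.0], volumes=[1.0])
        assert min_dose(d) == max_dose(d) == mean_dose(d) == 20.0

    def test_zero_volume_bin_ignored_by_min(self):
        d = DVH(kind="differential", doses=[10, 15, 30], volumes=[0.0, 0.5, 0.5])
        assert min_dose(d) == 15.0
        assert max_dose(d) == 30.0
        assert mean_dose(d) == pytest.approx(22.5)

    def test_small_cold_spot_still_sets_min(self):
        d = DVH(kind="differential", doses=[9.4, 20.0], volumes=[0.02, 0.98])
        assert min_dose(d) == 9.4

    @given(dvh=dvh_strategy())
    def test_min_mean_max_ordering(self, dvh):
        assert min_dose(dvh) <= mean_dose(dvh) + 1e-12
        assert mean_dose(dvh) <= max_dose(dvh) + 1e-12


class TestVolumeFractionBelow:
    def test_below_min_is_zero(self):
        assert volume_fraction_below(CUM, 5.0) == 0.0

    def test_above_max_is_one(self):
        assert volume_fraction_below(CUM, 50.0) == pytest.approx(1.0)

    def test_strict_inequality_hand_value(self):
        d = DVH(kind="differential", doses=[10, 20], volumes=[0.15, 0.85])
        assert volume_fraction_below(d, 18.5) == pytest.approx(0.15)
        assert volume_fraction_below(d, 10.0) == 0.0  # strict: dose == threshold excluded

    @given(dvh=dvh_strategy(), t1=st.floats(0, 110), t2=st.floats(0, 110))
    def test_monotone_in_threshold(self, dvh, t1, t2):
        lo, hi = sorted([t1, t2])
        assert volume_fraction_below(dvh, lo) <= volume_fraction_below(dvh, hi) + 1e-12


class TestDoseAtVolume:
    def test_uniform(self):
        d = DVH(kind="differential", doses=[20.0], volumes=[1.0])
        assert dose_at_volume(d, 0.8) == 20.0

    def test_exact_node(self):
        assert dose_at_volume(CUM, 0.8) == pytest.approx(20.0)

    def test_linear_interpolation(self):
        assert dose_at_volume(CUM, 0.55) == pytest.approx(25.0)

    def test_out_of_range_fraction(self):
        with pytest.raises(ValueError):
            dose_at_volume(CUM, 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(CUM, 1.5)


class TestIO:
    def test_differential_file(self):
        text = "# kind=differential unit=Gy-w target=GTV1\ndose,volume\n10,0.2\n20,0.5\n30,0.3\n"
        d = read_dvh(io.StringIO(text))
        assert d.kind == "differential"
        assert d.target_label == "GTV1"
        assert d.volumes.sum() == pytest.approx(1.0)

    def test_cumulative_file(self):
        text = "# kind=cumulative unit=Gy-w\n10,1.0\n20,0.8\n30,0.3\n"
        d = read_dvh(io.StringIO(text))
        assert d.kind == "cumulative"

    def test_bad_volume_sum_rejected(self):
        text = "# kind=differential unit=Gy-w\n10,0.4\n20,0.5\n"
        with pytest.raises(DVHParseError, match="sum"):
            read_dvh(io.StringIO(text))

    def test_non_monotone_doses_rejected(self):
        text = "# kind=differential unit=Gy-w\n20,0.5\n10,0.5\n"
        with pytest.raises(DVHParseError):
            read_dvh(io.StringIO(text))

    def test_missing_header_line_number(self):
        with pytest.raises(DVHParseError, match="line 1"):
            read_dvh(io.StringIO("10,0.5\n20,0.5\n"))

    def test_malformed_row_reports_line(self):
        text = "# kind=differential unit=Gy-w\n10,0.5\noops\n"
        with pytest.raises(DVHParseError, match="line 3"):
            read_dvh(io.StringIO(text))

    @given(dvh=dvh_strategy())
    def test_write_read_round_trip(self, dvh):
        buf = io.StringIO()
        write_dvh(dvh, buf)
        back = read_dvh(io.StringIO(buf.getvalue()))
        assert back.kind == dvh.kind
        np.testing.assert_allclose(back.doses, dvh.doses, rtol=1e-9)
        np.testing.assert_allclose(back.volumes, dvh.volumes, rtol=1e-9)

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "t.dvh"
        write_dvh(CUM, path)
        back = read_dvh(path)
        np.testing.assert_allclose(back.volumes, CUM.volumes)
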