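"""Domain-type invariants and CSV round-trip behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fingertap import (
    AccelTrace,
    ConfigError,
    DataError,
    FingerLabel,
    FormatError,
    SessionConfig,
    TestType,
    TrialRecord,
    read_trace_csv,
    write_metrics_table,
    write_trace_csv,
)
from fingertap.data_model_io import read_metrics_table

from conftest import make_trace


class TestAccelTrace:
    def test_duration_and_length(self):
        trace = make_trace(np.zeros(3600) + 0.1)
        assert trace.n_samples == 3600
        assert trace.duration == pytest.approx(3599 / 120)

    def test_rejects_short_trace(self):
        with pytest.raises(DataError, match="at least 2"):
            make_trace([0.0])

    def test_rejects_non_monotone_time(self):
        t = np.array([0.0, 1 / 120, 1 / 120, 3 / 120])
        with pytest.raises(DataError, match="strictly increasing"):
            AccelTrace("s", FingerLabel.INDEX_DOM, 120.0, t, t * 0, t * 0, t * 0)

    def test_rejects_irregular_sampling(self):
        t = np.array([0.0, 1 / 120, 2 / 120, 2.5 / 120])
        with pytest.raises(DataError, match="irregular sampling"):
            AccelTrace("s", FingerLabel.INDEX_DOM, 120.0, t, t * 0, t * 0, t * 0)

    def test_rejects_out_of_scale_acceleration(self):
        z = np.zeros(100)
        z[50] = 9.5  # beyond the +/-8 g full scale
        with pytest.raises(DataError, match="full scale"):
            make_trace(z)

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(DataError):
            AccelTrace(
                "s",
                FingerLabel.INDEX_DOM,
                120.0,
                np.arange(4) / 120,
                np.zeros(4),
                np.zeros(3),
                np.zeros(4),
            )


class TestTrialRecord:
    def _trial(self, f1, f2, test_type):
        return TrialRecord(
            "P1",
            test_type,
            make_trace(np.zeros(1200), finger=f1),
            make_trace(np.zeros(1200), finger=f2),
            duration=1200 / 120,
        )

    def test_finger_pair_must_match_test_type(self):
        self._trial(FingerLabel.INDEX_DOM, FingerLabel.MIDDLE_DOM, TestType.UNISIM)
        self._trial(FingerLabel.INDEX_RIGHT, FingerLabel.INDEX_LEFT, TestType.BIMALT)
        with pytest.raises(DataError, match="expects fingers"):
            self._trial(FingerLabel.INDEX_DOM, FingerLabel.INDEX_LEFT, TestType.UNISIM)

    def test_duplicate_finger_rejected(self):
        with pytest.raises(DataError, match="distinct fingers"):
            self._trial(FingerLabel.INDEX_DOM, FingerLabel.INDEX_DOM, TestType.UNISIM)

    def test_insufficient_overlap_rejected(self):
        t1 = make_trace(np.zeros(1200), finger=FingerLabel.INDEX_DOM)
        t2 = make_trace(np.zeros(1200), finger=FingerLabel.MIDDLE_DOM)
        t2.timestamps = t2.timestamps + 5.0  # shift by half the trial
        with pytest.raises(DataError, match="overlap"):
            TrialRecord("P1", TestType.UNISIM, t1, t2, duration=10.0)


class TestTraceCsv:
    def test_basic_read(self, tmp_path):
        n, fs = 3600, 120.0
        trace = make_trace(np.sin(np.arange(n) / 50), sampling_rate=fs)
        path = write_trace_csv(trace, tmp_path / "t.csv")
        back = read_trace_csv(path, FingerLabel.INDEX_DOM, sensor_id="test")
        assert back.n_samples == n
        assert back.duration == pytest.approx((n - 1) / fs)

    def test_round_trip_identity(self, tmp_path, rng):
        z = rng.normal(0, 1, 500)
        trace = make_trace(z, x=rng.normal(0, 0.1, 500), y=rng.normal(0, 0.1, 500))
        path = write_trace_csv(trace, tmp_path / "t.csv")
        back = read_trace_csv(
            path, trace.finger_label, sampling_rate=120.0, sensor_id="test"
        )
        assert back == trace

    def test_millisecond_time_column(self, tmp_path):
        n, fs = 240, 120.0
        path = tmp_path / "ms.csv"
        t_ms = np.arange(n) / fs * 1000.0
        lines = ["time,ax,ay,az"] + [
            f"{float(t_ms[i])!r},0.0,0.0,0.5" for i in range(n)
        ]
        path.write_text("\n".join(lines))
        trace = read_trace_csv(path, FingerLabel.INDEX_DOM, time_unit="ms")
        assert trace.duration == pytest.approx((n - 1) / fs)
        assert trace.sampling_rate == pytest.approx(fs)

    def test_sample_counter_time_column(self, tmp_path):
        path = tmp_path / "ctr.csv"
        lines = ["time,ax,ay,az"] + [f"{i},0.0,0.0,0.5" for i in range(120)]
        path.write_text("\n".join(lines))
        trace = read_trace_csv(
            path, FingerLabel.INDEX_DOM, time_unit="samples", sampling_rate=120.0
        )
        assert trace.duration == pytest.approx(119 / 120)
        with pytest.raises(ConfigError, match="sampling_rate"):
            read_trace_csv(path, FingerLabel.INDEX_DOM, time_unit="samples")

    def test_unit_conversion_from_ms2(self, tmp_path):
        path = tmp_path / "si.csv"
        lines = ["time,ax,ay,az"] + [
            f"{i / 120}," + "0.0,0.0,9.81" for i in range(10)
        ]
        path.write_text("\n".join(lines))
        trace = read_trace_csv(path, FingerLabel.INDEX_DOM, accel_unit="m/s2")
        assert trace.az == pytest.approx(np.ones(10))

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,ax,ay\n0,0,0\n0.1,0,0\n")
        with pytest.raises(FormatError, match="az"):
            read_trace_csv(path, FingerLabel.INDEX_DOM)

    def test_column_map_escape_hatch(self, tmp_path):
        path = tmp_path / "vendor.csv"
        path.write_text(
            "SampleTime,AccX,AccY,AccZ\n"
            + "\n".join(f"{i / 120},0,0,1" for i in range(10))
        )
        trace = read_trace_csv(
            path,
            FingerLabel.INDEX_DOM,
            column_map={"time": "SampleTime", "ax": "AccX", "ay": "AccY", "az": "AccZ"},
        )
        assert trace.n_samples == 10

    def test_non_monotone_reports_row(self, tmp_path):
        path = tmp_path / "nm.csv"
        path.write_text("time,ax,ay,az\n0,0,0,0\n0.008,0,0,0\n0.008,0,0,0\n0.025,0,0,0\n")
        with pytest.raises(DataError, match="row 2"):
            read_trace_csv(path, FingerLabel.INDEX_DOM)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError, match="no such file"):
            read_trace_csv(tmp_path / "absent.csv", FingerLabel.INDEX_DOM)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=2, max_value=200),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_round_trip_property(self, tmp_path_factory, n, seed):
        """write o read = identity on randomly generated valid traces."""
        r = np.random.default_rng(seed)
        trace = make_trace(
            np.clip(r.normal(0, 2, n), -7.9, 7.9),
            x=r.normal(0, 0.3, n),
            y=r.normal(0, 0.3, n),
        )
        path = tmp_path_factory.mktemp("rt") / "t.csv"
        write_trace_csv(trace, path)
        back = read_trace_csv(path, trace.finger_label, sampling_rate=120.0,
                              sensor_id="test")
        assert back == trace


class TestMetricsTable:
    def test_row_count_and_round_trip(self, tmp_path):
        rows = [
            {"participant_id": f"P{i}", "test_type": "UniSIM", "slope": 0.0123456789012 * i}
            for i in range(120)
        ]
        path = write_metrics_table(rows, tmp_path / "m.csv")
        df = read_metrics_table(path)
        assert len(df) == 120
        assert list(df.columns) == ["participant_id", "test_type", "slope"]
        # numeric values identical to >= 12 significant digits
        np.testing.assert_allclose(
            df["slope"].to_numpy(), [r["slope"] for r in rows], rtol=1e-12
        )

    def test_empty_list_gives_header_only(self, tmp_path):
        path = write_metrics_table([], tmp_path / "e.csv", columns=["a", "b"])
        assert path.read_text().strip() == "a,b"

    def test_heterogeneous_rows_rejected(self, tmp_path):
        with pytest.raises(DataError, match="heterogeneous"):
            write_metrics_table([{"a": 1}, {"b": 2}], tmp_path / "x.csv")


class TestSessionConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SessionConfig(min_prominence=0.7, simultaneity_threshold=0.12)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SessionConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ConfigError):
            SessionConfig(simultaneity_threshold=0.0)

    def test_rejects_unknown_keys(self, tmp_path):
        (tmp_path / "c.yaml").write_text("mystery_knob: 3\n")
        with pytest.raises(ConfigError, match="mystery_knob"):
            SessionConfig.from_yaml(tmp_path / "c.yaml")
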