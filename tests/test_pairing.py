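"""CGM/SMBG pairing, windowed detection and CSV ingest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hegrid.pairing import IngestError, detection_rate, pair_readings, validate_readings
from hegrid.readers import read_cgm_csv, read_smbg_csv

from .oracles import brute_force_pairs

BASE = pd.Timestamp("2022-01-03 10:00:00")


def readings(times_s, values, pid="P01", source="CGM"):
    return pd.DataFrame(
        {
            "patient_id": pid,
            "timestamp": [BASE + pd.Timedelta(seconds=int(t)) for t in times_s],
            "value": values,
            "source": source,
        }
    )


class TestPairing:
    def test_nearest_within_window(self):
        smbg = readings([0], [4.0], source="SMBG")
        cgm = readings([-180, 240], [5.0, 6.0])
        ps = pair_readings(smbg, cgm)
        assert len(ps) == 1
        assert ps.pairs.loc[0, "delta_t_s"] == -180
        assert ps.pairs.loc[0, "cgm_mmol"] == 5.0

    def test_outside_window_unpaired(self):
        smbg = readings([0], [4.0], source="SMBG")
        cgm = readings([360], [5.0])
        ps = pair_readings(smbg, cgm)
        assert len(ps) == 0
        assert ps.n_unpaired == 1

    def test_exact_tie_goes_to_earlier_reading(self):
        smbg = readings([0], [4.0], source="SMBG")
        cgm = readings([-300, 300], [5.0, 6.0])
        ps = pair_readings(smbg, cgm)
        assert ps.pairs.loc[0, "delta_t_s"] == -300
        assert ps.pairs.loc[0, "cgm_mmol"] == 5.0

    def test_window_is_closed(self):
        smbg = readings([0], [4.0], source="SMBG")
        cgm = readings([300], [5.0])
        assert len(pair_readings(smbg, cgm)) == 1

    def test_patient_ids_must_match(self):
        smbg = readings([0], [4.0], pid="P01", source="SMBG")
        cgm = readings([0], [5.0], pid="P02")
        ps = pair_readings(smbg, cgm)
        assert len(ps) == 0 and ps.n_unpaired == 1

    def test_derived_quantities(self):
        smbg = readings([0], [4.0], source="SMBG")
        cgm = readings([60], [5.0])
        row = pair_readings(smbg, cgm).pairs.loc[0]
        assert row["diff"] == pytest.approx(1.0)
        assert row["ard"] == pytest.approx(25.0)

    def test_cgm_reading_may_serve_multiple_smbg(self):
        smbg = readings([0, 120], [4.0, 4.1], source="SMBG")
        cgm = readings([60], [5.0])
        ps = pair_readings(smbg, cgm)
        assert len(ps) == 2
        assert (ps.pairs["cgm_mmol"] == 5.0).all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        smbg = readings(np.sort(rng.choice(86_400, 40, replace=False)),
                        rng.uniform(2, 9, 40), source="SMBG")
        cgm = readings(np.sort(rng.choice(86_400, 300, replace=False)),
                       rng.uniform(2, 9, 300))
        a = pair_readings(smbg, cgm).pairs
        b = pair_readings(
            smbg.sample(frac=1, random_state=0), cgm.sample(frac=1, random_state=1)
        ).pairs
        pd.testing.assert_frame_equal(a, b)

    def test_conflicting_duplicates_raise_equal_duplicates_dropped(self):
        dup_ok = readings([0, 0], [4.0, 4.0], source="SMBG")
        assert len(validate_readings(dup_ok)) == 1
        dup_bad = readings([0, 0], [4.0, 4.2], source="SMBG")
        with pytest.raises(IngestError):
            validate_readings(dup_bad)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 60), rng.integers(1, 120)
        st_s = np.sort(rng.choice(20_000, size=n, replace=False))
        ct_s = np.sort(rng.choice(20_000, size=m, replace=False))
        smbg = readings(st_s, rng.uniform(1, 10, n), source="SMBG")
        cgm = readings(ct_s, rng.uniform(1, 10, m))
        ps = pair_readings(smbg, cgm, window_s=300)
        expected = brute_force_pairs(st_s.tolist(), ct_s.tolist(), 300)
        exp_pairs = [(int(t), int(ct_s[j])) for t, j in zip(st_s, expected) if j is not None]
        got = [
            (int((r.t_smbg - BASE).total_seconds()), int((r.t_cgm - BASE).total_seconds()))
            for r in ps.pairs.itertuples()
        ]
        assert got == exp_pairs

    def test_brute_force_oracle_large_instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(10):
            n, m = rng.integers(50, 500), rng.integers(50, 500)
            st_s = np.sort(rng.choice(500_000, size=n, replace=False))
            ct_s = np.sort(rng.choice(500_000, size=m, replace=False))
            smbg = readings(st_s, rng.uniform(1, 10, n), source="SMBG")
            cgm = readings(ct_s, rng.uniform(1, 10, m))
            ps = pair_readings(smbg, cgm, window_s=300)
            expected = brute_force_pairs(st_s.tolist(), ct_s.tolist(), 300)
            exp = [(int(t), int(ct_s[j])) for t, j in zip(st_s, expected) if j is not None]
            got = [
                (int((r.t_smbg - BASE).total_seconds()), int((r.t_cgm - BASE).total_seconds()))
                for r in ps.pairs.itertuples()
            ]
            assert got == exp

    def test_no_pair_exceeds_window_mean_dt_bounded(self):
        rng = np.random.default_rng(9)
        smbg = readings(np.sort(rng.choice(86_400, 100, replace=False)),
                        rng.uniform(2, 9, 100), source="SMBG")
        cgm = readings(np.sort(rng.choice(86_400, 2000, replace=False)),
                       rng.uniform(2, 9, 2000))
        ps = pair_readings(smbg, cgm, window_s=300)
        dt = np.abs(ps.pairs["delta_t_s"])
        assert (dt <= 300).all()
        assert dt.mean() <= 150


class TestDetection:
    def test_worked_detection_rate(self):
        # 188 hypo events; 96 with a below-threshold CGM in window
        n = 188
        smbg = readings(np.arange(n) * 7200, np.full(n, 3.0), source="SMBG")
        cgm_vals = np.where(np.arange(n) < 96, 3.2, 5.0)
        cgm = readings(np.arange(n) * 7200 + 600, cgm_vals)
        det = detection_rate(smbg, cgm, threshold=3.5)
        assert (det.events, det.detected, det.no_coverage) == (188, 96, 0)
        assert det.rate_percent == 51

    def test_detected_inside_window_only(self):
        smbg = readings([0], [3.1], source="SMBG")
        cgm = readings([600], [3.2])
        assert detection_rate(smbg, cgm).detected == 1
        cgm_far = readings([1200], [3.2])
        det = detection_rate(smbg, cgm_far, half_window_s=900)
        assert det.detected == 0 and det.no_coverage == 1

    def test_no_events_gives_null_rate(self):
        smbg = readings([0], [5.0], source="SMBG")
        cgm = readings([0], [5.0])
        det = detection_rate(smbg, cgm)
        assert det.events == 0 and det.rate is None and det.rate_percent is None

    def test_no_coverage_excluded_from_denominator(self):
        smbg = readings([0, 40_000], [3.0, 3.0], source="SMBG")
        cgm = readings([60], [3.2])
        det = detection_rate(smbg, cgm)
        assert det.events == 2 and det.no_coverage == 1 and det.detected == 1
        assert det.rate == pytest.approx(1.0)

    def test_shrinking_window_converges_to_point_sensitivity(self):
        # co-timed readings: a zero-width window is exactly point agreement
        rng = np.random.default_rng(21)
        n = 300
        sv = rng.uniform(2.0, 6.0, n)
        cv = sv + rng.normal(0, 1.0, n)
        cv = np.clip(cv, 0.5, None)
        t = np.arange(n) * 3600
        smbg = readings(t, sv, source="SMBG")
        cgm = readings(t, cv)
        det = detection_rate(smbg, cgm, threshold=3.5, half_window_s=1)
        hypo = sv < 3.5
        point_sens = (cv[hypo] < 3.5).mean()
        assert det.rate == pytest.approx(point_sens)


class TestReaders:
    def test_generic_round_trip(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text(
            "patient_id,timestamp,glucose,unit\n"
            "P01,2022-01-03T10:00:00,4.5,mmol/L\n"
            "P01,2022-01-03T10:05:00,63,mg/dL\n"
            "P02,2022-01-03T10:00:00,5.5,mmol/L\n"
        )
        df = read_cgm_csv(path)
        assert len(df) == 3
        assert df.loc[df["value"].idxmin(), "value"] == pytest.approx(63 / 18.016)

    def test_unparseable_timestamp_reports_rows(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "patient_id,timestamp,glucose,unit\nP01,not-a-time,4.5,mmol/L\n"
        )
        with pytest.raises(IngestError, match="timestamp"):
            read_smbg_csv(path)

    def test_device_dialect_drops_event_rows(self, tmp_path):
        path = tmp_path / "dex.csv"
        path.write_text(
            "Patient ID,Timestamp,Event Type,Glucose Value (mg/dL)\n"
            "P01,2022-01-03T10:00:00,EGV,90\n"
            "P01,2022-01-03T10:05:00,Calibration,100\n"
            "P01,2022-01-03T10:10:00,EGV,81\n"
        )
        df = read_cgm_csv(path, dialect="dexcom")
        assert len(df) == 2
        assert df["value"].iloc[0] == pytest.approx(90 / 18.016)
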