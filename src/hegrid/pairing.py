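"""Temporal pairing of CGM and SMBG reading streams.

Readings are carried as pandas DataFrames with columns ``patient_id``,
``timestamp`` (datetime64, naive local time, second resolution), ``value``
(mmol/L) and ``source`` ("SMBG" or "CGM").

Two procedures are implemented:

* point pairing — each SMBG is matched to the same patient's closest-in-time
  CGM reading within a +/-5 minute window (ties broken toward the earlier,
  pre-SMBG reading, which is the value that likely triggered the fingerprick);
* windowed hypoglycaemia detection — an SMBG-confirmed hypoglycaemia counts
  as detected if any same-patient CGM value within +/-15 minutes is also
  below threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

READING_COLUMNS = ["patient_id", "timestamp", "value", "source"]
PAIR_COLUMNS = [
    "patient_id", "t_smbg", "t_cgm", "delta_t_s", "smbg_mmol", "cgm_mmol", "diff", "ard",
]


class IngestError(ValueError):
    """Raised for invalid or conflicting reading streams."""


def validate_readings(df: pd.DataFrame, source: str | None = None) -> pd.DataFrame:
    """Validate, de-duplicate and sort a reading table.

    Exact duplicate rows (same patient, timestamp and value) are dropped with
    a log message; duplicate timestamps with conflicting values raise.
    """
    missing = [c for c in ("patient_id", "timestamp", "value") if c not in df.columns]
    if missing:
        raise IngestError(f"reading table missing columns {missing}")
    out = df.copy()
    if source is not None and "source" not in out.columns:
        out["source"] = source
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.floor("s")
    if getattr(out["timestamp"].dt, "tz", None) is not None:
        raise IngestError("timestamps must be naive local time, not timezone-aware")
    out["value"] = out["value"].astype(float)
    if not np.isfinite(out["value"]).all() or (out["value"] <= 0).any():
        raise IngestError("glucose values must be positive and finite")
    n0 = len(out)
    out = out.drop_duplicates(subset=["patient_id", "timestamp", "value"])
    if len(out) < n0:
        logger.info("dropped %d exact duplicate reading(s)", n0 - len(out))
    conflict = out.duplicated(subset=["patient_id", "timestamp"], keep=False)
    if conflict.any():
        rows = out.loc[conflict].head(5)
        raise IngestError(
            f"conflicting values at identical timestamps:\n{rows.to_string(index=False)}"
        )
    return out.sort_values(["patient_id", "timestamp"]).reset_index(drop=True)


@dataclass
class PairedSet:
    """SMBG readings matched to their closest CGM readings.

    ``pairs`` columns: patient_id, t_smbg, t_cgm, delta_t_s (signed, CGM
    minus SMBG time), smbg_mmol, cgm_mmol, diff (cgm - smbg, mmol/L), ard
    (percent, |diff| / smbg x 100).
    """

    pairs: pd.DataFrame
    n_smbg: int = 0
    n_cgm: int = 0
    n_unpaired: int = 0

    def __len__(self):
        return len(self.pairs)


def pair_readings(smbg: pd.DataFrame, cgm: pd.DataFrame, window_s: int = 300) -> PairedSet:
    """Pair each SMBG with the closest same-patient CGM within the window.

    The window is closed (|dt| <= window_s, "within five minutes"); at an
    exact before/after tie the earlier CGM reading wins. A CGM reading may
    serve several SMBG values; SMBG readings with no candidate are counted
    as unpaired.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    smbg = validate_readings(smbg, source="SMBG")
    cgm = validate_readings(cgm, source="CGM")
    rows = []
    n_unpaired = 0
    for pid, sm in smbg.groupby("patient_id", sort=True):
        cg = cgm[cgm["patient_id"] == pid]
        if cg.empty:
            n_unpaired += len(sm)
            continue
        ct = cg["timestamp"].to_numpy(dtype="datetime64[s]").astype("int64")
        cv = cg["value"].to_numpy()
        st = sm["timestamp"].to_numpy(dtype="datetime64[s]").astype("int64")
        sv = sm["value"].to_numpy()
        idx = np.searchsorted(ct, st, side="right")
        before = np.clip(idx - 1, 0, len(ct) - 1)
        after = np.clip(idx, 0, len(ct) - 1)
        dt_before = st - ct[before]          # >= 0 where valid
        dt_after = ct[after] - st            # > 0 where valid
        has_before = idx > 0
        has_after = idx < len(ct)
        dt_before = np.where(has_before, dt_before, np.iinfo("int64").max)
        dt_after = np.where(has_after, dt_after, np.iinfo("int64").max)
        take_before = dt_before <= dt_after  # tie -> earlier (pre-SMBG) reading
        chosen = np.where(take_before, before, after)
        abs_dt = np.where(take_before, dt_before, dt_after)
        ok = abs_dt <= window_s
        n_unpaired += int((~ok).sum())
        signed_dt = ct[chosen] - st
        for k in np.nonzero(ok)[0]:
            rows.append(
                (
                    pid,
                    pd.Timestamp(st[k], unit="s"),
                    pd.Timestamp(ct[chosen[k]], unit="s"),
                    int(signed_dt[k]),
                    float(sv[k]),
                    float(cv[chosen[k]]),
                    float(cv[chosen[k]] - sv[k]),
                    float(abs(cv[chosen[k]] - sv[k]) / sv[k] * 100.0),
                )
            )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return PairedSet(pairs=pairs, n_smbg=len(smbg), n_cgm=len(cgm), n_unpaired=n_unpaired)


@dataclass
class DetectionResult:
    """Windowed hypoglycaemia detection outcome.

    ``rate_percent`` is detected / assessable events as a percentage rounded
    to the nearest integer, or None when no event has CGM coverage.
    """

    threshold: float
    events: int
    detected: int
    no_coverage: int
    rate: float | None = field(default=None)

    @property
    def assessable(self) -> int:
        return self.events - self.no_coverage

    @property
    def rate_percent(self) -> int | None:
        if self.rate is None:
            return None
        return int(np.floor(self.rate * 100.0 + 0.5))


def detection_rate(
    smbg: pd.DataFrame,
    cgm: pd.DataFrame,
    threshold: float = 3.5,
    half_window_s: int = 900,
) -> DetectionResult:
    """Hypoglycaemia detection over a diffuse window.

    Events are SMBG readings strictly below ``threshold``. An event is
    detected iff any same-patient CGM value within +/-``half_window_s``
    (default 15 minutes, a 30-minute window) is also strictly below the
    threshold. Events with no CGM reading in the window cannot be assessed
    and are excluded from both numerator and denominator.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    smbg = validate_readings(smbg, source="SMBG")
    cgm = validate_readings(cgm, source="CGM")
    events = detected = no_coverage = 0
    for pid, sm in smbg.groupby("patient_id", sort=True):
        hypo = sm[sm["value"] < threshold]
        if hypo.empty:
            continue
        cg = cgm[cgm["patient_id"] == pid]
        ct = cg["timestamp"].to_numpy(dtype="datetime64[s]").astype("int64")
        cv = cg["value"].to_numpy()
        for t in hypo["timestamp"].to_numpy(dtype="datetime64[s]").astype("int64"):
            events += 1
            lo = np.searchsorted(ct, t - half_window_s, side="left")
            hi = np.searchsorted(ct, t + half_window_s, side="right")
            if hi <= lo:
                no_coverage += 1
            elif (cv[lo:hi] < threshold).any():
                detected += 1
    assessable = events - no_coverage
    rate = (detected / assessable) if assessable > 0 else None
    return DetectionResult(
        threshold=threshold,
        events=events,
        detected=detected,
        no_coverage=no_coverage,
        rate=rate,
    )
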