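"""Accuracy statistics for paired CGM/SMBG datasets.

Conventions, matching clinical reporting practice:

* all differences are CGM minus SMBG; the SMBG fingerprick is the reference;
* MARD uses the SMBG value as denominator;
* every threshold comparison is strict — hypoglycaemia is ``value < 3.5``,
  a CGM stratum is ``cgm > cutoff`` — with equality on the non-event side;
* percentages are reported to 1 decimal place, glucose to 2, at the
  reporting layer only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RiskGrid, false_negative_mask
from .pairing import PairedSet


def _pairs_frame(pairs) -> pd.DataFrame:
    df = pairs.pairs if isinstance(pairs, PairedSet) else pairs
    if len(df) == 0:
        raise ValueError("empty paired set")
    return df


@dataclass
class AccuracySummary:
    n_pairs: int
    mean_diff: float      # mmol/L, mean of (cgm - smbg)
    mad: float            # mmol/L, mean |cgm - smbg|
    mard: float           # percent, mean of |cgm - smbg| / smbg * 100
    mean_abs_dt_min: float

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean_diff_mmol": round(self.mean_diff, 2),
            "mad_mmol": round(self.mad, 2),
            "mard_percent": round(self.mard, 1),
            "mean_abs_dt_min": round(self.mean_abs_dt_min, 1),
        }


def accuracy_summary(pairs) -> AccuracySummary:
    """Bias, MAD, MARD and mean absolute pairing time difference."""
    df = _pairs_frame(pairs)
    if (df["smbg_mmol"] <= 0).any():
        raise ValueError("SMBG values must be positive (ARD undefined at zero)")
    diff = df["cgm_mmol"].to_numpy() - df["smbg_mmol"].to_numpy()
    return AccuracySummary(
        n_pairs=len(df),
        mean_diff=float(diff.mean()),
        mad=float(np.abs(diff).mean()),
        mard=float((np.abs(diff) / df["smbg_mmol"].to_numpy() * 100.0).mean()),
        mean_abs_dt_min=float(np.abs(df["delta_t_s"].to_numpy()).mean() / 60.0),
    )


@dataclass
class ContingencyTable:
    """2x2 threshold classification; positive = SMBG < threshold,
    predicted positive = CGM < threshold (both strict)."""

    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    def as_dict(self) -> dict:
        sens, spec = self.sensitivity, self.specificity
        return {
            "threshold_mmol": self.threshold,
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "sensitivity_percent": None if sens is None else round(sens * 100.0, 1),
            "specificity_percent": None if spec is None else round(spec * 100.0, 1),
        }


def contingency(pairs, threshold: float) -> ContingencyTable:
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    df = _pairs_frame(pairs)
    s = df["smbg_mmol"].to_numpy() < threshold
    c = df["cgm_mmol"].to_numpy() < threshold
    return ContingencyTable(
        threshold=threshold,
        tp=int((s & c).sum()),
        fn=int((s & ~c).sum()),
        fp=int((~s & c).sum()),
        tn=int((~s & ~c).sum()),
    )


def sens_spec(table: ContingencyTable) -> tuple[float | None, float | None]:
    return table.sensitivity, table.specificity


def hypo_odds_table(
    pairs,
    cutoffs=(6.0, 5.0, 4.0, 3.5),
    hypo_thresholds=(3.5, 3.0),
) -> pd.DataFrame:
    """Incidence and odds of true (SMBG) hypoglycaemia within CGM strata.

    A stratum is the pairs whose CGM reads strictly above the cutoff. Both
    the incidence (hypo / stratum size) and the odds (hypo / non-hypo) are
    reported — published tables label such figures "OR" while quoting
    incidences, so neither is asserted as the canonical one.
    """
    df = _pairs_frame(pairs)
    cgm = df["cgm_mmol"].to_numpy()
    smbg = df["smbg_mmol"].to_numpy()
    rows = []
    for cutoff in cutoffs:
        stratum = cgm > cutoff
        n = int(stratum.sum())
        for thr in hypo_thresholds:
            if n == 0:
                rows.append((cutoff, thr, 0, None, None, None))
                continue
            k = int((smbg[stratum] < thr).sum())
            inc = k / n
            odds = k / (n - k) if n > k else np.inf
            rows.append((cutoff, thr, n, k, inc, odds))
    return pd.DataFrame(
        rows,
        columns=["cgm_cutoff", "hypo_threshold", "n_stratum", "n_true_hypo",
                 "incidence", "odds"],
    )


@dataclass
class ZoneSummary:
    """Percentage of pairs per risk zone for one grid."""

    grid_name: str
    n_pairs: int
    percent: dict          # zone label -> percent of pairs
    a_false_negative: float  # percent of pairs that are zone A and FN
    hypo_threshold: float

    @property
    def c_plus(self) -> float:
        return sum(self.percent.get(z, 0.0) for z in ("C", "D", "E"))

    def as_dict(self) -> dict:
        out = {"grid": self.grid_name, "n_pairs": self.n_pairs}
        for label in ("A", "B", "C", "D", "E"):
            if label in self.percent:
                out[label] = round(self.percent[label], 1)
        out["A_false_negative"] = round(self.a_false_negative, 1)
        out["C_plus"] = round(self.c_plus, 1)
        out["hypo_threshold_mmol"] = self.hypo_threshold
        return out


def zone_summary(pairs, grid: RiskGrid, hypo_threshold: float = 3.5) -> ZoneSummary:
    """Classify every pair against ``grid`` and tabulate zone percentages.

    ``a_false_negative`` is the share of pairs that land in zone A while
    being a false negative at ``hypo_threshold`` — the clinically dangerous
    no-risk misclassification legacy grids allow.
    """
    df = _pairs_frame(pairs)
    smbg = df["smbg_mmol"].to_numpy()
    cgm = df["cgm_mmol"].to_numpy()
    zones = grid.classify_points(smbg, cgm)
    labels = np.array([z.name for z in zones])
    n = len(df)
    percent = {}
    for z in grid.zone_labels():
        percent[z.name] = float((labels == z.name).sum()) / n * 100.0
    fn = false_negative_mask(smbg, cgm, hypo_threshold)
    a_fn = float(((labels == "A") & fn).sum()) / n * 100.0
    return ZoneSummary(
        grid_name=grid.name,
        n_pairs=n,
        percent=percent,
        a_false_negative=a_fn,
        hypo_threshold=hypo_threshold,
    )


def practical_subset(pairs, action_threshold: float = 4.0) -> PairedSet:
    """Pairs where at least one value is strictly below the action threshold.

    Keeps false negatives, false positives and true positives at the action
    cutoff (default 4.0 mmol/L, the level below which hyperinsulinism
    patients act); discards the both-normal true negatives that inflate
    headline accuracy without practical relevance.
    """
    if action_threshold <= 0:
        raise ValueError("action_threshold must be positive")
    df = _pairs_frame(pairs)
    keep = (df["smbg_mmol"] < action_threshold) | (df["cgm_mmol"] < action_threshold)
    src = pairs if isinstance(pairs, PairedSet) else PairedSet(pairs=df)
    return PairedSet(
        pairs=df[keep].reset_index(drop=True),
        n_smbg=src.n_smbg,
        n_cgm=src.n_cgm,
        n_unpaired=src.n_unpaired,
    )


@dataclass
class ArdTrend:
    points: pd.DataFrame          # columns: smbg_mmol, ard
    linear: tuple                 # (slope, intercept)
    quadratic: tuple              # (a2, a1, a0)
    n_excluded: int = 0
    exclusion_ceiling: float | None = None


def ard_by_glucose(pairs, exclusion_ceiling: float | None = None) -> ArdTrend:
    """Per-pair (SMBG, ARD) points with degree-1 and degree-2 trend fits.

    ARD typically traces a U shape with its minimum in the normal glucose
    range; ``exclusion_ceiling`` drops hyperglycaemic outliers above the
    given SMBG (e.g. 14 mmol/L) before fitting.
    """
    df = _pairs_frame(pairs)
    pts = df[["smbg_mmol", "ard"]].copy()
    n0 = len(pts)
    if exclusion_ceiling is not None:
        pts = pts[pts["smbg_mmol"] <= exclusion_ceiling]
    n_excluded = n0 - len(pts)
    if len(pts) < 3:
        raise ValueError("need at least 3 pairs for trend fits")
    x = pts["smbg_mmol"].to_numpy()
    y = pts["ard"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all pairs share one glucose value")
    lin = np.polyfit(x, y, 1)
    quad = np.polyfit(x, y, 2)
    return ArdTrend(
        points=pts.reset_index(drop=True),
        linear=(float(lin[0]), float(lin[1])),
        quadratic=(float(quad[0]), float(quad[1]), float(quad[2])),
        n_excluded=n_excluded,
        exclusion_ceiling=exclusion_ceiling,
    )


def hypo_prevalence(pairs, threshold: float = 3.5) -> float:
    """Fraction of paired SMBG values strictly below the threshold."""
    df = _pairs_frame(pairs)
    return float((df["smbg_mmol"] < threshold).mean())
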