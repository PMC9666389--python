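"""End-to-end accuracy report: pair, measure, classify, plot.

The analysis path is deterministic given its inputs; all randomness lives in
the simulator. Exclusions (unpaired SMBG, events without CGM coverage,
clamped values) are counted and carried in the report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .grid import ClampWarning, load_grid
from .metrics import (
    accuracy_summary,
    contingency,
    hypo_odds_table,
    hypo_prevalence,
    practical_subset,
    zone_summary,
)
from .pairing import PAIR_COLUMNS, PairedSet, detection_rate, pair_readings
from .plotting import plot_grid
from .readers import read_cgm_csv, read_smbg_csv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full accuracy run.

    Grids may be bundled names ("heg", "clarke", "parkes") or paths to grid
    definition files.
    """

    cgm_path: str
    smbg_path: str
    grids: list = field(default_factory=lambda: ["heg", "clarke", "parkes"])
    hypo_thresholds: list = field(default_factory=lambda: [3.0, 3.5, 3.9])
    primary_hypo_threshold: float = 3.5
    action_threshold: float = 4.0
    pairing_window_s: int = 300
    detection_half_window_s: int = 900
    dialect: str = "generic"
    out_dir: str | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def validate(self) -> None:
        for p in (self.cgm_path, self.smbg_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if any(t <= 0 for t in self.hypo_thresholds) or self.action_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.pairing_window_s <= 0 or self.detection_half_window_s <= 0:
            raise ValueError("windows must be positive")


def pairs_to_csv(paired: PairedSet, path) -> None:
    df = paired.pairs.copy()
    for col in ("t_smbg", "t_cgm"):
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def pairs_from_csv(path) -> PairedSet:
    df = pd.read_csv(path)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs file {path} missing columns {missing}")
    for col in ("t_smbg", "t_cgm"):
        df[col] = pd.to_datetime(df[col])
    return PairedSet(pairs=df, n_smbg=len(df), n_cgm=0, n_unpaired=0)


def _metrics_block(paired: PairedSet, grids, hypo_thresholds, primary_thr) -> dict:
    acc = accuracy_summary(paired)
    block = {
        "accuracy": acc.as_dict(),
        "contingency": [contingency(paired, t).as_dict() for t in hypo_thresholds],
        "zone_summaries": [
            zone_summary(paired, g, hypo_threshold=primary_thr).as_dict() for g in grids
        ],
        "hypo_prevalence_percent": round(hypo_prevalence(paired, primary_thr) * 100.0, 1),
    }
    return block


def run_full_report(config: RunConfig) -> dict:
    """Execute the full pipeline and return the report dictionary.

    Stages: ingest -> pair -> accuracy metrics (full and practical subset)
    -> windowed detection rates -> zone summaries for every requested grid
    -> optional plots.
    """
    config.validate()
    try:
        cgm = read_cgm_csv(config.cgm_path, dialect=config.dialect)
        smbg = read_smbg_csv(config.smbg_path, dialect=config.dialect)
    except Exception as exc:
        raise RuntimeError(f"ingest failed: {exc}") from exc
    if smbg.empty:
        raise RuntimeError(f"ingest failed: no SMBG readings in {config.smbg_path}")
    if cgm.empty:
        raise RuntimeError(f"ingest failed: no CGM readings in {config.cgm_path}")

    paired = pair_readings(smbg, cgm, window_s=config.pairing_window_s)
    if len(paired) == 0:
        raise RuntimeError("pairing produced no pairs within the window")
    grids = [load_grid(g) for g in config.grids]

    n_clamped = 0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ClampWarning)
        full_block = _metrics_block(paired, grids, config.hypo_thresholds,
                                    config.primary_hypo_threshold)
        practical = practical_subset(paired, config.action_threshold)
        practical_block = (
            _metrics_block(practical, grids, config.hypo_thresholds,
                           config.primary_hypo_threshold)
            if len(practical)
            else None
        )
        for w in caught:
            if issubclass(w.category, ClampWarning):
                n_clamped += 1

    detection = {}
    for thr in config.hypo_thresholds:
        det = detection_rate(smbg, cgm, threshold=thr,
                             half_window_s=config.detection_half_window_s)
        detection[f"{thr:g}"] = {
            "events": det.events,
            "detected": det.detected,
            "no_coverage": det.no_coverage,
            "rate_percent": det.rate_percent,
        }

    odds = hypo_odds_table(paired)
    report = {
        "inputs": {"cgm": str(config.cgm_path), "smbg": str(config.smbg_path)},
        "provenance": {
            "n_smbg": paired.n_smbg,
            "n_cgm": paired.n_cgm,
            "n_pairs": len(paired),
            "n_unpaired_smbg": paired.n_unpaired,
            "n_clamp_warnings": n_clamped,
        },
        "full": full_block,
        "practical_subset": {
            "action_threshold_mmol": config.action_threshold,
            "n_pairs": len(practical),
            **(practical_block or {}),
        },
        "detection": detection,
        "hypo_odds": odds.where(pd.notna(odds), None).to_dict(orient="records"),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pairs_to_csv(paired, out / "pairs.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2))
        if config.plots:
            for g in grids:
                plot_grid(paired, g, out / f"grid_{g.name.lower()}.png",
                          hypo_threshold=config.primary_hypo_threshold)
    return report


def format_report_text(report: dict) -> str:
    """Human-readable rendering of the report dictionary."""
    lines = []
    prov = report["provenance"]
    lines.append(
        f"{prov['n_pairs']} paired readings from {prov['n_smbg']} SMBG and "
        f"{prov['n_cgm']} CGM readings ({prov['n_unpaired_smbg']} SMBG unpaired)"
    )
    acc = report["full"]["accuracy"]
    lines.append(
        f"mean difference (CGM-SMBG) {acc['mean_diff_mmol']:+.2f} mmol/L, "
        f"MAD {acc['mad_mmol']:.2f} mmol/L, MARD {acc['mard_percent']:.1f}%, "
        f"mean |dt| {acc['mean_abs_dt_min']:.1f} min"
    )
    for ct in report["full"]["contingency"]:
        lines.append(
            f"threshold {ct['threshold_mmol']:g} mmol/L: sensitivity "
            f"{ct['sensitivity_percent']}%, specificity {ct['specificity_percent']}%"
        )
    for thr, det in report["detection"].items():
        lines.append(
            f"detection (<{thr} mmol/L, 30-min window): {det['detected']}/"
            f"{det['events'] - det['no_coverage']} = {det['rate_percent']}%"
        )
    lines.append("zone percentages (full dataset):")
    for zs in report["full"]["zone_summaries"]:
        zones = ", ".join(
            f"{k} {zs[k]:.1f}" for k in ("A", "B", "C", "D", "E") if k in zs
        )
        lines.append(
            f"  {zs['grid']}: {zones}; A-false-negative {zs['A_false_negative']:.1f}; "
            f"C+ {zs['C_plus']:.1f}"
        )
    ps = report["practical_subset"]
    if "accuracy" in ps:
        acc = ps["accuracy"]
        lines.append(
            f"practical subset (<{ps['action_threshold_mmol']:g} mmol/L, n={ps['n_pairs']}): "
            f"mean diff {acc['mean_diff_mmol']:+.2f}, MAD {acc['mad_mmol']:.2f}, "
            f"MARD {acc['mard_percent']:.1f}%"
        )
    return "\n".join(lines)
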