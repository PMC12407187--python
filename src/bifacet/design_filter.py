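"""Negative-design filtering over structure-prediction confidence metrics.

A design passes when its on-target C-D interface is confidently predicted
(r.m.s.d. < 2.0 A, mean pAE interaction < 10, pLDDT > 90), neither off-target
homodimer (C-C, D-D) is confidently predicted (r.m.s.d. < 2.0 A, pAE < 10,
pLDDT > 95), and the pAE gap between each off-target and the on-target
exceeds 10.  All comparisons are strict, so boundary values fail.  Metrics
are consumed from tables; structure prediction itself is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

INTERFACE_LABELS = ("CD", "CC", "DD")


@dataclass(frozen=True)
class MetricRecord:
    """Prediction metrics for one design/interface combination."""

    design_id: str
    interface_label: str
    rmsd: float
    pae_interaction: float
    plddt: float

    def __post_init__(self):
        if self.interface_label not in INTERFACE_LABELS:
            raise ValidationError(f"interface_label must be one of {INTERFACE_LABELS}")
        if self.rmsd < 0 or self.pae_interaction < 0 or not 0 <= self.plddt <= 100:
            raise ValidationError(
                f"{self.design_id}/{self.interface_label}: metrics out of range"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Decision thresholds; all comparisons against them are strict."""

    on_rmsd_max: float = 2.0
    on_pae_max: float = 10.0
    on_plddt_min: float = 90.0
    off_rmsd_max: float = 2.0
    off_pae_max: float = 10.0
    off_plddt_min: float = 95.0
    pae_gap_min: float = 10.0

    def __post_init__(self):
        vals = (self.on_rmsd_max, self.on_pae_max, self.on_plddt_min,
                self.off_rmsd_max, self.off_pae_max, self.off_plddt_min,
                self.pae_gap_min)
        if any(v <= 0 for v in vals):
            raise ValidationError("thresholds must be positive")


@dataclass(frozen=True)
class FilterVerdict:
    design_id: str
    passed: bool
    reasons: tuple[str, ...]
    metrics_used: tuple[MetricRecord, MetricRecord, MetricRecord]

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValidationError("passed must hold exactly when reasons is empty")


def _off_target_predicted(rec: MetricRecord, th: FilterThresholds) -> bool:
    return (
        rec.rmsd < th.off_rmsd_max
        and rec.pae_interaction < th.off_pae_max
        and rec.plddt > th.off_plddt_min
    )


def evaluate_design(
    cd: MetricRecord,
    cc: MetricRecord,
    dd: MetricRecord,
    th: FilterThresholds = FilterThresholds(),
    gap_mode: str = "both",
) -> FilterVerdict:
    """Apply the full decision procedure to one design.

    ``gap_mode`` controls the pAE-gap rule: "both" (default) requires the
    gap against each off-target interface; "any" accepts a gap against
    either one.
    """
    if not (cd.design_id == cc.design_id == dd.design_id):
        raise ValidationError("records must share a design_id")
    if (cd.interface_label, cc.interface_label, dd.interface_label) != INTERFACE_LABELS:
        raise ValidationError("records must be labeled CD, CC, DD in that order")
    if gap_mode not in ("both", "any"):
        raise ValidationError(f"unknown gap_mode {gap_mode!r}")

    reasons: list[str] = []
    on_ok = (
        cd.rmsd < th.on_rmsd_max
        and cd.pae_interaction < th.on_pae_max
        and cd.plddt > th.on_plddt_min
    )
    if not on_ok:
        reasons.append("on_target_fail")
    if _off_target_predicted(cc, th):
        reasons.append("off_target_CC_predicted")
    if _off_target_predicted(dd, th):
        reasons.append("off_target_DD_predicted")
    gap_cc = cc.pae_interaction - cd.pae_interaction > th.pae_gap_min
    gap_dd = dd.pae_interaction - cd.pae_interaction > th.pae_gap_min
    gap_ok = (gap_cc and gap_dd) if gap_mode == "both" else (gap_cc or gap_dd)
    if not gap_ok:
        reasons.append("gap_fail")
    return FilterVerdict(
        design_id=cd.design_id,
        passed=not reasons,
        reasons=tuple(reasons),
        metrics_used=(cd, cc, dd),
    )


def _maybe_rescale_plddt(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) and (df["plddt"] <= 1.0).all():
        logger.warning("pLDDT values all <= 1; rescaling to the 0-100 scale")
        df = df.copy()
        df["plddt"] = df["plddt"] * 100.0
    return df


def filter_batch(
    records: pd.DataFrame,
    th: FilterThresholds = FilterThresholds(),
    gap_mode: str = "both",
) -> tuple[pd.DataFrame, dict]:
    """Evaluate a metric table with one CD/CC/DD row triple per design.

    Returns a verdict table ordered by design_id and a summary with the
    total passed and per-reason counts.  Designs with missing, duplicated
    or invalid rows get an error entry instead of aborting the batch.
    """
    required = {"design_id", "interface", "rmsd", "pae_interaction", "plddt"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"metric table missing columns: {sorted(missing)}")
    records = _maybe_rescale_plddt(records)

    rows = []
    reason_counts: dict[str, int] = {}
    n_passed = 0
    for design_id in sorted(records["design_id"].unique()):
        sub = records[records["design_id"] == design_id]
        error = None
        recs = {}
        for label in INTERFACE_LABELS:
            hit = sub[sub["interface"] == label]
            if len(hit) != 1:
                error = f"expected exactly one {label} row, found {len(hit)}"
                break
            r = hit.iloc[0]
            try:
                recs[label] = MetricRecord(
                    design_id=str(design_id), interface_label=label,
                    rmsd=float(r["rmsd"]),
                    pae_interaction=float(r["pae_interaction"]),
                    plddt=float(r["plddt"]),
                )
            except ValidationError as exc:
                error = str(exc)
                break
        if error is not None:
            rows.append({"design_id": design_id, "passed": False,
                         "reasons": "", "error": error})
            continue
        verdict = evaluate_design(recs["CD"], recs["CC"], recs["DD"], th, gap_mode)
        if verdict.passed:
            n_passed += 1
        for reason in verdict.reasons:
            reason_counts[reason] = reason_counts.get(reason, 0) + 1
        rows.append({"design_id": design_id, "passed": verdict.passed,
                     "reasons": ";".join(verdict.reasons), "error": ""})
    verdicts = pd.DataFrame(rows, columns=["design_id", "passed", "reasons", "error"])
    summary = {
        "n_designs": len(rows),
        "n_passed": n_passed,
        "reason_counts": reason_counts,
    }
    return verdicts, summary


@dataclass(frozen=True)
class ExtensionThresholds:
    plddt_min: float = 90.0
    rmsd_max: float = 1.5


def evaluate_extension_design(
    plddt: float, rmsd_to_diffused: float,
    th: ExtensionThresholds = ExtensionThresholds(),
) -> bool:
    """Extension-design filter: pLDDT > 90 and r.m.s.d. to the diffused
    backbone < 1.5 A, both strict."""
    if not (np.isfinite(plddt) and np.isfinite(rmsd_to_diffused)):
        raise ValidationError("metrics must be finite")
    return plddt > th.plddt_min and rmsd_to_diffused < th.rmsd_max


def read_metric_table(path) -> pd.DataFrame:
    """Read a CSV/TSV metric table (separator sniffed from the extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)
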