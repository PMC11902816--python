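"""Aggregation of per-trial results into reporting tables: confusion matrix
with per-class TPR/FNR, and per-motion lead-time summaries with normal
95% confidence intervals and failure annotations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ALL_CLASSES, N_CLASSES, MotionClass
from .windownet import (
    STATUS_CONFIDENT,
    STATUS_CP_INCONCLUSIVE,
    STATUS_NOT_REACHED,
    LeadTimeRecord,
)


@dataclass
class ConfusionReport:
    matrix: np.ndarray  # (12, 12) counts, rows = truth
    per_class_tpr: np.ndarray
    per_class_fnr: np.ndarray
    overall_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        names = [str(c) for c in ALL_CLASSES]
        df = pd.DataFrame(self.matrix, index=names, columns=names)
        df["TPR"] = self.per_class_tpr
        df["FNR"] = self.per_class_fnr
        return df


def confusion_report(pairs: Sequence[Tuple[int, int]]) -> ConfusionReport:
    """Build the confusion report from (true, predicted) class-id pairs."""
    if len(pairs) == 0:
        raise ValueError("no predictions to score")
    matrix = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in pairs:
        matrix[t, p] += 1
    row_sums = matrix.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tpr = np.where(row_sums > 0, np.diag(matrix) / np.maximum(row_sums, 1), np.nan)
    fnr = np.where(row_sums > 0, 1.0 - tpr, np.nan)
    accuracy = float(np.trace(matrix) / matrix.sum())
    return ConfusionReport(matrix, tpr, fnr, accuracy)


@dataclass
class MotionLeadSummary:
    """Per-motion lead-time statistics in seconds, or a failure note when no
    confident record exists for the class."""

    label: MotionClass
    n_confident: int
    mean_lead_s: Optional[float] = None
    sd_lead_s: Optional[float] = None
    ci95_s: Optional[float] = None
    failure_note: Optional[str] = None


def _dominant_failure(records: List[LeadTimeRecord]) -> str:
    statuses = [r.status for r in records]
    if statuses.count(STATUS_CP_INCONCLUSIVE) >= statuses.count(STATUS_NOT_REACHED):
        return STATUS_CP_INCONCLUSIVE
    return STATUS_NOT_REACHED


def summarize_lead_times(records: Sequence[LeadTimeRecord]) -> List[MotionLeadSummary]:
    """One summary per motion class: mean, sd and 1.96*sd/sqrt(n) CI over
    confident records, or the class's dominant failure note."""
    by_class: Dict[int, List[LeadTimeRecord]] = {c.class_id: [] for c in ALL_CLASSES}
    for r in records:
        if r.label is not None:
            by_class[r.label.class_id].append(r)
    summaries = []
    for label in ALL_CLASSES:
        recs = by_class[label.class_id]
        leads = np.array(
            [r.lead_ms for r in recs if r.status == STATUS_CONFIDENT], dtype=float
        )
        if len(leads) == 0:
            note = _dominant_failure(recs) if recs else STATUS_NOT_REACHED
            summaries.append(MotionLeadSummary(label, 0, failure_note=note))
            continue
        mean_s = float(np.mean(leads)) / 1000.0
        sd_s = float(np.std(leads, ddof=1)) / 1000.0 if len(leads) > 1 else 0.0
        ci = 1.96 * sd_s / np.sqrt(len(leads)) if len(leads) >= 2 else None
        summaries.append(MotionLeadSummary(label, len(leads), mean_s, sd_s, ci))
    return summaries


def lead_summary_frame(summaries: Sequence[MotionLeadSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "label": str(s.label),
                "n_confident": s.n_confident,
                "mean_lead_s": s.mean_lead_s,
                "sd_s": s.sd_lead_s,
                "ci95_s": s.ci95_s,
                "failure_note": s.failure_note or "",
            }
        )
    return pd.DataFrame(rows)


def global_lead_stats(
    records: Sequence[LeadTimeRecord],
) -> Tuple[Optional[float], Optional[float], int]:
    """Pooled (mean_ms, sd_ms, n_confident) over confident records across
    all classes; (None, None, 0) when no record is confident."""
    leads = np.array(
        [r.lead_ms for r in records if r.status == STATUS_CONFIDENT], dtype=float
    )
    if len(leads) == 0:
        return None, None, 0
    sd = float(np.std(leads, ddof=1)) if len(leads) > 1 else 0.0
    return float(np.mean(leads)), sd, int(len(leads))
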