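"""End-to-end per-subject classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .excitability import (
    AbExResult,
    SizeIndices,
    classify_abex,
    compute_indices,
    supporting_asymmetries,
)
from .latency import AbLatResult, LatencyFindings, classify_latency
from .normative import NormativeLimits, default_limits
from .records import SIDES, SubjectRecord
from .recovery import brer_abnormal, brip_abnormal


@dataclass
class Classification:
    subject_id: str
    ablat: AbLatResult
    findings: LatencyFindings
    abex: AbExResult
    indices: SizeIndices
    support: dict[str, bool] = field(default_factory=dict)
    brer_abnormal: dict[str, bool] = field(default_factory=dict)
    brip_abnormal: dict[str, bool] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "is_ablat": self.ablat.is_ablat,
            "pattern": self.ablat.pattern,
            "side": self.ablat.side,
            "sbr_status": self.ablat.sbr_status,
            "is_abex": self.abex.is_abex,
            "enhanced_side": self.abex.enhanced_side,
            "evidence_ratio": self.abex.evidence.get("ratio", "none"),
            "evidence_area": self.abex.evidence.get("r2_area", "none"),
        }
        for measure in ("r1", "sbr", "brer", "brip"):
            row[f"evidence_{measure}"] = bool(self.support.get(measure, False))
        for s in SIDES:
            row[f"brer_abnormal_{s}"] = bool(self.brer_abnormal.get(s, False))
            row[f"brip_abnormal_{s}"] = bool(self.brip_abnormal.get(s, False))
        return row


def classify_subject(
    record: SubjectRecord, limits: NormativeLimits | None = None
) -> Classification:
    """Run the full latency + excitability classification for one subject."""
    limits = limits or default_limits()
    findings, ablat = classify_latency(record, limits)
    indices = compute_indices(record)
    abex = classify_abex(indices, limits)
    support = supporting_asymmetries(indices, limits, abex.enhanced_side)
    brer_flags = {
        s: brer_abnormal(
            curve,
            limits.brer_recovery_limit_pct,
            limits.brer_interval_limit_ms,
        )
        for s, curve in record.brer.items()
    }
    brip_flags = {
        s: brip_abnormal(b, limits.brip_lower_pct)
        for s, b in record.brip.items()
    }
    return Classification(
        subject_id=record.subject_id,
        ablat=ablat,
        findings=findings,
        abex=abex,
        indices=indices,
        support=support,
        brer_abnormal=brer_flags,
        brip_abnormal=brip_flags,
    )


def classify_cohort(
    records: list[SubjectRecord], limits: NormativeLimits | None = None
) -> pd.DataFrame:
    """Classification table (one row per subject)."""
    limits = limits or default_limits()
    return pd.DataFrame(
        [classify_subject(r, limits).to_row() for r in records]
    )
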