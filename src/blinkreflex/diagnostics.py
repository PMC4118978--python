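"""Diagnostic evaluation against the MRI gold standard.

The gold standard for conduction-type (latency) abnormalities is a
ponto-medullary lesion on brainstem MRI — a hyperintensity in the pons or
medulla, the region that houses the trigemino-facial reflex circuit.
Midbrain-only lesions count as negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps


@dataclass
class Contingency2x2:
    """Counts [[a, b], [c, d]]: rows = prediction +/−, cols = gold +/−."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def sensitivity_specificity(
    predictions: Mapping[str, bool], gold: Mapping[str, bool]
) -> dict:
    """Sensitivity/specificity (%) of binary predictions vs gold flags.

    Every subject must appear in both mappings.  When the gold standard has
    no positives (or no negatives) the corresponding rate is None.
    """
    missing = set(predictions) ^ set(gold)
    if missing:
        raise ValueError(f"subjects without both prediction and gold: {missing}")
    tp = sum(1 for k in gold if gold[k] and predictions[k])
    fn = sum(1 for k in gold if gold[k] and not predictions[k])
    fp = sum(1 for k in gold if not gold[k] and predictions[k])
    tn = sum(1 for k in gold if not gold[k] and not predictions[k])
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    return {
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "counts": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    }


def chi_square_2x2(table: Contingency2x2, yates: bool = False) -> dict:
    """Pearson chi-square (1 df) of a 2×2 table; uncorrected by default."""
    t = table.table
    margins = (t[0][0] + t[0][1], t[1][0] + t[1][1],
               t[0][0] + t[1][0], t[0][1] + t[1][1])
    if 0 in margins:
        return {"statistic": None, "p_value": None}
    stat, p, _, _ = sps.chi2_contingency(t, correction=yates)
    return {"statistic": float(stat), "p_value": float(p)}


def cohort_report(
    classification: pd.DataFrame,
    gold: pd.DataFrame | None = None,
) -> dict:
    """Per-subject table plus group summaries and diagnostic metrics.

    ``classification`` needs columns subject_id, is_ablat, pattern, side,
    sbr_status, is_abex, enhanced_side; ``gold`` needs subject_id plus the
    midbrain/pons/medulla boolean flags.  Returns a dict with the merged
    per-subject table, counts, and — when a gold standard is supplied —
    AbLat vs ponto-medullary sensitivity/specificity and the chi-square
    association.
    """
    df = classification.copy()
    report: dict = {"n_subjects": int(len(df))}
    if len(df) == 0:
        report["table"] = df
        report["markdown"] = _to_markdown(df)
        return report
    report["n_ablat"] = int(df["is_ablat"].sum())
    report["n_abex"] = int(df["is_abex"].sum())
    report["patterns"] = (
        df.loc[df["pattern"] != "none", "pattern"].value_counts().to_dict()
    )
    if gold is not None and len(gold):
        g = gold.copy()
        g["pontomedullary"] = g["pons"].astype(bool) | g["medulla"].astype(bool)
        df = df.merge(g, on="subject_id", how="left", validate="1:1")
        preds = dict(zip(df["subject_id"], df["is_ablat"].astype(bool)))
        truth = dict(zip(df["subject_id"], df["pontomedullary"].astype(bool)))
        metrics = sensitivity_specificity(preds, truth)
        c = metrics["counts"]
        table = Contingency2x2(c["tp"], c["fp"], c["fn"], c["tn"])
        metrics["chi_square"] = chi_square_2x2(table)
        report["ablat_vs_pontomedullary"] = metrics
    report["table"] = df
    report["markdown"] = _to_markdown(df)
    return report


def _to_markdown(df: pd.DataFrame) -> str:
    cols = [
        c
        for c in (
            "subject_id", "midbrain", "pons", "medulla",
            "is_ablat", "pattern", "side", "sbr_status",
            "is_abex", "enhanced_side",
        )
        if c in df.columns
    ]
    sub = df[cols] if cols else df
    header = "| " + " | ".join(sub.columns) + " |"
    sep = "|" + "|".join("---" for _ in sub.columns) + "|"
    rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in sub.values]
    return "\n".join([header, sep, *rows])


def load_reference_cohort() -> pd.DataFrame:
    """Reference 20-patient clinical cohort shipped with the package.

    Per-patient brainstem MRI lesion-site flags and blink-reflex latency
    classification (AbLat flag, Aramideh pattern and side, SBR status).
    """
    from importlib import resources

    with resources.files("blinkreflex.data").joinpath(
        "reference_cohort.csv"
    ).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    for col in ("midbrain", "pons", "medulla", "ablat"):
        df[col] = df[col].astype(bool)
    return df
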