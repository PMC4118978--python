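"""CSV/JSON readers and writers for the pipeline's tabular interfaces.

CSV dialect: UTF-8, comma-separated, mandatory header row, missing values
as empty fields.  Sides are encoded as the strings "right"/"left".
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, GroundTruth, RenderedTrial
from .records import (
    BrerCurve,
    BripMeasure,
    ResponseMeasure,
    SubjectMeta,
    SubjectRecord,
    build_subject,
)

MEASURE_COLUMNS = [
    "subject_id", "component", "stim_side", "rec_side", "trial",
    "latency_ms", "amplitude_uV", "area_uVms", "present",
]


# -- measures table --------------------------------------------------------

def measures_frame(
    trials: Mapping[str, Iterable[ResponseMeasure]]
) -> pd.DataFrame:
    rows = []
    for sid, ms in trials.items():
        for m in ms:
            rows.append(
                {
                    "subject_id": sid,
                    "component": m.component,
                    "stim_side": m.stim_side,
                    "rec_side": m.rec_side,
                    "trial": m.trial,
                    "latency_ms": m.latency_ms,
                    "amplitude_uV": m.amplitude_uV,
                    "area_uVms": m.area_uVms,
                    "present": m.present,
                }
            )
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)


def write_measures(path, trials: Mapping[str, Iterable[ResponseMeasure]]) -> None:
    measures_frame(trials).to_csv(path, index=False)


def read_measures(path) -> dict[str, list[ResponseMeasure]]:
    df = pd.read_csv(path)
    missing = set(MEASURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measures table lacks columns: {sorted(missing)}")
    out: dict[str, list[ResponseMeasure]] = {}
    for row in df.itertuples(index=False):
        present = bool(row.present)
        out.setdefault(str(row.subject_id), []).append(
            ResponseMeasure(
                component=row.component,
                stim_side=row.stim_side,
                rec_side=row.rec_side,
                latency_ms=(
                    None
                    if not present or pd.isna(row.latency_ms)
                    else float(row.latency_ms)
                ),
                area_uVms=float(row.area_uVms) if present else 0.0,
                amplitude_uV=(
                    None if pd.isna(row.amplitude_uV) else float(row.amplitude_uV)
                ),
                present=present,
                trial=None if pd.isna(row.trial) else int(row.trial),
            )
        )
    return out


# -- BRER / BRIP tables ----------------------------------------------------

def write_brer(path, records: Iterable[SubjectRecord]) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "side": side,
            "interval_ms": t,
            "recovery_pct": pct,
        }
        for r in records
        for side, curve in sorted(r.brer.items())
        for t, pct in sorted(curve.recovery_pct.items())
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "side", "interval_ms", "recovery_pct"]
    ).to_csv(path, index=False)


def read_brer(path) -> dict[str, dict[str, BrerCurve]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, BrerCurve]] = {}
    for (sid, side), grp in df.groupby(["subject_id", "side"], sort=True):
        out.setdefault(str(sid), {})[side] = BrerCurve(
            side,
            {
                int(t): float(p)
                for t, p in zip(grp["interval_ms"], grp["recovery_pct"])
            },
        )
    return out


def write_brip(path, records: Iterable[SubjectRecord]) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "side": side,
            "pct_of_control": b.pct_of_control,
        }
        for r in records
        for side, b in sorted(r.brip.items())
    ]
    pd.DataFrame(
        rows, columns=["subject_id", "side", "pct_of_control"]
    ).to_csv(path, index=False)


def read_brip(path) -> dict[str, dict[str, BripMeasure]]:
    df = pd.read_csv(path)
    out: dict[str, dict[str, BripMeasure]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject_id), {})[row.side] = BripMeasure(
            row.side, float(row.pct_of_control)
        )
    return out


# -- gold standard / ground truth ------------------------------------------

def write_gold(path, records: Iterable[SubjectRecord]) -> None:
    rows = []
    for r in records:
        meta = r.meta or SubjectMeta()
        rows.append(
            {
                "subject_id": r.subject_id,
                "midbrain": meta.midbrain,
                "pons": meta.pons,
                "medulla": meta.medulla,
                "edss": meta.edss,
                "brainstem_fs": meta.brainstem_fs,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gold(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("midbrain", "pons", "medulla"):
        if col not in df.columns:
            raise ValueError(f"gold-standard table lacks column: {col}")
        df[col] = df[col].astype(bool)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_ground_truth(path, truth: Mapping[str, GroundTruth]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({k: v.to_dict() for k, v in sorted(truth.items())}, fh, indent=2)


def read_ground_truth(path) -> dict[str, GroundTruth]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {k: GroundTruth(**v) for k, v in raw.items()}


# -- assembled subjects ----------------------------------------------------

def assemble_subjects(
    trials: Mapping[str, list[ResponseMeasure]],
    brer: Mapping[str, Mapping[str, BrerCurve]] | None = None,
    brip: Mapping[str, Mapping[str, BripMeasure]] | None = None,
    gold: pd.DataFrame | None = None,
) -> list[SubjectRecord]:
    meta_by_id: dict[str, SubjectMeta] = {}
    if gold is not None:
        for row in gold.itertuples(index=False):
            meta_by_id[str(row.subject_id)] = SubjectMeta(
                midbrain=bool(row.midbrain),
                pons=bool(row.pons),
                medulla=bool(row.medulla),
                edss=None if pd.isna(getattr(row, "edss", np.nan)) else float(row.edss),
            )
    out = []
    for sid in sorted(trials):
        out.append(
            build_subject(
                sid,
                trials[sid],
                (brer or {}).get(sid, {}),
                (brip or {}).get(sid, {}),
                meta_by_id.get(sid),
            )
        )
    return out


def write_cohort(outdir, cohort: Cohort) -> dict[str, Path]:
    """Write a simulated cohort to a directory of CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measures": outdir / "measures.csv",
        "brer": outdir / "brer.csv",
        "brip": outdir / "brip.csv",
        "gold": outdir / "gold.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_measures(paths["measures"], cohort.trials)
    write_brer(paths["brer"], cohort.subjects)
    write_brip(paths["brip"], cohort.subjects)
    write_gold(paths["gold"], cohort.patients)
    write_ground_truth(paths["ground_truth"], cohort.truth)
    return paths


def read_cohort_dir(indir) -> list[SubjectRecord]:
    indir = Path(indir)
    trials = read_measures(indir / "measures.csv")
    brer = read_brer(indir / "brer.csv") if (indir / "brer.csv").exists() else None
    brip = read_brip(indir / "brip.csv") if (indir / "brip.csv").exists() else None
    gold_path = indir / "gold.csv"
    gold = read_gold(gold_path) if gold_path.exists() else None
    return assemble_subjects(trials, brer, brip, gold)


# -- per-trial waveform files ----------------------------------------------

def write_trial_traces(outdir, subject_id: str, rendered: list[RenderedTrial]) -> None:
    """Per-trial CSV (time_ms, ooc_right_uV, ooc_left_uV) + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, rt in enumerate(rendered, start=1):
        any_trace = next(iter(rt.traces.values()))
        n = any_trace.samples.size
        t_ms = (np.arange(n) - any_trace.t0_index) * any_trace.dt_ms
        df = pd.DataFrame({"time_ms": t_ms})
        for side in ("right", "left"):
            if side in rt.traces:
                df[f"ooc_{side}_uV"] = rt.traces[side].samples
        stem = f"{subject_id}_trial{i:03d}"
        df.to_csv(outdir / f"{stem}.csv", index=False, float_format="%.4f")
        with open(outdir / f"{stem}.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "subject_id": subject_id,
                    "stimulation_site": rt.stimulation_site,
                    "trial": rt.trial,
                    "sampling_rate": any_trace.sampling_rate,
                },
                fh,
            )
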