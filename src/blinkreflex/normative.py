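"""Normative reference limits for blink-reflex measures.

Two kinds of limits coexist:

* fixed latency limits taken from published laboratory normative values
  (R1 12.8 ms, R2 38 ms, R2c 40 ms, SBR 66.7 ms; inter-side differences
  1.5 ms for R1, 5 ms for R2 and 8 ms between R2 and R2c);
* mean ± 2·SD cut-offs computed from a healthy cohort for the response-size
  measures (R2c/R2 ratio, side-averaged R2 area, R1 amplitude, SBR area,
  BRER index, BRIP percentage inhibition), both as absolute per-side values
  and as inter-side absolute differences.

The package ships a healthy-cohort summary (n = 12) from which the default
size cut-offs are derived at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Iterable, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .records import SubjectRecord

#: Size measures for which mean±2SD cut-offs are derived.
SIZE_MEASURES = (
    "r2c_r2_ratio",
    "r2_area",
    "r1_amp",
    "sbr_area",
    "brer_index",
    "brip",
)

FIXED_LATENCY_UPPER = {"R1": 12.8, "R2": 38.0, "R2c": 40.0, "SBR": 66.7}
FIXED_INTERSIDE_LATENCY_UPPER = {"R1": 1.5, "R2": 5.0, "R2_vs_R2c": 8.0}


def upper_cutoff(mean: float, sd: float) -> float:
    """Upper normative cut-off: mean + 2·SD."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return mean + 2.0 * sd


def lower_cutoff(mean: float, sd: float) -> float:
    """Lower normative cut-off: mean − 2·SD (not clamped)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return mean - 2.0 * sd


@dataclass
class MeasureStats:
    """Healthy-cohort summary of one size measure.

    ``mean``/``sd`` describe per-subject values (mean of the two sides);
    ``delta_mean``/``delta_sd`` describe the per-subject absolute
    inter-side differences |right − left|.
    """

    mean: float
    sd: float
    delta_mean: float
    delta_sd: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.delta_sd < 0:
            raise ValueError("sd must be non-negative")
        if self.delta_mean < 0:
            raise ValueError("delta_mean must be non-negative")


@dataclass
class HealthyCohortSummary:
    n: int
    measures: dict[str, MeasureStats]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 healthy subjects")


@dataclass
class NormativeLimits:
    """All cut-offs used by the classification stages."""

    latency_upper: dict[str, float] = field(
        default_factory=lambda: dict(FIXED_LATENCY_UPPER)
    )
    interside_latency_upper: dict[str, float] = field(
        default_factory=lambda: dict(FIXED_INTERSIDE_LATENCY_UPPER)
    )
    size_upper: dict[str, float] = field(default_factory=dict)
    interside_upper: dict[str, float] = field(default_factory=dict)
    brip_lower_pct: float = float("nan")
    brer_recovery_limit_pct: float = 30.0
    brer_interval_limit_ms: float = 300.0

    def __post_init__(self) -> None:
        for v in self.interside_upper.values():
            if v < 0:
                raise ValueError("inter-side cut-offs must be non-negative")

    # -- serialisation -----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NormativeLimits":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_summary(
        cls,
        summary: HealthyCohortSummary,
        derive_latency: bool = False,
        latency_stats: dict[str, MeasureStats] | None = None,
    ) -> "NormativeLimits":
        """Apply the mean±2SD rule to a healthy-cohort summary.

        Fixed latency limits are carried unchanged unless ``derive_latency``
        is set and latency statistics are supplied.
        """
        size_upper = {}
        interside_upper = {}
        for name, st in summary.measures.items():
            size_upper[name] = upper_cutoff(st.mean, st.sd)
            interside_upper[name] = upper_cutoff(st.delta_mean, st.delta_sd)
        brip_lower = float("nan")
        if "brip" in summary.measures:
            st = summary.measures["brip"]
            brip_lower = lower_cutoff(st.mean, st.sd)
        limits = cls(
            size_upper=size_upper,
            interside_upper=interside_upper,
            brip_lower_pct=brip_lower,
        )
        if derive_latency and latency_stats:
            for comp, st in latency_stats.items():
                limits.latency_upper[comp] = upper_cutoff(st.mean, st.sd)
        return limits


def _two_pass_mean_sd(values: Iterable[float]) -> tuple[float, float]:
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        return float(x.mean()) if x.size else float("nan"), 0.0
    return float(x.mean()), float(x.std(ddof=1))


def summarize_healthy(records: "Iterable[SubjectRecord]") -> HealthyCohortSummary:
    """Per-measure mean/SD summary of a healthy cohort.

    For each subject, the per-side values of every size measure are
    reduced to the two-side mean and the absolute inter-side difference;
    subjects missing a measure on either side are skipped for that measure
    (reported through the returned counts being smaller).  Sample SD
    (n−1 denominator) is used throughout.
    """
    from .excitability import size_profile  # deferred: avoids import cycle

    per_measure_mean: dict[str, list[float]] = {m: [] for m in SIZE_MEASURES}
    per_measure_delta: dict[str, list[float]] = {m: [] for m in SIZE_MEASURES}
    n = 0
    for record in records:
        n += 1
        profile = size_profile(record)
        for name in SIZE_MEASURES:
            sides = profile.get(name, {})
            right, left = sides.get("right"), sides.get("left")
            if right is None or left is None:
                continue
            per_measure_mean[name].append((right + left) / 2.0)
            per_measure_delta[name].append(abs(right - left))
    measures = {}
    for name in SIZE_MEASURES:
        if not per_measure_mean[name]:
            continue  # absent in every subject: dropped
        mean, sd = _two_pass_mean_sd(per_measure_mean[name])
        dmean, dsd = _two_pass_mean_sd(per_measure_delta[name])
        measures[name] = MeasureStats(mean, sd, dmean, dsd)
    return HealthyCohortSummary(n=n, measures=measures)


def derive_limits(records: "Iterable[SubjectRecord]") -> NormativeLimits:
    """Derive normative limits from a healthy cohort of SubjectRecords."""
    return NormativeLimits.from_summary(summarize_healthy(list(records)))


# -- packaged reference summary -------------------------------------------

def load_reference_summary() -> HealthyCohortSummary:
    """Healthy-cohort (n=12) reference summary shipped with the package."""
    text = resources.files("blinkreflex.data").joinpath(
        "healthy_reference.json"
    ).read_text(encoding="utf-8")
    raw = json.loads(text)
    return HealthyCohortSummary(
        n=raw["n"],
        measures={k: MeasureStats(**v) for k, v in raw["measures"].items()},
    )


def default_limits() -> NormativeLimits:
    """Packaged default limits: fixed latency values plus size cut-offs
    derived from the shipped healthy reference summary."""
    return NormativeLimits.from_summary(load_reference_summary())
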