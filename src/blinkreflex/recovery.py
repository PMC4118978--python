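"""Paired-pulse excitability recovery (BRER) and prepulse inhibition (BRIP).

BRER: pairs of supraorbital stimuli (conditioning, test) at inter-stimulus
intervals of 100–600 ms; the recovery at each interval is the test-R2 area
as a percentage of the conditioning-R2 area, averaged over three trials.
The BRER index condenses the curve into the sum of the six percentages.
A recovery larger than 30% at 300 ms or shorter marks abnormally enhanced
(disinhibited) excitability recovery.

BRIP: a weak somatosensory prepulse 100 ms before the supraorbital stimulus
inhibits the R2.  The primary measurement is the prepulse-trial R2 area as
a percentage of the mean unconditioned R2 area (``pct_of_control``); the
derived percentage inhibition (100 − pct_of_control) is the value compared
against the normative lower cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import BRER_INTERVALS_MS, BrerCurve, BripMeasure


@dataclass
class PairedTrial:
    """One conditioning/test stimulus pair (R2 areas in µV·ms)."""

    interval_ms: int
    conditioning_area: float
    test_area: float

    def __post_init__(self) -> None:
        if self.conditioning_area < 0 or self.test_area < 0:
            raise ValueError("areas must be non-negative")


def brer_curve(trials: Iterable[PairedTrial], side: str) -> BrerCurve:
    """Build the recovery curve from paired trials of one side.

    The recovery percentage is computed per pair (test/conditioning) and
    averaged over the trials of each interval.  Pairs whose conditioning
    response is absent (area 0) carry no information about recovery and are
    excluded with a warning; an interval with no usable pair is left out of
    the curve.
    """
    per_interval: dict[int, list[float]] = {}
    for t in trials:
        if t.interval_ms not in BRER_INTERVALS_MS:
            raise ValueError(f"unexpected BRER interval: {t.interval_ms}")
        if t.conditioning_area <= 0:
            warnings.warn(
                f"BRER pair at {t.interval_ms} ms excluded: "
                "conditioning R2 absent",
                stacklevel=2,
            )
            continue
        pct = 100.0 * max(t.test_area, 0.0) / t.conditioning_area
        per_interval.setdefault(t.interval_ms, []).append(pct)
    return BrerCurve(
        side=side,
        recovery_pct={
            t: sum(v) / len(v) for t, v in sorted(per_interval.items())
        },
    )


def brer_index(curve: BrerCurve) -> float | None:
    """Sum of the six recovery percentages; None if any interval missing."""
    if not curve.complete:
        return None
    return float(sum(curve.recovery_pct[t] for t in BRER_INTERVALS_MS))


def brer_abnormal(
    curve: BrerCurve,
    recovery_limit_pct: float = 30.0,
    interval_limit_ms: float = 300.0,
) -> bool:
    """True iff recovery exceeds the limit at any early interval (≤300 ms)."""
    return any(
        pct > recovery_limit_pct
        for t, pct in curve.recovery_pct.items()
        if t <= interval_limit_ms
    )


def brip_percent(
    prepulse_areas: Sequence[float],
    control_areas: Sequence[float],
    side: str,
) -> BripMeasure | None:
    """Prepulse-trial R2 area as a percentage of the mean control R2 area.

    Areas are floored at 0 before averaging.  Returns None (reported, not
    raised) when the control trials carry no response.
    """
    if not control_areas:
        raise ValueError("at least one control trial is required")
    if not prepulse_areas:
        raise ValueError("at least one prepulse trial is required")
    control_mean = sum(max(a, 0.0) for a in control_areas) / len(control_areas)
    if control_mean <= 0:
        warnings.warn(
            "BRIP undefined: mean control R2 area is zero", stacklevel=2
        )
        return None
    prepulse_mean = sum(max(a, 0.0) for a in prepulse_areas) / len(prepulse_areas)
    return BripMeasure(side=side, pct_of_control=100.0 * prepulse_mean / control_mean)


def brip_abnormal(measure: BripMeasure, inhibition_lower_pct: float) -> bool:
    """True iff the percentage inhibition falls below the lower cut-off."""
    return measure.inhibition_pct < inhibition_lower_pct
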