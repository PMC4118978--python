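"""Core domain records for blink-reflex studies.

A recording session yields, per subject:

* trigeminal blink reflex (TBR): 5 trials per stimulation side, each trial
  measured bilaterally from the orbicularis oculi (OOc) — R1 (early,
  ipsilateral), R2 (late, ipsilateral) and R2c (late, contralateral);
* somatosensory blink reflex (SBR): median-nerve stimulation, ipsilateral
  OOc response, first trial only (the SBR habituates quickly);
* blink-reflex excitability recovery (BRER): paired supraorbital stimuli at
  six inter-stimulus intervals, test-R2 area as a percentage of the
  conditioning-R2 area, three trials per interval;
* blink-reflex inhibition by a prepulse (BRIP): R2 area with a weak
  somatosensory prepulse 100 ms earlier, relative to unconditioned trials.

The convention for absent responses follows clinical practice: no latency
value is recorded and the area is entered as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

SIDES = ("right", "left")
COMPONENTS = ("R1", "R2", "R2c", "SBR")
BRER_INTERVALS_MS = (100, 200, 300, 400, 500, 600)


def opposite(side: str) -> str:
    """Return the contralateral side label."""
    if side == "right":
        return "left"
    if side == "left":
        return "right"
    raise ValueError(f"unknown side: {side!r}")


def recording_side(component: str, stim_side: str) -> str:
    """Side of the OOc muscle on which a component is recorded.

    R1, R2 and the SBR are ipsilateral to the stimulus; R2c is the crossed
    late response, recorded contralaterally.
    """
    if component == "R2c":
        return opposite(stim_side)
    if component in ("R1", "R2", "SBR"):
        return stim_side
    raise ValueError(f"unknown component: {component!r}")


@dataclass
class ResponseMeasure:
    """Latency/size measurements of one reflex component.

    ``latency_ms`` is measured from the stimulus artifact to response onset.
    R1 size is a peak-to-peak amplitude in µV; R2, R2c and SBR sizes are
    rectified areas in µV·ms.  When ``present`` is False the latency is
    None and the area is 0.
    """

    component: str
    stim_side: str
    rec_side: str
    latency_ms: float | None
    area_uVms: float
    amplitude_uV: float | None = None
    present: bool = True
    trial: int | None = None

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"unknown component: {self.component!r}")
        if self.stim_side not in SIDES or self.rec_side not in SIDES:
            raise ValueError("sides must be 'right' or 'left'")
        if not self.present:
            if self.latency_ms is not None:
                raise ValueError("absent response cannot carry a latency")
            if self.area_uVms != 0:
                raise ValueError("absent response must have area 0")
        else:
            if self.latency_ms is not None and self.latency_ms <= 0:
                raise ValueError("latency must be positive when present")
        if self.area_uVms < 0:
            raise ValueError("area must be non-negative")

    def mirrored(self) -> "ResponseMeasure":
        return replace(
            self,
            stim_side=opposite(self.stim_side),
            rec_side=opposite(self.rec_side),
        )


@dataclass
class BrerCurve:
    """Excitability recovery curve of one side.

    ``recovery_pct`` maps inter-stimulus interval (ms) to the mean test/
    conditioning R2 area percentage over three trials.  Missing intervals
    (e.g. all conditioning responses absent) are simply not present in the
    mapping.
    """

    side: str
    recovery_pct: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError("side must be 'right' or 'left'")
        for interval, pct in self.recovery_pct.items():
            if interval not in BRER_INTERVALS_MS:
                raise ValueError(f"unexpected BRER interval: {interval}")
            if pct < 0:
                raise ValueError("recovery percentage must be >= 0")

    @property
    def complete(self) -> bool:
        return all(t in self.recovery_pct for t in BRER_INTERVALS_MS)

    def mirrored(self) -> "BrerCurve":
        return BrerCurve(opposite(self.side), dict(self.recovery_pct))


@dataclass
class BripMeasure:
    """Prepulse inhibition of the R2 on one side.

    ``pct_of_control`` is the R2 area in prepulse trials expressed as a
    percentage of the mean R2 area of unconditioned (control) trials.
    ``inhibition_pct`` (100 − pct_of_control) is the percentage inhibition:
    high values mean strong (normal) prepulse inhibition, low values mean
    disinhibition.
    """

    side: str
    pct_of_control: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError("side must be 'right' or 'left'")
        if self.pct_of_control < 0:
            raise ValueError("pct_of_control must be >= 0")

    @property
    def inhibition_pct(self) -> float:
        return 100.0 - self.pct_of_control

    def mirrored(self) -> "BripMeasure":
        return BripMeasure(opposite(self.side), self.pct_of_control)


@dataclass
class SubjectMeta:
    """Clinical and MRI metadata attached to a subject.

    Lesion-site flags are per-region booleans read off the brainstem MRI.
    ``pontomedullary`` (pons or medulla involved) is the gold-standard flag
    for conduction-type blink-reflex abnormalities; the trigemino-facial
    reflex circuit runs through the pons and medulla.
    """

    midbrain: bool = False
    pons: bool = False
    medulla: bool = False
    edss: float | None = None
    brainstem_fs: float | None = None

    def __post_init__(self) -> None:
        if self.edss is not None and not (0 <= self.edss <= 10):
            raise ValueError("EDSS must be within 0-10")

    @property
    def pontomedullary(self) -> bool:
        return bool(self.pons or self.medulla)


@dataclass
class SubjectRecord:
    """All aggregated measures of one subject.

    ``measures`` maps ``(component, stim_side)`` to the trial-averaged
    :class:`ResponseMeasure` (mean of 5 TBR trials; first SBR trial).
    The recording side is implied by the component.
    """

    subject_id: str
    measures: dict[tuple[str, str], ResponseMeasure] = field(default_factory=dict)
    brer: dict[str, BrerCurve] = field(default_factory=dict)
    brip: dict[str, BripMeasure] = field(default_factory=dict)
    meta: SubjectMeta | None = None

    def measure(self, component: str, stim_side: str) -> ResponseMeasure | None:
        return self.measures.get((component, stim_side))

    def present(self, component: str, stim_side: str) -> bool:
        m = self.measure(component, stim_side)
        return bool(m is not None and m.present)

    def latency(self, component: str, stim_side: str) -> float | None:
        m = self.measure(component, stim_side)
        return None if m is None else m.latency_ms

    def area(self, component: str, stim_side: str) -> float:
        m = self.measure(component, stim_side)
        return 0.0 if m is None else m.area_uVms

    def r1_amplitude(self, side: str) -> float | None:
        m = self.measure("R1", side)
        return None if m is None else m.amplitude_uV

    def mirrored(self) -> "SubjectRecord":
        """Left/right mirror image of the record (metadata unchanged)."""
        return SubjectRecord(
            subject_id=self.subject_id,
            measures={
                (c, opposite(s)): m.mirrored() for (c, s), m in self.measures.items()
            },
            brer={opposite(s): c.mirrored() for s, c in self.brer.items()},
            brip={opposite(s): b.mirrored() for s, b in self.brip.items()},
            meta=self.meta,
        )


def aggregate_trials(
    trials: Iterable[ResponseMeasure],
    min_present_fraction: float = 0.5,
) -> dict[tuple[str, str], ResponseMeasure]:
    """Collapse per-trial measures into per-(component, stim side) means.

    A component counts as present when present in at least
    ``min_present_fraction`` of its trials.  Latencies and amplitudes are
    averaged over present trials only; areas are averaged over all trials
    with absent trials contributing 0, matching the convention of entering
    0 for the area of an absent response.
    """
    groups: dict[tuple[str, str], list[ResponseMeasure]] = {}
    for t in trials:
        groups.setdefault((t.component, t.stim_side), []).append(t)
    out: dict[tuple[str, str], ResponseMeasure] = {}
    for key, ms in groups.items():
        component, stim_side = key
        rec = recording_side(component, stim_side)
        present_ms = [m for m in ms if m.present]
        if len(present_ms) >= min_present_fraction * len(ms) and present_ms:
            latencies = [m.latency_ms for m in present_ms if m.latency_ms is not None]
            amplitudes = [
                m.amplitude_uV for m in present_ms if m.amplitude_uV is not None
            ]
            out[key] = ResponseMeasure(
                component=component,
                stim_side=stim_side,
                rec_side=rec,
                latency_ms=sum(latencies) / len(latencies) if latencies else None,
                area_uVms=sum(m.area_uVms for m in ms) / len(ms),
                amplitude_uV=(
                    sum(amplitudes) / len(amplitudes) if amplitudes else None
                ),
                present=True,
            )
        else:
            out[key] = ResponseMeasure(
                component=component,
                stim_side=stim_side,
                rec_side=rec,
                latency_ms=None,
                area_uVms=0.0,
                amplitude_uV=None,
                present=False,
            )
    return out


def build_subject(
    subject_id: str,
    trials: Iterable[ResponseMeasure],
    brer: Mapping[str, BrerCurve] | None = None,
    brip: Mapping[str, BripMeasure] | None = None,
    meta: SubjectMeta | None = None,
) -> SubjectRecord:
    """Assemble a :class:`SubjectRecord` from trial-level measures."""
    return SubjectRecord(
        subject_id=subject_id,
        measures=aggregate_trials(trials),
        brer=dict(brer or {}),
        brip=dict(brip or {}),
        meta=meta,
    )
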