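"""Latency-based abnormality flags and Aramideh pattern assignment.

A patient is latency-abnormal (AbLat) when any trigeminal blink-reflex
latency exceeds its fixed normative limit, when inter-side differences
exceed their limits (1.5 ms for R1, 5 ms for R2, 8 ms between R2 and R2c to
the same stimulus), or when a response is absent.  AbLat patients are
sub-typed with the Aramideh scheme:

* afferent — R2 and R2c both delayed/absent to stimulation of one side
  (lesion on the afferent, trigeminal limb of that side);
* efferent — the responses recorded from one OOc (ipsilateral R2 and the
  R2c elicited from the other side) delayed/absent (facial, efferent limb);
* commissural — R2c delayed/absent with all R2 normal (crossed pathway);
* mixed — any combination of the above, or a delay confined to R1.

The somatosensory blink reflex (SBR) is screened separately: delayed beyond
66.7 ms, or consistently absent on one side with the other present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .normative import NormativeLimits
from .records import SIDES, SubjectRecord, opposite

ABNORMAL = ("delayed", "absent")


@dataclass
class LatencyFindings:
    """Per-component latency statuses plus inter-side flags.

    ``status`` maps (component, stim_side) to normal/delayed/absent.
    ``relative_delay`` marks component instances implicated by inter-side
    rules (the relatively later side) even when absolutely normal.
    """

    status: dict[tuple[str, str], str] = field(default_factory=dict)
    interside: dict[str, bool] = field(default_factory=dict)
    relative_delay: set[tuple[str, str]] = field(default_factory=set)
    sbr_status: str = "normal"

    def abnormal(self, component: str, stim_side: str) -> bool:
        return (
            self.status.get((component, stim_side)) in ABNORMAL
            or (component, stim_side) in self.relative_delay
        )

    @property
    def tbr_abnormal(self) -> bool:
        return any(
            self.abnormal(c, s) for c in ("R1", "R2", "R2c") for s in SIDES
        ) or any(self.interside.values())

    @property
    def sbr_abnormal(self) -> bool:
        return self.sbr_status != "normal" and self.sbr_status != "absent_bilateral"


@dataclass
class AbLatResult:
    is_ablat: bool
    pattern: str  # afferent | efferent | commissural | mixed | none
    side: str  # right | left | bilateral | none
    sbr_status: str


def _absolute_status(
    record: SubjectRecord, component: str, stim_side: str, limit: float
) -> str:
    m = record.measure(component, stim_side)
    if m is None or not m.present:
        return "absent"
    if m.latency_ms is not None and m.latency_ms > limit:
        return "delayed"
    return "normal"


def flag_latencies(
    record: SubjectRecord, limits: NormativeLimits
) -> LatencyFindings:
    """Compare mean latencies against absolute and inter-side limits.

    Latencies are the per-side means of the 5-trial blocks carried by the
    record.  Inter-side rules are evaluated only when both latencies exist;
    an absent response is already abnormal through its absolute status.
    """
    f = LatencyFindings()
    for comp in ("R1", "R2", "R2c"):
        for s in SIDES:
            f.status[(comp, s)] = _absolute_status(
                record, comp, s, limits.latency_upper[comp]
            )
    for s in SIDES:
        f.status[("SBR", s)] = _absolute_status(
            record, "SBR", s, limits.latency_upper["SBR"]
        )

    # inter-side rules on R1 and R2 (right vs left stimulation)
    for comp in ("R1", "R2"):
        lat_r = record.latency(comp, "right")
        lat_l = record.latency(comp, "left")
        flagged = (
            lat_r is not None
            and lat_l is not None
            and abs(lat_r - lat_l) > limits.interside_latency_upper[comp]
        )
        f.interside[comp] = bool(flagged)
        if flagged:
            slower = "right" if lat_r > lat_l else "left"
            f.relative_delay.add((comp, slower))

    # R2 vs R2c difference to the same stimulus
    any_r2_r2c = False
    for s in SIDES:
        lat_r2 = record.latency("R2", s)
        lat_r2c = record.latency("R2c", s)
        flagged = (
            lat_r2 is not None
            and lat_r2c is not None
            and abs(lat_r2c - lat_r2) > limits.interside_latency_upper["R2_vs_R2c"]
        )
        f.interside[f"R2_vs_R2c_{s}"] = bool(flagged)
        if flagged:
            later = "R2c" if lat_r2c > lat_r2 else "R2"
            f.relative_delay.add((later, s))
            any_r2_r2c = True
    f.interside["R2_vs_R2c"] = any_r2_r2c

    # SBR status summary
    present = {s: record.present("SBR", s) for s in SIDES}
    delayed = {s: f.status[("SBR", s)] == "delayed" for s in SIDES}
    if not present["right"] and not present["left"]:
        f.sbr_status = "absent_bilateral"
    elif not present["right"] or not present["left"]:
        f.sbr_status = "absent_unilateral"
    elif delayed["right"] and delayed["left"]:
        f.sbr_status = "delayed_bilateral"
    elif delayed["right"] or delayed["left"]:
        f.sbr_status = "delayed_unilateral"
    else:
        f.sbr_status = "normal"
    return f


def _sides_to_label(sides: set[str]) -> str:
    if not sides:
        return "none"
    if len(sides) == 2:
        return "bilateral"
    return next(iter(sides))


def assign_pattern(findings: LatencyFindings) -> AbLatResult:
    """Assign the Aramideh pattern from the latency findings.

    When several pure patterns co-occur the result is mixed, as is an
    abnormality confined to R1.  Inter-side flags without any absolute
    abnormality are attributed to the relatively delayed component
    instance before the pattern rules are applied.
    """
    r2 = {s: findings.abnormal("R2", s) for s in SIDES}
    r2c = {s: findings.abnormal("R2c", s) for s in SIDES}
    r1 = {s: findings.abnormal("R1", s) for s in SIDES}

    afferent = {s for s in SIDES if r2[s] and r2c[s]}
    efferent = {m for m in SIDES if r2[m] and r2c[opposite(m)]}
    commissural: set[str] = set()
    if not any(r2.values()):
        # recording side of the abnormal crossed response
        commissural = {opposite(s) for s in SIDES if r2c[s]}

    conditions = [
        ("afferent", afferent),
        ("efferent", efferent),
        ("commissural", commissural),
    ]
    fired = [(name, sides) for name, sides in conditions if sides]

    is_ablat = findings.tbr_abnormal or findings.sbr_abnormal
    if not findings.tbr_abnormal:
        # SBR-only abnormality: no trigeminal pattern applies
        return AbLatResult(is_ablat, "none", "none", findings.sbr_status)

    if len(fired) > 1:
        pattern = "mixed"
        sides = set().union(*(s for _, s in fired))
    elif len(fired) == 1:
        pattern, sides = fired[0]
        if pattern == "afferent" and len(sides) == 2:
            # bilateral afferent involvement counts as combined
            pattern = "mixed"
    else:
        # no pure condition: attribute by the driving component
        abn_components = {
            c for c in ("R1", "R2", "R2c") for s in SIDES if findings.abnormal(c, s)
        }
        if abn_components == {"R2"}:
            pattern = "efferent"
            sides = {s for s in SIDES if r2[s]}
        elif abn_components == {"R2c"}:
            pattern = "commissural"
            sides = {opposite(s) for s in SIDES if r2c[s]}
        else:
            # R1-only, or several components without a pure pattern
            pattern = "mixed"
            sides = {
                s
                for s in SIDES
                if r1[s] or r2[s] or r2c[opposite(s)]
            }
    return AbLatResult(is_ablat, pattern, _sides_to_label(sides), findings.sbr_status)


def classify_latency(
    record: SubjectRecord, limits: NormativeLimits
) -> tuple[LatencyFindings, AbLatResult]:
    findings = flag_latencies(record, limits)
    return findings, assign_pattern(findings)
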