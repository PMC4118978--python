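"""Response-size indices and excitability (AbEx) classification.

Two complementary size measures are computed per subject:

* the R2c/R2 ratio to stimulation of each side (crossed late response area
  over ipsilateral late response area — below 1 in health, since the R2 is
  normally larger than the R2c);
* the side-averaged R2 area of each OOc muscle (the R2 elicited by
  ipsilateral stimulation averaged with the R2c elicited by contralateral
  stimulation, both recorded from that muscle).

A muscle side is implicated by the ratio when the ratio to stimulation of
the *opposite* side exceeds its cut-off (the crossed response is recorded
contralateral to the stimulus), or when the ratio inter-side difference
exceeds its cut-off with that side's crossed response relatively larger;
and by area when its side-averaged R2 area exceeds the absolute cut-off or
the area inter-side difference exceeds its cut-off with that side larger.
A patient is AbEx when both measures implicate the same side.

Supporting asymmetry evidence (R1 amplitude, SBR area, BRER index, BRIP)
strengthens an AbEx call when the abnormal inter-side difference lies on
the enhanced side (for BRIP: when the enhanced side is the more
disinhibited one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .normative import NormativeLimits
from .records import SIDES, SubjectRecord, opposite
from .recovery import brer_index


@dataclass
class SizeIndices:
    """Per-side response-size values of one subject.

    ``ratio`` is keyed by stimulation side, all other maps by the recording
    (muscle) side.  A ratio is None when undefined (R2 area 0).
    """

    ratio: dict[str, float | None] = field(default_factory=dict)
    mean_r2_area: dict[str, float] = field(default_factory=dict)
    r1_amp: dict[str, float | None] = field(default_factory=dict)
    sbr_area: dict[str, float | None] = field(default_factory=dict)
    brer_index: dict[str, float | None] = field(default_factory=dict)
    brip_inhibition: dict[str, float | None] = field(default_factory=dict)

    def interside(self, name: str) -> float | None:
        values = getattr(self, name)
        r, l = values.get("right"), values.get("left")
        if r is None or l is None:
            return None
        return abs(r - l)


@dataclass
class AbExResult:
    is_abex: bool
    enhanced_side: str  # right | left | bilateral | none
    evidence: dict[str, str] = field(default_factory=dict)  # measure -> side
    notes: list[str] = field(default_factory=list)


def r2c_r2_ratio(r2c_area: float, r2_area: float) -> float | None:
    """Crossed-over-ipsilateral late-response area ratio; None if undefined."""
    if r2c_area < 0 or r2_area < 0:
        raise ValueError("areas must be non-negative")
    if r2_area == 0:
        return None
    return r2c_area / r2_area


def mean_r2_area(r2_ipsi_area: float, r2c_contra_area: float) -> float:
    """Mean late-response area of one OOc muscle.

    Averages the R2 obtained by ipsilateral stimulation with the R2c
    obtained by contralateral stimulation, both recorded from the same
    muscle.
    """
    return (r2_ipsi_area + r2c_contra_area) / 2.0


def compute_indices(record: SubjectRecord) -> SizeIndices:
    """All per-side size indices of one subject."""
    idx = SizeIndices()
    for s in SIDES:
        idx.ratio[s] = r2c_r2_ratio(record.area("R2c", s), record.area("R2", s))
    for m in SIDES:
        idx.mean_r2_area[m] = mean_r2_area(
            record.area("R2", m), record.area("R2c", opposite(m))
        )
        idx.r1_amp[m] = record.r1_amplitude(m)
        idx.sbr_area[m] = (
            record.area("SBR", m) if record.present("SBR", m) else None
        )
        curve = record.brer.get(m)
        idx.brer_index[m] = brer_index(curve) if curve is not None else None
        brip = record.brip.get(m)
        idx.brip_inhibition[m] = (
            brip.inhibition_pct if brip is not None else None
        )
    return idx


def size_profile(record: SubjectRecord) -> dict[str, dict[str, float]]:
    """Per-side values of every normative size measure, for cohort summaries.

    Ratios are keyed here by the recording side of the crossed response
    (i.e. the muscle they describe) so that "side" means the same muscle
    across all measures.  Undefined values are omitted.
    """
    idx = compute_indices(record)
    profile: dict[str, dict[str, float]] = {}

    def put(name: str, side: str, value: float | None) -> None:
        if value is not None:
            profile.setdefault(name, {})[side] = value

    for m in SIDES:
        put("r2c_r2_ratio", m, idx.ratio[opposite(m)])
        put("r2_area", m, idx.mean_r2_area[m])
        put("r1_amp", m, idx.r1_amp[m])
        put("sbr_area", m, idx.sbr_area[m])
        put("brer_index", m, idx.brer_index[m])
        put("brip", m, idx.brip_inhibition[m])
    return profile


def _ratio_implicated(
    idx: SizeIndices, limits: NormativeLimits, notes: list[str]
) -> set[str]:
    implicated: set[str] = set()
    upper = limits.size_upper["r2c_r2_ratio"]
    for s in SIDES:
        ratio = idx.ratio[s]
        if ratio is None:
            notes.append(
                f"R2c/R2 ratio undefined for {s} stimulation (R2 area 0); "
                "side evaluated on the remaining measures"
            )
            continue
        if ratio > upper:
            implicated.add(opposite(s))  # R2c recorded contralaterally
    diff = idx.interside("ratio")
    if diff is not None and diff > limits.interside_upper["r2c_r2_ratio"]:
        larger_stim = "right" if idx.ratio["right"] > idx.ratio["left"] else "left"
        implicated.add(opposite(larger_stim))
    return implicated


def _area_implicated(idx: SizeIndices, limits: NormativeLimits) -> set[str]:
    implicated: set[str] = set()
    upper = limits.size_upper["r2_area"]
    for m in SIDES:
        if idx.mean_r2_area[m] > upper:
            implicated.add(m)
    diff = idx.interside("mean_r2_area")
    if diff is not None and diff > limits.interside_upper["r2_area"]:
        larger = (
            "right"
            if idx.mean_r2_area["right"] > idx.mean_r2_area["left"]
            else "left"
        )
        implicated.add(larger)
    return implicated


def classify_abex(idx: SizeIndices, limits: NormativeLimits) -> AbExResult:
    """AbEx when ratio- and area-based abnormality coincide on one side."""
    notes: list[str] = []
    by_ratio = _ratio_implicated(idx, limits, notes)
    by_area = _area_implicated(idx, limits)
    coincident = by_ratio & by_area
    evidence: dict[str, str] = {}
    if by_ratio:
        evidence["ratio"] = _sides_label(by_ratio)
    if by_area:
        evidence["r2_area"] = _sides_label(by_area)
    return AbExResult(
        is_abex=bool(coincident),
        enhanced_side=_sides_label(coincident),
        evidence=evidence,
        notes=notes,
    )


def _sides_label(sides: set[str]) -> str:
    if not sides:
        return "none"
    if len(sides) == 2:
        return "bilateral"
    return next(iter(sides))


def supporting_asymmetries(
    idx: SizeIndices,
    limits: NormativeLimits,
    enhanced_side: str,
) -> dict[str, bool]:
    """Flags for R1/SBR/BRER/BRIP asymmetries coinciding with the AbEx side.

    Each flag is set when the inter-side difference exceeds its cut-off and
    the larger value (for BRIP: the lower inhibition, i.e. the more
    disinhibited side) lies on ``enhanced_side``.
    """
    flags: dict[str, bool] = {}
    for measure, values_name, larger_is_abnormal in (
        ("r1", "r1_amp", True),
        ("sbr", "sbr_area", True),
        ("brer", "brer_index", True),
        ("brip", "brip_inhibition", False),
    ):
        limit_key = {
            "r1": "r1_amp",
            "sbr": "sbr_area",
            "brer": "brer_index",
            "brip": "brip",
        }[measure]
        values = getattr(idx, values_name)
        diff = idx.interside(values_name)
        flags[measure] = False
        if diff is None or enhanced_side not in SIDES:
            continue
        if diff <= limits.interside_upper[limit_key]:
            continue
        r, l = values["right"], values["left"]
        extreme = (
            ("right" if r > l else "left")
            if larger_is_abnormal
            else ("right" if r < l else "left")
        )
        flags[measure] = extreme == enhanced_side
    return flags
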