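"""Latency flags and Aramideh pattern assignment."""

import pytest

from blinkreflex.latency import assign_pattern, classify_latency, flag_latencies
from blinkreflex.records import (
    ResponseMeasure,
    SubjectRecord,
    recording_side,
)

HEALTHY_LATENCIES = {
    ("R1", "right"): 10.5, ("R1", "left"): 10.5,
    ("R2", "right"): 33.0, ("R2", "left"): 33.0,
    ("R2c", "right"): 34.0, ("R2c", "left"): 34.0,
    ("SBR", "right"): 55.0, ("SBR", "left"): 55.0,
}


def subject(**overrides) -> SubjectRecord:
    """Healthy-latency subject with selected (comp_side) overrides.

    Override keys look like ``R2_left``; a value of None marks the
    response absent.
    """
    lat = dict(HEALTHY_LATENCIES)
    for key, value in overrides.items():
        comp, side = key.rsplit("_", 1)
        lat[(comp, side)] = value
    measures = {}
    for (comp, side), value in lat.items():
        present = value is not None
        measures[(comp, side)] = ResponseMeasure(
            component=comp,
            stim_side=side,
            rec_side=recording_side(comp, side),
            latency_ms=value,
            area_uVms=1000.0 if present else 0.0,
            amplitude_uV=150.0 if comp == "R1" and present else None,
            present=present,
        )
    return SubjectRecord("s1", measures)


class TestFlagLatencies:
    def test_healthy_subject_has_no_flags(self, limits):
        f = flag_latencies(subject(), limits)
        assert all(v == "normal" for v in f.status.values())
        assert not any(f.interside.values())
        assert f.sbr_status == "normal"
        assert not f.tbr_abnormal

    def test_r1_interside_difference_flagged(self, limits):
        # Δ = 2.0 ms > 1.5 ms
        f = flag_latencies(subject(R1_right=12.0, R1_left=14.0), limits)
        assert f.interside["R1"]
        assert ("R1", "left") in f.relative_delay

    def test_r2_r2c_difference_flagged(self, limits):
        # R2 36, R2c 45 to the same stimulus: Δ = 9 > 8 ms
        f = flag_latencies(subject(R2_right=36.0, R2c_right=45.0), limits)
        assert f.interside["R2_vs_R2c_right"]
        assert ("R2c", "right") in f.relative_delay

    def test_boundary_differences_not_flagged(self, limits):
        f = flag_latencies(
            subject(R1_right=10.0, R1_left=11.5, R2_right=30.0, R2_left=35.0),
            limits,
        )
        assert not f.interside["R1"]
        assert not f.interside["R2"]

    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({"SBR_left": 70.0}, "delayed_unilateral"),
            ({"SBR_left": 70.0, "SBR_right": 68.0}, "delayed_bilateral"),
            ({"SBR_left": None}, "absent_unilateral"),
            ({"SBR_left": None, "SBR_right": None}, "absent_bilateral"),
        ],
    )
    def test_sbr_status(self, limits, overrides, expected):
        assert flag_latencies(subject(**overrides), limits).sbr_status == expected


class TestAssignPattern:
    def test_afferent_pattern_left(self, limits):
        """R2 and R2c delayed to left-side stimulation only."""
        _, result = classify_latency(
            subject(R2_left=43.0, R2c_left=45.0), limits
        )
        assert result.is_ablat
        assert (result.pattern, result.side) == ("afferent", "left")

    def test_efferent_pattern_left(self, limits):
        """Responses of the left OOc delayed to stimulation of either side."""
        _, result = classify_latency(
            subject(R2_left=43.0, R2c_right=45.0), limits
        )
        assert (result.pattern, result.side) == ("efferent", "left")

    def test_commissural_pattern(self, limits):
        """Delayed crossed response with all direct R2 normal."""
        _, result = classify_latency(subject(R2c_left=45.0), limits)
        assert result.pattern == "commissural"
        assert result.side == "right"  # recording side of the crossed response

    def test_mixed_pattern_bilateral(self, limits):
        """Bilateral R1 delay, R2/R2c absent to right and delayed to left."""
        _, result = classify_latency(
            subject(
                R1_right=14.0, R1_left=14.5,
                R2_right=None, R2c_right=None,
                R2_left=44.0, R2c_left=46.0,
            ),
            limits,
        )
        assert (result.pattern, result.side) == ("mixed", "bilateral")

    def test_r1_only_delay_is_mixed(self, limits):
        _, result = classify_latency(subject(R1_left=13.5), limits)
        assert (result.pattern, result.side) == ("mixed", "left")

    def test_no_abnormality_is_none(self, limits):
        _, result = classify_latency(subject(), limits)
        assert not result.is_ablat
        assert (result.pattern, result.side) == ("none", "none")

    def test_sbr_only_abnormality(self, limits):
        """Unilateral SBR absence marks the patient without a TBR pattern."""
        _, result = classify_latency(subject(SBR_left=None), limits)
        assert result.is_ablat
        assert result.pattern == "none"
        assert result.sbr_status == "absent_unilateral"

    def test_bilateral_sbr_absence_alone_is_not_ablat(self, limits):
        _, result = classify_latency(
            subject(SBR_left=None, SBR_right=None), limits
        )
        assert not result.is_ablat
        assert result.sbr_status == "absent_bilateral"

    @pytest.mark.parametrize(
        "overrides",
        [
            {"R2_left": 43.0, "R2c_left": 45.0},
            {"R2_left": 43.0, "R2c_right": 45.0},
            {"R2c_left": 45.0},
            {"R1_left": 13.5},
            {"R1_right": 14.0, "R2_right": None, "R2c_right": None},
        ],
    )
    def test_mirror_equivariance(self, limits, overrides):
        def flip(key):
            comp, side = key.rsplit("_", 1)
            return f"{comp}_{'left' if side == 'right' else 'right'}"

        _, direct = classify_latency(subject(**overrides), limits)
        mirrored_overrides = {flip(k): v for k, v in overrides.items()}
        _, mirrored = classify_latency(subject(**mirrored_overrides), limits)
        assert direct.pattern == mirrored.pattern
        flip_side = {"right": "left", "left": "right"}
        assert mirrored.side == flip_side.get(direct.side, direct.side)

    def test_deterministic(self, limits):
        rec = subject(R2_left=43.0, R2c_left=45.0)
        results = {assign_pattern(flag_latencies(rec, limits)).pattern
                   for _ in range(5)}
        assert results == {"afferent"}
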