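"""Synthetic cohort generator: calibration, determinism, scenario effects."""

import statistics

import numpy as np
import pytest

import blinkreflex as br
from blinkreflex.cohort import (
    ConductionLesion,
    Enhancement,
    GeneratorConfig,
    Scenario,
    default_scenarios,
    generate_cohort,
)
from blinkreflex.excitability import size_profile
from blinkreflex.io import measures_frame
from blinkreflex.pipeline import classify_subject


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        a = generate_cohort(GeneratorConfig(seed=5))
        b = generate_cohort(GeneratorConfig(seed=5))
        assert measures_frame(a.trials).equals(measures_frame(b.trials))
        for ra, rb in zip(a.subjects, b.subjects):
            assert ra.measures == rb.measures
            assert ra.brer == rb.brer
            assert ra.brip == rb.brip

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(seed=5))
        b = generate_cohort(GeneratorConfig(seed=6))
        assert not measures_frame(a.trials).equals(measures_frame(b.trials))


@pytest.fixture(scope="module")
def big_healthy():
    return generate_cohort(GeneratorConfig(n_healthy=1000, n_patients=0, seed=11))


class TestHealthyCalibration:
    def test_ratio_and_brip_match_reference_means(self, big_healthy):
        ratios, brips = [], []
        for record in big_healthy.healthy:
            profile = size_profile(record)
            ratios += list(profile["r2c_r2_ratio"].values())
            brips += list(profile["brip"].values())
        assert statistics.mean(ratios) == pytest.approx(0.815, abs=0.01)
        assert statistics.mean(brips) == pytest.approx(94.1, abs=0.5)

    def test_brer_curve_anchors_and_index(self, big_healthy):
        r300, r600, idx = [], [], []
        for record in big_healthy.healthy:
            for curve in record.brer.values():
                r300.append(curve.recovery_pct[300])
                r600.append(curve.recovery_pct[600])
                idx.append(br.brer_index(curve))
        assert statistics.mean(r300) == pytest.approx(4.4, abs=1.5)
        assert statistics.mean(r600) == pytest.approx(48.1, abs=5.0)
        assert statistics.mean(idx) == pytest.approx(92.4, rel=0.12)

    def test_healthy_false_positive_rates_are_small(self, big_healthy, limits):
        df = br.classify_cohort(big_healthy.healthy, limits)
        assert df["is_ablat"].mean() < 0.10
        assert df["is_abex"].mean() < 0.08


class TestScenarios:
    def test_default_mix_matches_study_design(self):
        scenarios = default_scenarios()
        assert len(scenarios) == 20
        n_conduction = sum(s.conduction is not None for s in scenarios)
        n_enh = sum(s.enhancement is not None for s in scenarios)
        n_both = sum(
            s.conduction is not None and s.enhancement is not None
            for s in scenarios
        )
        assert (n_conduction, n_enh, n_both) == (8, 9, 2)
        patterns = [
            s.conduction.pattern for s in scenarios if s.conduction is not None
        ]
        assert patterns.count("afferent") == 4

    def _classify_scenario(self, scenario, limits, seed=3):
        cohort = generate_cohort(
            GeneratorConfig(
                n_healthy=0, n_patients=1, scenarios=[scenario], seed=seed
            )
        )
        return classify_subject(cohort.patients[0], limits)

    def test_absent_conduction_lesion_classified_afferent(self, limits):
        scenario = Scenario(
            conduction=ConductionLesion("afferent", "left", "absent")
        )
        cls = self._classify_scenario(scenario, limits)
        assert cls.ablat.is_ablat
        assert (cls.ablat.pattern, cls.ablat.side) == ("afferent", "left")

    def test_enhancement_classified_abex_on_the_gained_side(self, limits):
        scenario = Scenario(enhancement=Enhancement("left", gain=2.0))
        cls = self._classify_scenario(scenario, limits)
        assert cls.abex.is_abex
        assert cls.abex.enhanced_side == "left"

    def test_enhancement_reduces_brip_and_shifts_brer(self, limits):
        scenario = Scenario(enhancement=Enhancement("right", gain=2.0))
        cohort = generate_cohort(
            GeneratorConfig(
                n_healthy=0, n_patients=1, scenarios=[scenario], seed=9
            )
        )
        record = cohort.patients[0]
        assert (
            record.brip["right"].inhibition_pct
            < record.brip["left"].inhibition_pct
        )
        assert br.brer_index(record.brer["right"]) > br.brer_index(
            record.brer["left"]
        )

    def test_mirrored_scenarios_give_mirrored_calls(self, limits):
        scenarios = default_scenarios()
        mirrored = [s.mirrored() for s in scenarios]
        flip = {"right": "left", "left": "right"}
        a = generate_cohort(
            GeneratorConfig(n_healthy=0, n_patients=20, scenarios=scenarios,
                            seed=17)
        )
        b = generate_cohort(
            GeneratorConfig(n_healthy=0, n_patients=20, scenarios=mirrored,
                            seed=17)
        )
        for sid in a.truth:
            ta, tb = a.truth[sid], b.truth[sid]
            assert tb.ablat_pattern == ta.ablat_pattern
            assert tb.ablat_side == flip.get(ta.ablat_side, ta.ablat_side)
            assert tb.abex_side == flip.get(ta.abex_side, ta.abex_side)

    def test_ground_truth_matches_scenarios(self):
        cohort = generate_cohort(GeneratorConfig(seed=2))
        scenarios = default_scenarios()
        patients = [t for sid, t in sorted(cohort.truth.items())
                    if sid.startswith("pt")]
        for truth, scenario in zip(patients, scenarios):
            assert truth.category == scenario.category
            if scenario.enhancement:
                assert truth.abex_side == scenario.enhancement.side


class TestConfigValidation:
    def test_scenario_count_must_match(self):
        with pytest.raises(ValueError, match="one scenario per patient"):
            generate_cohort(
                GeneratorConfig(n_patients=3, scenarios=[Scenario()])
            ).patients

    def test_bad_gain_rejected(self):
        with pytest.raises(ValueError):
            Enhancement("left", gain=-1.0)

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            ConductionLesion("sideways")

    def test_empty_cohort_is_valid(self):
        cohort = generate_cohort(GeneratorConfig(n_healthy=0, n_patients=0))
        assert cohort.subjects == []
        assert measures_frame(cohort.trials).empty
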