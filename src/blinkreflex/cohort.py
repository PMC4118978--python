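"""Synthetic blink-reflex cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* healthy size measures are drawn from moment-matched lognormal
  subject-level distributions (areas and amplitudes are positive and
  right-skewed), split into right/left values by an additive inter-side
  difference whose scale is calibrated so the cohort reproduces the
  healthy-reference inter-side Δ statistics;
* latencies are Gaussian at the subject level with small inter-side and
  trial-to-trial jitter;
* the BRER recovery curve is logistic in log-interval with a subject-level
  and a side-level horizontal shift, calibrated so the healthy cohort
  reproduces the reference recovery anchors (≈4.4% at 300 ms, ≈48% at
  600 ms) and BRER-index mean/SD/Δ;
* two lesion scenarios perturb a subject coherently: a conduction lesion
  delays or abolishes specific components (yielding a known Aramideh
  pattern), and an excitability enhancement multiplies one OOc muscle's
  response sizes by a gain, shifts that side's BRER curve left and reduces
  its prepulse inhibition.

Randomness is fully deterministic under a fixed seed: one spawned child
generator per subject, and base (healthy) draws are made before scenario
transforms so that the random stream does not depend on the scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .records import (
    BRER_INTERVALS_MS,
    BrerCurve,
    BripMeasure,
    ResponseMeasure,
    SIDES,
    SubjectMeta,
    SubjectRecord,
    build_subject,
    opposite,
    recording_side,
)
from .waveform import (
    DEFAULT_WINDOWS,
    EmgTrace,
    MeasurementConfig,
    measure_trial,
)

#: E|N(0,σ)| = σ·sqrt(2/π); converts a target mean |Δ| into the Δ SD.
_HALF_NORMAL = math.sqrt(2.0 / math.pi)


# --------------------------------------------------------------------------
# generative models
# --------------------------------------------------------------------------

@dataclass
class SizeModel:
    """Subject-level mean/SD and target mean inter-side |Δ| of a measure.

    Subject values are moment-matched lognormal.  The right/left split is
    either additive (value ± d/2) or multiplicative (value · e^{±e/2}; used
    for strictly positive measures whose asymmetry scales with size), with
    the split SD calibrated so the cohort mean |right − left| equals
    ``delta_mean``.
    """

    mean: float
    sd: float
    delta_mean: float
    floor: float = 0.0
    split: str = "additive"  # "additive" | "multiplicative"

    def draw_subject(self, rng: np.random.Generator) -> float:
        if self.sd <= 0:
            return self.mean
        sigma2 = math.log(1.0 + (self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))

    def split_sides(
        self, rng: np.random.Generator, value: float
    ) -> dict[str, float]:
        if self.split == "multiplicative":
            e = rng.normal(0.0, self.delta_mean / (self.mean * _HALF_NORMAL))
            return {
                "right": max(self.floor, value * math.exp(e / 2.0)),
                "left": max(self.floor, value * math.exp(-e / 2.0)),
            }
        d = rng.normal(0.0, self.delta_mean / _HALF_NORMAL)
        return {
            "right": max(self.floor, value + d / 2.0),
            "left": max(self.floor, value - d / 2.0),
        }


@dataclass
class LatencyModel:
    mean: float
    sd: float           # between-subject SD of the subject mean
    delta_sd: float     # SD of the right-left difference
    trial_sd: float     # within-subject trial jitter

    def draw_sides(self, rng: np.random.Generator) -> dict[str, float]:
        mu = rng.normal(self.mean, self.sd)
        d = rng.normal(0.0, self.delta_sd)
        return {"right": mu + d / 2.0, "left": mu - d / 2.0}


@dataclass
class BrerModel:
    """Logistic-in-log-interval recovery curve generator.

    recovery(t) = rmax · expit((ln t − μ) / w), with μ shifted per subject
    and per side.  The constants are calibrated so that a large healthy
    cohort reproduces the reference recovery anchors and the BRER-index
    mean (≈92), SD (≈34) and inter-side difference (≈13).
    """

    rmax: float = 200.0
    log_width: float = 0.2621
    log_mid: float = 6.7184
    subject_sd: float = 0.1158
    side_sd: float = 0.0579
    trial_cv: float = 0.14
    trial_floor_sd: float = 0.5
    n_trials: int = 3

    def curve(self, mu: float) -> dict[int, float]:
        return {
            t: float(self.rmax * expit((math.log(t) - mu) / self.log_width))
            for t in BRER_INTERVALS_MS
        }


@dataclass
class HealthyModel:
    """Healthy-subject generative parameters (reference-calibrated)."""

    latencies: dict[str, LatencyModel] = field(
        default_factory=lambda: {
            "R1": LatencyModel(10.5, 0.8, 0.4, 0.25),
            "R2": LatencyModel(33.0, 2.0, 1.6, 1.0),
            "SBR": LatencyModel(55.6, 4.0, 2.0, 1.5),
        }
    )
    #: R2c onset lags the same-stimulus R2 by a small crossed-pathway delay
    r2c_offset_mean: float = 1.0
    r2c_offset_sd: float = 0.8
    r2c_trial_sd: float = 1.0
    ratio: SizeModel = field(
        default_factory=lambda: SizeModel(0.815, 0.093, 0.170, floor=0.02)
    )
    r2_area: SizeModel = field(
        default_factory=lambda: SizeModel(4707.1, 2864.3, 546.8, floor=100.0)
    )
    r1_amp: SizeModel = field(
        default_factory=lambda: SizeModel(
            165.1, 79.1, 31.8, floor=20.0, split="multiplicative"
        )
    )
    sbr_area: SizeModel = field(
        default_factory=lambda: SizeModel(
            1716.0, 1061.1, 424.8, floor=400.0, split="multiplicative"
        )
    )
    #: BRIP modelled on the prepulse-trial percentage of control
    #: (100 − percentage inhibition): healthy inhibition 94.1 ± 4.7 %.
    brip_pct_of_control: SizeModel = field(
        default_factory=lambda: SizeModel(5.9, 4.7, 3.4, floor=0.2)
    )
    brer: BrerModel = field(default_factory=BrerModel)
    sbr_absent_prob: float = 0.15  # bilateral SBR absence (fast habituators)


# --------------------------------------------------------------------------
# scenarios and ground truth
# --------------------------------------------------------------------------

@dataclass
class ConductionLesion:
    """Focal conduction impairment producing a known latency pattern.

    ``pattern`` is one of afferent / efferent / commissural (with ``side``)
    or mixed (bilateral afferent-type involvement) / mixed_r1 (delay
    confined to R1, bilateral).
    """

    pattern: str
    side: str = "bilateral"
    mode: str = "delay"  # "delay" | "absent"
    delay_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.pattern not in (
            "afferent", "efferent", "commissural", "mixed", "mixed_r1"
        ):
            raise ValueError(f"unknown lesion pattern: {self.pattern!r}")
        if self.mode not in ("delay", "absent"):
            raise ValueError("mode must be 'delay' or 'absent'")
        if self.delay_ms < 0:
            raise ValueError("delay must be non-negative")

    def targets(self) -> set[tuple[str, str]]:
        """(component, stim_side) instances hit by the lesion."""
        s = self.side
        if self.pattern == "afferent":
            return {("R1", s), ("R2", s), ("R2c", s)}
        if self.pattern == "efferent":
            return {("R1", s), ("R2", s), ("R2c", opposite(s))}
        if self.pattern == "commissural":
            return {("R2c", opposite(s))}
        if self.pattern == "mixed":
            return {(c, s2) for c in ("R1", "R2", "R2c") for s2 in SIDES}
        return {("R1", s2) for s2 in SIDES}  # mixed_r1

    def expected_pattern(self) -> tuple[str, str]:
        if self.pattern in ("mixed", "mixed_r1"):
            return "mixed", "bilateral"
        return self.pattern, self.side

    def mirrored(self) -> "ConductionLesion":
        side = self.side if self.side == "bilateral" else opposite(self.side)
        return ConductionLesion(self.pattern, side, self.mode, self.delay_ms)


@dataclass
class Enhancement:
    """Unilateral excitability enhancement of one OOc muscle."""

    side: str
    gain: float = 2.0
    brer_shift: float = 0.405   # leftward shift of the recovery curve (ln ms)
    brip_reduction: float = 25.0  # percentage points of inhibition lost

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError("enhancement side must be 'right' or 'left'")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def mirrored(self) -> "Enhancement":
        return Enhancement(
            opposite(self.side), self.gain, self.brer_shift, self.brip_reduction
        )


@dataclass
class Scenario:
    conduction: ConductionLesion | None = None
    enhancement: Enhancement | None = None

    @property
    def category(self) -> str:
        if self.conduction and self.enhancement:
            return "both"
        if self.conduction:
            return "ablat"
        if self.enhancement:
            return "abex"
        return "healthy"

    def mirrored(self) -> "Scenario":
        return Scenario(
            self.conduction.mirrored() if self.conduction else None,
            self.enhancement.mirrored() if self.enhancement else None,
        )


@dataclass
class GroundTruth:
    subject_id: str
    category: str  # healthy | ablat | abex | both
    ablat_pattern: str = "none"
    ablat_side: str = "none"
    abex_side: str = "none"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def default_scenarios() -> list[Scenario]:
    """The study-like 20-patient scenario mix.

    8 conduction lesions (4 afferent, 1 efferent, 1 commissural, 2 mixed),
    9 excitability enhancements, 2 of them overlapping with a lesion, and
    5 unaffected patients.
    """
    return [
        Scenario(conduction=ConductionLesion("afferent", "right", "delay")),
        Scenario(conduction=ConductionLesion("afferent", "left", "absent")),
        Scenario(conduction=ConductionLesion("afferent", "right", "absent")),
        Scenario(conduction=ConductionLesion("afferent", "left", "delay")),
        Scenario(
            conduction=ConductionLesion("efferent", "left", "delay"),
            enhancement=Enhancement("left"),
        ),
        Scenario(conduction=ConductionLesion("commissural", "right", "delay")),
        Scenario(
            conduction=ConductionLesion("mixed", mode="delay"),
            enhancement=Enhancement("right"),
        ),
        Scenario(conduction=ConductionLesion("mixed_r1", mode="delay")),
        Scenario(enhancement=Enhancement("left")),
        Scenario(enhancement=Enhancement("right")),
        Scenario(enhancement=Enhancement("left")),
        Scenario(enhancement=Enhancement("right")),
        Scenario(enhancement=Enhancement("left")),
        Scenario(enhancement=Enhancement("right")),
        Scenario(enhancement=Enhancement("left")),
        Scenario(),
        Scenario(),
        Scenario(),
        Scenario(),
        Scenario(),
    ]


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    n_healthy: int = 12
    n_patients: int = 20
    seed: int = 0
    scenarios: list[Scenario] | None = None
    healthy: HealthyModel = field(default_factory=HealthyModel)
    n_tbr_trials: int = 5
    trial_cv: float = 0.10
    sampling_rate: float = 5000.0

    def resolved_scenarios(self) -> list[Scenario]:
        if self.scenarios is not None:
            if len(self.scenarios) != self.n_patients:
                raise ValueError("need one scenario per patient")
            return self.scenarios
        base = default_scenarios()
        if self.n_patients <= len(base):
            return base[: self.n_patients]
        return base + [Scenario() for _ in range(self.n_patients - len(base))]


@dataclass
class Cohort:
    healthy: list[SubjectRecord]
    patients: list[SubjectRecord]
    truth: dict[str, GroundTruth]
    trials: dict[str, list[ResponseMeasure]]
    config: GeneratorConfig

    @property
    def subjects(self) -> list[SubjectRecord]:
        return self.healthy + self.patients


def _gain_asym_sd(model: HealthyModel) -> float:
    """SD of the log muscle-gain asymmetry, from the target ratio Δ.

    |Δratio| ≈ 2·ratio·|γ|, so E|Δratio| = 2·mean·σ_γ·sqrt(2/π).
    """
    return model.ratio.delta_mean / (2.0 * model.ratio.mean * _HALF_NORMAL)


def _input_asym_sd(model: HealthyModel) -> float:
    """SD of the log stimulation-input asymmetry, from the target area Δ.

    The muscle-area log-asymmetry is γ + υ·(1−ρ)/(1+ρ); the υ term absorbs
    whatever Δ scale the muscle-gain term does not explain.
    """
    total = model.r2_area.delta_mean / (model.r2_area.mean * _HALF_NORMAL)
    gain = _gain_asym_sd(model)
    residual = max(0.0, total**2 - gain**2)
    rho = model.ratio.mean
    damp = (1.0 - rho) / (1.0 + rho)
    return math.sqrt(residual) / damp if damp > 0 else 0.0


def _draw_base(model: HealthyModel, rng: np.random.Generator) -> dict:
    """Draw every healthy-level quantity in a fixed order."""
    base: dict = {}
    base["lat"] = {
        comp: m.draw_sides(rng) for comp, m in sorted(model.latencies.items())
    }
    base["r2c_offset"] = {
        s: rng.normal(model.r2c_offset_mean, model.r2c_offset_sd) for s in SIDES
    }
    # The four late-response areas come from a latent multiplicative model:
    # A2(stim s)  = C · u_s · g_s          (recorded on muscle s)
    # A2c(stim s) = C · u_s · ρ · g_opp(s) (recorded on the crossed muscle)
    # with g the per-muscle excitability gain, u the per-stimulation-side
    # input strength and ρ the crossed-pathway attenuation.  Ratio and
    # muscle-area asymmetries thus co-vary coherently through g.  The
    # per-subject two-side means of the ratio and of the muscle area are
    # pinned exactly to the drawn subject-level targets.
    gamma = rng.normal(0.0, _gain_asym_sd(model))         # ln muscle-gain Δ
    ups = rng.normal(0.0, _input_asym_sd(model))          # ln input Δ
    ratio_target = model.ratio.draw_subject(rng)
    area_target = model.r2_area.draw_subject(rng)
    rho = ratio_target / math.cosh(gamma)
    g = {"right": math.exp(gamma / 2.0), "left": math.exp(-gamma / 2.0)}
    u = {"right": math.exp(ups / 2.0), "left": math.exp(-ups / 2.0)}
    v = {m: g[m] * (u[m] + rho * u[opposite(m)]) for m in SIDES}
    c_scale = 4.0 * area_target / (v["right"] + v["left"])
    base["r2_area_stim"] = {s: c_scale * u[s] * g[s] for s in SIDES}
    base["r2c_area_stim"] = {
        s: c_scale * u[s] * rho * g[opposite(s)] for s in SIDES
    }
    base["r1_amp"] = model.r1_amp.split_sides(rng, model.r1_amp.draw_subject(rng))
    base["sbr_area"] = model.sbr_area.split_sides(
        rng, model.sbr_area.draw_subject(rng)
    )
    base["sbr_absent"] = bool(rng.random() < model.sbr_absent_prob)
    brip = model.brip_pct_of_control
    base["brip_pct"] = brip.split_sides(rng, brip.draw_subject(rng))
    base["brer_mu"] = model.brer.log_mid + rng.normal(0, model.brer.subject_sd)
    base["brer_side"] = rng.normal(0, model.brer.side_sd)
    return base


def _apply_enhancement(base: dict, enh: Enhancement) -> None:
    m = enh.side
    base["r1_amp"][m] *= enh.gain
    base["sbr_area"][m] *= enh.gain
    base["r2_area_stim"][m] *= enh.gain            # R2 recorded on m
    base["r2c_area_stim"][opposite(m)] *= enh.gain  # R2c recorded on m
    base["brip_pct"][m] += enh.brip_reduction



def _clip_latency(component: str, latency_ms: float) -> float:
    """Keep a trial latency inside the component search window.

    Responses outside the physiological search window would not be labelled
    as that component; the clip also guarantees a rendered burst can realise
    the target (3 ms of window must remain for sustained onset detection).
    """
    start, end = DEFAULT_WINDOWS[component]
    return float(min(max(latency_ms, start + 0.3), end - 3.2))


def _tbr_trials(
    base: dict,
    lesion: ConductionLesion | None,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[ResponseMeasure]:
    model = config.healthy
    targets = lesion.targets() if lesion else set()
    delayed = targets if (lesion and lesion.mode == "delay") else set()
    absent = targets if (lesion and lesion.mode == "absent") else set()

    lat_mean: dict[tuple[str, str], float] = {}
    for s in SIDES:
        lat_mean[("R1", s)] = base["lat"]["R1"][s]
        lat_mean[("R2", s)] = base["lat"]["R2"][s]
        lat_mean[("R2c", s)] = base["lat"]["R2"][s] + base["r2c_offset"][s]
    for key in delayed:
        if key in lat_mean:
            lat_mean[key] += lesion.delay_ms

    trial_sd = {
        "R1": model.latencies["R1"].trial_sd,
        "R2": model.latencies["R2"].trial_sd,
        "R2c": model.r2c_trial_sd,
    }
    area_mean = {
        ("R2", s): base["r2_area_stim"][s] for s in SIDES
    } | {("R2c", s): base["r2c_area_stim"][s] for s in SIDES}

    out: list[ResponseMeasure] = []
    for s in SIDES:
        for trial in range(1, config.n_tbr_trials + 1):
            for comp in ("R1", "R2", "R2c"):
                # draw regardless of absence so the random stream does not
                # depend on the scenario
                lat = rng.normal(lat_mean[(comp, s)], trial_sd[comp])
                noise = rng.normal(0.0, config.trial_cv)
                if (comp, s) in absent:
                    out.append(
                        ResponseMeasure(
                            comp, s, recording_side(comp, s),
                            None, 0.0, None, present=False, trial=trial,
                        )
                    )
                    continue
                lat = _clip_latency(comp, lat)
                if comp == "R1":
                    amp = max(1.0, base["r1_amp"][s] * (1.0 + noise))
                    area = amp * 2.5  # not used downstream; keeps schema full
                    out.append(
                        ResponseMeasure(
                            comp, s, s, lat, area, amp, present=True, trial=trial
                        )
                    )
                else:
                    area = max(0.0, area_mean[(comp, s)] * (1.0 + noise))
                    out.append(
                        ResponseMeasure(
                            comp, s, recording_side(comp, s),
                            lat, area, None, present=True, trial=trial,
                        )
                    )
    return out


def _sbr_trials(
    base: dict, config: GeneratorConfig, rng: np.random.Generator
) -> list[ResponseMeasure]:
    model = config.healthy
    out = []
    for s in SIDES:
        lat = _clip_latency(
            "SBR",
            rng.normal(base["lat"]["SBR"][s], model.latencies["SBR"].trial_sd),
        )
        noise = rng.normal(0.0, config.trial_cv)
        if base["sbr_absent"]:
            out.append(
                ResponseMeasure(
                    "SBR", s, s, None, 0.0, None, present=False, trial=1
                )
            )
        else:
            area = max(0.0, base["sbr_area"][s] * (1.0 + noise))
            out.append(
                ResponseMeasure(
                    "SBR", s, s, lat, area, None, present=True, trial=1
                )
            )
    return out


def _brer_curves(
    base: dict,
    enh: Enhancement | None,
    model: BrerModel,
    rng: np.random.Generator,
) -> dict[str, BrerCurve]:
    mu = {
        "right": base["brer_mu"] - base["brer_side"] / 2.0,
        "left": base["brer_mu"] + base["brer_side"] / 2.0,
    }
    if enh is not None:
        mu[enh.side] -= enh.brer_shift
    curves = {}
    for s in SIDES:
        ideal = model.curve(mu[s])
        recovery = {}
        for t in BRER_INTERVALS_MS:
            trials = [
                max(
                    0.0,
                    ideal[t] * (1.0 + rng.normal(0, model.trial_cv))
                    + rng.normal(0, model.trial_floor_sd),
                )
                for _ in range(model.n_trials)
            ]
            recovery[t] = sum(trials) / len(trials)
        curves[s] = BrerCurve(s, recovery)
    return curves


def _brip_measures(base: dict) -> dict[str, BripMeasure]:
    return {s: BripMeasure(s, base["brip_pct"][s]) for s in SIDES}


def _meta(scenario: Scenario | None, rng: np.random.Generator) -> SubjectMeta:
    """Plausible clinical/MRI metadata consistent with the scenario."""
    if scenario is None:
        return SubjectMeta()  # healthy control: no lesions
    if scenario.conduction is not None:
        return SubjectMeta(
            midbrain=bool(rng.random() < 0.6),
            pons=True,
            medulla=bool(rng.random() < 0.7),
            edss=float(rng.choice([1.5, 2.0, 2.5, 3.0, 3.5])),
            brainstem_fs=float(rng.choice([0.0, 1.0, 2.0])),
        )
    if scenario.enhancement is not None:
        return SubjectMeta(
            midbrain=bool(rng.random() < 0.2),
            pons=False,
            medulla=False,
            edss=float(rng.choice([0.0, 1.0, 1.5, 2.0])),
            brainstem_fs=0.0,
        )
    return SubjectMeta(
        midbrain=bool(rng.random() < 0.25),
        pons=bool(rng.random() < 0.2),
        medulla=False,
        edss=float(rng.choice([0.0, 1.0, 1.5, 2.0])),
        brainstem_fs=0.0,
    )


def _truth(subject_id: str, scenario: Scenario | None) -> GroundTruth:
    if scenario is None:
        return GroundTruth(subject_id, "healthy")
    gt = GroundTruth(subject_id, scenario.category)
    if scenario.conduction is not None:
        gt.ablat_pattern, gt.ablat_side = scenario.conduction.expected_pattern()
    if scenario.enhancement is not None:
        gt.abex_side = scenario.enhancement.side
    return gt


def _generate_subject(
    subject_id: str,
    scenario: Scenario | None,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[SubjectRecord, list[ResponseMeasure]]:
    base = _draw_base(config.healthy, rng)
    enh = scenario.enhancement if scenario else None
    lesion = scenario.conduction if scenario else None
    if enh is not None:
        _apply_enhancement(base, enh)
    trials = _tbr_trials(base, lesion, config, rng)
    trials += _sbr_trials(base, config, rng)
    brer = _brer_curves(base, enh, config.healthy.brer, rng)
    brip = _brip_measures(base)
    meta = _meta(scenario, rng)
    record = build_subject(subject_id, trials, brer, brip, meta)
    return record, trials


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate healthy controls plus scenario-perturbed patients."""
    config = config or GeneratorConfig()
    if config.n_healthy < 0 or config.n_patients < 0:
        raise ValueError("cohort sizes must be non-negative")
    scenarios = config.resolved_scenarios()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_healthy + config.n_patients)
    healthy: list[SubjectRecord] = []
    patients: list[SubjectRecord] = []
    truth: dict[str, GroundTruth] = {}
    trials: dict[str, list[ResponseMeasure]] = {}
    for i in range(config.n_healthy):
        sid = f"hs{i + 1:03d}"
        rng = np.random.default_rng(streams[i])
        record, tr = _generate_subject(sid, None, config, rng)
        healthy.append(record)
        truth[sid] = _truth(sid, None)
        trials[sid] = tr
    for j in range(config.n_patients):
        sid = f"pt{j + 1:03d}"
        rng = np.random.default_rng(streams[config.n_healthy + j])
        record, tr = _generate_subject(sid, scenarios[j], config, rng)
        patients.append(record)
        truth[sid] = _truth(sid, scenarios[j])
        trials[sid] = tr
    return Cohort(healthy, patients, truth, trials, config)


# --------------------------------------------------------------------------
# waveform rendering (inverse of the feature extractor)
# --------------------------------------------------------------------------

@dataclass
class RenderConfig:
    sampling_rate: float = 5000.0
    pre_ms: float = 25.0
    post_ms: float = 160.0
    noise_sd: float = 1.5
    ramp_ms: float = 1.0
    durations_ms: dict[str, float] = field(
        default_factory=lambda: {"R1": 6.0, "R2": 35.0, "R2c": 35.0, "SBR": 40.0}
    )
    carrier_hz: dict[str, float] = field(
        default_factory=lambda: {"R1": 250.0, "R2": 120.0, "R2c": 120.0, "SBR": 120.0}
    )
    artifact_uv: float = 400.0  # stimulus artifact spike amplitude


@dataclass
class RenderedTrial:
    stimulation_site: str
    trial: int
    traces: dict[str, EmgTrace]


def _unit_burst(
    component: str, n: int, onset_idx: int, cfg: RenderConfig
) -> np.ndarray:
    """Tukey-windowed cosine burst of unit carrier amplitude."""
    fs = cfg.sampling_rate
    dur = cfg.durations_ms[component] / 1000.0
    ramp = cfg.ramp_ms / 1000.0
    n_burst = int(round(dur * fs))
    tau = np.arange(n_burst) / fs
    env = np.ones(n_burst)
    n_ramp = max(1, int(round(ramp * fs)))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = up
    env[-n_ramp:] = np.minimum(env[-n_ramp:], up[::-1])
    burst = env * np.cos(2 * np.pi * cfg.carrier_hz[component] * tau)
    out = np.zeros(n)
    stop = min(n, onset_idx + n_burst)
    if onset_idx < 0 or stop <= onset_idx:
        raise ValueError("burst outside the rendered trace")
    out[onset_idx:stop] = burst[: stop - onset_idx]
    return out


def _render_trace(
    measures: Sequence[ResponseMeasure],
    rec_side: str,
    stimulation_site: str,
    cfg: RenderConfig,
    rng: np.random.Generator,
) -> EmgTrace:
    fs = cfg.sampling_rate
    n_pre = int(round(cfg.pre_ms / 1000.0 * fs))
    n_post = int(round(cfg.post_ms / 1000.0 * fs))
    n = n_pre + n_post + 1
    t0 = n_pre
    signal = rng.normal(0.0, cfg.noise_sd, n)
    signal[t0] += cfg.artifact_uv  # stimulus artifact at t = 0
    for m in measures:
        if not m.present or m.latency_ms is None:
            continue
        comp = m.component
        window_end = DEFAULT_WINDOWS[comp][1]
        if not (DEFAULT_WINDOWS[comp][0] <= m.latency_ms < window_end):
            raise ValueError(
                f"target {comp} latency {m.latency_ms:.1f} ms outside its "
                "search window; cannot be realised"
            )
        onset_idx = t0 + int(round(m.latency_ms / 1000.0 * fs))
        unit = _unit_burst(comp, n, onset_idx, cfg)
        if comp == "R1":
            scale = (m.amplitude_uV or 0.0) / float(np.ptp(unit))
        else:
            unit_area = float(
                np.trapezoid(np.abs(unit), dx=1000.0 / fs)
            )
            # compensate for the rectified noise integrated between the end
            # of the burst and the end of the measurement window
            span_out = max(
                0.0, (window_end - m.latency_ms) - cfg.durations_ms[comp]
            )
            target = m.area_uVms - cfg.noise_sd * _HALF_NORMAL * span_out
            if target <= 0:
                raise ValueError(
                    f"target {comp} area {m.area_uVms:.1f} µV·ms not "
                    "achievable above the noise floor"
                )
            scale = target / unit_area
        signal += scale * unit
    return EmgTrace(signal, fs, t0, rec_side, stimulation_site)


def render_waveforms(
    trials: Sequence[ResponseMeasure],
    cfg: RenderConfig,
    rng: np.random.Generator,
) -> list[RenderedTrial]:
    """Render EMG traces realising the per-trial target measures.

    Covers single-stimulus trials (TBR and SBR).  Supraorbital trials emit
    bilateral traces (R1+R2 ipsilateral, R2c contralateral); median-nerve
    trials emit the ipsilateral trace only.
    """
    rendered: list[RenderedTrial] = []
    tbr: dict[tuple[str, int], list[ResponseMeasure]] = {}
    sbr: dict[tuple[str, int], list[ResponseMeasure]] = {}
    for m in trials:
        key = (m.stim_side, m.trial or 1)
        if m.component == "SBR":
            sbr.setdefault(key, []).append(m)
        else:
            tbr.setdefault(key, []).append(m)
    for (stim_side, trial), ms in sorted(tbr.items()):
        site = f"supraorbital_{stim_side}"
        ipsi = [m for m in ms if m.component in ("R1", "R2")]
        contra = [m for m in ms if m.component == "R2c"]
        traces = {
            stim_side: _render_trace(ipsi, stim_side, site, cfg, rng),
            opposite(stim_side): _render_trace(
                contra, opposite(stim_side), site, cfg, rng
            ),
        }
        rendered.append(RenderedTrial(site, trial, traces))
    for (stim_side, trial), ms in sorted(sbr.items()):
        site = f"median_{stim_side}"
        traces = {stim_side: _render_trace(ms, stim_side, site, cfg, rng)}
        rendered.append(RenderedTrial(site, trial, traces))
    return rendered


def remeasure(
    rendered: Sequence[RenderedTrial],
    config: MeasurementConfig | None = None,
) -> list[ResponseMeasure]:
    """Run the feature extractor over rendered trials (round trip)."""
    out: list[ResponseMeasure] = []
    for rt in rendered:
        out.extend(
            measure_trial(rt.traces, rt.stimulation_site, config, rt.trial)
        )
    return out
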