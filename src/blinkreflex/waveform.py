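"""Feature extraction from surface-EMG blink-reflex traces.

Measurement conventions: response latency is the time from the stimulus
artifact to response onset; R1 size is the peak-to-peak amplitude within its
search window; R2, R2c and SBR sizes are rectified areas (µV·ms).  Traces
are assumed already band-pass filtered (20–2000 Hz) by the acquisition
hardware.

Onset detection is intentionally simple and robust: the baseline-corrected,
rectified signal is smoothed with a short trailing moving average, a burst
is detected where it exceeds ``baseline mean + k·SD`` of the pre-stimulus
baseline for a sustained minimum duration, and the reported onset is then
refined back to the point where a short centred average of the rectified
signal last sat at baseline level (two-threshold scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import math

import numpy as np

from .records import ResponseMeasure, SIDES, opposite

SUPRAORBITAL_SITES = ("supraorbital_right", "supraorbital_left")
MEDIAN_SITES = ("median_right", "median_left")
PREPULSE_SITES = ("index_finger_right", "index_finger_left")

#: Default post-stimulus search windows (ms).  They bracket the normative
#: latency limits (12.8 / 38 / 40 / 66.7 ms) with margin for pathology.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "R1": (8.0, 18.0),
    "R2": (25.0, 87.0),
    "R2c": (25.0, 87.0),
    "SBR": (35.0, 110.0),
}


@dataclass
class EmgTrace:
    """One OOc surface-EMG sweep around a single stimulus.

    ``samples`` are voltages in µV; the stimulus occurs at ``t0_index``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0_index: int
    recording_side: str
    stimulation_site: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 <= self.t0_index < self.samples.size):
            raise ValueError("t0_index outside the trace")
        if self.recording_side not in SIDES:
            raise ValueError("recording_side must be 'right' or 'left'")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_post_ms(self) -> float:
        return (self.samples.size - 1 - self.t0_index) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Sample index of post-stimulus time ``t_ms`` (rounded)."""
        return self.t0_index + int(round(t_ms / self.dt_ms))


@dataclass
class SearchWindow:
    component: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not (0 < self.start_ms < self.end_ms):
            raise ValueError("require 0 < start_ms < end_ms")


@dataclass
class OnsetConfig:
    """Parameters of the threshold-crossing onset detector.

    Detection uses a high threshold (``k`` baseline SDs) sustained for
    ``min_duration_ms``; the reported onset is then refined by walking
    back from the detection point to where the smoothed signal last sat
    below the low threshold (``k_low`` SDs) — a standard two-threshold
    scheme that removes most of the rise-time detection lag.
    """

    k: float = 4.0                 # detection threshold in baseline SDs
    k_low: float = 2.0             # onset-refinement threshold
    min_duration_ms: float = 3.0   # sustained supra-threshold time
    smooth_ms: float = 2.0         # trailing moving-average width (detection)
    refine_smooth_ms: float = 1.0  # centred moving-average width (refinement)
    max_refine_ms: float = 3.0     # how far the onset walk-back may reach
    baseline_ms: float = 20.0      # pre-stimulus baseline span
    artifact_blank_ms: float = 1.0  # blanked just before the stimulus


def _window_slice(trace: EmgTrace, window: SearchWindow) -> slice:
    i0 = trace.index_at(window.start_ms)
    i1 = trace.index_at(window.end_ms)
    if i0 < 0 or i1 > trace.samples.size - 1 or i0 >= i1:
        raise ValueError(
            f"window {window.start_ms}-{window.end_ms} ms outside trace "
            f"(post-stimulus duration {trace.duration_post_ms:.1f} ms)"
        )
    return slice(i0, i1 + 1)


def _baseline(trace: EmgTrace, config: OnsetConfig) -> np.ndarray:
    n_blank = int(round(config.artifact_blank_ms / trace.dt_ms))
    n_base = int(round(config.baseline_ms / trace.dt_ms))
    stop = trace.t0_index - n_blank
    start = stop - n_base
    if start < 0 or stop <= start:
        raise ValueError("trace too short for the configured baseline window")
    return trace.samples[start:stop]


def _smoothed_rectified(x: np.ndarray, n: int) -> np.ndarray:
    """Trailing moving average of |x| over n samples."""
    rect = np.abs(x)
    if n <= 1:
        return rect
    kernel = np.ones(n) / n
    out = np.convolve(rect, kernel, mode="full")[: rect.size]
    # leading edge: renormalise the partial sums
    head = min(n - 1, rect.size)
    out[:head] *= n / np.arange(1, head + 1)
    return out


def detect_onset(
    trace: EmgTrace,
    window: SearchWindow,
    noise_sd: float | None = None,
    config: OnsetConfig | None = None,
) -> float | None:
    """Detect the onset latency (ms post-stimulus) of a burst, or None.

    ``noise_sd`` overrides the raw baseline noise SD estimate (µV); by
    default it is estimated from the pre-stimulus baseline of the trace
    itself.
    """
    config = config or OnsetConfig()
    sl = _window_slice(trace, window)
    base = _baseline(trace, config)
    base_mean = float(base.mean())
    n_smooth = max(1, int(round(config.smooth_ms / trace.dt_ms)))
    corrected = trace.samples - base_mean
    smooth = _smoothed_rectified(corrected, n_smooth)

    base_smooth = _smoothed_rectified(base - base_mean, n_smooth)[n_smooth:]
    if base_smooth.size == 0:
        raise ValueError("baseline shorter than the smoothing window")
    # The raw-noise SD is estimated over the whole baseline (stable);
    # the SD of the smoothed rectified noise follows analytically for
    # Gaussian noise: σ·sqrt(1 − 2/π)/sqrt(W).
    sd_raw = (
        float(np.std(base - base_mean)) if noise_sd is None else float(noise_sd)
    )
    sd_smooth = sd_raw * math.sqrt(1.0 - 2.0 / math.pi) / math.sqrt(n_smooth)
    threshold = float(base_smooth.mean()) + config.k * sd_smooth

    # refinement runs on a short *centred* moving average, so that a single
    # pre-onset noise spike cannot drag the walk-back a full window early
    n_ref = max(1, int(round(config.refine_smooth_ms / trace.dt_ms)))
    rect = np.abs(corrected)
    refine = np.convolve(rect, np.ones(n_ref) / n_ref, mode="same")
    sd_ref = sd_raw * math.sqrt(1.0 - 2.0 / math.pi) / math.sqrt(n_ref)
    low_threshold = float(base_smooth.mean()) + config.k_low * sd_ref

    n_sustain = max(1, int(round(config.min_duration_ms / trace.dt_ms)))
    seg = smooth[sl]
    above = seg > threshold
    # first run of >= n_sustain consecutive supra-threshold samples
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_sustain:
            onset_idx = sl.start + i - n_sustain + 1
            # refine: walk back to the last sub-low-threshold sample
            j = onset_idx
            j_min = max(sl.start, onset_idx - int(round(
                config.max_refine_ms / trace.dt_ms)))
            while j > j_min and refine[j - 1] > low_threshold:
                j -= 1
            # the centred refinement window sees the burst half a window
            # early; compensate so steep onsets are unbiased
            j = min(onset_idx, j + n_ref // 2)
            return (j - trace.t0_index) * trace.dt_ms
    return None


def peak_to_peak(trace: EmgTrace, window: SearchWindow) -> float:
    """Peak-to-peak amplitude (µV) within the window."""
    seg = trace.samples[_window_slice(trace, window)]
    return float(seg.max() - seg.min())


def rectified_area(trace: EmgTrace, window: SearchWindow) -> float:
    """Trapezoidal integral of |voltage| over the window, in µV·ms."""
    seg = np.abs(trace.samples[_window_slice(trace, window)])
    return float(np.trapezoid(seg, dx=trace.dt_ms))


@dataclass
class MeasurementConfig:
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    onset: OnsetConfig = field(default_factory=OnsetConfig)

    def window(self, component: str) -> SearchWindow:
        start, end = self.windows[component]
        return SearchWindow(component, start, end)


def _measure_component(
    trace: EmgTrace,
    component: str,
    stim_side: str,
    config: MeasurementConfig,
    trial: int | None,
) -> ResponseMeasure:
    window = config.window(component)
    onset = detect_onset(trace, window, config=config.onset)
    base_mean = float(_baseline(trace, config.onset).mean())
    if onset is None:
        return ResponseMeasure(
            component=component,
            stim_side=stim_side,
            rec_side=trace.recording_side,
            latency_ms=None,
            area_uVms=0.0,
            amplitude_uV=None,
            present=False,
            trial=trial,
        )
    corrected = EmgTrace(
        trace.samples - base_mean,
        trace.sampling_rate,
        trace.t0_index,
        trace.recording_side,
        trace.stimulation_site,
    )
    # area from the detected onset to the end of the component window;
    # amplitude (R1) over the full window
    area = rectified_area(
        corrected, SearchWindow(component, max(onset, 1e-9), window.end_ms)
    )
    amplitude = peak_to_peak(corrected, window) if component == "R1" else None
    return ResponseMeasure(
        component=component,
        stim_side=stim_side,
        rec_side=trace.recording_side,
        latency_ms=onset,
        area_uVms=area,
        amplitude_uV=amplitude,
        present=True,
        trial=trial,
    )


def measure_trial(
    traces: Mapping[str, EmgTrace],
    stimulation_site: str,
    config: MeasurementConfig | None = None,
    trial: int | None = None,
) -> list[ResponseMeasure]:
    """Measure all components elicited by one stimulus.

    For supraorbital stimulation, emits R1 and R2 from the ipsilateral
    trace and R2c from the contralateral trace; both traces are required.
    For median-nerve stimulation, emits the SBR from the ipsilateral trace
    (first-trial convention is the caller's responsibility).
    """
    config = config or MeasurementConfig()
    if stimulation_site in SUPRAORBITAL_SITES:
        stim_side = stimulation_site.rsplit("_", 1)[1]
        ipsi = traces.get(stim_side)
        contra = traces.get(opposite(stim_side))
        if ipsi is None or contra is None:
            raise ValueError(
                "supraorbital trial requires traces from both OOc sides"
            )
        return [
            _measure_component(ipsi, "R1", stim_side, config, trial),
            _measure_component(ipsi, "R2", stim_side, config, trial),
            _measure_component(contra, "R2c", stim_side, config, trial),
        ]
    if stimulation_site in MEDIAN_SITES:
        stim_side = stimulation_site.rsplit("_", 1)[1]
        ipsi = traces.get(stim_side)
        if ipsi is None:
            raise ValueError("median-nerve trial requires the ipsilateral trace")
        return [_measure_component(ipsi, "SBR", stim_side, config, trial)]
    raise ValueError(f"unknown stimulation site: {stimulation_site!r}")
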