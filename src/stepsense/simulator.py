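"""Synthetic wrist-accelerometer recordings with known ground-truth steps.

The gait waveform is a raised-cosine pulse train riding on the 1 g gravity
baseline: one pulse per step, apex ``1 + swing_amplitude_g``, pulse width a
fixed fraction of the step period.  The magnitude is distributed across the
three axes through a fixed rotation, so the Euclidean norm of the noise-free
signal reproduces the programmed magnitude exactly.  This gives analytic
control over exactly the features the step detector's filters test: peak
height, inter-peak period, peak-to-peak similarity, and motion variance.

Non-step arm-movement artefacts are short aperiodic bursts of high-amplitude
peaks with irregular spacing; they contain zero true steps by construction.

All randomness flows from one integer seed per scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

from ._util import DataError
from .metrics import DailySummary, aggregate_epochs
from .signal_io import RawRecording
from .step_core import StepEvents, VERISENSE_2

__all__ = [
    "DeviceModel",
    "GaitBoutSpec",
    "DayScenario",
    "GroundTruth",
    "WRIST_DEVICE",
    "REFERENCE_DEVICE",
    "simulate_bout",
    "simulate_artefacts",
    "simulate_day",
    "simulate_reference_device",
]

#: fraction of the step period occupied by each half of the raised-cosine pulse
PULSE_HALF_WIDTH_FRACTION = 0.45

#: relative asymmetry between the rising and falling pulse flanks.  Real gait
#: impacts load faster than they unload; structurally this also guarantees the
#: sampled waveform has a strict maximum (a perfectly symmetric pulse whose
#: apex falls midway between two samples would tie and defeat peak detection).
PULSE_SKEW = 0.2

#: continuous low-amplitude oscillation present throughout a gait bout,
#: emulating the broadband arm movement that accompanies stepping.  At 5 Hz
#: (3 samples per cycle on a 15 Hz grid) every 4-sample window sees a full
#: cycle, so in-bout motion variance never collapses at pulse apexes/troughs;
#: the amplitude stays well below the step magnitude thresholds so the
#: texture itself produces no countable peaks.
TEXTURE_FREQ_HZ = 5.0
TEXTURE_AMPLITUDE_RATIO = 0.45
TEXTURE_MAX_G = 0.18

#: fixed rotation distributing the magnitude across axes (unit column vector)
_AXIS_DIRECTION = np.array([0.36, -0.48, 0.80])  # 0.36² + 0.48² + 0.80² = 1


@dataclass(frozen=True)
class DeviceModel:
    sample_rate_hz: float
    dynamic_range_g: float
    label: str = ""


WRIST_DEVICE = DeviceModel(sample_rate_hz=100.0, dynamic_range_g=8.0, label="wrist")
REFERENCE_DEVICE = DeviceModel(sample_rate_hz=20.0, dynamic_range_g=2.0, label="thigh-reference")


@dataclass(frozen=True)
class GaitBoutSpec:
    """One continuous stepping bout at a programmed cadence."""

    cadence_spm: float
    duration_s: float
    swing_amplitude_g: float = 0.6
    harmonic_ratio: float = 0.0
    phase_jitter_sd: float = 0.0  # seconds

    def __post_init__(self) -> None:
        if not 20.0 < self.cadence_spm < 240.0:
            raise DataError("cadence must be in (20, 240) steps/min")
        if not self.duration_s > 0:
            raise DataError("duration_s must be positive")
        if self.swing_amplitude_g < 0:
            raise DataError("swing_amplitude_g must be non-negative")
        if not 0.0 <= self.harmonic_ratio <= 1.0:
            raise DataError("harmonic_ratio must lie in [0, 1]")

    @property
    def programmed_steps(self) -> int:
        return int(round(self.cadence_spm * self.duration_s / 60.0))


@dataclass
class DayScenario:
    """Bouts with start offsets, artefacts, noise, and device settings."""

    bouts: list[tuple[float, GaitBoutSpec]] = field(default_factory=list)  # (start offset s, spec)
    artefact_rate_per_hour: float = 0.0
    artefact_amplitude_g: float = 2.0
    noise_sd_g: float = 0.0
    device: DeviceModel = WRIST_DEVICE
    seed: int = 0
    start_time: datetime = datetime(2022, 1, 3, 0, 0, 0)
    duration_s: float = 86_400.0

    def __post_init__(self) -> None:
        if self.duration_s > 86_400.0:
            raise DataError("scenario span cannot exceed 24 h")
        spans = sorted((off, off + b.duration_s) for off, b in self.bouts)
        for (_, prev_end), (nxt_start, _) in zip(spans, spans[1:]):
            if nxt_start < prev_end:
                raise DataError("bouts overlap")
        for off, b in self.bouts:
            if off < 0 or off + b.duration_s > self.duration_s:
                raise DataError("bout extends beyond the scenario span")


@dataclass
class GroundTruth:
    """Programmed step times and the daily totals they imply."""

    step_times: pd.DatetimeIndex
    daily_total: int
    daily_mvpa: int

    def __post_init__(self) -> None:
        if self.daily_total != len(self.step_times):
            raise DataError("daily_total must equal the number of step times")
        if self.daily_mvpa > self.daily_total:
            raise DataError("daily_mvpa cannot exceed daily_total")

    def to_json(self) -> str:
        return json.dumps(
            {
                "step_times": [t.isoformat() for t in self.step_times],
                "daily_total": self.daily_total,
                "daily_mvpa": self.daily_mvpa,
            },
            indent=2,
        )


def _pulse_magnitude(
    t: np.ndarray, step_times_s: np.ndarray, spec: GaitBoutSpec, sample_rate_hz: float
) -> np.ndarray:
    """Noise-free magnitude (g) of a pulse train evaluated at uniform times ``t``.

    Each pulse only touches the samples within its half-width, so the cost is
    O(total pulse samples), not O(steps x samples).
    """
    period = 60.0 / spec.cadence_spm
    half_width = PULSE_HALF_WIDTH_FRACTION * period
    rise = half_width * (1.0 - PULSE_SKEW)
    fall = half_width * (1.0 + PULSE_SKEW)
    mag = np.zeros_like(t)
    n = t.size
    reach = int(np.ceil(fall * sample_rate_hz)) + 1
    for ts in step_times_s:
        centre = int(round(ts * sample_rate_hz))
        lo = max(centre - reach, 0)
        hi = min(centre + reach + 1, n)
        if lo >= hi:
            continue
        dt = t[lo:hi] - ts
        u = np.where(dt < 0, dt / rise, dt / fall)
        inside = np.abs(u) < 1.0
        base = 0.5 * (1.0 + np.cos(np.pi * u[inside]))
        shaped = (1.0 - spec.harmonic_ratio) * base + spec.harmonic_ratio * base * base
        seg = mag[lo:hi]
        seg[inside] += spec.swing_amplitude_g * shaped
    texture = min(TEXTURE_AMPLITUDE_RATIO * spec.swing_amplitude_g, TEXTURE_MAX_G)
    if texture > 0:
        mag += texture * np.sin(2.0 * np.pi * TEXTURE_FREQ_HZ * t)
    return 1.0 + mag


def simulate_bout(
    spec: GaitBoutSpec,
    device: DeviceModel = WRIST_DEVICE,
    rng: np.random.Generator | None = None,
    noise_sd_g: float = 0.0,
    start_time: datetime = datetime(2022, 1, 3, 12, 0, 0),
) -> tuple[RawRecording, pd.DatetimeIndex]:
    """Simulate one gait bout; returns the recording and exact step times.

    Step ``i`` is programmed at ``(i + 0.5) * period`` (plus optional Gaussian
    phase jitter) so pulses sit clear of the bout edges.
    """
    if spec.swing_amplitude_g > device.dynamic_range_g - 1.0:
        raise DataError(
            f"swing amplitude {spec.swing_amplitude_g} g would clip on a "
            f"±{device.dynamic_range_g} g device"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(round(spec.duration_s * device.sample_rate_hz))
    t = np.arange(n) / device.sample_rate_hz
    period = 60.0 / spec.cadence_spm
    steps_s = (np.arange(spec.programmed_steps) + 0.5) * period
    if spec.phase_jitter_sd > 0:
        steps_s = steps_s + rng.normal(0.0, spec.phase_jitter_sd, steps_s.size)
        steps_s = np.sort(np.clip(steps_s, 0.0, spec.duration_s))
    mag = _pulse_magnitude(t, steps_s, spec, device.sample_rate_hz)
    samples = mag[:, None] * _AXIS_DIRECTION[None, :]
    if noise_sd_g > 0:
        samples = samples + rng.normal(0.0, noise_sd_g, samples.shape)
    np.clip(samples, -device.dynamic_range_g, device.dynamic_range_g, out=samples)
    recording = RawRecording(
        start_time=start_time,
        sample_rate_hz=device.sample_rate_hz,
        samples=samples,
        dynamic_range_g=device.dynamic_range_g,
        device_label=device.label,
    )
    times = pd.Timestamp(start_time) + pd.to_timedelta(steps_s, unit="s")
    return recording, pd.DatetimeIndex(times)


def simulate_artefacts(
    rate_per_hour: float,
    amplitude_g: float,
    span_s: float,
    rng: np.random.Generator,
    sample_rate_hz: float = 100.0,
) -> list[tuple[int, np.ndarray]]:
    """Aperiodic arm-movement bursts containing zero true steps.

    Returns ``(start_sample, magnitude_increment)`` pairs to add onto a day's
    magnitude baseline.  Each burst holds 3-6 sharp peaks with irregular
    0.05-0.2 s spacing — too close together to pass a periodicity filter
    tuned to human stepping, and dissimilar in height.
    """
    if rate_per_hour < 0:
        raise DataError("artefact rate must be non-negative")
    n_bursts = rng.poisson(rate_per_hour * span_s / 3600.0)
    increments: list[tuple[int, np.ndarray]] = []
    for _ in range(n_bursts):
        burst_start = rng.uniform(0.0, max(span_s - 2.0, 0.0))
        n_peaks = int(rng.integers(3, 7))
        gaps = rng.uniform(0.05, 0.2, n_peaks)
        peak_times = burst_start + np.cumsum(gaps)
        heights = amplitude_g * rng.uniform(0.4, 1.0, n_peaks)
        length = int(round((peak_times[-1] - burst_start + 0.3) * sample_rate_hz))
        t = burst_start + np.arange(length) / sample_rate_hz
        inc = np.zeros(length)
        for pt, h in zip(peak_times, heights):
            u = (t - pt) / 0.04  # 40 ms spike half-width
            inside = np.abs(u) < 1.0
            inc[inside] += h * 0.5 * (1.0 + np.cos(np.pi * u[inside]))
        increments.append((int(round(burst_start * sample_rate_hz)), inc))
    return increments


def simulate_day(scenario: DayScenario) -> tuple[RawRecording, GroundTruth]:
    """Rest baseline + gait bouts + artefacts over the scenario span.

    Ground-truth MVPA steps are the programmed steps falling in 5-s epochs
    whose programmed cadence reaches 100 steps/min.
    """
    rng = np.random.default_rng(scenario.seed)
    device = scenario.device
    n = int(round(scenario.duration_s * device.sample_rate_hz))
    magnitude = np.ones(n)

    all_steps: list[pd.Timestamp] = []
    for offset_s, spec in sorted(scenario.bouts):
        seg_n = int(round(spec.duration_s * device.sample_rate_hz))
        start_idx = int(round(offset_s * device.sample_rate_hz))
        t = np.arange(seg_n) / device.sample_rate_hz
        period = 60.0 / spec.cadence_spm
        steps_s = (np.arange(spec.programmed_steps) + 0.5) * period
        if spec.phase_jitter_sd > 0:
            steps_s = steps_s + rng.normal(0.0, spec.phase_jitter_sd, steps_s.size)
            steps_s = np.sort(np.clip(steps_s, 0.0, spec.duration_s))
        magnitude[start_idx : start_idx + seg_n] = _pulse_magnitude(
            t, steps_s, spec, device.sample_rate_hz
        )
        base = pd.Timestamp(scenario.start_time) + pd.Timedelta(seconds=offset_s)
        all_steps.extend(base + pd.to_timedelta(steps_s, unit="s"))

    for start_idx, inc in simulate_artefacts(
        scenario.artefact_rate_per_hour,
        scenario.artefact_amplitude_g,
        scenario.duration_s,
        rng,
        sample_rate_hz=device.sample_rate_hz,
    ):
        stop = min(start_idx + inc.size, n)
        magnitude[start_idx:stop] += inc[: stop - start_idx]

    samples = magnitude[:, None] * _AXIS_DIRECTION[None, :]
    if scenario.noise_sd_g > 0:
        samples = samples + rng.normal(0.0, scenario.noise_sd_g, samples.shape)
    if np.abs(samples).max() > device.dynamic_range_g:
        np.clip(samples, -device.dynamic_range_g, device.dynamic_range_g, out=samples)

    recording = RawRecording(
        start_time=scenario.start_time,
        sample_rate_hz=device.sample_rate_hz,
        samples=samples,
        dynamic_range_g=device.dynamic_range_g,
        device_label=device.label,
    )
    step_index = pd.DatetimeIndex(sorted(all_steps))
    # ground-truth MVPA is defined by the *programmed* bout cadence, not the
    # realized integer epoch counts (a bout at exactly 100 steps/min would
    # otherwise alternate 8- and 9-step epochs and lose half its steps)
    mvpa = sum(
        spec.programmed_steps for _, spec in scenario.bouts if spec.cadence_spm >= 100.0
    )
    truth = GroundTruth(
        step_times=step_index,
        daily_total=len(step_index),
        daily_mvpa=mvpa,
    )
    return recording, truth


def simulate_reference_device(
    truth: GroundTruth,
    error_model: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    day: date | None = None,
    epoch_length_s: float = 5.0,
) -> DailySummary:
    """Daily totals of an imperfect thigh-worn comparator.

    ``error_model = (miss_below_cadence_spm, random_miss_rate)``: steps in
    epochs whose cadence is below the floor are never detected, and every
    remaining step is independently missed with the given probability.
    """
    floor_spm, miss_rate = error_model
    if not 0.0 <= miss_rate <= 1.0:
        raise DataError("random_miss_rate must lie in [0, 1]")
    if floor_spm < 0:
        raise DataError("miss_below_cadence_spm must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(0)

    if len(truth.step_times) == 0:
        today = day or date(2022, 1, 3)
        return DailySummary(date=today, total_steps=0, mvpa_steps=0)

    events = StepEvents(times=truth.step_times, source_params=VERISENSE_2)
    series = aggregate_epochs(events, epoch_length_s=epoch_length_s)
    cadence_ok = series.cadence_spm >= floor_spm
    detected = series.steps.copy()
    detected[~cadence_ok] = 0
    if miss_rate > 0:
        detected = rng.binomial(detected, 1.0 - miss_rate)
    mvpa_mask = series.is_mvpa
    total = int(detected.sum())
    mvpa = int(detected[mvpa_mask].sum())
    return DailySummary(
        date=(day or truth.step_times[0].date()),
        total_steps=total,
        mvpa_steps=mvpa,
    )
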