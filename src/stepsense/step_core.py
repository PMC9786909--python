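"""Wrist step-count algorithm: peak detection plus staged artefact filters.

The detector operates on the Euclidean-norm magnitude signal (gravity
included) resampled to a fixed algorithm rate, and applies four filters in a
frozen order:

1. magnitude  — peak height must reach ``magnitude_threshold_g``;
2. periodicity — the sample gap to the previously retained peak must lie in
   ``[min_period_samples, max_period_samples]`` (closed interval);
3. similarity — a peak must be within ``|similarity_threshold_g|`` g of the
   height of at least one neighbouring peak;
4. continuity — enough of the fixed-size windows around the peak must be "in
   motion", i.e. have sample variance above ``variance_threshold_g2``.

Two parameter presets ship with the package (``VERISENSE_1``, the original
published thresholds, and ``VERISENSE_2``, the bias-optimized revision); see
``presets/*.json`` for the same values in serialized form.

Conventions frozen for reproducibility (dialect switches, not tunables):

* the algorithm rate is 15 Hz; all "samples" thresholds are in 15 Hz samples,
  so the periodicity windows correspond to 45-225 steps/min;
* a candidate peak is a *strict* maximum over a symmetric ±k sample window;
  plateaus produce no peak;
* periodicity gaps are measured to the previously *retained* peak; the first
  peak of a run seeds the chain and is kept only if a compliant gap follows;
* continuity examines the 2·m windows centred on the peak's own window
  (m on each side, the peak's window excluded); windows beyond the signal
  count as not in motion;
* window variance is the population variance (divisor n).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._util import DataError, EmptyInputError
from .signal_io import MagnitudeSeries, RawRecording, resample_magnitude, vector_magnitude

__all__ = [
    "StepParameters",
    "PeakList",
    "StepEvents",
    "VERISENSE_1",
    "VERISENSE_2",
    "load_preset",
    "find_candidate_peaks",
    "filter_magnitude",
    "filter_periodicity",
    "filter_similarity",
    "filter_continuity",
    "count_steps",
    "naive_count_steps",
]

#: frequency the detector operates at; "samples" thresholds are in these units
DEFAULT_ALGORITHM_RATE_HZ = 15.0


@dataclass(frozen=True)
class StepParameters:
    """One algorithm variant: the eight detector thresholds plus the rate."""

    peak_win_samples: int
    min_period_samples: int
    max_period_samples: int
    similarity_threshold_g: float
    continuity_window_samples: int
    continuity_count_threshold: int
    variance_threshold_g2: float
    magnitude_threshold_g: float
    algorithm_rate_hz: float = DEFAULT_ALGORITHM_RATE_HZ
    name: str = field(default="", compare=False)  # label only, not an algorithm input

    def __post_init__(self) -> None:
        if self.min_period_samples > self.max_period_samples:
            raise DataError("min_period_samples must be <= max_period_samples")
        if self.similarity_threshold_g > 0:
            raise DataError("similarity_threshold_g must be <= 0")
        for attr in (
            "peak_win_samples",
            "min_period_samples",
            "max_period_samples",
            "continuity_window_samples",
            "continuity_count_threshold",
            "variance_threshold_g2",
            "magnitude_threshold_g",
            "algorithm_rate_hz",
        ):
            if not getattr(self, attr) > 0:
                raise DataError(f"{attr} must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


VERISENSE_1 = StepParameters(
    peak_win_samples=3,
    min_period_samples=5,
    max_period_samples=15,
    similarity_threshold_g=-0.5,
    continuity_window_samples=4,
    continuity_count_threshold=4,
    variance_threshold_g2=0.001,
    magnitude_threshold_g=1.2,
    name="verisense1",
)

VERISENSE_2 = StepParameters(
    peak_win_samples=4,
    min_period_samples=4,
    max_period_samples=20,
    similarity_threshold_g=-1.0,
    continuity_window_samples=4,
    continuity_count_threshold=4,
    variance_threshold_g2=0.01,
    magnitude_threshold_g=1.25,
    name="verisense2",
)

_PRESETS = {"verisense1": VERISENSE_1, "verisense2": VERISENSE_2}


def load_preset(name_or_path: str) -> StepParameters:
    """Resolve a preset name (``verisense1``/``verisense2``) or a JSON path."""
    key = name_or_path.lower()
    if key in _PRESETS:
        return _PRESETS[key]
    with open(name_or_path) as fh:
        payload = json.load(fh)
    return StepParameters(**payload)


@dataclass
class PeakList:
    """Candidate (or filtered) peaks: sample indices plus their heights."""

    indices: np.ndarray  # strictly increasing sample indices
    heights_g: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.heights_g = np.asarray(self.heights_g, dtype=float)
        if self.indices.shape != self.heights_g.shape:
            raise DataError("indices and heights must have equal length")
        if self.indices.size > 1 and not (np.diff(self.indices) > 0).all():
            raise DataError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def take(self, mask_or_positions) -> "PeakList":
        return PeakList(self.indices[mask_or_positions], self.heights_g[mask_or_positions])


@dataclass
class StepEvents:
    """Timestamps of counted steps plus the parameters that produced them."""

    times: pd.DatetimeIndex
    source_params: StepParameters

    def __len__(self) -> int:
        return len(self.times)

    @property
    def count(self) -> int:
        return len(self.times)


def find_candidate_peaks(mag: MagnitudeSeries, peak_win_samples: int) -> PeakList:
    """Strict local maxima over a symmetric ±k window.

    Index ``i`` is a candidate iff ``mag[i] > mag[j]`` for every ``j`` in
    ``[i-k, i+k], j != i``.  Indices within ``k`` of either end are never
    candidates; plateau ties yield no candidate.
    """
    values = mag.values_g
    n = values.size
    k = int(peak_win_samples)
    if n <= 2 * k:
        warnings.warn("magnitude series too short for peak detection")
        return PeakList(np.empty(0, dtype=np.int64), np.empty(0))
    is_peak = np.ones(n - 2 * k, dtype=bool)  # interior indices k .. n-k-1
    centre = values[k : n - k]
    for offset in range(1, k + 1):
        is_peak &= centre > values[k - offset : n - k - offset]
        is_peak &= centre > values[k + offset : n - k + offset]
    idx = np.nonzero(is_peak)[0] + k
    return PeakList(idx, values[idx])


def filter_magnitude(peaks: PeakList, magnitude_threshold_g: float) -> PeakList:
    """Retain peaks whose height reaches the magnitude threshold."""
    return peaks.take(peaks.heights_g >= magnitude_threshold_g)


def filter_periodicity(
    peaks: PeakList, min_period_samples: int, max_period_samples: int
) -> PeakList:
    """Retain peaks forming chains of compliant inter-peak gaps.

    A peak is retained iff its index gap to the previously retained peak lies
    in the closed interval ``[min_period_samples, max_period_samples]``.  A
    non-compliant gap breaks the chain and the offending peak becomes the
    tentative seed of a new chain; seeds are retained only once a compliant
    gap follows them.
    """
    if min_period_samples > max_period_samples:
        raise DataError("min_period_samples must be <= max_period_samples")
    keep: list[int] = []
    seed: int | None = None  # position of an unconfirmed chain seed
    tail: int | None = None  # position of the last retained peak
    for pos in range(len(peaks)):
        if tail is None and seed is None:
            seed = pos
            continue
        anchor = tail if tail is not None else seed
        gap = int(peaks.indices[pos] - peaks.indices[anchor])
        if min_period_samples <= gap <= max_period_samples:
            if tail is None:
                keep.append(seed)
            keep.append(pos)
            tail = pos
            seed = None
        else:
            tail = None
            seed = pos
    return peaks.take(np.asarray(keep, dtype=np.int64))


def filter_similarity(peaks: PeakList, similarity_threshold_g: float) -> PeakList:
    """Retain peaks similar in height to at least one neighbouring peak.

    Consecutive peaks (p, q) are similar iff ``-|height(p) - height(q)| >=
    similarity_threshold_g`` (the threshold is non-positive), i.e. their
    height difference is at most ``|threshold|``.
    """
    n = len(peaks)
    if n == 0:
        return peaks.take(np.empty(0, dtype=np.int64))
    diffs = np.abs(np.diff(peaks.heights_g))
    pair_ok = -diffs >= similarity_threshold_g
    keep = np.zeros(n, dtype=bool)
    keep[:-1] |= pair_ok
    keep[1:] |= pair_ok
    return peaks.take(keep)


def _window_motion(values: np.ndarray, window_samples: int, variance_threshold_g2: float) -> np.ndarray:
    """Per consecutive window of ``window_samples``: population variance > threshold."""
    n_windows = values.size // window_samples
    tail = values.size - n_windows * window_samples
    blocks = values[: n_windows * window_samples].reshape(n_windows, window_samples)
    motion = blocks.var(axis=1) > variance_threshold_g2
    if tail:  # trailing partial window judged on its own samples
        motion = np.append(motion, values[-tail:].var() > variance_threshold_g2)
    return motion


def filter_continuity(
    peaks: PeakList,
    mag: MagnitudeSeries,
    continuity_window_samples: int,
    continuity_count_threshold: int,
    variance_threshold_g2: float,
) -> PeakList:
    """Retain peaks surrounded by enough in-motion windows.

    The signal is partitioned into consecutive windows of
    ``continuity_window_samples``; a window is in motion iff its population
    variance exceeds ``variance_threshold_g2``.  A peak in window ``j`` is
    retained iff at least ``continuity_count_threshold`` of the 2·m windows
    ``j-m .. j+m`` (excluding ``j`` itself, m = continuity_count_threshold)
    are in motion.  Windows beyond either end count as not in motion.
    """
    if len(peaks) == 0:
        return peaks.take(np.empty(0, dtype=np.int64))
    motion = _window_motion(mag.values_g, continuity_window_samples, variance_threshold_g2)
    m = int(continuity_count_threshold)
    n_windows = motion.size
    keep = np.zeros(len(peaks), dtype=bool)
    for pos, idx in enumerate(peaks.indices):
        j = int(idx) // continuity_window_samples
        count = 0
        for off in range(-m, m + 1):
            if off == 0:
                continue
            w = j + off
            if 0 <= w < n_windows and motion[w]:
                count += 1
        keep[pos] = count >= m
    return peaks.take(keep)


def _detect_on_magnitude(mag15: MagnitudeSeries, params: StepParameters) -> PeakList:
    """Full filter chain on an already-resampled magnitude series."""
    peaks = find_candidate_peaks(mag15, params.peak_win_samples)
    peaks = filter_magnitude(peaks, params.magnitude_threshold_g)
    peaks = filter_periodicity(peaks, params.min_period_samples, params.max_period_samples)
    peaks = filter_similarity(peaks, params.similarity_threshold_g)
    peaks = filter_continuity(
        peaks,
        mag15,
        params.continuity_window_samples,
        params.continuity_count_threshold,
        params.variance_threshold_g2,
    )
    return peaks


def _events_from_peaks(peaks: PeakList, mag15: MagnitudeSeries, params: StepParameters) -> StepEvents:
    offsets = peaks.indices / mag15.sample_rate_hz
    times = pd.Timestamp(mag15.start_time) + pd.to_timedelta(offsets, unit="s")
    return StepEvents(times=pd.DatetimeIndex(times), source_params=params)


def count_steps(recording: RawRecording, params: StepParameters = VERISENSE_2) -> StepEvents:
    """Count steps in a raw recording; one time-stamped event per retained peak.

    Pipeline: vector magnitude -> linear resample to ``params.algorithm_rate_hz``
    -> candidate peaks -> magnitude -> periodicity -> similarity -> continuity.
    Deterministic for fixed input and parameters.
    """
    if recording.n_samples == 0:
        raise EmptyInputError("recording has no samples")
    mag = vector_magnitude(recording)
    min_len = max(2, params.continuity_window_samples)
    if recording.duration_s * params.algorithm_rate_hz < min_len or recording.n_samples < 2:
        warnings.warn("recording shorter than one continuity window; 0 steps")
        return StepEvents(pd.DatetimeIndex([]), params)
    mag15 = resample_magnitude(mag, params.algorithm_rate_hz)
    peaks = _detect_on_magnitude(mag15, params)
    return _events_from_peaks(peaks, mag15, params)


# ---------------------------------------------------------------------------
# Reference implementation (test oracle): same contract, plain Python loops,
# no shared code with the fast path beyond the parameter dataclass.
# ---------------------------------------------------------------------------


def naive_count_steps(recording: RawRecording, params: StepParameters = VERISENSE_2) -> StepEvents:
    """Loop-based reference implementation of :func:`count_steps` (tests only)."""
    if recording.n_samples == 0:
        raise EmptyInputError("recording has no samples")
    n = recording.n_samples
    src_rate = recording.sample_rate_hz

    mag = [
        math.sqrt(
            recording.samples[i, 0] * recording.samples[i, 0]
            + recording.samples[i, 1] * recording.samples[i, 1]
            + recording.samples[i, 2] * recording.samples[i, 2]
        )
        for i in range(n)
    ]
    min_len = max(2, params.continuity_window_samples)
    if (n / src_rate) * params.algorithm_rate_hz < min_len or n < 2:
        warnings.warn("recording shorter than one continuity window; 0 steps")
        return StepEvents(pd.DatetimeIndex([]), params)

    # linear interpolation onto the algorithm grid (same formula as np.interp)
    rate = params.algorithm_rate_hz
    src_t = [i / src_rate for i in range(n)]
    n_out = int(math.floor(src_t[-1] * rate)) + 1
    sig: list[float] = []
    j = 0
    for k in range(n_out):
        t = k / rate
        while j < n - 2 and src_t[j + 1] <= t:
            j += 1
        slope = (mag[j + 1] - mag[j]) / (src_t[j + 1] - src_t[j])
        sig.append(slope * (t - src_t[j]) + mag[j])

    # strict local maxima over ±k
    k = params.peak_win_samples
    peaks: list[int] = []
    for i in range(k, n_out - k):
        if all(sig[i] > sig[i + d] for d in range(-k, k + 1) if d != 0):
            peaks.append(i)

    # magnitude
    peaks = [p for p in peaks if sig[p] >= params.magnitude_threshold_g]

    # periodicity (chain to previously retained peak, seeds need confirmation)
    retained: list[int] = []
    seed: int | None = None
    tail: int | None = None
    for p in peaks:
        if tail is None and seed is None:
            seed = p
            continue
        anchor = tail if tail is not None else seed
        if params.min_period_samples <= p - anchor <= params.max_period_samples:
            if tail is None:
                retained.append(seed)
            retained.append(p)
            tail = p
            seed = None
        else:
            tail = None
            seed = p
    peaks = retained

    # similarity (vs either neighbouring peak)
    kept: list[int] = []
    for i, p in enumerate(peaks):
        ok = False
        if i > 0 and -abs(sig[p] - sig[peaks[i - 1]]) >= params.similarity_threshold_g:
            ok = True
        if i < len(peaks) - 1 and -abs(sig[p] - sig[peaks[i + 1]]) >= params.similarity_threshold_g:
            ok = True
        if ok:
            kept.append(p)
    peaks = kept

    # continuity
    w = params.continuity_window_samples
    m = params.continuity_count_threshold
    n_windows = n_out // w + (1 if n_out % w else 0)

    def window_in_motion(widx: int) -> bool:
        lo = widx * w
        hi = min(lo + w, n_out)
        vals = sig[lo:hi]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / len(vals)
        return var > params.variance_threshold_g2

    final: list[int] = []
    for p in peaks:
        jw = p // w
        count = 0
        for off in range(-m, m + 1):
            if off == 0:
                continue
            widx = jw + off
            if 0 <= widx < n_windows and window_in_motion(widx):
                count += 1
        if count >= m:
            final.append(p)

    times = pd.Timestamp(recording.start_time) + pd.to_timedelta(
        [p / rate for p in final], unit="s"
    )
    return StepEvents(times=pd.DatetimeIndex(times), source_params=params)
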