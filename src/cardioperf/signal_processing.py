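"""Beat detection and frequency extraction from densitometric traces.

Converts a raw optical trace into beat times (peak picking with a
prominence threshold and a refractory constraint) and then into a binned
contraction-frequency :class:`~cardioperf.core_io.Recording`.

The peak selection rule is deterministic: all strict local maxima whose
prominence reaches ``min_prominence`` are considered, ordered by amplitude
(ties broken by earlier time), and accepted greedily subject to the
refractory spacing.  Beat times are refined by parabolic interpolation of
the apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import peak_prominences

from .core_io import Recording, RecordingMeta, Trace, ValidationError

__all__ = ["DetectionParams", "BeatSet", "detect_beats", "frequency_from_beats"]


@dataclass(frozen=True)
class DetectionParams:
    min_prominence: float = 0.5  # signal units
    refractory: float = 0.2  # s, minimal accepted inter-beat spacing
    smoothing_width: float = 0.0  # s, moving-mean width; 0 = off

    def __post_init__(self) -> None:
        if self.refractory <= 0:
            raise ValidationError("refractory must be > 0")
        if self.min_prominence < 0 or self.smoothing_width < 0:
            raise ValidationError("detection parameters must be >= 0")


@dataclass(frozen=True)
class BeatSet:
    beat_times: np.ndarray  # s, strictly increasing
    detection_params: DetectionParams | None = None

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        if bt.size and np.any(np.diff(bt) <= 0):
            raise ValidationError("beat times must be strictly increasing")
        if self.detection_params is not None and bt.size >= 2:
            if np.min(np.diff(bt)) < self.detection_params.refractory - 1e-9:
                raise ValidationError("beat intervals violate the refractory constraint")

    def __len__(self) -> int:
        return int(self.beat_times.size)


def _moving_mean(x: np.ndarray, width_samples: int) -> np.ndarray:
    if width_samples <= 1:
        return x
    if width_samples % 2 == 0:
        width_samples += 1
    kernel = np.ones(width_samples) / width_samples
    pad = width_samples // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _parabolic_apex(x: np.ndarray, i: int, sample_rate: float) -> float:
    """Sub-sample apex time around index ``i`` via a 3-point parabola."""
    if i == 0 or i == x.size - 1:
        return i / sample_rate
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom >= 0:  # flat or non-concave neighbourhood; keep the sample
        return i / sample_rate
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return (i + delta) / sample_rate


def detect_beats(trace: Trace, params: DetectionParams | None = None) -> BeatSet:
    """Pick beats from a trace.

    Raises if the refractory period is not shorter than the trace itself.
    """
    params = params or DetectionParams()
    if params.refractory >= trace.duration:
        raise ValidationError(f"refractory {params.refractory}s >= trace duration {trace.duration}s")
    x = trace.values
    if params.smoothing_width > 0:
        x = _moving_mean(x, int(round(params.smoothing_width * trace.sample_rate)))
    if x.size < 3:
        return BeatSet(np.empty(0), params)

    interior = np.arange(1, x.size - 1)
    is_max = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
    candidates = interior[is_max]
    if candidates.size == 0:
        return BeatSet(np.empty(0), params)
    prominences = peak_prominences(x, candidates)[0]
    keep = prominences >= params.min_prominence
    candidates = candidates[keep]
    if candidates.size == 0:
        return BeatSet(np.empty(0), params)

    # greedy: highest amplitude first, earlier sample wins ties; the
    # refractory spacing is enforced on the interpolated apex times
    apex = {int(i): _parabolic_apex(x, int(i), trace.sample_rate) for i in candidates}
    order = sorted(range(candidates.size), key=lambda j: (-x[candidates[j]], candidates[j]))
    accepted: list[float] = []
    for j in order:
        t = apex[int(candidates[j])]
        if all(abs(t - a) >= params.refractory for a in accepted):
            accepted.append(t)
    return BeatSet(np.sort(np.asarray(accepted)), params)


def frequency_from_beats(
    beats: BeatSet,
    bin_minutes: float = 0.5,
    span: tuple[float, float] | None = None,
    trace_duration_s: float | None = None,
    meta: RecordingMeta | None = None,
) -> Recording:
    """Bin beat times into a contraction-frequency recording.

    ``span`` is in minutes; default covers ``[0, trace_duration]`` (or the
    last beat).  Per-bin frequency is the beat count scaled to
    contractions/min; a partial terminal bin is scaled by its actual width.
    Bin timestamps are the bin midpoints.
    """
    if bin_minutes <= 0:
        raise ValidationError("bin width must be > 0")
    beats_min = beats.beat_times / 60.0
    if span is None:
        end = trace_duration_s / 60.0 if trace_duration_s is not None else (float(beats_min[-1]) if len(beats) else bin_minutes)
        span = (0.0, end)
    t0, t1 = span
    if t1 <= t0:
        raise ValidationError("empty span")
    if trace_duration_s is not None and (t0 < -1e-9 or t1 > trace_duration_s / 60.0 + 1e-9):
        raise ValidationError(f"span {span} outside trace duration {trace_duration_s / 60:g} min")

    edges = [t0]
    while edges[-1] + bin_minutes < t1 - 1e-12:
        edges.append(edges[-1] + bin_minutes)
    edges.append(t1)
    edges_arr = np.asarray(edges)
    widths = np.diff(edges_arr)
    ok = widths > 1e-12
    counts, _ = np.histogram(beats_min, bins=edges_arr)
    freqs = counts[ok] / widths[ok]
    mids = (edges_arr[:-1] + edges_arr[1:])[ok] / 2.0
    return Recording(mids, freqs, meta or RecordingMeta(preparation_id="beats"))
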