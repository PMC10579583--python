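"""Stride segmentation and representative-stride selection from vertical GRF.

The representative stride of a trial is found in six steps: (1) segment
strides at a 25 N threshold on the vertical GRF (foot-strike = upward
crossing, toe-off = downward crossing); (2) resample every stride to 100
equidistant values; (3) take the pointwise median across strides; (4) take
each stride's absolute deviation from that median profile; (5) integrate the
deviation over normalized stride time (the functional median distance, FMD
depth); (6) select the stride with the smallest depth.  Spatiotemporal
parameters (stance duration, stride duration/length, normalized stride
length) are measured on the selected stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, lfilter


@dataclass
class Stride:
    """One segmented stride: foot-strike to the next foot-strike (half-open)."""

    source_trial_id: str
    start_time: float  # s, interpolated foot-strike
    duration: float  # s
    stance_duration: float  # s, time above threshold within the stride
    raw_time: np.ndarray  # native samples covering the stride (with 1 pad each side)
    raw_grf: np.ndarray
    grf_resampled: np.ndarray | None = field(default=None)


@dataclass
class MedianProfile:
    values: np.ndarray  # pointwise medians, same units as the strides


@dataclass
class DepthResult:
    depths: np.ndarray  # per-stride FMD depth
    selected_index: int


@dataclass
class SpatiotemporalSummary:
    stance_duration: float  # s
    stride_duration: float  # s
    stride_length: float  # m
    normalized_stride_length: float  # stride length / body height


def lowpass_filter(
    signal: np.ndarray,
    sampling_rate: float,
    cutoff: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Fourth-order Butterworth low-pass; zero-phase (forward-backward) by
    default, causal single-pass with ``zero_phase=False``.

    The order refers to the underlying filter design; forward-backward
    application doubles the effective attenuation order (standard practice for
    gait signals, avoiding phase lag at stride boundaries).
    """
    nyquist = sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    b, a = butter(order, cutoff / nyquist, btype="low")
    if zero_phase:
        return filtfilt(b, a, signal)
    return lfilter(b, a, signal)


def _threshold_crossings(time: np.ndarray, grf: np.ndarray, threshold: float):
    """Interpolated upward/downward threshold-crossing times."""
    above = grf >= threshold
    switch = np.diff(above.astype(np.int8))
    ups, downs = [], []
    for i in np.flatnonzero(switch):
        t = time[i] + (threshold - grf[i]) / (grf[i + 1] - grf[i]) * (
            time[i + 1] - time[i]
        )
        (ups if switch[i] > 0 else downs).append(t)
    return np.asarray(ups), np.asarray(downs)


def segment_strides(
    time: np.ndarray,
    grf: np.ndarray,
    threshold: float = 25.0,
    debounce: float = 0.05,
    trial_id: str = "",
) -> list[Stride]:
    """Segment a uniformly sampled vertical GRF series into complete strides.

    Crossing times are located by linear interpolation between the bracketing
    samples; contact/flight intervals shorter than ``debounce`` are merged
    into their neighbours so noise cannot create micro-strides.  Incomplete
    leading/trailing strides are discarded.  Raises if no complete stride
    remains.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    time = np.asarray(time, dtype=float)
    grf = np.asarray(grf, dtype=float)
    ups, downs = _threshold_crossings(time, grf, threshold)
    if len(ups) < 2 or len(downs) == 0:
        raise ValueError("no complete stride found")

    # Pair each up-crossing with its following down-crossing, then drop
    # short contacts and short flights (debounce).
    events = sorted([(t, +1) for t in ups] + [(t, -1) for t in downs])
    contacts: list[list[float]] = []
    for t, kind in events:
        if kind > 0:
            if contacts and t - contacts[-1][1] < debounce:
                contacts[-1][1] = np.nan  # reopen: flight too short, merge
            else:
                contacts.append([t, np.nan])
        elif contacts and np.isnan(contacts[-1][1]):
            contacts[-1][1] = t
    contacts = [c for c in contacts if not np.isnan(c[1])]
    contacts = [c for c in contacts if c[1] - c[0] >= debounce]
    if len(contacts) < 2:
        raise ValueError("no complete stride found")

    dt = time[1] - time[0]
    strides: list[Stride] = []
    for (t_on, t_off), (t_next, _) in zip(contacts[:-1], contacts[1:]):
        i0 = max(int(np.floor(t_on / dt)), 0)
        i1 = min(int(np.ceil(t_next / dt)) + 1, len(time) - 1)
        strides.append(
            Stride(
                source_trial_id=trial_id,
                start_time=float(t_on),
                duration=float(t_next - t_on),
                stance_duration=float(t_off - t_on),
                raw_time=time[i0 : i1 + 1].copy(),
                raw_grf=grf[i0 : i1 + 1].copy(),
            )
        )
    return strides


def resample_stride(stride: Stride, n: int = 100) -> Stride:
    """Linearly interpolate the stride onto ``n`` equidistant points over
    [0, duration); the first point corresponds to foot-strike."""
    if n < 2:
        raise ValueError("need n >= 2 resample points")
    if len(stride.raw_time) < 2:
        raise ValueError("stride has fewer than 2 raw samples")
    grid = stride.start_time + np.arange(n) * stride.duration / n
    stride.grf_resampled = np.interp(grid, stride.raw_time, stride.raw_grf)
    return stride


def median_profile(strides: list[Stride]) -> MedianProfile:
    """Pointwise sample median across resampled strides (an even count takes
    the mean of the two central order statistics)."""
    if not strides:
        raise ValueError("no strides")
    mat = np.vstack([s.grf_resampled for s in strides])
    return MedianProfile(values=np.median(mat, axis=0))


def fmd_depth(values: np.ndarray, profile: MedianProfile) -> float:
    """Functional median distance: trapezoidal integral of the absolute
    deviation from the median profile over normalized stride time [0, 1].

    Zero iff the stride equals the profile at every point; a constant offset
    of c integrates to exactly c.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != profile.values.shape:
        raise ValueError("stride/profile length mismatch")
    x = np.linspace(0.0, 1.0, len(values))
    return float(np.trapezoid(np.abs(values - profile.values), x))


def select_representative(strides: list[Stride]) -> DepthResult:
    """Argmin of the FMD depth against the pointwise median profile; ties
    break to the earliest stride (stable argmin)."""
    if not strides:
        raise ValueError("no strides")
    profile = median_profile(strides)
    depths = np.array([fmd_depth(s.grf_resampled, profile) for s in strides])
    return DepthResult(depths=depths, selected_index=int(np.argmin(depths)))


def spatiotemporal_summary(
    stride: Stride, height: float, speed: float = 3.0
) -> SpatiotemporalSummary:
    """Stance/stride durations and (normalized) stride length of a stride.

    On a treadmill at constant belt speed, stride length is
    speed x stride duration; normalization is by body height.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    stride_length = speed * stride.duration
    return SpatiotemporalSummary(
        stance_duration=stride.stance_duration,
        stride_duration=stride.duration,
        stride_length=stride_length,
        normalized_stride_length=stride_length / height,
    )


def representative_stride(
    time: np.ndarray,
    grf: np.ndarray,
    threshold: float = 25.0,
    n_points: int = 100,
    trial_id: str = "",
) -> tuple[Stride, DepthResult, list[Stride]]:
    """Full six-step selection on a raw trial; returns the selected stride,
    the depth table, and all segmented strides."""
    strides = segment_strides(time, grf, threshold=threshold, trial_id=trial_id)
    for s in strides:
        resample_stride(s, n_points)
    result = select_representative(strides)
    return strides[result.selected_index], result, strides
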