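"""DC removal and fixed-size windowing of 6-channel IMU traces.

The DC (gravity) component is removed by subtracting the output of a
first-order low-pass IIR filter from the signal, which is equivalent to a
first-order high-pass with the same cutoff (default 0.15 Hz).  The filtered
trace is then cut into non-overlapping 3-s windows (75 samples at 25 Hz),
each labelled with the majority activity's intensity class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from oxiflow.synthetic_data import ACTIVITY_INTENSITY, Activity, ImuTrace, Intensity

__all__ = [
    "FilterSpec",
    "WindowingSpec",
    "LabeledWindow",
    "remove_dc",
    "segment_windows",
]


@dataclass(frozen=True)
class FilterSpec:
    """First-order DC-removal filter: high-pass cutoff in Hz."""

    cutoff_hz: float = 0.15
    fs: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_hz < self.fs / 2):
            raise ValueError("cutoff_hz must lie in (0, fs/2)")

    @property
    def alpha(self) -> float:
        """Low-pass smoothing coefficient dt/(RC + dt), RC = 1/(2*pi*fc)."""
        dt = 1.0 / self.fs
        rc = 1.0 / (2.0 * np.pi * self.cutoff_hz)
        return dt / (rc + dt)


@dataclass(frozen=True)
class WindowingSpec:
    """Fixed windowing: 3 s / 75 samples at 25 Hz, no overlap by default."""

    window_s: float = 3.0
    fs: float = 25.0
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.fs <= 0:
            raise ValueError("window_s and fs must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def samples_per_window(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def step(self) -> int:
        return max(1, int(round(self.samples_per_window * (1.0 - self.overlap))))


@dataclass
class LabeledWindow:
    """One 75 x 6 window (ax ay az gx gy gz) with an intensity-class label."""

    samples: np.ndarray
    label: Intensity
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ValueError("samples must be an (n, 6) array")
        self.label = Intensity(self.label)


def remove_dc(trace: ImuTrace, spec: Optional[FilterSpec] = None) -> ImuTrace:
    """Subtract a first-order low-pass from each channel (DC/gravity removal).

    The low-pass state is initialised to the first sample of each channel,
    which minimises the startup transient; output length equals input length
    and labels are preserved.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if spec is None:
        spec = FilterSpec(fs=trace.fs)
    if spec.fs != trace.fs:
        raise ValueError("FilterSpec.fs does not match trace.fs")
    a = spec.alpha
    out = {}
    for name in ImuTrace.CHANNELS:
        x = getattr(trace, name)
        # y[n] = a*x[n] + (1-a)*y[n-1], y[-1] = x[0]
        low, _ = lfilter([a], [1.0, a - 1.0], x, zi=np.array([(1.0 - a) * x[0]]))
        out[name] = x - low
    return ImuTrace(
        t=trace.t.copy(), fs=trace.fs,
        labels=None if trace.labels is None else trace.labels.copy(),
        **out,
    )


def _window_intensity(labels: np.ndarray) -> Intensity:
    """Majority intensity within a window; ties go to the lower intensity."""
    counts = {}
    for lab in labels:
        inten = ACTIVITY_INTENSITY[Activity(str(lab))]
        counts[inten] = counts.get(inten, 0) + 1
    # max count wins; ties break toward the lower intensity (conservative
    # dosing on ambiguous windows) because max() keeps the first maximum
    # when iterating in ascending intensity order
    return max(sorted(counts), key=lambda k: counts[k])


def segment_windows(
    trace: ImuTrace,
    spec: Optional[WindowingSpec] = None,
    subject_id: str = "",
) -> list[LabeledWindow]:
    """Cut a labelled trace into non-overlapping fixed-size windows.

    Yields ``floor(N / samples_per_window)`` windows at zero overlap; the
    trailing partial window is discarded.  Each window's label is the
    intensity class of the majority activity within it.
    """
    if spec is None:
        spec = WindowingSpec(fs=trace.fs)
    if spec.fs != trace.fs:
        raise ValueError("WindowingSpec.fs does not match trace.fs")
    if trace.labels is None:
        raise ValueError("trace has no labels; labelled windowing requires them")
    w = spec.samples_per_window
    mat = trace.channel_matrix()
    windows = []
    start = 0
    while start + w <= len(trace):
        samples = mat[start : start + w]
        label = _window_intensity(trace.labels[start : start + w])
        windows.append(LabeledWindow(samples=samples, label=label, subject_id=subject_id))
        start += spec.step
    return windows
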