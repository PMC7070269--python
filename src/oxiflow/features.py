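"""The 98 time-domain features extracted from each 6-channel window.

Frequency-domain and non-linear features are deliberately absent: the
feature set is meant to run on a small microcontroller in real time, so
everything here is computable with sums, sorts and first differences.

Feature families and counts (channels are ax ay az gx gy gz; SMV is the
per-sensor signal magnitude vector sqrt(x^2+y^2+z^2); SMA the signal
magnitude area mean(|x|+|y|+|z|)):

==============================================  =====
RMS, standard deviation, absolute mean           18
Mean of the derivative                            6
Pairwise correlations (within each sensor)        6
Simplified energy (mean of squares)               6
Skewness, kurtosis, median                       18
Min, max, max - min                              18
Interquartile range                               6
SMV mean, SD, median, skewness, kurtosis         10
SMV IQR, max, min, max - min                      8
SMA (per sensor)                                  2
Total                                            98
==============================================  =====

Statistical conventions: SD is the n-1 sample standard deviation; skewness
is the bias-uncorrected g1 = m3 / m2^(3/2); kurtosis is the non-excess
Pearson m4 / m2^2; IQR is Q3 - Q1 with linear interpolation; the derivative
mean is scaled by the sampling rate (units per second).  Zero-variance
inputs yield 0 for correlation, skewness and kurtosis by convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from oxiflow.preprocessing import LabeledWindow

__all__ = [
    "FeatureDescriptor",
    "FeatureVector",
    "feature_catalog",
    "catalog_names",
    "catalog_hash",
    "extract_features",
    "extract_matrix",
    "feature_matrix",
]

_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
_CORR_PAIRS = (("ax", "ay"), ("ax", "az"), ("ay", "az"),
               ("gx", "gy"), ("gx", "gz"), ("gy", "gz"))
_SENSORS = ("acc", "gyro")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One catalog entry: stable name, feature family, input channels."""

    name: str
    family: str
    channels: tuple


def _build_catalog() -> tuple:
    cat = []

    def add(name, family, channels):
        cat.append(FeatureDescriptor(name, family, tuple(channels)))

    for stat in ("rms", "sd", "absmean"):
        for ch in _CHANNELS:
            add(f"{stat}_{ch}", "rms_sd_absmean", (ch,))
    for ch in _CHANNELS:
        add(f"dmean_{ch}", "mean_derivative", (ch,))
    for a, b in _CORR_PAIRS:
        add(f"corr_{a}_{b}", "pairwise_correlation", (a, b))
    for ch in _CHANNELS:
        add(f"energy_{ch}", "simplified_energy", (ch,))
    for stat in ("skew", "kurt", "median"):
        for ch in _CHANNELS:
            add(f"{stat}_{ch}", "moments", (ch,))
    for stat in ("min", "max", "range"):
        for ch in _CHANNELS:
            add(f"{stat}_{ch}", "min_max_range", (ch,))
    for ch in _CHANNELS:
        add(f"iqr_{ch}", "iqr", (ch,))
    for sensor in _SENSORS:
        chans = _CHANNELS[:3] if sensor == "acc" else _CHANNELS[3:]
        for stat in ("mean", "sd", "median", "skew", "kurt"):
            add(f"smv_{sensor}_{stat}", "smv_moments", chans)
    for sensor in _SENSORS:
        chans = _CHANNELS[:3] if sensor == "acc" else _CHANNELS[3:]
        for stat in ("iqr", "max", "min", "range"):
            add(f"smv_{sensor}_{stat}", "smv_spread", chans)
    for sensor in _SENSORS:
        chans = _CHANNELS[:3] if sensor == "acc" else _CHANNELS[3:]
        add(f"sma_{sensor}", "sma", chans)
    return tuple(cat)


_CATALOG = _build_catalog()
assert len(_CATALOG) == 98


def feature_catalog() -> list[FeatureDescriptor]:
    """The ordered 98-entry feature catalog."""
    return list(_CATALOG)


def catalog_names() -> list[str]:
    return [d.name for d in _CATALOG]


def catalog_hash() -> str:
    """Stable hash of the catalog order, embedded in serialized models."""
    joined = ",".join(catalog_names()).encode()
    return hashlib.sha256(joined).hexdigest()[:16]


@dataclass
class FeatureVector:
    """Ordered 98-element feature vector with its catalog names."""

    values: np.ndarray
    names: tuple = tuple(catalog_names())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (98,):
            raise ValueError("feature vector must have exactly 98 values")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    m = x.mean()
    d = x - m
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        return 0.0, 0.0
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return m3 / m2**1.5, m4 / m2**2


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    denom = float(np.sqrt(np.sum(da * da) * np.sum(db * db)))
    if denom == 0.0:
        return 0.0
    return float(np.sum(da * db) / denom)


def extract_features(window: LabeledWindow, fs: float = 25.0) -> FeatureVector:
    """Compute the 98-feature vector for one window.

    A pure, deterministic function of the window samples; raises on windows
    that are not (n, 6) or contain non-finite values.
    """
    x = np.asarray(window.samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 6:
        raise ValueError("window samples must be an (n, 6) array")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")

    cols = {ch: x[:, i] for i, ch in enumerate(_CHANNELS)}
    vals: list[float] = []

    n = x.shape[0]
    # RMS, SD (n-1), absolute mean
    for stat in ("rms", "sd", "absmean"):
        for ch in _CHANNELS:
            c = cols[ch]
            if stat == "rms":
                vals.append(float(np.sqrt(np.mean(c * c))))
            elif stat == "sd":
                vals.append(float(np.std(c, ddof=1)) if n > 1 else 0.0)
            else:
                vals.append(float(np.mean(np.abs(c))))
    # mean of the derivative, units per second
    for ch in _CHANNELS:
        c = cols[ch]
        vals.append(float(np.mean(np.diff(c)) * fs) if n > 1 else 0.0)
    # within-sensor pairwise Pearson correlations
    for a, b in _CORR_PAIRS:
        vals.append(_corr(cols[a], cols[b]))
    # simplified energy = mean of squares (no FFT on the target MCU)
    for ch in _CHANNELS:
        c = cols[ch]
        vals.append(float(np.mean(c * c)))
    # moments
    sk = {ch: _skew_kurt(cols[ch]) for ch in _CHANNELS}
    for ch in _CHANNELS:
        vals.append(sk[ch][0])
    for ch in _CHANNELS:
        vals.append(sk[ch][1])
    for ch in _CHANNELS:
        vals.append(float(np.median(cols[ch])))
    # min, max, range
    for ch in _CHANNELS:
        vals.append(float(np.min(cols[ch])))
    for ch in _CHANNELS:
        vals.append(float(np.max(cols[ch])))
    for ch in _CHANNELS:
        vals.append(float(np.max(cols[ch]) - np.min(cols[ch])))
    # IQR with linear interpolation
    for ch in _CHANNELS:
        q1, q3 = np.percentile(cols[ch], [25.0, 75.0])
        vals.append(float(q3 - q1))
    # signal magnitude vector per sensor
    smv = {
        "acc": np.sqrt(cols["ax"] ** 2 + cols["ay"] ** 2 + cols["az"] ** 2),
        "gyro": np.sqrt(cols["gx"] ** 2 + cols["gy"] ** 2 + cols["gz"] ** 2),
    }
    for sensor in _SENSORS:
        m = smv[sensor]
        s, k = _skew_kurt(m)
        vals.extend(
            [
                float(np.mean(m)),
                float(np.std(m, ddof=1)) if n > 1 else 0.0,
                float(np.median(m)),
                s,
                k,
            ]
        )
    for sensor in _SENSORS:
        m = smv[sensor]
        q1, q3 = np.percentile(m, [25.0, 75.0])
        vals.extend(
            [
                float(q3 - q1),
                float(np.max(m)),
                float(np.min(m)),
                float(np.max(m) - np.min(m)),
            ]
        )
    # signal magnitude area per sensor
    vals.append(float(np.mean(np.abs(cols["ax"]) + np.abs(cols["ay"]) + np.abs(cols["az"]))))
    vals.append(float(np.mean(np.abs(cols["gx"]) + np.abs(cols["gy"]) + np.abs(cols["gz"]))))

    return FeatureVector(values=np.array(vals))


def extract_matrix(windows, fs: float = 25.0) -> np.ndarray:
    """Stack feature vectors for a list of windows into an (m, 98) matrix."""
    return np.vstack([extract_features(w, fs=fs).values for w in windows])


def feature_matrix(windows, fs: float = 25.0):
    """(X, y, subjects) arrays for a list of labelled windows."""
    X = extract_matrix(windows, fs=fs)
    y = np.array([int(w.label) for w in windows])
    subjects = np.array([w.subject_id for w in windows])
    return X, y, subjects
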