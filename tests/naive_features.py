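"""Naive, loop-based re-implementation of every window feature.

Deliberately written with plain Python loops and no numpy vectorisation so
it serves as an independent oracle for the production extractor.
"""

import math

CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
CORR_PAIRS = (("ax", "ay"), ("ax", "az"), ("ay", "az"),
              ("gx", "gy"), ("gx", "gz"), ("gy", "gz"))


def _mean(xs):
    return sum(xs) / len(xs)


def _sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def _moments(xs):
    m = _mean(xs)
    m2 = sum((x - m) ** 2 for x in xs) / len(xs)
    if m2 == 0:
        return 0.0, 0.0
    m3 = sum((x - m) ** 3 for x in xs) / len(xs)
    m4 = sum((x - m) ** 4 for x in xs) / len(xs)
    return m3 / m2**1.5, m4 / m2**2


def _median(xs):
    s = sorted(xs)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])


def _quantile(xs, q):
    """Linear-interpolation quantile at fraction q."""
    s = sorted(xs)
    pos = (len(s) - 1) * q
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return s[lo] + (s[hi] - s[lo]) * (pos - lo)


def _iqr(xs):
    return _quantile(xs, 0.75) - _quantile(xs, 0.25)


def _corr(a, b):
    ma, mb = _mean(a), _mean(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    den = math.sqrt(
        sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b)
    )
    if den == 0:
        return 0.0
    return num / den


def naive_features(samples, fs=25.0):
    """Feature-name -> value dict computed with direct loops."""
    cols = {ch: [float(row[i]) for row in samples] for i, ch in enumerate(CHANNELS)}
    n = len(cols["ax"])
    out = {}
    for ch in CHANNELS:
        c = cols[ch]
        out[f"rms_{ch}"] = math.sqrt(sum(x * x for x in c) / n)
        out[f"sd_{ch}"] = _sd(c)
        out[f"absmean_{ch}"] = sum(abs(x) for x in c) / n
        out[f"dmean_{ch}"] = _mean([c[i + 1] - c[i] for i in range(n - 1)]) * fs
        out[f"energy_{ch}"] = sum(x * x for x in c) / n
        sk, ku = _moments(c)
        out[f"skew_{ch}"] = sk
        out[f"kurt_{ch}"] = ku
        out[f"median_{ch}"] = _median(c)
        out[f"min_{ch}"] = min(c)
        out[f"max_{ch}"] = max(c)
        out[f"range_{ch}"] = max(c) - min(c)
        out[f"iqr_{ch}"] = _iqr(c)
    for a, b in CORR_PAIRS:
        out[f"corr_{a}_{b}"] = _corr(cols[a], cols[b])
    for sensor, chans in (("acc", CHANNELS[:3]), ("gyro", CHANNELS[3:])):
        m = [
            math.sqrt(sum(cols[ch][i] ** 2 for ch in chans))
            for i in range(n)
        ]
        sk, ku = _moments(m)
        out[f"smv_{sensor}_mean"] = _mean(m)
        out[f"smv_{sensor}_sd"] = _sd(m)
        out[f"smv_{sensor}_median"] = _median(m)
        out[f"smv_{sensor}_skew"] = sk
        out[f"smv_{sensor}_kurt"] = ku
        out[f"smv_{sensor}_iqr"] = _iqr(m)
        out[f"smv_{sensor}_max"] = max(m)
        out[f"smv_{sensor}_min"] = min(m)
        out[f"smv_{sensor}_range"] = max(m) - min(m)
        out[f"sma_{sensor}"] = _mean(
            [sum(abs(cols[ch][i]) for ch in chans) for i in range(n)]
        )
    return out
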