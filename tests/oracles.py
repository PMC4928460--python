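"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: Pearson correlation
from sums of products, lag handling by explicit slicing, and the closed-form
Butterworth band-pass magnitude response.
"""

import numpy as np


def oracle_pearson(x, y):
    """Pearson r from first principles: sums of products."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def oracle_lagged(seed, voxel, tr, lag_limit):
    """Explicit slice-and-correlate at every whole-TR lag."""
    n = len(seed)
    k_max = int(np.floor(lag_limit / tr + 1e-9))
    out = []
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            a, b = seed[: n - k], voxel[k:]
        else:
            a, b = seed[-k:], voxel[: n + k]
        out.append((k * tr, oracle_pearson(list(a), list(b))))
    return out


def oracle_best(pairs):
    """Maximum r; ties -> smallest |lag|, then negative lag."""
    return max(pairs, key=lambda p: (p[1], -abs(p[0]), -p[0]))


def butter_bandpass_mag2(f, low_hz, high_hz, fs, order=3):
    """Closed-form squared magnitude of the digital order-N Butterworth
    band-pass designed by bilinear transform with frequency prewarping:
    |H|^2 = 1 / (1 + w^(2N)) with w = (W^2 - W1*W2) / ((W2-W1)*W), where
    W = 2*fs*tan(pi*f/fs) is the prewarped analog frequency."""
    warp = lambda x: 2.0 * fs * np.tan(np.pi * x / fs)
    w1, w2 = warp(low_hz), warp(high_hz)
    wd = warp(np.asarray(f, dtype=float))
    w = (wd**2 - w1 * w2) / ((w2 - w1) * wd)
    return 1.0 / (1.0 + w ** (2 * order))
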