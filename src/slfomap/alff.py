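"""Amplitude of low-frequency fluctuation (ALFF) mapping.

Per voxel: demean, take the discrete Fourier transform, form the one-sided
amplitude spectrum A_j = 2|X_j|/n for 0 < f_j <= Nyquist (no doubling at the
Nyquist bin when n is even), and sum A_j over bins inside the low-frequency
band, endpoints inclusive.  Under this convention a unit cosine sitting
exactly on an in-band bin yields ALFF = 1; any fixed convention only rescales
the map, and all downstream statistics are rank-based, hence invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidBandError, ShapeError
from .types import BoldSeries4D


@dataclass
class AlffMap:
    alff: np.ndarray  # 3D nonnegative field, NaN outside brain
    band: tuple[float, float] = (0.01, 0.15)
    subject_id: str = ""


def alff_timecourse(
    x: np.ndarray, tr_seconds: float, low_hz: float = 0.01, high_hz: float = 0.15
) -> np.ndarray:
    """ALFF of timecourse(s); time on the last axis, any leading shape."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    nyquist = 0.5 / tr_seconds
    if high_hz >= nyquist + 1e-12:
        raise InvalidBandError(f"high_hz {high_hz} >= Nyquist {nyquist:.4g}")
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    in_band = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    if not in_band.any():
        raise InvalidBandError(
            f"no Fourier bin inside [{low_hz}, {high_hz}] Hz at n={n}, TR={tr_seconds}"
        )
    xc = x - x.mean(axis=-1, keepdims=True)
    spectrum = np.fft.rfft(xc, axis=-1)
    amp = 2.0 * np.abs(spectrum) / n
    if n % 2 == 0:
        amp[..., -1] /= 2.0  # Nyquist bin appears once; no doubling
    return amp[..., in_band].sum(axis=-1)


def compute_alff(
    series: BoldSeries4D,
    brain_mask: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
) -> AlffMap:
    """ALFF map over the brain mask; NaN outside."""
    brain = np.asarray(brain_mask, dtype=bool)
    if brain.shape != series.grid_shape:
        raise ShapeError(f"brain mask shape {brain.shape} != grid {series.grid_shape}")
    vals = alff_timecourse(series.data[brain], series.tr_seconds, low_hz, high_hz)
    out = np.full(series.grid_shape, np.nan)
    out[brain] = vals
    return AlffMap(alff=out, band=(low_hz, high_hz), subject_id=series.subject_id)
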