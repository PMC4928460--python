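"""Temporal band-pass filtering and spatial smoothing of 4D BOLD series.

The temporal filter is the zero-phase (forward–backward) third-order
Butterworth band-pass at 0.01–0.15 Hz; the spatial filter is an isotropic
Gaussian specified by FWHM in mm (FSL convention).  Both are linear, so their
order of application per voxel/timepoint is immaterial; the pipeline applies
smoothing first and records the order in its manifest.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .exceptions import InvalidBandError, InvalidLengthError, ParameterError
from .types import BoldSeries4D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


def butter_bandpass_sos(
    low_hz: float, high_hz: float, tr_seconds: float, order: int = 3
) -> np.ndarray:
    """Design the band-pass as second-order sections (numerically robust)."""
    nyquist = 0.5 / tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise InvalidBandError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:.4g} Hz"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")


def bandpass_filter(
    series,
    tr_seconds: float | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    order: int = 3,
):
    """Zero-phase Butterworth band-pass of each voxel timecourse.

    Accepts a :class:`BoldSeries4D` (returns a filtered copy) or a plain
    array with time on the last axis (``tr_seconds`` then required).  The
    forward–backward pass squares the magnitude response and cancels the
    phase; edges are handled by reflective ("even") padding of length
    3 × 2 × order samples, hence the minimum-length precondition.
    """
    if isinstance(series, BoldSeries4D):
        out = bandpass_filter(series.data, series.tr_seconds, low_hz, high_hz, order)
        return BoldSeries4D(
            data=out,
            tr_seconds=series.tr_seconds,
            affine=series.affine.copy(),
            subject_id=series.subject_id,
        )
    if tr_seconds is None:
        raise ParameterError("tr_seconds required when filtering a plain array")
    x = np.asarray(series, dtype=np.float64)
    padlen = 3 * 2 * order
    if x.shape[-1] <= padlen:
        raise InvalidLengthError(
            f"series length {x.shape[-1]} too short for order-{order} zero-phase "
            f"filter (needs > {padlen})"
        )
    sos = butter_bandpass_sos(low_hz, high_hz, tr_seconds, order)
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def spatial_smooth(series: BoldSeries4D, fwhm_mm: float = 3.0) -> BoldSeries4D:
    """Convolve each volume with an isotropic Gaussian of the given FWHM.

    ``fwhm_mm = 0`` is the identity.  The discrete kernel is normalized to
    unit mass, so the spatial sum over interior-supported inputs is conserved.
    """
    if fwhm_mm < 0:
        raise ParameterError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return BoldSeries4D(
            data=series.data.copy(),
            tr_seconds=series.tr_seconds,
            affine=series.affine.copy(),
            subject_id=series.subject_id,
        )
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / series.voxel_size_mm
    out = ndimage.gaussian_filter(series.data, sigma=tuple(sigma_vox) + (0.0,))
    return BoldSeries4D(
        data=out,
        tr_seconds=series.tr_seconds,
        affine=series.affine.copy(),
        subject_id=series.subject_id,
    )
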