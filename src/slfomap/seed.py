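"""Seed-regressor extraction: the averaged timecourse over a venous ROI."""

from __future__ import annotations

import numpy as np

from .exceptions import EmptyRoiError, ShapeError
from .types import BoldSeries4D, SeedTimecourse


def extract_seed(
    series: BoldSeries4D, roi_mask: np.ndarray, source_label: str = "SSS"
) -> SeedTimecourse:
    """Unweighted mean timecourse over the ROI voxels.

    The caller is responsible for band-pass filtering the series first; the
    seed carries no filtering state of its own.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != series.grid_shape:
        raise ShapeError(f"ROI shape {roi.shape} != series grid {series.grid_shape}")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyRoiError("seed ROI is empty")
    values = series.data[roi].mean(axis=0)
    return SeedTimecourse(
        values=values,
        tr_seconds=series.tr_seconds,
        source_label=source_label,
        subject_id=series.subject_id,
        n_roi_voxels=n_roi,
    )
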