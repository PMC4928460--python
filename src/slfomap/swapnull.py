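"""Swapped-seed null control.

Recomputing every subject's maxcc map with every *other* subject's seed
regressor removes the subject-specific systemic oscillation from the
regressor, so any residual tissue structure in the swapped distribution
graphs reflects only non-specific (SNR-driven) effects.  An 8-subject cohort
yields 8×7 = 56 swapped maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distribution import (
    GroupDistribution,
    average_distributions,
    bin_tissue_fractions,
    fit_distribution_slope,
    rank_and_bin,
    test_slope_nonzero,
)
from .exceptions import (
    CohortCompatibilityError,
    CohortSizeError,
    InsufficientVoxelsError,
)
from .lagcorr import LagCorrelationMap, compute_maxcc_map
from .seed import extract_seed
from .types import BoldSeries4D, TissueMasks

SLOPE_TISSUES = ("GM", "WM", "CSF", "VA")


@dataclass
class SwapResult:
    """All ordered-pair swapped maps and their distribution summaries.

    ``pair_ids`` tags each map (data_subject, seed_subject); maps whose
    valid-voxel count falls below ``n_bins`` are recorded in ``insufficient``
    and excluded from the distribution statistics rather than failing the
    run.
    """

    pair_ids: list = field(default_factory=list)
    maps: list = field(default_factory=list)
    tables: list = field(default_factory=list)
    insufficient: list = field(default_factory=list)
    group: GroupDistribution | None = None
    slopes_by_tissue: dict = field(default_factory=dict)
    slope_tests: dict = field(default_factory=dict)

    @property
    def n_maps(self) -> int:
        return len(self.maps)


def swap_seed_maps(
    cohort: list[tuple[BoldSeries4D, TissueMasks]],
    threshold: float = 0.3,
    lag_limit_s: float = 6.0,
    n_bins: int = 10,
    keep_maps: bool = True,
) -> SwapResult:
    """Compute maxcc maps for every ordered (data, seed) pair with i ≠ j.

    ``cohort`` entries are ``(series, masks)`` (extra tuple members such as
    ground truth are ignored); series must already be preprocessed.  Seeds
    are extracted from each subject's own SSS ROI and applied to every other
    subject with the standard threshold and lag window.
    """
    n = len(cohort)
    if n < 2:
        raise CohortSizeError(f"swap analysis needs >= 2 subjects, got {n}")
    series_list = [entry[0] for entry in cohort]
    masks_list = [entry[1] for entry in cohort]
    trs = {round(s.tr_seconds, 9) for s in series_list}
    nts = {s.n_timepoints for s in series_list}
    if len(trs) != 1:
        raise CohortCompatibilityError(f"subjects disagree on TR: {sorted(trs)}")
    if len(nts) != 1:
        raise CohortCompatibilityError(
            f"subjects disagree on n_timepoints: {sorted(nts)}"
        )

    seeds = [extract_seed(s, m.sss) for s, m in zip(series_list, masks_list)]

    result = SwapResult()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lag_map = compute_maxcc_map(
                series_list[i],
                seeds[j],
                masks_list[i].brain,
                threshold=threshold,
                lag_limit_s=lag_limit_s,
            )
            pair = (series_list[i].subject_id or f"sub-{i + 1:02d}",
                    series_list[j].subject_id or f"sub-{j + 1:02d}")
            result.pair_ids.append(pair)
            result.maps.append(lag_map if keep_maps else _strip_map(lag_map))
            try:
                bins = rank_and_bin(lag_map.maxcc, lag_map.valid, n_bins=n_bins)
            except InsufficientVoxelsError:
                result.insufficient.append(pair)
                result.tables.append(None)
                continue
            table = bin_tissue_fractions(
                bins, masks_list[i], subject_id=pair[0], source_map="maxcc_swap"
            )
            result.tables.append(table)

    usable = [t for t in result.tables if t is not None]
    if len(usable) >= 2:
        result.group = average_distributions(usable)
    for tissue in SLOPE_TISSUES:
        slopes = [fit_distribution_slope(t, tissue) for t in usable]
        result.slopes_by_tissue[tissue] = slopes
        if len(slopes) >= 2:
            result.slope_tests[tissue] = test_slope_nonzero(slopes)
    return result


def _strip_map(lag_map: LagCorrelationMap) -> LagCorrelationMap:
    """Drop the dense fields, keeping validity only (disk/memory economy)."""
    return LagCorrelationMap(
        maxcc=np.empty(0),
        lag_s=np.empty(0),
        valid=lag_map.valid,
        threshold=lag_map.threshold,
        lag_limit_s=lag_map.lag_limit_s,
        subject_id=lag_map.subject_id,
        seed_label=lag_map.seed_label,
    )
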