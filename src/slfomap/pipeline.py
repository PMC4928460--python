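"""Per-subject and cohort orchestration of the full analysis.

Per subject: spatial smoothing → temporal band-pass → seed extraction from
the SSS ROI → voxelwise maxcc map → ALFF map → equal-count binning of both
maps → tissue distribution tables → per-tissue slopes.

Per cohort: per-subject runs, group-averaged distribution graphs, per-tissue
slope-vs-zero tests, the bin-10 vs bin-9 contrasts for CSF and VA, maxcc/ALFF
curve correlations per tissue, the swapped-seed null, and the true-vs-swapped
slope contrast for GM and WM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alff import AlffMap, compute_alff
from .config import AnalysisConfig
from .distribution import (
    DistributionTable,
    GroupDistribution,
    average_distributions,
    bin_tissue_fractions,
    compare_bins,
    compare_slope_sets,
    curve_correlation,
    fit_distribution_slope,
    rank_and_bin,
    test_slope_nonzero,
)
from .exceptions import CohortSizeError
from .lagcorr import LagCorrelationMap, compute_maxcc_map
from .preprocess import bandpass_filter, spatial_smooth
from .seed import extract_seed
from .swapnull import SLOPE_TISSUES, SwapResult, swap_seed_maps
from .types import BoldSeries4D, TissueMasks

log = logging.getLogger("slfomap")


@dataclass
class SubjectResult:
    subject_id: str
    lag_map: LagCorrelationMap
    alff_map: AlffMap
    table_maxcc: DistributionTable
    table_alff: DistributionTable
    slopes_maxcc: dict
    slopes_alff: dict
    manifest: dict = field(default_factory=dict)


@dataclass
class CohortResult:
    subjects: list
    group_maxcc: GroupDistribution
    group_alff: GroupDistribution
    slope_tests_maxcc: dict
    slope_tests_alff: dict
    bin_contrasts: dict
    curve_correlations: dict
    swap: SwapResult
    true_vs_swap: dict


def preprocess_subject(
    series: BoldSeries4D, config: AnalysisConfig
) -> BoldSeries4D:
    """Smoothing and band-pass in the configured order."""
    stages = []
    if config.smooth_before_filter:
        stages = [("smooth", lambda s: spatial_smooth(s, config.fwhm_mm)),
                  ("bandpass", lambda s: bandpass_filter(
                      s, low_hz=config.band_low_hz, high_hz=config.band_high_hz,
                      order=config.filter_order))]
    else:
        stages = [("bandpass", lambda s: bandpass_filter(
                      s, low_hz=config.band_low_hz, high_hz=config.band_high_hz,
                      order=config.filter_order)),
                  ("smooth", lambda s: spatial_smooth(s, config.fwhm_mm))]
    out = series
    for name, fn in stages:
        out = fn(out)
        log.debug("subject %s: %s done", series.subject_id, name)
    return out


def run_subject(
    series: BoldSeries4D,
    masks: TissueMasks,
    config: AnalysisConfig | None = None,
    preprocessed: bool = False,
) -> SubjectResult:
    """Full single-subject analysis; ``preprocessed=True`` skips smoothing
    and filtering (inputs already conditioned)."""
    config = config or AnalysisConfig()
    config.validate()
    masks.validate()

    filtered = series if preprocessed else preprocess_subject(series, config)
    seed = extract_seed(filtered, masks.sss)
    lag_map = compute_maxcc_map(
        filtered,
        seed,
        masks.brain,
        threshold=config.maxcc_threshold,
        lag_limit_s=config.lag_limit_s,
    )
    log.info(
        "subject %s: %d valid voxels (threshold %.2f, window ±%.2f s)",
        series.subject_id, lag_map.n_valid, config.maxcc_threshold, config.lag_limit_s,
    )
    alff_map = compute_alff(
        filtered, masks.brain, low_hz=config.band_low_hz, high_hz=config.band_high_hz
    )

    bins_maxcc = rank_and_bin(lag_map.maxcc, lag_map.valid, n_bins=config.n_bins)
    alff_valid = lag_map.valid if config.alff_valid_mode == "maxcc_valid" else masks.brain
    bins_alff = rank_and_bin(alff_map.alff, alff_valid, n_bins=config.n_bins)

    table_maxcc = bin_tissue_fractions(
        bins_maxcc, masks, subject_id=series.subject_id, source_map="maxcc"
    )
    table_alff = bin_tissue_fractions(
        bins_alff, masks, subject_id=series.subject_id, source_map="alff"
    )
    slopes_maxcc = {t: fit_distribution_slope(table_maxcc, t) for t in SLOPE_TISSUES}
    slopes_alff = {t: fit_distribution_slope(table_alff, t) for t in SLOPE_TISSUES}

    manifest = {
        "subject_id": series.subject_id,
        "stages": (["smooth", "bandpass"] if config.smooth_before_filter
                   else ["bandpass", "smooth"]) if not preprocessed else [],
        "n_valid_maxcc": lag_map.n_valid,
        "n_roi_voxels": seed.n_roi_voxels,
        "n_bins": config.n_bins,
        "alff_valid_mode": config.alff_valid_mode,
    }
    return SubjectResult(
        subject_id=series.subject_id,
        lag_map=lag_map,
        alff_map=alff_map,
        table_maxcc=table_maxcc,
        table_alff=table_alff,
        slopes_maxcc=slopes_maxcc,
        slopes_alff=slopes_alff,
        manifest=manifest,
    )


def run_cohort(
    cohort: list,
    config: AnalysisConfig | None = None,
    preprocessed: bool = False,
) -> CohortResult:
    """Full group analysis over ``[(series, masks), ...]`` (extra tuple
    members such as phantom ground truth are ignored)."""
    config = config or AnalysisConfig()
    config.validate()
    if len(cohort) < 2:
        raise CohortSizeError(f"cohort analysis needs >= 2 subjects, got {len(cohort)}")

    pre = []
    subjects = []
    for entry in cohort:
        series, masks = entry[0], entry[1]
        filtered = series if preprocessed else preprocess_subject(series, config)
        pre.append((filtered, masks))
        subjects.append(run_subject(filtered, masks, config, preprocessed=True))

    group_maxcc = average_distributions([s.table_maxcc for s in subjects])
    group_alff = average_distributions([s.table_alff for s in subjects])

    slope_tests_maxcc = {
        t: test_slope_nonzero([s.slopes_maxcc[t] for s in subjects])
        for t in SLOPE_TISSUES
    }
    slope_tests_alff = {
        t: test_slope_nonzero([s.slopes_alff[t] for s in subjects])
        for t in SLOPE_TISSUES
    }

    tables_maxcc = [s.table_maxcc for s in subjects]
    nb = config.n_bins
    bin_contrasts = {
        tissue: compare_bins(tables_maxcc, tissue, nb, nb - 1)
        for tissue in ("CSF", "VA")
    }
    curve_correlations = {
        t: curve_correlation(group_maxcc, group_alff, t) for t in SLOPE_TISSUES
    }

    swap = swap_seed_maps(
        pre,
        threshold=config.maxcc_threshold,
        lag_limit_s=config.lag_limit_s,
        n_bins=config.n_bins,
        keep_maps=False,
    )
    true_vs_swap = {}
    for tissue in ("GM", "WM"):
        swapped = swap.slopes_by_tissue.get(tissue, [])
        if len(swapped) >= 2:
            true_vs_swap[tissue] = compare_slope_sets(
                [s.slopes_maxcc[tissue] for s in subjects], swapped
            )
    return CohortResult(
        subjects=subjects,
        group_maxcc=group_maxcc,
        group_alff=group_alff,
        slope_tests_maxcc=slope_tests_maxcc,
        slope_tests_alff=slope_tests_alff,
        bin_contrasts=bin_contrasts,
        curve_correlations=curve_correlations,
        swap=swap,
        true_vs_swap=true_vs_swap,
    )
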