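"""Equal-count binning of valid voxels and tissue-distribution statistics.

Valid voxels are ranked in ascending order of a scalar map (maxcc or ALFF)
and split into 10 equal-count bins; each bin's composition across the
exclusive tissue classes (GM, WM, CSF, VA, other) forms the "distribution
graph" in numeric form.  Slopes of the fraction-vs-bin curves, group
averages, bin contrasts and curve correlations quantify how the systemic-LFO
content tracks tissue type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientVoxelsError, ParameterError, ShapeError
from .types import TISSUE_CLASSES, TissueMasks


@dataclass
class BinAssignment:
    """Equal-count decile assignment of valid voxels.

    ``bin_index`` is 1..n_bins on valid voxels and 0 elsewhere; counts per
    bin differ by at most one, with remainder voxels in the lowest bins.
    ``bin_edges`` holds the map values separating consecutive bins (the value
    of the first voxel of each bin after the first).
    """

    bin_index: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    n_valid: int

    def bin_counts(self) -> np.ndarray:
        return np.bincount(self.bin_index.ravel(), minlength=self.n_bins + 1)[1:]


@dataclass
class DistributionTable:
    """Per-bin tissue fractions: n_bins × (GM, WM, CSF, VA, other).

    Fractions are within-bin (each row sums to 1), matching stacked
    distribution bars.
    """

    fractions: np.ndarray
    classes: tuple = TISSUE_CLASSES
    subject_id: str = ""
    source_map: str = "maxcc"  # "maxcc" | "alff" | "maxcc_swap"

    @property
    def n_bins(self) -> int:
        return self.fractions.shape[0]

    def curve(self, tissue: str) -> np.ndarray:
        return self.fractions[:, self.classes.index(tissue)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=list(self.classes))
        df.insert(0, "bin", np.arange(1, self.n_bins + 1))
        return df


@dataclass
class SlopeEstimate:
    """OLS slope of a tissue's fraction-vs-bin curve (fraction per bin)."""

    tissue: str
    slope: float
    intercept: float
    stderr: float
    subject_id: str = ""


@dataclass
class GroupDistribution:
    """Entrywise mean and sample sd of distribution tables across subjects."""

    mean_fractions: np.ndarray
    sd_fractions: np.ndarray
    n_subjects: int
    classes: tuple = TISSUE_CLASSES
    source_map: str = "maxcc"

    def curve(self, tissue: str) -> np.ndarray:
        return self.mean_fractions[:, self.classes.index(tissue)]


class TTestResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# binning


def rank_and_bin(value_map: np.ndarray, valid: np.ndarray, n_bins: int = 10) -> BinAssignment:
    """Ascending equal-count bins over the valid voxels of a scalar map.

    Sorting is stable with ties resolved by linear voxel index in x-fastest
    order; when n_valid is not divisible by n_bins the remainder voxels go to
    the lowest-index bins.
    """
    value_map = np.asarray(value_map, dtype=np.float64)
    valid = np.asarray(valid, dtype=bool)
    if value_map.shape != valid.shape:
        raise ShapeError(f"map shape {value_map.shape} != valid shape {valid.shape}")
    flat_vals = value_map.ravel(order="F")  # x-fastest linear index
    flat_valid = valid.ravel(order="F")
    idx = np.nonzero(flat_valid)[0]
    n_valid = idx.size
    if n_valid < n_bins:
        raise InsufficientVoxelsError(f"{n_valid} valid voxels < {n_bins} bins")
    v = flat_vals[idx]
    order = np.argsort(v, kind="stable")  # ties keep ascending x-fastest index

    base, rem = divmod(n_valid, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    bin_of_pos = np.empty(n_valid, dtype=np.int32)
    for b in range(n_bins):
        bin_of_pos[bounds[b] : bounds[b + 1]] = b + 1

    flat_bins = np.zeros(flat_vals.size, dtype=np.int32)
    flat_bins[idx[order]] = bin_of_pos
    bin_index = flat_bins.reshape(value_map.shape, order="F")

    v_sorted = v[order]
    edges = v_sorted[bounds[1:-1]] if n_bins > 1 else np.empty(0)
    return BinAssignment(bin_index=bin_index, n_bins=n_bins, bin_edges=edges, n_valid=n_valid)


def bin_tissue_fractions(
    bins: BinAssignment,
    masks: TissueMasks,
    subject_id: str = "",
    source_map: str = "maxcc",
) -> DistributionTable:
    """Within-bin tissue composition of the valid voxels."""
    if bins.bin_index.shape != masks.brain.shape:
        raise ShapeError(
            f"bin grid {bins.bin_index.shape} != mask grid {masks.brain.shape}"
        )
    labels = masks.exclusive_labels()
    n_classes = len(TISSUE_CLASSES)
    sel = bins.bin_index > 0
    flat = (bins.bin_index[sel] - 1) * n_classes + labels[sel]
    counts = np.bincount(flat, minlength=bins.n_bins * n_classes).reshape(
        bins.n_bins, n_classes
    )
    totals = counts.sum(axis=1, keepdims=True)
    fractions = counts / totals
    return DistributionTable(
        fractions=fractions, subject_id=subject_id, source_map=source_map
    )


# ---------------------------------------------------------------------------
# statistics


def fit_distribution_slope(table: DistributionTable, tissue: str) -> SlopeEstimate:
    """OLS of the tissue fraction against bin index 1..n_bins."""
    if table.n_bins < 3:
        raise ParameterError("slope fit needs at least 3 bins")
    x = np.arange(1, table.n_bins + 1, dtype=np.float64)
    y = table.curve(tissue)
    res = stats.linregress(x, y)
    return SlopeEstimate(
        tissue=tissue,
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        subject_id=table.subject_id,
    )


def average_distributions(tables: Sequence[DistributionTable]) -> GroupDistribution:
    """Entrywise mean and sample sd (n−1 denominator) across subjects."""
    if len(tables) < 2:
        raise ParameterError("group averaging needs >= 2 tables (sd undefined)")
    shapes = {t.fractions.shape for t in tables}
    classes = {t.classes for t in tables}
    if len(shapes) != 1 or len(classes) != 1:
        raise ShapeError("distribution tables disagree on shape or class order")
    stack = np.stack([t.fractions for t in tables])
    return GroupDistribution(
        mean_fractions=stack.mean(axis=0),
        sd_fractions=stack.std(axis=0, ddof=1),
        n_subjects=len(tables),
        classes=tables[0].classes,
        source_map=tables[0].source_map,
    )


def _slope_values(slopes) -> np.ndarray:
    return np.asarray(
        [s.slope if isinstance(s, SlopeEstimate) else float(s) for s in slopes]
    )


def test_slope_nonzero(slopes: Sequence) -> TTestResult:
    """One-sample two-sided t-test of subject slopes against zero.

    A zero-variance sample is degenerate: all-zero slopes give (t=0, p=1);
    identical nonzero slopes give (t=±inf, p=0), both flagged.
    """
    x = _slope_values(slopes)
    if x.size < 2:
        raise ParameterError("slope test needs >= 2 values")
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=float(np.sign(x[0]) * np.inf), p=0.0, degenerate=True)
    t, p = stats.ttest_1samp(x, popmean=0.0)
    return TTestResult(t=float(t), p=float(p))


def _two_sample_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Pooled (equal-variance) two-sample two-sided t-test with degenerate
    zero-variance handling."""
    if x.size < 2 or y.size < 2:
        raise ParameterError("two-sample test needs >= 2 values per group")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        if x[0] == y[0]:
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=float(np.sign(x[0] - y[0]) * np.inf), p=0.0, degenerate=True)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(t), p=float(p))


def compare_slope_sets(slopes_a: Sequence, slopes_b: Sequence) -> TTestResult:
    """Two-sample t-test between two sets of slopes (e.g. true vs swapped)."""
    return _two_sample_t(_slope_values(slopes_a), _slope_values(slopes_b))


def compare_bins(
    tables: Sequence[DistributionTable], tissue: str, bin_a: int, bin_b: int
) -> TTestResult:
    """Two-sample t-test between per-subject fractions at two bins."""
    if not tables:
        raise ParameterError("no tables")
    nb = tables[0].n_bins
    for b in (bin_a, bin_b):
        if not (1 <= b <= nb):
            raise ParameterError(f"bin {b} outside 1..{nb}")
    a = np.asarray([t.curve(tissue)[bin_a - 1] for t in tables])
    b = np.asarray([t.curve(tissue)[bin_b - 1] for t in tables])
    return _two_sample_t(a, b)


def curve_correlation(table_a, table_b, tissue: str) -> float:
    """Pearson correlation between two fraction-vs-bin curves for a tissue."""
    a = table_a.curve(tissue)
    b = table_b.curve(tissue)
    if a.size != b.size:
        raise ShapeError("curves have different numbers of bins")
    return float(stats.pearsonr(a, b).statistic)


def export_quantile_masks(bins: BinAssignment, group_size: int = 2) -> list[np.ndarray]:
    """Disjoint spatial masks covering consecutive groups of bins.

    With 10 bins and group size 2 this yields 5 masks, each holding 20% of
    the valid voxels ranked by increasing map value; their union is the valid
    mask.
    """
    if group_size < 1 or bins.n_bins % group_size != 0:
        raise ParameterError(
            f"n_bins={bins.n_bins} not divisible by group_size={group_size}"
        )
    masks = []
    for start in range(1, bins.n_bins + 1, group_size):
        sel = (bins.bin_index >= start) & (bins.bin_index < start + group_size)
        masks.append(sel)
    return masks
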