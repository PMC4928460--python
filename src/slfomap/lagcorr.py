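"""Voxelwise maximum lagged cross-correlation ("maxcc") mapping.

Each voxel timecourse is Pearson-correlated with the venous seed regressor at
every whole-TR lag inside a ±6 s window; the map stores the maximum
correlation, the lag at which it occurs, and a validity flag (maxcc strictly
above a 0.3 threshold).  Correlations use the truncated overlapping segment
at each lag, re-standardized per lag — truncation, not circular wraparound,
is the physical situation.

Sign convention: lag > 0 means the voxel is DELAYED relative to the seed,
i.e. voxel(t) ≈ seed(t − lag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import EmptyRoiError, InvalidLengthError, SamplingError, ShapeError
from .types import BoldSeries4D, SeedTimecourse


class LagPair(NamedTuple):
    lag_s: float
    r: float
    degenerate: bool = False  # zero-variance overlap; r reported as 0


@dataclass
class LagCorrelationMap:
    """Per-voxel maxcc, optimal lag and validity against one seed.

    ``maxcc`` and ``lag_s`` are NaN outside the brain mask; ``valid`` is
    ``maxcc > threshold`` (strict) with the optimal lag inside the window.
    """

    maxcc: np.ndarray
    lag_s: np.ndarray
    valid: np.ndarray
    threshold: float = 0.3
    lag_limit_s: float = 6.0
    subject_id: str = ""
    seed_label: str = "SSS"

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _lag_schedule(tr_seconds: float, lag_limit_s: float) -> list[int]:
    """Integer TR shifts ordered by tie-break priority: |lag| ascending,
    negative before positive at equal magnitude."""
    k_max = int(np.floor(lag_limit_s / tr_seconds + 1e-9))
    order = [0]
    for k in range(1, k_max + 1):
        order.extend([-k, k])
    return order


def _overlap_slices(n: int, k: int):
    """Seed/voxel index ranges for integer shift k (voxel delayed by k)."""
    if k >= 0:
        return slice(0, n - k), slice(k, n)
    return slice(-k, n), slice(0, n + k)


def lagged_pearson(
    seed: np.ndarray,
    voxel: np.ndarray,
    tr_seconds: float,
    lag_limit_s: float = 6.0,
) -> list[LagPair]:
    """Pearson r on the truncated overlap at every whole-TR lag in the window.

    Returned in ascending lag order.  A zero-variance overlap segment yields
    r = 0 with the ``degenerate`` flag set rather than an exception.
    """
    seed = np.asarray(seed, dtype=np.float64)
    voxel = np.asarray(voxel, dtype=np.float64)
    if seed.shape != voxel.shape or seed.ndim != 1:
        raise ShapeError(f"seed shape {seed.shape} != voxel shape {voxel.shape}")
    n = seed.size
    k_max = int(np.floor(lag_limit_s / tr_seconds + 1e-9))
    if n - k_max < 10:
        raise InvalidLengthError(
            f"series length {n} leaves fewer than 10 overlap samples at k_max={k_max}"
        )
    pairs = []
    for k in range(-k_max, k_max + 1):
        s_sl, v_sl = _overlap_slices(n, k)
        a = seed[s_sl] - seed[s_sl].mean()
        b = voxel[v_sl] - voxel[v_sl].mean()
        ssa = float(a @ a)
        ssb = float(b @ b)
        if ssa == 0.0 or ssb == 0.0:
            pairs.append(LagPair(lag_s=k * tr_seconds, r=0.0, degenerate=True))
        else:
            r = float(a @ b) / np.sqrt(ssa * ssb)
            pairs.append(LagPair(lag_s=k * tr_seconds, r=r))
    return pairs


def max_correlation(pairs: Sequence) -> tuple[float, float]:
    """Pick (maxcc, lag) from (lag, r) pairs.

    Ties on r are broken by the smallest |lag|, then by the negative lag.
    """
    if len(pairs) == 0:
        raise EmptyRoiError("no (lag, r) pairs to maximize over")
    best = max(pairs, key=lambda p: (p[1], -abs(p[0]), -p[0]))
    return float(best[1]), float(best[0])


def compute_maxcc_map(
    series: BoldSeries4D,
    seed: SeedTimecourse,
    brain_mask: np.ndarray,
    threshold: float = 0.3,
    lag_limit_s: float = 6.0,
) -> LagCorrelationMap:
    """Voxelwise maxcc/lag/validity map over the brain mask.

    Vectorized over voxels per lag; semantics identical to applying
    :func:`lagged_pearson` + :func:`max_correlation` per voxel.  Zero-variance
    voxels get maxcc = 0 (hence invalid), never an exception.
    """
    if abs(seed.tr_seconds - series.tr_seconds) > 1e-9:
        raise SamplingError(
            f"seed TR {seed.tr_seconds} != series TR {series.tr_seconds}"
        )
    if seed.values.size != series.n_timepoints:
        raise ShapeError(
            f"seed length {seed.values.size} != series n_timepoints {series.n_timepoints}"
        )
    brain = np.asarray(brain_mask, dtype=bool)
    if brain.shape != series.grid_shape:
        raise ShapeError(f"brain mask shape {brain.shape} != grid {series.grid_shape}")

    n = series.n_timepoints
    k_max = int(np.floor(lag_limit_s / series.tr_seconds + 1e-9))
    if n - k_max < 10:
        raise InvalidLengthError(
            f"series length {n} leaves fewer than 10 overlap samples at k_max={k_max}"
        )

    Y = series.data[brain]  # (n_voxels, n_t)
    s = seed.values
    best_r = np.full(Y.shape[0], -np.inf)
    best_lag = np.zeros(Y.shape[0])
    # priority order makes a strict '>' update reproduce the tie-break rule
    for k in _lag_schedule(series.tr_seconds, lag_limit_s):
        s_sl, v_sl = _overlap_slices(n, k)
        a = s[s_sl] - s[s_sl].mean()
        ssa = float(a @ a)
        B = Y[:, v_sl]
        Bc = B - B.mean(axis=1, keepdims=True)
        ssb = np.einsum("ij,ij->i", Bc, Bc)
        num = Bc @ a
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / np.sqrt(ssb * ssa)
        r[(ssb == 0.0) | (ssa == 0.0)] = 0.0
        better = r > best_r
        best_r[better] = r[better]
        best_lag[better] = k * series.tr_seconds

    maxcc = np.full(series.grid_shape, np.nan)
    lag_s = np.full(series.grid_shape, np.nan)
    maxcc[brain] = best_r
    lag_s[brain] = best_lag
    with np.errstate(invalid="ignore"):
        valid = brain & (maxcc > threshold) & (np.abs(lag_s) <= lag_limit_s)
    return LagCorrelationMap(
        maxcc=maxcc,
        lag_s=lag_s,
        valid=valid,
        threshold=threshold,
        lag_limit_s=lag_limit_s,
        subject_id=series.subject_id,
        seed_label=seed.source_label,
    )
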