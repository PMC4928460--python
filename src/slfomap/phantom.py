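"""Synthetic 4D BOLD phantoms with known systemic-LFO (sLFO) structure.

The phantom emulates the data model under study: every brain voxel carries a
subject-specific band-limited (0.01–0.15 Hz) systemic oscillation, delayed by
a smooth voxelwise lag field and mixed in with a tissue-dependent fraction
ordered VA > GM > WM (CSF ≈ 0), plus an aliased cardiac sinusoid confined to
an inferior "arterial" zone and white thermal noise:

    s_v(t) = a_v · L(t − τ_v) + c_v · cos(2π f_card t) + ε_v(t)

with ``L`` the planted unit-variance sLFO, ``τ_v`` a whole-TR lag, ``a_v`` the
tissue mixing fraction and ``ε`` white noise.  Lags are realized as whole-TR
circular shifts so the ground truth is exactly representable on the analysis
lag grid.  Geometry is synthetic concentric shapes (WM core, GM shell, CSF
rim, VA filaments with a posterior–superior SSS strip): the downstream
analysis depends only on mask membership, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import (
    CohortSizeError,
    GeometryError,
    InvalidBandError,
    InvalidLengthError,
    ParameterError,
)
from .types import BoldSeries4D, TissueMasks

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31

TISSUE_LABELS = ("GM", "WM", "CSF", "VA")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    Defaults mirror the emulated acquisition: TR 0.72 s, 500 timepoints,
    0.01–0.15 Hz sLFO band, lag field within ±4 s, mixing fractions
    VA 0.9 / GM 0.5 / WM 0.15 / CSF 0.0, cardiac tone at 1.1 Hz in the
    arterial zone, white-noise sd 0.5.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    n_timepoints: int = 500
    tr_seconds: float = 0.72
    band_low_hz: float = 0.01
    band_high_hz: float = 0.15
    mixing_fraction_by_tissue: dict = field(
        default_factory=lambda: {"VA": 0.9, "GM": 0.5, "WM": 0.15, "CSF": 0.0}
    )
    lag_field_range_s: tuple[float, float] = (-4.0, 4.0)
    cardiac_hz: float = 1.1
    cardiac_amplitude_by_tissue: dict = field(
        default_factory=lambda: {"VA": 0.0, "GM": 0.0, "WM": 0.0, "CSF": 0.0}
    )
    cardiac_amplitude_arterial: float = 0.5
    noise_sd: float = 0.5
    voxel_size_mm: float = 3.0
    rng_seed: int = 0

    def validate(self) -> None:
        nyquist = 0.5 / self.tr_seconds
        if not (0.0 < self.band_low_hz < self.band_high_hz < nyquist):
            raise InvalidBandError(
                f"band [{self.band_low_hz}, {self.band_high_hz}] Hz invalid for "
                f"Nyquist {nyquist:.4g} Hz"
            )
        for tissue, frac in self.mixing_fraction_by_tissue.items():
            if not (0.0 <= frac <= 1.0):
                raise ParameterError(f"mixing fraction for {tissue} not in [0,1]: {frac}")
        lo, hi = self.lag_field_range_s
        if not (-6.0 <= lo <= hi <= 6.0):
            raise ParameterError(f"lag field range {self.lag_field_range_s} outside ±6 s")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if any(n < 1 for n in self.grid_shape):
            raise GeometryError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.n_timepoints < 1:
            raise ParameterError("n_timepoints must be positive")


@dataclass
class PhantomGroundTruth:
    """Planted truth for parameter-recovery tests.

    ``true_lag_s`` is the lag actually realized (already rounded to the TR
    grid); ``true_mixing_fraction`` is zero outside the brain mask;
    ``slfo_timecourse`` is the planted unit-variance oscillation.
    """

    true_lag_s: np.ndarray
    true_mixing_fraction: np.ndarray
    slfo_timecourse: np.ndarray
    rng_seed: int


def make_slfo_timecourse(
    n_timepoints: int,
    tr_seconds: float,
    band_low_hz: float = 0.01,
    band_high_hz: float = 0.15,
    rng_seed: int = 0,
) -> np.ndarray:
    """Draw a zero-mean, unit-variance, band-limited oscillation.

    White Gaussian noise is drawn and only the spectral components inside
    ``[band_low_hz, band_high_hz]`` are retained, so out-of-band power is
    numerically zero; identical ``rng_seed`` gives identical output.
    """
    nyquist = 0.5 / tr_seconds
    if not (0.0 < band_low_hz < band_high_hz < nyquist):
        raise InvalidBandError(
            f"band [{band_low_hz}, {band_high_hz}] Hz invalid for Nyquist {nyquist:.4g} Hz"
        )
    if n_timepoints < 100:
        raise InvalidLengthError(f"n_timepoints must be >= 100, got {n_timepoints}")
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    in_band = (freqs >= band_low_hz) & (freqs <= band_high_hz)
    if not in_band.any():
        raise InvalidLengthError(
            f"no Fourier bin inside [{band_low_hz}, {band_high_hz}] Hz at "
            f"n={n_timepoints}, TR={tr_seconds}"
        )
    rng = np.random.default_rng(rng_seed)
    white = rng.standard_normal(n_timepoints)
    spectrum = np.fft.rfft(white)
    spectrum[~in_band] = 0.0
    x = np.fft.irfft(spectrum, n=n_timepoints)
    x -= x.mean()
    x /= x.std()
    return x


# ---------------------------------------------------------------------------
# geometry


def _normalized_radius(grid_shape):
    """Ellipsoidal radius field; brain is r < 1."""
    centers = [(n - 1) / 2.0 for n in grid_shape]
    half_axes = [0.46 * n for n in grid_shape]
    coords = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    r2 = sum(((c - ctr) / ax) ** 2 for c, ctr, ax in zip(coords, centers, half_axes))
    return np.sqrt(r2), centers, half_axes


def _nearest_brain_voxels(brain, target, k):
    """Indices of the k brain voxels nearest to a real-valued target point."""
    idx = np.argwhere(brain)
    d2 = ((idx - np.asarray(target)) ** 2).sum(axis=1)
    # tie-break by x-fastest linear index for determinism
    nx, ny, nz = brain.shape
    lin = idx[:, 0] + nx * (idx[:, 1] + ny * idx[:, 2])
    order = np.lexsort((lin, d2))
    return idx[order[:k]]


def make_tissue_masks(grid_shape: tuple[int, int, int], sss_size: int = 20) -> TissueMasks:
    """Concentric synthetic geometry: WM core, GM shell, CSF rim, VA filaments.

    The ``sss`` seed strip is the ``sss_size`` brain voxels nearest to a
    posterior–superior point on the outer shell; VA adds two through-brain
    venous columns.  VA takes precedence over the concentric labels so the
    four tissue masks are pairwise disjoint.
    """
    r, centers, half_axes = _normalized_radius(grid_shape)
    brain = r < 1.0
    if brain.sum() < max(sss_size, 50):
        raise GeometryError(f"grid {grid_shape} too small for a brain mask")

    wm = r < 0.55
    gm = (r >= 0.55) & (r < 0.85)
    csf = (r >= 0.85) & brain

    # SSS: posterior (+y) superior (+z) strip on the shell
    target = [
        centers[0],
        centers[1] + 0.62 * half_axes[1],
        centers[2] + 0.52 * half_axes[2],
    ]
    sss_idx = _nearest_brain_voxels(brain, target, sss_size)
    sss = np.zeros(grid_shape, dtype=bool)
    sss[tuple(sss_idx.T)] = True

    # two straight venous columns through the brain
    va = sss.copy()
    for dx, dy in ((0.3, 0.3), (-0.3, -0.3)):
        ix = int(round(centers[0] + dx * half_axes[0]))
        iy = int(round(centers[1] + dy * half_axes[1]))
        col = np.zeros(grid_shape, dtype=bool)
        col[ix, iy, :] = True
        va |= col & brain

    wm &= ~va
    gm &= ~va
    csf &= ~va

    masks = TissueMasks(wm=wm, gm=gm, csf=csf, va=va, brain=brain, sss=sss)
    for name in ("wm", "gm", "csf", "va", "sss"):
        if not getattr(masks, name).any():
            raise GeometryError(f"tissue mask {name!r} empty at grid {grid_shape}")
    masks.validate()
    return masks


def arterial_zone(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Inferior brain slab emulating the arterial base of the brain.

    The cardiac confound lives here and the sLFO mixing fraction is forced to
    zero, reproducing high-amplitude / low-correlation voxels near the
    inferior arteries.
    """
    r, centers, half_axes = _normalized_radius(grid_shape)
    brain = r < 1.0
    z = np.arange(grid_shape[2])[None, None, :]
    inferior = z < centers[2] - 0.5 * half_axes[2]
    return brain & np.broadcast_to(inferior, grid_shape)


def _smooth_lag_field(grid_shape, lag_range, tr_seconds, rng) -> np.ndarray:
    """Smooth random field scaled to ``lag_range`` and snapped to the TR grid."""
    lo, hi = lag_range
    raw = rng.standard_normal(grid_shape)
    sigma = [max(n / 8.0, 1.0) for n in grid_shape]
    smooth = ndimage.gaussian_filter(raw, sigma=sigma)
    lo_raw, hi_raw = smooth.min(), smooth.max()
    if hi_raw > lo_raw:
        scaled = lo + (smooth - lo_raw) * (hi - lo) / (hi_raw - lo_raw)
    else:  # pragma: no cover - constant field only on degenerate grids
        scaled = np.full(grid_shape, 0.5 * (lo + hi))
    k = np.rint(scaled / tr_seconds)
    return k * tr_seconds


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[BoldSeries4D, TissueMasks, PhantomGroundTruth]:
    """Generate one subject: 4D series, tissue masks, and ground truth.

    Deterministic given ``spec`` (including ``spec.rng_seed``).  The seed ROI
    strip gets lag 0 so the extracted seed regressor is phase-aligned with the
    planted sLFO and recovered voxel lags equal the planted lag field.
    """
    spec.validate()
    masks = make_tissue_masks(spec.grid_shape)
    artery = arterial_zone(spec.grid_shape)

    ss = np.random.SeedSequence(spec.rng_seed)
    s_slfo, s_lag, s_noise = (int(v) & _SEED_MASK for v in ss.generate_state(3))

    slfo = make_slfo_timecourse(
        spec.n_timepoints,
        spec.tr_seconds,
        spec.band_low_hz,
        spec.band_high_hz,
        rng_seed=s_slfo,
    )

    lag = _smooth_lag_field(
        spec.grid_shape, spec.lag_field_range_s, spec.tr_seconds, np.random.default_rng(s_lag)
    )
    lag[masks.sss] = 0.0  # seed strip is the sLFO reference phase
    lag[~masks.brain] = 0.0
    np.clip(lag, -6.0, 6.0, out=lag)

    mixing = np.zeros(spec.grid_shape)
    cardiac_amp = np.zeros(spec.grid_shape)
    labels = {"GM": masks.gm, "WM": masks.wm, "CSF": masks.csf, "VA": masks.va}
    for tissue, mask in labels.items():
        mixing[mask] = spec.mixing_fraction_by_tissue.get(tissue, 0.0)
        cardiac_amp[mask] = spec.cardiac_amplitude_by_tissue.get(tissue, 0.0)
    # arterial zone: cardiac-dominated, essentially no sLFO
    mixing[artery] = 0.0
    cardiac_amp[artery] = spec.cardiac_amplitude_arterial

    nt = spec.n_timepoints
    data = np.zeros(spec.grid_shape + (nt,))
    k_field = np.rint(lag / spec.tr_seconds).astype(int)
    for k in np.unique(k_field[masks.brain]):
        sel = masks.brain & (k_field == k)
        # positive lag = delayed: s(t) = L(t - τ), i.e. a forward roll by k
        data[sel] = mixing[sel, None] * np.roll(slfo, k)[None, :]

    if np.any(cardiac_amp > 0):
        t = np.arange(nt) * spec.tr_seconds
        tone = np.cos(2.0 * np.pi * spec.cardiac_hz * t)
        nz = cardiac_amp > 0
        data[nz] += cardiac_amp[nz, None] * tone[None, :]

    if spec.noise_sd > 0:
        rng_noise = np.random.default_rng(s_noise)
        noise = rng_noise.normal(0.0, spec.noise_sd, size=(int(masks.brain.sum()), nt))
        data[masks.brain] += noise

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    series = BoldSeries4D(data=data, tr_seconds=spec.tr_seconds, affine=affine)
    truth = PhantomGroundTruth(
        true_lag_s=lag,
        true_mixing_fraction=mixing,
        slfo_timecourse=slfo,
        rng_seed=spec.rng_seed,
    )
    return series, masks, truth


def generate_cohort(
    n_subjects: int = 8,
    spec: PhantomSpec | None = None,
    rng_seed: int = 0,
) -> list[tuple[BoldSeries4D, TissueMasks, PhantomGroundTruth]]:
    """Generate a cohort sharing geometry with independent sLFOs/lags/noise.

    Per-subject seeds are derived deterministically from ``rng_seed``; the
    swap-null analysis requires at least two subjects.
    """
    if n_subjects < 2:
        raise CohortSizeError(f"cohort needs >= 2 subjects, got {n_subjects}")
    if spec is None:
        spec = PhantomSpec()
    sub_seeds = np.random.SeedSequence(rng_seed).generate_state(n_subjects)
    cohort = []
    for i, s in enumerate(sub_seeds):
        sub_spec = replace(spec, rng_seed=int(s) & _SEED_MASK)
        series, masks, truth = generate_phantom(sub_spec)
        series.subject_id = f"sub-{i + 1:02d}"
        cohort.append((series, masks, truth))
    return cohort
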