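"""Core in-memory containers shared across pipeline stages.

The pipeline operates on three simple objects: a 4D BOLD-like series with its
repetition time (TR), a set of aligned binary tissue masks, and a 1D seed
timecourse extracted from a venous region of interest.  All arrays are plain
numpy arrays; NIfTI round-tripping lives in :mod:`slfomap.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ShapeError

#: Tissue class order used in every distribution table.  "other" absorbs
#: valid voxels carried by none of the four masks.
TISSUE_CLASSES = ("GM", "WM", "CSF", "VA", "other")


def _default_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


@dataclass
class BoldSeries4D:
    """A 4D voxel timeseries grid (x, y, z, t) with its sampling interval.

    Parameters
    ----------
    data:
        4D float array, time on the last axis; arbitrary signal units.
    tr_seconds:
        Repetition time (sampling interval) in seconds.
    affine:
        4x4 voxel-to-world affine; carried opaquely from input to output.
        Voxel spacing (mm) is read off its columns for spatial smoothing.
    subject_id:
        Free-text subject identifier, propagated to derived maps.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=_default_affine)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ShapeError(f"expected 4D data, got ndim={self.data.ndim}")
        if not (self.tr_seconds > 0):
            raise ShapeError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class TissueMasks:
    """Aligned binary masks: WM / GM / CSF / VA tissue classes, whole brain,
    and the venous seed ROI (``sss``, a subset of VA emulating the superior
    sagittal sinus).

    Invariants (checked by :meth:`validate`): one shared grid; every tissue
    mask is a subset of ``brain``; ``sss`` is a subset of ``va``; the four
    tissue masks are pairwise disjoint (VA takes precedence over the
    segmentation labels during construction).
    """

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    va: np.ndarray
    brain: np.ndarray
    sss: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wm", "gm", "csf", "va", "brain", "sss"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))

    def validate(self) -> None:
        shape = self.brain.shape
        for name in ("wm", "gm", "csf", "va", "sss"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ShapeError(f"mask {name!r} shape {m.shape} != {shape}")
            if name != "sss" and np.any(m & ~self.brain):
                raise ShapeError(f"mask {name!r} is not a subset of brain")
        if np.any(self.sss & ~self.va):
            raise ShapeError("sss must be a subset of va")
        tissues = [self.gm, self.wm, self.csf, self.va]
        for i in range(len(tissues)):
            for j in range(i + 1, len(tissues)):
                if np.any(tissues[i] & tissues[j]):
                    raise ShapeError("tissue masks are not pairwise disjoint")

    def exclusive_labels(self) -> np.ndarray:
        """Integer label volume indexing :data:`TISSUE_CLASSES`.

        VA is applied last so it wins over GM/WM/CSF should an input violate
        disjointness; voxels in no mask get the "other" code.
        """
        other = len(TISSUE_CLASSES) - 1
        lab = np.full(self.brain.shape, other, dtype=np.int8)
        for code, mask in enumerate((self.gm, self.wm, self.csf, self.va)):
            lab[mask] = code
        return lab


@dataclass
class SeedTimecourse:
    """Averaged timecourse over a venous ROI — the sLFO regressor."""

    values: np.ndarray
    tr_seconds: float
    source_label: str = "SSS"
    subject_id: str = ""
    n_roi_voxels: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ShapeError("seed timecourse must be 1D")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("seed timecourse must be finite")
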