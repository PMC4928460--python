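"""NIfTI-1 and plain-text I/O for every pipeline object.

4D series carry TR in the NIfTI header's 4th pixdim; masks are uint8
volumes; seed timecourses are one-value-per-line text files with a small
key=value sidecar; distribution tables and statistics are TSV.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ParameterError
from .types import BoldSeries4D, SeedTimecourse, TissueMasks

MASK_NAMES = ("wm", "gm", "csf", "va", "brain", "sss")


def save_series(series: BoldSeries4D, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    zooms = tuple(series.voxel_size_mm) + (series.tr_seconds,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_series(path, subject_id: str = "") -> BoldSeries4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ParameterError(f"{path}: expected a 4D series, got ndim={data.ndim}")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ParameterError(f"{path}: TR missing from NIfTI header (pixdim[4]={tr})")
    return BoldSeries4D(data=data, tr_seconds=tr, affine=np.asarray(img.affine),
                        subject_id=subject_id or Path(path).name.split(".")[0])


def save_volume(vol: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol).astype(dtype), affine), str(path))
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def save_masks(masks: TissueMasks, affine: np.ndarray, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in MASK_NAMES:
        paths[name] = save_volume(
            getattr(masks, name), affine, outdir / f"{name}.nii.gz", dtype=np.uint8
        )
    return paths


def load_masks(maskdir) -> TissueMasks:
    maskdir = Path(maskdir)
    fields = {name: load_volume(maskdir / f"{name}.nii.gz") > 0.5 for name in MASK_NAMES}
    masks = TissueMasks(**fields)
    masks.validate()
    return masks


def save_timecourse(seed: SeedTimecourse, path) -> Path:
    """One value per line, plus a key=value sidecar next to it."""
    path = Path(path)
    np.savetxt(path, seed.values, fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".info")
    sidecar.write_text(
        f"tr_seconds={seed.tr_seconds}\n"
        f"source_label={seed.source_label}\n"
        f"subject_id={seed.subject_id}\n"
        f"n_roi_voxels={seed.n_roi_voxels}\n"
    )
    return path


def load_timecourse(path) -> SeedTimecourse:
    path = Path(path)
    values = np.loadtxt(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".info")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    tr = float(meta.get("tr_seconds", 0) or 0)
    if tr <= 0:
        raise ParameterError(f"{path}: TR missing from timecourse sidecar")
    return SeedTimecourse(
        values=values,
        tr_seconds=tr,
        source_label=meta.get("source_label", "SSS"),
        subject_id=meta.get("subject_id", ""),
        n_roi_voxels=int(meta.get("n_roi_voxels", 0) or 0),
    )


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
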