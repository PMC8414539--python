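"""NIfTI and tabular I/O helpers shared by the CLI and pipeline."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .freewater import FreeWaterFit, ScalarMapSet, corrected_scalars
from .gradients import write_fsl_gradients
from .phantom import Phantom


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_phantom(phantom: Phantom, outdir: str | Path) -> dict[str, Path]:
    """Write a phantom as NIfTI DWI + FSL gradients + truth maps + masks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"dwi": save_nifti(phantom.data, phantom.affine, outdir / "dwi.nii.gz")}
    write_fsl_gradients(phantom.gtab, outdir / "dwi.bval", outdir / "dwi.bvec")
    paths["bval"] = outdir / "dwi.bval"
    paths["bvec"] = outdir / "dwi.bvec"
    for key, vol in phantom.truth.items():
        name = f"truth_{key}.nii.gz".replace("_T.", ".")
        paths[f"truth_{key}"] = save_nifti(vol, phantom.affine, outdir / name)
    for name, mask in phantom.masks.items():
        paths[f"mask_{name}"] = save_nifti(
            mask.astype(np.float64), phantom.affine, outdir / f"mask_{name}.nii.gz"
        )
    return paths


_MAP_FILES = {
    "FA_T": "fa_t.nii.gz",
    "MD_T": "md_t.nii.gz",
    "AD_T": "ad_t.nii.gz",
    "RD_T": "rd_t.nii.gz",
    "FW": "fw.nii.gz",
}


def save_scalar_maps(
    maps: ScalarMapSet, affine: np.ndarray, outdir: str | Path
) -> dict[str, Path]:
    """Write the five scalar maps plus the valid-voxel mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for key, arr in maps.as_dict().items():
        paths[key] = save_nifti(arr, affine, outdir / _MAP_FILES[key])
    paths["valid"] = save_nifti(
        maps.valid.astype(np.float64), affine, outdir / "valid.nii.gz"
    )
    return paths


def load_scalar_maps(indir: str | Path) -> tuple[ScalarMapSet, np.ndarray]:
    indir = Path(indir)
    arrays = {}
    affine = None
    for key, fname in _MAP_FILES.items():
        arrays[key], affine = load_nifti(indir / fname)
    valid, _ = load_nifti(indir / "valid.nii.gz")
    maps = ScalarMapSet(
        fa=arrays["FA_T"],
        md=arrays["MD_T"],
        ad=arrays["AD_T"],
        rd=arrays["RD_T"],
        fw=arrays["FW"],
        valid=valid > 0.5,
    )
    return maps, affine


def save_flags(fit: FreeWaterFit, affine: np.ndarray, path: str | Path) -> Path:
    return save_nifti(fit.flags.astype(np.float64), affine, path)


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    """UTF-8 CSV with full float precision (exact read-back for floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
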