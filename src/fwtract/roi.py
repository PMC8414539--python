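"""Tract-ROI aggregation of scalar maps.

A tract atlas is an ordered set of named 3-D masks on one shared grid.
The canonical atlas has 11 white matter tracts — five medial temporal lobe
projections (cingulum bundle, fornix, inferior longitudinal fasciculus,
uncinate fasciculus, tapetum), five frontal transcallosal tracts (inferior
frontal gyrus pars opercularis / orbitalis / triangularis, medial frontal
gyrus, middle frontal gyrus) and the superior longitudinal fasciculus —
and crossing it with the five free-water-corrected metrics yields the
55-value per-subject profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .freewater import ScalarMapSet

CANONICAL_TRACTS = (
    "cingulum_bundle",
    "fornix",
    "ilf",
    "ifg_opercularis",
    "ifg_orbitalis",
    "ifg_triangularis",
    "tapetum",
    "medial_frontal_gyrus",
    "middle_frontal_gyrus",
    "slf",
    "uf",
)

TRACT_LABELS = {
    "cingulum_bundle": "Cingulum Bundle",
    "fornix": "Fornix",
    "ilf": "Inferior Longitudinal Fasciculus",
    "ifg_opercularis": "IFG Pars Opercularis",
    "ifg_orbitalis": "IFG Pars Orbitalis",
    "ifg_triangularis": "IFG Pars Triangularis",
    "tapetum": "Tapetum",
    "medial_frontal_gyrus": "Medial Frontal Gyrus",
    "middle_frontal_gyrus": "Middle Frontal Gyrus",
    "slf": "Superior Longitudinal Fasciculus",
    "uf": "Uncinate Fasciculus",
}

METRICS = ("FW", "FAt", "MDt", "ADt", "RDt")

_METRIC_ATTR = {"FW": "fw", "FAt": "fa", "MDt": "md", "ADt": "ad", "RDt": "rd"}

_AFFINE_TOL = 1e-4


def metric_columns(tracts=CANONICAL_TRACTS, metrics=METRICS) -> list[str]:
    """Wide-table column names, tract-major: ``{tract}_{metric}``."""
    return [f"{t}_{m}" for t in tracts for m in metrics]


@dataclass(frozen=True)
class TractAtlas:
    """Ordered named binary masks sharing one grid and affine."""

    names: tuple
    masks: tuple
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.masks):
            raise ValueError("names and masks must pair up")
        if not self.names:
            raise ValueError("atlas needs at least one tract")
        shape = self.masks[0].shape
        for name, mask in zip(self.names, self.masks):
            if mask.shape != shape:
                raise ValueError(
                    f"mask {name!r} has shape {mask.shape}, expected {shape}"
                )
            if not mask.any():
                raise ValueError(f"mask {name!r} is empty after binarization")

    @property
    def shape(self) -> tuple:
        return self.masks[0].shape

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.masks))

    @classmethod
    def from_arrays(cls, named_masks: dict, affine: np.ndarray | None = None) -> "TractAtlas":
        names = tuple(named_masks)
        masks = tuple(np.asarray(m, dtype=bool) for m in named_masks.values())
        if affine is None:
            affine = np.eye(4)
        return cls(names=names, masks=masks, affine=affine)


def load_atlas(paths, threshold: float = 0.0, names=None) -> TractAtlas:
    """Load NIfTI template masks into a :class:`TractAtlas`.

    ``paths`` is a mapping name -> path or a sequence of paths (names then
    derive from file stems).  Probabilistic templates are binarized as
    ``value > threshold``; the default 0 treats templates inclusively.
    All masks must agree in grid shape and affine (within 1e-4); the first
    offending mask is named in the error.
    """
    if isinstance(paths, dict):
        items = list(paths.items())
    else:
        items = [(Path(p).name.split(".")[0], p) for p in paths]
    if names is not None:
        items = [(n, p) for n, (_, p) in zip(names, items)]

    masks = []
    ref_shape = None
    ref_affine = None
    for name, path in items:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        if ref_shape is None:
            ref_shape, ref_affine = data.shape, img.affine
        else:
            if data.shape != ref_shape:
                raise ValueError(
                    f"mask {name!r} ({path}): shape {data.shape} does not match "
                    f"atlas grid {ref_shape}"
                )
            if np.max(np.abs(img.affine - ref_affine)) > _AFFINE_TOL:
                raise ValueError(
                    f"mask {name!r} ({path}): affine disagrees with the atlas "
                    f"reference beyond {_AFFINE_TOL}"
                )
        binary = data > threshold
        if not binary.any():
            raise ValueError(
                f"mask {name!r} ({path}) is empty after thresholding at {threshold}"
            )
        masks.append(binary)
    return TractAtlas(
        names=tuple(n for n, _ in items), masks=tuple(masks), affine=ref_affine
    )


def extract_metrics(
    maps: ScalarMapSet, atlas: TractAtlas, statistic: str = "mean"
) -> pd.DataFrame:
    """Aggregate the five scalar maps within each tract mask.

    Returns a tidy table with one row per (tract, metric): columns
    ``tract``, ``metric``, ``value``, ``n_valid_voxels``.  Each value is
    the mean (or median, if configured) of the map over the mask
    intersected with the valid-voxel mask; cells with zero valid voxels
    are NaN, never zero.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if maps.valid.shape != atlas.shape:
        raise ValueError(
            f"scalar maps on grid {maps.valid.shape} but atlas on {atlas.shape}"
        )
    reducer = np.mean if statistic == "mean" else np.median
    rows = []
    for tract, mask in atlas:
        roi_valid = mask & maps.valid
        n = int(roi_valid.sum())
        for metric in METRICS:
            arr = getattr(maps, _METRIC_ATTR[metric])
            value = float(reducer(arr[roi_valid])) if n > 0 else np.nan
            rows.append(
                {"tract": tract, "metric": metric, "value": value,
                 "n_valid_voxels": n}
            )
    return pd.DataFrame(rows)


def tidy_to_wide(tidy: pd.DataFrame, subject_id: str | None = None) -> pd.DataFrame:
    """Pivot a tidy metrics table into one wide row (``{tract}_{metric}``)."""
    row = {
        f"{r.tract}_{r.metric}": r.value for r in tidy.itertuples(index=False)
    }
    out = pd.DataFrame([row])
    if subject_id is not None:
        out.insert(0, "subject_id", subject_id)
    return out
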