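"""Diffusion acquisition schemes: b-values and gradient directions.

The acquisition emulated throughout the package is a single-shell scheme —
one or more b = 0 volumes plus one non-zero shell (b = 1000 s/mm² by
default) sampled along directions spread quasi-uniformly over the
half-sphere.  Directions are generated deterministically by electrostatic
repulsion with antipodal symmetry, the standard layout for diffusion
gradient schemes.

FSL's plain-text ``bval``/``bvec`` dialect (one row of b-values; three rows
of direction cosines) is the on-disk representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

_B0_TOL = 1e-8  # b-values at or below this count as b = 0
_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-value (s/mm²) and unit gradient direction.

    Invariants enforced on construction: equal lengths, at least one
    b = 0 entry, and unit-norm directions wherever b > 0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float)).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must have shape (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise ValueError(
                f"length mismatch: {len(bvals)} b-values vs {len(bvecs)} directions"
            )
        if not np.any(bvals <= _B0_TOL):
            raise ValueError("acquisition scheme needs at least one b = 0 volume")
        dwi = bvals > _B0_TOL
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= _B0_TOL

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > _B0_TOL

    @property
    def shells(self) -> np.ndarray:
        """Distinct non-zero b-values, rounded to the nearest unit."""
        return np.unique(np.round(self.bvals[self.dwi_mask]))

    @property
    def is_single_shell(self) -> bool:
        return len(self.shells) == 1


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform seed layout on the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _repel(points: np.ndarray, n_iter: int = 500, step: float | None = None) -> np.ndarray:
    """Electrostatic repulsion on the sphere with antipodal symmetry.

    Each direction repels every other direction and its antipode, so the
    layout is optimized for axes rather than points (diffusion encoding is
    antipodally symmetric).  Fixed-step projected gradient descent; fully
    deterministic.
    """
    x = points.copy()
    n = len(x)
    if step is None:
        step = 0.02 / n
    for _ in range(n_iter):
        d_minus = x[:, None, :] - x[None, :, :]
        d_plus = x[:, None, :] + x[None, :, :]
        r_minus = np.linalg.norm(d_minus, axis=-1)
        r_plus = np.linalg.norm(d_plus, axis=-1)
        np.fill_diagonal(r_minus, np.inf)
        force = (d_minus / r_minus[..., None] ** 3).sum(axis=1)
        force += (d_plus / r_plus[..., None] ** 3).sum(axis=1)
        # tangential component only, then back to the sphere
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x = x + step * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    flip = x[:, 2] < 0.0
    x[flip] *= -1.0
    return x


def make_gradient_table(n_dirs: int, bval: float = 1000.0, n_b0: int = 1) -> GradientTable:
    """Build a single-shell scheme with ``n_b0`` b = 0 volumes.

    Parameters
    ----------
    n_dirs:
        Number of diffusion-weighted directions; at least 6 (a symmetric
        tensor has six degrees of freedom).
    bval:
        Shell b-value in s/mm².
    n_b0:
        Number of leading unweighted volumes.

    The direction set is deterministic for fixed inputs.
    """
    if n_dirs < 6:
        raise ValueError(
            f"n_dirs must be >= 6 to determine a tensor, got {n_dirs}"
        )
    if bval <= 0:
        raise ValueError(f"bval must be positive, got {bval}")
    if n_b0 < 1:
        raise ValueError("at least one b = 0 volume is required")
    dirs = _repel(_fibonacci_hemisphere(n_dirs))
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def minimum_pairwise_angle(bvecs: np.ndarray) -> float:
    """Smallest angle (degrees) between any two diffusion axes.

    Antipodal pairs are identified: the angle between axes g and h is
    arccos(|g·h|).
    """
    g = np.asarray(bvecs, dtype=float)
    dots = np.abs(np.clip(g @ g.T, -1.0, 1.0))
    iu = np.triu_indices(len(g), k=1)
    return float(np.degrees(np.arccos(dots[iu])).min())


def _parse_numeric_rows(path: str | Path) -> list[list[float]]:
    rows: list[list[float]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        row: list[float] = []
        for col_no, tok in enumerate(line.split(), start=1):
            try:
                row.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric token {tok!r} at line {line_no}, "
                    f"field {col_no}"
                ) from None
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no numeric data found")
    return rows


def read_fsl_gradients(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read an FSL-style bval/bvec pair into a :class:`GradientTable`.

    ``bval`` is one whitespace-separated row, ``bvec`` three rows (x, y, z).
    Files with the directions laid out one per row (n × 3) are auto-detected
    by shape and transposed with a logged warning.  Directions with b > 0
    are normalized to unit length.
    """
    bvals = np.array([v for row in _parse_numeric_rows(bval_path) for v in row])

    vec_rows = _parse_numeric_rows(bvec_path)
    lengths = {len(r) for r in vec_rows}
    if len(lengths) != 1:
        raise ValueError(f"{bvec_path}: ragged rows with lengths {sorted(lengths)}")
    vec = np.array(vec_rows)
    if vec.shape[0] != 3 and vec.shape[1] == 3:
        log.warning(
            "%s: directions laid out one per row (%d x 3); transposing to the "
            "FSL 3-row convention", bvec_path, vec.shape[0],
        )
        vec = vec.T
    if vec.shape[0] != 3:
        raise ValueError(
            f"{bvec_path}: expected 3 rows (x, y, z), got shape {vec.shape}"
        )
    if vec.shape[1] != len(bvals):
        raise ValueError(
            f"length mismatch: {len(bvals)} b-values but {vec.shape[1]} "
            f"direction columns"
        )
    bvecs = vec.T.astype(float)
    dwi = bvals > _B0_TOL
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length direction for a diffusion-weighted volume")
    bvecs[dwi] /= norms[:, None]
    return GradientTable(bvals, bvecs)


def write_fsl_gradients(gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a scheme as FSL bval (one row) and bvec (three rows) files."""
    Path(bval_path).write_text(" ".join(f"{b:.6g}" for b in gtab.bvals) + "\n")
    lines = [" ".join(f"{v:.17g}" for v in gtab.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")
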