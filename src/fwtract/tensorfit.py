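"""Single diffusion-tensor estimation and rotation-invariant scalars.

The baseline model for a voxel is the monoexponential tensor signal
``S(b, g) = S0 * exp(-b * g' D g)`` with a symmetric positive semi-definite
diffusion tensor D (mm²/s).  Fitting is weighted least squares on the
log-signal: an ordinary least-squares pass on ``log S`` followed by one
reweighting with weights proportional to the squared predicted signal,
which is the standard correction for the log transform's noise distortion.

Scalars follow the usual definitions: MD = (λ1+λ2+λ3)/3, AD = λ1,
RD = (λ2+λ3)/2 and FA = sqrt(3/2)·‖λ − λ̄‖/‖λ‖.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .gradients import GradientTable

EVAL_MIN = 1e-6  # mm²/s floor applied when projecting onto the PSD cone


class TensorScalars(NamedTuple):
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray


@dataclass
class TensorFitResult:
    """Voxelwise tensor field with S0 estimates and a validity mask."""

    tensors: np.ndarray  # (..., 3, 3) mm²/s
    s0: np.ndarray  # (...,)
    valid: np.ndarray  # (...,) bool; False where the signal was unusable

    @property
    def shape(self) -> tuple:
        return self.s0.shape


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Log-linear design: columns for Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0."""
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )


def _tensor_from_coeffs(p: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = p[:6]
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def sorted_eigensystem(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues in descending order with matching eigenvector columns.

    The eigenvector matrix is flipped to a proper rotation (det = +1).
    """
    vals, vecs = np.linalg.eigh(tensor)
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    if np.linalg.det(vecs) < 0:
        vecs = vecs.copy()
        vecs[:, 2] *= -1.0
    return vals, vecs


def fit_tensor_wls(signals: np.ndarray, gtab: GradientTable) -> TensorFitResult:
    """Fit the single-tensor model voxelwise by weighted least squares.

    Parameters
    ----------
    signals:
        Array of shape ``(..., n_volumes)``; any leading shape (a single
        voxel, a flat list of voxels, or a 3-D volume grid).
    gtab:
        Acquisition scheme; needs >= 6 distinct DW directions and >= 1 b0.

    Voxels with any non-positive signal are flagged invalid and skipped,
    never fit.  Eigenvalues of the returned tensors are floored at
    ``EVAL_MIN`` mm²/s.
    """
    sig = np.asarray(signals, dtype=float)
    if sig.shape[-1] != gtab.n_volumes:
        raise ValueError(
            f"signal has {sig.shape[-1]} volumes but scheme has {gtab.n_volumes}"
        )
    if int(gtab.dwi_mask.sum()) < 6:
        raise ValueError("need at least 6 diffusion-weighted volumes")

    lead_shape = sig.shape[:-1]
    flat = sig.reshape(-1, sig.shape[-1])
    n_vox = flat.shape[0]

    X = design_matrix(gtab)
    tensors = np.full((n_vox, 3, 3), np.nan)
    s0 = np.full(n_vox, np.nan)
    valid = np.zeros(n_vox, dtype=bool)

    for v in range(n_vox):
        s = flat[v]
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            continue
        y = np.log(s)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        # reweight by predicted signal (WLS on the log-linearized model)
        w = np.exp(X @ beta)
        beta, *_ = np.linalg.lstsq(w[:, None] * X, w * y, rcond=None)
        d = _tensor_from_coeffs(beta)
        vals, vecs = sorted_eigensystem(d)
        vals = np.maximum(vals, EVAL_MIN)
        tensors[v] = (vecs * vals) @ vecs.T
        s0[v] = np.exp(beta[6])
        valid[v] = True

    return TensorFitResult(
        tensors=tensors.reshape(lead_shape + (3, 3)),
        s0=s0.reshape(lead_shape),
        valid=valid.reshape(lead_shape),
    )


def tensor_scalars(evals: np.ndarray) -> TensorScalars:
    """FA, MD, AD, RD from ordered eigenvalues ``(..., 3)``.

    Requires λ1 >= λ2 >= λ3 >= 0.  The degenerate all-zero voxel maps to
    FA = MD = AD = RD = 0.  MD is computed as ``(AD + 2·RD)/3`` so that the
    identity holds exactly in floating point.
    """
    ev = np.asarray(evals, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected trailing dimension of 3 eigenvalues")
    if np.any(ev < -1e-15):
        raise ValueError("eigenvalues must be non-negative")
    if np.any(np.diff(ev, axis=-1) > 1e-15):
        raise ValueError("eigenvalues must be ordered descending (λ1 ≥ λ2 ≥ λ3)")

    ad = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    md = (ad + 2.0 * rd) / 3.0
    norm_sq = (ev**2).sum(axis=-1)
    dev = ev - md[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * (dev**2).sum(axis=-1) / norm_sq)
    fa = np.where(norm_sq > 0.0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return TensorScalars(fa=fa, md=md, ad=ad, rd=rd)
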