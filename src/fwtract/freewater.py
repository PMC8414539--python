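"""Single-shell free-water elimination by voxelwise bounded least squares.

Each voxel's signal is decomposed into an anisotropic tissue compartment
and an isotropic free-water compartment,

    S(b, g) = S0 * [ (1 - f) * exp(-b * g' D_t g) + f * exp(-b * d_iso) ],

and the fraction ``f`` together with the tissue tensor ``D_t`` is estimated
by trust-region-reflective nonlinear least squares with box constraints:
f ∈ [0, 1] and tissue eigenvalues inside a physiological window
(default [0.1e-3, 2.5e-3] mm²/s, which keeps the tissue tensor from
absorbing the water compartment).  The tensor is parameterized by its
eigenvalues and a z-y-z Euler rotation; S0 is fixed at the mean of the
unweighted volumes, which the model reproduces exactly at b = 0.

Identifiability.  With a single shell the model is not identifiable when
the tissue compartment is itself isotropic: a continuum of (f, d) pairs
yields the same two-point decay curve.  The fitter therefore flags voxels
whose fitted tissue FA falls below a configurable floor as
``FLAG_UNIDENTIFIABLE`` rather than silently reporting one member of the
ridge.  Initialization uses the classic warm start: a single-tensor fit,
with f seeded from where the observed mean diffusivity falls between a
tissue-MD prior and the free-water diffusivity.

Even for anisotropic tissue the likelihood surface has a long, shallow
valley trading f against the tissue trace (the Fisher information for f
alone is nearly singular at a single shell), so an unpenalized voxelwise
fit is accurate only in the noise-free limit.  The estimator therefore
adds a noise-adaptive Gaussian prior on the tissue mean diffusivity,
MD_t ~ N(md_tissue_prior, md_prior_sd²), entering the objective as an
extra residual weighted by the voxel's estimated noise level σ̂ (from an
unpenalized first pass).  As noise vanishes the penalty vanishes with it,
so exact data are still recovered exactly; under noise it selects the
physiologically plausible point on the valley, which is the standard
resolution of the single-shell free-water degeneracy.

Voxels are fit independently; results do not depend on traversal order.
An optional spatial smoothness penalty on f (``reg_weight``) couples
voxels through a small number of smooth-then-refit outer iterations and is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .gradients import GradientTable
from .phantom import D_ISO_DEFAULT
from .tensorfit import fit_tensor_wls, sorted_eigensystem, tensor_scalars

FLAG_OK = 0
FLAG_INVALID_SIGNAL = 1
FLAG_NOT_CONVERGED = 2
FLAG_UNIDENTIFIABLE = 3

FLAG_LABELS = {
    FLAG_OK: "ok",
    FLAG_INVALID_SIGNAL: "invalid_signal",
    FLAG_NOT_CONVERGED: "not_converged",
    FLAG_UNIDENTIFIABLE: "unidentifiable",
}


@dataclass(frozen=True)
class FreeWaterOptions:
    """Tunable knobs of the free-water fit.

    d_iso:
        Free-water diffusivity, mm²/s.
    lambda_min, lambda_max:
        Box constraints on the tissue eigenvalues, mm²/s.
    max_iter:
        Cap on model evaluations per voxel.
    tol:
        Relative tolerance on the squared-residual decrease.
    reg_weight:
        Weight of the optional spatial smoothness penalty on f (0 = off).
    fa_floor:
        Fitted tissue FA below which the voxel is flagged unidentifiable.
    md_tissue_prior:
        Mean of the tissue-MD prior (mm²/s); also seeds f from the
        observed MD in the warm start.
    md_prior_sd:
        SD of the tissue-MD prior (mm²/s); the penalty weight scales with
        the voxel's estimated noise level, so it is inert on noise-free
        data.  Set to ``inf`` (or 0 noise) for a pure unpenalized fit.
    """

    d_iso: float = D_ISO_DEFAULT
    lambda_min: float = 0.1e-3
    lambda_max: float = 2.5e-3
    max_iter: int = 200
    tol: float = 1e-10
    reg_weight: float = 0.0
    fa_floor: float = 0.10
    md_tissue_prior: float = 0.6e-3
    md_prior_sd: float = 0.1e-3
    f_init_bounds: tuple = (0.01, 0.99)

    def __post_init__(self) -> None:
        if self.d_iso <= 0:
            raise ValueError("d_iso must be positive")
        if not 0 < self.lambda_min < self.lambda_max:
            raise ValueError("need 0 < lambda_min < lambda_max")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.md_prior_sd <= 0:
            raise ValueError("md_prior_sd must be positive")


@dataclass
class FreeWaterFit:
    """Voxelwise free-water decomposition.

    Arrays share the leading shape of the input signal.  ``flags`` encodes
    per-voxel status (see ``FLAG_LABELS``); only ``FLAG_OK`` voxels enter
    downstream scalar maps.  ``ssr`` is the final sum of squared residuals.
    """

    f: np.ndarray
    tissue_evals: np.ndarray  # (..., 3), descending
    tissue_evecs: np.ndarray  # (..., 3, 3), columns
    s0: np.ndarray
    flags: np.ndarray
    ssr: np.ndarray
    options: FreeWaterOptions

    @property
    def shape(self) -> tuple:
        return self.f.shape

    @property
    def converged(self) -> np.ndarray:
        return self.flags != FLAG_NOT_CONVERGED


@dataclass
class ScalarMapSet:
    """The five co-registered scalar maps plus the valid-voxel mask.

    FA_T is unitless in [0, 1]; MD_T, AD_T, RD_T are in mm²/s; FW is the
    free-water fraction in [0, 1].  Voxels outside ``valid`` are NaN.
    """

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    fw: np.ndarray
    valid: np.ndarray

    def as_dict(self) -> dict:
        return {
            "FA_T": self.fa,
            "MD_T": self.md,
            "AD_T": self.ad,
            "RD_T": self.rd,
            "FW": self.fw,
        }


def _rot_zyz(a: float, b: float, c: float) -> np.ndarray:
    """Rz(a) @ Ry(b) @ Rz(c)."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array(
        [
            [ca * cb * cc - sa * sc, -ca * cb * sc - sa * cc, ca * sb],
            [sa * cb * cc + ca * sc, -sa * cb * sc + ca * cc, sa * sb],
            [-sb * cc, sb * sc, cb],
        ]
    )


def _rot_zyz_with_grad(a, b, c):
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz_a = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry_b = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rz_c = np.array([[cc, -sc, 0.0], [sc, cc, 0.0], [0.0, 0.0, 1.0]])
    d_rz_a = np.array([[-sa, -ca, 0.0], [ca, -sa, 0.0], [0.0, 0.0, 0.0]])
    d_ry_b = np.array([[-sb, 0.0, cb], [0.0, 0.0, 0.0], [-cb, 0.0, -sb]])
    d_rz_c = np.array([[-sc, -cc, 0.0], [cc, -sc, 0.0], [0.0, 0.0, 0.0]])
    r = rz_a @ ry_b @ rz_c
    return r, d_rz_a @ ry_b @ rz_c, rz_a @ d_ry_b @ rz_c, rz_a @ ry_b @ d_rz_c


def _model_and_jac(params, b, g, s0, sw):
    """Bi-tensor model values and analytic Jacobian wrt (f, λ1..3, a, b, c)."""
    f = params[0]
    lam = params[1:4]
    r, d_ra, d_rb, d_rc = _rot_zyz_with_grad(*params[4:7])
    gr = g @ r  # components of each gradient along the tensor axes
    q = (gr**2 * lam).sum(axis=1)
    st = np.exp(-b * q)
    model = s0 * ((1.0 - f) * st + f * sw)

    jac = np.empty((len(b), 7))
    jac[:, 0] = s0 * (sw - st)
    coef = -s0 * (1.0 - f) * b * st
    jac[:, 1] = coef * gr[:, 0] ** 2
    jac[:, 2] = coef * gr[:, 1] ** 2
    jac[:, 3] = coef * gr[:, 2] ** 2
    for k, dr in enumerate((d_ra, d_rb, d_rc)):
        dq = 2.0 * (gr * (g @ dr) * lam).sum(axis=1)
        jac[:, 4 + k] = coef * dq
    return model, jac


def _fit_voxel(sig, b, g, sw, x0, bounds, x_scale, opts, sigma_hat=0.0,
               f_prior=None):
    """Bounded NLLS for one voxel.

    ``sigma_hat > 0`` activates the tissue-MD prior (an extra residual
    ``σ̂ (MD_t − m0)/τ``); ``f_prior`` tethers f to a spatial target when
    the smoothness penalty is on.
    """
    x0_s0 = x0[-1]
    md_w = sigma_hat / (3.0 * opts.md_prior_sd)  # per-eigenvalue weight
    f_w = np.sqrt(opts.reg_weight) * x0_s0 if f_prior is not None else 0.0

    def fun(p):
        model, _ = _model_and_jac(p, b, g, x0_s0, sw)
        res = model - sig
        if md_w > 0:
            res = np.append(
                res, md_w * (p[1] + p[2] + p[3] - 3.0 * opts.md_tissue_prior)
            )
        if f_w > 0:
            res = np.append(res, f_w * (p[0] - f_prior))
        return res

    def jac(p):
        _, j = _model_and_jac(p, b, g, x0_s0, sw)
        if md_w > 0:
            extra = np.zeros((1, 7))
            extra[0, 1:4] = md_w
            j = np.vstack([j, extra])
        if f_w > 0:
            extra = np.zeros((1, 7))
            extra[0, 0] = f_w
            j = np.vstack([j, extra])
        return j

    res = least_squares(
        fun,
        x0[:7],
        jac=jac,
        bounds=bounds,
        method="trf",
        x_scale=x_scale,
        ftol=opts.tol,
        xtol=1e-14,
        gtol=1e-14,
        max_nfev=opts.max_iter,
    )
    return res


def fit_free_water(
    signals: np.ndarray,
    gtab: GradientTable,
    options: FreeWaterOptions | None = None,
    mask: np.ndarray | None = None,
) -> FreeWaterFit:
    """Fit the bi-tensor free-water model at every voxel.

    Parameters
    ----------
    signals:
        ``(..., n_volumes)`` signal array (single voxel, voxel list, or 4-D
        volume).
    gtab:
        Single-shell scheme (exactly one non-zero b) with >= 1 b0 volume.
    options:
        :class:`FreeWaterOptions`; defaults are used when omitted.
    mask:
        Optional boolean array over the leading shape; voxels outside it
        are flagged ``FLAG_INVALID_SIGNAL`` and skipped.
    """
    opts = options or FreeWaterOptions()
    sig = np.asarray(signals, dtype=float)
    if not gtab.is_single_shell:
        raise ValueError(
            f"free-water elimination here requires single-shell data; "
            f"scheme has shells {gtab.shells}"
        )
    lead_shape = sig.shape[:-1]
    flat = sig.reshape(-1, sig.shape[-1])
    n_vox = flat.shape[0]
    if mask is not None:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1)
        if mask_flat.shape[0] != n_vox:
            raise ValueError("mask shape does not match signal grid")
    else:
        mask_flat = np.ones(n_vox, dtype=bool)

    b = gtab.bvals
    g = gtab.bvecs
    sw = np.exp(-b * opts.d_iso)
    b0 = gtab.b0_mask

    tensor_fit = fit_tensor_wls(flat, gtab)
    tensors = tensor_fit.tensors.reshape(-1, 3, 3)

    f_out = np.full(n_vox, np.nan)
    evals_out = np.full((n_vox, 3), np.nan)
    evecs_out = np.full((n_vox, 3, 3), np.nan)
    s0_out = np.full(n_vox, np.nan)
    flags = np.full(n_vox, FLAG_INVALID_SIGNAL, dtype=np.int8)
    ssr = np.full(n_vox, np.nan)

    lb = np.array([0.0, opts.lambda_min, opts.lambda_min, opts.lambda_min,
                   -np.inf, -np.inf, -np.inf])
    ub = np.array([1.0, opts.lambda_max, opts.lambda_max, opts.lambda_max,
                   np.inf, np.inf, np.inf])
    x_scale = np.array([0.1, 1e-3, 1e-3, 1e-3, 1.0, 1.0, 1.0])

    valid_flat = tensor_fit.valid.reshape(-1) & mask_flat
    starts = np.full((n_vox, 8), np.nan)
    for v in np.flatnonzero(valid_flat):
        starts[v] = _warm_start(flat[v], tensors[v], b0, opts)

    n_free = 7
    dof = max(gtab.n_volumes - n_free, 1)

    def run_pass(f_prior_map=None):
        for v in np.flatnonzero(valid_flat):
            x0 = starts[v]
            f_prior = None if f_prior_map is None else f_prior_map[v]
            # pass 1: unpenalized fit, also yields the noise-level estimate
            res = _fit_voxel(flat[v], b, g, sw, x0, (lb, ub), x_scale, opts,
                             f_prior=f_prior)
            data_ssr = 2.0 * res.cost
            sigma_hat = np.sqrt(data_ssr / dof)
            if sigma_hat > 0:
                # pass 2: tissue-MD prior weighted by the noise level
                x1 = np.append(res.x, x0[-1])
                res = _fit_voxel(flat[v], b, g, sw, x1, (lb, ub), x_scale,
                                 opts, sigma_hat=sigma_hat, f_prior=f_prior)
                model, _ = _model_and_jac(res.x, b, g, x0[-1], sw)
                data_ssr = float(((model - flat[v]) ** 2).sum())
            f_out[v] = res.x[0]
            d_t = _rot_zyz(*res.x[4:7])
            d_t = (d_t * res.x[1:4]) @ d_t.T
            vals, vecs = sorted_eigensystem(d_t)
            evals_out[v] = vals
            evecs_out[v] = vecs
            s0_out[v] = x0[-1]
            ssr[v] = data_ssr
            if res.status <= 0:
                flags[v] = FLAG_NOT_CONVERGED
            elif tensor_scalars(np.maximum(vals, 0.0)).fa < opts.fa_floor:
                flags[v] = FLAG_UNIDENTIFIABLE
            else:
                flags[v] = FLAG_OK

    run_pass()

    if opts.reg_weight > 0 and len(lead_shape) == 3:
        # smooth-then-refit outer loop: tether each voxel's f to the local mean
        for _ in range(3):
            f_prior_map = _neighbor_mean(
                f_out.reshape(lead_shape), (flags == FLAG_OK).reshape(lead_shape)
            ).reshape(-1)
            # refit from the current estimate
            for v in np.flatnonzero(valid_flat):
                starts[v, 0] = f_out[v]
                starts[v, 1:4] = np.clip(
                    evals_out[v], opts.lambda_min, opts.lambda_max
                )
                starts[v, 4:7] = Rotation.from_matrix(evecs_out[v]).as_euler("ZYZ")
            run_pass(f_prior_map=np.where(np.isfinite(f_prior_map), f_prior_map,
                                          f_out))

    return FreeWaterFit(
        f=f_out.reshape(lead_shape),
        tissue_evals=evals_out.reshape(lead_shape + (3,)),
        tissue_evecs=evecs_out.reshape(lead_shape + (3, 3)),
        s0=s0_out.reshape(lead_shape),
        flags=flags.reshape(lead_shape),
        ssr=ssr.reshape(lead_shape),
        options=opts,
    )


def _warm_start(sig, tensor, b0_mask, opts: FreeWaterOptions) -> np.ndarray:
    """Initial (f, λ1..3, angles, S0) from the single-tensor fit."""
    s0 = float(sig[b0_mask].mean())
    vals, vecs = sorted_eigensystem(tensor)
    md = vals.mean()
    f0 = (md - opts.md_tissue_prior) / (opts.d_iso - opts.md_tissue_prior)
    f0 = float(np.clip(f0, *opts.f_init_bounds))
    # undo the water compartment's pull on the observed eigenvalues
    lam0 = (vals - f0 * opts.d_iso) / (1.0 - f0)
    lam0 = np.clip(lam0, opts.lambda_min, opts.lambda_max)
    angles = Rotation.from_matrix(vecs).as_euler("ZYZ")
    return np.array([f0, *lam0, *angles, s0])


def _neighbor_mean(volume: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean over the 6-neighborhood of each voxel, ignoring invalid voxels."""
    acc = np.zeros_like(volume, dtype=float)
    cnt = np.zeros_like(volume, dtype=float)
    filled = np.where(valid, volume, 0.0)
    w = valid.astype(float)
    for axis in range(3):
        for shift in (1, -1):
            acc += np.roll(filled, shift, axis=axis)
            cnt += np.roll(w, shift, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = acc / cnt
    return out


def corrected_scalars(fit: FreeWaterFit) -> ScalarMapSet:
    """Free-water-corrected scalar maps from a completed fit.

    Applies the standard eigenvalue scalars to the tissue tensor and copies
    f into the FW map.  Voxels with any non-OK flag are masked out (NaN).
    """
    valid = fit.flags == FLAG_OK
    shape = fit.shape
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    ad = np.full(shape, np.nan)
    rd = np.full(shape, np.nan)
    fw = np.full(shape, np.nan)
    if valid.any():
        ev = np.maximum(fit.tissue_evals[valid], 0.0)
        s = tensor_scalars(ev)
        fa[valid] = s.fa
        md[valid] = s.md
        ad[valid] = s.ad
        rd[valid] = s.rd
        fw[valid] = np.clip(fit.f[valid], 0.0, 1.0)
    return ScalarMapSet(fa=fa, md=md, ad=ad, rd=rd, fw=fw, valid=valid)
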