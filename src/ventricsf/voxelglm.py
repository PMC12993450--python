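"""Mass-univariate voxel-wise linear models with random-field-theory (RFT)
multiple-comparison correction.

Per in-mask voxel, the outcome images are regressed on a shared design
matrix and a t-statistic is computed for a contrast of interest.  Field
smoothness (FWHM per axis) is estimated from the normalized residual images
via the standard roughness estimator, the search volume is converted to
resolution elements (resels), and the corrected threshold is the t value at
which the expected Euler characteristic of the thresholded field equals the
requested family-wise alpha.  Euler-characteristic densities are implemented
for a t-field in dimensions 0..3; lower-dimensional resel counts are
approximated from the mask's surface area and bounding-box extents, which is
exact for box-shaped masks and a standard approximation otherwise.

A voxel-wise Benjamini-Hochberg FDR mode is provided as an alternative to
RFT for the same maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy import ndimage, optimize
from scipy.special import gammaln

from .stats import bh_fdr
from .volumes import ScalarVolume

__all__ = [
    "DesignMatrix",
    "TMapResult",
    "build_design",
    "fit_voxelwise",
    "estimate_fwhm",
    "rft_threshold",
    "fdr_threshold",
    "simulate_smooth_field",
]

#: t values are capped here for voxels fit exactly (zero residual variance
#: with a non-zero effect).
T_CAP = 1e6


@dataclass(frozen=True)
class DesignMatrix:
    """Named design matrix with a contrast selecting the tested effect."""

    X: np.ndarray
    names: tuple[str, ...]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        if X.ndim != 2 or len(self.names) != X.shape[1]:
            raise ValueError("X must be (n, p) with one name per column")
        if c.shape != (X.shape[1],):
            raise ValueError("contrast length must equal the number of columns")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient (collinear columns)")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "contrast", c)
        object.__setattr__(self, "names", tuple(self.names))


def build_design(
    table: pd.DataFrame, predictor: str, covariates=("age", "sex", "apoe4")
) -> DesignMatrix:
    """Intercept + standardized predictor of interest + standardized
    covariates, with the contrast on the predictor."""
    cols = [np.ones(len(table))]
    names = ["intercept", predictor]
    x = table[predictor].to_numpy(dtype=float)
    cols.append((x - x.mean()) / x.std(ddof=1))
    for c in covariates:
        v = table[c].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        cols.append((v - v.mean()) / sd if sd > 0 and len(np.unique(v)) > 2 else v - v.mean())
        names.append(c)
    contrast = np.zeros(len(names))
    contrast[1] = 1.0
    return DesignMatrix(X=np.column_stack(cols), names=tuple(names), contrast=contrast)


@dataclass
class TMapResult:
    tmap: ScalarVolume
    df: int
    mask: np.ndarray
    residuals: np.ndarray  # (n, *shape), for smoothness estimation
    fwhm_est_mm: tuple[float, float, float] | None = None
    resels: float | None = None
    corrected_threshold: float | None = None
    significant_mask: np.ndarray | None = None
    degenerate_mask: np.ndarray | None = None
    mode: str = "rft"


def fit_voxelwise(volumes, design: DesignMatrix, mask: np.ndarray) -> TMapResult:
    """OLS fit and contrast t-statistic at every in-mask voxel.

    ``volumes`` is a sequence of ScalarVolume (or arrays) on one grid, one
    per row of the design.  Out-of-mask voxels get t = 0.  Voxels with zero
    residual variance get t = 0 (flagged in ``degenerate_mask``) when the
    effect is also zero, and the documented cap otherwise.
    """
    arrays = [v.data if isinstance(v, ScalarVolume) else np.asarray(v, float) for v in volumes]
    vox = volumes[0].voxel_size_mm if isinstance(volumes[0], ScalarVolume) else (1.0, 1.0, 1.0)
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all volumes must share one grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask grid does not match the volumes")
    if not mask.any():
        raise ValueError("mask is empty")
    X = design.X
    n, p = X.shape
    if n != len(arrays):
        raise ValueError(f"design has {n} rows but {len(arrays)} volumes were given")
    if n < p + 3:
        raise ValueError(f"need at least rank+3={p + 3} participants, got {n}")

    Y = np.stack([a[mask] for a in arrays])  # (n, nvox)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, nvox)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    c = design.contrast
    var_c = float(c @ np.linalg.inv(X.T @ X) @ c)
    effect = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(sigma2 * var_c)
    degenerate = sigma2 <= np.finfo(float).eps * np.abs(Y).max() ** 2
    t = np.where(degenerate & (np.abs(effect) <= 1e-12), 0.0, t)
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)

    tvol = np.zeros(shape)
    tvol[mask] = t
    res4 = np.zeros((n,) + shape)
    res4[:, mask] = resid
    deg = np.zeros(shape, dtype=bool)
    deg[mask] = degenerate
    return TMapResult(
        tmap=ScalarVolume(data=tvol, voxel_size_mm=vox, tracer="none"),
        df=dof,
        mask=mask,
        residuals=res4,
        degenerate_mask=deg,
    )


def estimate_fwhm(residuals: np.ndarray, mask: np.ndarray, voxel_size_mm) -> tuple[float, float, float]:
    """Per-axis smoothness (FWHM, mm) from normalized residual images.

    Residual images are scaled to unit sum-of-squares at every voxel; the
    variance of their spatial forward differences then estimates the field
    roughness lambda per axis, and FWHM = sqrt(4 ln 2 / lambda) * voxel size.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 4 or R.shape[0] < 3:
        raise ValueError("need at least 3 residual volumes of shape (n, nx, ny, nz)")
    mask = np.asarray(mask, dtype=bool)
    norm = np.sqrt((R ** 2).sum(axis=0))
    ok = mask & (norm > 0)
    U = np.zeros_like(R)
    U[:, ok] = R[:, ok] / norm[ok]
    fwhm = []
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        pair = ok[tuple(sl_hi)] & ok[tuple(sl_lo)]
        if not pair.any():
            raise ValueError("mask too thin to estimate smoothness along axis %d" % ax)
        d = U[(slice(None),) + tuple(sl_hi)] - U[(slice(None),) + tuple(sl_lo)]
        lam = float((d[:, pair] ** 2).sum(axis=0).mean())
        lam = max(lam, 1e-12)
        fwhm.append(float(np.sqrt(4.0 * np.log(2.0) / lam) * voxel_size_mm[ax]))
    return tuple(fwhm)


# --- Euler-characteristic densities of a t-field (dimensions 0..3) --------

def _ec_densities(t: float, df: int) -> np.ndarray:
    v = float(df)
    a = 4.0 * np.log(2.0)
    base = (1.0 + t * t / v) ** (-(v - 1.0) / 2.0)
    lg = np.exp(gammaln((v + 1.0) / 2.0) - gammaln(v / 2.0))
    rho0 = sps.t.sf(t, df)
    rho1 = np.sqrt(a) / (2.0 * np.pi) * base
    rho2 = a / (2.0 * np.pi) ** 1.5 * lg / np.sqrt(v / 2.0) * t * base
    rho3 = a ** 1.5 / (2.0 * np.pi) ** 2 * base * ((v - 1.0) / v * t * t - 1.0)
    return np.array([rho0, rho1, rho2, rho3])


def _resel_counts(mask: np.ndarray, voxel_size_mm, fwhm_mm) -> np.ndarray:
    """Resel counts R_0..R_3: volume from the voxel count, surface (R_2)
    from exposed voxel faces, extents (R_1) from the bounding box."""
    mask = np.asarray(mask, dtype=bool)
    vx = np.asarray(voxel_size_mm, dtype=float)
    f = np.asarray(fwhm_mm, dtype=float)
    f = np.maximum(f, 1e-6)
    vol = mask.sum() * vx.prod()
    r3 = vol / f.prod()
    # exposed faces per axis -> surface area; for a cuboid S/2 = ab+ac+bc
    surf = 0.0
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        diff = mask[tuple(sl_hi)] ^ mask[tuple(sl_lo)]
        nfaces = diff.sum() + mask.take(0, axis=ax).sum() + mask.take(-1, axis=ax).sum()
        face_area = vx.prod() / vx[ax]
        other = [i for i in range(3) if i != ax]
        surf += nfaces * face_area / (f[other[0]] * f[other[1]])
    r2 = surf / 2.0
    idx = np.where(mask)
    extents = [(idx[ax].max() - idx[ax].min() + 1) * vx[ax] / f[ax] for ax in range(3)]
    r1 = float(sum(extents))
    return np.array([1.0, r1, r2, r3])


def expected_ec(t: float, df: int, resels: np.ndarray) -> float:
    return float(resels @ _ec_densities(t, df))


def rft_threshold(
    result: TMapResult,
    alpha: float = 0.001,
    fwhm_mm=None,
    two_sided: bool = True,
) -> TMapResult:
    """Complete a TMapResult with the RFT-corrected threshold and mask.

    Solves for the smallest t at which the expected Euler characteristic of
    the thresholded t-field is ``alpha`` (``alpha/2`` per tail when
    two-sided).  Smoothness defaults to the estimate from the residuals; a
    nominal kernel FWHM can be supplied instead via ``fwhm_mm``.
    """
    if result.df < 10:
        raise ValueError("RFT threshold requires df >= 10")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    vox = result.tmap.voxel_size_mm
    if fwhm_mm is None:
        fwhm_mm = estimate_fwhm(result.residuals, result.mask, vox)
    else:
        fwhm_mm = tuple(float(f) for f in np.broadcast_to(fwhm_mm, 3))
    resels = _resel_counts(result.mask, vox, fwhm_mm)
    tail = alpha / 2.0 if two_sided else alpha

    def g(t):
        return expected_ec(t, result.df, resels) - tail

    lo = float(sps.t.isf(tail, result.df))  # EC >= rho0*R0 => root is above this
    hi = lo + 1.0
    while g(hi) > 0 and hi < 1e3:
        hi *= 1.5
    if not np.isfinite(g(lo)) or not np.isfinite(g(hi)) or g(hi) > 0:
        raise ArithmeticError(
            f"expected-EC solve failed (resels={resels}, df={result.df}, alpha={alpha})"
        )
    thr = float(optimize.brentq(g, lo, hi, xtol=1e-8))
    sig = np.zeros(result.mask.shape, dtype=bool)
    t = result.tmap.data
    sig[result.mask] = np.abs(t[result.mask]) >= thr if two_sided else t[result.mask] >= thr
    return replace(
        result,
        fwhm_est_mm=tuple(fwhm_mm),
        resels=float(resels[3]),
        corrected_threshold=thr,
        significant_mask=sig,
        mode="rft",
    )


def fdr_threshold(result: TMapResult, q: float = 0.001) -> TMapResult:
    """Voxel-wise Benjamini-Hochberg alternative to RFT on the same t-map."""
    t = result.tmap.data[result.mask]
    p = 2.0 * sps.t.sf(np.abs(t), result.df)
    _, reject = bh_fdr(p, q=q)
    sig = np.zeros(result.mask.shape, dtype=bool)
    sig[result.mask] = reject
    thr = float(np.abs(t[reject]).min()) if reject.any() else float("inf")
    return replace(result, corrected_threshold=thr, significant_mask=sig, mode="voxel-fdr")


def simulate_smooth_field(
    shape, fwhm_mm: float, voxel_size_mm, rng: np.random.Generator
) -> np.ndarray:
    """Stationary unit-variance Gaussian field with the requested smoothness.

    White noise is generated on a padded grid, convolved with the Gaussian
    kernel, cropped, and rescaled by the theoretical kernel norm so the
    field is stationary (no boundary variance roll-off)."""
    vox = np.broadcast_to(np.asarray(voxel_size_mm, float), 3)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    pad = np.ceil(4 * sigma_vox).astype(int)
    big = tuple(s + 2 * p for s, p in zip(shape, pad))
    w = rng.standard_normal(big)
    sm = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="constant")
    sl = tuple(slice(p, p + s) for p, s in zip(pad, shape))
    out = sm[sl]
    # var of smoothed unit white noise = prod_i 1/(2 sqrt(pi) sigma_i)
    var = float(np.prod(1.0 / (2.0 * np.sqrt(np.pi) * sigma_vox)))
    return out / np.sqrt(var)
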