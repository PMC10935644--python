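"""Mass-univariate voxelwise regression with random-field-theory correction.

Per voxel, image intensity (tau-PET SUVR) is regressed on a functional
score plus covariates by OLS, giving a t-map for the score term.
Familywise error over the map is controlled at the peak level with
random field theory (RFT): the corrected threshold is the smallest t at
which the expected Euler characteristic of the one-sided excursion set
of a t-field, over the search region measured in resels, falls below
alpha. Residual smoothness (FWHM per axis) is estimated from the
variance of spatial derivatives of the normalised residuals.

The suprathreshold map is then compared with Braak ROI masks: for each
ROI the report gives the fraction of ROI voxels that are suprathreshold
(default denominator) and the fraction of suprathreshold voxels inside
the ROI.

Inputs must be pre-aligned volumes on a common grid; no registration or
resampling is performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "VoxelImageSet",
    "TMap",
    "OverlapReport",
    "fit_voxelwise_glm",
    "estimate_smoothness",
    "expected_euler_characteristic",
    "rft_threshold",
    "roi_overlap",
    "load_images",
    "save_tmap",
]

_LN2_4 = 4.0 * np.log(2.0)


@dataclass
class VoxelImageSet:
    """n aligned 3D volumes on a common grid plus an analysis mask."""

    data: np.ndarray  # (n_subjects, nx, ny, nz)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mask: np.ndarray | None = None  # bool (nx, ny, nz); None = full grid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_subjects, nx, ny, nz)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape does not match image grid")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass
class TMap:
    """Voxelwise t-statistics with RFT bookkeeping."""

    t: np.ndarray  # 3D; NaN outside mask
    df: int
    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    degenerate: np.ndarray  # voxels with zero residual variance (t forced to 0)
    residuals: np.ndarray | None = None  # (n_subjects, nx, ny, nz), for smoothness
    fwhm_mm: np.ndarray | None = None
    resels: float | None = None
    alpha: float | None = None
    threshold: float | None = None
    suprathreshold: np.ndarray | None = field(default=None)


def fit_voxelwise_glm(images: VoxelImageSet, score, covariates=None) -> TMap:
    """Per-voxel OLS of intensity on score + covariates; t for the score term.

    ``covariates`` is a 2D array / DataFrame of numeric columns (e.g. age,
    male indicator, amyloid SUVR), or None. Voxels with zero residual
    variance get t = 0 and are annotated in ``TMap.degenerate``.
    """
    score = np.asarray(score, dtype=float)
    n = images.n_subjects
    if score.shape != (n,):
        raise ValueError("score length must equal the number of subjects")
    parts = [np.ones(n), score]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows must equal the number of subjects")
        parts.append(C)
    X = np.column_stack(parts)
    if not np.all(np.isfinite(X)):
        raise ValueError("score and covariates must be complete (no missing values)")
    p = X.shape[1]
    if n < p + 2:
        raise ValueError(f"n={n} subjects too few for {p} parameters")

    mask = images.mask
    Y = images.data[:, mask]  # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    c_ss = xtx_inv[1, 1]
    sigma2 = rss / df
    # zero residual variance up to float precision (e.g. constant voxels)
    scale = np.mean(Y * Y, axis=0)
    degenerate_flat = rss <= 1e-12 * scale
    se = np.sqrt(np.where(degenerate_flat, 1.0, sigma2 * c_ss))
    t_flat = np.where(degenerate_flat, 0.0, beta[1] / se)

    t = np.full(mask.shape, np.nan)
    t[mask] = t_flat
    degenerate = np.zeros(mask.shape, dtype=bool)
    degenerate[mask] = degenerate_flat
    res_vol = np.zeros((n,) + mask.shape)
    res_vol[:, mask] = resid
    return TMap(
        t=t,
        df=df,
        mask=mask,
        voxel_size=tuple(images.voxel_size),
        degenerate=degenerate,
        residuals=res_vol,
    )


def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray, voxel_size):
    """Estimate per-axis FWHM (mm) and resel count from model residuals.

    Residuals are normalised per voxel to unit sum of squares across
    subjects; the roughness along each axis is the mean squared spatial
    derivative of the normalised residuals, and FWHM_i = sqrt(4 ln 2 /
    roughness_i) voxels. Resels = masked voxels / prod(FWHM in voxels).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 4 or residuals.shape[0] < 10:
        raise ValueError("need >= 10 residual volumes of shape (n, nx, ny, nz)")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 27:
        raise ValueError("mask smaller than 3x3x3 voxels")
    voxel_size = np.asarray(voxel_size, dtype=float)

    rss = np.sum(residuals**2, axis=0)
    ok = mask & (rss > 0)
    u = np.zeros_like(residuals)
    u[:, ok] = residuals[:, ok] / np.sqrt(rss[ok])

    fwhm_vox = np.empty(3)
    for ax in range(3):
        d = np.diff(u, axis=ax + 1)
        both = np.logical_and(
            np.take(ok, range(ok.shape[ax] - 1), axis=ax),
            np.take(ok, range(1, ok.shape[ax]), axis=ax),
        )
        if both.sum() == 0:
            raise ValueError(f"no neighbouring in-mask voxel pairs along axis {ax}")
        lam = float(np.mean(np.sum(d[:, both] ** 2, axis=0)))
        fwhm_vox[ax] = np.sqrt(_LN2_4 / lam) if lam > 0 else np.inf
    fwhm_mm = fwhm_vox * voxel_size
    resels = float(mask.sum() / np.prod(fwhm_vox))
    return fwhm_mm, resels


def _ec_densities(t: float, df: int) -> np.ndarray:
    """EC densities rho_0..rho_3 of a one-sided t-field (unit-resel scale)."""
    nu = float(df)
    base = (1.0 + t * t / nu) ** (-(nu - 1.0) / 2.0)
    rho0 = stats.t.sf(t, nu)
    rho1 = np.sqrt(_LN2_4) / (2.0 * np.pi) * base
    g = np.exp(special.gammaln((nu + 1.0) / 2.0) - special.gammaln(nu / 2.0))
    rho2 = (_LN2_4 / (2.0 * np.pi) ** 1.5) * g / np.sqrt(nu / 2.0) * t * base
    rho3 = (_LN2_4**1.5 / (2.0 * np.pi) ** 2) * base * ((nu - 1.0) / nu * t * t - 1.0)
    return np.array([rho0, rho1, rho2, rho3])


def _resel_counts(resels: float) -> np.ndarray:
    # cube model for the search region: side s resels per dimension
    s = max(resels, 0.0) ** (1.0 / 3.0)
    return np.array([1.0, 3.0 * s, 3.0 * s * s, s**3])


def expected_euler_characteristic(t: float, df: int, resels: float) -> float:
    """Expected EC of the one-sided excursion set above t (peak-level FWE proxy)."""
    return float(_resel_counts(resels) @ _ec_densities(t, df))


def rft_threshold(tmap: TMap, alpha: float = 0.001) -> tuple[float, np.ndarray]:
    """Peak-level RFT-corrected threshold and the suprathreshold mask.

    Estimates smoothness from the stored residuals if not yet done, then
    solves E[EC](t) = alpha for the one-sided positive contrast. Sets
    ``tmap.threshold`` / ``tmap.suprathreshold`` and returns them.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tmap.df <= 2:
        raise ValueError("degrees of freedom must exceed 2")
    if tmap.resels is None:
        if tmap.residuals is None:
            raise ValueError("smoothness not estimated and no residuals stored")
        tmap.fwhm_mm, tmap.resels = estimate_smoothness(
            tmap.residuals, tmap.mask, tmap.voxel_size
        )

    def f(t):
        return expected_euler_characteristic(t, tmap.df, tmap.resels) - alpha

    lo = 1.0
    while f(lo) < 0 and lo > 1e-3:
        lo /= 2.0  # alpha large enough that even low t suffices
    hi = 100.0
    if f(lo) < 0:
        thr = lo
    else:
        thr = float(optimize.brentq(f, lo, hi))
    supra = np.zeros_like(tmap.mask)
    supra[tmap.mask] = np.nan_to_num(tmap.t[tmap.mask]) > thr
    tmap.alpha = alpha
    tmap.threshold = thr
    tmap.suprathreshold = supra
    return thr, supra


@dataclass
class OverlapReport:
    """Per-ROI overlap between the suprathreshold map and Braak masks."""

    table: pd.DataFrame  # roi, n_roi, n_supra, n_intersect, frac_of_roi, frac_of_tmap
    denominator: str = "roi"

    def proportion(self, roi: str) -> float:
        col = "frac_of_roi" if self.denominator == "roi" else "frac_of_tmap"
        return float(self.table.set_index("roi").loc[roi, col])


def roi_overlap(
    suprathreshold: np.ndarray,
    roi_masks: dict[str, np.ndarray],
    denominator: str = "roi",
) -> OverlapReport:
    """Overlap proportions between a suprathreshold map and ROI masks.

    ``frac_of_roi`` = |supra ∩ ROI| / |ROI| (default reported proportion);
    ``frac_of_tmap`` = |supra ∩ ROI| / |supra|. Both appear in the table.
    """
    if denominator not in ("roi", "tmap"):
        raise ValueError("denominator must be 'roi' or 'tmap'")
    supra = np.asarray(suprathreshold, dtype=bool)
    n_supra = int(supra.sum())
    rows = []
    for name, m in roi_masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != supra.shape:
            raise ValueError(f"ROI mask {name!r} grid does not match the t-map grid")
        inter = int(np.logical_and(supra, m).sum())
        n_roi = int(m.sum())
        rows.append(
            {
                "roi": name,
                "n_roi": n_roi,
                "n_supra": n_supra,
                "n_intersect": inter,
                "frac_of_roi": inter / n_roi if n_roi else np.nan,
                "frac_of_tmap": inter / n_supra if n_supra else np.nan,
            }
        )
    return OverlapReport(table=pd.DataFrame(rows), denominator=denominator)


def load_images(paths, mask_path=None) -> VoxelImageSet:
    """Stack NIfTI volumes (identical grids required) into a VoxelImageSet."""
    import nibabel as nib

    vols, affine, shape = [], None, None
    for p in paths:
        img = nib.load(str(p))
        if affine is None:
            affine, shape = img.affine, img.shape
        elif img.shape != shape or not np.allclose(img.affine, affine):
            raise ValueError(f"volume {p} is not on the common grid")
        vols.append(np.asarray(img.get_fdata(), dtype=float))
    voxel_size = tuple(float(z) for z in nib.affines.voxel_sizes(affine))
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if mimg.shape != shape:
            raise ValueError("mask grid does not match the image grid")
        mask = np.asarray(mimg.get_fdata()) > 0
    return VoxelImageSet(np.stack(vols), voxel_size=voxel_size, mask=mask)


def save_tmap(tmap: TMap, path, sidecar_path=None) -> None:
    """Write the t-map as NIfTI plus a JSON sidecar with the RFT summary."""
    import nibabel as nib

    affine = np.diag(list(tmap.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.nan_to_num(tmap.t), affine), str(path))
    if sidecar_path is not None:
        meta = {
            "df": int(tmap.df),
            "fwhm_mm": None if tmap.fwhm_mm is None else list(map(float, tmap.fwhm_mm)),
            "resels": tmap.resels,
            "alpha": tmap.alpha,
            "threshold": tmap.threshold,
            "n_suprathreshold": None
            if tmap.suprathreshold is None
            else int(tmap.suprathreshold.sum()),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
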