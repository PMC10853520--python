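"""Tracing-accuracy scoring.

A child's tracing is aligned to the target shape by an affine transform
(translation, rotation, anisotropic scale about the raster center — no
shear) chosen to minimize the pixel-wise correlation distance

    loss = -NCC(T', S) = -(1/N) * sum_p (T'_p - mean T') (S_p - mean S) / (sd T' * sd S)

between the aligned tracing ``T'`` and the target ``S``.  The residual
correlation distance ``1 - NCC`` after alignment is the *shape error*; the
magnitudes of the recovered translation, rotation, and scaling components
are the *spatial errors*.  An ordinal (proportional-odds) regression with
per-rater intercepts calibrates these four error components plus shape
identity against human 1-5 quality ratings, and the fitted latent-scale
linear predictor serves as the tracing score.

Registration is multi-resolution gradient-free descent (Powell) on
Gaussian-smoothed rasters, restarted from several initial rotations to
avoid local minima, and is deterministic for fixed options.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

__all__ = [
    "AffineParams",
    "TracingErrors",
    "RegistrationOptions",
    "RegistrationResult",
    "TracingCalibration",
    "warp_raster",
    "ncc",
    "register_affine",
    "tracing_errors",
    "fit_tracing_calibration",
    "score_tracings",
    "ERROR_COLUMNS",
]

ERROR_COLUMNS = ("shape_error", "translation_mag", "rotation_mag", "scaling_mag")


@dataclass(frozen=True)
class AffineParams:
    """Translation + rotation + anisotropic scale about the raster center.

    The forward map of image content, in (x, y) pixel coordinates with
    center ``c``, is ``p -> R(theta) @ diag(sx, sy) @ (p - c) + c + (tx, ty)``.
    """

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    sx: float = 1.0
    sy: float = 1.0

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("scale factors must be positive")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    def inverse(self) -> "AffineParams":
        """Exact inverse when sx == sy; otherwise the rotation/scale order
        does not commute and the inverse leaves this family — raise."""
        if not math.isclose(self.sx, self.sy, rel_tol=1e-9):
            raise ValueError("inverse of anisotropic affine leaves the family")
        s = self.sx
        ct, st = math.cos(-self.theta), math.sin(-self.theta)
        tx, ty = -self.tx, -self.ty
        return AffineParams(
            tx=(ct * tx - st * ty) / s,
            ty=(st * tx + ct * ty) / s,
            theta=-self.theta,
            sx=1.0 / s,
            sy=1.0 / s,
        )


def _linear_part(params: AffineParams) -> np.ndarray:
    ct, st = math.cos(params.theta), math.sin(params.theta)
    r = np.array([[ct, -st], [st, ct]])
    return r @ np.diag([params.sx, params.sy])


def warp_raster(
    image: np.ndarray, params: AffineParams, order: int = 1, cval: float = 1.0
) -> np.ndarray:
    """Apply the forward affine map to image content (white background fill)."""
    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    c = (n - 1) / 2.0
    m = _linear_part(params)
    m_inv = np.linalg.inv(m)
    # ndimage uses (row, col) = (y, x); conjugate the xy matrix by the swap.
    p = np.array([[0.0, 1.0], [1.0, 0.0]])
    matrix_yx = p @ m_inv @ p
    center = np.array([c, c])
    shift = np.array([params.tx, params.ty])
    offset_xy = center - m_inv @ (center + shift)
    offset_yx = p @ offset_xy
    return ndimage.affine_transform(
        img, matrix_yx, offset=offset_yx, order=order, mode="constant", cval=cval
    )


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation (Pearson r over pixels), in [-1, 1].

    Returns NaN if either image has zero variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return float("nan")
    return float((a @ b) / denom)


@dataclass(frozen=True)
class RegistrationOptions:
    """Registration settings; defaults are the documented deterministic ones."""

    smooth_sigma: float = 2.0
    #: heavier smoothing for the reported shape error, so the residual
    #: correlation distance reflects contour mismatch rather than the
    #: sub-pixel resampling blur introduced by scaling a tracing
    shape_error_sigma: float = 4.0
    coarse_factor: float = 0.5
    rotation_starts_deg: tuple[float, ...] = (0.0, 20.0, -20.0)
    max_translation: float = 0.35  # fraction of raster size
    #: rotations are searched within +/- 45 degrees: tracings are assumed
    #: not to be turned further than that, and the bound keeps the rotation
    #: component unique for 4-fold-symmetric targets like the square
    max_rotation: float = math.pi / 4
    log_scale_bound: float = math.log(2.5)
    coarse_xtol: float = 1e-3
    fine_xtol: float = 1e-6
    max_iter: int = 400


@dataclass(frozen=True)
class RegistrationResult:
    params: AffineParams
    final_ncc: float
    converged: bool
    blank: bool = False


def _vec_to_params(v: np.ndarray) -> AffineParams:
    return AffineParams(
        tx=float(v[0]),
        ty=float(v[1]),
        theta=float(v[2]),
        sx=float(math.exp(v[3])),
        sy=float(math.exp(v[4])),
    )


def register_affine(
    tracing: np.ndarray,
    target: np.ndarray,
    options: Optional[RegistrationOptions] = None,
) -> RegistrationResult:
    """Find the affine transform of the tracing maximizing NCC with the target.

    Returns the transform applied to the *tracing*; for a tracing generated
    by applying transform A to the target, the recovered transform
    approximates A^{-1}.  A blank (constant) tracing is flagged and returned
    with the identity transform and NaN NCC.
    """
    opts = options or RegistrationOptions()
    trac = np.asarray(tracing, dtype=float)
    targ = np.asarray(target, dtype=float)
    if trac.shape != targ.shape:
        raise ValueError("tracing and target must share raster dimensions")
    if targ.std() == 0:
        raise ValueError("target raster is constant; registration undefined")
    if trac.std() == 0:
        return RegistrationResult(
            AffineParams.identity(), float("nan"), converged=False, blank=True
        )

    n = trac.shape[0]
    f = opts.coarse_factor
    trac_c = ndimage.zoom(trac, f, order=1)
    targ_c = ndimage.zoom(targ, f, order=1)
    # smooth the *fixed* image once; the moving image is warped raw and
    # smoothed after warping, so the blur scale is identical on both sides
    # regardless of the scale component of the transform
    targ_s = ndimage.gaussian_filter(targ, opts.smooth_sigma)
    targ_cs = ndimage.gaussian_filter(targ_c, opts.smooth_sigma)

    def objective(v: np.ndarray, moving: np.ndarray, fixed_s: np.ndarray, scale: float) -> float:
        p = AffineParams(
            tx=float(v[0]) * scale,
            ty=float(v[1]) * scale,
            theta=float(v[2]),
            sx=float(math.exp(v[3])),
            sy=float(math.exp(v[4])),
        )
        w = warp_raster(moving, p, cval=float(moving.max()))
        val = ncc(ndimage.gaussian_filter(w, opts.smooth_sigma), fixed_s)
        if math.isnan(val):
            return 1.0
        return -val

    tmax = opts.max_translation * n
    bounds = [
        (-tmax, tmax),
        (-tmax, tmax),
        (-opts.max_rotation, opts.max_rotation),
        (-opts.log_scale_bound, opts.log_scale_bound),
        (-opts.log_scale_bound, opts.log_scale_bound),
    ]

    best = None
    for deg in opts.rotation_starts_deg:
        x0 = np.array([0.0, 0.0, math.radians(deg), 0.0, 0.0])
        res = optimize.minimize(
            objective,
            x0,
            args=(trac_c, targ_cs, f),
            method="Powell",
            bounds=bounds,
            options={"xtol": opts.coarse_xtol, "maxiter": opts.max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res

    fine = optimize.minimize(
        objective,
        best.x,
        args=(trac, targ_s, 1.0),
        method="Powell",
        bounds=bounds,
        options={"xtol": opts.fine_xtol, "maxiter": opts.max_iter},
    )
    params = _vec_to_params(fine.x)
    aligned = warp_raster(trac, params, cval=float(trac.max()))
    final = ncc(
        ndimage.gaussian_filter(aligned, opts.shape_error_sigma),
        ndimage.gaussian_filter(targ, opts.shape_error_sigma),
    )
    return RegistrationResult(params, float(final), converged=bool(fine.success))


@dataclass(frozen=True)
class TracingErrors:
    """Shape error (correlation distance) plus spatial error magnitudes."""

    shape_error: float
    translation_mag: float
    rotation_mag: float
    scaling_mag: float

    def as_dict(self) -> dict[str, float]:
        return {
            "shape_error": self.shape_error,
            "translation_mag": self.translation_mag,
            "rotation_mag": self.rotation_mag,
            "scaling_mag": self.scaling_mag,
        }


def tracing_errors(params: AffineParams, final_ncc: float) -> TracingErrors:
    """Decompose a registration result into the four error components.

    shape_error = 1 - NCC; translation magnitude is the Euclidean norm of
    (tx, ty) in pixels; rotation magnitude is |theta| in radians; scaling
    magnitude is |log sx| + |log sy| (symmetric in expansion vs shrinkage).
    """
    return TracingErrors(
        shape_error=float(1.0 - final_ncc),
        translation_mag=float(math.hypot(params.tx, params.ty)),
        rotation_mag=float(abs(params.theta)),
        scaling_mag=float(abs(math.log(params.sx)) + abs(math.log(params.sy))),
    )


# ---------------------------------------------------------------------------
# ordinal calibration against human ratings
# ---------------------------------------------------------------------------


@dataclass
class TracingCalibration:
    """Fitted proportional-odds calibration of error components to ratings.

    The latent model is ``P(rating <= k) = logistic(alpha_k - eta)`` with
    ``eta = X @ coef + u_rater`` and ridge-penalized per-rater intercepts
    ``u`` (an approximation to Gaussian random intercepts; the penalty is
    set from the estimated intercept variance by one reweighting pass).
    """

    coef: pd.Series
    se: pd.Series
    thresholds: np.ndarray
    rater_var: float
    n_obs: int
    converged: bool
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")


def _design_matrix(errors: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [c for c in ERROR_COLUMNS if c in errors.columns]
    if len(cols) != 4:
        missing = set(ERROR_COLUMNS) - set(errors.columns)
        raise ValueError(f"errors table missing columns: {sorted(missing)}")
    x = errors[list(cols)].to_numpy(dtype=float)
    names = list(cols)
    if "shape_id" in errors.columns:
        levels = sorted(errors["shape_id"].unique())
        for lev in levels[1:]:
            x = np.column_stack([x, (errors["shape_id"] == lev).astype(float)])
            names.append(f"shape[{lev}]")
    return x, tuple(names)


def _ordinal_nll_grad(
    theta: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    rater_idx: np.ndarray,
    n_raters: int,
    n_levels: int,
    ridge: float,
) -> tuple[float, np.ndarray]:
    """Penalized negative log-likelihood and gradient of the ordinal model.

    Parameter vector: [beta (p), a1, log-diffs (n_levels-2), u (n_raters)].
    """
    p = x.shape[1]
    ncut = n_levels - 1
    beta = theta[:p]
    a1 = theta[p]
    d = theta[p + 1 : p + ncut]
    u = theta[p + ncut :]
    alphas = np.concatenate([[a1], a1 + np.cumsum(np.exp(d))])

    eta = x @ beta + u[rater_idx]
    hi = np.where(y < ncut, alphas[np.minimum(y, ncut - 1)] - eta, np.inf)
    lo = np.where(y > 0, alphas[np.maximum(y - 1, 0)] - eta, -np.inf)
    f_hi = expit(hi)
    f_lo = expit(lo)
    prob = np.clip(f_hi - f_lo, 1e-12, None)
    nll = -np.sum(np.log(prob)) + 0.5 * ridge * np.sum(u**2)

    pdf_hi = np.where(np.isinf(hi), 0.0, f_hi * (1 - f_hi))
    pdf_lo = np.where(np.isinf(lo), 0.0, f_lo * (1 - f_lo))
    dl_deta = (pdf_hi - pdf_lo) / prob  # = -dL/deta for NLL sign handled below

    grad = np.zeros_like(theta)
    grad[:p] = x.T @ dl_deta
    # threshold gradients: dNLL/dalpha_k
    g_alpha = np.zeros(ncut)
    for k in range(ncut):
        upper = (y == k) & np.isfinite(hi)
        lower = (y == k + 1) & np.isfinite(lo)
        g_alpha[k] = -np.sum(pdf_hi[upper] / prob[upper]) + np.sum(
            pdf_lo[lower] / prob[lower]
        )
    grad[p] = g_alpha.sum()
    cum = np.cumsum(g_alpha[::-1])[::-1]
    grad[p + 1 : p + ncut] = cum[1:] * np.exp(d)
    grad[p + ncut :] = np.bincount(rater_idx, weights=dl_deta, minlength=n_raters)
    grad[p + ncut :] += ridge * u
    return float(nll), grad


def fit_tracing_calibration(
    errors: pd.DataFrame,
    ratings: pd.DataFrame,
    rater_var_init: float = 1.0,
    n_levels: int = 5,
    estimate_rater_var: bool = True,
) -> TracingCalibration:
    """Fit the proportional-odds calibration of tracing errors to ratings.

    Parameters
    ----------
    errors
        One row per tracing, indexed by tracing id, with the four error
        components and optionally ``shape_id``.
    ratings
        Long table with columns ``tracing_id``, ``rater_id``, ``rating``
        (integers 1..n_levels); each tracing rated at least once.
    """
    if ratings["rating"].nunique() < 2:
        raise ValueError("ratings are degenerate: fewer than 2 distinct levels")
    x_all, names = _design_matrix(errors)
    row_of = {tid: i for i, tid in enumerate(errors.index)}
    try:
        obs_rows = np.array([row_of[t] for t in ratings["tracing_id"]])
    except KeyError as exc:
        raise ValueError(f"rating refers to unknown tracing id {exc}") from exc
    x = x_all[obs_rows]
    y = ratings["rating"].to_numpy(dtype=int) - 1
    if y.min() < 0 or y.max() > n_levels - 1:
        raise ValueError(f"ratings must lie in 1..{n_levels}")
    raters = pd.Categorical(ratings["rater_id"])
    rater_idx = raters.codes.astype(int)
    n_raters = len(raters.categories)
    p = x.shape[1]
    ncut = n_levels - 1

    def fit_once(ridge: float, x0: np.ndarray) -> optimize.OptimizeResult:
        return optimize.minimize(
            _ordinal_nll_grad,
            x0,
            args=(x, y, rater_idx, n_raters, n_levels, ridge),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8},
        )

    x0 = np.zeros(p + ncut + n_raters)
    x0[p + 1 : p + ncut] = 0.0  # unit log-spacing of thresholds
    x0[p] = -1.5
    ridge = 1.0 / max(rater_var_init, 1e-6)
    def var_update(theta: np.ndarray, ridge_cur: float) -> float:
        # EM-style variance update: E[u^2] = u_hat^2 + posterior variance,
        # with the curvature of the penalized objective as the posterior
        # precision (Laplace approximation per rater intercept)
        u_hat = theta[p + ncut :]
        eps = 1e-4
        post_var = np.empty(n_raters)
        for j in range(n_raters):
            tp = theta.copy()
            tp[p + ncut + j] += eps
            _, gp = _ordinal_nll_grad(tp, x, y, rater_idx, n_raters, n_levels, ridge_cur)
            tm = theta.copy()
            tm[p + ncut + j] -= eps
            _, gm = _ordinal_nll_grad(tm, x, y, rater_idx, n_raters, n_levels, ridge_cur)
            curv = (gp[p + ncut + j] - gm[p + ncut + j]) / (2 * eps)
            post_var[j] = 1.0 / max(curv, 1e-6)
        return float(np.mean(u_hat**2 + post_var))

    res = fit_once(ridge, x0)
    rater_var = var_update(res.x, ridge) if n_raters > 1 else 0.0
    if not estimate_rater_var:
        rater_var = rater_var_init
    elif rater_var > 1e-4:
        for _ in range(3):
            res = fit_once(1.0 / rater_var, res.x)
            new_var = var_update(res.x, 1.0 / rater_var)
            if abs(new_var - rater_var) < 0.02 * rater_var:
                rater_var = new_var
                break
            rater_var = new_var
    if not res.success:
        raise RuntimeError(
            f"ordinal calibration did not converge: {res.message} "
            f"(grad norm {np.linalg.norm(res.jac):.3g})"
        )

    # observed-information SEs from a finite-difference Hessian of the
    # penalized objective (analytic gradient differences).
    theta_hat = res.x
    ridge_hat = 1.0 / max(rater_var, 1e-6)
    m = len(theta_hat)
    hess = np.zeros((m, m))
    eps = 1e-5
    for j in range(m):
        tp = theta_hat.copy()
        tp[j] += eps
        _, gp = _ordinal_nll_grad(tp, x, y, rater_idx, n_raters, n_levels, ridge_hat)
        tm = theta_hat.copy()
        tm[j] -= eps
        _, gm = _ordinal_nll_grad(tm, x, y, rater_idx, n_raters, n_levels, ridge_hat)
        hess[j] = (gp - gm) / (2 * eps)
    hess = (hess + hess.T) / 2
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    a1 = theta_hat[p]
    thresholds = np.concatenate(
        [[a1], a1 + np.cumsum(np.exp(theta_hat[p + 1 : p + ncut]))]
    )
    return TracingCalibration(
        coef=pd.Series(theta_hat[:p], index=list(names)),
        se=pd.Series(se, index=list(names)),
        thresholds=thresholds,
        rater_var=rater_var,
        n_obs=len(y),
        converged=bool(res.success),
        feature_names=names,
    )


def score_tracings(
    errors: pd.DataFrame, calibration: TracingCalibration
) -> pd.Series:
    """Per-session tracing scores on the latent calibration scale.

    Each tracing's score is its linear predictor ``X @ coef`` (rater effects
    excluded); higher means a better tracing under a calibration whose error
    coefficients are negative.  Scores are averaged over each session's
    tracings (``session_id`` column required); sessions with no tracings
    simply do not appear.
    """
    if "session_id" not in errors.columns:
        raise ValueError("errors table requires a session_id column")
    # build the design in the calibration's feature basis (the table need
    # not contain every shape level the calibration was fit on)
    cols = []
    for name in calibration.feature_names:
        if name.startswith("shape[") and name.endswith("]"):
            level = name[len("shape[") : -1]
            if "shape_id" not in errors.columns:
                raise ValueError("errors table requires a shape_id column")
            cols.append((errors["shape_id"] == level).astype(float).to_numpy())
        elif name in errors.columns:
            cols.append(errors[name].to_numpy(dtype=float))
        else:
            raise ValueError(f"errors table missing column {name!r}")
    x = np.column_stack(cols)
    eta = x @ calibration.coef.to_numpy()
    per_tracing = pd.Series(eta, index=errors.index, name="tracing_score")
    return per_tracing.groupby(errors["session_id"].to_numpy()).mean()
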