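"""Diffusion tensor estimation: log-linear, weighted, and robust IRLS fits.

The monoexponential tensor representation ``ln S = ln S0 - b gᵀDg`` is linear
in the seven parameters (ln S0 and the six unique tensor elements), so all
fits reduce to (weighted) linear least squares on log-signals:

* ``fit_lls`` — ordinary least squares; fast baseline, biased at low SNR;
* ``fit_wls`` — weights equal to squared predicted signals, the standard
  correction for the log-transform's heteroscedasticity, which also
  mitigates the Rician rectification bias of magnitude data;
* ``fit_robust`` — iteratively reweighted least squares combining the WLS
  weights with a Geman-McClure M-estimator weight on standardized
  log-residuals (scale 1.4826 x median absolute deviation), which
  down-weights and flags outlier volumes such as motion-corrupted images.

Signals are floor-clamped before the log (never dropped silently); fitted
tensors may be indefinite at high noise, and negative eigenvalues are clipped
only downstream in metric computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "design_matrix",
    "TensorFitResult",
    "RobustFitConfig",
    "fit_lls",
    "fit_wls",
    "fit_robust",
    "predict_signals",
    "params_to_tensors",
]


class FitError(ValueError):
    """Invalid fitting input."""


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """N x 7 design: column of ones (ln S0) and ``-b (gx², gy², gz², 2gxgy,
    2gxgz, 2gygz)`` per volume.

    Parameter order is ``(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.
    """
    b = np.asarray(bvals, dtype=float).ravel()
    g = np.atleast_2d(np.asarray(bvecs, dtype=float))
    if g.shape[0] != b.size:
        raise FitError("bvals and bvecs lengths differ")
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    second = np.column_stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )
    return np.column_stack([np.ones_like(b), -b[:, None] * second])


def params_to_tensors(params: np.ndarray) -> np.ndarray:
    """(..., 7) parameter vectors -> (..., 3, 3) symmetric tensors."""
    p = np.asarray(params, dtype=float)
    t = np.empty(p.shape[:-1] + (3, 3))
    t[..., 0, 0] = p[..., 1]
    t[..., 1, 1] = p[..., 2]
    t[..., 2, 2] = p[..., 3]
    t[..., 0, 1] = t[..., 1, 0] = p[..., 4]
    t[..., 0, 2] = t[..., 2, 0] = p[..., 5]
    t[..., 1, 2] = t[..., 2, 1] = p[..., 6]
    return t


@dataclass
class TensorFitResult:
    """Per-voxel fit output.

    ``params`` is (V, 7): ln S0 followed by the six tensor elements (mm²/s).
    ``weights`` are the final per-volume weights normalized to max 1 per
    voxel; ``outlier_mask`` marks volumes whose robust weight fell below the
    configured cutoff (all False for non-robust fits).
    """

    params: np.ndarray
    weights: np.ndarray
    outlier_mask: np.ndarray
    n_iter: int
    converged: np.ndarray
    clamped: np.ndarray

    @property
    def ln_s0(self) -> np.ndarray:
        return self.params[:, 0]

    @property
    def tensor_elements(self) -> np.ndarray:
        return self.params[:, 1:]

    @property
    def tensors(self) -> np.ndarray:
        return params_to_tensors(self.params)


@dataclass(frozen=True)
class RobustFitConfig:
    """Tuning of the robust IRLS fit.

    ``gm_scale`` is the Geman-McClure tuning constant in MAD-standardized
    residual units; residuals beyond a few times this scale receive nearly
    zero weight.  ``outlier_cutoff`` flags volumes whose final M-estimator
    weight is below it.
    """

    max_iter: int = 50
    tol: float = 1e-8
    gm_scale: float = 3.0
    outlier_cutoff: float = 0.1
    wls_iters: int = 2
    min_volumes: int = 10


def _clamp_signals(
    signals: np.ndarray, floor_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp non-positive/tiny signals to a per-voxel floor; flag voxels."""
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    peak = s.max(axis=1, keepdims=True)
    if np.any(peak <= 0):
        raise FitError("voxel with no positive signal cannot be fitted")
    floor = floor_frac * peak
    clamped = (s < floor).any(axis=1)
    return np.maximum(s, floor), clamped


def _weighted_solve(design: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-voxel weighted least squares, batched over voxels.

    design (N, 7), y (V, N), w (V, N) -> params (V, 7).
    """
    xtwx = np.einsum("vn,ni,nj->vij", w, design, design)
    xtwy = np.einsum("vn,ni,vn->vi", w, design, y)
    return np.linalg.solve(xtwx, xtwy[..., None])[..., 0]


def fit_lls(
    signals: np.ndarray, design: np.ndarray, floor_frac: float = 1e-6
) -> TensorFitResult:
    """Ordinary least squares on log-signals (closed form)."""
    s, clamped = _clamp_signals(signals, floor_frac)
    if design.shape[0] != s.shape[1]:
        raise FitError("design rows must equal volume count")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("rank-deficient design matrix")
    y = np.log(s)
    params, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    v = s.shape[0]
    return TensorFitResult(
        params=params.T,
        weights=np.ones_like(s),
        outlier_mask=np.zeros_like(s, dtype=bool),
        n_iter=1,
        converged=np.ones(v, dtype=bool),
        clamped=clamped,
    )


def fit_wls(
    signals: np.ndarray,
    design: np.ndarray,
    n_iter: int = 2,
    floor_frac: float = 1e-6,
) -> TensorFitResult:
    """Weighted least squares with weights = squared predicted signals.

    Initialized from the log-linear fit; ``n_iter`` reweighting passes
    (default 2) re-derive the weights from each iterate's predictions.
    """
    base = fit_lls(signals, design, floor_frac)
    s, clamped = _clamp_signals(signals, floor_frac)
    y = np.log(s)
    params = base.params
    w = np.ones_like(s)
    for _ in range(n_iter):
        pred = np.exp(params @ design.T)
        w = pred**2
        params = _weighted_solve(design, y, w)
    w_norm = w / w.max(axis=1, keepdims=True)
    return TensorFitResult(
        params=params,
        weights=w_norm,
        outlier_mask=np.zeros_like(s, dtype=bool),
        n_iter=n_iter,
        converged=np.ones(s.shape[0], dtype=bool),
        clamped=clamped,
    )


def fit_robust(
    signals: np.ndarray,
    design: np.ndarray,
    config: RobustFitConfig | None = None,
    floor_frac: float = 1e-6,
) -> TensorFitResult:
    """Robust weighted least squares (IRLS with Geman-McClure weights).

    Combined weight = WLS weight (squared predicted signal) x M-estimator
    weight ``1 / (1 + (z/c)²)²`` on MAD-standardized log-residuals ``z``.
    Iterates until the largest tensor-element change is below ``tol`` or
    ``max_iter`` is reached (non-converged voxels are returned flagged, not
    raised).  Volumes with final M-weight < ``outlier_cutoff`` are flagged in
    ``outlier_mask``.
    """
    cfg = config or RobustFitConfig()
    s, clamped = _clamp_signals(signals, floor_frac)
    n_vol = s.shape[1]
    if n_vol < cfg.min_volumes:
        warnings.warn(
            f"robust fitting with only {n_vol} volumes is poorly constrained",
            stacklevel=2,
        )
    start = fit_wls(signals, design, n_iter=cfg.wls_iters, floor_frac=floor_frac)
    y = np.log(s)
    params = start.params
    v = s.shape[0]
    converged = np.zeros(v, dtype=bool)
    w_robust = np.ones_like(s)
    n_done = 0
    for it in range(cfg.max_iter):
        pred_log = params @ design.T
        resid = y - pred_log
        med = np.median(resid, axis=1, keepdims=True)
        mad = np.median(np.abs(resid - med), axis=1, keepdims=True)
        scale = 1.4826 * mad
        # noiseless voxels: scale ~ 0 -> no reweighting (all weights 1)
        safe = np.maximum(scale, 1e-10)
        z = np.where(scale > 1e-12, resid / safe, 0.0)
        w_robust = 1.0 / (1.0 + (z / cfg.gm_scale) ** 2) ** 2
        w = np.exp(pred_log) ** 2 * w_robust
        new_params = _weighted_solve(design, y, w)
        delta = np.abs(new_params[:, 1:] - params[:, 1:]).max(axis=1)
        params = new_params
        converged = delta < cfg.tol
        n_done = it + 1
        if converged.all():
            break
    w_final = np.exp(params @ design.T) ** 2 * w_robust
    w_norm = w_final / w_final.max(axis=1, keepdims=True)
    return TensorFitResult(
        params=params,
        weights=w_norm,
        outlier_mask=w_robust < cfg.outlier_cutoff,
        n_iter=n_done,
        converged=converged,
        clamped=clamped,
    )


def predict_signals(
    fit: TensorFitResult | np.ndarray, design: np.ndarray
) -> np.ndarray:
    """Predicted signals ``exp(design @ params)`` per voxel and volume."""
    params = fit.params if isinstance(fit, TensorFitResult) else np.asarray(fit)
    return np.exp(np.atleast_2d(params) @ design.T)
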