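"""Elliptical population receptive field (pRF) model: forward model and fit.

A voxel's pRF is a 2D Gaussian in visual space.  Its predicted BOLD response
to an aperture movie s(x, y, t) is the per-frame overlap sum(s * g) convolved
with the observer's hemodynamic kernel h(t):

    y(t) = h(t) * sum_{x,y} s(x, y, t) g(x, y)

Fitting proceeds in the two stages used for anisotropy mapping:

1. an isotropic Gaussian locates the pRF centre (x0, y0) and width sigma;
2. with the centre frozen, an elliptical Gaussian whose axes are fixed to
   the radial/tangential directions of that centre refines (sigma, AR),
   where AR = sigma_radial / sigma_tangential.

Both stages minimise 1 - r between observed and predicted series, so fits
are invariant to the scale and offset of the measured signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from ._optimize import minimize_bounded
from .hirf import HIRFParams, hirf_evaluate
from .stimulus import StimulusMovie

__all__ = ["PRFParams", "FitResult", "PRFFitter",
           "evaluate_prf", "predict_bold", "DegenerateSeriesError"]

# fit bounds shared by both stages
ECC_BOUNDS = (0.7, 7.9)
SIGMA_BOUNDS = (0.1, 5.0)
LOG_AR_BOUND = 2.0     # |ln AR| <= 2 by default; results stable when widened


class DegenerateSeriesError(ValueError):
    """Observed series has no variance; the correlation cost is undefined."""


@dataclass(frozen=True)
class PRFParams:
    """pRF centre, geometric-mean width and radial/tangential aspect ratio."""

    x0: float
    y0: float
    sigma: float
    ar: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.ar <= 0:
            raise ValueError("aspect ratio must be positive")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def theta(self) -> float:
        """Polar angle of the centre; the radial axis direction."""
        return float(np.arctan2(self.y0, self.x0))

    @property
    def sigma_radial(self) -> float:
        return self.sigma * np.sqrt(self.ar)

    @property
    def sigma_tangential(self) -> float:
        return self.sigma / np.sqrt(self.ar)


@dataclass(frozen=True)
class FitResult:
    params: PRFParams
    r: float
    stage: str                      # "isotropic" | "elliptical"
    converged: bool = True


def evaluate_prf(params: PRFParams, grid_x, grid_y) -> np.ndarray:
    """Gaussian pRF weights over the raster grid (peak value 1 at centre).

    Coordinates are rotated so the first axis is radial (along the line from
    fixation through the pRF centre); the Gaussian widths on the rotated
    axes are sigma*sqrt(AR) (radial) and sigma/sqrt(AR) (tangential).
    AR = 1 reduces exactly to the isotropic form.
    """
    gx = np.asarray(grid_x, dtype=float)
    gy = np.asarray(grid_y, dtype=float)
    c, s = np.cos(params.theta), np.sin(params.theta)
    # rotate by -theta: maps the centre onto the positive x' (radial) axis
    xr = c * gx[None, :] + s * gy[:, None]
    yr = -s * gx[None, :] + c * gy[:, None]
    x0r = c * params.x0 + s * params.y0      # = eccentricity
    y0r = -s * params.x0 + c * params.y0     # = 0
    sr = params.sigma_radial
    st = params.sigma_tangential
    return np.exp(-((xr - x0r) ** 2) / (2 * sr ** 2)
                  - ((yr - y0r) ** 2) / (2 * st ** 2))


def _tr_kernel(hirf: HIRFParams, tr: float, oversample: int,
               kernel_seconds: float) -> np.ndarray:
    """Effective TR-domain kernel for a piecewise-constant (per-TR) input.

    Equivalent to convolving at ``oversample`` x TR resolution and reading
    out at frame onsets, folded into a single TR-spaced kernel.
    """
    dt = tr / oversample
    n_hi = int(np.ceil(kernel_seconds / dt))
    h = hirf_evaluate(hirf, np.arange(n_hi) * dt) * dt
    n_tr = int(np.ceil(n_hi / oversample)) + 1
    k = np.zeros(n_tr)
    for j in range(n_tr):
        idx = j * oversample - np.arange(oversample)
        idx = idx[(idx >= 0) & (idx < n_hi)]
        k[j] = h[idx].sum()
    return k


def _convolve_frames(neural: np.ndarray, kernel: np.ndarray,
                     frames_per_cycle: int) -> np.ndarray:
    """Causal TR-domain convolution with steady-state (periodic) edge.

    The movie is treated as preceded by copies of its final cycle, matching
    an acquisition whose initial transient frames were discarded.
    """
    T = neural.shape[0]
    pad = int(np.ceil((kernel.size - 1) / frames_per_cycle)) * frames_per_cycle
    if pad:
        lead = neural[T - pad:T]
        padded = np.concatenate([lead, neural], axis=0)
    else:
        padded = neural
    if padded.ndim == 1:
        out = np.convolve(padded, kernel)[:padded.shape[0]]
    else:
        out = fftconvolve(padded, kernel[:, None], axes=0)[:padded.shape[0]]
    return out[pad:]


def predict_bold(prf: PRFParams, movie: StimulusMovie, hirf: HIRFParams, *,
                 oversample: int = 10, kernel_seconds: float = 32.0,
                 frames_per_cycle: int | None = None) -> np.ndarray:
    """Forward-model BOLD series for one pRF and one aperture movie."""
    g = evaluate_prf(prf, movie.grid_x, movie.grid_y)
    neural = movie.frames_flat.astype(float) @ g.ravel()
    kernel = _tr_kernel(hirf, movie.frame_duration, oversample, kernel_seconds)
    if frames_per_cycle is None:
        frames_per_cycle = movie.n_frames
    return _convolve_frames(neural, kernel, frames_per_cycle)


def _corr_with(obs_unit: np.ndarray, pred: np.ndarray) -> float:
    pc = pred - pred.mean()
    norm = np.sqrt(pc @ pc)
    if norm < 1e-12:
        return 0.0
    return float((pc / norm) @ obs_unit)


class PRFFitter:
    """Fits pRFs to voxel series recorded under one or more scans.

    The movie stack is convolved with the hemodynamic kernel once at
    construction; every candidate pRF prediction is then a single
    matrix-vector product, and the coarse initialisation grid (centres at
    1-deg spacing x sigma in {0.5, 1, 2}) is pre-evaluated for all voxels
    at once.
    """

    def __init__(self, movies: Sequence[StimulusMovie], hirf: HIRFParams, *,
                 frames_per_cycle: int = 16, oversample: int = 10,
                 kernel_seconds: float = 32.0,
                 init_grid_step: float = 1.0,
                 init_sigmas: Sequence[float] = (0.5, 1.0, 2.0),
                 log_ar_bound: float = LOG_AR_BOUND):
        if not movies:
            raise ValueError("at least one movie required")
        self.grid_x = movies[0].grid_x
        self.grid_y = movies[0].grid_y
        for m in movies[1:]:
            if not (np.array_equal(m.grid_x, self.grid_x)
                    and np.array_equal(m.grid_y, self.grid_y)):
                raise ValueError("all movies must share one raster grid")
        self.log_ar_bound = float(log_ar_bound)
        kernel = _tr_kernel(hirf, movies[0].frame_duration, oversample,
                            kernel_seconds)
        blocks = []
        for m in movies:
            conv = _convolve_frames(m.frames_flat.astype(np.float64), kernel,
                                    frames_per_cycle)
            blocks.append(conv.astype(np.float32))
        self.design = np.concatenate(blocks, axis=0)      # (T_total, npix)
        self.n_frames = self.design.shape[0]
        X, Y = np.meshgrid(self.grid_x, self.grid_y)
        self._X = X.ravel()
        self._Y = Y.ravel()

        # coarse initialisation table
        xs = np.arange(-np.floor(ECC_BOUNDS[1]), np.floor(ECC_BOUNDS[1]) + 0.5,
                       init_grid_step)
        cx, cy = np.meshgrid(xs, xs)
        ecc = np.hypot(cx, cy).ravel()
        keep = (ecc >= ECC_BOUNDS[0]) & (ecc <= ECC_BOUNDS[1])
        self._init_centers = np.column_stack([cx.ravel()[keep], cy.ravel()[keep]])
        cands = []
        self._init_params = []
        for sig in init_sigmas:
            for x0, y0 in self._init_centers:
                self._init_params.append((x0, y0, sig))
                g = evaluate_prf(PRFParams(x0, y0, sig), self.grid_x, self.grid_y)
                cands.append(g.ravel().astype(np.float32))
        preds = self.design @ np.asarray(cands).T            # (T, ncand)
        preds = preds - preds.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(preds, axis=0)
        norms[norms < 1e-12] = np.inf
        self._init_preds_unit = (preds / norms).astype(np.float32)

    # ------------------------------------------------------------------
    def _prepare(self, series) -> np.ndarray:
        obs = np.asarray(series, dtype=float)
        if obs.shape != (self.n_frames,):
            raise ValueError(
                f"series length {obs.shape} does not match design {self.n_frames}")
        obs = obs - obs.mean()
        norm = np.sqrt(obs @ obs)
        if norm < 1e-12:
            raise DegenerateSeriesError("constant series: correlation undefined")
        return obs / norm

    def _predict(self, params: PRFParams) -> np.ndarray:
        g = evaluate_prf(params, self.grid_x, self.grid_y)
        return self.design @ g.ravel().astype(np.float32)

    def grid_init(self, obs_unit: np.ndarray):
        scores = self._init_preds_unit.T @ obs_unit.astype(np.float32)
        return self._init_params[int(np.argmax(scores))]

    def fit_isotropic(self, series) -> FitResult:
        """Stage 1: isotropic Gaussian, locates the pRF centre."""
        obs_unit = self._prepare(series)
        x0, y0, sig0 = self.grid_init(obs_unit)
        ecc0 = float(np.hypot(x0, y0))
        ang0 = float(np.arctan2(y0, x0))
        X, Y = self._X, self._Y

        def cost(p):
            ecc, ang, sig = p
            g = np.exp(-((X - ecc * np.cos(ang)) ** 2
                         + (Y - ecc * np.sin(ang)) ** 2) / (2 * sig * sig))
            return 1.0 - _corr_with(obs_unit,
                                    self.design @ g.astype(np.float32))

        lower = [ECC_BOUNDS[0], ang0 - np.pi, SIGMA_BOUNDS[0]]
        upper = [ECC_BOUNDS[1], ang0 + np.pi, SIGMA_BOUNDS[1]]
        x_opt, f_opt, ok = minimize_bounded(
            cost, [np.clip(ecc0, *ECC_BOUNDS), ang0, sig0], lower, upper,
            xtol=1e-3, ftol=1e-6, maxfev=1500,
            initial_step=[0.5, 0.15, 0.25])
        ecc, ang, sig = x_opt
        params = PRFParams(ecc * np.cos(ang), ecc * np.sin(ang), sig)
        return FitResult(params=params, r=1.0 - f_opt, stage="isotropic",
                         converged=ok)

    def fit_elliptical(self, series, center: PRFParams) -> FitResult:
        """Stage 2: (sigma, AR) with the stage-1 centre and axes frozen."""
        obs_unit = self._prepare(series)
        x0, y0 = center.x0, center.y0
        # the elongation axes are frozen to the radial/tangential directions
        # of the stage-1 centre, so the rotated squared offsets are constants
        c, s = np.cos(center.theta), np.sin(center.theta)
        xr2 = (c * self._X + s * self._Y - center.eccentricity) ** 2
        yr2 = (-s * self._X + c * self._Y) ** 2

        def cost(p):
            sig, logar = p
            ar = np.exp(logar)
            sr2 = sig * sig * ar
            g = np.exp(xr2 / (-2 * sr2) + yr2 * (-ar / (2 * sig * sig)))
            return 1.0 - _corr_with(obs_unit,
                                    self.design @ g.astype(np.float32))

        x_opt, f_opt, ok = minimize_bounded(
            cost, [center.sigma, 0.0],
            [SIGMA_BOUNDS[0], -self.log_ar_bound],
            [SIGMA_BOUNDS[1], +self.log_ar_bound],
            xtol=1e-3, ftol=1e-6, maxfev=1000,
            initial_step=[0.25, 0.3])
        sig, logar = x_opt
        params = PRFParams(x0, y0, sig, np.exp(logar))
        return FitResult(params=params, r=1.0 - f_opt, stage="elliptical",
                         converged=ok)

    def fit_voxel(self, series) -> tuple[FitResult, FitResult]:
        """Run both stages on one voxel series."""
        stage1 = self.fit_isotropic(series)
        stage2 = self.fit_elliptical(series, stage1.params)
        return stage1, stage2
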