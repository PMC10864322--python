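"""Circularity-judgment observer model: choice probability and MLE.

On each two-alternative trial the observer sees a physically isotropic
standard Gabor (aspect ratio 1) and a probe whose radial-to-tangential
aspect ratio AR varies along a log-spaced ladder, and picks the stimulus
that looks closer to a perfect circle.  Perceived log aspect ratios are
modelled as Gaussian variables sharing one internal bias beta — the
perceived AR of the isotropic standard:

    X_P ~ N(mu_p + log(beta), sigma),  mu_p = log(AR_probe)
    X_S ~ N(      log(beta), sigma)

The observer chooses the standard when X_S^2 < X_P^2 (its perceived log AR
is closer to 0), so

    p(standard | mu_p) = integral over x_p of
        p(X_S^2 < x_p^2) p(x_p | mu_p) dx_p  +  const.

with the inner probability in closed form via the normal CDF and the outer
integral by fixed-order Gauss-Legendre quadrature over +-8 SD.  The small
additive constant (``lapse_const``) absorbs stimulus-independent errors;
probabilities are clipped away from 0 and 1.

The psychometric curve attains its minimum at mu_p = -log(beta), so the
probe AR that looks perfectly circular is 1/beta and the perceived AR of
the standard is beta itself; log(beta) is the perceptual radial bias index.

By default all logarithms are natural.  ``log_base="mixed"`` reproduces a
variant in which the internal bias enters as log2(beta) while the probe
abscissa stays natural-log, in which case the recovered perceived AR is
beta**(1/ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._optimize import minimize_bounded

__all__ = ["ObserverParams", "PsychFit", "choice_prob_standard",
           "fit_observer", "psychometric_curve", "trial_table_schema"]

_PCLIP = (1e-6, 1.0 - 1e-6)
_QUAD_ORDER = 201

#: required columns of a trial table (one row per 2AFC trial)
trial_table_schema = ("orientation_condition", "probe_ar", "radial_axis_deg",
                      "chose_standard")


@dataclass(frozen=True)
class ObserverParams:
    sigma_obs: float               # SD of perceived log aspect ratio
    beta: float = 1.0              # perceived AR of the isotropic standard
    lapse_const: float = 0.0       # additive offset to the choice probability
    log_base: str = "natural"      # "natural" | "mixed"

    def __post_init__(self):
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be positive")
        if not 0.25 <= self.beta <= 4.0:
            raise ValueError("beta outside its plausible range [0.25, 4]")
        if not 0.0 <= self.lapse_const <= 0.2:
            raise ValueError("lapse_const outside [0, 0.2]")
        if self.log_base not in ("natural", "mixed"):
            raise ValueError("log_base must be 'natural' or 'mixed'")

    @property
    def bias(self) -> float:
        """Mean shift of the perceived log aspect ratios."""
        if self.log_base == "mixed":
            return float(np.log2(self.beta))
        return float(np.log(self.beta))


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_QUAD_ORDER)


def _normal_cdf(z):
    from scipy.special import ndtr
    return ndtr(z)


def _p_standard_raw(mu_p, params: ObserverParams):
    """P(X_S^2 < X_P^2 | mu_p) without lapse, vectorised over mu_p."""
    mu_p = np.atleast_1d(np.asarray(mu_p, dtype=float))
    m_s = params.bias
    m_p = mu_p + m_s
    sig = params.sigma_obs
    # outer integral over x_p on m_p +- 8 sigma, split at x = 0 where the
    # inner probability has a derivative kink (|x| enters the CDFs)
    lo = m_p - 8.0 * sig
    hi = m_p + 8.0 * sig
    mid = np.clip(0.0, lo, hi)
    total = np.zeros_like(m_p)
    for a, b in ((lo, mid), (mid, hi)):
        half = (b - a) / 2.0
        center = (a + b) / 2.0
        x = center[:, None] + half[:, None] * _GL_NODES[None, :]
        w = half[:, None] * _GL_WEIGHTS[None, :]
        dens = np.exp(-((x - m_p[:, None]) ** 2) / (2 * sig ** 2)) / (
            sig * np.sqrt(2 * np.pi))
        ax = np.abs(x)
        inner = _normal_cdf((ax - m_s) / sig) - _normal_cdf((-ax - m_s) / sig)
        total += (w * dens * inner).sum(axis=1)
    return total


def choice_prob_standard(mu_p, params: ObserverParams):
    """Probability of choosing the standard at log-probe-AR ``mu_p``."""
    p = _p_standard_raw(mu_p, params) + params.lapse_const
    out = np.clip(p, *_PCLIP)
    return float(out[0]) if np.isscalar(mu_p) or np.ndim(mu_p) == 0 else out


def psychometric_curve(params: ObserverParams, ar_grid):
    """Choice-probability curve over probe aspect ratios; returns (p, argmin).

    ``argmin`` is the grid AR at the curve minimum — the probe that looks
    most circular, equal to 1/AR_perc up to grid resolution.
    """
    ar = np.asarray(ar_grid, dtype=float)
    if np.any(ar <= 0):
        raise ValueError("aspect ratios must be positive")
    p = choice_prob_standard(np.log(ar), params)
    return p, float(ar[int(np.argmin(p))])


@dataclass(frozen=True)
class PsychFit:
    params: ObserverParams
    loglik: float
    n_trials: int
    converged: bool
    boundary: bool                 # all-identical responses (separable data)

    @property
    def ar_perc(self) -> float:
        """Perceived aspect ratio of the isotropic standard."""
        if self.params.log_base == "mixed":
            return float(np.exp(self.params.bias))
        return self.params.beta

    @property
    def probed_ar_physical(self) -> float:
        return 1.0 / self.ar_perc

    @property
    def ri_perc(self) -> float:
        return float(np.log(self.ar_perc))


_FIT_LOWER = np.array([0.02, 0.25, 0.0])
_FIT_UPPER = np.array([2.00, 4.00, 0.2])
_BETA_STARTS = (0.8, 1.0, 1.25)


def fit_observer(trials: pd.DataFrame, *, log_base: str = "natural",
                 sigma_init: float = 0.25) -> PsychFit:
    """Maximum-likelihood observer fit for one orientation condition.

    ``trials`` needs columns probe_ar and chose_standard with at least two
    distinct probe levels.  The likelihood is binomial per probe level; the
    three parameters (sigma, beta, const) are optimised with bounded
    Nelder-Mead from multiple beta starts.
    """
    if trials["probe_ar"].nunique() < 2:
        raise ValueError("need >= 2 distinct probe AR levels")
    grouped = trials.groupby("probe_ar")["chose_standard"]
    levels = np.array(sorted(grouped.groups))
    n = grouped.count().reindex(levels).to_numpy(dtype=float)
    k = grouped.sum().reindex(levels).to_numpy(dtype=float)
    mu = np.log(levels)
    boundary = bool(k.sum() == 0 or k.sum() == n.sum())

    def negloglik(x):
        params = ObserverParams(sigma_obs=x[0], beta=x[1], lapse_const=x[2],
                                log_base=log_base)
        p = np.clip(_p_standard_raw(mu, params) + x[2], *_PCLIP)
        return -float(k @ np.log(p) + (n - k) @ np.log1p(-p))

    best = None
    for b0 in _BETA_STARTS:
        x_opt, f_opt, ok = minimize_bounded(
            negloglik, [sigma_init, b0, 0.02], _FIT_LOWER, _FIT_UPPER,
            xtol=1e-5, ftol=1e-7, maxfev=2000,
            initial_step=[0.08, 0.15, 0.03])
        if best is None or f_opt < best[1]:
            best = (x_opt, f_opt, ok)
    x_opt, f_opt, ok = best
    params = ObserverParams(sigma_obs=x_opt[0], beta=x_opt[1],
                            lapse_const=x_opt[2], log_base=log_base)
    return PsychFit(params=params, loglik=-f_opt, n_trials=int(n.sum()),
                    converged=ok, boundary=boundary)
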