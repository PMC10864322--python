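"""Bounded derivative-free minimisation via trigonometric parameter transforms.

Nelder-Mead is run in an unconstrained space; each doubly-bounded parameter
is mapped onto its interval with a sine transform, so the simplex can never
propose an infeasible point and no penalty terms are needed.  Parameters with
``lower == -inf`` and ``upper == inf`` pass through untouched.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["minimize_bounded"]


def _to_unconstrained(x, lower, upper):
    u = np.asarray(x, dtype=float).copy()
    for i, (lo, hi) in enumerate(zip(lower, upper)):
        if np.isfinite(lo) and np.isfinite(hi):
            # clip into the open interval before inverting the sine map
            frac = (min(max(x[i], lo), hi) - lo) / (hi - lo)
            u[i] = np.arcsin(2.0 * frac - 1.0)
    return u


def _to_constrained(u, lower, upper):
    x = np.asarray(u, dtype=float).copy()
    for i, (lo, hi) in enumerate(zip(lower, upper)):
        if np.isfinite(lo) and np.isfinite(hi):
            x[i] = lo + (hi - lo) * (np.sin(u[i]) + 1.0) / 2.0
    return x


def minimize_bounded(fun, x0, lower, upper, *, xtol=1e-6, ftol=1e-6,
                     maxfev=None, args=(), initial_step=None):
    """Minimise ``fun`` subject to box bounds with Nelder-Mead.

    ``initial_step`` gives the size of the starting simplex per parameter in
    the *original* units; without it, parameters starting at 0.0 would get
    Nelder-Mead's minuscule default perturbation and could stall.  Returns
    ``(x_opt, f_opt, converged)``; non-convergence is reported via the flag
    rather than an exception so callers can attach diagnostics.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    lower = np.atleast_1d(np.asarray(lower, dtype=float))
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    if lower.shape != x0.shape or upper.shape != x0.shape:
        raise ValueError("bounds must match the parameter vector length")
    if np.any(upper < lower):
        raise ValueError("upper bound below lower bound")

    def wrapped(u):
        return fun(_to_constrained(u, lower, upper), *args)

    u0 = _to_unconstrained(x0, lower, upper)
    options = {
        "xatol": xtol, "fatol": ftol,
        "maxfev": maxfev if maxfev is not None else 400 * len(x0),
    }
    if initial_step is not None:
        step = np.atleast_1d(np.asarray(initial_step, dtype=float))
        simplex = np.tile(u0, (u0.size + 1, 1))
        for i in range(u0.size):
            lo, hi = lower[i], upper[i]
            target = x0[i] + step[i]
            if np.isfinite(lo) and np.isfinite(hi) and target >= hi:
                target = x0[i] - step[i]
            du = _to_unconstrained(
                np.where(np.arange(u0.size) == i, target, x0),
                lower, upper)[i] - u0[i]
            simplex[i + 1, i] += du if du != 0 else 0.1
        options["initial_simplex"] = simplex
    res = minimize(wrapped, u0, method="Nelder-Mead", options=options)
    return _to_constrained(res.x, lower, upper), float(res.fun), bool(res.success)
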