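"""Voxel screening for pRF analysis.

A voxel enters the pRF analysis only if its signal is convincingly locked to
the 1/24-Hz stimulus cycle, its response phase is consistent with the
stimulus-driven hemodynamic delay, its Fourier SNR clears threshold, it is
not in the top decile of series variance (a proxy for draining-vein
contamination), and its pRF-model fit quality clears threshold in every
scan.

Phase handling: the criterion is evaluated on the phase of the best-fitting
sinusoid at the stimulus frequency *after* subtracting a reference phase
(``phase_ref``).  Passing the phase of the predicted stimulus-locked
response (e.g. from the fitted HIRF) as the reference expresses the intended
check — the voxel's hemodynamic phase must sit within +-pi/4 of the common
stimulus-onset-locked phase — while a reference of 0 gives the raw phase
relative to stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VoxelMetrics", "voxel_quality_metrics", "series_phase",
           "apply_selection", "SelectionThresholds"]


@dataclass(frozen=True)
class VoxelMetrics:
    r_sinusoid: float   # correlation with best-fitting stimulus-frequency sinusoid
    phase: float        # radians, relative to the reference phase, in (-pi, pi]
    snr: float          # Fourier amplitude ratio (stimulus bin / high bins)
    variance: float     # raw series variance (psc^2)


@dataclass(frozen=True)
class SelectionThresholds:
    r_sinusoid_min: float = 0.4
    phase_halfwidth: float = np.pi / 4
    snr_min: float = 2.0
    variance_percentile: float = 90.0
    fit_r_min: float = 0.25


def _wrap(phase: float) -> float:
    return float(np.angle(np.exp(1j * phase)))


def series_phase(series, f_stim: float, tr: float) -> float:
    """Phase of the best-fitting sinusoid at f_stim, relative to t = 0.

    The series is modelled as A*cos(2*pi*f*t - phi); phi grows with response
    delay, so a later response has a larger (positive) phase.
    """
    y = np.asarray(series, dtype=float)
    t = np.arange(y.size) * tr
    w = 2 * np.pi * f_stim * t
    a = 2.0 / y.size * float(np.cos(w) @ (y - y.mean()))
    b = 2.0 / y.size * float(np.sin(w) @ (y - y.mean()))
    return float(np.arctan2(b, a))


def voxel_quality_metrics(series, f_stim: float = 1.0 / 24.0, tr: float = 1.5,
                          *, phase_ref: float = 0.0,
                          snr_band: str = "geq3f") -> VoxelMetrics:
    """Stimulus-locked modulation metrics for one voxel series.

    snr divides the amplitude at the stimulus frequency by the mean
    amplitude of the high-frequency components: all DFT bins at or above
    three times the stimulus frequency (``snr_band="geq3f"``, default) or
    the single bin at 3 f ("at3f").
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    cycle_frames = 1.0 / (f_stim * tr)
    if abs(n / cycle_frames - round(n / cycle_frames)) > 1e-9:
        raise ValueError("series length must be a whole number of stimulus cycles")
    var = float(y.var())
    if var < 1e-30:
        return VoxelMetrics(r_sinusoid=np.nan, phase=np.nan, snr=0.0, variance=var)

    t = np.arange(n) * tr
    w = 2 * np.pi * f_stim * t
    X = np.column_stack([np.cos(w), np.sin(w)])
    yc = y - y.mean()
    coef, *_ = np.linalg.lstsq(X, yc, rcond=None)
    resid = yc - X @ coef
    r2 = 1.0 - float(resid @ resid) / float(yc @ yc)
    r_sin = float(np.sqrt(max(r2, 0.0)))
    phase = _wrap(np.arctan2(coef[1], coef[0]) - phase_ref)

    amp = np.abs(np.fft.rfft(yc))
    freqs = np.fft.rfftfreq(n, d=tr)
    k_stim = int(round(f_stim * n * tr))
    if snr_band == "geq3f":
        noise_bins = freqs >= 3.0 * f_stim - 1e-12
    elif snr_band == "at3f":
        noise_bins = np.zeros_like(freqs, dtype=bool)
        noise_bins[3 * k_stim] = True
    else:
        raise ValueError(f"unknown snr_band {snr_band!r}")
    denom = float(amp[noise_bins].mean())
    snr = float(amp[k_stim] / denom) if denom > 0 else np.inf
    return VoxelMetrics(r_sinusoid=r_sin, phase=phase, snr=snr, variance=var)


def apply_selection(metrics: pd.DataFrame, fit_rs=None,
                    thresholds: SelectionThresholds | None = None) -> pd.DataFrame:
    """Combine the screening criteria into keep flags with reason codes.

    ``metrics`` holds one row per voxel with columns r_sinusoid, phase, snr,
    variance.  ``fit_rs`` is an optional (n_voxels, n_scans) table of
    per-scan pRF fit correlations; the minimum across scans must clear the
    fit threshold.  The variance cut rejects voxels strictly above the
    90th percentile (linear-interpolation quantile; ties retained).
    """
    th = thresholds or SelectionThresholds()
    out = pd.DataFrame(index=metrics.index)
    if len(metrics) == 0:
        out["keep"] = pd.Series(dtype=bool)
        out["reasons"] = pd.Series(dtype=object)
        return out

    fail = {}
    with np.errstate(invalid="ignore"):
        fail["sinusoid"] = ~(metrics["r_sinusoid"].to_numpy() > th.r_sinusoid_min)
        fail["phase"] = ~(np.abs(metrics["phase"].to_numpy()) <= th.phase_halfwidth)
        fail["snr"] = ~(metrics["snr"].to_numpy() > th.snr_min)
        var_cut = np.percentile(metrics["variance"].to_numpy(),
                                th.variance_percentile)
        fail["vessel"] = metrics["variance"].to_numpy() > var_cut
        if fit_rs is not None:
            fr = np.asarray(fit_rs, dtype=float)
            if fr.ndim == 1:
                fr = fr[:, None]
            fail["fit"] = ~(fr.min(axis=1) > th.fit_r_min)

    reasons = []
    for i in range(len(metrics)):
        reasons.append(",".join(code for code, f in fail.items() if f[i]))
    out["keep"] = [r == "" for r in reasons]
    out["reasons"] = reasons
    return out
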