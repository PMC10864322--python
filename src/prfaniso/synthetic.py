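"""Synthetic cohorts with known ground truth for the full pipeline.

Everything the analysis consumes can be generated here by running the
paper-style forward models in reverse:

- voxel BOLD series come from the elliptical-pRF forward model (aperture
  movie x Gaussian pRF, convolved with a difference-of-gammas HIRF) plus
  i.i.d. Gaussian noise in percent-signal-change units;
- HIRF-estimation scans come from the pulsed full-field design;
- 2AFC circularity-judgment trials come from the observer model itself;
- cohorts link neural and perceptual anisotropy through a linear
  individual-differences model with controllable correlation.

All randomness flows from one seeded generator, so identical seeds yield
identical data bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hirf import HIRFDesign, HIRFParams, hirf_predict
from .prf import PRFParams, predict_bold
from .psychophysics import ObserverParams, _p_standard_raw
from .stimulus import ProbeLadder, ScanConfig, StimulusMovie, probe_ladder, \
    rasterize_movie, ring_layout, wedge_layout

__all__ = ["GroundTruthVoxel", "CohortSpec", "IndividualData", "CohortBundle",
           "simulate_voxels", "simulate_trials", "simulate_cohort",
           "noise_sd_for_target_snr", "build_movies", "ar_for_subtractive_ri"]

CONDITIONS = ("radial", "tangential")


@dataclass(frozen=True)
class GroundTruthVoxel:
    """One simulated voxel: a pRF per orientation condition plus noise."""

    prf_radial: PRFParams | None
    prf_tangential: PRFParams | None
    noise_sd: float                 # percent signal change
    amplitude: float = 2.0          # peak stimulus-driven response, psc
    label: str = "driven"           # "driven" | "noise" | "vessel"

    def __post_init__(self):
        if self.label not in ("driven", "noise", "vessel"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label == "driven" and (self.prf_radial is None
                                       or self.prf_tangential is None):
            raise ValueError("driven voxels need a pRF per condition")


def noise_sd_for_target_snr(clean_series, target_snr: float,
                            f_stim: float = 1.0 / 24.0, tr: float = 1.5) -> float:
    """Noise SD giving an expected Fourier SNR for a clean driven series.

    For white noise of SD s over n frames, the expected DFT bin amplitude is
    s * sqrt(n * pi) / 2 (Rayleigh mean), so the SNR metric concentrates at
    A_stim / that value.
    """
    y = np.asarray(clean_series, dtype=float)
    n = y.size
    k_stim = int(round(f_stim * n * tr))
    a_stim = float(np.abs(np.fft.rfft(y - y.mean()))[k_stim])
    return 2.0 * a_stim / (target_snr * np.sqrt(n * np.pi))


def ar_for_subtractive_ri(sigma: float, ri: float, *, max_log_ar: float = 2.0) -> float:
    """Aspect ratio giving sigma_radial - sigma_tangential = ri at fixed sigma.

    Solves sigma*(sqrt(ar) - 1/sqrt(ar)) = ri for ar > 0.
    """
    d = ri / sigma
    root = (d + np.sqrt(d * d + 4.0)) / 2.0
    log_ar = np.clip(2.0 * np.log(root), -max_log_ar, max_log_ar)
    return float(np.exp(log_ar))


def build_movies(scan_kinds, grid_step_deg: float = 0.1,
                 n_cycles: int = 9) -> list[StimulusMovie]:
    """Rasterise the requested traveling-aperture scans on a shared grid."""
    movies = []
    for kind in scan_kinds:
        cfg = ScanConfig(aperture_kind=kind, grid_step_deg=grid_step_deg,
                         n_cycles=n_cycles)
        layout = ring_layout() if kind.startswith("ring") else wedge_layout()
        movies.append(rasterize_movie(cfg, layout))
    return movies


# ---------------------------------------------------------------------------
# Voxel series
# ---------------------------------------------------------------------------

def simulate_voxels(truths, movies, hirf: HIRFParams, seed,
                    *, hirf_design: HIRFDesign | None = None,
                    frames_per_cycle: int = 16) -> dict:
    """Generate traveling-scan and pulsed-scan series for a set of voxels.

    Returns ``{"radial": DataFrame, "tangential": DataFrame,
    "hirf_scan": DataFrame}``; each table is frames x voxels with columns
    ``v000, v001, ...``.  Driven voxels carry the forward-model signal for
    that condition's pRF scaled to their peak amplitude; noise voxels are
    noise only; vessel voxels get 3x the noise variance.
    """
    rng = np.random.default_rng(seed)
    design = hirf_design or HIRFDesign()
    t_total = sum(m.n_frames for m in movies)
    cols = [f"v{i:03d}" for i in range(len(truths))]

    pulse = hirf_predict(hirf, design)
    pulse_peak = float(np.max(np.abs(pulse))) or 1.0

    out = {}
    for cond in CONDITIONS:
        data = np.empty((t_total, len(truths)))
        for j, vox in enumerate(truths):
            sd = vox.noise_sd * (np.sqrt(3.0) if vox.label == "vessel" else 1.0)
            series = rng.normal(0.0, sd, size=t_total)
            if vox.label == "driven":
                prf = vox.prf_radial if cond == "radial" else vox.prf_tangential
                clean = np.concatenate([
                    predict_bold(prf, m, hirf, frames_per_cycle=frames_per_cycle)
                    for m in movies])
                peak = float(np.max(np.abs(clean)))
                if peak > 0:
                    series += vox.amplitude * clean / peak
            data[:, j] = series
        out[cond] = pd.DataFrame(data, columns=cols)

    data = np.empty((design.n_usable, len(truths)))
    for j, vox in enumerate(truths):
        sd = vox.noise_sd * (np.sqrt(3.0) if vox.label == "vessel" else 1.0)
        series = rng.normal(0.0, sd, size=design.n_usable)
        if vox.label == "driven":
            series += vox.amplitude * pulse / pulse_peak
        data[:, j] = series
    out["hirf_scan"] = pd.DataFrame(data, columns=cols)
    return out


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def simulate_trials(params_by_condition: dict, ladder: ProbeLadder,
                    n_per_level: int, seed,
                    axes=(0.0, 45.0, 90.0, 135.0)) -> pd.DataFrame:
    """Generate a 2AFC trial table from the observer model itself.

    Choices are made by drawing the perceived log aspect ratios X_S and X_P
    and choosing the standard when X_S^2 < X_P^2.  The additive lapse of
    the likelihood is realised by flipping probe choices to the standard
    with the level-dependent probability c / (1 - p_model), which makes the
    marginal choice probability exactly p_model + c — the generator and the
    likelihood agree by construction.  Trials are balanced across the four
    radial axes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDITIONS:
        params: ObserverParams = params_by_condition[cond]
        c = params.lapse_const
        base = replace(params, lapse_const=0.0)
        for level in ladder.ar_values:
            mu = np.log(level)
            xs = rng.normal(params.bias, params.sigma_obs, size=n_per_level)
            xp = rng.normal(mu + params.bias, params.sigma_obs, size=n_per_level)
            chose = xs ** 2 < xp ** 2
            if c > 0:
                p_model = float(_p_standard_raw(mu, base)[0])
                flip_p = min(c / max(1.0 - p_model, 1e-12), 1.0)
                flips = rng.random(n_per_level) < flip_p
                chose = chose | flips
            for i in range(n_per_level):
                rows.append({
                    "orientation_condition": cond,
                    "probe_ar": float(level),
                    "radial_axis_deg": float(axes[(len(rows)) % len(axes)]),
                    "chose_standard": bool(chose[i]),
                })
    df = pd.DataFrame(rows)
    return df


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a linked neural-perceptual synthetic cohort.

    Index means and spreads follow the magnitudes reported for early visual
    cortex cohorts: a radial bias of ~0.11 deg in pRF width difference with
    ~0.12 deg across-individual SD, a co-axial modulation of ~0.055 deg,
    and perceptual biases of ~+0.26 / -0.20 log units in the radial /
    tangential orientation conditions.  The neural-to-perceptual link is
    linear per condition with a residual chosen to give ``link_rho``.
    """

    n_individuals: int = 27
    seed: int = 0

    # neural ground-truth indices (degrees)
    ri_mean: float = 0.11
    ri_sd: float = 0.12
    cmi_mean: float = 0.055
    cmi_sd: float = 0.10

    # perceptual intercepts (log units) and neural->perceptual link
    perc_intercept_radial: float = 0.26
    perc_intercept_tangential: float = -0.20
    link_slope: float = 1.0        # log units per degree
    link_rho: float = 0.6          # latent correlation per condition

    # observer model
    sigma_obs: float = 0.25
    lapse_const: float = 0.02
    trials_per_condition: int = 500

    # voxel population
    n_driven: int = 24
    n_noise: int = 3
    n_vessel: int = 3
    voxel_sigma_range: tuple = (0.5, 1.1)
    voxel_ecc_range: tuple = (1.5, 6.0)
    voxel_log_ar_jitter_sd: float = 0.10
    amplitude: float = 2.0
    target_snr: float = 6.0

    # scan geometry / problem size
    scan_kinds: tuple = ("ring_expand", "ring_contract", "wedge_cw", "wedge_ccw")
    grid_step_deg: float = 0.25
    n_cycles: int = 9

    # across-individual hemodynamic variability (multiplicative time-scale)
    hirf_scale_jitter_sd: float = 0.08

    def __post_init__(self):
        if min(self.ri_sd, self.cmi_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.link_rho < 1.0:
            raise ValueError("link_rho must be in [0, 1)")

    @property
    def link_residual_sd(self) -> float:
        """Residual SD making the latent per-condition correlation link_rho."""
        sd_cond = np.sqrt(self.ri_sd ** 2 + self.cmi_sd ** 2 / 4.0)
        if self.link_rho == 0.0:
            return abs(self.link_slope) * sd_cond * 10.0
        return float(abs(self.link_slope) * sd_cond
                     * np.sqrt(1.0 / self.link_rho ** 2 - 1.0))


@dataclass
class IndividualData:
    index: int
    hirf_true: HIRFParams
    observer_true: dict            # condition -> ObserverParams
    truths: list                   # GroundTruthVoxel per voxel
    indices_true: dict             # latent ri/cmi/perceptual indices
    voxel_series: dict             # "radial"/"tangential"/"hirf_scan" frames
    trials: pd.DataFrame


@dataclass
class CohortBundle:
    spec: CohortSpec
    movies: list
    ladder: ProbeLadder
    individuals: list

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            rows.append({"individual": ind.index, **ind.indices_true})
        return pd.DataFrame(rows)


def _draw_voxel_truths(rng, spec: CohortSpec, ri_by_cond, movies,
                       hirf: HIRFParams) -> list:
    lo_e, hi_e = spec.voxel_ecc_range
    lo_s, hi_s = spec.voxel_sigma_range
    truths = []
    driven_sds, driven_vars = [], []
    for _ in range(spec.n_driven):
        ecc = rng.uniform(lo_e, hi_e)
        ang = rng.uniform(0.0, 2 * np.pi)
        sig = rng.uniform(lo_s, hi_s)
        x0, y0 = ecc * np.cos(ang), ecc * np.sin(ang)
        prfs = {}
        for cond in CONDITIONS:
            jitter = rng.normal(0.0, spec.voxel_log_ar_jitter_sd)
            ar = ar_for_subtractive_ri(sig, ri_by_cond[cond]) * np.exp(jitter)
            ar = float(np.clip(ar, np.exp(-2.0), np.exp(2.0)))
            prfs[cond] = PRFParams(x0, y0, sig, ar)
        clean = np.concatenate([
            predict_bold(prfs["radial"], m, hirf, frames_per_cycle=16)
            for m in movies])
        clean = spec.amplitude * clean / float(np.max(np.abs(clean)))
        sd = noise_sd_for_target_snr(clean, spec.target_snr)
        driven_sds.append(sd)
        driven_vars.append(float(clean.var() + sd * sd))
        truths.append(GroundTruthVoxel(prfs["radial"], prfs["tangential"],
                                       noise_sd=sd, amplitude=spec.amplitude))
    # non-driven voxels share the typical noise floor; vessels are given a
    # noise variance matching the typical driven *total* variance, so their
    # 3x inflation puts them in the top variance decile, as in real cortex
    sd_noise = float(np.median(driven_sds)) if driven_sds else 0.5 * spec.amplitude
    sd_vessel = float(np.sqrt(np.median(driven_vars))) if driven_vars else sd_noise
    for label, sd in ([("noise", sd_noise)] * spec.n_noise
                      + [("vessel", sd_vessel)] * spec.n_vessel):
        truths.append(GroundTruthVoxel(None, None, noise_sd=sd,
                                       amplitude=spec.amplitude, label=label))
    return truths


def simulate_cohort(spec: CohortSpec, movies=None) -> CohortBundle:
    """Draw a full linked cohort: ground truths, voxel series and trials."""
    rng = np.random.default_rng(spec.seed)
    if movies is None:
        movies = build_movies(spec.scan_kinds, spec.grid_step_deg, spec.n_cycles)
    ladder = probe_ladder()
    resid_sd = spec.link_residual_sd

    individuals = []
    for i in range(spec.n_individuals):
        ri_base = rng.normal(spec.ri_mean, spec.ri_sd)
        cmi = rng.normal(spec.cmi_mean, spec.cmi_sd)
        ri_by_cond = {"radial": ri_base + cmi / 2.0,
                      "tangential": ri_base - cmi / 2.0}
        intercepts = {"radial": spec.perc_intercept_radial,
                      "tangential": spec.perc_intercept_tangential}
        ri_perc = {}
        observers = {}
        for cond in CONDITIONS:
            sign = 1.0 if cond == "radial" else -1.0
            cond_mean = spec.ri_mean + sign * spec.cmi_mean / 2.0
            centered = ri_by_cond[cond] - cond_mean
            ri_perc[cond] = (intercepts[cond] + spec.link_slope * centered
                             + rng.normal(0.0, resid_sd))
            beta = float(np.clip(np.exp(ri_perc[cond]), 0.26, 3.9))
            observers[cond] = ObserverParams(sigma_obs=spec.sigma_obs,
                                             beta=beta,
                                             lapse_const=spec.lapse_const)
        scale_jit = np.exp(rng.normal(0.0, spec.hirf_scale_jitter_sd))
        hirf_true = HIRFParams(scale1=1.0 * scale_jit, scale2=1.0 * scale_jit)
        truths = _draw_voxel_truths(rng, spec, ri_by_cond, movies, hirf_true)
        vox_seed = int(rng.integers(2 ** 31 - 1))
        trial_seed = int(rng.integers(2 ** 31 - 1))
        series = simulate_voxels(truths, movies, hirf_true, vox_seed)
        trials = simulate_trials(observers, ladder,
                                 spec.trials_per_condition // len(ladder.ar_values),
                                 trial_seed)
        individuals.append(IndividualData(
            index=i, hirf_true=hirf_true, observer_true=observers,
            truths=truths,
            indices_true={
                "ri_prf_radial": ri_by_cond["radial"],
                "ri_prf_tangential": ri_by_cond["tangential"],
                "cmi_prf": cmi,
                "ri_perc_radial": ri_perc["radial"],
                "ri_perc_tangential": ri_perc["tangential"],
            },
            voxel_series=series, trials=trials))
    return CohortBundle(spec=spec, movies=movies, ladder=ladder,
                        individuals=individuals)
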