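"""Anisotropy indices and group-level correspondence/variability analysis.

Definitions (per individual unless stated):

- RI_pRF = sigma_radial - sigma_tangential (degrees), the subtractive
  radial bias of a fitted pRF; averaged over selected voxels within a
  visual area, then (unweighted) across areas for the per-individual value.
  A divisive variant sigma_radial / sigma_tangential is exported alongside.
- CMI_pRF = RI_pRF(radial condition) - RI_pRF(tangential condition): the
  co-axial modulation of the neural radial bias by stimulus orientation.
- RI_perc = log(AR_perc), the perceptual radial bias from the observer fit.
- CI_perc re-signs RI_perc so positive values mean elongation along the
  stimulus orientation: CI = +RI in the radial condition, -RI in the
  tangential condition; mean CI averages the two conditions.

The group analysis pairs these indices across individuals: paired t-tests
on RI_pRF between conditions, one-sample t-tests on RI_perc per condition,
and one-tailed (positive-association) Pearson correlations with regression
lines for RI_perc-on-RI_pRF per condition and mean-CI-on-CMI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compute_prf_indices", "compute_perc_indices", "group_summary",
           "cohort_invariant_violations", "COHORT_COLUMNS"]

CONDITIONS = ("radial", "tangential")

COHORT_COLUMNS = (
    "individual", "ri_prf_radial", "ri_prf_tangential", "cmi_prf",
    "ri_perc_radial", "ri_perc_tangential",
    "ci_perc_radial", "ci_perc_tangential", "mean_ci_perc",
)


def compute_prf_indices(sigma_radial, sigma_tangential) -> dict:
    """Voxel-level or individual-level pRF anisotropy from fitted widths.

    ``sigma_radial`` / ``sigma_tangential`` map condition name ->
    array-like of widths (degrees).  Returns the across-voxel mean
    subtractive index per condition, its divisive (log-reported) variant,
    and the co-axial modulation index.
    """
    ri = {}
    ri_divisive = {}
    for cond in CONDITIONS:
        sr = np.asarray(sigma_radial[cond], dtype=float)
        st = np.asarray(sigma_tangential[cond], dtype=float)
        if np.any(sr <= 0) or np.any(st <= 0):
            raise ValueError("pRF widths must be positive")
        ri[cond] = float(np.mean(sr - st))
        ri_divisive[cond] = float(np.mean(np.log(sr / st)))
    return {
        "ri_prf": ri,
        "ri_prf_divisive_log": ri_divisive,
        "cmi_prf": ri["radial"] - ri["tangential"],
    }


def compute_perc_indices(psych_fits: dict) -> dict:
    """Perceptual indices from per-condition observer fits.

    ``psych_fits`` maps condition -> PsychFit (or any object exposing
    ``ri_perc``).  A missing condition yields a partial result with the
    dependent quantities set to NaN and ``complete`` False.
    """
    ri = {c: (float(psych_fits[c].ri_perc) if c in psych_fits else np.nan)
          for c in CONDITIONS}
    ci = {"radial": ri["radial"], "tangential": -ri["tangential"]}
    complete = not any(np.isnan(v) for v in ri.values())
    mean_ci = (ci["radial"] + ci["tangential"]) / 2.0 if complete else np.nan
    return {"ri_perc": ri, "ci_perc": ci, "mean_ci_perc": mean_ci,
            "complete": complete}


def _one_tailed_pearson(x, y):
    """Pearson r with a one-tailed p for a positive association."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        return {"r": np.nan, "p_one_tailed": np.nan, "n": int(x.size),
                "flag": "zero-variance input"}
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    p_two = float(res.pvalue)
    p_one = p_two / 2.0 if r > 0 else 1.0 - p_two / 2.0
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": r, "p_one_tailed": float(p_one), "n": int(x.size),
            "slope": float(slope), "intercept": float(intercept)}


def _mean_ci95(x):
    x = np.asarray(x, dtype=float)
    se = stats.sem(x)
    half = se * stats.t.ppf(0.975, x.size - 1)
    m = float(np.mean(x))
    return [m - float(half), m + float(half)]


def group_summary(cohort: pd.DataFrame) -> dict:
    """Group-level statistics over a per-individual cohort table."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 individuals")
    out = {"n": int(len(cohort))}

    t = stats.ttest_rel(cohort["ri_prf_radial"], cohort["ri_prf_tangential"])
    out["paired_t_ri_prf"] = {
        "t": float(t.statistic), "p_two_tailed": float(t.pvalue),
        "mean_difference": float(
            (cohort["ri_prf_radial"] - cohort["ri_prf_tangential"]).mean()),
        "ci95": _mean_ci95(cohort["ri_prf_radial"] - cohort["ri_prf_tangential"]),
    }
    for cond in CONDITIONS:
        t1 = stats.ttest_1samp(cohort[f"ri_perc_{cond}"], 0.0)
        out[f"one_sample_t_ri_perc_{cond}"] = {
            "t": float(t1.statistic), "p_two_tailed": float(t1.pvalue),
            "mean": float(cohort[f"ri_perc_{cond}"].mean()),
            "ci95": _mean_ci95(cohort[f"ri_perc_{cond}"]),
        }
        out[f"corr_ri_perc_on_ri_prf_{cond}"] = _one_tailed_pearson(
            cohort[f"ri_prf_{cond}"], cohort[f"ri_perc_{cond}"])
    out["corr_mean_ci_on_cmi"] = _one_tailed_pearson(
        cohort["cmi_prf"], cohort["mean_ci_perc"])
    return out


def cohort_invariant_violations(cohort: pd.DataFrame) -> dict:
    """Max absolute violation of the index algebra on a cohort table.

    All three identities must hold exactly (up to float rounding) on every
    pipeline output: CMI = RI_r - RI_t, CI_t = -RI_t (with CI_r = RI_r),
    and mean CI = (CI_r + CI_t) / 2.
    """
    def dev(a, b):
        return float(np.max(np.abs(a - b))) if len(cohort) else 0.0

    return {
        "cmi": dev(cohort["cmi_prf"],
                   cohort["ri_prf_radial"] - cohort["ri_prf_tangential"]),
        "ci_radial": dev(cohort["ci_perc_radial"], cohort["ri_perc_radial"]),
        "ci_tangential": dev(cohort["ci_perc_tangential"],
                             -cohort["ri_perc_tangential"]),
        "mean_ci": dev(cohort["mean_ci_perc"],
                       (cohort["ci_perc_radial"] + cohort["ci_perc_tangential"]) / 2),
    }
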