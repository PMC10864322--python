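"""Synthetic-data generators: determinism and model consistency."""

import numpy as np
import pytest

from prfaniso.hirf import HIRFParams
from prfaniso.prf import PRFParams, predict_bold
from prfaniso.psychophysics import ObserverParams, choice_prob_standard
from prfaniso.selection import voxel_quality_metrics
from prfaniso.stimulus import probe_ladder
from prfaniso.synthetic import CohortSpec, GroundTruthVoxel, \
    ar_for_subtractive_ri, noise_sd_for_target_snr, simulate_cohort, \
    simulate_trials, simulate_voxels


class TestVoxelSimulation:
    def test_zero_noise_equals_forward_model(self, movies, hirf):
        prf = PRFParams(2.0, 1.0, 0.6, 1.3)
        vox = GroundTruthVoxel(prf, prf, noise_sd=0.0, amplitude=2.0)
        out = simulate_voxels([vox], movies, hirf, seed=0)
        clean = np.concatenate([
            predict_bold(prf, m, hirf, frames_per_cycle=16) for m in movies])
        clean = 2.0 * clean / np.abs(clean).max()
        assert np.allclose(out["radial"]["v000"].to_numpy(), clean)

    def test_same_seed_reproduces(self, movies, hirf):
        prf = PRFParams(2.0, 1.0, 0.6)
        vox = GroundTruthVoxel(prf, prf, noise_sd=0.5)
        a = simulate_voxels([vox], movies, hirf, seed=42)
        b = simulate_voxels([vox], movies, hirf, seed=42)
        for key in a:
            assert a[key].equals(b[key])

    def test_vessel_variance_inflated(self, movies, hirf):
        noise = GroundTruthVoxel(None, None, noise_sd=1.0, label="noise")
        vessel = GroundTruthVoxel(None, None, noise_sd=1.0, label="vessel")
        out = simulate_voxels([noise, vessel], movies, hirf, seed=1)
        v_noise = out["radial"]["v000"].var()
        v_vessel = out["radial"]["v001"].var()
        assert v_vessel / v_noise == pytest.approx(3.0, rel=0.35)

    def test_noise_calibration_hits_target_snr(self, movies, hirf, rng):
        prf = PRFParams(3.0, 0.5, 0.7)
        clean = np.concatenate([
            predict_bold(prf, m, hirf, frames_per_cycle=16) for m in movies])
        clean = 2.0 * clean / np.abs(clean).max()
        sd = noise_sd_for_target_snr(clean, 5.0)
        n = clean.size
        snrs = [voxel_quality_metrics(
            clean + rng.normal(0, sd, n)).snr for _ in range(200)]
        assert np.mean(snrs) == pytest.approx(5.0, rel=0.15)

    def test_driven_voxel_needs_prfs(self):
        with pytest.raises(ValueError):
            GroundTruthVoxel(None, None, noise_sd=0.1, label="driven")


class TestTrialSimulation:
    def test_noiseless_limit_chooses_standard_for_all_nonunity_probes(self):
        params = {c: ObserverParams(1e-6, 1.0, 0.0)
                  for c in ("radial", "tangential")}
        trials = simulate_trials(params, probe_ladder(), 20, seed=0)
        non_unity = trials[trials["probe_ar"] != 1.0]
        assert non_unity["chose_standard"].all()

    def test_same_seed_identical_table(self):
        params = {c: ObserverParams(0.25, 1.2, 0.02)
                  for c in ("radial", "tangential")}
        a = simulate_trials(params, probe_ladder(), 30, seed=9)
        b = simulate_trials(params, probe_ladder(), 30, seed=9)
        assert a.equals(b)

    def test_axes_balanced(self):
        params = {c: ObserverParams(0.25, 1.0, 0.0)
                  for c in ("radial", "tangential")}
        trials = simulate_trials(params, probe_ladder(), 20, seed=2)
        counts = trials["radial_axis_deg"].value_counts()
        assert counts.min() == counts.max()

    def test_generator_matches_likelihood_including_lapse(self):
        """Empirical choice fractions agree with the fitted likelihood."""
        params = {c: ObserverParams(0.25, 1.2, 0.05)
                  for c in ("radial", "tangential")}
        trials = simulate_trials(params, probe_ladder(), 20000, seed=3)
        sub = trials[trials["orientation_condition"] == "radial"]
        emp = sub.groupby("probe_ar")["chose_standard"].mean()
        for ar, frac in emp.items():
            model = choice_prob_standard(np.log(ar), params["radial"])
            assert frac == pytest.approx(model, abs=0.01)


@pytest.fixture(scope="module")
def tiny_bundle(movies):
    spec = CohortSpec(n_individuals=4, seed=5, n_driven=3, n_noise=1,
                      n_vessel=1, trials_per_condition=90,
                      scan_kinds=("ring_expand", "wedge_cw"),
                      grid_step_deg=0.25)
    return simulate_cohort(spec, movies=movies)


class TestCohort:
    def test_reproducible_given_seed(self, movies, tiny_bundle):
        spec = tiny_bundle.spec
        again = simulate_cohort(spec, movies=movies)
        assert tiny_bundle.truth_table().equals(again.truth_table())
        assert tiny_bundle.individuals[0].trials.equals(
            again.individuals[0].trials)

    def test_truth_table_algebra(self, tiny_bundle):
        t = tiny_bundle.truth_table()
        assert np.allclose(t["cmi_prf"],
                           t["ri_prf_radial"] - t["ri_prf_tangential"])

    def test_voxel_ar_realizes_target_ri(self):
        sig, ri = 0.8, 0.15
        ar = ar_for_subtractive_ri(sig, ri)
        assert sig * np.sqrt(ar) - sig / np.sqrt(ar) == pytest.approx(ri)

    def test_link_residual_sd_zero_rho_large(self):
        spec = CohortSpec(link_rho=0.0)
        assert spec.link_residual_sd > 1.0

    def test_latent_link_correlation_near_target(self):
        spec = CohortSpec(n_individuals=3000, seed=8, link_rho=0.6)
        # draw only the latent indices (no voxel series) via the same rule
        rng = np.random.default_rng(0)
        ri = rng.normal(spec.ri_mean, spec.ri_sd, 3000)
        cmi = rng.normal(spec.cmi_mean, spec.cmi_sd, 3000)
        neural = ri + cmi / 2
        perc = spec.link_slope * (neural - neural.mean()) \
            + rng.normal(0, spec.link_residual_sd, 3000)
        r = np.corrcoef(neural, perc)[0, 1]
        assert r == pytest.approx(0.6, abs=0.03)
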