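"""The cohort generators: determinism, couplings, artifact bookkeeping."""

import numpy as np
import pytest

from narousal import (CouplingSpec, generate_annotation_cohort,
                      generate_eeg_cohort, generate_latent_arousal,
                      generate_pupil_cohort, pairwise_isc)
from narousal.montage import standard_montage
from narousal.synthetic import PupilArtifactParams, generate_luminance
from narousal.experiments import RECOVERY_CHANNELS, RECOVERY_POSTERIOR


class TestLatent:
    def test_standardized_and_sized(self):
        lat = generate_latent_arousal(1200, seed=1)
        assert lat.values.size == 1200
        assert abs(lat.values.mean()) < 1e-9
        assert abs(lat.values.std() - 1.0) < 1e-9

    def test_deterministic_given_seed(self):
        a = generate_latent_arousal(300, seed=42).values
        b = generate_latent_arousal(300, seed=42).values
        assert np.array_equal(a, b)
        c = generate_latent_arousal(300, seed=43).values
        assert not np.array_equal(a, c)

    def test_smoothness_creates_strong_lag1_autocorrelation(self):
        # 40 s low-pass at 1 Hz leaves consecutive samples nearly equal
        lat = generate_latent_arousal(1200, smoothness_s=40.0, seed=2)
        ac1 = np.corrcoef(lat.values[:-1], lat.values[1:])[0, 1]
        assert ac1 > 0.9

    def test_rejects_too_short_duration(self):
        with pytest.raises(ValueError):
            generate_latent_arousal(30, seed=0)


class TestAnnotations:
    def test_full_fidelity_raters_are_identical(self, latent):
        cohort = generate_annotation_cohort(latent, 3, fidelity=1.0, seed=3)
        res = pairwise_isc(np.stack([s.values for s in cohort]))
        assert res.mean_r > 1 - 1e-9

    def test_zero_fidelity_raters_are_uncorrelated(self, latent):
        cohort = generate_annotation_cohort(latent, 8, fidelity=0.0, seed=4)
        res = pairwise_isc(np.stack([s.values for s in cohort]))
        assert abs(res.mean_r) < 0.25  # smooth series: few effective dof

    def test_values_stay_on_rating_scale(self, latent):
        cohort = generate_annotation_cohort(latent, 5, fidelity=0.5, seed=5)
        for s in cohort:
            assert s.values.min() >= 0.0 and s.values.max() <= 250.0
            assert s.fs == 1.0

    def test_mid_fidelity_isc_matches_direct_oracle(self):
        # oracle: explicit pairwise Pearson loop over replicate cohorts
        lat = generate_latent_arousal(400, seed=6)
        zs = []
        for rep in range(20):
            cohort = generate_annotation_cohort(lat, 6, fidelity=0.7,
                                                seed=100 + rep)
            mat = np.stack([s.values for s in cohort])
            rs = [np.corrcoef(mat[i], mat[j])[0, 1]
                  for i in range(6) for j in range(i + 1, 6)]
            zs.append(np.mean(np.arctanh(rs)))
        oracle_mean_z = np.mean(zs)
        res = pairwise_isc(np.stack(
            [s.values for s in
             generate_annotation_cohort(lat, 6, fidelity=0.7, seed=100)]))
        assert abs(res.mean_z - oracle_mean_z) < 0.25

    def test_needs_at_least_two_raters(self, latent):
        with pytest.raises(ValueError):
            generate_annotation_cohort(latent, 1, fidelity=0.5)


class TestPupil:
    def test_no_artifacts_means_raw_equals_clean(self, latent, luminance):
        params = PupilArtifactParams(blink_rate_per_min=0,
                                     spike_rate_per_min=0,
                                     missing_rate_per_min=0, noise_sd=0,
                                     slow_noise_sd=0)
        sim = generate_pupil_cohort(latent, luminance, 2, seed=7,
                                    artifact_params=params)[0]
        assert np.array_equal(sim.raw.values, sim.clean.values)
        assert not sim.raw.missing_mask.any()

    def test_blink_sample_count_matches_injection(self, latent, luminance):
        params = PupilArtifactParams(spike_rate_per_min=0,
                                     missing_rate_per_min=0, noise_sd=0,
                                     slow_noise_sd=0)
        sim = generate_pupil_cohort(latent, luminance, 1, seed=8,
                                    artifact_params=params)[0]
        near_zero = sim.raw.values < 0.5 * sim.clean.values
        # every near-zero excursion is inside the recorded blink mask
        assert near_zero.sum() > 0
        assert np.all(sim.blink_mask[near_zero])

    def test_luminance_contamination_is_negative(self, latent, luminance):
        sim = generate_pupil_cohort(latent, luminance, 1, seed=9)[0]
        ok = ~sim.raw.missing_mask
        lum_up = np.interp(np.arange(ok.size) / 60.0,
                           np.arange(len(luminance), dtype=float),
                           luminance.values)
        assert np.corrcoef(sim.raw.values[ok], lum_up[ok])[0, 1] < 0

    def test_duration_mismatch_raises(self, latent):
        short = generate_luminance(300, seed=1)
        with pytest.raises(ValueError):
            generate_pupil_cohort(latent, short, 2)


class TestEeg:
    def test_deterministic_given_seed(self, latent):
        mont = standard_montage(RECOVERY_CHANNELS)
        coup = CouplingSpec.null(mont.n_channels)
        a = generate_eeg_cohort(latent, mont, coup, seed=10, n_subjects=2)
        b = generate_eeg_cohort(latent, mont, coup, seed=10, n_subjects=2)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        assert a[0].meta["iaf"] == b[0].meta["iaf"]

    def test_sine_carrier_power_monotone_in_latent(self, latent):
        # noiseless configuration: epoch power must track the envelope
        mont = standard_montage(["Oz", "O1"])
        coup = CouplingSpec(np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.5]]))
        rec = generate_eeg_cohort(
            latent, mont, coup, seed=11, n_subjects=1, noise_scale=0.0,
            envelope_noise=0.0, carrier="sine",
            band_amplitudes={"alpha": 1.0})[0]
        fs = int(rec.fs)
        epochs = rec.data[0, :latent.duration_s * fs].reshape(-1, fs)
        power = (epochs ** 2).mean(axis=1)
        order = np.argsort(latent.values)
        # monotone up to the sub-percent epoch-phase discretization of a
        # non-integer-frequency sinusoid sampled over 1 s windows
        assert np.all(np.diff(power[order]) >= -0.01 * power[order][:-1])

    def test_uncoupled_channels_independent_of_latent(self, latent):
        mont = standard_montage(RECOVERY_CHANNELS)
        coup = CouplingSpec.null(mont.n_channels)
        cohort = generate_eeg_cohort(latent, mont, coup, seed=12,
                                     n_subjects=6)
        # envelope ground truth itself must be flat when beta = 0
        for rec in cohort:
            env = rec.meta["envelopes_1hz"]
            drift = env / env.mean(axis=-1, keepdims=True)
            # correlation of every channel/band envelope with the latent
            lat = latent.values - latent.values.mean()
            num = (drift - drift.mean(axis=-1, keepdims=True)) @ lat
            den = (np.linalg.norm(lat)
                   * np.linalg.norm(drift - drift.mean(axis=-1, keepdims=True),
                                    axis=-1))
            r = num / np.maximum(den, 1e-12)
            assert np.abs(np.mean(r)) < 0.2

    def test_excessive_beta_warns_and_clips(self, latent):
        mont = standard_montage(["Oz"])
        coup = CouplingSpec(np.array([[0.0, 0.0, 1.0]]))
        with pytest.warns(RuntimeWarning, match="clip"):
            rec = generate_eeg_cohort(latent, mont, coup, seed=13,
                                      n_subjects=1, envelope_noise=0.0)[0]
        assert rec.meta["envelopes_1hz"].min() > 0

    def test_coupled_posterior_alpha_is_negative_on_average(self, latent):
        from narousal import bandpower
        from narousal.trajectories import ArousalTrajectory
        mont = standard_montage(RECOVERY_CHANNELS)
        coup = CouplingSpec.posterior(mont, RECOVERY_POSTERIOR, beta=-0.3,
                                      bands=("alpha",))
        traj = ArousalTrajectory(latent.values, 1, "annotation")
        post = mont.index(RECOVERY_POSTERIOR)
        rs = []
        cohort = generate_eeg_cohort(latent, mont, coup, seed=14,
                                     n_subjects=8)
        for rec in cohort:
            series = bandpower.epoch_band_power(
                rec, bandpower.correlation_bands(rec.meta["iaf"]))["low_iaf"]
            z = bandpower.transform_power(series)
            rs.append(bandpower.correlate_with_arousal(z, traj)[post].mean())
        assert np.mean(rs) < -0.05
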