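"""Generator-level properties: latent identities, calibration targets,
determinism, artifact plumbing and molecular structure."""

import numpy as np
import pytest

from motionlat.config import SimulationConfig, scaled_config
from motionlat.molecular import pearson, zscore_within_batch
from motionlat.simulate import (CohortSimulator, inject_artifacts,
                                simulate_molecular, simulate_truth,
                                synthesize_epochs)


def truth_moments(mean_li, mu, kappa, scale):
    """Independent moment oracle for Var(LI) = Var(T*(2*pi-1))."""
    m_t = mean_li / (2 * mu - 1)
    e_t2 = m_t ** 2 + scale ** 2
    var_pi = mu * (1 - mu) / (kappa + 1)
    e_c = 2 * mu - 1                      # E[2*pi - 1]
    e_c2 = 4 * (var_pi + mu ** 2) - 4 * mu + 1
    return e_t2 * e_c2 - (m_t * e_c) ** 2


class TestTruth:
    def test_li_identity_exact(self):
        t = simulate_truth(scaled_config({"TC": 30, "WS": 30}, seed=2))
        assert np.array_equal(t.LI_true, t.S_R_true - t.S_L_true)

    def test_zero_variance_degenerate(self):
        cfg = scaled_config({"TC": 5, "WS": 5}, sensitivity_scale=0.0,
                            allocation_params={"TC": (0.25, np.inf),
                                               "WS": (0.75, np.inf)},
                            seed=3)
        t = simulate_truth(cfg)
        for g, sub in t.groupby("group"):
            assert np.allclose(sub.LI_true, cfg.group_means[g], atol=1e-12)
            assert sub.LI_true.nunique() == 1

    def test_symmetric_allocation_gives_zero_li(self):
        cfg = scaled_config({"TC": 4, "WS": 4}, seed=4,
                            group_means={"TC": 0.0, "WS": 0.0},
                            allocation_params={"TC": (0.5, np.inf),
                                               "WS": (0.5, np.inf)})
        t = simulate_truth(cfg)
        assert np.allclose(t.LI_true, 0.0, atol=1e-12)

    def test_group_mean_within_monte_carlo_ci(self):
        cfg = scaled_config({"TC": 1000, "WS": 2}, seed=5)
        t = simulate_truth(cfg).query("group == 'TC'")
        mu, kappa = cfg.allocation_params["TC"]
        var = truth_moments(cfg.group_means["TC"], mu, kappa,
                            cfg.sensitivity_scale)
        half = 2.576 * np.sqrt(var / 1000)
        assert abs(t.LI_true.mean() - cfg.group_means["TC"]) < half

    def test_inverse_interhemispheric_structure(self):
        t = simulate_truth(scaled_config({"TC": 1000, "WS": 1000}, seed=6))
        for _, sub in t.groupby("group"):
            assert pearson(sub.S_R_true, sub.S_L_true) < -0.3

    def test_rejects_invalid_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(artifact_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(rho_expression=1.2)
        with pytest.raises(ValueError):
            scaled_config({"TC": 1, "WS": 5})


class TestEpochs:
    def test_noise_free_round_trip_exact(self, noise_free_run):
        truth, _, lat = noise_free_run
        m = lat.merge(truth, on="subject")
        assert np.abs(m.S_R_uV - m.S_R_true).max() <= 1e-9
        assert np.abs(m.S_L_uV - m.S_L_true).max() <= 1e-9
        assert np.abs(m.LI_uV - m.LI_true).max() <= 1e-9

    def test_zero_amplitude_zero_noise_gives_flat_epochs(self, layout):
        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=2, noise_sd=0.0,
                            seed=7)
        for spec in cfg.component_params.values():
            spec.amplitude_uV = 0.0
        t = simulate_truth(cfg)
        t[["S_R_true", "S_L_true", "LI_true"]] = 0.0
        ep = synthesize_epochs(t, cfg, layout)
        assert np.allclose(ep.data, 0.0)

    def test_determinism_and_seed_sensitivity(self, layout):
        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=3, seed=8)
        t = simulate_truth(cfg)
        a = synthesize_epochs(t, cfg, layout)
        b = synthesize_epochs(t, cfg, layout)
        assert np.array_equal(a.data, b.data)
        cfg2 = scaled_config({"TC": 2, "WS": 2}, n_trials=3, seed=9)
        c = synthesize_epochs(t, cfg2, layout)
        assert not np.array_equal(a.data, c.data)

    def test_subjectwise_generation_matches_cohort(self, layout):
        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=3, seed=10)
        t = simulate_truth(cfg)
        whole = synthesize_epochs(t, cfg, layout)
        parts = [synthesize_epochs(t.iloc[[i]], cfg, layout)
                 for i in range(len(t))]
        stacked = np.concatenate([p.data for p in parts], axis=0)
        assert np.array_equal(whole.data, stacked)

    def test_component_latency_outside_window_rejected(self):
        cfg = SimulationConfig()
        cfg.component_params["N2"].latency_ms = 1500.0
        with pytest.raises(ValueError):
            SimulationConfig(component_params=cfg.component_params)

    def test_noisy_sensitivity_within_analytic_bound(self, layout):
        """At white noise sd 5 and 300 trials the pipeline estimate of S_R
        stays within 3 analytic standard errors of the planted value.

        The SE comes from the exact linear operator of the measurement
        chain (baseline -> zero-phase low-pass -> window mean) applied to
        white noise, including the mastoid-reference contribution.
        """
        from motionlat.components import ComponentExtractor
        from motionlat.laterality import LateralityScorer
        from motionlat.preprocess import lowpass_array, preprocess_epochs

        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=300, noise_sd=5.0,
                            pink_fraction=0.0, artifact_rate=0.0, seed=11)
        sim = CohortSimulator(cfg, layout)
        truth = sim.truth().iloc[[0]]
        ep = sim.epochs(truth, with_artifacts=False)
        avgs = preprocess_epochs(ep, layout)
        comp = ComponentExtractor(layout).transform(avgs)
        lat = LateralityScorer().transform(comp)

        # composite weight vector: impulse response of the measurement chain
        times = ep.times
        eye = np.eye(len(times))
        bmask = (times >= -100) & (times < 0)
        chain = eye - bmask.astype(float) / bmask.sum()
        chain = lowpass_array(chain, cfg.sampling_rate, 30.0, 4)
        wmask = (times >= 155) & (times <= 195)
        w = chain[:, wmask].mean(axis=1)  # weights applied to one channel
        norm2 = float(w @ w)
        n_set = len(layout.rh_set)
        var_a = cfg.noise_sd ** 2 * norm2 * (1 / n_set + 0.5) / cfg.n_trials
        se_sr = np.sqrt(2 * var_a)       # difference of two conditions
        m = lat.merge(truth, on="subject").iloc[0]
        assert abs(m.S_R_uV - m.S_R_true) < 3 * se_sr


class TestArtifacts:
    def test_rate_zero_is_identity(self, layout):
        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=4, artifact_rate=0.0,
                            seed=12)
        t = simulate_truth(cfg)
        ep = synthesize_epochs(t, cfg, layout)
        out = inject_artifacts(ep, cfg, layout)
        assert np.array_equal(ep.data, out.data)
        assert not out.info.artifact_true.any()

    def test_rate_one_spikes_always_trip_threshold(self, layout):
        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=30, noise_sd=0.0,
                            artifact_rate=1.0, seed=13)
        t = simulate_truth(cfg)
        ep = inject_artifacts(synthesize_epochs(t, cfg, layout), cfg, layout)
        assert ep.info.artifact_true.all()
        spikes = ep.info.artifact_kind == "spike"
        analysis = ep.channel_index(layout.analysis_channels)
        exceeded = (np.abs(ep.data[:, analysis, :]) > 200).any(axis=(1, 2))
        assert exceeded[spikes.to_numpy()].all()

    def test_flag_count_within_binomial_interval(self, layout):
        from scipy.stats import binom
        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=300,
                            artifact_rate=0.1, seed=14)
        t = simulate_truth(cfg)
        ep = inject_artifacts(
            synthesize_epochs(t.iloc[[0]], cfg, layout, ("M_SL",)),
            cfg, layout)
        lo, hi = binom.ppf([0.005, 0.995], 300, 0.1)
        assert lo <= ep.info.artifact_true.sum() <= hi


class TestMolecular:
    def test_perfect_rho_gives_exact_correlation(self):
        cfg = scaled_config({"TC": 6, "WS": 6}, rho_expression=1.0, seed=15,
                            expression_batch_scales={"b1": (10.0, 3.0)})
        t = simulate_truth(cfg)
        mol = zscore_within_batch(simulate_molecular(t, cfg))
        sub = mol[mol.feature == "BUD23"].merge(t[["subject", "LI_true"]],
                                                on="subject")
        assert pearson(sub.value_z, sub.LI_true) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_perfect_rho_exact_within_each_batch(self):
        """With two batches the noise-free identity holds exactly within
        each batch (pooling re-standardized batches of finite size leaves
        it near, not at, one)."""
        cfg = scaled_config({"TC": 6, "WS": 6}, rho_expression=1.0, seed=15)
        t = simulate_truth(cfg)
        mol = zscore_within_batch(simulate_molecular(t, cfg))
        sub = mol[mol.feature == "BUD23"].merge(t[["subject", "LI_true"]],
                                                on="subject")
        for _, bsub in sub.groupby("batch"):
            assert pearson(bsub.value_z, bsub.LI_true) == pytest.approx(
                1.0, abs=1e-9)
        assert pearson(sub.value_z, sub.LI_true) > 0.98

    def test_null_rho_large_n_near_zero(self):
        cfg = scaled_config({"WS": 10000}, rho_expression=0.0, seed=16,
                            methylation_features={})
        t = simulate_truth(cfg)
        mol = zscore_within_batch(simulate_molecular(t, cfg))
        sub = mol[mol.feature == "BUD23"].merge(t[["subject", "LI_true"]],
                                                on="subject")
        assert abs(pearson(sub.value_z, sub.LI_true)) < 0.05

    def test_mean_recovered_r_matches_target(self):
        """rho=0.5, n=200: the mean recovered within-batch z-score
        correlation over many seeds sits within 0.03 of the target."""
        rs = []
        for seed in range(120):
            cfg = scaled_config({"WS": 200}, rho_expression=0.5, seed=seed)
            t = simulate_truth(cfg)
            mol = zscore_within_batch(simulate_molecular(t, cfg))
            sub = mol[mol.feature == "BUD23"].merge(
                t[["subject", "LI_true"]], on="subject")
            rs.append(pearson(sub.value_z, sub.LI_true))
        assert abs(np.mean(rs) - 0.5) < 0.03

    def test_methylation_in_unit_interval_and_opposite_sign(self):
        cfg = scaled_config({"TC": 200, "WS": 200}, seed=17)
        t = simulate_truth(cfg)
        mol = simulate_molecular(t, cfg)
        beta = mol[mol.measure_type == "methylation"]
        assert beta.value.between(0, 1).all()
        sub = beta[beta.feature == "cg12099727"].merge(
            t[["subject", "LI_true"]], on="subject")
        assert pearson(sub.value, sub.LI_true) < 0

    def test_degenerate_li_rejected(self):
        cfg = scaled_config({"TC": 4, "WS": 4}, seed=18)
        t = simulate_truth(cfg)
        t["LI_true"] = 1.0
        with pytest.raises(ValueError):
            simulate_molecular(t, cfg)

    def test_batches_split_by_acquisition_parity(self):
        cfg = scaled_config({"WS": 10}, seed=19)
        t = simulate_truth(cfg)
        mol = simulate_molecular(t, cfg)
        expr = mol[(mol.measure_type == "expression")
                   & (mol.feature == "BUD23")]
        b = expr.sort_values("subject").batch.to_numpy()
        assert list(b[:4]) == ["batch1", "batch2", "batch1", "batch2"]
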