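"""Poisson maximum-likelihood fitness inference."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppiseq import fitness, pipeline, simulate

GENS = np.array([0.0, 3.0, 6.0, 9.0, 12.0])


def _model_counts(f0: np.ndarray, s: np.ndarray, depth: float) -> np.ndarray:
    """Noiseless counts from the model equations (frequencies renormalized)."""
    phi = f0[:, None] * np.exp(s[:, None] * GENS[None, :])
    phi /= phi.sum(axis=0, keepdims=True)
    return depth * phi


class TestNoiselessRecovery:
    def test_two_lineage_closed_form(self):
        """With noiseless model-generated counts the fitted fitness gap
        equals the closed-form log-ratio slope ln(phi_A/phi_B)/t = 0.1."""
        counts = _model_counts(np.array([0.5, 0.5]), np.array([0.1, 0.0]), 1e6)
        fit = fitness.infer_fitness(counts, GENS)
        s = fit.estimates["fitness"].to_numpy()
        assert s[0] - s[1] == pytest.approx(0.1, abs=1e-4)
        assert fit.mean_fitness[0] == 0.0
        # mean-fitness curve matches ln of the pool normalizer once the
        # linear gauge (s shifted so lineage B sits at 0) is fixed
        expect = np.log(0.5 * np.exp(0.1 * GENS) + 0.5)
        assert np.allclose(fit.mean_fitness - s[1] * GENS, expect, atol=1e-3)
        # perfect fit scores ~0 on the normalized likelihood and is used
        assert (fit.estimates["log_likelihood"] > -1e-3).all()
        assert fit.estimates["used"].all()

    def test_many_lineage_exact_recovery(self):
        rng = np.random.default_rng(0)
        true_s = rng.uniform(0, 0.4, size=40)
        f0 = rng.dirichlet(np.ones(40))
        counts = _model_counts(f0, true_s, 1e6)
        fit = fitness.infer_fitness(counts, GENS)
        est = fit.estimates["fitness"].to_numpy()
        # fitnesses are identified up to a common shift
        centered = est - est.mean() - (true_s - true_s.mean())
        assert np.abs(centered).max() < 1e-4

    def test_higher_fitness_has_smaller_se_at_equal_f0(self):
        counts = _model_counts(np.array([0.3, 0.3, 0.4]), np.array([0.2, 0.0, 0.0]), 1e4)
        fit = fitness.infer_fitness(counts, GENS)
        se = fit.estimates["se"].to_numpy()
        assert se[0] < se[1]


class TestInvariances:
    def test_scaling_counts_and_depths(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(_model_counts(rng.dirichlet(np.ones(30)), rng.uniform(0, 0.3, 30), 2e4))
        s1 = fitness.infer_fitness(base.astype(float), GENS).estimates["fitness"]
        s2 = fitness.infer_fitness(base.astype(float) * 10, GENS).estimates["fitness"]
        assert np.nanmax(np.abs(s1.to_numpy() - s2.to_numpy())) < 1e-3

    def test_neutral_pool_estimates_near_zero(self, neutral_experiment_config):
        cfg = replace(neutral_experiment_config, reads_per_barcode=400.0, chimera_rate=0.0)
        res = simulate.simulate_pool(cfg, seed=2)
        fit = fitness.infer_fitness(res.reads_observed, res.generations)
        est = fitness.normalize_to_reference(
            fit.estimates, np.flatnonzero(res.library_table["is_control"])
        )
        assert abs(est["fitness"].mean()) < 0.005
        assert np.nanmax(np.abs(fit.mean_fitness)) < 0.05


class TestReferenceZeroing:
    def _estimates(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "fitness": rng.normal(-0.03, 0.01, size=20),
                "log_likelihood": np.zeros(20),
                "used": True,
                "se": 0.01,
                "f0": 0.05,
            },
            index=pd.Index([f"l{i}" for i in range(20)], name="entry_id"),
        )
        return df

    def test_control_mean_exactly_zero(self):
        df = self._estimates()
        controls = [f"l{i}" for i in range(5)]
        out = fitness.normalize_to_reference(df, controls)
        assert out.loc[controls, "fitness"].mean() == pytest.approx(0.0, abs=1e-14)

    def test_translation_invariance(self):
        df = self._estimates()
        controls = [f"l{i}" for i in range(5)]
        a = fitness.normalize_to_reference(df, controls)["fitness"]
        shifted = df.copy()
        shifted["fitness"] += 0.7
        b = fitness.normalize_to_reference(shifted, controls)["fitness"]
        assert np.allclose(a, b)

    def test_no_usable_control_raises(self):
        df = self._estimates()
        df.loc["l0", "used"] = False
        with pytest.raises(ValueError, match="reference"):
            fitness.normalize_to_reference(df, ["l0"])


class TestFlagging:
    def test_corrupted_time_point_flagged(self):
        counts = _model_counts(np.full(10, 0.1), np.zeros(10), 1e4)
        depths = counts.sum(axis=0)
        counts[0, 2] *= 100  # one observation far off its expectation
        fit = fitness.infer_fitness(counts, GENS, depths=depths)
        est = fit.estimates
        assert not est["used"].iloc[0]
        assert est["used"].iloc[1:].all()
        assert est["log_likelihood"].iloc[0] < 10 * fitness.DEFAULT_LIKELIHOOD_THRESHOLD

    def test_threshold_minus_inf_uses_everything(self):
        counts = _model_counts(np.full(4, 0.25), np.zeros(4), 1e3)
        counts[0, 2] *= 100
        est = fitness.infer_fitness(counts, GENS).estimates
        assert fitness.flag_trajectories(est, -np.inf)["used"].all()

    def test_extinct_after_first_sample_hits_decay_bound(self):
        counts = np.zeros((3, 5))
        counts[:, :] = _model_counts(np.full(3, 1 / 3), np.zeros(3), 3000)
        counts[0] = [50, 0, 0, 0, 0]
        fit = fitness.infer_fitness(counts, GENS)
        assert fit.estimates["fitness"].iloc[0] == fitness.S_BOUNDS[0]
        assert np.isfinite(fit.estimates["log_likelihood"].iloc[0])


class TestSimulatedRecovery:
    def test_regression_of_estimate_on_truth(self, experiment_config):
        """Across s in [0, 0.5] at experiment-scale depth, the regression of
        inferred on true fitness has slope ~1 and intercept ~0."""
        values = np.linspace(0.0, 0.5, 81)
        fmap = {
            (i, j): float(values[(i - 1) * 9 + (j - 1)])
            for i in range(1, 10)
            for j in range(1, 10)
        }
        cfg = replace(experiment_config, fitness_map=fmap)
        out = pipeline.validate_inference(config=cfg, seed=6)
        fitted, truth = out["fitted"], out["truth"]
        mask = fitted["Trajectory_used"].to_numpy() & np.isfinite(fitted["Fitness"])
        slope, intercept = np.polyfit(truth[mask], fitted.loc[mask, "Fitness"], 1)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.01)

    def test_replicate_concordance_exceeds_real_data_floor(self, experiment_config):
        traj, _ = simulate.simulate_experiment(experiment_config, n_replicates=3, seed=20)
        fitted = pipeline.fit_trajectories(traj, corrected=False)
        used = fitted.loc[fitted["Trajectory_used"]]
        wide = used.pivot_table(index="barcode_pair", columns="Replicate", values="Fitness").dropna()
        for i, j in [(1, 2), (1, 3), (2, 3)]:
            r = stats.pearsonr(wide[i], wide[j]).statistic
            assert r > 0.91


class TestEdgeCases:
    def test_all_zero_trajectory_unused(self):
        counts = _model_counts(np.full(3, 1 / 3), np.zeros(3), 1000)
        counts[2] = 0.0
        est = fitness.infer_fitness(counts, GENS).estimates
        assert not est["used"].iloc[2]
        assert np.isnan(est["fitness"].iloc[2])

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError):
            fitness.infer_fitness(np.ones((3, 2)), [0, 3], depths=[100, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fitness.infer_fitness(np.array([[1.0, -1.0, 2.0, 1.0, 1.0]]), GENS)
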