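import numpy as np
import pytest

from tsgc import (
    LocalizedEffect,
    NoiseSpec,
    SimConfig,
    generate_panel,
    true_difference_set,
)
from tsgc.errors import ConfigurationError
from tsgc.simulate import default_random_cov


class TestGenerate:
    def test_noiseless_single_group_is_exact_quadratic(self):
        cfg = SimConfig(
            n_groups=1, n_experiments=1, replicas_per_experiment=2,
            n_timepoints=20, group_offsets=(0.0,),
            random_cov=np.zeros((3, 3)), noise=NoiseSpec(kind="iid", sd=0.0),
            seed=1,
        )
        panel, truth = generate_panel(cfg)
        t = np.arange(1, 21, dtype=float)
        b0, b1, b2 = cfg.fixed_effects
        expected = b0 + b1 * t + b2 * t**2
        for subj in panel.subjects:
            np.testing.assert_allclose(panel.series(subj), expected, atol=1e-12)

    def test_reference_design_counts(self):
        panel, _ = generate_panel(SimConfig(seed=2))
        assert panel.n_subjects == 27
        assert panel.n_observations == 3267
        assert panel.axis.n_timepoints == 121

    def test_determinism(self):
        p1, _ = generate_panel(SimConfig(seed=42, n_timepoints=20))
        p2, _ = generate_panel(SimConfig(seed=42, n_timepoints=20))
        assert p1.data.equals(p2.data)
        p3, _ = generate_panel(SimConfig(seed=43, n_timepoints=20))
        assert not p1.data["value"].equals(p3.data["value"])

    def test_ar1_noise_lag1_autocorrelation(self):
        cfg = SimConfig(
            n_groups=1, n_experiments=1, replicas_per_experiment=3,
            n_timepoints=2000, group_offsets=(0.0,),
            random_cov=np.zeros((3, 3)), fixed_effects=(0.0, 0.0, 0.0),
            noise=NoiseSpec(kind="ar1", phi=0.8, sd=0.02), seed=9,
        )
        panel, _ = generate_panel(cfg)
        r1 = []
        for subj in panel.subjects:
            e = panel.series(subj)
            ec = e - e.mean()
            r1.append(np.sum(ec[:-1] * ec[1:]) / np.sum(ec**2))
        assert np.mean(r1) == pytest.approx(0.8, abs=0.05)

    def test_random_effect_covariance_converges(self):
        cov = default_random_cov()
        cfg = SimConfig(
            n_groups=1, n_experiments=1, replicas_per_experiment=400,
            n_timepoints=10, group_offsets=(0.0,), random_cov=cov,
            noise=NoiseSpec(kind="iid", sd=0.0), seed=10,
        )
        _, truth = generate_panel(cfg)
        emp = np.cov(truth.random_effects.to_numpy().T)
        sd = np.sqrt(np.diag(cov))
        emp_sd = np.sqrt(np.diag(emp))
        np.testing.assert_allclose(emp_sd, sd, rtol=0.15)

    def test_scaling_preserves_difference_signs_for_shared_baseline(self):
        """When the compared groups share the same baseline mean (difference
        injected after the first timepoint), baseline scaling cannot flip the
        sign of their mean difference."""
        eff = LocalizedEffect(group="G2", start_minutes=10, end_minutes=40,
                              magnitude=0.5)
        cfg = SimConfig(
            n_timepoints=30, fixed_effects=(5.0, 0.04, -2e-4),
            group_offsets=(0.0, 0.0, 0.0), localized_effect=eff,
            noise=NoiseSpec(kind="iid", sd=0.01), scale_baseline=True, seed=13,
        )
        panel, truth = generate_panel(cfg)
        assert panel.scaled
        d_pre = (truth.group_curves["G2"] - truth.group_curves["G1"]).to_numpy()
        d_post = (
            truth.scaled_group_curves["G2"] - truth.scaled_group_curves["G1"]
        ).to_numpy()
        mask = np.abs(d_pre) > 1e-6
        assert (np.sign(d_pre[mask]) == np.sign(d_post[mask])).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(noise=NoiseSpec(kind="ar1", phi=1.2))
        with pytest.raises(ConfigurationError):
            SimConfig(random_cov=np.array([[1, 2, 0], [2, 1, 0], [0, 0, 1.0]]))
        with pytest.raises(ConfigurationError):
            SimConfig(n_timepoints=5)
        with pytest.raises(ConfigurationError):
            SimConfig(group_offsets=(0.0, 0.1))


class TestTruth:
    def test_constant_offset_differs_everywhere(self):
        _, truth = generate_panel(SimConfig(seed=3, n_timepoints=25))
        assert true_difference_set(truth, ("G1", "G2")) == set(range(1, 26))

    def test_identical_groups_differ_nowhere(self):
        cfg = SimConfig(seed=4, n_timepoints=25, group_offsets=(0.0, 0.0, 0.0))
        _, truth = generate_panel(cfg)
        assert true_difference_set(truth, ("G1", "G3")) == set()

    def test_localized_effect_marks_exact_window(self):
        eff = LocalizedEffect(group="G2", start_minutes=20, end_minutes=60, magnitude=0.2)
        cfg = SimConfig(
            seed=5, n_timepoints=41, group_offsets=(0.0, 0.0, 0.0),
            localized_effect=eff,
        )
        _, truth = generate_panel(cfg)
        # minute m lives at index m/2 + 1
        expected = set(range(11, 32))
        assert true_difference_set(truth, ("G1", "G2")) == expected
        assert true_difference_set(truth, ("G2", "G3")) == expected
        assert true_difference_set(truth, ("G1", "G3")) == set()

    def test_unknown_pair_rejected(self):
        _, truth = generate_panel(SimConfig(seed=6, n_timepoints=20))
        with pytest.raises(KeyError):
            true_difference_set(truth, ("G1", "G9"))
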