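"""Synthetic trial generation: survival draws, KM curves, digitization,
effect trajectories and end-to-end parameter recovery."""

import numpy as np
import pytest

from shpn_cea import (
    SyntheticTrialSpec,
    WeibullSurvival,
    default_effect_profile,
    digitize_curve,
    fit_weibull,
    generate_effect_trajectories,
    km_estimate,
    qol_effect_from_config,
    secondary_icer,
    simulate_survival,
    simulate_trial,
)


def one_arm_spec(w, n, censoring_days=1e9, seed=0):
    return SyntheticTrialSpec(
        survival={"arm": w}, n_per_arm={"arm": n}, censoring_days=censoring_days, seed=seed
    )


class TestSimulateSurvival:
    def test_exponential_mean_identity(self):
        w = WeibullSurvival(shape=1.0, scale=0.02, time_unit_days=1.0)
        data = simulate_survival(one_arm_spec(w, 100_000))
        mean = w.time_unit_days / w.scale  # 50 days
        se = mean / np.sqrt(len(data))  # exponential: sd == mean
        assert abs(data["time_days"].mean() - mean) < 3 * se
        assert data["event"].all()

    def test_immediate_censoring_censors_everyone(self):
        w = WeibullSurvival(shape=1.0, scale=0.02, time_unit_days=1.0)
        data = simulate_survival(one_arm_spec(w, 50, censoring_days=1e-9))
        assert (data["event"] == 0).all()
        assert np.allclose(data["time_days"], 1e-9)

    def test_fixed_seed_reproduces_dataset(self):
        w = WeibullSurvival(shape=0.9, scale=0.05)
        a = simulate_survival(one_arm_spec(w, 30, seed=42))
        b = simulate_survival(one_arm_spec(w, 30, seed=42))
        assert a.equals(b)

    def test_spec_validation(self):
        w = WeibullSurvival(shape=1.0, scale=0.1)
        with pytest.raises(ValueError):
            SyntheticTrialSpec(survival={"a": w}, n_per_arm={"a": 1})
        with pytest.raises(ValueError):
            SyntheticTrialSpec(survival={"a": w}, n_per_arm={"b": 5})


class TestKmEstimate:
    def test_hand_product_limit_all_events(self):
        pts = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert pts.times.tolist() == [1.0, 2.0, 3.0]
        assert pts.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_single_subject_drops_to_zero(self):
        pts = km_estimate([5.0], [1])
        assert pts.times.tolist() == [5.0]
        assert pts.survival == pytest.approx([0.0])

    def test_curve_stays_positive_when_last_observation_censored(self):
        # event first, censored afterwards: S drops to 3/4 and never to 0
        pts = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        assert pts.survival == pytest.approx([0.75])
        # event last: the curve does reach 0
        pts2 = km_estimate([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 1])
        assert pts2.survival == pytest.approx([0.0])

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([1.0, 2.0], [0, 0])


class TestDigitizeCurve:
    def make_km(self):
        rng_w = WeibullSurvival(shape=0.9, scale=0.05)
        data = simulate_survival(one_arm_spec(rng_w, 100, seed=1))
        return km_estimate(data["time_days"], data["event"])

    def test_zero_jitter_lies_on_step_function(self):
        km = self.make_km()
        dig = digitize_curve(km, n_points=20, jitter_sd=0.0, seed=2)
        from shpn_cea.synthetic_data import _km_step

        expected = np.clip(_km_step(km, dig.times), 1e-6, 1.0)
        assert dig.survival == pytest.approx(expected)

    def test_jitter_stays_clipped_to_unit_interval(self):
        km = self.make_km()
        dig = digitize_curve(km, n_points=200, jitter_sd=0.2, seed=3)
        assert (dig.survival > 0).all()
        assert (dig.survival <= 1.0).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            digitize_curve(self.make_km(), n_points=2)


class TestEffectTrajectories:
    def test_zero_noise_returns_means_exactly(self, fixture_config):
        means = default_effect_profile(fixture_config)
        out = generate_effect_trajectories(
            means, noise_sd={m: 0.0 for m in ("Qol", "BMI", "FFM", "FFMI", "Handgrip", "6MWT")},
            seed=0,
        )
        assert out == means

    def test_qol_means_reproduce_config_secondary_icer(self, fixture_config):
        profile = {d.metric: d for d in default_effect_profile(fixture_config)}
        from_config = secondary_icer(qol_effect_from_config(fixture_config), 3, fixture_config)
        from_profile = secondary_icer(profile["Qol"], 3, fixture_config)
        assert from_profile.icer == pytest.approx(from_config.icer)

    def test_noisy_mean_recovery(self, fixture_config):
        qol = qol_effect_from_config(fixture_config)
        sd = 0.02
        reps = np.array(
            [
                generate_effect_trajectories([qol], noise_sd={"Qol": sd}, seed=s)[0]
                .changes["sHPN"][0]
                for s in range(10_000)
            ]
        )
        se = sd / np.sqrt(reps.size)
        assert abs(reps.mean() - qol.changes["sHPN"][0]) < 3 * se


def _recovery_errors(n, seeds=100, n_points=30, jitter_sd=0.01):
    """Median |relative error| of (shape, scale) over the full pipeline:
    simulate -> Kaplan-Meier -> digitize -> complementary-log-log fit."""
    truth = WeibullSurvival(shape=0.89735193, scale=0.05464799, time_unit_days=42.0)
    errs_shape, errs_scale = [], []
    for seed in range(seeds):
        spec = one_arm_spec(truth, n, censoring_days=5 * 365.25, seed=seed)
        data = simulate_survival(spec)
        km = km_estimate(data["time_days"], data["event"])
        dig = digitize_curve(km, n_points=n_points, jitter_sd=jitter_sd, seed=seed + 10_000)
        fit = fit_weibull(dig, time_unit_days=42.0)
        errs_shape.append(abs(fit.shape / truth.shape - 1))
        errs_scale.append(abs(fit.scale / truth.scale - 1))
    return float(np.median(errs_shape)), float(np.median(errs_scale))


class TestParameterRecovery:
    def test_shape_recovered_and_scale_error_shrinks_with_cohort_size(self):
        """The shape recovers tightly at trial-like precision; the scale —
        an extrapolation of the fitted line to t = one time unit — carries
        the slope noise amplified by the mean log-time, so its error is
        larger but falls as the simulated cohort grows."""
        shape_500, scale_500 = _recovery_errors(500)
        shape_5000, scale_5000 = _recovery_errors(5000)
        assert shape_500 <= 0.10
        assert shape_5000 <= shape_500
        assert scale_5000 < scale_500
        assert scale_5000 <= 0.10


class TestSimulateTrial:
    def test_produces_all_pipeline_inputs(self, fixture_config):
        data = simulate_trial(fixture_config, seed=9)
        assert set(data) == {"patients", "km", "digitized", "effects"}
        assert len(data["patients"]) == 47
        assert set(data["km"]) == {"sHPN", "Non-sHPN"}
        metrics = {e.metric for e in data["effects"]}
        assert metrics == {"Qol", "BMI", "FFM", "FFMI", "Handgrip", "6MWT"}

    def test_deterministic_given_seed(self, fixture_config):
        a = simulate_trial(fixture_config, seed=4)
        b = simulate_trial(fixture_config, seed=4)
        assert a["patients"].equals(b["patients"])
        assert a["digitized"] == b["digitized"]
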