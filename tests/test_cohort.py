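"""Cohort generation: marginals, the disturbance model, and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thresholdsim import (
    Cohort,
    SimulationConfig,
    apply_disturbance,
    draw_disturbance,
    draw_true_scores,
    generate_cohort,
    read_cohort_csv,
    sample_skewness,
    write_cohort_csv,
)
from thresholdsim.cohort import ConfigurationError


class TestDrawTrueScores:
    def test_marginal_moments_at_study_size(self, rng):
        iq, cr = draw_true_scores(6400, 100.0, 15.0, 0.3, rng)
        for v in (iq, cr):
            assert abs(v.mean() - 100.0) < 1.0
            assert abs(v.std(ddof=1) - 15.0) < 1.0

    def test_perfect_correlation_gives_identical_vectors(self, rng):
        iq, cr = draw_true_scores(50, 100.0, 15.0, 1.0, rng)
        np.testing.assert_allclose(iq, cr, rtol=1e-9)
        assert np.corrcoef(iq, cr)[0, 1] == pytest.approx(1.0)

    def test_zero_correlation_null_bound(self, rng):
        # CLT: under rho=0 the sample r is O(1/sqrt(n))
        iq, cr = draw_true_scores(100_000, 100.0, 15.0, 0.0, rng)
        assert abs(np.corrcoef(iq, cr)[0, 1]) < 3.0 / np.sqrt(100_000)

    @pytest.mark.parametrize("rho", [0.25, 0.5, 0.85])
    def test_population_correlation_is_induced(self, rho, rng):
        iq, cr = draw_true_scores(200_000, 100.0, 15.0, rho, rng)
        assert np.corrcoef(iq, cr)[0, 1] == pytest.approx(rho, abs=0.01)

    @pytest.mark.parametrize("bad", [{"rho": 1.5}, {"rho": -0.1}, {"sd": 0.0}, {"sd": -3.0}])
    def test_invalid_parameters_raise(self, bad, rng):
        kwargs = {"n": 10, "mean": 100.0, "sd": 15.0, "rho": 0.5, "rng": rng}
        kwargs.update(bad)
        with pytest.raises(ConfigurationError):
            draw_true_scores(**kwargs)


class TestDrawDisturbance:
    def test_support_is_unit_interval(self, rng):
        d = draw_disturbance(10_000, 0.5, 0.5, rng)
        assert d.min() >= 0.0 and d.max() <= 1.0

    def test_negative_skew_shape_mean(self, rng):
        # Beta(9, 1): mean alpha/(alpha+beta) = 0.9, negatively skewed
        d = draw_disturbance(100_000, 9.0, 1.0, rng)
        assert d.mean() == pytest.approx(0.9, abs=0.01)
        assert sample_skewness(d) < 0.0

    def test_symmetric_shape_has_no_skew(self, rng):
        d = draw_disturbance(100_000, 9.0, 9.0, rng)
        assert sample_skewness(d) == pytest.approx(0.0, abs=0.05)

    def test_positive_skew(self, rng):
        assert sample_skewness(draw_disturbance(100_000, 1.0, 9.0, rng)) > 0.0

    def test_nonpositive_shapes_raise(self, rng):
        with pytest.raises(ConfigurationError):
            draw_disturbance(10, 0.0, 9.0, rng)
        with pytest.raises(ConfigurationError):
            draw_disturbance(10, 9.0, -1.0, rng)


class TestApplyDisturbance:
    def test_hand_arithmetic(self):
        np.testing.assert_allclose(
            apply_disturbance(np.array([150.0, 80.0]), np.array([0.5, 1.0])),
            [75.0, 80.0],
        )

    def test_identity_and_annihilation(self):
        t = np.array([10.0, 20.0, 30.0])
        np.testing.assert_array_equal(apply_disturbance(t, np.ones(3)), t)
        np.testing.assert_array_equal(apply_disturbance(t, np.zeros(3)), np.zeros(3))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            apply_disturbance(np.ones(3), np.ones(4))

    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_observed_bracketed_by_zero_and_true(self, n, seed):
        rng = np.random.default_rng(seed)
        t = np.abs(rng.normal(100, 15, n))
        d = rng.uniform(0, 1, n)
        obs = apply_disturbance(t, d)
        assert np.all(obs >= 0.0) and np.all(obs <= t)


class TestGenerateCohort:
    def test_invariants_and_shared_disturbance(self, disturbed_cohort):
        c = disturbed_cohort
        assert c.n == 400
        np.testing.assert_array_equal(c.observed_iq, c.true_iq * c.disturbance)
        np.testing.assert_array_equal(
            c.observed_creativity, c.true_creativity * c.disturbance
        )
        assert c.disturbance.min() >= 0.0 and c.disturbance.max() <= 1.0

    def test_attenuation_direction(self, disturbed_cohort):
        c = disturbed_cohort
        if (c.true_iq > 0).all():
            assert c.observed_iq.mean() <= c.true_iq.mean()
            assert c.observed_creativity.mean() <= c.true_creativity.mean()

    def test_disabled_disturbance_is_bit_identical(self, null_cohort):
        assert null_cohort.observed_iq is null_cohort.true_iq
        np.testing.assert_array_equal(null_cohort.disturbance, 1.0)

    def test_seeded_determinism(self):
        config = SimulationConfig(n=100, rho="uniform", seed=7)
        a, b = generate_cohort(config), generate_cohort(config)
        np.testing.assert_array_equal(a.observed_iq, b.observed_iq)
        np.testing.assert_array_equal(a.disturbance, b.disturbance)
        assert a.rho == b.rho

    def test_worked_example_generative_setting(self):
        # n=400 subjects, true scores ~ N(120, 15), rho=0, Beta(9,1) disturbance
        config = SimulationConfig(
            n=400, true_mean=120.0, true_sd=15.0, rho=0.0,
            beta_alpha=9.0, beta_beta=1.0, seed=1,
        )
        c = generate_cohort(config)
        assert c.true_iq.mean() == pytest.approx(120.0, abs=2.5)
        assert abs(np.corrcoef(c.true_iq, c.true_creativity)[0, 1]) < 0.15
        assert sample_skewness(c.disturbance) < 0.0

    @pytest.mark.parametrize(
        "bad",
        [
            {"n": 3},
            {"rho": 1.2},
            {"rho": "unifrom"},
            {"beta_alpha": 0.0},
            {"alpha_level": 1.0},
            {"true_sd": -1.0},
        ],
    )
    def test_config_validation(self, bad):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**{"n": 100, **bad})

    def test_cohort_invariant_enforcement(self):
        with pytest.raises(ValueError):
            Cohort(np.ones(3), np.ones(3), np.ones(4), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            Cohort(np.ones(3), np.ones(3), np.full(3, 1.5), np.ones(3), np.ones(3))


class TestCohortCsvRoundTrip:
    def test_round_trip(self, tmp_path, disturbed_cohort):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(disturbed_cohort, path)
        back = read_cohort_csv(path)
        np.testing.assert_allclose(back.observed_iq, disturbed_cohort.observed_iq)
        np.testing.assert_allclose(back.disturbance, disturbed_cohort.disturbance)

    def test_deposited_column_names_are_mapped(self, tmp_path, disturbed_cohort):
        # synthetic stand-in for the deposited worked-example CSV layout
        df = disturbed_cohort.to_frame().rename(
            columns={
                "true_iq": "true.iq",
                "true_creativity": "true.crea",
                "disturbance": "dist",
                "observed_iq": "obs.iq",
                "observed_creativity": "obs.crea",
            }
        )
        path = tmp_path / "deposited_synthetic.csv"
        df.to_csv(path, index=False)
        back = read_cohort_csv(path)
        np.testing.assert_allclose(back.true_iq, disturbed_cohort.true_iq)
        np.testing.assert_allclose(
            back.observed_creativity, disturbed_cohort.observed_creativity
        )

    def test_observed_reconstructed_when_missing(self, tmp_path, disturbed_cohort):
        df = disturbed_cohort.to_frame()[["true_iq", "true_creativity", "disturbance"]]
        path = tmp_path / "partial.csv"
        df.to_csv(path, index=False)
        back = read_cohort_csv(path)
        np.testing.assert_allclose(back.observed_iq, disturbed_cohort.observed_iq)
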