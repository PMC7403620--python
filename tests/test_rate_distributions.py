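"""Discrete rate distributions: construction, CV, unconstrained transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from busteds.rate_distributions import (AlphaDistribution,
                                        DiscreteDistribution,
                                        OmegaDistribution, alpha_from_vector,
                                        alpha_to_vector, check_degenerate,
                                        coefficient_of_variation,
                                        constrained_omega_from_vector,
                                        constrained_omega_to_vector,
                                        logits_to_weights,
                                        make_alpha_distribution,
                                        omega_from_vector, omega_to_vector,
                                        point_mass_alpha, weights_to_logits)


class TestAlphaConstruction:
    def test_point_mass_reduction(self):
        ad = make_alpha_distribution(1.0, 1.0, 0.3, 0.4)
        assert ad.is_point_mass()
        assert ad.mean() == pytest.approx(1.0, abs=1e-15)

    @given(a1=st.floats(0.01, 0.99), a3=st.floats(1.01, 50.0),
           f1=st.floats(0.05, 0.45), f2=st.floats(0.05, 0.45))
    @settings(max_examples=50, deadline=None)
    def test_unit_mean_to_machine_precision(self, a1, a3, f1, f2):
        ad = make_alpha_distribution(a1, a3, f1, f2)
        assert abs(float(ad.weights @ ad.rates) - 1.0) < 1e-12
        assert np.all(np.diff(ad.rates) >= -1e-12)

    def test_reference_alpha_distribution_recovered(self):
        """Hyperparameters chosen to realize rates (0.12, 0.53, 6.2) with
        weights (0.19, 0.72, 0.09) reproduce those rates after the
        unit-mean renormalization (up to the common scale)."""
        rates = np.array([0.12, 0.53, 6.2])
        weights = np.array([0.19, 0.72, 0.09])
        ad = make_alpha_distribution(0.12 / 0.53, 6.2 / 0.53, 0.19, 0.72)
        mean = weights @ rates
        assert np.allclose(ad.rates, rates / mean, rtol=1e-12)
        assert np.allclose(ad.weights, weights)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            make_alpha_distribution(1.2, 2.0, 0.3, 0.3)  # a1 > 1
        with pytest.raises(ValueError):
            make_alpha_distribution(0.5, 0.9, 0.3, 0.3)  # a3 < 1
        with pytest.raises(ValueError):
            make_alpha_distribution(0.5, 2.0, 0.7, 0.4)  # weights > 1


class TestCV:
    def test_point_mass_cv_zero(self):
        assert coefficient_of_variation(point_mass_alpha()) == 0.0

    def test_reference_distribution_cv(self):
        """The 3-bin distribution printed for a flavivirus polymerase
        alignment: CV computes to ~1.72 from the rounded rates."""
        d = DiscreteDistribution(rates=[0.12, 0.53, 6.2],
                                 weights=[0.19, 0.72, 0.09])
        assert coefficient_of_variation(d) == pytest.approx(1.7195, abs=2e-4)

    def test_two_point_symmetric(self):
        d = DiscreteDistribution(rates=[0.0, 2.0], weights=[0.5, 0.5])
        assert coefficient_of_variation(d) == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.floats(0.01, 20.0), min_size=1, max_size=10))
    @settings(max_examples=40, deadline=None)
    def test_moment_formula_agrees_with_explicit_sum(self, rates):
        rates = sorted(rates)
        w = np.full(len(rates), 1.0 / len(rates))
        d = DiscreteDistribution(rates=np.array(rates), weights=w)
        m = sum(wi * ri for wi, ri in zip(w, rates))
        var = sum(wi * (ri - m) ** 2 for wi, ri in zip(w, rates))
        assert coefficient_of_variation(d) == pytest.approx(
            np.sqrt(var) / m, abs=1e-12)

    def test_zero_mean_rejected(self):
        d = DiscreteDistribution(rates=[0.0, 0.0], weights=[0.5, 0.5])
        with pytest.raises(ValueError):
            coefficient_of_variation(d)


class TestOmegaValidation:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            OmegaDistribution(rates=[0.5, 0.1, 2.0],
                              weights=[0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            OmegaDistribution(rates=[0.1, 1.5, 2.0],
                              weights=[0.3, 0.3, 0.4])  # middle > 1

    def test_boundary_omega3_is_valid(self):
        d = OmegaDistribution(rates=[0.1, 1.0, 1.0], weights=[0.6, 0.3, 0.1])
        assert d.omega3 == 1.0


class TestTransforms:
    @pytest.mark.parametrize("K", [2, 3, 4, 5])
    def test_omega_round_trip(self, K):
        rng = np.random.default_rng(K)
        for _ in range(20):
            below = np.sort(rng.uniform(0.02, 0.98, size=K - 1))
            rates = np.concatenate([below, [1.0 + rng.uniform(0.01, 50)]])
            w = rng.dirichlet(np.full(K, 2.0))
            d = OmegaDistribution(rates=rates, weights=w)
            back = omega_from_vector(omega_to_vector(d), K)
            assert np.allclose(back.rates, d.rates, rtol=1e-9)
            assert np.allclose(back.weights, d.weights, atol=1e-9)

    def test_constrained_omega_round_trip(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rates = np.concatenate([np.sort(rng.uniform(0.02, 0.98, 2)), [1.0]])
            d = OmegaDistribution(rates=rates, weights=rng.dirichlet([2, 2, 2]))
            back = constrained_omega_from_vector(
                constrained_omega_to_vector(d), 3)
            assert back.rates[-1] == 1.0
            assert np.allclose(back.rates, d.rates, rtol=1e-9)
            assert np.allclose(back.weights, d.weights, atol=1e-9)

    def test_alpha_round_trip(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ad = make_alpha_distribution(rng.uniform(0.05, 0.95),
                                         1 + rng.uniform(0.05, 30),
                                         rng.uniform(0.05, 0.4),
                                         rng.uniform(0.05, 0.4))
            back = alpha_from_vector(alpha_to_vector(ad))
            assert np.allclose(back.rates, ad.rates, rtol=1e-9)
            assert np.allclose(back.weights, ad.weights, atol=1e-9)

    def test_boundary_omega3_maps_to_finite_vector(self):
        d = OmegaDistribution(rates=[0.1, 0.5, 1.0], weights=[0.6, 0.3, 0.1])
        assert np.all(np.isfinite(omega_to_vector(d)))

    def test_degenerate_weights_representable_in_closure(self):
        w = logits_to_weights(weights_to_logits(np.array([1.0, 0.0, 0.0])))
        assert np.allclose(w, [1.0, 0.0, 0.0], atol=1e-9)

    def test_non_finite_vector_rejected(self):
        with pytest.raises(ValueError):
            omega_from_vector(np.array([np.nan] * 5), 3)
        with pytest.raises(ValueError):
            alpha_from_vector(np.array([np.inf, 0, 0, 0]))


def test_overfitting_warnings():
    near_equal = DiscreteDistribution(rates=[0.5, 0.5000001, 2.0],
                                      weights=[0.4, 0.4, 0.2])
    with pytest.warns(UserWarning, match="nearly equal"):
        issues = check_degenerate(near_equal)
    assert len(issues) == 1
    tiny_weight = DiscreteDistribution(rates=[0.1, 1.0, 2.0],
                                       weights=[0.5, 0.5 - 1e-6, 1e-6])
    with pytest.warns(UserWarning, match="negligible"):
        check_degenerate(tiny_weight)
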