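"""MG94 x GTR generator structure, reversibility, and transition matrices."""

import numpy as np
import pytest

from busteds.codon_model import (NucleotideExchangeabilities, SpectralQ,
                                 build_generator, expected_rate,
                                 flux_decomposition, mixture_scale,
                                 transition_matrix, unscaled_q)
from busteds.genetic_code import classify_substitution
from busteds.rate_distributions import (OmegaDistribution,
                                        make_alpha_distribution,
                                        point_mass_alpha)
from tests.conftest import random_positional_frequencies, random_theta


def test_rate_entry_follows_mg94_factorization(code, uniform_freqs):
    """q(ACT->AGT) = alpha * omega * theta_CG * pi2_G (nonsynonymous,
    second position, C<->G)."""
    theta = NucleotideExchangeabilities(ac=0.3, at=0.7, cg=1.7, ct=2.0, gt=0.4)
    rng = np.random.default_rng(0)
    freqs = random_positional_frequencies(rng)
    alpha, omega = 1.3, 0.6
    Q = unscaled_q(code, theta, freqs, alpha, omega)
    i, j = code.index["ACT"], code.index["AGT"]
    assert Q[i, j] == pytest.approx(alpha * omega * 1.7 * freqs.pi[1, 2],
                                    rel=1e-12)
    # a synonymous entry has no omega factor: CTT -> CTC (Leu, position 3)
    i, j = code.index["CTT"], code.index["CTC"]
    assert Q[i, j] == pytest.approx(alpha * 2.0 * freqs.pi[2, 1], rel=1e-12)


def test_alpha_scales_whole_generator(code, uniform_freqs, hky_theta):
    Q1 = unscaled_q(code, hky_theta, uniform_freqs, 1.0, 0.4)
    Q2 = unscaled_q(code, hky_theta, uniform_freqs, 2.5, 0.4)
    assert np.allclose(Q2, 2.5 * Q1, rtol=1e-12)


def test_multistep_entries_zero_and_rows_sum_zero(code, uniform_freqs,
                                                 hky_theta):
    Q = unscaled_q(code, hky_theta, uniform_freqs, 1.0, 2.0)
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    off = Q - np.diag(np.diag(Q))
    assert np.all(off >= 0)
    rng = np.random.default_rng(3)
    sense = code.sense_codons
    for _ in range(300):
        i, j = rng.integers(0, 61, 2)
        if i == j:
            continue
        kind = classify_substitution(code, sense[i], sense[j]).kind
        if kind == "multi_step":
            assert Q[i, j] == 0.0


def test_reversibility(code):
    rng = np.random.default_rng(11)
    theta, freqs = random_theta(rng), random_positional_frequencies(rng)
    Q = unscaled_q(code, theta, freqs, 1.0, 1.7)
    pi = freqs.codon_frequencies(code)
    flux = pi[:, None] * Q
    assert np.allclose(flux, flux.T, atol=1e-14)


def test_negative_rates_rejected(code, uniform_freqs, hky_theta):
    with pytest.raises(ValueError):
        unscaled_q(code, hky_theta, uniform_freqs, -0.1, 1.0)
    with pytest.raises(ValueError):
        unscaled_q(code, hky_theta, uniform_freqs, 1.0, -2.0)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, code, uniform_freqs, hky_theta):
        gen = build_generator(code, hky_theta, uniform_freqs, 1.0, 0.5)
        assert np.allclose(transition_matrix(gen, 0.0), np.eye(61), atol=1e-12)

    def test_long_time_reaches_stationarity(self, code):
        """Oracle: the stationary distribution is the left null vector of Q;
        every row of P(t) converges to it."""
        rng = np.random.default_rng(5)
        theta, freqs = random_theta(rng), random_positional_frequencies(rng)
        gen = build_generator(code, theta, freqs, 1.0, 0.8)
        null = np.linalg.svd(gen.Q.T)[2][-1]
        null = np.abs(null) / np.abs(null).sum()
        assert np.abs(null - gen.pi).max() < 1e-8
        P = transition_matrix(gen, 1e4)
        assert np.abs(P - gen.pi[None, :]).max() < 1e-6

    def test_chapman_kolmogorov(self, code):
        rng = np.random.default_rng(9)
        for _ in range(5):
            theta = random_theta(rng)
            freqs = random_positional_frequencies(rng)
            gen = build_generator(code, theta, freqs, 1.0,
                                  rng.uniform(0.1, 3.0))
            s, t = rng.uniform(0.05, 1.0, 2)
            Ps, Pt = transition_matrix(gen, s), transition_matrix(gen, t)
            Pst = transition_matrix(gen, s + t)
            assert np.abs(Ps @ Pt - Pst).max() < 1e-8

    def test_detailed_balance_of_p(self, code):
        rng = np.random.default_rng(13)
        theta, freqs = random_theta(rng), random_positional_frequencies(rng)
        gen = build_generator(code, theta, freqs, 1.0, 0.3)
        P = transition_matrix(gen, 0.7)
        flux = gen.pi[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_time_alpha_identity(self, code, uniform_freqs, hky_theta):
        """P(t; alpha Q) = P(alpha t; Q): the shortcut the engine exploits."""
        pi = uniform_freqs.codon_frequencies(code)
        Q1 = unscaled_q(code, hky_theta, uniform_freqs, 1.0, 0.5)
        Qa = unscaled_q(code, hky_theta, uniform_freqs, 1.9, 0.5)
        P_a = SpectralQ(Qa, pi).transition_matrices(np.array([0.4]))[0]
        P_1 = SpectralQ(Q1, pi).transition_matrices(np.array([1.9 * 0.4]))[0]
        assert np.abs(P_a - P_1).max() < 1e-10

    def test_negative_time_rejected(self, code, uniform_freqs, hky_theta):
        gen = build_generator(code, hky_theta, uniform_freqs, 1.0, 0.5)
        with pytest.raises(ValueError):
            transition_matrix(gen, -0.1)


def test_neutral_flux_ratio_matches_enumeration(code, uniform_freqs):
    """At omega = 1 the expected syn:nonsyn flux ratio equals the ratio
    obtained by classifying every one-step pair and weighting by pi."""
    theta = NucleotideExchangeabilities()  # all exchangeabilities equal
    syn_rate, nonsyn_rate = flux_decomposition(code, theta, uniform_freqs)
    pi = uniform_freqs.codon_frequencies(code)
    syn = nonsyn = 0.0
    sense = code.sense_codons
    Q = unscaled_q(code, theta, uniform_freqs, 1.0, 1.0)
    for i in range(61):
        for j in range(61):
            if i == j or Q[i, j] == 0:
                continue
            kind = classify_substitution(code, sense[i], sense[j]).kind
            if kind == "synonymous":
                syn += pi[i] * Q[i, j]
            else:
                nonsyn += pi[i] * Q[i, j]
    assert syn_rate / nonsyn_rate == pytest.approx(syn / nonsyn, rel=1e-10)


def test_hky85_mapping_gives_kappa_ratio():
    theta = NucleotideExchangeabilities.hky85(2.0)
    arr = theta.as_array()  # AC AG AT CG CT GT
    transitions = [arr[1], arr[4]]
    transversions = [arr[0], arr[2], arr[3], arr[5]]
    for ti in transitions:
        for tv in transversions:
            assert ti / tv == pytest.approx(2.0)


def test_default_scaling_gives_unit_expected_rate(code, uniform_freqs,
                                                  hky_theta):
    gen = build_generator(code, hky_theta, uniform_freqs, 1.3, 0.7)
    assert -float(gen.pi @ np.diag(gen.Q)) == pytest.approx(1.0, rel=1e-12)


def test_mixture_scale_closed_form(code, uniform_freqs, hky_theta):
    om = OmegaDistribution(rates=[0.1, 1.0, 3.0], weights=[0.6, 0.3, 0.1])
    ad = make_alpha_distribution(0.3, 2.0, 0.25, 0.5)
    syn, nonsyn = flux_decomposition(code, hky_theta, uniform_freqs)
    expected = ad.mean() * (syn + om.mean() * nonsyn)
    assert mixture_scale(code, hky_theta, uniform_freqs, om, ad) == \
        pytest.approx(expected, rel=1e-12)
    # brute force over the joint categories
    brute = sum(f * p * expected_rate(code, hky_theta, uniform_freqs, a, w)
                for a, f in zip(ad.rates, ad.weights)
                for w, p in zip(om.rates, om.weights))
    assert brute == pytest.approx(expected, rel=1e-12)
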