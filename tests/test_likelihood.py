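"""Pruning likelihood vs the exhaustive oracle, and engine invariants."""

import dendropy
import numpy as np
import pytest

from busteds.likelihood import (LikelihoodEngine, ModelParameters,
                                brute_force_likelihood)
from busteds.rate_distributions import (OmegaDistribution,
                                        make_alpha_distribution,
                                        point_mass_alpha)
from busteds.seq_io import CodonAlignment, Phylogeny
from tests.conftest import (random_model, random_positional_frequencies,
                            random_theta, random_tiny_instance)


def test_pruning_matches_brute_force_on_random_instances(code):
    """50 random tiny instances: exhaustive enumeration over all per-branch
    omega and per-site alpha assignments agrees with pruning to 1e-8."""
    rng = np.random.default_rng(101)
    for trial in range(50):
        aln, tree = random_tiny_instance(rng, code)
        mixing = "branch-site" if trial % 2 == 0 else "site"
        model = random_model(rng, code, k_omega=2, k_alpha=2, mixing=mixing)
        ll_prune = LikelihoodEngine(aln, tree).log_likelihood(model)
        ll_brute = brute_force_likelihood(aln, tree, model)
        assert ll_prune == pytest.approx(ll_brute, abs=1e-8)


def test_brute_force_against_hand_expansion(code, uniform_freqs, hky_theta):
    """2-taxon, 1-site, 2 omega categories: write the mixture sum out by
    hand with raw matrix exponentials."""
    from busteds.codon_model import SpectralQ, mixture_scale, unscaled_q

    aln = CodonAlignment.from_strings([("A", "AAA"), ("B", "AGA")], code)
    tree = Phylogeny.from_newick("(A:0.2,B:0.3);")
    om = OmegaDistribution(rates=[0.2, 2.0], weights=[0.7, 0.3])
    model = ModelParameters(code=code, theta=hky_theta, freqs=uniform_freqs,
                            omega_dist=om)
    pi = uniform_freqs.codon_frequencies(code)
    scale = mixture_scale(code, hky_theta, uniform_freqs, om,
                          point_mass_alpha())
    i, j = code.index["AAA"], code.index["AGA"]
    hand = 0.0
    for ka, pa in zip(om.rates, om.weights):
        Pa = SpectralQ(unscaled_q(code, hky_theta, uniform_freqs, 1, ka),
                       pi).transition_matrices(np.array([0.2 / scale]))[0]
        for kb, pb in zip(om.rates, om.weights):
            Pb = SpectralQ(unscaled_q(code, hky_theta, uniform_freqs, 1, kb),
                           pi).transition_matrices(np.array([0.3 / scale]))[0]
            hand += pa * pb * float(pi @ (Pa[:, i] * Pb[:, j]))
    assert brute_force_likelihood(aln, tree, model) == \
        pytest.approx(np.log(hand), abs=1e-10)
    assert LikelihoodEngine(aln, tree).log_likelihood(model) == \
        pytest.approx(np.log(hand), abs=1e-10)


def test_brute_force_rejects_large_instances(code, uniform_freqs, hky_theta):
    rng = np.random.default_rng(0)
    sense = code.sense_codons
    seqs = [(f"s{i}", sense[int(rng.integers(61))]) for i in range(6)]
    aln = CodonAlignment.from_strings(seqs, code)
    newick = "((s0:.1,s1:.1):.1,(s2:.1,s3:.1):.1,(s4:.1,s5:.1):.1);"
    tree = Phylogeny.from_newick(newick)
    model = ModelParameters(code=code, theta=hky_theta, freqs=uniform_freqs,
                            omega_dist=OmegaDistribution(rates=[0.5, 2.0],
                                                         weights=[0.5, 0.5]))
    with pytest.raises(ValueError, match="too large"):
        brute_force_likelihood(aln, tree, model, max_branches=5)


def test_alpha_point_mass_reproduces_no_srv_likelihood(code):
    """A 3-bin alpha distribution collapsed to a point mass gives exactly
    the no-SRV model's likelihood at every site."""
    rng = np.random.default_rng(77)
    sense = code.sense_codons
    seqs = [(f"s{i}", "".join(sense[j] for j in rng.integers(0, 61, 30)))
            for i in range(5)]
    aln = CodonAlignment.from_strings(seqs, code)
    tree = Phylogeny.from_newick(
        "((s0:0.1,s1:0.15):0.05,(s2:0.2,s3:0.1):0.1,s4:0.3);")
    base = random_model(rng, code, k_omega=3, k_alpha=1)
    pm3 = make_alpha_distribution(1.0, 1.0, 0.2, 0.5)  # 3 bins, all rates 1
    srv_model = ModelParameters(code=code, theta=base.theta, freqs=base.freqs,
                                omega_dist=base.omega_dist, alpha_dist=pm3)
    eng = LikelihoodEngine(aln, tree)
    sl_no_srv = eng.site_log_likelihoods(base)
    sl_pm = eng.site_log_likelihoods(srv_model)
    assert np.abs(sl_no_srv.site_loglik - sl_pm.site_loglik).max() < 1e-8


def test_zero_branch_identical_codons_gives_equilibrium_frequency(
        code, uniform_freqs, hky_theta):
    aln = CodonAlignment.from_strings([("A", "ACG"), ("B", "ACG")], code)
    tree = Phylogeny.from_newick("(A:0.0,B:0.0);")
    model = ModelParameters(code=code, theta=hky_theta, freqs=uniform_freqs,
                            omega_dist=OmegaDistribution(rates=[1.0],
                                                         weights=[1.0]))
    sl = LikelihoodEngine(aln, tree).site_log_likelihoods(model)
    pi = uniform_freqs.codon_frequencies(code)
    assert sl.site_loglik[0] == pytest.approx(
        np.log(pi[code.index["ACG"]]), abs=1e-12)


def test_all_missing_site_contributes_zero(code, uniform_freqs, hky_theta):
    aln = CodonAlignment.from_strings([("A", "ACG---"), ("B", "ACGNNN")], code)
    tree = Phylogeny.from_newick("(A:0.1,B:0.2);")
    model = ModelParameters(code=code, theta=hky_theta, freqs=uniform_freqs,
                            omega_dist=OmegaDistribution(rates=[1.0],
                                                         weights=[1.0]))
    sl = LikelihoodEngine(aln, tree).site_log_likelihoods(model)
    assert sl.site_loglik[1] == pytest.approx(0.0, abs=1e-10)


def test_duplicated_site_doubles_its_contribution(code):
    rng = np.random.default_rng(5)
    model = random_model(rng, code)
    aln1 = CodonAlignment.from_strings([("s0", "ACG"), ("s1", "AGG"),
                                        ("s2", "ACA")], code)
    aln2 = CodonAlignment.from_strings([("s0", "ACGACG"), ("s1", "AGGAGG"),
                                        ("s2", "ACAACA")], code)
    tree = Phylogeny.from_newick("((s0:0.1,s1:0.2):0.1,s2:0.3);")
    ll1 = LikelihoodEngine(aln1, tree).log_likelihood(model)
    ll2 = LikelihoodEngine(aln2, tree).log_likelihood(model)
    assert ll2 == pytest.approx(2 * ll1, abs=1e-9)


def test_taxon_permutation_leaves_likelihood_unchanged(code):
    rng = np.random.default_rng(21)
    sense = code.sense_codons
    rows = {f"s{i}": "".join(sense[j] for j in rng.integers(0, 61, 10))
            for i in range(4)}
    newick = "((s0:0.1,s1:0.2):0.05,(s2:0.15,s3:0.25):0.1);"
    tree = Phylogeny.from_newick(newick)
    model = random_model(rng, code, k_alpha=2)
    lls = []
    for order in (["s0", "s1", "s2", "s3"], ["s3", "s1", "s0", "s2"]):
        aln = CodonAlignment.from_strings([(n, rows[n]) for n in order], code)
        lls.append(LikelihoodEngine(aln, tree).log_likelihood(model))
    assert lls[0] == pytest.approx(lls[1], abs=1e-10)


def test_rerooting_invariance_under_reversibility(code):
    """Likelihood of the reversible model does not depend on which node
    anchors the pruning recursion.  (Rerooting must happen at an existing
    node: placing a root mid-branch would split that branch into two
    independent omega draws and genuinely change the branch-site model.)"""
    rng = np.random.default_rng(33)
    sense = code.sense_codons
    seqs = [(f"s{i}", "".join(sense[j] for j in rng.integers(0, 61, 8)))
            for i in range(4)]
    aln = CodonAlignment.from_strings(seqs, code)
    # unrooted-style storage so both representations share one branch set
    newick = "(s0:0.1,s1:0.2,(s2:0.15,s3:0.25):0.1);"
    model = random_model(rng, code, k_alpha=2)

    ll_orig = LikelihoodEngine(aln, Phylogeny.from_newick(newick)
                               ).log_likelihood(model)
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    node = dtree.find_node_with_taxon_label("s2").parent_node
    dtree.reroot_at_node(node, update_bipartitions=False,
                         suppress_unifurcations=True)
    ll_reroot = LikelihoodEngine(aln, Phylogeny.from_dendropy(dtree)
                                 ).log_likelihood(model)
    assert ll_orig == pytest.approx(ll_reroot, abs=1e-8)


def test_cache_reuse_is_transparent(code):
    """Evaluating with changed parameters and then the originals must give
    the same value as a fresh engine (cache invalidation correctness)."""
    rng = np.random.default_rng(55)
    aln, tree = random_tiny_instance(rng, code, n_sites=5)
    m1 = random_model(rng, code, k_alpha=2)
    m2 = random_model(rng, code, k_alpha=2)
    eng = LikelihoodEngine(aln, tree)
    first = eng.log_likelihood(m1)
    eng.log_likelihood(m2)
    again = eng.log_likelihood(m1)
    fresh = LikelihoodEngine(aln, tree).log_likelihood(m1)
    assert first == again == fresh


def test_taxa_mismatch_raises(code, tiny_tree):
    aln = CodonAlignment.from_strings([("A", "AAA"), ("B", "AAA"),
                                       ("X", "AAA")], code)
    with pytest.raises(ValueError, match="mismatch"):
        LikelihoodEngine(aln, tiny_tree)
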