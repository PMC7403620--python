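import numpy as np
import pytest

from busteds.codon_model import NucleotideExchangeabilities
from busteds.frequencies import PositionalFrequencies
from busteds.genetic_code import get_code
from busteds.likelihood import ModelParameters
from busteds.rate_distributions import (AlphaDistribution, OmegaDistribution,
                                        point_mass_alpha)
from busteds.seq_io import CodonAlignment, Phylogeny


@pytest.fixture(scope="session")
def code():
    return get_code()


@pytest.fixture
def uniform_freqs():
    return PositionalFrequencies(pi=np.full((3, 4), 0.25))


@pytest.fixture
def hky_theta():
    return NucleotideExchangeabilities.hky85(2.0)


@pytest.fixture
def tiny_alignment(code):
    return CodonAlignment.from_strings(
        [("A", "AAACCTGGA"), ("B", "AAGCCTGGA"), ("C", "ACACGTGGC")], code)


@pytest.fixture
def tiny_tree():
    return Phylogeny.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")


def random_positional_frequencies(rng):
    pi = rng.dirichlet(np.full(4, 5.0), size=3)
    return PositionalFrequencies(pi=pi)


def random_theta(rng):
    vals = rng.lognormal(mean=0.0, sigma=0.4, size=5)
    return NucleotideExchangeabilities(*vals)


def random_model(rng, code, k_omega=2, k_alpha=2, mixing="branch-site"):
    """A random small mixture model for oracle comparisons."""
    below = np.sort(rng.uniform(0.05, 1.0, size=k_omega - 1))
    rates = np.concatenate([below, [1.0 + rng.uniform(0.0, 4.0)]])
    w = rng.dirichlet(np.full(k_omega, 2.0))
    om = OmegaDistribution(rates=rates, weights=w)
    if k_alpha == 1:
        ad = point_mass_alpha()
    else:
        raw = np.sort(rng.uniform(0.2, 3.0, size=k_alpha))
        fw = rng.dirichlet(np.full(k_alpha, 2.0))
        ad = AlphaDistribution.from_raw(raw, fw)
    return ModelParameters(code=code,
                           theta=random_theta(rng),
                           freqs=random_positional_frequencies(rng),
                           omega_dist=om, alpha_dist=ad, omega_mixing=mixing)


def random_tiny_instance(rng, code, n_taxa=3, n_sites=2):
    """Random alignment + tree small enough for exhaustive enumeration."""
    sense = code.sense_codons
    seqs = [(f"s{i}", "".join(sense[j] for j in
                              rng.integers(0, len(sense), n_sites)))
            for i in range(n_taxa)]
    aln = CodonAlignment.from_strings(seqs, code)
    bl = rng.uniform(0.01, 0.6, size=4)
    newick = (f"((s0:{bl[0]:.4f},s1:{bl[1]:.4f}):{bl[2]:.4f},s2:{bl[3]:.4f});"
              if n_taxa == 3 else None)
    assert newick is not None, "only 3-taxon instances supported here"
    return aln, Phylogeny.from_newick(newick)
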