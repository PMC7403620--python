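"""Parametric simulation of codon alignments under the branch-site model.

The generative process mirrors the fitted model exactly, including its
branch-length scaling convention, so that simulation followed by fitting is
a well-posed parameter-recovery problem:

* root codons are drawn from the equilibrium (CF3x4 product-form) codon
  frequencies;
* each site draws a synonymous rate category alpha_s (shared across
  branches);
* each branch-site combination independently draws an omega category;
* each child state is drawn from P(t_b; alpha_s, omega^bs), with branch
  lengths in expected substitutions per codon site under the full mixture.

Defaults follow the null-simulation design used for the false-positive-rate
experiments: equal base frequencies and an HKY85 nucleotide component with
kappa = 2, expressed through the GTR exchangeability slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_model import (NucleotideExchangeabilities, SpectralQ,
                          mixture_scale, unscaled_q)
from .frequencies import PositionalFrequencies
from .genetic_code import GeneticCode, get_code
from .rate_distributions import AlphaDistribution, OmegaDistribution
from .seq_io import CodonAlignment, Phylogeny


def make_model_tree(n_taxa: int, total_length: float = 4.0,
                    shape: str = "balanced", seed: int = 0) -> Phylogeny:
    """Deterministic-given-seed model tree scaled to a total branch length.

    ``shape="balanced"`` splits taxa as evenly as possible with equal branch
    lengths; ``shape="yule"`` grows a random Yule topology with iid
    exponential branch lengths, rescaled so branches sum to ``total_length``.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    names = [f"t{i + 1}" for i in range(n_taxa)]
    rng = np.random.default_rng(seed)

    if shape == "balanced":
        def build(lo, hi):
            if hi - lo == 1:
                return f"{names[lo]}:1"
            mid = (lo + hi + 1) // 2
            return f"({build(lo, mid)},{build(mid, hi)}):1"
        if n_taxa % 2 == 0:  # binary root: 2n-2 branches
            mid = n_taxa // 2
            newick = f"({build(0, mid)},{build(mid, n_taxa)});"
        else:  # trifurcating (unrooted-style) root: 2n-3 branches
            a = (n_taxa + 2) // 3
            b = a + (n_taxa - a + 1) // 2
            newick = (f"({build(0, a)},{build(a, b)},{build(b, n_taxa)});")
        tree = Phylogeny.from_newick(newick)
        lengths = np.ones(tree.n_nodes)
    elif shape == "yule":
        # random-join construction (uniform labelled histories, the Yule
        # topology distribution): merge two uniformly chosen subtrees
        tips = [f"{n}:1" for n in names]
        while len(tips) > 2:
            i, j = rng.choice(len(tips), size=2, replace=False)
            i, j = int(min(i, j)), int(max(i, j))
            merged = f"({tips[i]},{tips[j]}):1"
            tips[i] = merged
            tips.pop(j)
        newick = f"({tips[0]},{tips[1]});"
        tree = Phylogeny.from_newick(newick)
        lengths = rng.exponential(size=tree.n_nodes)
    else:
        raise ValueError(f"unknown tree shape {shape!r}")

    lengths[tree.root] = 0.0
    tree.edge_length[:] = lengths * (total_length / lengths[np.arange(
        tree.n_nodes) != tree.root].sum())
    tree.edge_length[tree.root] = 0.0
    return tree


@dataclass
class SimulationSpec:
    """Everything needed to simulate one alignment reproducibly."""

    omega_dist: OmegaDistribution
    alpha_dist: AlphaDistribution
    n_codons: int = 300
    tree: Phylogeny | None = None
    n_taxa: int = 16
    total_length: float = 4.0
    tree_shape: str = "balanced"
    kappa: float | None = 2.0
    theta: NucleotideExchangeabilities | None = None
    freqs: PositionalFrequencies | str = "equal"
    code: GeneticCode = field(default_factory=get_code)
    seed: int = 0

    def resolve(self):
        tree = self.tree or make_model_tree(self.n_taxa, self.total_length,
                                            self.tree_shape, self.seed)
        if self.theta is not None:
            theta = self.theta
        elif self.kappa is not None:
            theta = NucleotideExchangeabilities.hky85(self.kappa)
        else:
            theta = NucleotideExchangeabilities()
        freqs = (PositionalFrequencies(pi=np.full((3, 4), 0.25))
                 if isinstance(self.freqs, str) else self.freqs)
        return tree, theta, freqs


def _draw_rows(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    """Vectorized categorical draw of child states from P[parent] rows."""
    rows = np.cumsum(P[parents], axis=1)
    rows /= rows[:, -1:]
    u = rng.random((len(parents), 1))
    return (rows < u).sum(axis=1).astype(np.int32)


def simulate_alignment(spec: SimulationSpec
                       ) -> tuple[CodonAlignment, dict]:
    """Simulate one codon alignment; returns it with a truth record.

    The truth record stores the per-site alpha category, the per-branch-site
    omega category matrix, and the realized fraction of branch-site
    combinations in the selected (omega > 1) class.
    """
    tree, theta, freqs = spec.resolve()
    code = spec.code
    om, ad = spec.omega_dist, spec.alpha_dist
    N = spec.n_codons
    if N < 1:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(spec.seed)
    pi = freqs.codon_frequencies(code)
    scale = mixture_scale(code, theta, freqs, om, ad)
    spect = [SpectralQ(unscaled_q(code, theta, freqs, 1.0, w), pi)
             for w in om.rates]

    alpha_cat = rng.choice(ad.K, size=N, p=ad.weights / ad.weights.sum())
    states = {tree.root: rng.choice(code.n_states, size=N, p=pi / pi.sum())}

    non_root = [v for v in tree.postorder() if v != tree.root][::-1]  # preorder
    omega_cat = np.zeros((len(non_root), N), dtype=np.int8)
    for b, v in enumerate(non_root):
        parent_states = states[tree.parent[v]]
        k_draw = rng.choice(om.K, size=N, p=om.weights / om.weights.sum())
        omega_cat[b] = k_draw
        child = np.empty(N, dtype=np.int32)
        t_eff = tree.edge_length[v] / scale
        for m in range(ad.K):
            for k in range(om.K):
                sel = (alpha_cat == m) & (k_draw == k)
                if not np.any(sel):
                    continue
                P = spect[k].transition_matrices(
                    np.array([ad.rates[m] * t_eff]))[0]
                child[sel] = _draw_rows(P, parent_states[sel], rng)
        states[v] = child

    names = tree.taxa
    leaf_rows = {tree.labels[v]: states[v] for v in tree.leaves}
    seqs = [(name, "".join(code.sense_codons[s] for s in leaf_rows[name]))
            for name in names]
    aln = CodonAlignment.from_strings(seqs, code)

    selected = (om.rates[omega_cat] > 1.0)
    truth = {
        "seed": spec.seed,
        "n_codons": N,
        "tree_newick": tree.to_newick(),
        "scale": scale,
        "omega_distribution": om.to_pairs(),
        "alpha_distribution": ad.to_pairs(),
        "alpha_category": alpha_cat.tolist(),
        "omega_category": omega_cat,
        "fraction_selected": float(selected.mean()),
    }
    return aln, truth


def gillespie_branch_counts(code: GeneticCode,
                            theta: NucleotideExchangeabilities,
                            freqs: PositionalFrequencies, alpha: float,
                            omega: float, t: float, n_sites: int,
                            rng=None, scale: float = 1.0
                            ) -> tuple[int, int]:
    """Event-by-event simulation along one branch; returns (syn, nonsyn)
    substitution counts.  Used to cross-check the model's expected flux."""
    from .genetic_code import classify_substitution

    rng = rng or np.random.default_rng(0)
    Q = unscaled_q(code, theta, freqs, alpha, omega) / scale
    pi = freqs.codon_frequencies(code)
    exit_rate = -np.diag(Q)
    jump = Q.copy()
    jump[np.diag_indices_from(jump)] = 0.0
    jump_cum = np.cumsum(jump, axis=1)
    jump_cum /= np.maximum(jump_cum[:, -1:], 1e-300)
    syn = nonsyn = 0
    start = rng.choice(code.n_states, size=n_sites, p=pi / pi.sum())
    for s in range(n_sites):
        state, clock = int(start[s]), 0.0
        while True:
            rate = exit_rate[state]
            if rate <= 0:
                break
            clock += rng.exponential(1.0 / rate)
            if clock > t:
                break
            nxt = int(np.searchsorted(jump_cum[state], rng.random()))
            kind = classify_substitution(code, code.sense_codons[state],
                                         code.sense_codons[nxt]).kind
            if kind == "synonymous":
                syn += 1
            else:
                nonsyn += 1
            state = nxt
    return syn, nonsyn
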