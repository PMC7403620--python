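"""Phylogenetic likelihood for the branch-site omega / site alpha mixture.

The model's likelihood at site s is

    L_s = sum_m f_m L_s(alpha_m)

where the inner term is computed by Felsenstein pruning in which each branch
b uses the category-averaged transition matrix

    A_{b,m} = sum_k p_k P(t_b; alpha_m, omega_k).

Averaging the matrix over omega within each branch is exact for the
branch-site random-effects model because omega^bs is drawn independently for
every branch-site combination; alpha_s, by contrast, is shared by all
branches at a site, hence the outer mixture.  Site-level ("M-series") omega
mixtures are supported by replacing the averaged matrices with pure
per-class matrices.

All transition matrices are computed spectrally via the identity
P(t; alpha, omega) = P(alpha * t; 1, omega), so only one eigendecomposition
per omega category is required regardless of the number of branches or
alpha categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .codon_model import (NucleotideExchangeabilities, SpectralQ,
                          mixture_scale, unscaled_q)
from .frequencies import PositionalFrequencies
from .genetic_code import GeneticCode
from .rate_distributions import (AlphaDistribution, OmegaDistribution,
                                 point_mass_alpha)
from .seq_io import CodonAlignment, Phylogeny, check_taxa

_LOG_ZERO_GUARD = 1e-300


@dataclass(frozen=True)
class ModelParameters:
    """Full parameterization of one codon mixture model.

    ``omega_mixing`` selects how the omega GDD applies: ``"branch-site"``
    (independent draw per branch-site combination, the BUSTED family) or
    ``"site"`` (one draw per site shared by all branches, the M1a/M2a
    family).
    """

    code: GeneticCode
    theta: NucleotideExchangeabilities
    freqs: PositionalFrequencies
    omega_dist: OmegaDistribution
    alpha_dist: AlphaDistribution = field(default_factory=point_mass_alpha)
    omega_mixing: str = "branch-site"

    def __post_init__(self):
        if self.omega_mixing not in ("branch-site", "site"):
            raise ValueError(f"unknown omega mixing mode {self.omega_mixing!r}")

    def scale(self) -> float:
        return mixture_scale(self.code, self.theta, self.freqs,
                             self.omega_dist, self.alpha_dist)


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods and per-alpha-category conditionals."""

    site_loglik: np.ndarray        # (N,)
    cond_loglik: np.ndarray        # (N, K_alpha) log L_s(alpha_m)
    alpha_dist: AlphaDistribution

    @property
    def total(self) -> float:
        return float(self.site_loglik.sum())


class LikelihoodEngine:
    """Pruning-based likelihood evaluator bound to one alignment and tree.

    Spectral decompositions of the per-omega generators are cached across
    evaluations keyed by the parameters that define them, so optimizer steps
    that move only mixture weights or branch scaling reuse them.
    """

    def __init__(self, aln: CodonAlignment, tree: Phylogeny):
        check_taxa(aln, tree)
        self.aln = aln
        self.tree = tree
        self.code = aln.code
        self.n_sites = aln.n_codons
        self.n_states = self.code.n_states
        self._postorder = tree.postorder()
        self._non_root = [v for v in self._postorder if v != tree.root]
        self._node_index = {v: i for i, v in enumerate(self._non_root)}
        row_of = {name: i for i, name in enumerate(aln.taxa)}
        # Leaf state arrays: codon index per site, with ambiguous cells
        # replaced by 0 and patched via indicator products.
        self._leaf_states: dict[int, np.ndarray] = {}
        self._leaf_amb: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for v in tree.leaves:
            s = row_of[tree.labels[v]]
            states = aln.states[s].copy()
            amb_cols = np.nonzero(states < 0)[0]
            if amb_cols.size:
                ind = np.stack([aln.ambiguities[(s, int(n))] for n in amb_cols],
                               axis=1).astype(float)
                self._leaf_amb[v] = (amb_cols, ind)
                states = np.where(states < 0, 0, states)
            self._leaf_states[v] = states
        self._spectral_cache: dict[bytes, SpectralQ] = {}

    # -- transition matrix assembly ------------------------------------

    def _spectral(self, theta, freqs, omega: float) -> SpectralQ:
        key = (theta.as_array().tobytes() + freqs.pi.tobytes()
               + np.float64(omega).tobytes())
        spect = self._spectral_cache.get(key)
        if spect is None:
            Q = unscaled_q(self.code, theta, freqs, 1.0, omega)
            spect = SpectralQ(Q, freqs.codon_frequencies(self.code))
            if len(self._spectral_cache) > 64:
                self._spectral_cache.clear()
            self._spectral_cache[key] = spect
        return spect

    def _averaged_matrices(self, model: ModelParameters, lengths: np.ndarray,
                           scale: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-class per-branch matrices.

        Returns (A, class_weights, class_alpha_rates):
          A            (M, B, K, K)
          class_weights (M,) mixture weights of the pruning classes
          class_alpha  (M,) alpha rate attached to each class
        """
        om, ad = model.omega_dist, model.alpha_dist
        t_eff = lengths[self._non_root] / scale
        B = len(self._non_root)
        if model.omega_mixing == "branch-site":
            # classes = alpha categories; average P over omega inside each branch
            alphas, fw = ad.rates, ad.weights
            M = len(alphas)
            A = np.zeros((M, B, self.n_states, self.n_states))
            times = np.multiply.outer(alphas, t_eff).ravel()  # (M*B,)
            for k in range(om.K):
                spect = self._spectral(model.theta, model.freqs, om.rates[k])
                P = spect.transition_matrices(times)
                A += om.weights[k] * P.reshape(M, B, self.n_states, self.n_states)
            return A, fw, alphas
        # site mixing: classes = joint (alpha_m, omega_k), pure matrices
        classes = [(a, f, k) for a, f in zip(ad.rates, ad.weights)
                   for k in range(om.K)]
        A = np.zeros((len(classes), B, self.n_states, self.n_states))
        weights = np.empty(len(classes))
        alphas = np.empty(len(classes))
        for c, (a, f, k) in enumerate(classes):
            spect = self._spectral(model.theta, model.freqs, om.rates[k])
            A[c] = spect.transition_matrices(a * t_eff)
            weights[c] = f * om.weights[k]
            alphas[c] = a
        return A, weights, alphas

    # -- pruning --------------------------------------------------------

    def _prune_class(self, A_class: np.ndarray, pi: np.ndarray) -> np.ndarray:
        """Log-likelihood per site for one pruning class.

        ``A_class``: (B, K, K) transition matrix per non-root branch.
        """
        N, K = self.n_sites, self.n_states
        tree = self.tree
        partials: dict[int, np.ndarray] = {}
        log_scale = np.zeros(N)
        for v in self._postorder:
            if not tree.children[v]:
                continue
            L = np.ones((K, N))
            for c in tree.children[v]:
                A = A_class[self._node_index[c]]
                if not tree.children[c]:  # leaf: gather columns
                    M = A[:, self._leaf_states[c]]
                    amb = self._leaf_amb.get(c)
                    if amb is not None:
                        cols, ind = amb
                        M[:, cols] = A @ ind
                else:
                    M = A @ partials.pop(c)
                L *= M
            mx = L.max(axis=0)
            safe = np.maximum(mx, _LOG_ZERO_GUARD)
            L /= safe
            log_scale += np.log(safe)
            partials[v] = L
        site_lik = pi @ partials[tree.root]
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(site_lik, 0.0)) + log_scale

    def site_log_likelihoods(self, model: ModelParameters,
                             lengths: np.ndarray | None = None,
                             scale: float | None = None) -> SiteLikelihoods:
        """Per-site log-likelihoods under the mixture model.

        ``lengths`` overrides the tree's branch lengths (indexed by node);
        ``scale`` overrides the model-level branch-length normalizer.
        """
        if lengths is None:
            lengths = self.tree.edge_length
        if scale is None:
            scale = model.scale()
        pi = model.freqs.codon_frequencies(self.code)
        A, weights, class_alphas = self._averaged_matrices(model, lengths, scale)
        M = A.shape[0]
        cond = np.empty((self.n_sites, M))
        for m in range(M):
            cond[:, m] = self._prune_class(A[m], pi)
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)),
                            -np.inf)
        site_ll = logsumexp(cond + logw[None, :], axis=1)
        if model.omega_mixing == "branch-site":
            alpha_cond = cond
            alpha_dist = model.alpha_dist
        else:
            # collapse joint (alpha, omega) classes back onto alpha categories
            ad = model.alpha_dist
            Kom = model.omega_dist.K
            alpha_cond = np.empty((self.n_sites, ad.K))
            with np.errstate(divide="ignore"):
                logp = np.log(np.maximum(model.omega_dist.weights, 1e-300))
            for m in range(ad.K):
                block = cond[:, m * Kom:(m + 1) * Kom]
                alpha_cond[:, m] = logsumexp(block + logp[None, :], axis=1)
            alpha_dist = ad
        return SiteLikelihoods(site_loglik=site_ll, cond_loglik=alpha_cond,
                               alpha_dist=alpha_dist)

    def log_likelihood(self, model: ModelParameters,
                       lengths: np.ndarray | None = None,
                       scale: float | None = None) -> float:
        return self.site_log_likelihoods(model, lengths, scale).total


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_likelihood(aln: CodonAlignment, tree: Phylogeny,
                           model: ModelParameters,
                           lengths: np.ndarray | None = None,
                           scale: float | None = None,
                           max_branches: int = 6,
                           max_categories: int = 4) -> float:
    """Exhaustive-enumeration likelihood (test oracle; exponential cost).

    Sums over every joint assignment of per-branch omega categories
    (branch-site mixing) or per-site omega categories (site mixing) and
    per-site alpha categories, weighting each by its probability.  Agrees
    with the pruning engine on tiny instances.
    """
    check_taxa(aln, tree)
    code = aln.code
    if lengths is None:
        lengths = tree.edge_length
    if scale is None:
        scale = model.scale()
    non_root = [v for v in tree.postorder() if v != tree.root]
    B = len(non_root)
    om, ad = model.omega_dist, model.alpha_dist
    if B > max_branches or om.K > max_categories or ad.K > max_categories:
        raise ValueError("instance too large for the brute-force oracle")
    pi = model.freqs.codon_frequencies(code)
    row_of = {name: i for i, name in enumerate(aln.taxa)}
    N = aln.n_codons

    spect = {k: SpectralQ(unscaled_q(code, model.theta, model.freqs, 1.0,
                                     om.rates[k]), pi)
             for k in range(om.K)}

    def leaf_indicator(v, site):
        s = row_of[tree.labels[v]]
        st = aln.states[s, site]
        if st >= 0:
            out = np.zeros(len(pi))
            out[st] = 1.0
            return out
        return aln.ambiguities[(s, site)].astype(float)

    def site_lik_given(P_by_node, site):
        def rec(v):
            if not tree.children[v]:
                return leaf_indicator(v, site)
            out = np.ones(len(pi))
            for c in tree.children[v]:
                out = out * (P_by_node[c] @ rec(c))
            return out
        return float(pi @ rec(tree.root))

    from itertools import product as iproduct

    total = np.zeros(N)
    if model.omega_mixing == "branch-site":
        for m in range(ad.K):
            alpha = ad.rates[m]
            P = {(b, k): spect[k].transition_matrices(
                    np.array([alpha * lengths[v] / scale]))[0]
                 for b, v in enumerate(non_root) for k in range(om.K)}
            for assignment in iproduct(range(om.K), repeat=B):
                w = ad.weights[m] * np.prod([om.weights[k] for k in assignment])
                if w == 0:
                    continue
                P_by_node = {v: P[(b, assignment[b])]
                             for b, v in enumerate(non_root)}
                for s in range(N):
                    total[s] += w * site_lik_given(P_by_node, s)
    else:
        for m in range(ad.K):
            alpha = ad.rates[m]
            for k in range(om.K):
                P_by_node = {v: spect[k].transition_matrices(
                                 np.array([alpha * lengths[v] / scale]))[0]
                             for v in non_root}
                w = ad.weights[m] * om.weights[k]
                if w == 0:
                    continue
                for s in range(N):
                    total[s] += w * site_lik_given(P_by_node, s)
    return float(np.sum(np.log(total)))
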