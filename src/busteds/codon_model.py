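"""MG94 x GTR codon rate matrices and transition probabilities.

The instantaneous rate of a one-step change between sense codons i and j
differing at codon position p (nucleotides x -> y) is

    q_ij = alpha * theta_xy * pi^p_y          (synonymous)
    q_ij = alpha * omega * theta_xy * pi^p_y  (nonsynonymous)

and 0 for multi-nucleotide changes.  theta are the five free GTR
exchangeabilities (theta_AG fixed at 1), pi^p the position-specific target
nucleotide frequencies, alpha a synonymous rate multiplier and omega the
dN/dS ratio.  The model is time-reversible with respect to the product-form
codon frequencies, which permits a symmetric eigendecomposition: all
transition matrices P(t) = exp(Qt) here are computed spectrally.

Branch lengths are measured in expected substitutions per codon site under
the fitted mixture, i.e. the generator is divided by the expected total rate
averaged over the joint (alpha, omega) category distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .frequencies import PositionalFrequencies
from .genetic_code import NUC_INDEX, GeneticCode, one_step_pairs
from .rate_distributions import AlphaDistribution, OmegaDistribution

#: Canonical order of unordered nucleotide pairs for the six theta slots.
THETA_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIR_INDEX = {frozenset(p): i for i, p in enumerate(THETA_PAIRS)}


@dataclass(frozen=True)
class NucleotideExchangeabilities:
    """GTR exchangeabilities; theta_AG is the reference, fixed at 1."""

    ac: float = 1.0
    at: float = 1.0
    cg: float = 1.0
    ct: float = 1.0
    gt: float = 1.0

    def __post_init__(self):
        vals = (self.ac, self.at, self.cg, self.ct, self.gt)
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError("exchangeabilities must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        """Six rates in :data:`THETA_PAIRS` order (AG = 1)."""
        return np.array([self.ac, 1.0, self.at, self.cg, self.ct, self.gt])

    @classmethod
    def from_array(cls, arr) -> "NucleotideExchangeabilities":
        ac, ag, at, cg, ct, gt = (float(v) for v in arr)
        if abs(ag - 1.0) > 1e-12:
            raise ValueError("theta_AG is fixed at 1")
        return cls(ac=ac, at=at, cg=cg, ct=ct, gt=gt)

    @classmethod
    def hky85(cls, kappa: float) -> "NucleotideExchangeabilities":
        """HKY85 through the GTR slots: transitions = kappa x transversions.

        With theta_AG fixed at 1, transversion slots become 1/kappa.
        """
        tv = 1.0 / kappa
        return cls(ac=tv, at=tv, cg=tv, ct=1.0, gt=tv)


@lru_cache(maxsize=8)
def _one_step_structure(code: GeneticCode):
    """Sparse structure of one-step sense-codon changes, cached per code."""
    rows, cols, theta_idx, pos, target, syn = [], [], [], [], [], []
    for i, j, sc in one_step_pairs(code):
        rows.append(code.index[i])
        cols.append(code.index[j])
        theta_idx.append(_PAIR_INDEX[sc.pair])
        pos.append(sc.position - 1)
        target.append(NUC_INDEX[j[sc.position - 1]])
        syn.append(sc.kind == "synonymous")
    return (np.array(rows), np.array(cols), np.array(theta_idx),
            np.array(pos), np.array(target), np.array(syn))


def _offdiag_rates(code, theta: NucleotideExchangeabilities,
                   freqs: PositionalFrequencies, alpha: float, omega: float):
    rows, cols, t_idx, pos, target, syn = _one_step_structure(code)
    base = theta.as_array()[t_idx] * freqs.pi[pos, target]
    return rows, cols, alpha * base * np.where(syn, 1.0, omega)


def unscaled_q(code: GeneticCode, theta: NucleotideExchangeabilities,
               freqs: PositionalFrequencies, alpha: float, omega: float
               ) -> np.ndarray:
    if alpha < 0 or omega < 0:
        raise ValueError("alpha and omega must be non-negative")
    K = code.n_states
    Q = np.zeros((K, K))
    rows, cols, rates = _offdiag_rates(code, theta, freqs, alpha, omega)
    Q[rows, cols] = rates
    Q[np.diag_indices(K)] = -Q.sum(axis=1)
    return Q


def expected_rate(code: GeneticCode, theta: NucleotideExchangeabilities,
                  freqs: PositionalFrequencies, alpha: float, omega: float
                  ) -> float:
    """Expected substitutions per codon per unit time, -sum_i pi_i q_ii."""
    pi = freqs.codon_frequencies(code)
    rows, _, rates = _offdiag_rates(code, theta, freqs, alpha, omega)
    return float(np.sum(pi[rows] * rates))


def flux_decomposition(code: GeneticCode, theta: NucleotideExchangeabilities,
                       freqs: PositionalFrequencies) -> tuple[float, float]:
    """(synonymous, nonsynonymous-per-unit-omega) components of the total rate.

    expected_rate(alpha, omega) = alpha * (syn + omega * nonsyn).
    """
    syn = expected_rate(code, theta, freqs, 1.0, 0.0)
    total = expected_rate(code, theta, freqs, 1.0, 1.0)
    return syn, total - syn


def mixture_scale(code: GeneticCode, theta: NucleotideExchangeabilities,
                  freqs: PositionalFrequencies, omega_dist: OmegaDistribution,
                  alpha_dist: AlphaDistribution) -> float:
    """Branch-length normalizer: expected total rate over the joint mixture."""
    syn, nonsyn = flux_decomposition(code, theta, freqs)
    mean_alpha = alpha_dist.mean()
    mean_omega = omega_dist.mean()
    return mean_alpha * (syn + mean_omega * nonsyn)


@dataclass(frozen=True)
class CodonGenerator:
    """A scaled generator Q/scale with its stationary distribution."""

    Q: np.ndarray
    pi: np.ndarray
    scale: float


def build_generator(code: GeneticCode, theta: NucleotideExchangeabilities,
                    freqs: PositionalFrequencies, alpha: float, omega: float,
                    scale: float | None = None) -> CodonGenerator:
    """Build the scaled MG94 x GTR generator for one (alpha, omega) pair.

    ``scale`` defaults to this matrix's own expected rate so that, absent a
    mixture, branch lengths are expected substitutions per codon site; mixture
    models pass the :func:`mixture_scale` of their category distributions.
    """
    Q = unscaled_q(code, theta, freqs, alpha, omega)
    if scale is None:
        scale = expected_rate(code, theta, freqs, alpha, omega)
    if scale <= 0 or not np.isfinite(scale):
        raise ValueError(f"invalid scaling constant {scale}")
    return CodonGenerator(Q=Q / scale, pi=freqs.codon_frequencies(code),
                          scale=float(scale))


class SpectralQ:
    """Eigendecomposition of a reversible generator for fast P(t) evaluation.

    For reversible Q, S = D^(1/2) Q D^(-1/2) is symmetric (D = diag(pi)), so
    Q = V diag(lam) W with V = D^(-1/2) U, W = U^T D^(1/2) and real lam.
    Then P(t) = (V * exp(lam t)) W, evaluated for many t at once.
    """

    _PI_FLOOR = 1e-12

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        if not np.all(np.isfinite(Q)):
            raise ValueError("non-finite generator")
        pi = np.maximum(np.asarray(pi, dtype=float), self._PI_FLOOR)
        pi = pi / pi.sum()
        sq = np.sqrt(pi)
        S = Q * (sq[:, None] / sq[None, :])
        S = 0.5 * (S + S.T)
        lam, U = np.linalg.eigh(S)
        self.lam = lam
        self.V = U / sq[:, None]
        self.W = U.T * sq[None, :]
        self.pi = pi

    def transition_matrices(self, times: np.ndarray) -> np.ndarray:
        """Stack of P(t) for each t in ``times``; rows sum to 1, entries >= 0."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(t < 0):
            raise ValueError("branch lengths must be non-negative")
        E = np.exp(np.multiply.outer(t, self.lam))  # (B, K)
        P = np.matmul(self.V[None, :, :] * E[:, None, :], self.W)
        np.clip(P, 0.0, None, out=P)
        return P


def transition_matrix(gen: CodonGenerator, t: float) -> np.ndarray:
    """P(t) = exp(Q t) for a scaled generator, computed spectrally."""
    P = SpectralQ(gen.Q, gen.pi).transition_matrices(np.array([t]))[0]
    rows = P.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-8):
        raise ArithmeticError("transition matrix rows failed to normalize")
    return P / rows[:, None]
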