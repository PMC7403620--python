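"""Position-specific nucleotide frequencies and CF3x4 codon frequencies.

The MG94-style model uses position-specific nucleotide frequencies pi^p_j
(p = codon position 1-3, j = A,C,G,T; nine free parameters) and equilibrium
codon frequencies proportional to the product pi^1 * pi^2 * pi^3 over sense
codons.  The naive F3x4 plug-in (use observed position frequencies directly)
is biased because stop codons are excluded from the state space; the CF3x4
corrected estimator instead solves for the positional parameters whose
*implied* stop-excluded positional marginals match the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .genetic_code import NUC_INDEX, GeneticCode, get_code
from .seq_io import CodonAlignment


@dataclass(frozen=True)
class PositionalFrequencies:
    """pi[p, j]: nucleotide frequencies per codon position, rows on the simplex."""

    pi: np.ndarray  # (3, 4)

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (3, 4):
            raise ValueError("positional frequencies must be a 3x4 table")
        if np.any(pi < -1e-12) or np.any(np.abs(pi.sum(axis=1) - 1) > 1e-8):
            raise ValueError("each positional row must lie on the simplex")

    def codon_frequencies(self, code: GeneticCode | None = None) -> np.ndarray:
        """Equilibrium frequencies of sense codons (renormalized product form)."""
        code = code or get_code()
        freqs = np.array([
            self.pi[0, NUC_INDEX[c[0]]]
            * self.pi[1, NUC_INDEX[c[1]]]
            * self.pi[2, NUC_INDEX[c[2]]]
            for c in code.sense_codons
        ])
        total = freqs.sum()
        if total <= 0:
            raise ValueError("degenerate positional frequencies: zero total mass")
        return freqs / total


def implied_marginals(pf: PositionalFrequencies,
                      code: GeneticCode | None = None) -> np.ndarray:
    """Observable 3x4 positional marginals of the stop-excluded codon distribution."""
    code = code or get_code()
    cf = pf.codon_frequencies(code)
    out = np.zeros((3, 4))
    for idx, codon in enumerate(code.sense_codons):
        for p in range(3):
            out[p, NUC_INDEX[codon[p]]] += cf[idx]
    return out


def count_positional_frequencies(aln: CodonAlignment) -> np.ndarray:
    """Observed 3x4 nucleotide frequency table over unambiguous alignment cells."""
    counts = np.zeros((3, 4))
    states = aln.states
    unamb = states[states >= 0]
    if unamb.size == 0:
        raise ValueError("alignment has no unambiguous codons to count")
    for st in unamb:
        codon = aln.code.sense_codons[st]
        for p in range(3):
            counts[p, NUC_INDEX[codon[p]]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def estimate_f3x4(observed: np.ndarray) -> PositionalFrequencies:
    """Uncorrected F3x4: use the observed table as the positional parameters."""
    obs = np.asarray(observed, dtype=float)
    return PositionalFrequencies(pi=obs / obs.sum(axis=1, keepdims=True))


_ZERO_FLOOR = 1e-8


def estimate_cf3x4(observed: np.ndarray, code: GeneticCode | None = None,
                   tol: float = 1e-10, max_restarts: int = 4
                   ) -> PositionalFrequencies:
    """Corrected F3x4: positional parameters whose implied stop-excluded
    marginals reproduce the observed table.

    Solved as a least-squares match over the product of three simplices
    (softmax parameterization), multistarted from the observed table.
    Observed zeros are floored at 1e-8 before solving to keep the problem
    interior; the solution is reported as estimated.
    """
    code = code or get_code()
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (3, 4) or np.any(obs < -1e-12):
        raise ValueError("observed table must be non-negative and 3x4")
    obs = np.maximum(obs, _ZERO_FLOOR)
    obs = obs / obs.sum(axis=1, keepdims=True)

    def unpack(x):
        z = x.reshape(3, 4)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return PositionalFrequencies(pi=e / e.sum(axis=1, keepdims=True))

    def residuals(x):
        return (implied_marginals(unpack(x), code) - obs).ravel()

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts):
        x0 = np.log(obs).ravel()
        if attempt > 0:
            x0 = x0 + rng.normal(scale=0.2 * attempt, size=x0.shape)
        sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < tol:
            break
    if best.cost >= 1e-6:
        raise RuntimeError(
            f"CF3x4 failed to match observed marginals (residual cost "
            f"{best.cost:.3e} after {max_restarts} starts)"
        )
    return unpack(best.x)
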