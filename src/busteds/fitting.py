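"""Maximum-likelihood fitting of the BUSTED family and MG94 M1a/M2a models.

Optimization is staged to keep the number of expensive mixture-likelihood
evaluations small:

1. a single-omega MG94 fit estimates the GTR exchangeabilities, a global
   tree-scale factor, and a gene-wide omega;
2. the no-SRV branch-site mixture (BUSTED) starts from those values and
   optimizes the omega GDD and the scale;
3. the SRV model (BUSTED[S]) starts from the BUSTED solution and adds the
   four alpha hyperparameters;
4. constrained (omega3 = 1) fits start from the corresponding unconstrained
   maximum with the selected class clamped, which keeps the likelihood-ratio
   statistic non-negative up to optimizer tolerance.

Exchangeabilities and position-specific frequencies are estimated once (in
stage 1 and by CF3x4 counting, respectively) and held fixed in the mixture
stages; branch lengths are, by default, re-optimized per model through a
single multiplicative tree-scale factor applied to the input branch lengths
(set ``branch_mode="full"`` to free every branch length instead).

All optimizer stages run in unconstrained transformed coordinates
(log/logit/stick-breaking) with L-BFGS-B and finite-difference gradients.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .codon_model import NucleotideExchangeabilities
from .frequencies import (PositionalFrequencies, count_positional_frequencies,
                          estimate_cf3x4)
from .likelihood import LikelihoodEngine, ModelParameters
from .rate_distributions import (AlphaDistribution, OmegaDistribution,
                                 alpha_from_vector, alpha_to_vector,
                                 check_degenerate,
                                 constrained_omega_from_vector,
                                 constrained_omega_to_vector,
                                 logits_to_weights, omega_from_vector,
                                 omega_to_vector, point_mass_alpha,
                                 weights_to_logits, _logit, _sigmoid)
from .seq_io import CodonAlignment, Phylogeny

log = logging.getLogger(__name__)

MODEL_NAMES = ("MG94", "BUSTED", "BUSTED-constrained", "BUSTED[S]",
               "BUSTED[S]-constrained", "M1a", "M2a")


@dataclass(frozen=True)
class FitConfig:
    """Options controlling the optimization pipeline."""

    k_omega: int = 3
    k_alpha: int = 3
    n_restarts: int = 0          # random restarts of the final stage
    branch_mode: str = "scale"   # "scale" (tree-scale factor) or "full"
    seed: int = 0
    ftol: float = 1e-9           # relative L-BFGS-B tolerance
    fd_step: float = 1e-6        # finite-difference step in transformed coords
    maxfun_stage: int = 300      # evaluation cap for the MG94 stage
    maxfun_mixture: int = 400    # evaluation cap per mixture stage
    genetic_code: str = "universal"


@dataclass
class ModelFit:
    """A fitted model: MLEs, likelihood, information criteria, per-site terms."""

    model_name: str
    theta: NucleotideExchangeabilities
    freqs: PositionalFrequencies
    omega_dist: OmegaDistribution
    alpha_dist: AlphaDistribution
    omega_mixing: str
    tree_scale: float
    branch_lengths: np.ndarray
    log_likelihood: float
    k: int
    n_obs: int
    aicc: float
    site_loglik: np.ndarray
    cond_loglik: np.ndarray
    converged: bool
    n_evals: int
    data_fingerprint: str
    config: FitConfig

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "log_likelihood": self.log_likelihood,
            "k": self.k,
            "n": self.n_obs,
            "AICc": self.aicc,
            "theta": dict(zip(("AC", "AT", "CG", "CT", "GT"),
                              (self.theta.ac, self.theta.at, self.theta.cg,
                               self.theta.ct, self.theta.gt))),
            "positional_frequencies": self.freqs.pi.tolist(),
            "omega_distribution": self.omega_dist.to_pairs(),
            "alpha_distribution": self.alpha_dist.to_pairs(),
            "omega_mixing": self.omega_mixing,
            "tree_scale": self.tree_scale,
            "converged": self.converged,
            "n_evals": self.n_evals,
            "branch_length_units":
                "expected substitutions per codon site under the full mixture",
        }


def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def data_fingerprint(aln: CodonAlignment, tree: Phylogeny) -> str:
    h = hashlib.sha1()
    h.update(aln.states.tobytes())
    h.update("|".join(aln.taxa).encode())
    h.update(tree.to_newick().encode())
    return h.hexdigest()[:16]


def compare_models(fitA: ModelFit, fitB: ModelFit) -> dict:
    """AICc comparison record for two fits of the same data."""
    if fitA.data_fingerprint != fitB.data_fingerprint:
        raise ValueError("fits were produced from different data")
    delta = fitA.aicc - fitB.aicc
    from .rate_distributions import coefficient_of_variation as cv
    return {
        "models": [fitA.model_name, fitB.model_name],
        "AICc": [fitA.aicc, fitB.aicc],
        "delta_AICc": delta,
        "preferred": fitB.model_name if delta > 0 else fitA.model_name,
        "cv_omega": [cv(fitA.omega_dist), cv(fitB.omega_dist)],
        "cv_alpha": [cv(fitA.alpha_dist), cv(fitB.alpha_dist)],
        "log_likelihood": [fitA.log_likelihood, fitB.log_likelihood],
    }


# ---------------------------------------------------------------------------
# Session: shared staged fitting over one data set
# ---------------------------------------------------------------------------

class FitSession:
    """Caches shared stages (frequencies, engine, MG94, warm starts) so that
    fitting several related models to one data set avoids repeated work."""

    def __init__(self, aln: CodonAlignment, tree: Phylogeny,
                 config: FitConfig | None = None):
        self.aln = aln
        self.tree = tree
        self.config = config or FitConfig()
        self.engine = LikelihoodEngine(aln, tree)
        observed = count_positional_frequencies(aln)
        self.freqs = estimate_cf3x4(observed, aln.code)
        self.fingerprint = data_fingerprint(aln, tree)
        self.n_obs = aln.n_sequences * aln.n_codons
        self._fits: dict[str, ModelFit] = {}
        self._rng = np.random.default_rng(self.config.seed)
        if len({aln.states[:, j].tobytes() for j in range(aln.n_codons)}) <= 1:
            warnings.warn("alignment has a single unique site pattern; "
                          "estimates will be poorly determined")
        # base (relative) branch lengths; zero-length trees get a nominal scale
        base = tree.edge_length.copy()
        if base.sum() <= 0:
            base[:] = 0.01
        self._base_lengths = base

    # -- generic optimization machinery --------------------------------

    def _lengths_scale(self, x_bl: np.ndarray) -> np.ndarray:
        if self.config.branch_mode == "full":
            lengths = np.zeros(self.tree.n_nodes)
            lengths[self.engine._non_root] = np.exp(x_bl)
            return lengths
        return self._base_lengths * np.exp(x_bl[0])

    def _bl_start(self) -> np.ndarray:
        if self.config.branch_mode == "full":
            return np.log(np.maximum(
                self._base_lengths[self.engine._non_root], 1e-6))
        return np.zeros(1)

    def _n_bl(self) -> int:
        return (len(self.engine._non_root)
                if self.config.branch_mode == "full" else 1)

    def _optimize(self, objective, x0: np.ndarray, maxfun: int):
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxfun": maxfun, "ftol": self.config.ftol,
                                "eps": self.config.fd_step, "maxcor": 12})
        return res

    def _run_starts(self, objective, starts, maxfun):
        best = None
        evals = 0
        for x0 in starts:
            res = self._optimize(objective, x0, maxfun)
            evals += res.nfev
            if best is None or res.fun < best.fun:
                best = res
        return best, evals

    def _restart_points(self, x_opt: np.ndarray):
        for _ in range(self.config.n_restarts):
            yield x_opt + self._rng.normal(scale=0.4, size=x_opt.shape)

    # -- model definitions ----------------------------------------------

    def _make_objective(self, unpack):
        engine, freqs = self.engine, self.freqs
        code = self.aln.code
        nbl = self._n_bl()

        def objective(x):
            try:
                theta, om, ad, mixing = unpack(x[nbl:])
                model = ModelParameters(code=code, theta=theta, freqs=freqs,
                                        omega_dist=om, alpha_dist=ad,
                                        omega_mixing=mixing)
                lengths = self._lengths_scale(x[:nbl])
                ll = engine.log_likelihood(model, lengths=lengths)
                if not np.isfinite(ll):
                    return 1e10
                return -ll
            except (ValueError, FloatingPointError, np.linalg.LinAlgError):
                return 1e10
        return objective

    def _finalize(self, name, x, unpack, k_extra, res, evals) -> ModelFit:
        nbl = self._n_bl()
        theta, om, ad, mixing = unpack(x[nbl:])
        lengths = self._lengths_scale(x[:nbl])
        model = ModelParameters(code=self.aln.code, theta=theta,
                                freqs=self.freqs, omega_dist=om,
                                alpha_dist=ad, omega_mixing=mixing)
        sl = self.engine.site_log_likelihoods(model, lengths=lengths)
        k = 5 + 9 + self._n_bl() + k_extra
        fit = ModelFit(
            model_name=name, theta=theta, freqs=self.freqs, omega_dist=om,
            alpha_dist=ad, omega_mixing=mixing,
            tree_scale=(float(np.exp(x[0]))
                        if self.config.branch_mode == "scale" else float("nan")),
            branch_lengths=lengths, log_likelihood=sl.total, k=k,
            n_obs=self.n_obs, aicc=aicc(sl.total, k, self.n_obs),
            site_loglik=sl.site_loglik, cond_loglik=sl.cond_loglik,
            converged=bool(res.status == 0), n_evals=evals,
            data_fingerprint=self.fingerprint, config=self.config)
        if name not in ("MG94",):
            check_degenerate(om)
            if ad.K > 1:
                check_degenerate(ad)
        return fit

    # .. MG94 single-omega ...........................................

    def _fit_mg94(self) -> ModelFit:
        def unpack(z):
            theta = NucleotideExchangeabilities(*np.exp(z[:5]))
            om = OmegaDistribution(rates=[np.exp(z[5])], weights=[1.0])
            return theta, om, point_mass_alpha(), "branch-site"

        objective = self._make_objective(unpack)
        x0 = np.concatenate([self._bl_start(), np.zeros(5), [np.log(0.5)]])
        res, evals = self._run_starts(objective, [x0], self.config.maxfun_stage)
        return self._finalize("MG94", res.x, unpack, 1, res, evals)

    # .. BUSTED family ................................................

    def _omega_unpack(self, constrained: bool):
        K = self.config.k_omega
        if constrained:
            return (lambda z: constrained_omega_from_vector(z, K)), 2 * K - 2
        return (lambda z: omega_from_vector(z, K)), 2 * K - 1

    def _fit_busted_family(self, name: str, srv: bool, constrained: bool
                           ) -> ModelFit:
        mg94 = self.fit("MG94")
        theta = mg94.theta
        omega_unpack, n_om = self._omega_unpack(constrained)
        K = self.config.k_omega

        if srv:
            def unpack(z):
                om = omega_unpack(z[:n_om])
                ad = alpha_from_vector(z[n_om:n_om + 4])
                return theta, om, ad, "branch-site"
        else:
            def unpack(z):
                om = omega_unpack(z[:n_om])
                return theta, om, point_mass_alpha(), "branch-site"

        # warm starts
        starts = []
        bl0 = (np.log(np.maximum(mg94.branch_lengths[self.engine._non_root],
                                 1e-8))
               if self.config.branch_mode == "full"
               else np.array([np.log(mg94.tree_scale)]))

        def omega_start_default():
            mid = np.clip(mg94.omega_dist.rates[0], 0.05, 0.95)
            rates = np.linspace(0.1, min(mid, 0.5), max(K - 1, 1)).tolist()
            rates += [1.0 if constrained else 2.0]
            w = np.array([0.7] + [0.25 / max(K - 2, 1)] * (K - 2) + [0.05])
            dist = OmegaDistribution(rates=np.sort(rates), weights=w / w.sum())
            return (constrained_omega_to_vector(dist) if constrained
                    else omega_to_vector(dist))

        def alpha_start_default():
            return alpha_to_vector(
                AlphaDistribution.from_raw([0.6, 1.0, 1.8], [0.25, 0.5, 0.25]))

        warm = None
        if constrained:
            parent = self.fit("BUSTED[S]" if srv else "BUSTED")
            om_w = OmegaDistribution(
                rates=np.concatenate([parent.omega_dist.rates[:-1], [1.0]]),
                weights=parent.omega_dist.weights)
            z = [constrained_omega_to_vector(om_w)]
            if srv:
                z.append(alpha_to_vector(parent.alpha_dist))
            warm_bl = (np.log(np.maximum(
                parent.branch_lengths[self.engine._non_root], 1e-8))
                if self.config.branch_mode == "full"
                else np.array([np.log(parent.tree_scale)]))
            warm = np.concatenate([warm_bl] + z)
        elif srv:
            parent = self.fit("BUSTED")
            z = [omega_to_vector(parent.omega_dist), alpha_start_default()]
            warm_bl = (np.log(np.maximum(
                parent.branch_lengths[self.engine._non_root], 1e-8))
                if self.config.branch_mode == "full"
                else np.array([np.log(parent.tree_scale)]))
            warm = np.concatenate([warm_bl] + z)

        # a reliable warm start (from the nested/parent model's optimum)
        # replaces the default start entirely; cold fits use the default
        default = np.concatenate(
            [bl0, omega_start_default()]
            + ([alpha_start_default()] if srv else []))
        starts = [warm] if warm is not None else [default]

        objective = self._make_objective(unpack)
        res, evals = self._run_starts(objective, starts,
                                      self.config.maxfun_mixture)
        for x0 in self._restart_points(res.x):
            r2 = self._optimize(objective, x0, self.config.maxfun_mixture)
            evals += r2.nfev
            if r2.fun < res.fun:
                res = r2

        k_extra = n_om + (4 if srv else 0)
        fit = self._finalize(name, res.x, unpack, k_extra, res, evals)

        # nesting safeguards: an enriched model must fit at least as well as
        # the model its start came from
        if srv and not constrained:
            busted = self.fit("BUSTED")
            if fit.log_likelihood < busted.log_likelihood - 1e-6:
                near_pm = alpha_to_vector(AlphaDistribution.from_raw(
                    [0.999, 1.0, 1.001], [0.1, 0.8, 0.1]))
                x0 = np.concatenate([res.x[:self._n_bl() + n_om], near_pm])
                r2 = self._optimize(objective, x0, self.config.maxfun_mixture)
                evals += r2.nfev
                if r2.fun < res.fun:
                    fit = self._finalize(name, r2.x, unpack, k_extra, r2, evals)
        return fit

    # .. M1a / M2a sites models .......................................

    def _fit_sites_model(self, name: str) -> ModelFit:
        mg94 = self.fit("MG94")
        theta = mg94.theta
        two_class = name == "M1a"

        if two_class:
            def unpack(z):
                w0 = _sigmoid(z[0])
                p0 = _sigmoid(z[1])
                om = OmegaDistribution(rates=[w0, 1.0], weights=[p0, 1 - p0])
                return theta, om, point_mass_alpha(), "site"
            k_extra = 2
        else:
            def unpack(z):
                w0 = _sigmoid(z[0])
                w2 = 1.0 + np.exp(z[1])
                w = logits_to_weights(z[2:4])
                om = OmegaDistribution(rates=[w0, 1.0, w2], weights=w)
                return theta, om, point_mass_alpha(), "site"
            k_extra = 4

        bl0 = (np.log(np.maximum(mg94.branch_lengths[self.engine._non_root],
                                 1e-8))
               if self.config.branch_mode == "full"
               else np.array([np.log(mg94.tree_scale)]))
        if two_class:
            w0 = np.clip(mg94.omega_dist.rates[0], 0.02, 0.9)
            x0 = np.concatenate([bl0, [_logit(w0), _logit(0.7)]])
            starts = [x0]
        else:
            m1a = self.fit("M1a")
            w0 = m1a.omega_dist.rates[0]
            p0 = m1a.omega_dist.weights[0]
            wts = np.array([p0 * 0.95, (1 - p0) * 0.95, 0.05])
            x0 = np.concatenate([
                (np.log(np.maximum(
                    m1a.branch_lengths[self.engine._non_root], 1e-8))
                 if self.config.branch_mode == "full"
                 else np.array([np.log(m1a.tree_scale)])),
                [_logit(np.clip(w0, 1e-6, 1 - 1e-6)), np.log(2.0 - 1.0)],
                weights_to_logits(wts)])
            starts = [x0]

        objective = self._make_objective(unpack)
        res, evals = self._run_starts(objective, starts,
                                      self.config.maxfun_mixture)
        for x0 in self._restart_points(res.x):
            r2 = self._optimize(objective, x0, self.config.maxfun_mixture)
            evals += r2.nfev
            if r2.fun < res.fun:
                res = r2
        fit = self._finalize(name, res.x, unpack, k_extra, res, evals)
        if not two_class:
            m1a = self.fit("M1a")
            if fit.log_likelihood < m1a.log_likelihood - 1e-6:
                # restart from the M1a solution with an (almost) empty w2
                # class, where the M2a likelihood equals the M1a one
                w0 = np.clip(m1a.omega_dist.rates[0], 1e-6, 1 - 1e-6)
                p0 = m1a.omega_dist.weights[0]
                eps = 1e-7
                x_fb = np.concatenate([
                    starts[0][:self._n_bl()],
                    [_logit(w0), np.log(1.0)],
                    weights_to_logits(np.array([p0 * (1 - eps),
                                                (1 - p0) * (1 - eps), eps]))])
                r2 = self._optimize(objective, x_fb,
                                    self.config.maxfun_mixture)
                evals += r2.nfev
                if r2.fun < res.fun:
                    fit = self._finalize(name, r2.x, unpack, k_extra, r2, evals)
        return fit

    # -- public API ------------------------------------------------------

    def fit(self, model_name: str) -> ModelFit:
        """Fit (or return the cached fit of) one named model."""
        canon = {n.lower(): n for n in MODEL_NAMES}
        canon.update({"busted-s": "BUSTED[S]", "busted[s]": "BUSTED[S]",
                      "busted-s-constrained": "BUSTED[S]-constrained",
                      "busted[s]-constrained": "BUSTED[S]-constrained"})
        name = canon.get(model_name.lower())
        if name is None:
            raise ValueError(f"unknown model {model_name!r}; "
                             f"choose from {MODEL_NAMES}")
        if name in self._fits:
            return self._fits[name]
        log.info("fitting %s (%s sites x %s sequences)", name,
                 self.aln.n_codons, self.aln.n_sequences)
        if name == "MG94":
            fit = self._fit_mg94()
        elif name == "BUSTED":
            fit = self._fit_busted_family(name, srv=False, constrained=False)
        elif name == "BUSTED-constrained":
            fit = self._fit_busted_family(name, srv=False, constrained=True)
        elif name == "BUSTED[S]":
            fit = self._fit_busted_family(name, srv=True, constrained=False)
        elif name == "BUSTED[S]-constrained":
            fit = self._fit_busted_family(name, srv=True, constrained=True)
        elif name in ("M1a", "M2a"):
            fit = self._fit_sites_model(name)
        self._fits[name] = fit
        log.info("%s: logL=%.4f AICc=%.2f (%d evals)", name,
                 fit.log_likelihood, fit.aicc, fit.n_evals)
        return fit


def fit_model(aln: CodonAlignment, tree: Phylogeny, model: str,
              config: FitConfig | None = None) -> ModelFit:
    """One-shot convenience wrapper around :class:`FitSession`."""
    return FitSession(aln, tree, config).fit(model)
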