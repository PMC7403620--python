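# Methods

## The model

`busteds` implements gene-wide tests of episodic diversifying selection in
protein-coding genes, built on an MG94 x GTR codon substitution process.
For sense codons *i* and *j* differing at exactly one nucleotide position
*p* (nucleotides *x* → *y*), the instantaneous rate is

    q_ij = alpha_s        * theta_xy * pi^p_y   (synonymous change)
    q_ij = alpha_s * w^bs * theta_xy * pi^p_y   (nonsynonymous change)

and `q_ij = 0` when two or three positions differ.  The components are:

* `theta_xy` — symmetric GTR nucleotide exchangeabilities, five free
  parameters with `theta_AG = 1` as the reference;
* `pi^p_y` — position-specific equilibrium frequencies of the target
  nucleotide, nine free parameters estimated by the CF3x4 procedure (below);
* `w^bs` (dN/dS) — drawn independently for every branch-site combination
  from a 3-bin general discrete distribution (GDD) constrained
  `0 <= w1 <= w2 <= 1 <= w3`, five free hyperparameters.  The `w3` class is
  the (potentially) positively selected class;
* `alpha_s` — a site-specific synonymous rate multiplier shared by all
  branches at a site, drawn from a separate 3-bin GDD with mean constrained
  to 1 for identifiability (four free hyperparameters: shapes
  `0 <= a1 <= 1 <= a3` and two weights; realized rates are `c*a1, c, c*a3`
  with `c` restoring unit mean).

The model with free `alpha_s` is BUSTED[S]; collapsing the alpha
distribution to a point mass at 1 gives BUSTED (no synonymous rate
variation, SRV).  Both category counts are user-adjustable (`K_omega`,
`K_alpha`, default 3).  A sites-model pair, M1a (`w0 < 1`, `w1 = 1`) versus
M2a (adds `w2 >= 1`), is provided on the same MG94 substitution core with
site-level (branch-shared) omega draws.

### Likelihood

Because `w^bs` is independent across branch-site combinations, the inner
mixture is exact per branch: site *s* in alpha category *m* uses the
category-averaged transition matrix `A_bm = sum_k p_k P(t_b; alpha_m, w_k)`
on each branch *b*, accumulated by Felsenstein pruning with per-node
rescaling; the outer mixture sums over alpha categories, which are shared
across branches within a site.  All transition matrices come from one
symmetric eigendecomposition per omega category via the identity
`P(t; alpha, w) = P(alpha*t; 1, w)` (the chain is reversible with respect
to the CF3x4 product-form codon frequencies).  An exhaustive-enumeration
oracle (sum over all joint per-branch omega and per-site alpha assignments)
validates the pruning engine on small instances to 1e-8.

### Frequencies

Position-specific nucleotide frequencies are estimated by CF3x4: the nine
positional parameters are solved (penalty-free least squares over the
product of three simplices, softmax-parameterized, multistarted, tolerance
1e-10) so that the positional marginals of the *stop-codon-excluded* codon
distribution reproduce the observed position-specific frequencies.
Observed zeros are floored at 1e-8 before solving.  An uncorrected F3x4
fallback is available.

### The selection test

The test statistic is `LRT = 2(logL_unconstrained - logL_constrained)`,
where the constrained model pins `w3 = 1`.  Since the null places `w3` on
the boundary of its space, p-values use the 50:50 mixture of chi2(0) and
chi2(2): `p = 0.5 * exp(-LRT/2)`, which equals 0.5 exactly at `LRT = 0`.
Negative statistics from optimizer noise are clipped to 0.  M1a-M2a
verdicts use the plain chi2(2) convention customary for that test (the
mixture value is reported alongside).  No multiple-testing correction is
applied; verdicts are raw `P <= 0.05` unless the level is changed.

Per-site evidence ratios `ER_s = L_s(unconstrained)/L_s(constrained)` are
plug-in ratios at each model's own MLEs (no per-site re-optimization);
`ER >= 5` flags a site as supporting selection, `ER <= 1` as not.  The
posterior mean site-specific synonymous rate is
`alpha_hat_s = sum_m alpha_m f_m L_s(alpha_m) / sum_m f_m L_s(alpha_m)`.

## Optimization

Fitting is staged to keep the number of mixture-likelihood evaluations
small, with every stage warm-starting the next:

1. **MG94 single-omega** — estimates the five exchangeabilities, a global
   tree-scale factor, and one gene-wide omega (L-BFGS-B in log coordinates).
2. **BUSTED** — fixes theta from stage 1; optimizes the omega GDD
   (rates via chained sigmoids below the anchor at 1, `w3 = 1 + exp(x)`
   capped at 1e4, stick-breaking weights) plus the tree scale.
3. **BUSTED[S]** — starts from the BUSTED optimum and adds the four alpha
   hyperparameters (start: mild SRV, a1 = 0.6, a3 = 1.8).  If the optimum
   falls below the BUSTED likelihood (the models are nested at the alpha
   point mass) the fit is retried from a near-point-mass start and the
   better solution kept.
4. **Constrained fits** start from the corresponding unconstrained optimum
   with the selected class clamped to 1, which keeps `LRT >= 0` up to
   tolerance.  M2a analogously falls back to the M1a solution with an
   emptied `w2` class if needed.

Numerical choices: finite-difference step 1e-6 in the transformed
coordinates (the likelihood is smooth and |logL| ~ 1e4, so smaller steps
drown the gradient in round-off); relative function tolerance 1e-9;
evaluation caps of 300 (stage 1) and 400 (mixture stages) per start; random
restarts are off by default (`FitConfig.n_restarts`) — on the simulated
regimes used here they reproduce the same optima while multiplying cost.
Degenerate mixtures (near-equal rates, near-zero weights) trigger an
overfitting warning rather than an error.

**Branch lengths.**  Input branch lengths are treated as relative; each
model re-optimizes a single multiplicative tree-scale factor
(`FitConfig(branch_mode="full")` frees every branch length instead, at
substantially higher cost).  Branch lengths are expressed in expected
substitutions per codon site under the full joint (alpha, omega) mixture:
the generator is divided by `E[alpha] * (r_syn + E[omega] * r_ns)`, where
`r_syn` and `r_ns` are the synonymous and per-unit-omega nonsynonymous
components of the expected rate.  The simulator uses the identical
convention, making simulate-then-fit parameter recovery well-posed.

**AICc.**  `AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)` with `n = S x N`
(sequences x codons).  Parameter counts include theta (5), frequencies (9),
branch-length parameters (1 in scale mode), and the distribution
hyperparameters (omega: 5 unconstrained / 4 constrained; alpha: +4), so
BUSTED[S] always carries 4 more parameters than BUSTED.

## The simulator and what it does (not) emulate

`simulate_alignment` draws root codons from the equilibrium distribution,
one alpha category per site, and an independent omega category per
branch-site combination, then samples each child codon from the exact
transition matrix (no Gillespie path needed for sampling; an event-logging
Gillespie mode exists for flux cross-checks).  Defaults mirror the null
simulation design of the false-positive-rate experiments: equal base
frequencies and HKY85 with kappa = 2 expressed through the GTR slots.

Model trees are balanced (binary root for even taxon counts; trifurcating,
unrooted-style root for odd, so a 31-taxon tree has 2n-3 = 59 branches)
with equal branch lengths scaled to a total tree length of 4.0 expected
substitutions/codon for 16 taxa and 6.0 for 31 — typical of curated
vertebrate gene alignments.  A seeded random-join ("yule") shape is also
available.

The omega design for the study grid is `0.1 / 1.0 / w3` with weights
`(0.67, 0.30, 0.03)`: 3% of branch-site combinations in the selected class
(`w3 = 1` gives the null).  The CV(alpha) sweep fixes the alpha weights at
`0.25/0.60/0.15` and solves one shape parameter for the target CV: `a3`
with `a1 = 0.2` for CV above ~0.43, otherwise `a1` with `a3 = 1` (the CV of
the alpha GDD is invariant to the unit-mean rescaling, so the 1-D solve is
exact).  CV = 0 is the point mass.

What the simulator does *not* emulate: indels and alignment error,
compositional (base-frequency) heterogeneity across sites or lineages,
recombination, and selection on synonymous codon usage itself — SRV enters
only through the alpha multiplier.  Passing tests therefore demonstrate the
statistical behavior of the tests *under the model family*, including
misspecification of the alpha distribution (fitting a no-SRV model to SRV
data), but not robustness to these unmodeled real-data features.

## Study scale

The simulation-study driver defaults to a reduced scale — 20 replicates per
grid cell (the `--full-scale` flag restores 100) — and the packaged
experiments use 20 null replicates for Type I error, 10 for power, and 5
for the long-sequence (5,000 codon) condition.  These sizes give one-sided
binomial bounds sharp enough for the qualitative claims being checked
(e.g., 3/20 rejections is the 95% acceptance bound for a true rate of
0.05) while keeping a full run on a single CPU in minutes.

## Known limitations and design notes

* The parameter-recovery harness simulates with the middle omega category
  in the interior (0.7) rather than at its boundary (1.0): when the truth
  sits exactly on the `w2 <= 1` constraint, the fitted `w2` lands below 1
  and the selected class absorbs neutral branch-site mass, so `w3`/`p3`
  are intrinsically confounded there even at 5,000 codons.  This is a
  property of the model's geometry, not of the optimizer.
* Exchangeabilities are not re-refined jointly with the mixture
  hyperparameters; on simulated data the staged estimates are within
  sampling error of the truth, and the LRT compares models sharing the
  same theta, so the test is internally consistent.
* Foreground/background branch partitions (testing a subset of branches)
  are not implemented; all tests are gene-wide over all branches.
* Site-level inference is limited to plug-in evidence ratios; a dedicated
  site-level test is out of scope.
* The mitochondrial (vertebrate) genetic code is available via
  `--code vertebrate-mito`; choosing the correct code for organellar genes
  is the user's responsibility.
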