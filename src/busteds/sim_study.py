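"""False-positive-rate and power experiments over a grid of conditions.

Each grid cell crosses a level of synonymous rate variation (target CV of
the alpha distribution), a selection intensity omega3 (1 = null), a sequence
length and a taxon count; every cell simulates seeded replicate alignments
and applies the requested selection tests.  The defaults run a reduced-scale
version of the full design (fewer replicates per cell), flagged in the
output metadata.

The CV sweep realizes target CVs with a fixed-weight three-bin alpha
distribution (f = 0.25/0.60/0.15): for moderate-to-high CV the fast rate a3
is solved for with a1 pinned at 0.2; for low CV (below what a1 = 0.2 can
reach) a3 is pinned at 1 and the slow rate a1 is solved for instead.  The
CV of the alpha GDD is invariant to the unit-mean rescaling, so the solve
works on the raw shape parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binomtest

from .fitting import FitConfig, FitSession
from .rate_distributions import (AlphaDistribution, OmegaDistribution,
                                 coefficient_of_variation,
                                 make_alpha_distribution)
from .selection import ConcordanceTable, cohens_kappa, run_selection_test
from .simulate import SimulationSpec, make_model_tree, simulate_alignment

log = logging.getLogger(__name__)

_ALPHA_WEIGHTS = (0.25, 0.60, 0.15)
_A1_DEFAULT = 0.2


def _raw_cv(a1: float, a3: float) -> float:
    w = np.array(_ALPHA_WEIGHTS)
    r = np.array([a1, 1.0, a3])
    m = w @ r
    return float(np.sqrt(w @ (r - m) ** 2) / m)


def alpha_for_cv(cv: float) -> AlphaDistribution:
    """Three-bin unit-mean alpha GDD achieving a target coefficient of
    variation (weights fixed at 0.25/0.60/0.15)."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    if cv < 1e-9:
        return make_alpha_distribution(1.0, 1.0, *_ALPHA_WEIGHTS[:2])
    pivot = _raw_cv(_A1_DEFAULT, 1.0)
    if cv <= pivot:
        a1 = brentq(lambda a: _raw_cv(a, 1.0) - cv, 0.0, 1.0)
        return make_alpha_distribution(a1, 1.0, *_ALPHA_WEIGHTS[:2])
    hi = 2.0
    while _raw_cv(_A1_DEFAULT, hi) < cv:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"target CV {cv} unreachable with fixed weights")
    a3 = brentq(lambda a: _raw_cv(_A1_DEFAULT, a) - cv, 1.0, hi)
    return make_alpha_distribution(_A1_DEFAULT, a3, *_ALPHA_WEIGHTS[:2])


def omega_for(omega3: float, p3: float = 0.03) -> OmegaDistribution:
    """Omega GDD of the simulation design: a conserved class at 0.1, a
    neutral class, and a fraction p3 of branch-site combinations at omega3
    (omega3 = 1 gives the no-selection null)."""
    if omega3 < 1:
        raise ValueError("omega3 must be >= 1 in this design")
    return OmegaDistribution(rates=[0.1, 1.0, omega3],
                             weights=[1.0 - 0.30 - p3, 0.30, p3])


#: Model-tree total branch lengths (expected substitutions per codon site)
#: by taxon count.
TOTAL_LENGTH = {16: 4.0, 31: 6.0}


@dataclass
class StudyGrid:
    """Cross-product experimental design with deterministic per-cell seeds."""

    cv_levels: tuple = (0.0, 0.5, 1.0)
    omega3_levels: tuple = (1.0, 2.077, 6.0)
    n_codons: tuple = (300,)
    taxa: tuple = (16,)
    replicates: int = 20
    methods: tuple = ("BUSTED", "BUSTED[S]")
    p3: float = 0.03
    base_seed: int = 1
    alpha_level: float = 0.05
    full_scale: bool = False
    fit_config: FitConfig | None = None

    def conditions(self):
        for taxa in self.taxa:
            for n in self.n_codons:
                for cv in self.cv_levels:
                    for w3 in self.omega3_levels:
                        yield {"taxa": taxa, "n_codons": n, "cv_alpha": cv,
                               "omega3": w3}

    def replicate_seed(self, cond_index: int, rep: int) -> int:
        ss = np.random.SeedSequence(entropy=self.base_seed,
                                    spawn_key=(cond_index, rep))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def run_replicate(cond: dict, seed: int, methods, p3: float = 0.03,
                  alpha_level: float = 0.05,
                  fit_config: FitConfig | None = None) -> list[dict]:
    """Simulate one alignment for a condition and apply each method."""
    tree = make_model_tree(cond["taxa"], TOTAL_LENGTH.get(cond["taxa"], 4.0),
                           "balanced", seed=0)
    spec = SimulationSpec(
        omega_dist=omega_for(cond["omega3"], p3),
        alpha_dist=alpha_for_cv(cond["cv_alpha"]),
        n_codons=cond["n_codons"], tree=tree, seed=seed)
    aln, truth = simulate_alignment(spec)
    session = FitSession(aln, tree, fit_config or FitConfig(seed=seed))
    rows = []
    for method in methods:
        result = run_selection_test(aln, tree, method, session=session,
                                    alpha_level=alpha_level)
        fit = result.fit_unconstrained
        rows.append({
            **cond, "seed": seed, "method": result.method,
            "statistic": result.statistic, "p_value": result.p_value,
            "reject": bool(result.significant),
            "cv_alpha_hat": coefficient_of_variation(fit.alpha_dist),
            "cv_omega_hat": coefficient_of_variation(fit.omega_dist),
            "omega3_hat": fit.omega_dist.omega3, "p3_hat": fit.omega_dist.p3,
            "logL_unc": fit.log_likelihood,
            "logL_con": result.fit_constrained.log_likelihood,
            "fraction_selected_true": truth["fraction_selected"],
        })
    return rows


def run_grid(grid: StudyGrid, out_dir=None) -> pd.DataFrame:
    """Run the full grid; one row per (condition, method, replicate).

    When ``out_dir`` is given, each completed cell is written to a TSV and
    re-runs skip cells whose files already exist (resumability); replicate
    failures are logged and recorded with NaN statistics, not fatal.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for ci, cond in enumerate(grid.conditions()):
        tag = (f"cell_t{cond['taxa']}_n{cond['n_codons']}"
               f"_cv{cond['cv_alpha']:g}_w{cond['omega3']:g}.tsv")
        if out_dir is not None and (out_dir / tag).exists():
            frames.append(pd.read_csv(out_dir / tag, sep="\t"))
            continue
        rows = []
        for rep in range(grid.replicates):
            seed = grid.replicate_seed(ci, rep)
            try:
                rep_rows = run_replicate(cond, seed, grid.methods, grid.p3,
                                         grid.alpha_level, grid.fit_config)
            except Exception:  # noqa: BLE001 - cell failures must not abort
                log.exception("replicate failed: %s seed=%d", cond, seed)
                rep_rows = [{**cond, "seed": seed, "method": m,
                             "statistic": np.nan, "p_value": np.nan,
                             "reject": False} for m in grid.methods]
            for r in rep_rows:
                r["replicate"] = rep
            rows.extend(rep_rows)
        cell = pd.DataFrame(rows)
        if out_dir is not None:
            cell.to_csv(out_dir / tag, sep="\t", index=False)
        frames.append(cell)
    df = pd.concat(frames, ignore_index=True)
    df.attrs["replicates"] = grid.replicates
    df.attrs["scale"] = "full" if grid.full_scale else "reduced"
    df.attrs["base_seed"] = grid.base_seed
    return df


def summarize(results: pd.DataFrame, alpha_level: float = 0.05,
              window: float = 0.2, step: float = 0.1,
              min_points: int = 10) -> dict[str, pd.DataFrame]:
    """Per-condition rejection rates with binomial CIs, per-CV-level method
    concordance (Cohen's kappa), and sliding-window detection-rate ratios
    over the fitted CV(alpha) (windows with fewer than ``min_points``
    datasets are suppressed)."""
    if results.empty:
        raise ValueError("empty results table")
    df = results.dropna(subset=["p_value"]).copy()

    cond_cols = ["taxa", "n_codons", "cv_alpha", "omega3", "method"]
    rows = []
    for key, grp in df.groupby(cond_cols):
        n, k = len(grp), int(grp["reject"].sum())
        ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
        rows.append(dict(zip(cond_cols, key)) | {
            "n": n, "rejections": k, "rate": k / n,
            "ci_low": ci.low, "ci_high": ci.high})
    conditions = pd.DataFrame(rows)

    methods = sorted(df["method"].unique())
    kappa_rows = []
    if len(methods) >= 2:
        key_cols = ["taxa", "n_codons", "cv_alpha", "omega3", "seed"]
        wide = df.pivot_table(index=key_cols, columns="method",
                              values="reject", aggfunc="first")
        for ma in methods:
            for mb in methods:
                if ma >= mb:
                    continue
                for cv, grp in wide.dropna().groupby(level="cv_alpha"):
                    a = grp[ma].astype(bool).to_numpy()
                    b = grp[mb].astype(bool).to_numpy()
                    table = ConcordanceTable.from_verdicts(a, b, (ma, mb))
                    try:
                        kap = cohens_kappa(table)
                    except ValueError:
                        kap = np.nan
                    kappa_rows.append({"method_a": ma, "method_b": mb,
                                       "cv_alpha": cv, "n": len(grp),
                                       "kappa": kap})
    kappa = pd.DataFrame(kappa_rows)

    window_rows = []
    if len(methods) >= 2 and "cv_alpha_hat" in df.columns:
        key_cols = ["taxa", "n_codons", "cv_alpha", "omega3", "seed"]
        ref = methods[-1]  # SRV-aware method provides the fitted CV
        cv_hat = df[df["method"] == ref].set_index(key_cols)["cv_alpha_hat"]
        wide = df.pivot_table(index=key_cols, columns="method",
                              values="reject", aggfunc="first").dropna()
        wide = wide.join(cv_hat.rename("cv_hat")).dropna()
        if len(wide):
            lo = np.floor(wide["cv_hat"].min() / step) * step
            hi = wide["cv_hat"].max()
            center = lo + window / 2
            while center - window / 2 <= hi:
                sel = wide[(wide["cv_hat"] >= center - window / 2)
                           & (wide["cv_hat"] < center + window / 2)]
                if len(sel) >= min_points:
                    ra = sel[methods[0]].mean()
                    rb = sel[ref].mean()
                    table = ConcordanceTable.from_verdicts(
                        sel[methods[0]].astype(bool),
                        sel[ref].astype(bool))
                    try:
                        kap = cohens_kappa(table)
                    except ValueError:
                        kap = np.nan
                    window_rows.append({
                        "cv_center": round(center, 10), "n": len(sel),
                        f"rate_{methods[0]}": ra, f"rate_{ref}": rb,
                        "detection_ratio": ra / rb if rb > 0 else np.inf,
                        "kappa": kap})
                center += step
    windows = pd.DataFrame(window_rows)
    return {"conditions": conditions, "kappa": kappa, "windows": windows}


def plot_rejection(summary: dict, path) -> None:
    """Rejection fraction vs CV(alpha), one panel per omega3, lines by
    sequence length and method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cond = summary["conditions"]
    omega3s = sorted(cond["omega3"].unique())
    fig, axes = plt.subplots(1, len(omega3s), figsize=(4 * len(omega3s), 3.2),
                             squeeze=False, sharey=True)
    for ax, w3 in zip(axes[0], omega3s):
        sub = cond[cond["omega3"] == w3]
        for (method, n), grp in sub.groupby(["method", "n_codons"]):
            grp = grp.sort_values("cv_alpha")
            ax.errorbar(grp["cv_alpha"], grp["rate"],
                        yerr=[grp["rate"] - grp["ci_low"],
                              grp["ci_high"] - grp["rate"]],
                        marker="o", capsize=2, label=f"{method}, {n} codons")
        ax.axhline(0.05, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("CV(alpha)")
        ax.set_title(f"omega3 = {w3:g}")
    axes[0][0].set_ylabel("rejection fraction")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
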