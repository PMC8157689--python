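"""Selection scans: Bayesian F_ST-outlier detection and joint sweep scan.

The outlier model decomposes differentiation logistically: for locus i and
population j, logit(F_ST(i, j)) = alpha_i + beta_j, where beta_j is a
population-specific component shared by all loci and alpha_i a
locus-specific component shared by all populations.  Alternate allele
counts are beta-binomial given the locus's ancestral frequency p_i and
theta_ij = 1/F_ST(i,j) - 1 (the within-population frequency is marginalized
out).  A locus is under selection when its alpha is included in the model;
inclusion carries a Bernoulli indicator with prior odds 1:prior_odds.  The
sampler is Metropolis-within-Gibbs with a fixed-dimension
Gibbs-variable-selection move for the indicator (the excluded alpha is
refreshed from its prior, which leaves the same posterior as a reversible
jump).  Posterior error probabilities (1 - inclusion probability) yield
q-values as cumulative means in PEP rank order; diversifying selection is
declared for included loci with positive alpha, balancing for negative.

The sweep scan flags unigenes jointly in the top tail of between-group
F_ST and of log2(pi_background / pi_focal): high differentiation plus
diversity loss in the focal (adapting) group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit

from .io import GenotypeMatrix

__all__ = [
    "OutlierResult",
    "SweepResult",
    "bayescan_outliers",
    "pep_to_qvalues",
    "sweep_scan",
]


@dataclass
class OutlierResult:
    table: pd.DataFrame  # per locus: alpha, inclusion_prob, pep, q, fst, class
    beta: np.ndarray  # posterior mean per population
    prior_odds: float
    converged: bool


def pep_to_qvalues(pep: np.ndarray) -> np.ndarray:
    """q(i) = mean PEP over loci ranked at or better than i (ascending PEP)."""
    pep = np.asarray(pep, dtype=float)
    order = np.argsort(pep, kind="stable")
    q_sorted = np.cumsum(pep[order]) / np.arange(1, len(pep) + 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _counts(G: GenotypeMatrix, pops: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pops = np.asarray(pops)
    names = list(dict.fromkeys(pops.tolist()))
    alt = np.empty((G.n_loci, len(names)))
    cop = np.empty((G.n_loci, len(names)))
    for j, name in enumerate(names):
        a, c = G.allele_counts(np.flatnonzero(pops == name))
        alt[:, j] = a
        cop[:, j] = c
    return alt, cop, names


def _loglik(a, n, p, f):
    """Beta-binomial log likelihood (binomial coefficient omitted: constant).

    theta = 1/F - 1; counts a of n with Beta(theta*p, theta*(1-p)) frequency.
    """
    f = np.clip(f, 1e-9, 1.0 - 1e-9)
    theta = 1.0 / f - 1.0
    u = theta * p
    v = theta * (1.0 - p)
    return betaln(a + u, n - a + v) - betaln(u, v)


def bayescan_outliers(
    G: GenotypeMatrix,
    pops: np.ndarray,
    prior_odds: float = 10.0,
    n_iter: int = 3000,
    burn_in: int = 1000,
    thin: int = 3,
    seed: int | None = None,
    q_threshold: float = 0.001,
) -> OutlierResult:
    """F_ST-outlier detection by the logistic alpha/beta decomposition.

    Priors mirror the reference defaults: p_i ~ Beta(1,1),
    beta_j ~ Normal(-1, 1.8^2), alpha_i ~ Normal(0, 1), inclusion indicator
    at prior odds 1:``prior_odds`` for inclusion.  ``n_iter`` counts kept
    (post-burn-in) iterations before thinning.
    """
    rng = np.random.default_rng(seed)
    a_cnt, n_cnt, names = _counts(G, pops)
    L, J = a_cnt.shape
    if J < 2:
        raise ValueError("need >= 2 populations")

    # state
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = (a_cnt.sum(axis=1) + 1.0) / (n_cnt.sum(axis=1) + 2.0)
    x = np.log(p0 / (1.0 - p0))  # logit ancestral frequency
    alpha = np.zeros(L)
    delta = np.zeros(L, dtype=bool)
    beta = np.full(J, -1.0)
    prior_logit_incl = np.log(1.0 / prior_odds)

    def ll_matrix(xv, al, de, be):
        p = expit(xv)[:, None]
        f = expit((de * al)[:, None] + be[None, :])
        return _loglik(a_cnt, n_cnt, p, f)

    cur = ll_matrix(x, alpha, delta, beta)
    s_x, s_a, s_b = 0.5, 0.6, 0.15

    keep_every = max(thin, 1)
    n_kept = 0
    incl_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    alpha_n = np.zeros(L)
    fst_sum = np.zeros(L)
    beta_sum = np.zeros(J)
    halves: list[np.ndarray] = [np.zeros(L), np.zeros(L)]
    halves_n = [0, 0]
    total_iter = burn_in + n_iter

    for it in range(total_iter):
        # --- ancestral frequency (logit RW; uniform prior on p => Jacobian)
        x_prop = x + rng.normal(0.0, s_x, L)
        prop = ll_matrix(x_prop, alpha, delta, beta)
        log_jac = (np.log(expit(x_prop)) + np.log(expit(-x_prop))) - (
            np.log(expit(x)) + np.log(expit(-x))
        )
        log_r = prop.sum(axis=1) - cur.sum(axis=1) + log_jac
        acc = np.log(rng.random(L)) < log_r
        x[acc] = x_prop[acc]
        cur[acc] = prop[acc]

        # --- alpha: MH for included loci, prior refresh for excluded
        a_prop = alpha + rng.normal(0.0, s_a, L)
        prop = ll_matrix(x, a_prop, delta, beta)
        log_r = (
            prop.sum(axis=1)
            - cur.sum(axis=1)
            + 0.5 * (alpha**2 - a_prop**2)  # N(0,1) prior
        )
        acc = (np.log(rng.random(L)) < log_r) & delta
        alpha[acc] = a_prop[acc]
        cur[acc] = prop[acc]
        excl = ~delta
        alpha[excl] = rng.normal(0.0, 1.0, excl.sum())
        # excluded alpha does not enter the likelihood; no cur update needed

        # --- indicator flip (alpha fixed)
        prop = ll_matrix(x, alpha, ~delta, beta)
        sign = np.where(delta, -1.0, 1.0)  # +: propose inclusion
        log_r = prop.sum(axis=1) - cur.sum(axis=1) + sign * prior_logit_incl
        acc = np.log(rng.random(L)) < log_r
        delta[acc] = ~delta[acc]
        cur[acc] = prop[acc]

        # --- beta (per-population RW, vectorized over columns)
        b_prop = beta + rng.normal(0.0, s_b, J)
        prop = ll_matrix(x, alpha, delta, b_prop)
        log_r = (
            prop.sum(axis=0)
            - cur.sum(axis=0)
            + ((beta + 1.0) ** 2 - (b_prop + 1.0) ** 2) / (2.0 * 1.8**2)
        )
        acc = np.log(rng.random(J)) < log_r
        beta[acc] = b_prop[acc]
        cur[:, acc] = prop[:, acc]

        if it >= burn_in and (it - burn_in) % keep_every == 0:
            n_kept += 1
            incl_sum += delta
            alpha_sum += np.where(delta, alpha, 0.0)
            alpha_n += delta
            f = expit((delta * alpha)[:, None] + beta[None, :])
            fst_sum += f.mean(axis=1)
            beta_sum += beta
            half = 0 if (it - burn_in) < n_iter // 2 else 1
            halves[half] += delta
            halves_n[half] += 1

    incl = incl_sum / n_kept
    pep = 1.0 - incl
    q = pep_to_qvalues(pep)
    with np.errstate(invalid="ignore"):
        alpha_mean = np.where(alpha_n > 0, alpha_sum / np.maximum(alpha_n, 1), 0.0)
    selected = q < q_threshold
    cls = np.where(
        selected & (alpha_mean > 0),
        "diversifying",
        np.where(selected & (alpha_mean < 0), "balancing", "neutral"),
    )
    converged = True
    if min(halves_n) > 0:
        h0 = halves[0] / halves_n[0]
        h1 = halves[1] / halves_n[1]
        frac_disagree = np.mean(np.abs(h0 - h1) > 0.1)
        if frac_disagree > 0.05:
            converged = False
            warnings.warn(
                f"possible non-convergence: split-chain inclusion probabilities "
                f"disagree by >0.1 for {100 * frac_disagree:.1f}% of loci"
            )
    table = pd.DataFrame(
        {
            "locus": G.locus_ids,
            "alpha": alpha_mean,
            "inclusion_prob": incl,
            "pep": pep,
            "q": q,
            "fst": fst_sum / n_kept,
            "classification": cls,
        }
    )
    return OutlierResult(table, beta_sum / n_kept, prior_odds, converged)


# ---------------------------------------------------------------------------
# sweep scan
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    table: pd.DataFrame  # per unigene: fst, log2_pi_ratio, candidate
    fst_threshold: float
    ratio_threshold: float
    top_frac: float


def sweep_scan(
    G: GenotypeMatrix,
    pops: np.ndarray,
    focal_pops: list[str],
    background_pops: list[str],
    top_frac: float = 0.05,
) -> SweepResult:
    """Joint top-tail scan for selective sweeps, per unigene.

    Per unigene: multilocus Weir-Cockerham F_ST between the pooled focal and
    background groups, and log2(pi_background / pi_focal) — oriented so large
    values mean diversity LOSS in the focal (adapting) group.  Zero pi values
    are floored at half the smallest nonzero pi before the ratio.  Thresholds
    are the empirical (1 - top_frac) quantiles over unigenes with finite
    statistics; candidates strictly exceed both.  Deterministic given data.
    """
    from .popgen import weir_cockerham_components, _per_site_pi

    if set(focal_pops) & set(background_pops):
        raise ValueError("focal and background groups must be disjoint")
    pops = np.asarray(pops)
    focal_rows = np.flatnonzero(np.isin(pops, focal_pops))
    bg_rows = np.flatnonzero(np.isin(pops, background_pops))
    if len(focal_rows) == 0 or len(bg_rows) == 0:
        raise ValueError("empty focal or background group")

    rows = np.concatenate([focal_rows, bg_rows])
    labels = np.array(["focal"] * len(focal_rows) + ["background"] * len(bg_rows))
    sub = G.take_samples(rows)
    a, b, c = weir_cockerham_components(sub, labels)

    unigene_index = pd.Index(G.unigenes)
    a_s = pd.Series(a).groupby(unigene_index).sum()
    abc_s = pd.Series(a + b + c).groupby(unigene_index).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_u = a_s / abc_s

    pi_focal = (
        pd.Series(_per_site_pi(G.genotypes[focal_rows])).groupby(unigene_index).sum(min_count=1)
    )
    pi_bg = (
        pd.Series(_per_site_pi(G.genotypes[bg_rows])).groupby(unigene_index).sum(min_count=1)
    )
    nonzero = pd.concat([pi_focal[pi_focal > 0], pi_bg[pi_bg > 0]])
    if nonzero.empty:
        raise ValueError("all unigenes have zero diversity")
    floor = 0.5 * nonzero.min()
    ratio = np.log2(np.maximum(pi_bg, floor) / np.maximum(pi_focal, floor))

    table = pd.DataFrame(
        {"fst": fst_u, "log2_pi_ratio": ratio}
    ).dropna()
    if len(table) < 20:
        raise ValueError("fewer than 20 unigenes: top-tail thresholds unreliable")
    if top_frac >= 1.0:
        fst_thr = -np.inf
        ratio_thr = -np.inf
    else:
        fst_thr = float(table["fst"].quantile(1.0 - top_frac))
        ratio_thr = float(table["log2_pi_ratio"].quantile(1.0 - top_frac))
    table["candidate"] = (table["fst"] > fst_thr) & (table["log2_pi_ratio"] > ratio_thr)
    return SweepResult(table, fst_thr, ratio_thr, top_frac)
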