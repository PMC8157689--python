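"""Population expression statistics from FPKM matrices.

FPKM = (1e9 * C) / (N * L) with C fragments mapped to the transcript, N the
individual's total mappable reads and L the transcript length.  Analyses run
on log2(FPKM+1) values after a per-unigene upper Tukey-fence mask; a unigene
is retained when at least half of the individuals express it (log2 value
> 0).

Two population summaries are computed per unigene:

* E_p — population expression level: the mean FPKM over the population's
  individuals;
* E_d — expression diversity: the mean absolute pairwise difference of
  log2(FPKM+1) among the population's individuals (the expression analogue
  of nucleotide diversity).  The exact published definition of E_d is not
  spelled out by its originating method description, so the pairwise-
  difference form is this package's documented definition, isolated in
  :func:`_mean_abs_pairwise_diff` so it can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "ExpressionSummary",
    "fpkm",
    "filter_expression",
    "population_expression",
    "expression_diversity",
    "ep_similarity",
    "diversity_expression_correlation",
]


def fpkm(
    counts: np.ndarray,
    lengths: np.ndarray,
    mapped_totals: np.ndarray,
    sample_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """FPKM from fragment counts: (1e9 * C) / (N * L).

    ``counts`` is individuals x unigenes, ``lengths`` is per unigene (bp) and
    ``mapped_totals`` is per individual.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    mapped_totals = np.asarray(mapped_totals, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("unigene lengths must be positive")
    if np.any(mapped_totals <= 0):
        raise ValueError("mapped read totals must be positive")
    values = 1e9 * counts / (mapped_totals[:, None] * lengths[None, :])
    n, g = values.shape
    return ExpressionMatrix(
        values,
        sample_ids or [f"S{i + 1}" for i in range(n)],
        gene_ids or [f"UN{j + 1:05d}" for j in range(g)],
        lengths=lengths,
        mapped_totals=mapped_totals,
    )


def _tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Tukey hinges (median-inclusive fourths) of a 1-D array."""
    x = np.sort(x)
    n = len(x)
    d = (np.floor((n + 1) / 2.0) + 1.0) / 2.0  # hinge depth
    lo = int(np.floor(d)) - 1
    hi = int(np.ceil(d)) - 1
    q1 = 0.5 * (x[lo] + x[hi])
    q3 = 0.5 * (x[n - 1 - lo] + x[n - 1 - hi])
    return q1, q3


def filter_expression(
    E: ExpressionMatrix,
    min_fraction_expressed: float = 0.5,
    log_transform: bool = True,
) -> tuple[ExpressionMatrix, list[str]]:
    """log2(FPKM+1) transform, upper Tukey-fence outlier mask, and retention.

    Per unigene, values above Q3 + 1.5*IQR (Tukey hinges on the non-missing
    log2 values) are masked as missing; the lower tail is left untouched.  A
    unigene is retained iff at least ``min_fraction_expressed`` of the
    individuals have log2 value > 0.  The masking is single-pass: fences are
    not recomputed after masking.

    Set ``log_transform=False`` when ``E`` already holds log2 values (e.g.
    re-filtering a filtered matrix).
    """
    x = E.values.copy()
    if log_transform:
        x = np.log2(x + 1.0)
    n_ind = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 4:
            continue
        q1, q3 = _tukey_hinges(col[ok])
        fence = q3 + 1.5 * (q3 - q1)
        col[ok & (col > fence)] = np.nan
    expressed = np.nansum(x > 0, axis=0)
    keep = expressed >= min_fraction_expressed * n_ind
    retained = [g for g, k in zip(E.gene_ids, keep) if k]
    out = ExpressionMatrix(
        x[:, keep],
        list(E.sample_ids),
        retained,
        log_scale=True,
    )
    return out, retained


@dataclass
class ExpressionSummary:
    """Per-unigene x population E_p and E_d with population means."""

    ep: pd.DataFrame  # genes x populations, FPKM scale
    ed: pd.DataFrame  # genes x populations, log2 scale
    ep_means: pd.Series
    ed_means: pd.Series
    retained_unigenes: list[str]


def _pop_blocks(sample_ids: list[str], pops: np.ndarray) -> dict[str, np.ndarray]:
    pops = np.asarray(pops)
    return {p: np.flatnonzero(pops == p) for p in dict.fromkeys(pops.tolist())}


def population_expression(E_log: ExpressionMatrix, pops: np.ndarray) -> pd.DataFrame:
    """E_p per unigene x population: mean FPKM over non-missing individuals.

    ``E_log`` holds log2(FPKM+1) values (the filter's output); means are taken
    after back-transforming to the FPKM scale.
    """
    x = E_log.values
    fpkm_vals = np.exp2(x) - 1.0 if E_log.log_scale else x
    blocks = _pop_blocks(E_log.sample_ids, pops)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells -> NaN
        for name, rows in blocks.items():
            out[name] = np.nanmean(fpkm_vals[rows], axis=0)
    return pd.DataFrame(out, index=E_log.gene_ids)


def _mean_abs_pairwise_diff(x: np.ndarray) -> np.ndarray:
    """Mean |x_i - x_j| over unordered pairs per column, NaNs excluded;
    columns with < 2 non-missing values give NaN."""
    m, g = x.shape
    diffs = np.abs(x[:, None, :] - x[None, :, :])  # m x m x g
    iu = np.triu_indices(m, k=1)
    pair_vals = diffs[iu[0], iu[1], :]
    valid = ~np.isnan(pair_vals)
    with np.errstate(invalid="ignore"):
        s = np.where(valid, pair_vals, 0.0).sum(axis=0)
        n = valid.sum(axis=0)
        return np.where(n > 0, s / np.maximum(n, 1), np.nan)


def expression_diversity(E_log: ExpressionMatrix, pops: np.ndarray) -> pd.DataFrame:
    """E_d per unigene x population: mean absolute pairwise log2 difference."""
    x = E_log.values if E_log.log_scale else np.log2(E_log.values + 1.0)
    blocks = _pop_blocks(E_log.sample_ids, pops)
    out = {}
    for name, rows in blocks.items():
        if len(rows) < 2:
            out[name] = np.full(x.shape[1], np.nan)
        else:
            out[name] = _mean_abs_pairwise_diff(x[rows])
    return pd.DataFrame(out, index=E_log.gene_ids)


def expression_summary(E_log: ExpressionMatrix, pops: np.ndarray) -> ExpressionSummary:
    ep = population_expression(E_log, pops)
    ed = expression_diversity(E_log, pops)
    return ExpressionSummary(
        ep=ep,
        ed=ed,
        ep_means=ep.mean(axis=0, skipna=True),
        ed_means=ed.mean(axis=0, skipna=True),
        retained_unigenes=list(E_log.gene_ids),
    )


def ep_similarity(E_log: ExpressionMatrix, pops: np.ndarray) -> pd.DataFrame:
    """Population x population expression similarity: the mean Pearson r
    between cross-population individual expression profiles."""
    x = E_log.values
    blocks = _pop_blocks(E_log.sample_ids, pops)
    names = list(blocks)
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    # individual-by-individual correlation on complete gene pairs
    n = x.shape[0]
    profiles = np.ma.masked_invalid(x)
    corr = np.ma.corrcoef(profiles)
    corr = np.asarray(corr.filled(np.nan))
    sim = np.ones((len(names), len(names)))
    for a in range(len(names)):
        for b in range(len(names)):
            if a == b:
                continue
            block = corr[np.ix_(blocks[names[a]], blocks[names[b]])]
            if np.all(np.isnan(block)):
                warnings.warn(f"degenerate profiles between {names[a]} and {names[b]}")
                sim[a, b] = np.nan
            else:
                sim[a, b] = np.nanmean(block)
    return pd.DataFrame(sim, index=names, columns=names)


def diversity_expression_correlation(
    pi_per_unigene: np.ndarray,
    ed_per_unigene: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Pearson r between per-unigene pi and E_d within one population, with a
    two-sided permutation p-value (shuffling one vector)."""
    a = np.asarray(pi_per_unigene, dtype=float)
    b = np.asarray(ed_per_unigene, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if len(a) < 10:
        raise ValueError("need >= 10 unigenes with both statistics")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = np.corrcoef(a, rng.permutation(b))[0, 1]
        if abs(rp) >= abs(r):
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return r, p


def pi_per_unigene(G, pops: np.ndarray) -> pd.DataFrame:
    """Per-unigene, per-population nucleotide diversity proxy: the sum of
    per-site unbiased heterozygosities over the unigene's SNPs (length-free;
    used for pi vs E_d correlations and sweep-scan ratios)."""
    from .popgen import _per_site_pi, _pop_blocks as blocks_of

    out = {}
    unigene_index = pd.Index(G.unigenes)
    for name, rows in blocks_of(np.asarray(pops)).items():
        pi_s = _per_site_pi(G.genotypes[rows])
        out[name] = pd.Series(pi_s).groupby(unigene_index).sum(min_count=1)
    return pd.DataFrame(out)
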