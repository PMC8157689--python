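"""Diversity and differentiation statistics.

Implements the per-site unbiased nucleotide-diversity estimator with
non-overlapping windows along each unigene, observed/expected heterozygosity
and the inbreeding coefficient F_IS = 1 - H_O/H_E, the Weir & Cockerham (1984)
variance-component F_ST estimator with permutation tests, a two-level
gene-copy AMOVA with Phi_ST, and allele-frequency-scaled PCA.

All estimators accept a :class:`~popadapt.io.GenotypeMatrix` plus a
per-individual population label array and tolerate missing genotypes (NaN):
missing gene copies simply drop out of the per-locus counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "AmovaResult",
    "FstMatrix",
    "nucleotide_diversity",
    "heterozygosities",
    "weir_cockerham_components",
    "weir_cockerham_fst",
    "pairwise_fst",
    "amova",
    "amova_from_ss",
    "pca",
]

SPECIES_LEVEL = "species"


def _pop_blocks(pops: np.ndarray) -> dict[str, np.ndarray]:
    pops = np.asarray(pops)
    return {p: np.flatnonzero(pops == p) for p in dict.fromkeys(pops.tolist())}


def _perm_pvalue(null: np.ndarray, observed: float) -> float:
    return (1.0 + np.sum(null >= observed)) / (1.0 + len(null))


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def _per_site_pi(g: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity (n/(n-1))(1 - p^2 - q^2) for one
    block of individuals; sites with < 2 called copies give NaN."""
    called = ~np.isnan(g)
    copies = 2.0 * called.sum(axis=0)
    alt = np.nansum(g, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / copies
        pi = np.where(
            copies >= 2,
            copies / (copies - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2),
            np.nan,
        )
    return pi


def nucleotide_diversity(
    G: GenotypeMatrix,
    pops: np.ndarray,
    window_len: int = 1000,
) -> pd.Series:
    """Per-population and pooled ("species") nucleotide diversity per bp.

    Sites are grouped into non-overlapping ``window_len``-bp windows anchored
    per unigene (coordinates restart on every transcript); window pi is the
    sum of per-site pi over the window divided by ``window_len``, and the
    reported value is the mean over windows that contain at least one SNP.
    """
    window_key = pd.MultiIndex.from_arrays(
        [G.unigenes, (G.positions - 1) // window_len], names=["unigene", "window"]
    )
    out: dict[str, float] = {}
    blocks = _pop_blocks(pops)
    blocks[SPECIES_LEVEL] = np.arange(G.n_individuals)
    for name, rows in blocks.items():
        pi_s = _per_site_pi(G.genotypes[rows])
        if np.all(np.isnan(pi_s)):
            warnings.warn(f"population {name}: no sites with >=2 called copies")
            out[name] = np.nan
            continue
        s = pd.Series(pi_s, index=window_key)
        window_pi = s.groupby(level=["unigene", "window"]).sum(min_count=1) / window_len
        out[name] = float(window_pi.mean())
    return pd.Series(out, name="pi")


# ---------------------------------------------------------------------------
# heterozygosities / F_IS
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-population H_O, H_E, F_IS (rows) with a pooled species-level row."""

    table: pd.DataFrame  # index: population (+ "species"), columns Ho, He, Fis


def heterozygosities(G: GenotypeMatrix, pops: np.ndarray) -> DiversitySummary:
    """Observed/expected heterozygosity and F_IS = 1 - mean(H_O)/mean(H_E).

    Averages are taken over loci polymorphic in the total dataset so that
    per-population values are comparable on one locus set.  H_E uses the
    gene-copy unbiased estimator (n/(n-1))(1 - p^2 - q^2).
    """
    p_tot = G.allele_freqs()
    poly = (p_tot > 0) & (p_tot < 1)
    if not poly.any():
        raise ValueError("no polymorphic loci in the dataset")
    rows_out = {}
    blocks = _pop_blocks(pops)
    blocks[SPECIES_LEVEL] = np.arange(G.n_individuals)
    for name, rows in blocks.items():
        g = G.genotypes[np.ix_(rows, np.flatnonzero(poly))]
        called = ~np.isnan(g)
        n_called = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.nansum(g == 1.0, axis=0) / n_called
            copies = 2.0 * n_called
            p = np.nansum(g, axis=0) / copies
            he = np.where(
                copies >= 2,
                copies / (copies - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2),
                np.nan,
            )
        mean_ho = float(np.nanmean(ho))
        mean_he = float(np.nanmean(he))
        fis = 1.0 - mean_ho / mean_he if mean_he > 0 else np.nan
        if mean_he <= 0:
            warnings.warn(f"population {name}: H_E is zero, F_IS undefined")
        rows_out[name] = {"Ho": mean_ho, "He": mean_he, "Fis": fis}
    return DiversitySummary(pd.DataFrame.from_dict(rows_out, orient="index"))


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------


def weir_cockerham_components(
    G: GenotypeMatrix, pops: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir & Cockerham (1984) variance components (a, b, c).

    a: among populations, b: among individuals within populations,
    c: within individuals.  Loci monomorphic across the populations
    contribute zeros.
    """
    blocks = list(_pop_blocks(pops).values())
    r = len(blocks)
    if r < 2:
        raise ValueError("need >= 2 populations")
    L = G.n_loci
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, rows in enumerate(blocks):
        g = G.genotypes[rows]
        called = ~np.isnan(g)
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(g, axis=0) / (2.0 * n)
            h = np.nansum(g == 1.0, axis=0) / n
        n_i[k] = n
        p_i[k] = np.where(n > 0, p, 0.0)
        h_i[k] = np.where(n > 0, h, 0.0)
    if np.any(n_i.sum(axis=0) == 0):
        raise ValueError("locus with no called genotypes in any population")
    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1.0)
    pbar = (n_i * p_i).sum(axis=0) / sum_n
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / sum_n
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    mono = (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[mono] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    return a, b, c


def weir_cockerham_fst(G: GenotypeMatrix, pops: np.ndarray) -> float:
    """Multilocus theta = sum(a) / sum(a + b + c)."""
    a, b, c = weir_cockerham_components(G, pops)
    denom = (a + b + c).sum()
    if denom == 0:
        return np.nan
    return float(a.sum() / denom)


@dataclass
class FstMatrix:
    """Pairwise multilocus Weir-Cockerham theta with permutation p-values."""

    theta: pd.DataFrame
    p_values: pd.DataFrame


def pairwise_fst(
    G: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> FstMatrix:
    """All pairwise multilocus theta values; significance by permuting
    individuals across each pair ``n_perm`` times.  Negative estimates are
    reported as-is (the unbiased estimator centres at zero)."""
    rng = np.random.default_rng(seed)
    pops = np.asarray(pops)
    names = list(dict.fromkeys(pops.tolist()))
    k = len(names)
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            rows = np.flatnonzero((pops == names[i]) | (pops == names[j]))
            sub = G.take_samples(rows)
            labels = pops[rows]
            obs = weir_cockerham_fst(sub, labels)
            null = np.empty(n_perm)
            for b in range(n_perm):
                null[b] = weir_cockerham_fst(sub, rng.permutation(labels))
            theta[i, j] = theta[j, i] = obs
            pmat[i, j] = pmat[j, i] = _perm_pvalue(null, obs)
    return FstMatrix(
        pd.DataFrame(theta, index=names, columns=names),
        pd.DataFrame(pmat, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    df_among: float
    df_within: float
    ss_among: float
    ss_within: float
    va: float
    vb: float
    pct_among: float
    pct_within: float
    phi_st: float
    n0: float
    p_value: float | None = None
    copies_per_pop: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SS": [self.ss_among, self.ss_within, self.ss_among + self.ss_within],
                "variance": [self.va, self.vb, self.va + self.vb],
                "pct": [self.pct_among, self.pct_within, 100.0],
            },
            index=["among_populations", "within_populations", "total"],
        )


def amova_from_ss(
    ss_among: float,
    ss_within: float,
    df_among: float,
    df_within: float,
    copies_per_pop: "list[float] | np.ndarray",
) -> AmovaResult:
    """Closed-form two-level AMOVA from printed sums of squares.

    ``copies_per_pop`` are gene-copy counts (2n for diploids).  The weighted
    average copy number is n0 = (sum c - sum c^2 / sum c) / (k - 1);
    Va = (MSA - MSW)/n0, Vb = MSW, Phi_ST = Va/(Va+Vb).
    """
    c = np.asarray(copies_per_pop, dtype=float)
    if len(c) != df_among + 1:
        raise ValueError("copies_per_pop length must equal df_among + 1")
    if df_among <= 0 or df_within <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_among < 0 or ss_within < 0:
        raise ValueError("sums of squares must be non-negative")
    total = c.sum()
    k = len(c)
    n0 = (total - (c**2).sum() / total) / (k - 1.0)
    msa = ss_among / df_among
    msw = ss_within / df_within
    va = (msa - msw) / n0
    vb = msw
    tot = va + vb
    if tot == 0:  # degenerate zero-variance data
        return AmovaResult(
            df_among=df_among, df_within=df_within, ss_among=ss_among,
            ss_within=ss_within, va=va, vb=vb, pct_among=0.0,
            pct_within=100.0, phi_st=0.0, n0=n0, copies_per_pop=list(c),
        )
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        va=va,
        vb=vb,
        pct_among=100.0 * va / tot,
        pct_within=100.0 * vb / tot,
        phi_st=va / tot,
        n0=n0,
        copies_per_pop=list(c),
    )


def _amova_ss(G: GenotypeMatrix, blocks: list[np.ndarray]) -> tuple[float, float, np.ndarray]:
    """Sums of squares on allele indicators summed over loci.

    For a binary indicator with ``a`` alt copies among ``c`` called copies the
    within-group SS is a - a^2/c; summing the ref-allele indicator doubles it,
    matching squared Euclidean distances on two-column allele profiles.
    Returns (SS_among, SS_within, mean called copies per population).
    """
    ss_within = 0.0
    copies_mean = np.empty(len(blocks))
    alt_tot = np.zeros(G.n_loci)
    cop_tot = np.zeros(G.n_loci)
    for k, rows in enumerate(blocks):
        alt, cop = G.allele_counts(rows)
        ok = cop > 0
        ss_within += 2.0 * np.sum(alt[ok] - alt[ok] ** 2 / cop[ok])
        copies_mean[k] = cop.mean()
        alt_tot += alt
        cop_tot += cop
    ok = cop_tot > 0
    ss_total = 2.0 * np.sum(alt_tot[ok] - alt_tot[ok] ** 2 / cop_tot[ok])
    return ss_total - ss_within, ss_within, copies_mean


def amova(
    G: GenotypeMatrix,
    pops: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level gene-copy AMOVA with a permutation test on Phi_ST.

    Distances are squared Euclidean on allele indicators summed over loci
    (equivalent to allele-frequency AMOVA for biallelic data).  Per-population
    gene-copy counts are per-locus called copies averaged over loci, so the
    degrees of freedom equal k-1 and sum(c)-k exactly when no data are
    missing.  The null permutes individuals across populations.
    """
    pops = np.asarray(pops)
    blocks = list(_pop_blocks(pops).values())
    k = len(blocks)
    if k < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    ss_among, ss_within, copies = _amova_ss(G, blocks)
    df_among = k - 1.0
    df_within = copies.sum() - k
    res = amova_from_ss(ss_among, ss_within, df_among, df_within, copies)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_blocks = list(_pop_blocks(rng.permutation(pops)).values())
            sa, sw, cp = _amova_ss(G, perm_blocks)
            r = amova_from_ss(sa, sw, len(perm_blocks) - 1.0, cp.sum() - len(perm_blocks), cp)
            null[b] = r.phi_st
        res.p_value = _perm_pvalue(null, res.phi_st)
    return res


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(G: GenotypeMatrix, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Allele-frequency-scaled PCA of the genotype matrix.

    Genotypes are centred per locus at 2p and scaled by sqrt(2p(1-p));
    missing values are imputed to the locus mean before scaling.
    Returns (scores of shape n_individuals x k, variance fraction per axis);
    fractions are relative to the total variance of the scaled matrix, so
    they sum to <= 1.
    """
    if G.n_individuals < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = G.genotypes.copy()
    p = G.allele_freqs()
    mean = 2.0 * p
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mean, inds[1])
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    X = (X[:, keep] - mean[keep]) / scale[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(s))
    total = np.sum(X**2)
    scores = U[:, :n_components] * s[:n_components]
    fractions = s[:n_components] ** 2 / total
    return scores, fractions
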