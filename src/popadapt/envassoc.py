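"""Genotype-environment association and spatial analysis.

Covers: iterative VIF pruning of environmental variables, distance-based
Moran's eigenvector maps (dbMEM) as geographic predictors, redundancy
analysis (RDA) with permutation tests, forward selection with the double
stopping rule, variation partitioning on the adjusted-R^2 scale, a
least-squares latent-factor mixed model (LFMM) with genomic-control
calibration, Mantel tests (via scikit-bio), and the geographic /
environmental distance matrices used for isolation-by-distance and
isolation-by-environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .io import GenotypeMatrix, SampleMetadata
from .simulate import haversine_km

__all__ = [
    "RdaResult",
    "VarpartResult",
    "LfmmResult",
    "MantelResult",
    "vif_prune",
    "dbmem",
    "hellinger_transform",
    "rda_fit",
    "forward_select",
    "varpart",
    "lfmm",
    "mantel",
    "ibd_ibe_distances",
]


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------


def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_k = 1 / (1 - R^2_k), R^2 from OLS of column k on the others."""
    n, m = X.shape
    vifs = np.empty(m)
    for k in range(m):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        r2 = min(r2, 1.0 - 1e-12)
        vifs[k] = 1.0 / (1.0 - r2)
    return vifs


def vif_prune(env: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the variable with the largest VIF until all <= threshold.

    Ties (e.g. a perfectly collinear pair) drop the later-listed variable
    first, a deterministic rule.  Returns retained column names in original
    order.
    """
    cols = list(env.columns)
    if len(cols) < 2:
        return cols
    X = env.to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        warnings.warn(
            "fewer sites than variables: VIFs computed on a least-squares "
            "pseudo-inverse fit (ridge-like fallback)"
        )
    keep = list(range(len(cols)))
    while len(keep) >= 2:
        vifs = _vif(X[:, keep])
        worst = np.max(vifs)
        if worst <= threshold:
            break
        # later-listed wins ties
        drop_pos = len(vifs) - 1 - int(np.argmax(vifs[::-1]))
        keep.pop(drop_pos)
    return [cols[i] for i in keep]


# ---------------------------------------------------------------------------
# dbMEM
# ---------------------------------------------------------------------------


def dbmem(
    coords: pd.DataFrame,
    truncation: float | None = None,
) -> pd.DataFrame:
    """Distance-based Moran's eigenvector maps from site coordinates.

    Great-circle distances above the truncation threshold (default: the
    longest minimum-spanning-tree edge) are replaced by 4x the threshold;
    the matrix is Gower-centred (-0.5 d^2 double-centred) and the
    eigenvectors with positive eigenvalues (positive spatial
    autocorrelation) are returned in decreasing eigenvalue order as columns
    dbMEM1, dbMEM2, ...
    """
    xy = coords[["lon", "lat"]].to_numpy(dtype=float)
    if len(np.unique(xy, axis=0)) < 3:
        raise ValueError("need >= 3 distinct sites")
    d = haversine_km(xy)
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    d_trunc = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(d_trunc, 0.0)
    n = len(d_trunc)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d_trunc**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-9 * max(evals.max(), 1.0)
    vecs = evecs[:, pos]
    return pd.DataFrame(
        vecs,
        index=coords.index,
        columns=[f"dbMEM{i + 1}" for i in range(vecs.shape[1])],
    )


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------


def hellinger_transform(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Row-proportion square-root transform of nonnegative count data.

    Genotype matrices have missing calls imputed to the locus mean first.
    """
    if isinstance(G, GenotypeMatrix):
        X = G.genotypes.copy()
        mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(mean, inds[1])
    else:
        X = np.asarray(G, dtype=float)
    if np.any(X < 0):
        raise ValueError("Hellinger transform requires nonnegative data")
    row_sums = X.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("row with zero sum")
    return np.sqrt(X / row_sums[:, None])


@dataclass
class RdaResult:
    scores: np.ndarray  # site scores on constrained axes
    eigenvalues: np.ndarray  # nonincreasing
    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float | None
    axis_p_values: np.ndarray | None
    n_predictors: int


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _fit_ss(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Sum of squares of fitted values of centred Y on centred X."""
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return float(np.sum((Xc @ coef) ** 2))


def ezekiel_adj_r2(r2: float, n: int, m: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - m - 1.0)


def rda_fit(
    Y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> RdaResult:
    """Redundancy analysis: constrained ordination of Y on X.

    R^2 = SS(fitted)/SS(total); adjusted R^2 uses Ezekiel's formula with
    m = rank of the centred predictor matrix.  The global test permutes rows
    of Y and compares the pseudo-F.  Per-axis p-values compare each
    constrained eigenvalue with its permutation distribution (approximate
    marginal test).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X row counts differ")
    n = Y.shape[0]
    Yc, Xc = _center(Y), _center(X)
    m = int(np.linalg.matrix_rank(Xc))
    if m >= n - 1:
        raise ValueError("too many predictors for the sample size")
    ss_tot = float(np.sum(Yc**2))
    if ss_tot == 0:
        raise ValueError("response matrix has zero variance")
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ coef
    ss_fit = float(np.sum(Yhat**2))
    r2 = ss_fit / ss_tot
    adj = ezekiel_adj_r2(r2, n, m)
    U, s, _ = np.linalg.svd(Yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    k = min(m, np.sum(s > 1e-12 * max(s.max(), 1.0)))
    scores = U[:, :k] * s[:k]
    eig = eig[:k]
    resid_df = n - m - 1
    ss_res = max(ss_tot - ss_fit, 0.0)
    if ss_res <= 1e-12 * ss_tot:  # perfect fit
        pseudo_f = np.inf
    else:
        pseudo_f = (ss_fit / m) / (ss_res / resid_df)
    p_val = None
    axis_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null_f = np.empty(n_perm)
        null_eig = np.empty((n_perm, k))
        for b in range(n_perm):
            Yp = Yc[rng.permutation(n)]
            coef_p, *_ = np.linalg.lstsq(Xc, Yp, rcond=None)
            Yhat_p = Xc @ coef_p
            ss_p = np.sum(Yhat_p**2)
            ss_rp = max(ss_tot - ss_p, 1e-12 * ss_tot)
            null_f[b] = (ss_p / m) / (ss_rp / resid_df)
            sp = np.linalg.svd(Yhat_p, compute_uv=False)
            null_eig[b] = (sp[:k] ** 2) / (n - 1)
        p_val = (1.0 + np.sum(null_f >= pseudo_f)) / (1.0 + n_perm)
        axis_p = (1.0 + (null_eig >= eig[None, :]).sum(axis=0)) / (1.0 + n_perm)
    return RdaResult(scores, eig, r2, adj, pseudo_f, p_val, axis_p, m)


def forward_select(
    Y: np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    use_adj_r2_cap: bool = True,
) -> list[str]:
    """Greedy forward selection of predictors with the double stopping rule.

    At each step the candidate maximizing adjusted R^2 enters unless its
    partial permutation p-value exceeds ``alpha`` or the model's adjusted
    R^2 would exceed the all-variable model's (guarding against
    over-selection).  Candidate significance uses Freedman-Lane permutation
    of the residuals of Y on the already-selected set.
    """
    rng = np.random.default_rng(seed)
    Y = _center(np.asarray(Y, dtype=float))
    cols = list(X.columns)
    Xall = _center(X.to_numpy(dtype=float))
    n = Y.shape[0]
    ss_tot = float(np.sum(Y**2))
    m_all = int(np.linalg.matrix_rank(Xall))
    adj_cap = ezekiel_adj_r2(_fit_ss(Y, Xall) / ss_tot, n, m_all)

    selected: list[int] = []
    while len(selected) < len(cols):
        best_j, best_adj = None, -np.inf
        for j in range(len(cols)):
            if j in selected:
                continue
            Xs = Xall[:, selected + [j]]
            m = int(np.linalg.matrix_rank(Xs))
            if m >= n - 1:
                continue
            adj = ezekiel_adj_r2(_fit_ss(Y, Xs) / ss_tot, n, m)
            if adj > best_adj:
                best_adj, best_j = adj, j
        if best_j is None or (
            use_adj_r2_cap and np.isfinite(adj_cap) and best_adj > adj_cap
        ):
            break
        # Freedman-Lane test of the candidate given the current set
        if selected:
            Xs = Xall[:, selected]
            coef, *_ = np.linalg.lstsq(Xs, Y, rcond=None)
            fitted = Xs @ coef
            resid = Y - fitted
        else:
            fitted = np.zeros_like(Y)
            resid = Y
        Xfull = Xall[:, selected + [best_j]]
        m_full = int(np.linalg.matrix_rank(Xfull))
        df_res = n - m_full - 1
        ss_sel = _fit_ss(Y, Xall[:, selected]) if selected else 0.0
        ss_full = _fit_ss(Y, Xfull)
        f_obs = (ss_full - ss_sel) / ((np.sum(Y**2) - ss_full) / df_res)
        count = 0
        for _ in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            Yp = _center(Yp)
            ss_sel_p = _fit_ss(Yp, Xall[:, selected]) if selected else 0.0
            ss_full_p = _fit_ss(Yp, Xfull)
            f_p = (ss_full_p - ss_sel_p) / ((np.sum(Yp**2) - ss_full_p) / df_res)
            if f_p >= f_obs:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
        if p > alpha:
            break
        selected.append(best_j)
    return [cols[j] for j in selected]


# ---------------------------------------------------------------------------
# variation partitioning
# ---------------------------------------------------------------------------


@dataclass
class VarpartResult:
    a: float  # env | geo
    b: float  # shared
    c: float  # geo | env
    d: float  # unexplained
    adj_env: float  # [a+b]
    adj_geo: float  # [c+b]
    adj_both: float  # [a+b+c]
    f_a: float | None = None
    p_a: float | None = None
    f_c: float | None = None
    p_c: float | None = None

    def fractions(self) -> dict[str, float]:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


def varpart_from_adj_r2(adj_env: float, adj_geo: float, adj_both: float) -> VarpartResult:
    """Fraction arithmetic from the three model adjusted R^2 values."""
    a = adj_both - adj_geo
    c = adj_both - adj_env
    b = adj_env + adj_geo - adj_both
    d = 1.0 - adj_both
    return VarpartResult(a, b, c, d, adj_env, adj_geo, adj_both)


def _partial_f_test(
    Y: np.ndarray,
    X_test: np.ndarray,
    X_cond: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation partial F for Y ~ X_test | X_cond (Freedman-Lane under the
    conditioning model)."""
    n = Y.shape[0]
    Xb = np.column_stack([X_cond, X_test])
    m_b = int(np.linalg.matrix_rank(Xb))
    m_c = int(np.linalg.matrix_rank(X_cond))
    m_t = m_b - m_c
    df_res = n - m_b - 1
    coef, *_ = np.linalg.lstsq(X_cond, Y, rcond=None)
    fitted = X_cond @ coef
    resid = Y - fitted
    ss_tot = float(np.sum(Y**2))
    f_obs = ((_fit_ss(Y, Xb) - _fit_ss(Y, X_cond)) / m_t) / (
        (ss_tot - _fit_ss(Y, Xb)) / df_res
    )
    count = 0
    for _ in range(n_perm):
        Yp = _center(fitted + resid[rng.permutation(n)])
        ssp_tot = float(np.sum(Yp**2))
        f_p = ((_fit_ss(Yp, Xb) - _fit_ss(Yp, X_cond)) / m_t) / (
            (ssp_tot - _fit_ss(Yp, Xb)) / df_res
        )
        if f_p >= f_obs:
            count += 1
    return f_obs, (1.0 + count) / (1.0 + n_perm)


def varpart(
    Y: np.ndarray,
    X_env: np.ndarray | pd.DataFrame,
    X_geo: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> VarpartResult:
    """Variation partitioning of Y between environment and geography.

    Fits Y~env, Y~geo, Y~env+geo, converts each R^2 to the adjusted scale,
    and derives the pure ([a], [c]), shared ([b]) and unexplained ([d])
    fractions.  Testable fractions get partial-RDA permutation F tests.
    """
    Y = _center(np.asarray(Y, dtype=float))
    Xe = _center(np.asarray(X_env, dtype=float))
    Xg = _center(np.asarray(X_geo, dtype=float))
    n = Y.shape[0]
    ss_tot = float(np.sum(Y**2))

    def adj_of(X):
        m = int(np.linalg.matrix_rank(X))
        if m >= n - 1:
            raise ValueError("too many predictors for the sample size")
        return ezekiel_adj_r2(_fit_ss(Y, X) / ss_tot, n, m)

    res = varpart_from_adj_r2(adj_of(Xe), adj_of(Xg), adj_of(np.column_stack([Xe, Xg])))
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        res.f_a, res.p_a = _partial_f_test(Y, Xe, Xg, n_perm, rng)
        res.f_c, res.p_c = _partial_f_test(Y, Xg, Xe, n_perm, rng)
    return res


# ---------------------------------------------------------------------------
# LFMM
# ---------------------------------------------------------------------------


@dataclass
class LfmmResult:
    z: pd.DataFrame  # loci x variables, median combined z-scores
    p: pd.DataFrame  # calibrated p-values
    k: int
    lambda_gc: pd.Series  # inflation factor per variable
    significant: pd.DataFrame  # bool at p < threshold
    p_threshold: float


_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


def _lfmm_single(
    Gc: np.ndarray,
    x: np.ndarray,
    K: int,
    rng: np.random.Generator,
    n_iter: int = 30,
) -> np.ndarray:
    """One repetition: alternating least squares for the rank-K latent
    factors, then per-locus z-scores of the environmental effect given the
    factors."""
    n, L = Gc.shape
    if K == 0:
        design = np.column_stack([np.ones(n), x])
    else:
        B = np.zeros(L)
        U = None
        for _ in range(n_iter):
            R = Gc - np.outer(x, B)
            R = R - R.mean(axis=0)
            if U is None:
                # jittered initialization decorrelates repetitions
                R0 = R + 0.01 * np.std(R) * rng.standard_normal(R.shape)
            else:
                R0 = R
            Uf, s, Vt = np.linalg.svd(R0, full_matrices=False)
            U = Uf[:, :K] * s[:K]
            W = Gc - U @ Vt[:K]
            denom = float(x @ x)
            B_new = (x @ W) / denom
            if np.allclose(B_new, B, atol=1e-8):
                B = B_new
                break
            B = B_new
        design = np.column_stack([np.ones(n), x, U])
    # per-locus OLS of genotype on [1, x, factors]; z for the x effect
    Q, Rm = np.linalg.qr(design)
    coef = np.linalg.solve(Rm, Q.T @ Gc)
    resid = Gc - design @ coef
    df = n - design.shape[1]
    sigma2 = np.sum(resid**2, axis=0) / df
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    return coef[1] / se


def lfmm(
    G: GenotypeMatrix | np.ndarray,
    env: pd.DataFrame,
    K: int = 4,
    n_repetitions: int = 10,
    p_threshold: float = 0.005,
    seed: int | None = None,
) -> LfmmResult:
    """Latent factor mixed model association, least-squares formulation.

    For each environmental variable: minimize ||G_c - U V' - x b'||^2 with U
    of rank K by alternating least squares; per-locus z-scores come from the
    regression of each locus on [1, x, U].  The run is repeated
    ``n_repetitions`` times with jittered initializations and combined by
    the median z; genomic control rescales z by sqrt(lambda) with
    lambda = median(z^2)/0.456 before two-sided chi-square p-values.
    """
    if isinstance(G, GenotypeMatrix):
        X = G.genotypes.copy()
        mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(mean, inds[1])
        loci = G.locus_ids
    else:
        X = np.asarray(G, dtype=float)
        loci = [f"L{j}" for j in range(X.shape[1])]
    n, L = X.shape
    if K >= n:
        raise ValueError("K must be smaller than the number of individuals")
    Gc = X - X.mean(axis=0)
    z_out, p_out, lam_out, sig_out = {}, {}, {}, {}
    rng = np.random.default_rng(seed)
    for var in env.columns:
        x = env[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"environmental variable {var!r} is constant")
        x = x - x.mean()
        reps = np.column_stack(
            [_lfmm_single(Gc, x, K, rng) for _ in range(n_repetitions)]
        )
        z = np.median(reps, axis=1)
        lam = np.median(z**2) / _CHI2_MEDIAN_1DF
        lam = max(lam, 1e-12)
        z_cal = z / np.sqrt(lam)
        p = stats.chi2.sf(z_cal**2, df=1)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        z_out[var] = z
        p_out[var] = p
        lam_out[var] = lam
        sig_out[var] = p < p_threshold
    return LfmmResult(
        z=pd.DataFrame(z_out, index=loci),
        p=pd.DataFrame(p_out, index=loci),
        k=K,
        lambda_gc=pd.Series(lam_out),
        significant=pd.DataFrame(sig_out, index=loci),
        p_threshold=p_threshold,
    )


# ---------------------------------------------------------------------------
# Mantel / IBD / IBE
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel(
    A: np.ndarray | pd.DataFrame,
    B: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel matrix correlation with a one-sided (greater) permutation test.

    r is the Pearson correlation over the off-diagonal lower triangles;
    p = (1 + #{permuted r >= observed r}) / (1 + n_perm), permuting the
    rows/columns of one matrix jointly.  Delegates to
    :func:`skbio.stats.distance.mantel`.
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel as _sk_mantel

    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if A.shape[0] < 4:
        warnings.warn("matrix smaller than 4x4: permutation space is tiny")
    # hollow-symmetrize defensively (DistanceMatrix requires it)
    def _dm(M):
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 0.0)
        return DistanceMatrix(M)

    if seed is not None:
        np.random.seed(seed % (2**32))  # skbio uses the global RNG
    r, p, _ = _sk_mantel(
        _dm(A), _dm(B), method="pearson", permutations=n_perm, alternative="greater"
    )
    return MantelResult(float(r), float(p), n_perm)


def ibd_ibe_distances(
    meta: SampleMetadata,
    env: pd.DataFrame,
    n_env_pcs: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-level geographic (haversine km) and environmental
    (Euclidean on the first ``n_env_pcs`` PCs of the standardized variables)
    distance matrices."""
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    sites = meta.sites()
    pops = list(sites.index)
    geo = haversine_km(sites[["lon", "lat"]].to_numpy(dtype=float))
    env = env.loc[pops]
    n_pcs = min(n_env_pcs, env.shape[1], len(pops) - 1)
    if n_pcs < n_env_pcs:
        warnings.warn(f"n_env_pcs capped at {n_pcs}")
    Z = StandardScaler().fit_transform(env.to_numpy(dtype=float))
    pcs = PCA(n_components=n_pcs).fit_transform(Z)
    envd = squareform(pdist(pcs))
    return (
        pd.DataFrame(geo, index=pops, columns=pops),
        pd.DataFrame(envd, index=pops, columns=pops),
    )
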