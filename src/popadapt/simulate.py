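"""Synthetic genotype / environment / expression data generators.

The generators emulate the statistical structure of a range-wide
transcriptome study of a montane conifer: ten small populations (5-12
diploids each) drifted apart under an island model, a minority of loci whose
allele frequencies track an environmental gradient, spatially autocorrelated
site environments, and a per-individual FPKM expression matrix with
population effects and tunable within-population dispersion.

Genotypes follow the Balding-Nichols model: for a neutral locus with
ancestral frequency p and drift parameter F, the population frequency is a
draw from Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected Weir-Cockerham F_ST
is F — this is what makes estimator-recovery tests possible.  Adaptive loci
additionally shift logit(p_pop) by ``env_effect`` times the standardized
focal environmental value at the population's site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GenotypeMatrix,
    SampleMetadata,
    write_expression_tsv,
    write_sample_metadata,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_coordinates",
    "simulate_environment",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Great-circle distance matrix in km from (lon, lat) decimal degrees."""
    a = np.radians(np.asarray(coords_a, dtype=float))
    b = a if coords_b is None else np.radians(np.asarray(coords_b, dtype=float))
    lon1, lat1 = a[:, 0][:, None], a[:, 1][:, None]
    lon2, lat2 = b[:, 0][None, :], b[:, 1][None, :]
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the sampling design the analyses assume: 10 populations
    of 5-12 diploids (108 individuals), moderate island-model drift, a small
    minority of environment-associated loci, and log2-scale expression with
    between-population SD comparable to the within-population SD.
    """

    n_pops: int = 10
    n_ind_per_pop: list[int] = field(
        default_factory=lambda: [12, 12, 8, 12, 11, 12, 12, 12, 12, 5]
    )
    n_loci: int = 2000
    fst_target: float = 0.25
    n_adaptive: int = 0
    env_effect: float = 1.5
    n_env_vars: int = 8
    spatial_range: float = 300.0  # autocorrelation length, km
    env_noise: float = 0.3  # independent noise SD on top of the spatial field
    n_genes: int = 1000
    expr_pop_sd: float = 0.4  # between-population SD of log2(FPKM+1)
    expr_ind_sd: float = 0.5  # within-population SD of log2(FPKM+1)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_ind_per_pop) != self.n_pops:
            raise ValueError("n_ind_per_pop length must equal n_pops")
        for name in ("n_pops", "n_loci", "n_env_vars", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(n < 1 for n in self.n_ind_per_pop):
            raise ValueError("all population sizes must be >= 1")
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError("fst_target must lie strictly in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_adaptive < 0 or self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive must lie in [0, n_loci]")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.n_ind_per_pop))

    @property
    def pop_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated genotype matrix."""

    ancestral_freqs: np.ndarray  # per locus
    pop_freqs: np.ndarray  # n_pops x n_loci
    adaptive_loci: np.ndarray  # locus indices
    adaptive_env_var: np.ndarray  # env-variable index per adaptive locus
    pop_membership: np.ndarray  # population name per individual

    def to_json(self, path: str | Path) -> None:
        obj = {
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "pop_freqs": self.pop_freqs.tolist(),
            "adaptive_loci": self.adaptive_loci.tolist(),
            "adaptive_env_var": self.adaptive_env_var.tolist(),
            "pop_membership": self.pop_membership.tolist(),
        }
        Path(path).write_text(json.dumps(obj))


def simulate_coordinates(config: SimConfig) -> pd.DataFrame:
    """Population site coordinates scattered over a subtropical montane
    region (lon 108-120 E, lat 24-30 N, altitude 900-1500 m)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lon = rng.uniform(108.0, 120.0, config.n_pops)
    lat = rng.uniform(24.0, 30.0, config.n_pops)
    alt = rng.uniform(900.0, 1500.0, config.n_pops)
    return pd.DataFrame(
        {"lon": lon, "lat": lat, "altitude": alt}, index=config.pop_names
    )


def simulate_environment(coords: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Spatially autocorrelated environmental variables at the sites.

    Each variable is a zero-mean Gaussian-process draw with exponential
    covariance exp(-d / spatial_range) on great-circle distances, plus
    independent Gaussian noise (SD ``env_noise``), then standardized to
    zero mean / unit SD across sites.
    """
    if len(coords) < 2:
        raise ValueError("need >= 2 sites")
    xy = coords[["lon", "lat"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    d = haversine_km(xy)
    if config.spatial_range <= 0:
        cov = np.eye(len(coords))
    else:
        cov = np.exp(-d / config.spatial_range)
    # jitter keeps the Cholesky stable when sites are near-duplicated
    L = np.linalg.cholesky(cov + 1e-9 * np.eye(len(coords)))
    z = L @ rng.standard_normal((len(coords), config.n_env_vars))
    z += config.env_noise * rng.standard_normal(z.shape)
    z = (z - z.mean(axis=0)) / z.std(axis=0)
    cols = [f"env{i + 1}" for i in range(config.n_env_vars)]
    return pd.DataFrame(z, index=coords.index, columns=cols)


def exponential_covariance(coords: pd.DataFrame, spatial_range: float) -> np.ndarray:
    """The GP covariance used by :func:`simulate_environment` (exposed for
    positive-semi-definiteness checks)."""
    d = haversine_km(coords[["lon", "lat"]].to_numpy(dtype=float))
    return np.exp(-d / spatial_range)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_genotypes(
    config: SimConfig,
    env: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Balding-Nichols genotypes for the configured design.

    Ancestral frequencies are Uniform(0.05, 0.95); neutral population
    frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws.  If ``config``
    requests adaptive loci, each one is assigned a focal environmental
    variable (round-robin) and its per-population logit frequency is shifted
    by ``env_effect`` times the standardized focal value at the population's
    site; ``env`` defaults to an internally simulated table on simulated
    coordinates.  Genotypes are Binomial(2, p_pop); a ``missing_rate``
    fraction of calls is masked.
    """
    F = config.fst_target  # validated in (0,1); F=0/1 would degenerate the Beta
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    if env is None and config.n_adaptive > 0:
        env = simulate_environment(simulate_coordinates(config), config)
    p_anc = rng.uniform(0.05, 0.95, config.n_loci)
    shape1 = p_anc * (1.0 - F) / F
    shape2 = (1.0 - p_anc) * (1.0 - F) / F
    pop_freqs = rng.beta(
        shape1[None, :], shape2[None, :], size=(config.n_pops, config.n_loci)
    )
    pop_freqs = np.clip(pop_freqs, 1e-9, 1.0 - 1e-9)

    adaptive = np.arange(config.n_adaptive)
    adaptive_var = np.zeros(config.n_adaptive, dtype=int)
    if config.n_adaptive > 0:
        assert env is not None
        Z = env.to_numpy(dtype=float)
        Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        adaptive_var = np.arange(config.n_adaptive) % Z.shape[1]
        shift = config.env_effect * Z[:, adaptive_var]  # n_pops x n_adaptive
        lg = _logit(pop_freqs[:, adaptive]) + shift
        pop_freqs[:, adaptive] = np.clip(_expit(lg), 1e-9, 1.0 - 1e-9)

    membership = np.repeat(config.pop_names, config.n_ind_per_pop)
    pop_index = np.repeat(np.arange(config.n_pops), config.n_ind_per_pop)
    geno = rng.binomial(2, pop_freqs[pop_index, :]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = np.nan

    sample_ids = [
        f"{pop}_{i + 1}"
        for pop, n in zip(config.pop_names, config.n_ind_per_pop)
        for i in range(n)
    ]
    # loci are spread over unigenes, 5 SNPs per unigene, 200 bp apart
    per_unigene = 5
    unigenes = np.array(
        [f"UN{j // per_unigene + 1:05d}" for j in range(config.n_loci)], dtype=object
    )
    positions = np.array(
        [200 * (j % per_unigene) + 100 for j in range(config.n_loci)], dtype=int
    )
    G = GenotypeMatrix(geno, sample_ids, unigenes, positions)
    truth = SimTruth(
        ancestral_freqs=p_anc,
        pop_freqs=pop_freqs,
        adaptive_loci=adaptive,
        adaptive_env_var=adaptive_var,
        pop_membership=membership,
    )
    return G, truth


def simulate_expression(
    pop_membership: np.ndarray,
    config: SimConfig,
    diversity: np.ndarray | None = None,
    coupling: float = 0.0,
) -> ExpressionMatrix:
    """FPKM expression matrix with population structure.

    On the log2(FPKM+1) scale each value is
    ``gene baseline + population effect + individual noise`` with the two
    random effects drawn at SD ``expr_pop_sd`` and ``expr_ind_sd``; values
    are floored at 0 before back-transforming so FPKM >= 0.

    ``diversity`` (genes x populations, e.g. simulated per-unigene allelic
    diversity) with ``coupling`` > 0 plants a negative association between a
    gene's diversity and its within-population dispersion: the noise SD is
    scaled by exp(-coupling * standardized diversity), exercising the
    pi vs E_d correlation analysis.
    """
    pop_membership = np.asarray(pop_membership)
    pops = list(dict.fromkeys(pop_membership.tolist()))
    if len(pop_membership) == 0:
        raise ValueError("empty membership")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 19]))
    n_ind = len(pop_membership)
    G = config.n_genes
    baseline = rng.gamma(2.0, 1.2, G)  # right-skewed log2 baselines
    pop_eff = rng.normal(0.0, config.expr_pop_sd, (len(pops), G))
    sd = np.full((len(pops), G), float(config.expr_ind_sd))
    if diversity is not None and coupling != 0.0:
        div = np.asarray(diversity, dtype=float).T  # pops x genes
        if div.shape != sd.shape:
            raise ValueError("diversity must be genes x populations")
        z = (div - div.mean()) / (div.std() if div.std() > 0 else 1.0)
        sd = sd * np.exp(-coupling * z)
    pop_idx = np.array([pops.index(p) for p in pop_membership])
    x = (
        baseline[None, :]
        + pop_eff[pop_idx, :]
        + sd[pop_idx, :] * rng.standard_normal((n_ind, G))
    )
    x = np.maximum(x, 0.0)
    fpkm = np.exp2(x) - 1.0
    sample_ids = _expression_sample_ids(pop_membership)
    gene_ids = [f"UN{j + 1:05d}" for j in range(G)]
    return ExpressionMatrix(fpkm, sample_ids, gene_ids)


def _expression_sample_ids(pop_membership: np.ndarray) -> list[str]:
    counts: dict[str, int] = {}
    out = []
    for p in pop_membership:
        counts[p] = counts.get(p, 0) + 1
        out.append(f"{p}_{counts[p]}")
    return out


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None):
    """Generate a coherent dataset: coordinates, environment, genotypes,
    expression, and sample metadata.  If ``out_dir`` is given, writes
    genotypes.vcf, popmap.tsv, fpkm.tsv, env.tsv and truth.json there.

    Returns (GenotypeMatrix, SimTruth, ExpressionMatrix, env DataFrame,
    SampleMetadata).
    """
    coords = simulate_coordinates(config)
    env = simulate_environment(coords, config)
    G, truth = simulate_genotypes(config, env=env)
    E = simulate_expression(truth.pop_membership, config)
    rows = []
    for sample, pop in zip(G.sample_ids, truth.pop_membership):
        site = coords.loc[pop]
        rows.append(
            {
                "sample": sample,
                "population": pop,
                # groups: populations paired off, mirroring a regional grouping
                "group": f"G{config.pop_names.index(pop) // 3 + 1}",
                "lon": site["lon"],
                "lat": site["lat"],
                "altitude": site["altitude"],
            }
        )
    meta = SampleMetadata(pd.DataFrame(rows).set_index("sample"))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(G, out / "genotypes.vcf")
        write_sample_metadata(meta, out / "popmap.tsv")
        write_expression_tsv(E, out / "fpkm.tsv")
        env.rename_axis("site").to_csv(out / "env.tsv", sep="\t")
        truth.to_json(out / "truth.json")
    return G, truth, E, env, meta
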