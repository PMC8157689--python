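"""Core data containers and file IO.

The pipeline operates on four in-memory tables:

* :class:`GenotypeMatrix` — individuals x biallelic loci, genotypes coded as
  the count of alternate alleles (0/1/2) with NaN for missing calls.  Each
  locus carries the unigene (transcript contig) it sits on and its 1-based
  position within that unigene.
* :class:`SampleMetadata` — sample -> population -> group assignment plus the
  site coordinates (decimal degrees) and altitude.
* :class:`ExpressionMatrix` — individuals x unigenes, FPKM-scale or
  log2(FPKM+1)-scale values with NaN for masked entries.
* environment tables are plain :class:`pandas.DataFrame` objects
  (site/population rows x named variables).

VCF parsing goes through :mod:`cyvcf2`; writing uses a minimal GT-only
VCF 4.2 emitter so that simulated datasets round-trip.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "SampleMetadata",
    "ExpressionMatrix",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "exclude_extreme_expression_unigenes",
    "read_sample_metadata",
    "read_expression_tsv",
    "read_env_tsv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci; values in {0, 1, 2, NaN}."""

    genotypes: np.ndarray  # float array (n_individuals, n_loci)
    sample_ids: list[str]
    unigenes: np.ndarray  # str per locus
    positions: np.ndarray  # int per locus, 1-based (VCF convention)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.unigenes = np.asarray(self.unigenes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=int)
        n_ind, n_loci = self.genotypes.shape
        if len(self.sample_ids) != n_ind:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.unigenes) != n_loci or len(self.positions) != n_loci:
            raise ValueError("locus annotation length does not match columns")
        if np.any(self.positions < 0):
            raise ValueError("locus positions must be non-negative")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.genotypes) & ~np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("genotypes must be 0, 1, 2 or NaN")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [f"{u}:{p}" for u, p in zip(self.unigenes, self.positions)]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return ~np.isnan(self.genotypes)

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alt allele count, called gene-copy count) over ``rows``."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = ~np.isnan(g)
        alt = np.nansum(g, axis=0)
        copies = 2.0 * called.sum(axis=0)
        return alt, copies

    def allele_freqs(self, rows: np.ndarray | None = None) -> np.ndarray:
        alt, copies = self.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / copies, np.nan)

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.sample_ids),
            self.unigenes[idx],
            self.positions[idx],
        )

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[idx],
            [self.sample_ids[i] for i in idx],
            self.unigenes.copy(),
            self.positions.copy(),
        )


@dataclass
class SampleMetadata:
    """Sample -> population/group map plus per-population site information.

    ``table`` is indexed by sample id with columns ``population``, ``group``,
    ``lon``, ``lat``, ``altitude`` (coordinates repeat the population's single
    site on every one of its samples).
    """

    table: pd.DataFrame

    REQUIRED = ("population", "group", "lon", "lat", "altitude")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")

    def populations_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(sample_ids), "population"].to_numpy()

    def groups_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(sample_ids), "group"].to_numpy()

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def sites(self) -> pd.DataFrame:
        """One row per population: lon, lat, altitude (first sample's values)."""
        return (
            self.table.groupby("population", sort=False)[["lon", "lat", "altitude"]]
            .first()
        )

    def group_of(self) -> dict[str, str]:
        return dict(
            self.table.groupby("population", sort=False)["group"].first().items()
        )


@dataclass
class ExpressionMatrix:
    """Individuals x unigenes expression values (FPKM or log2(FPKM+1))."""

    values: np.ndarray  # float (n_individuals, n_genes), NaN = masked
    sample_ids: list[str]
    gene_ids: list[str]
    lengths: np.ndarray | None = None  # bp per unigene
    mapped_totals: np.ndarray | None = None  # reads per individual
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("expression matrix shape does not match labels")
        if not self.log_scale and np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("FPKM values must be non-negative")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=float)
            if np.any(self.lengths <= 0):
                raise ValueError("unigene lengths must be positive")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only biallelic SNP matrix from a VCF.

    Multiallelic records and non-SNP records (indels, MNPs) are dropped with a
    logged count.  ``./.`` becomes NaN; phased and unphased genotypes are
    treated identically.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    unigenes: list[str] = []
    positions: list[int] = []
    n_dropped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    remap = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        cols.append(remap[var.gt_types])
        unigenes.append(var.CHROM)
        positions.append(var.POS)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    geno = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=float)
    )
    G = GenotypeMatrix(geno, samples, np.array(unigenes, dtype=object), np.array(positions, dtype=int))
    G.n_dropped_records = n_dropped  # type: ignore[attr-defined]
    return G


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF 4.2 (REF=A, ALT=T placeholders)."""
    path = Path(path)
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    # contig lengths: max position per unigene (cyvcf2 warns without contigs)
    contig_len: dict[str, int] = {}
    for u, p in zip(G.unigenes, G.positions):
        contig_len[u] = max(contig_len.get(u, 0), int(p))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popadapt\n")
        for u, ln in contig_len.items():
            fh.write(f"##contig=<ID={u},length={ln + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j in range(G.n_loci):
            gts = [
                gt_codes.get(g, "./.") if not np.isnan(g) else "./."
                for g in G.genotypes[:, j]
            ]
            fh.write(
                f"{G.unigenes[j]}\t{G.positions[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_snps(
    G: GenotypeMatrix,
    min_maf: float = 0.05,
    min_call_rate: float = 0.5,
) -> GenotypeMatrix:
    """Locus filter: call rate strictly > ``min_call_rate``, minor allele
    frequency strictly > ``min_maf`` (computed on called alleles), and
    monomorphic loci removed.

    Read-depth screening belongs to the upstream variant caller and is not
    re-applied here.
    """
    called = G.called()
    call_rate = called.mean(axis=0)
    alt, copies = G.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(copies > 0, alt / copies, np.nan)
    maf = np.fmin(p, 1.0 - p)
    keep = (call_rate > min_call_rate) & (maf > min_maf) & (maf > 0)
    keep &= ~np.isnan(maf)
    n_removed = int(G.n_loci - keep.sum())
    if n_removed:
        logger.info("filter_snps: removed %d of %d loci", n_removed, G.n_loci)
    if not keep.any():
        warnings.warn("filter_snps: no loci survived filtering", stacklevel=2)
    return G.take_loci(np.flatnonzero(keep))


def exclude_extreme_expression_unigenes(
    G: GenotypeMatrix, retained_unigenes: Iterable[str]
) -> GenotypeMatrix:
    """Drop SNPs sitting on unigenes outside the retained (expression-filtered)
    set, keeping the SNP and expression analyses on one unigene universe."""
    retained = set(retained_unigenes)
    keep = np.array([u in retained for u in G.unigenes], dtype=bool)
    if not keep.any():
        warnings.warn(
            "exclude_extreme_expression_unigenes: no loci retained", stacklevel=2
        )
    return G.take_loci(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# TSV readers/writers
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample map TSV (sample, population, group, lon, lat, altitude)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    df = df.set_index("sample")
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.rename_axis("sample").to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, log_scale: bool = False) -> ExpressionMatrix:
    """Read an FPKM TSV laid out genes x samples (first column = unigene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        df.to_numpy().T,
        sample_ids=[str(c) for c in df.columns],
        gene_ids=[str(i) for i in df.index],
        log_scale=log_scale,
    )


def write_expression_tsv(E: ExpressionMatrix, path: str | Path) -> None:
    E.to_frame().T.rename_axis("unigene").to_csv(path, sep="\t")


def read_env_tsv(path: str | Path) -> pd.DataFrame:
    """Read the site x environmental-variable TSV (first column = site)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError("environment table contains non-finite values")
    return df
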