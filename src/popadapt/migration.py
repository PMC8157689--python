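"""Directional relative migration networks.

For every unordered population pair a hypothetical migrant pool is built
whose per-locus allele frequencies are the unweighted mean of the two
populations'.  Differentiation between each population and the pool is then
measured with a two-deme statistic (G_ST, Jost's D, or Nm), and the
gene-flow-INTO-a-population score is the Nm-form (or reciprocal
differentiation) of that population-vs-pool comparison: a population close
to the migrant pool is one receiving many migrants.  All directed scores
are divided by the global maximum, so the strongest edge is 1; bootstrap
confidence intervals resample individuals within populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["MigrationNetwork", "directional_relative_migration", "MEASURES"]

MEASURES = ("GST", "JostD", "Nm")
_EPS = 1e-6  # clamp for non-positive differentiation before reciprocals


@dataclass
class MigrationNetwork:
    edges: pd.DataFrame  # columns: from, to, measure, m_R, ci_low, ci_high
    measure: str
    normalization: float  # pre-normalization maximum directed score

    def matrix(self) -> pd.DataFrame:
        pops = sorted(set(self.edges["from"]) | set(self.edges["to"]))
        m = pd.DataFrame(np.nan, index=pops, columns=pops)
        for _, row in self.edges.iterrows():
            m.loc[row["from"], row["to"]] = row["m_R"]
        return m

    def to_dot(self) -> str:
        lines = ["digraph migration {"]
        for _, row in self.edges.iterrows():
            lines.append(
                f'  "{row["from"]}" -> "{row["to"]}" [label="{row["m_R"]:.2f}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def _pair_pool_differentiation(
    p_x: np.ndarray,
    c_x: np.ndarray,
    p_pool: np.ndarray,
    c_pool: np.ndarray,
    measure: str,
) -> float:
    """Two-deme differentiation between population X and the migrant pool,
    averaged over loci (H_S and H_T averaged first, then combined).

    Plain (uncorrected) heterozygosities are used on purpose: the pool is a
    deterministic average of the pair's sample frequencies, not an
    independent sample, so small-sample "unbiased" corrections systematically
    push H_S above H_T at the small per-population sizes this design has
    (5-12 diploids) and clamp every pair.  Uncorrected H_S <= H_T always
    holds here (Jensen), keeping GST >= 0 and rankings stable.
    """
    hs = 0.5 * (2.0 * p_x * (1.0 - p_x) + 2.0 * p_pool * (1.0 - p_pool))
    pbar = 0.5 * (p_x + p_pool)
    ht = 2.0 * pbar * (1.0 - pbar)
    ok = ~np.isnan(hs) & (ht > 0)
    if not ok.any():
        return np.nan
    HS, HT = float(np.mean(hs[ok])), float(np.mean(ht[ok]))
    if HT <= 0:
        return np.nan
    gst = (HT - HS) / HT
    if measure == "GST":
        return gst
    if measure == "JostD":
        return 2.0 * (HT - HS) / (1.0 - HS) if HS < 1 else np.nan
    if measure == "Nm":
        g = max(gst, _EPS)
        return 0.25 * (1.0 / g - 1.0)
    raise ValueError(f"unknown measure {measure!r}")


def _directed_scores(
    G: GenotypeMatrix, pops: np.ndarray, names: list[str], measure: str
) -> dict[tuple[str, str], float]:
    """Raw (un-normalized) directed gene-flow scores for all ordered pairs."""
    pops = np.asarray(pops)
    freqs, copies = {}, {}
    for name in names:
        rows = np.flatnonzero(pops == name)
        alt, cop = G.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[name] = np.where(cop > 0, alt / cop, np.nan)
        copies[name] = cop
    scores: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p_pool = 0.5 * (freqs[a] + freqs[b])
            c_pool = copies[a] + copies[b]
            poly = (
                ~np.isnan(p_pool) & (p_pool > 0) & (p_pool < 1)
            )
            if not poly.any():
                scores[(b, a)] = np.nan
                scores[(a, b)] = np.nan
                continue
            for target, other in ((a, b), (b, a)):
                d = _pair_pool_differentiation(
                    freqs[target][poly],
                    copies[target][poly],
                    p_pool[poly],
                    c_pool[poly],
                    measure,
                )
                if measure == "Nm":
                    flow = d
                else:
                    if not np.isnan(d) and d <= 0:
                        logger.debug("clamping non-positive %s to %g", measure, _EPS)
                    flow = np.nan if np.isnan(d) else 1.0 / max(d, _EPS)
                # edge other -> target: gene flow into the target population
                scores[(other, target)] = flow
    return scores


def directional_relative_migration(
    G: GenotypeMatrix,
    pops: np.ndarray,
    measure: str = "Nm",
    n_boot: int = 1000,
    seed: int | None = None,
    neutral_loci: np.ndarray | None = None,
) -> MigrationNetwork:
    """Directional relative migration rates m_R among populations.

    ``neutral_loci`` optionally restricts the computation to a putatively
    neutral locus subset (e.g. outliers removed).  Bootstrap CIs (95%,
    percentile) resample individuals within populations ``n_boot`` times.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    pops = np.asarray(pops)
    names = list(dict.fromkeys(pops.tolist()))
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    if neutral_loci is not None:
        G = G.take_loci(np.asarray(neutral_loci))

    raw = _directed_scores(G, pops, names, measure)
    finite = [v for v in raw.values() if np.isfinite(v)]
    if not finite:
        raise ValueError("all pairs monomorphic: migration undefined")
    norm = max(finite)
    rel = {k: (v / norm if np.isfinite(v) else np.nan) for k, v in raw.items()}

    ci: dict[tuple[str, str], tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots: dict[tuple[str, str], list[float]] = {k: [] for k in raw}
        blocks = {p: np.flatnonzero(pops == p) for p in names}
        for _ in range(n_boot):
            rows = np.concatenate(
                [rng.choice(blocks[p], size=len(blocks[p]), replace=True) for p in names]
            )
            Gb = G.take_samples(rows)
            labels = pops[rows]
            raw_b = _directed_scores(Gb, labels, names, measure)
            fin = [v for v in raw_b.values() if np.isfinite(v)]
            if not fin:
                continue
            nb = max(fin)
            for k, v in raw_b.items():
                if np.isfinite(v):
                    boots[k].append(v / nb)
        for k, vals in boots.items():
            if vals:
                ci[k] = tuple(np.percentile(vals, [2.5, 97.5]))
            else:
                ci[k] = (np.nan, np.nan)

    rows_out = []
    for (src, dst), v in rel.items():
        lo, hi = ci.get((src, dst), (np.nan, np.nan))
        rows_out.append(
            {"from": src, "to": dst, "measure": measure, "m_R": v, "ci_low": lo, "ci_high": hi}
        )
    return MigrationNetwork(pd.DataFrame(rows_out), measure, norm)
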