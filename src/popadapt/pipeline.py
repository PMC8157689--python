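"""End-to-end pipeline orchestration.

``run_pipeline`` executes the enabled stages in methods order — SNP/sample
filters, diversity + AMOVA + PCA, expression summaries, directional
migration, selection scans, environment associations — each consuming the
previous stage's in-memory outputs, and writes a machine-readable JSON
report plus per-stage TSVs.  A failed stage is recorded in the report
without destroying earlier outputs; stages depending on it refuse with an
error naming the missing artifact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import envassoc, expression, io, migration, popgen, selection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_STAGES = ("filter", "popgen", "expression", "migration", "scan", "assoc")


@dataclass
class RunConfig:
    """Inputs, stage toggles and stage parameters for one pipeline run."""

    vcf: str
    popmap: str
    out_dir: str
    fpkm: str | None = None
    env: str | None = None
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    min_maf: float = 0.05
    min_call_rate: float = 0.5
    n_perm: int = 199
    n_boot: int = 199
    migration_measure: str = "Nm"
    bayescan_iters: int = 2000
    bayescan_burn: int = 800
    lfmm_k: int = 4
    lfmm_reps: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)

    def validate(self) -> None:
        for p in (self.vcf, self.popmap, self.fpkm, self.env):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns (and writes) the JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "stages": {},
    }
    seed = int(config.seed)

    G = io.read_vcf(config.vcf)
    meta = io.read_sample_metadata(config.popmap)
    pops = meta.populations_for(G.sample_ids)
    E_log = None
    retained = None

    def need(stage: str):
        if stage not in report["stages"] or "error" in report["stages"][stage]:
            raise RuntimeError(
                f"stage depends on missing artifact: output of stage {stage!r}"
            )

    # ---- filter ---------------------------------------------------------
    if "filter" in config.stages:
        try:
            n0 = G.n_loci
            G = io.filter_snps(G, config.min_maf, config.min_call_rate)
            report["stages"]["filter"] = {
                "n_loci_in": n0,
                "n_loci_out": G.n_loci,
                "min_maf": config.min_maf,
                "min_call_rate": config.min_call_rate,
            }
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("filter stage failed")
            report["stages"]["filter"] = {"error": str(exc)}

    # ---- expression (before popgen's unigene harmonization is optional) -
    if "expression" in config.stages and config.fpkm is not None:
        try:
            E = io.read_expression_tsv(config.fpkm)
            E_log, retained = expression.filter_expression(E)
            epops = meta.populations_for(E_log.sample_ids)
            summ = expression.expression_summary(E_log, epops)
            summ.ep.to_csv(out / "ep.tsv", sep="\t")
            summ.ed.to_csv(out / "ed.tsv", sep="\t")
            report["stages"]["expression"] = {
                "n_unigenes_retained": len(retained),
                "ep_means": summ.ep_means,
                "ed_means": summ.ed_means,
            }
        except Exception as exc:
            logger.exception("expression stage failed")
            report["stages"]["expression"] = {"error": str(exc)}

    # ---- popgen ---------------------------------------------------------
    if "popgen" in config.stages:
        try:
            pi = popgen.nucleotide_diversity(G, pops)
            het = popgen.heterozygosities(G, pops)
            am = popgen.amova(G, pops, n_perm=config.n_perm, seed=seed + 1)
            scores, fracs = popgen.pca(G, n_components=4)
            div = het.table.copy()
            div["pi"] = pi
            div.rename_axis("population").to_csv(out / "diversity.tsv", sep="\t")
            am.as_frame().rename_axis("source").to_csv(out / "amova.tsv", sep="\t")
            report["stages"]["popgen"] = {
                "pi": pi,
                "diversity": {
                    p: dict(row) for p, row in het.table.iterrows()
                },
                "amova": {
                    "phi_st": am.phi_st,
                    "va": am.va,
                    "vb": am.vb,
                    "pct_among": am.pct_among,
                    "p_value": am.p_value,
                },
                "pca_variance_fractions": fracs,
                "seed": seed + 1,
            }
        except Exception as exc:
            logger.exception("popgen stage failed")
            report["stages"]["popgen"] = {"error": str(exc)}

    # ---- migration ------------------------------------------------------
    if "migration" in config.stages:
        try:
            net = migration.directional_relative_migration(
                G,
                pops,
                measure=config.migration_measure,
                n_boot=config.n_boot,
                seed=seed + 2,
            )
            net.edges.to_csv(out / "migration.tsv", sep="\t", index=False)
            (out / "migration.dot").write_text(net.to_dot())
            report["stages"]["migration"] = {
                "measure": net.measure,
                "normalization": net.normalization,
                "n_edges": len(net.edges),
                "seed": seed + 2,
            }
        except Exception as exc:
            logger.exception("migration stage failed")
            report["stages"]["migration"] = {"error": str(exc)}

    # ---- selection scans ------------------------------------------------
    if "scan" in config.stages:
        try:
            res = selection.bayescan_outliers(
                G,
                pops,
                n_iter=config.bayescan_iters,
                burn_in=config.bayescan_burn,
                seed=seed + 3,
            )
            res.table.to_csv(out / "outliers.tsv", sep="\t", index=False)
            n_out = int((res.table["classification"] != "neutral").sum())
            report["stages"]["scan"] = {
                "n_outliers": n_out,
                "n_diversifying": int(
                    (res.table["classification"] == "diversifying").sum()
                ),
                "converged": res.converged,
                "seed": seed + 3,
            }
            groups = meta.groups_for(G.sample_ids)
            gnames = list(dict.fromkeys(groups.tolist()))
            if len(gnames) >= 2:
                g2p = meta.group_of()
                focal = [p for p, g in g2p.items() if g == gnames[0]]
                background = [p for p, g in g2p.items() if g == gnames[1]]
                try:
                    sw = selection.sweep_scan(G, pops, focal, background)
                    sw.table.rename_axis("unigene").to_csv(
                        out / "sweep.tsv", sep="\t"
                    )
                    report["stages"]["scan"]["sweep_candidates"] = int(
                        sw.table["candidate"].sum()
                    )
                except ValueError as exc:
                    report["stages"]["scan"]["sweep_skipped"] = str(exc)
        except Exception as exc:
            logger.exception("scan stage failed")
            report["stages"]["scan"] = {"error": str(exc)}

    # ---- environment associations --------------------------------------
    if "assoc" in config.stages and config.env is not None:
        try:
            env = io.read_env_tsv(config.env)
            keep = envassoc.vif_prune(env)
            env_kept = env[keep]
            sites = meta.sites()
            mems = envassoc.dbmem(sites)
            # individual-level design: each sample inherits its site's values
            pop_of = pops
            env_ind = env_kept.loc[pop_of].to_numpy(dtype=float)
            geo_ind = mems.loc[pop_of].to_numpy(dtype=float)
            Y = envassoc.hellinger_transform(G)
            vp = envassoc.varpart(
                Y, env_ind, geo_ind, n_perm=config.n_perm, seed=seed + 4
            )
            lf = envassoc.lfmm(
                G,
                pd.DataFrame(env_ind, columns=keep),
                K=config.lfmm_k,
                n_repetitions=config.lfmm_reps,
                seed=seed + 5,
            )
            lf.p.rename_axis("locus").to_csv(out / "lfmm_p.tsv", sep="\t")
            geo_d, env_d = envassoc.ibd_ibe_distances(meta, env_kept)
            fst = popgen.pairwise_fst(G, pops, n_perm=0).theta
            order = list(geo_d.index)
            ibd = envassoc.mantel(
                fst.loc[order, order], geo_d, n_perm=config.n_perm, seed=seed + 6
            )
            ibe = envassoc.mantel(
                fst.loc[order, order], env_d, n_perm=config.n_perm, seed=seed + 7
            )
            report["stages"]["assoc"] = {
                "vif_retained": keep,
                "n_dbmem": mems.shape[1],
                "varpart": vp.fractions()
                | {"adj_env": vp.adj_env, "adj_geo": vp.adj_geo, "adj_both": vp.adj_both},
                "lfmm_lambda": lf.lambda_gc,
                "lfmm_n_significant": int(lf.significant.to_numpy().sum()),
                "ibd": {"r": ibd.r, "p": ibd.p},
                "ibe": {"r": ibe.r, "p": ibe.p},
                "seeds": [seed + 4, seed + 5, seed + 6, seed + 7],
            }
        except Exception as exc:
            logger.exception("assoc stage failed")
            report["stages"]["assoc"] = {"error": str(exc)}

    report_json = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(report_json)
    return report
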