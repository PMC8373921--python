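"""Pipeline orchestration and summaries of external clustering runs.

`run_pipeline` executes the analysis sequence of a fragmented-population
microsatellite survey — clone screen, marker QC, diversity, F-statistics
and structure, identity disequilibrium/selfing, and (optionally) effective
size and isolation-by-distance dispersal — from a single YAML-serializable
configuration, writing CSV/JSON reports with every threshold and seed
logged.

`evanno_deltak` condenses a table of clustering log-likelihoods (K,
replicate, lnP) produced by any external engine into the second-difference
statistic used to pick the number of clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, dispersal, fstats, hwe_ld, qc, selfing
from .genotypes import (GenotypeTable, SiteHierarchy, filter_min_loci,
                        load_site_metadata, read_genepop, read_long_csv)
from .simulate import SimulationConfig, simulate_hierarchical_fmodel

logger = logging.getLogger("msatpop")

__all__ = ["PipelineConfig", "evanno_deltak", "run_pipeline"]


def evanno_deltak(table: pd.DataFrame) -> pd.DataFrame:
    """Evanno second-order rate of change of the clustering likelihood.

    Input columns: ``K``, ``replicate``, ``lnP``.  For each interior K with
    across-replicate sd > 0,
    ``deltaK = |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / sd(lnP(K))``;
    endpoints and sd = 0 rows carry NaN.
    """
    required = {"K", "replicate", "lnP"}
    if not required.issubset(table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    grp = table.groupby("K")["lnP"]
    if (grp.count() < 2).any():
        raise ValueError("need >= 2 replicates per K")
    ks = np.array(sorted(grp.groups))
    if len(ks) < 3:
        raise ValueError("need >= 3 distinct K values")
    mean = grp.mean().reindex(ks).to_numpy()
    sd = grp.std(ddof=1).reindex(ks).to_numpy()
    dk = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd[i] > 0:
            dk[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd[i]
    return pd.DataFrame({"K": ks, "mean_lnP": mean, "sd_lnP": sd, "deltaK": dk})


@dataclass
class PipelineConfig:
    """Inputs, stage toggles, seeds and thresholds for a full run."""

    genotypes: str | None = None          # genepop (.gen) or long CSV (.csv)
    metadata: str | None = None           # site,sea,basin,lat,lon CSV
    simulate: dict | None = None          # SimulationConfig fields instead
    output_dir: str = "msatpop_out"
    allele_digits: int = 3
    min_loci: int = 6
    pi_threshold: float = 1.8e-5
    min_shared_loci: int = 6
    rarefaction_g: int = 5
    alpha: float = 0.05
    motif_len: int = 2
    pcrit: float = 0.05
    n_perm: int = 10000
    n_boot: int = 5000
    g2_iterations: int = 1000
    seed: int = 0
    run_ld_pairs: bool = True
    run_ne_ibd: bool = True
    genetic_distance: str = "chord"       # chord | theta

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _load_inputs(cfg: PipelineConfig) -> tuple[GenotypeTable, SiteHierarchy]:
    if cfg.simulate is not None:
        sim = SimulationConfig(**cfg.simulate)
        table, hier, _ = simulate_hierarchical_fmodel(sim)
        return table, hier
    if cfg.genotypes is None or cfg.metadata is None:
        raise ValueError("config needs either simulate: or genotypes:+metadata:")
    path = Path(cfg.genotypes)
    table = (read_long_csv(path) if path.suffix.lower() == ".csv"
             else read_genepop(path, cfg.allele_digits))
    return table, load_site_metadata(cfg.metadata)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage in order and write the report bundle.

    Returns a summary dict (also dumped as ``summary.json``); any stage
    failure raises with the stage name in the message.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    summary: dict = {"config": asdict(cfg)}
    rng_seed = cfg.seed

    def stage(name):
        logger.info("--- stage: %s", name)

    try:
        stage("load")
        table, hierarchy = _load_inputs(cfg)
        summary["n_individuals_raw"] = table.n_individuals
        summary["n_loci"] = table.n_loci

        stage("filter")
        table, removed = filter_min_loci(table, cfg.min_loci)
        logger.info("min_loci=%d removed %d individuals", cfg.min_loci, removed)
        summary["removed_min_loci"] = removed

        stage("clones")
        report = diversity.find_clones(table, cfg.min_shared_loci, cfg.pi_threshold)
        table = diversity.keep_unique_genotypes(table, report)
        summary["clone_groups"] = len(report.groups)
        summary["n_individuals"] = table.n_individuals

        stage("diversity")
        div = diversity.diversity_stats(table, hierarchy, cfg.rarefaction_g)
        div.per_site.to_csv(out / "diversity_per_site.csv")

        stage("fstats")
        est = fstats.resampling_cis(table, n_boot=cfg.n_boot, seed=rng_seed,
                                    n_perm=min(cfg.n_perm, 200))
        est.per_locus.to_csv(out / "fstats_per_locus.csv", index=False)
        summary["f"] = est.f
        summary["theta"] = est.theta
        summary["ci_theta"] = list(est.ci_theta)

        stage("qc")
        qrep = qc.locus_qc(table, motif_len=cfg.motif_len)
        qrep.per_locus.to_csv(out / "locus_qc.csv", index=False)
        key = qc.determination_key(table, est, qrep, alpha=cfg.alpha)
        summary["determination_flags"] = key.flags

        stage("structure")
        ena = fstats.ena_corrected_fst(table, n_boot=cfg.n_boot, seed=rng_seed)
        summary["fst_ena"] = ena.fst_ena_global
        summary["ci_fst_ena"] = list(ena.ci_ena)
        chord = fstats.chord_distance(table)
        chord.to_csv(out / "chord_distance.csv")

        stage("inbreeding")
        g2_rows = []
        sarr = np.asarray(table.sites)
        for site in table.site_labels():
            sub = table.subset(sarr == site)
            try:
                g2 = selfing.g2_estimate(sub, n_iter=cfg.g2_iterations,
                                         seed=rng_seed)
                fit = selfing.selfing_ml(sub)
                g2_rows.append({"site": site, "g2": g2.g2, "sd": g2.sd,
                                "p": g2.p, "s_hat": fit.s_hat,
                                "delta_dev": fit.delta_dev, "p_selfing": fit.p})
            except ValueError as exc:
                g2_rows.append({"site": site, "error": str(exc)})
        pd.DataFrame(g2_rows).to_csv(out / "inbreeding_selfing.csv", index=False)

        if cfg.run_ne_ibd:
            stage("ne_ibd")
            ne = dispersal.ld_ne(table, pcrit=cfg.pcrit, seed=rng_seed)
            summary["ne"] = None if np.isinf(ne.ne) else ne.ne
            geo = dispersal.geo_distances(hierarchy)
            gen = (chord if cfg.genetic_distance == "chord"
                   else fstats.pairwise_fst(table, n_perm=0).theta)
            try:
                fit = dispersal.ibd_fit(gen, geo, n_perm=min(cfg.n_perm, 2000),
                                        seed=rng_seed)
                summary["ibd_slope"] = fit.slope
                summary["ibd_p"] = fit.mantel_p
                if fit.slope > 0 and summary.get("ne"):
                    chain = dispersal.dispersal_chain(
                        fit.slope, Ne=ne.ne, K_range=(10, 100),
                        area_km2=138000.0)
                    summary["dispersal"] = {
                        "nb": chain.nb, "nem": chain.nem,
                        "delta_m": list(chain.delta_m)}
            except ValueError as exc:
                summary["ibd_error"] = str(exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
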