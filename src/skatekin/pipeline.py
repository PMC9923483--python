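"""End-to-end workflow: simulate -> QC -> kin -> CKMR -> Ne -> CPUE.

Each stage writes its artifacts (plus a manifest carrying the resolved
configuration and seed) under the run's output directory; the returned
report collects per-stage counts, mirroring a QC summary table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ckmr, kin, popgen, qc, survey
from .config import RunConfig
from .growth import age_from_length, assign_cohort
from .io import write_genotypes, write_manifest
from .matrix import GenotypeMatrix
from .simulate import simulate_dataset

log = logging.getLogger("skatekin")


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def run_pipeline(config: RunConfig,
                 genotypes: GenotypeMatrix | None = None,
                 metadata: pd.DataFrame | None = None,
                 effort: pd.DataFrame | None = None) -> dict:
    """Run every stage on provided data, simulating any that is missing."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    s_sim, s_qc, s_kin, s_ckmr = _seeds(config.seed, 4)
    report: dict = {"seed": config.seed}

    truth = None
    if genotypes is None or metadata is None:
        sim_cfg = config.simulate
        sim_cfg.seed = s_sim
        ds = simulate_dataset(sim_cfg)
        genotypes, metadata, effort, truth = (ds.genotypes, ds.metadata,
                                              ds.effort, ds.truth)
        write_genotypes(genotypes, out / "genotypes.csv")
        metadata.to_csv(out / "metadata.csv", index=False)
        truth.to_csv(out / "kin_truth.csv", index=False)
        log.info("simulated %d samples x %d loci", genotypes.n_samples,
                 genotypes.n_loci)

    # QC
    p = config.qc
    gm, qc_report = qc.qc_pipeline(
        genotypes, call_rate=p.call_rate, min_maf=p.min_maf,
        hwe_alpha=p.hwe_alpha, hwe_n_perm=p.hwe_n_perm,
        ld_r2_max=p.ld_r2_max, dup_mismatch=p.dup_mismatch, seed=s_qc)
    report["qc"] = qc_report
    write_genotypes(gm, out / "genotypes_qc.csv")
    log.info("QC: %d samples x %d loci retained", gm.n_samples, gm.n_loci)

    # kin classification
    k = config.kin
    n_comp = kin.n_pairs(gm.n_samples)
    thresholds, calib_info = kin.calibrate_thresholds(
        gm.allele_freq(), n_comp, error_rate=k.error_rate,
        n_sim=k.n_sim, target_expected_fp=k.target_expected_fp, rng=s_kin)
    meta = metadata[metadata["id"].isin(gm.samples)].reset_index(drop=True)
    kin_table = kin.classify_pairs(gm, thresholds, metadata=meta,
                                   error_rate=k.error_rate)
    kin_table.to_csv(out / "kin_pairs.csv", index=False)
    report["kin"] = {"n_comparisons": n_comp,
                     "threshold_hs_u": thresholds.hs_u,
                     "n_hs": int((kin_table["category"] == "HS").sum()),
                     "n_fs": int((kin_table["category"] == "FS").sum()),
                     "n_fc": int((kin_table["category"] == "FC").sum())}
    log.info("kin: %s", report["kin"])

    # age assignment and CKMR
    c = config.ckmr
    meta = meta.copy()
    meta["age_est"] = [age_from_length(min(L, 148.99)) for L in meta["length"]]
    meta["birth_year"] = [assign_cohort(y, a)
                          for y, a in zip(meta["year"], meta["age_est"])]
    counts = ckmr.build_comparisons(meta, kin_table, age_cap=c.age_cap)
    chain = ckmr.run_mh(
        counts, ckmr.Priors(n0_bounds=tuple(c.n0_prior)),
        ckmr.MCMCConfig(iterations=c.iterations, thin=c.thin,
                        burnin=c.burnin), seed=s_ckmr)
    chain.draws.to_csv(out / "chain.csv", index=False)
    years = range(int(meta["birth_year"].min()), int(meta["year"].max()) + 1)
    summary = ckmr.summarize_posterior(chain, years)
    summary.to_csv(out / "posterior_summary.csv", index=False)
    report["ckmr"] = {"n_comparisons": counts.total_comparisons,
                      "n_hsp": counts.total_hsp, "year0": counts.year0,
                      "acceptance": chain.acceptance, "ess": chain.ess}
    log.info("ckmr: %s", report["ckmr"])

    # diversity and Ne
    n = config.ne
    grouping = meta.set_index("id")["year"] if n.group_by_year else None
    div = popgen.diversity(gm, grouping)
    div.to_csv(out / "diversity.csv", index=False)
    ne_res = popgen.ld_ne(gm, crit_maf=n.crit_maf)
    report["ne"] = {"ne": ne_res.ne, "ci": ne_res.ci,
                    "mean_r2": ne_res.mean_r2, "warnings": ne_res.warnings}
    log.info("ne: %.1f (CI %s)", ne_res.ne, ne_res.ci)

    # CPUE and kin spatial analysis
    if effort is not None:
        records = [survey.EffortRecord(r.station, r.year, r.net_length_km,
                                       r.soak_time_h, tuple(r.lengths_cm))
                   for r in effort.itertuples()]
        prime = set(config.cpue.prime_stations) or None
        cpue_df = survey.annual_summary(records, prime)
        cpue_df.to_csv(out / "cpue.csv", index=False)
        report["cpue"] = {"years": sorted(cpue_df["year"].unique().tolist())}
    if {"lat", "lon"}.issubset(meta.columns) and len(kin_table):
        sibs = kin_table[kin_table["category"].isin(["HS", "FS"])]
        if len(sibs) >= 2:
            pos = meta.set_index("id")
            iu, ju = np.triu_indices(len(meta), k=1)
            all_d = survey.haversine_km(
                pos["lat"].to_numpy()[iu], pos["lon"].to_numpy()[iu],
                pos["lat"].to_numpy()[ju], pos["lon"].to_numpy()[ju])
            kin_d = sibs["distance_km"].to_numpy()
            report["kin_proximity"] = survey.kin_proximity_test(
                kin_d, all_d, n_perm=config.cpue.ks_n_perm, rng=config.seed)

    write_manifest(out / "manifest.json", config=config.to_dict(),
                   report=report)
    return report
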