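"""End-to-end pipeline: filter -> impute -> kinship -> means/H2 -> spatial
-> GWAS -> genomic-prediction CV -> calibration optimization.

Each stage writes TSV results under the output directory; a JSON manifest
records the resolved configuration, its hash, and the seeds used, so any
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from poolgp import calibopt, gpredict, grm, gwas, phenostats, spatialstats
from poolgp.dataio import (
    PipelineConfig,
    read_frequencies,
    read_panel,
    read_phenotypes,
    write_frequencies,
)

logger = logging.getLogger("poolgp")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages in order and write results to *out_dir*.

    Returns the manifest dict (also written as ``manifest.json``).
    Requires ``frequencies`` and ``phenotypes`` paths in the config;
    ``panel`` (coordinates) enables the spatial and geography-aware
    stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.params
    cfg_hash = config.hash()
    manifest: dict = {"config": {k: v for k, v in cfg.items()}, "config_hash": cfg_hash, "stages": []}
    seed = int(cfg["seed"])

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s done: %s", stage, info)

    def fail(stage: str, exc: Exception):
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------------ load
    try:
        if not cfg["frequencies"] or not cfg["phenotypes"]:
            raise FileNotFoundError("config must set 'frequencies' and 'phenotypes' paths")
        freqs = read_frequencies(cfg["frequencies"])
        records = read_phenotypes(cfg["phenotypes"])
        panel = read_panel(cfg["panel"]) if cfg["panel"] else None
        clusters = None
        if cfg["clusters"]:
            cl = pd.read_csv(cfg["clusters"], sep="\t", dtype=str)
            clusters = cl.set_index("pop_id")["cluster"].reindex(freqs.pop_ids).tolist()
    except StageError:
        raise
    except Exception as exc:
        fail("load", exc)

    # ---------------------------------------------------------------- filter
    try:
        kept = grm.filter_markers(freqs, maf_min=cfg["maf_min"], min_pops=cfg["maf_min_pops"])
        write_frequencies(kept, out / "frequencies_filtered.tsv")
        pd.DataFrame(
            {
                "marker": freqs.marker_ids,
                "kept": [m in set(kept.marker_ids) for m in freqs.marker_ids],
                "config_hash": cfg_hash,
            }
        ).to_csv(out / "marker_filter_report.tsv", sep="\t", index=False)
        record("filter", markers_in=freqs.n_markers, markers_kept=kept.n_markers)
    except Exception as exc:
        fail("filter", exc)

    # ---------------------------------------------------------------- impute
    try:
        imputed = grm.impute_missing(kept)
        record("impute", imputed_cells=int(np.isnan(kept.values).sum()))
    except Exception as exc:
        fail("impute", exc)

    # --------------------------------------------------------------- kinship
    try:
        Gmat = grm.kinship(imputed)
        gdf = pd.DataFrame(Gmat.G, index=Gmat.pop_ids, columns=Gmat.pop_ids)
        gdf.index.name = "pop_id"
        gdf.to_csv(out / "kinship.tsv", sep="\t", float_format="%.8g")
        record("kinship", K=Gmat.K)
    except Exception as exc:
        fail("kinship", exc)

    # ----------------------------------------------------------- means / H2
    try:
        means_rows, h2_rows, per_trait_means = [], [], {}
        for trait in records.traits:
            sub = records.for_trait(trait)
            envs = sorted(sub["env"].unique())
            fits = []
            for env in envs:
                fit1 = phenostats.fit_model1(records, trait, env)
                fits.append(fit1)
                am = phenostats.adjusted_means(fit1)
                h2_rows.append(
                    {
                        "trait": trait,
                        "scope": env,
                        "model": 1,
                        "H2": phenostats.heritability(fit1),
                        "F": fit1.f_statistic,
                        "p": fit1.p_value,
                        "config_hash": cfg_hash,
                    }
                )
                for pop, v in am.values.items():
                    means_rows.append({"trait": am.trait, "scope": env, "pop_id": pop, "mean": v})
            if len(envs) >= 2:
                fit2 = phenostats.fit_model2(records, trait)
                am = phenostats.adjusted_means(fit2)
                per_trait_means[trait] = am.values
                h2_rows.append(
                    {
                        "trait": trait,
                        "scope": "avg",
                        "model": 2,
                        "H2": phenostats.heritability(fit2),
                        "F": fit2.f_statistic,
                        "p": fit2.p_value,
                        "config_hash": cfg_hash,
                    }
                )
                for pop, v in am.values.items():
                    means_rows.append({"trait": am.trait, "scope": "avg", "pop_id": pop, "mean": v})
            else:
                per_trait_means[trait] = phenostats.adjusted_means(fits[0]).values
        pd.DataFrame(means_rows).to_csv(out / "adjusted_means.tsv", sep="\t", index=False, float_format="%.8g")
        pd.DataFrame(h2_rows).to_csv(out / "heritability.tsv", sep="\t", index=False, float_format="%.8g")
        record("means", traits=len(records.traits))
    except Exception as exc:
        fail("means", exc)

    # -------------------------------------------------------------- spatial
    if panel is not None:
        try:
            order = [panel.pop_ids.index(p) for p in imputed.pop_ids]
            import dataclasses

            panel = dataclasses.replace(
                panel,
                pop_ids=[panel.pop_ids[i] for i in order],
                lon=panel.lon[order],
                lat=panel.lat[order],
                is_cultivar=panel.is_cultivar[order],
            )
            D_geo = spatialstats.geo_distances(panel)
            D_gen = spatialstats.euclidean_distances(imputed.values, imputed.pop_ids)
            W = spatialstats.inverse_distance_weights(D_geo)
            sp_rows = []
            for trait, means in per_trait_means.items():
                vals = means.reindex(imputed.pop_ids).to_numpy()
                mi = spatialstats.morans_i(vals, W)
                D_phe = spatialstats.euclidean_distances(vals[:, None], imputed.pop_ids, units="euclidean-phenotypic")
                r_pg, p_pg = spatialstats.mantel(D_phe, D_geo, n_perm=cfg["n_mantel_perm"], seed=seed)
                r_pn, p_pn = spatialstats.mantel(D_phe, D_gen, n_perm=cfg["n_mantel_perm"], seed=seed)
                sp_rows.append(
                    {
                        "trait": trait,
                        "moran_I": mi.I,
                        "moran_p": mi.p_value,
                        "mantel_phe_geo_r": r_pg,
                        "mantel_phe_geo_p": p_pg,
                        "mantel_phe_gen_r": r_pn,
                        "mantel_phe_gen_p": p_pn,
                        "config_hash": cfg_hash,
                    }
                )
            r_gg, p_gg = spatialstats.mantel(D_gen, D_geo, n_perm=cfg["n_mantel_perm"], seed=seed)
            sp = pd.DataFrame(sp_rows)
            sp.attrs["mantel_gen_geo"] = (r_gg, p_gg)
            sp.to_csv(out / "spatial_stats.tsv", sep="\t", index=False, float_format="%.6g")
            pd.DataFrame(
                [{"pair": "genetic~geographic", "mantel_r": r_gg, "mantel_p": p_gg, "config_hash": cfg_hash}]
            ).to_csv(out / "mantel_genetic_geographic.tsv", sep="\t", index=False, float_format="%.6g")
            record("spatial", mantel_gen_geo_r=r_gg)
        except Exception as exc:
            fail("spatial", exc)

    # ----------------------------------------------------------------- gwas
    try:
        gwas_frames = []
        for trait, means in per_trait_means.items():
            yv = means.reindex(imputed.pop_ids).to_numpy()
            res = gwas.run_gwas(
                yv,
                imputed,
                model=cfg["gwas_model"],
                G=Gmat if "kinship" in cfg["gwas_model"] else None,
                clusters=clusters,
            )
            tab = res.table.copy()
            tab.insert(0, "trait", trait)
            tab["config_hash"] = cfg_hash
            gwas_frames.append(tab)
        pd.concat(gwas_frames).to_csv(out / "gwas.tsv", sep="\t", index=False, float_format="%.6g")
        record("gwas", traits=len(gwas_frames), model=cfg["gwas_model"])
    except Exception as exc:
        fail("gwas", exc)

    # ---------------------------------------------------------------- gp-cv
    try:
        cv_rows = []
        for trait, means in per_trait_means.items():
            yv = means.reindex(imputed.pop_ids).to_numpy()
            holdout = min(cfg["cv_holdout"], imputed.n_pops // 3)
            rep = gpredict.cross_validate(
                imputed, yv, n_repeats=cfg["n_cv_repeats"], holdout=holdout, seed=seed
            )
            cv_rows.append(
                {
                    "trait": trait,
                    "mean_pa": rep.mean,
                    "sd_pa": rep.sd,
                    "n_repeats": rep.n_repeats,
                    "holdout": rep.holdout,
                    "config_hash": cfg_hash,
                }
            )
        pd.DataFrame(cv_rows).to_csv(out / "gp_cv.tsv", sep="\t", index=False, float_format="%.6g")
        record("gp_cv", traits=len(cv_rows))
    except Exception as exc:
        fail("gp_cv", exc)

    # ----------------------------------------------------------- calibration
    try:
        k = min(cfg["calibration_k"], imputed.n_pops - 5)
        D_gen = spatialstats.euclidean_distances(imputed.values, imputed.pop_ids)
        cal_rows = []
        selections = {"genetic": calibopt.select_by_clustering(D_gen, k)}
        if panel is not None:
            D_geo = spatialstats.geo_distances(panel)
            selections["spatial"] = calibopt.select_by_clustering(D_geo, k)
            selections["clustgeo"] = calibopt.select_clustgeo(D_gen, D_geo, k, alpha=cfg["clustgeo_alpha"])
        selections["cdmean"] = calibopt.select_cdmean(Gmat, k, n_iter=cfg["cdmean_iters"], seed=seed)
        for trait, means in per_trait_means.items():
            yv = means.reindex(imputed.pop_ids).to_numpy()
            for name, sel in selections.items():
                score = calibopt.evaluate_calibration(imputed, yv, sel, n_random=100, seed=seed)
                cal_rows.append(
                    {
                        "trait": trait,
                        "method": name,
                        "k": sel.k,
                        "opt_pa": score.opt_pa,
                        "min_pa": score.min_pa,
                        "max_pa": score.max_pa,
                        "score": score.score,
                        "config_hash": cfg_hash,
                    }
                )
        pd.DataFrame(cal_rows).to_csv(out / "calibration.tsv", sep="\t", index=False, float_format="%.6g")
        record("calibration", methods=list(selections))
    except Exception as exc:
        fail("calibration", exc)

    manifest["seed"] = seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
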