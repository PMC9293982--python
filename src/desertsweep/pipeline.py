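"""End-to-end orchestration: QC → structure → scans → candidate sets →
expression association, driven by a single config mapping.

Every default the source protocol leaves unstated (ancestral policy, flank,
tails, standardization bins, cutoffs) is resolved here and recorded in the
run manifest, which is itself a valid config: feeding ``manifest.json``
back through :func:`run_all` reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import candidate_sets as cs
from . import popstruct, qc, sweep_stats
from . import expression as expr_mod
from .genotype_io import (
    GenotypeMatrix,
    read_gff,
    read_pop_map,
    read_vcf,
    to_haplotypes,
    write_newick,
    write_score_table,
)

logger = logging.getLogger("desertsweep.pipeline")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


DEFAULTS: dict[str, Any] = {
    "anc_policy": "major_allele",
    "qc": {"min_call_rate": 0.90, "min_maf": 0.05, "min_hwe_p": 1e-6},
    "ld": {"window_snps": 50, "step_snps": 10, "r2_max": 0.1},
    "ld_decay": {"max_dist_bp": 500_000, "bin_width_bp": 1_000},
    "sweep": {
        "ehh_cutoff": 0.05,
        "core_maf_min": 0.05,
        "freq_bins": 20,
        "min_bin_count": 10,
        "edge_policy": "discard",
        "standardize": "zscore",
    },
    "tails": {"ihs": "two_sided", "fst": "upper", "xpehh": "two_sided",
              "rsb": "two_sided"},
    "thresholds": [0.01, 0.05],
    "flank_bp": 50_000,
    "segs_fraction": 0.07,
    "cgs_rule": "union",
    "cgs_threshold": 0.01,
    "pca_components": 10,
    "seed": 0,
}


def _resolve(config: Mapping[str, Any]) -> dict[str, Any]:
    out = json.loads(json.dumps(DEFAULTS))  # deep copy
    for k, v in config.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _load_genotypes(cfg: dict[str, Any]) -> GenotypeMatrix:
    if "vcf" in cfg:
        if "pop_map" not in cfg:
            raise ConfigError("'vcf' input requires a 'pop_map' file")
        for key in ("vcf", "pop_map"):
            if not Path(cfg[key]).exists():
                raise ConfigError(f"input file not found: {cfg[key]}")
        return read_vcf(cfg["vcf"], read_pop_map(cfg["pop_map"]))
    raise ConfigError("config must name a 'vcf' input")


def _comparisons(cfg: dict[str, Any], g: GenotypeMatrix) -> list[dict[str, Any]]:
    comps = cfg.get("comparisons")
    if not comps:
        raise ConfigError("config must define 'comparisons'")
    known = set(g.pops)
    for comp in comps:
        for side in ("pop_a", "pop_b"):
            if side not in comp:
                raise ConfigError(f"comparison missing {side!r}")
            missing = set(comp[side]) - known
            if missing:
                raise ConfigError(
                    f"comparison references unknown population(s) {sorted(missing)}"
                )
    return comps


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_all(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Execute the full workflow; returns the results directory."""
    cfg = _resolve(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- load -------------------------------------------------------------
    t0 = _stage("load")
    g = _load_genotypes(cfg)
    comps = _comparisons(cfg, g)
    ihs_pops = cfg.get("ihs_pops") or [g.pops[0]]

    # ---- qc ---------------------------------------------------------------
    _stage("qc")
    thresholds = qc.QcThresholds(**cfg["qc"])
    g_qc, report = qc.apply_qc(g, thresholds)
    (out / "qc_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    if g_qc.n_snps == 0:
        raise DataError("qc: no SNPs survive filtering")

    # ---- structure --------------------------------------------------------
    _stage("structure")
    n_comp = min(cfg["pca_components"], g_qc.n_samples - 1, g_qc.n_snps)
    pca_res = popstruct.pca(g_qc, n_components=n_comp)
    pd.DataFrame(
        pca_res.coords,
        index=g_qc.samples,
        columns=[f"PC{i+1}" for i in range(n_comp)],
    ).to_csv(out / "pca_scores.tsv", sep="\t")
    dm = popstruct.p_distance_matrix(g_qc)
    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
        out / "p_distance.tsv", sep="\t"
    )
    tree = popstruct.neighbor_joining(dm)
    write_newick(tree, out / "nj_tree.nwk")

    retained = popstruct.ld_prune(g_qc, **cfg["ld"])
    pd.DataFrame({"snp_id": [g_qc.snps[i].id for i in retained]}).to_csv(
        out / "ld_pruned_snps.tsv", sep="\t", index=False
    )
    decay = popstruct.ld_decay(g_qc, **cfg["ld_decay"])
    rows = []
    for pop, means in decay.mean_r2.items():
        for b in range(len(means)):
            if decay.pair_counts[pop][b] > 0:
                rows.append(
                    {
                        "pop": pop,
                        "dist_lo": int(decay.bin_edges[b]),
                        "dist_hi": int(decay.bin_edges[b + 1]),
                        "mean_r2": means[b],
                        "n_pairs": int(decay.pair_counts[pop][b]),
                    }
                )
    pd.DataFrame(rows).to_csv(out / "ld_decay.tsv", sep="\t", index=False)

    # ---- scans ------------------------------------------------------------
    _stage("scans")
    sweep_cfg = sweep_stats.SweepConfig(**cfg["sweep"])
    try:
        haps = to_haplotypes(g_qc, anc_policy=cfg["anc_policy"])
    except ValueError as exc:
        raise DataError(f"scans: {exc}") from exc

    tables: dict[str, sweep_stats.ScoreTable] = {}
    focal = haps.subset_pops(ihs_pops)
    tables["ihs"] = sweep_stats.ihs(focal, sweep_cfg)
    for comp in comps:
        name = comp.get("name") or f"{'+'.join(comp['pop_a'])}_vs_{'+'.join(comp['pop_b'])}"
        rows_a = g_qc.sample_indices(comp["pop_a"])
        rows_b = g_qc.sample_indices(comp["pop_b"])
        tables[f"fst.{name}"] = sweep_stats.wc_fst(g_qc, rows_a, rows_b)
        haps_a = haps.subset_pops(comp["pop_a"])
        haps_b = haps.subset_pops(comp["pop_b"])
        ies_a, reach_a = sweep_stats.ies_scan(haps_a, sweep_cfg)
        ies_b, reach_b = sweep_stats.ies_scan(haps_b, sweep_cfg)
        shared = dict(ies_a=ies_a, reached_a=reach_a, ies_b=ies_b, reached_b=reach_b)
        tables[f"xpehh.{name}"] = sweep_stats.xpehh(haps_a, haps_b, sweep_cfg, **shared)
        tables[f"rsb.{name}"] = sweep_stats.rsb(haps_a, haps_b, sweep_cfg, **shared)

    for key, table in tables.items():
        stat = key.split(".")[0]
        cs.flag_significant(table, tail=cfg["tails"][stat])
        write_score_table(table, out / f"scores_{key}.tsv")

    # ---- candidate sets ---------------------------------------------------
    _stage("candidates")
    annotation = None
    if cfg.get("gff"):
        if not Path(cfg["gff"]).exists():
            raise ConfigError(f"annotation file not found: {cfg['gff']}")
        annotation = read_gff(cfg["gff"])

    gene_sets_by_threshold: dict[float, list[cs.GeneSet]] = {}
    if annotation is not None:
        for frac in cfg["thresholds"]:
            sets = []
            for key, table in tables.items():
                stat = key.split(".")[0]
                sel = cs.select_top(table, frac, tail=cfg["tails"][stat])
                sets.append(
                    cs.annotate_genes(
                        sorted(sel), table, annotation, cfg["flank_bp"],
                        name=key,
                        provenance=(stat, key, f"{frac:g}"),
                    )
                )
            gene_sets_by_threshold[frac] = sets
            rows = [
                {"gene_id": gid, "set": s.name, "statistic": s.provenance[0],
                 "threshold": s.provenance[2]}
                for s in sets
                for gid in sorted(s.gene_ids)
            ]
            pd.DataFrame(rows, columns=["gene_id", "set", "statistic", "threshold"]).to_csv(
                out / f"gene_sets_{frac:g}.tsv", sep="\t", index=False
            )
            upset = cs.intersect_sets(sets)
            urows = [
                {
                    **{n: int(m) for n, m in zip(upset.set_names, combo)},
                    "size": size,
                }
                for combo, size in sorted(upset.sizes.items(), reverse=True)
            ]
            pd.DataFrame(urows).to_csv(
                out / f"upset_{frac:g}.tsv", sep="\t", index=False
            )

        cgs_sets = gene_sets_by_threshold[cfg["cgs_threshold"]]
        cgs_set = cs.cgs(cgs_sets, rule=cfg["cgs_rule"])
        pd.DataFrame({"gene_id": sorted(cgs_set.gene_ids)}).to_csv(
            out / "cgs.tsv", sep="\t", index=False
        )
    else:
        cgs_set = None
        logger.warning("candidates: no annotation given, gene sets skipped")

    # ---- expression -------------------------------------------------------
    expr_cfg = cfg.get("expression") or {}
    matrix = _load_expression(expr_cfg)
    association = None
    if matrix is None:
        logger.warning("expression inputs absent: association stage skipped")
    else:
        _stage("expression")
        segs = expr_mod.build_segs(matrix, segs_fraction=cfg["segs_fraction"])
        rows = [
            {"stage": stage, "gene_id": gid, "t": segs.tstat[stage][k],
             "rank": int(segs.rank[stage][k]),
             "in_segs": int(gid in segs.members[stage])}
            for stage in segs.stages
            for k, gid in enumerate(segs.gene_ids)
        ]
        pd.DataFrame(rows).to_csv(out / "segs.tsv", sep="\t", index=False)
        if cgs_set is not None and cgs_set.gene_ids:
            inter, contrib = expr_mod.associate(cgs_set, segs)
            association = {
                "intersections": inter,
                "contributions": contrib,
            }
            (out / "association.json").write_text(
                json.dumps(association, indent=2, sort_keys=True) + "\n"
            )

    # ---- manifest ---------------------------------------------------------
    manifest = dict(cfg)
    manifest["n_snps_input"] = report.n_input
    manifest["n_snps_qc"] = g_qc.n_snps
    manifest["n_snps_pruned"] = len(retained)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return out


def _load_expression(expr_cfg: Mapping[str, Any]) -> expr_mod.ExpressionMatrix | None:
    if not expr_cfg:
        return None
    stages_path = expr_cfg.get("stages")
    if not stages_path or not Path(stages_path).exists():
        return None
    stages_df = pd.read_csv(stages_path, sep="\t")
    stage_of = dict(zip(stages_df.iloc[:, 0].astype(str), stages_df.iloc[:, 1]))

    if expr_cfg.get("fpkm") and Path(expr_cfg["fpkm"]).exists():
        df = pd.read_csv(expr_cfg["fpkm"], sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
    elif expr_cfg.get("counts") and Path(expr_cfg["counts"]).exists():
        lengths_path = expr_cfg.get("lengths")
        if not lengths_path or not Path(lengths_path).exists():
            raise ConfigError("'counts' expression input requires 'lengths'")
        df = pd.read_csv(expr_cfg["counts"], sep="\t", index_col=0)
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0].reindex(df.index)
        if lengths.isna().any():
            raise DataError("gene-length table does not cover the counts table")
        values = expr_mod.fpkm_from_counts(
            df.to_numpy(dtype=float), lengths.to_numpy(dtype=float)
        )
    else:
        return None
    missing = [s for s in df.columns if s not in stage_of]
    if missing:
        raise DataError(f"samples absent from the stage map: {missing}")
    return expr_mod.ExpressionMatrix(
        gene_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        stage_of_sample=[stage_of[str(c)] for c in df.columns],
        values=values,
    )
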