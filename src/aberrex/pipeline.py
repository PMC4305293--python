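"""End-to-end orchestration: simulate → QC → SSMD classification → outlier
calling → population diffSSMD → twin discordance → eSNP comparison →
private-SNP enrichment, with per-stage tables, parameter echo, and a seed
ledger.  Stages communicate via files in the configured working directory so
each is independently runnable and resumable.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io as fio
from . import population_diff, private_variants, ssmd, synthetic, twins
from . import esnp as esnp_mod
from ._rng import spawn
from .errors import ValidationError
from .robust_distance import call_outliers

logger = logging.getLogger("aberrex")

STAGES = (
    "simulate", "qc", "ssmd", "outliers", "diffssmd", "twins", "esnp",
    "private_snps",
)


@dataclass
class PipelineReport:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)


def outlier_matrix(
    calls: dict[str, list[str]], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Binary sample × set membership table of outlier calls.

    Row marginals give per-sample flag counts (distinct outliers = rows with
    any flag); column marginals give per-set outlier counts.
    """
    if not calls:
        return pd.DataFrame()
    if sample_ids is None:
        sample_ids = sorted({s for ss in calls.values() for s in ss})
    mat = pd.DataFrame(0, index=sample_ids, columns=sorted(calls), dtype=int)
    for set_name, samples in calls.items():
        for s in samples:
            mat.loc[s, set_name] = 1
    return mat.loc[mat.sum(axis=1) > 0]


def _workdir(config: fio.RunConfig) -> Path:
    wd = Path(config.paths.get("workdir", "."))
    wd.mkdir(parents=True, exist_ok=True)
    return wd


def _stage_simulate(config, report, wd):
    p = config.stage(
        "simulate",
        preset="benchmark",
        n_mz=40, n_dz=40, n_twin_genes=120, env_sensitive=30,
        chrom_size=40_000_000, gene_spacing=2_000_000,
        base_rate_per_mb=0.5, enhancer_multiplier=2.0,
        n_esnps=20, esnp_maf=0.3, esnp_beta=0.8,
    )
    seed = config.seed
    report.seeds["simulate"] = seed
    if p["preset"] == "benchmark":
        bench = synthetic.benchmark_preset(seed=seed)
    elif p["preset"] == "tiny":
        specs = (
            [synthetic.SetSpec(f"L_{k}", 6, kind="L", rho=0.9, n_outliers=4,
                               displacement=10.0) for k in range(3)]
            + [synthetic.SetSpec(f"S_{k}", 6, kind="S") for k in range(3)]
        )
        expr, coll, truth = synthetic.simulate_expression(
            populations=(("EUR", 90), ("AFR", 30)), sets=specs,
            n_background_genes=200, seed=seed,
        )
        for gs in synthetic.make_null_sets(expr, 6, 6, seed=seed):
            coll.add(gs)
        bench = {"expression": expr, "collection": coll, "truth": truth}
    else:
        raise ValidationError(f"unknown preset {p['preset']!r}")
    expr, coll, truth = bench["expression"], bench["collection"], bench["truth"]

    fio.write_expression(expr, wd / "expression.tsv")
    fio.write_population_labels(expr.population, wd / "population.tsv")
    fio.write_gmt(coll, wd / "sets.gmt")
    truth.to_json(wd / "truth.json")

    # genome coordinates for the planted set genes (for cis windows)
    chrom = "1"
    planted = [g for g in expr.gene_ids if not g.startswith("BG_")]
    coords = {}
    pos = 1_000_000
    for g in planted:
        coords[g] = (chrom, pos, "+")
        pos += p["gene_spacing"]
        if pos > p["chrom_size"] - 1_000_000:
            break
    pd.DataFrame(
        [(g, c, t, s) for g, (c, t, s) in coords.items()],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(wd / "genes.tsv", sep="\t", index=False)

    chrom_sizes = {chrom: p["chrom_size"]}
    seg = synthetic.make_segmentation(chrom_sizes, seed=seed)
    private_variants.write_bed(seg.intervals, wd / "segmentation.bed")

    outlier_map = {}
    for set_name, samples in truth.planted_outliers.items():
        genes = [g for g in coords if g.startswith(set_name + "_")]
        for s in samples:
            outlier_map.setdefault(s, [])
            outlier_map[s] = sorted(set(outlier_map[s]) | set(genes))
    esnp_genes = [g for g in coords if g.startswith("L_")][: p["n_esnps"]]
    gt, esnp_table, gt_truth = synthetic.simulate_genotypes(
        expr.sample_ids, coords, seg, chrom_sizes,
        outlier_genes=outlier_map,
        class_multipliers={"E": p["enhancer_multiplier"]},
        base_rate_per_mb=p["base_rate_per_mb"],
        esnp_spec=[(g, p["esnp_maf"], p["esnp_beta"]) for g in esnp_genes],
        seed=seed,
    )
    private_variants.write_vcf(gt, wd / "genotypes.vcf", chrom_sizes)
    esnp_table.to_csv(wd / "esnp.tsv", sep="\t", index=False)
    gt_truth.to_json(wd / "genotype_truth.json")

    cohort, twin_truth = synthetic.simulate_twins(
        n_mz=p["n_mz"], n_dz=p["n_dz"], n_genes=p["n_twin_genes"],
        env_sensitive_genes=p["env_sensitive"], seed=seed,
    )
    fio.write_expression(cohort.expression, wd / "twin_expression.tsv")
    with open(wd / "twin_pairs.tsv", "w") as fh:
        for a, b, z in cohort.pairs:
            fh.write(f"{a}\t{b}\t{z}\n")
    twin_truth.to_json(wd / "twin_truth.json")

    report.params["simulate"] = p
    report.outputs["simulate"] = str(wd)


def _load_expression(wd):
    return fio.read_expression(wd / "expression.tsv", wd / "population.tsv")


def _stage_qc(config, report, wd):
    p = config.stage("qc", n_components=2, sd_cutoff=4.0)
    expr = _load_expression(wd)
    kept, excluded = fio.pca_sample_qc(expr, p["n_components"], p["sd_cutoff"])
    fio.write_expression(kept, wd / "expression.qc.tsv")
    fio.write_population_labels(kept.population, wd / "population.qc.tsv")
    report.tables["qc_excluded"] = pd.DataFrame({"sample_id": excluded})
    report.params["qc"] = p


def _qc_expression(wd):
    if (wd / "expression.qc.tsv").exists():
        return fio.read_expression(wd / "expression.qc.tsv", wd / "population.qc.tsv")
    return _load_expression(wd)


def _stage_ssmd(config, report, wd):
    p = config.stage(
        "ssmd", alpha=0.01, max_size=150, n_perm_start=1000, max_perm=10_000,
    )
    expr = _qc_expression(wd)
    coll = fio.read_gmt(wd / "sets.gmt")
    report.seeds["ssmd"] = config.seed
    results, table = ssmd.classify_collection(
        expr, coll, alpha=p["alpha"], n_perm_start=p["n_perm_start"],
        max_perm=p["max_perm"], max_size=p["max_size"], seed=config.seed,
    )
    table.to_csv(wd / "ssmd_results.tsv", sep="\t", index=False)
    report.tables["ssmd"] = table
    report.params["ssmd"] = p


def _stage_outliers(config, report, wd):
    p = config.stage("outliers", quantile=0.975, method="quantile")
    expr = _qc_expression(wd)
    table = pd.read_csv(wd / "ssmd_results.tsv", sep="\t")
    coll = fio.read_gmt(wd / "sets.gmt")
    calls = {}
    for _, row in table[table.verdict == "L"].iterrows():
        rs = fio.restrict_set(coll.sets[row.set_name], expr)
        profile = ssmd.md_profile_for_set(
            expr, rs.genes, seed=spawn(config.seed, "outliers", rs.name)
        )
        call = call_outliers(profile, quantile=p["quantile"], method=p["method"])
        calls[row.set_name] = call.outlier_sample_ids
    mat = outlier_matrix(calls, expr.sample_ids)
    mat.to_csv(wd / "outlier_matrix.tsv", sep="\t")
    with open(wd / "outlier_calls.json", "w") as fh:
        json.dump(calls, fh, indent=1)
    report.tables["outlier_matrix"] = mat
    report.params["outliers"] = p
    report.seeds["outliers"] = config.seed


def _stage_diffssmd(config, report, wd):
    p = config.stage("diffssmd", n_perm=1000, groups=None, max_size=150)
    expr = _qc_expression(wd)
    pops = sorted(set(expr.population.values()))
    groups = p["groups"] or pops[:2]
    if len(groups) < 2:
        raise ValidationError("diffssmd needs two population groups")
    coll = fio.read_gmt(wd / "sets.gmt")
    rows = []
    for gs in coll:
        rs = fio.restrict_set(gs, expr, p["max_size"])
        if not 2 <= rs.size < p["max_size"]:
            continue
        res = population_diff.diff_ssmd_test(
            expr, rs.genes, groups[0], groups[1], n_perm=p["n_perm"],
            seed=config.seed, set_name=rs.name,
        )
        rows.append(
            {
                "set_name": rs.name, "m": rs.size, "diff": res.diff_observed,
                "null_mean": float(res.null_values.mean()),
                "null_min": float(res.null_values.min()),
                "null_max": float(res.null_values.max()),
                "verdict": res.verdict,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(wd / "diffssmd_results.tsv", sep="\t", index=False)
    report.tables["diffssmd"] = table
    report.params["diffssmd"] = p
    report.seeds["diffssmd"] = config.seed


def _planted_gene_groups(wd):
    with open(wd / "truth.json") as fh:
        truth = json.load(fh)
    coll = fio.read_gmt(wd / "sets.gmt")
    genes_l = [g for s in truth["planted_L_sets"] for g in coll.sets[s].genes]
    genes_s = [g for s in truth["planted_S_sets"] for g in coll.sets[s].genes]
    return genes_l, genes_s


def _stage_twins(config, report, wd):
    p = config.stage("twins", n_reassign=50)
    expr = fio.read_expression(wd / "twin_expression.tsv")
    pairs = twins.read_twin_pairs(wd / "twin_pairs.tsv")
    cohort = twins.TwinCohort(pairs=pairs, expression=expr)
    table = twins.rmd_table(cohort, n_reassign=p["n_reassign"], seed=config.seed)
    table.to_csv(wd / "rmd_table.tsv", sep="\t")
    with open(wd / "twin_truth.json") as fh:
        twin_truth = json.load(fh)
    env_genes = twin_truth["twin_model"]["env_sensitive_genes"]
    other = [g for g in table.index if g not in set(env_genes)]
    comps = twins.compare_rmd_groups(table, env_genes, other)
    comp_table = pd.DataFrame(
        [{"comparison": k, "ks_D": v[0], "ks_p": v[1]} for k, v in comps.items()]
    )
    comp_table.to_csv(wd / "rmd_comparisons.tsv", sep="\t", index=False)
    report.tables["rmd"] = table
    report.tables["rmd_comparisons"] = comp_table
    report.params["twins"] = p
    report.seeds["twins"] = config.seed


def _called_outlier_map(wd):
    with open(wd / "outlier_calls.json") as fh:
        calls = json.load(fh)
    coll = fio.read_gmt(wd / "sets.gmt")
    out = {}
    for set_name, samples in calls.items():
        for s in samples:
            out.setdefault(s, set()).update(coll.sets[set_name].genes)
    return {s: sorted(g) for s, g in out.items()}


def _stage_esnp(config, report, wd):
    p = config.stage("esnp", most_significant_only=False)
    expr = _qc_expression(wd)
    gt = private_variants.read_vcf(wd / "genotypes.vcf")
    esnp_table = pd.read_csv(wd / "esnp.tsv", sep="\t")
    records = esnp_mod.read_esnp_table(wd / "esnp.tsv")
    lookup = synthetic.esnp_genotype_lookup(gt, esnp_table)
    esnp_mod.attach_genotypes(records, lookup)
    outlier_map = _called_outlier_map(wd)
    outliers = [s for s in expr.sample_ids if s in outlier_map]
    non_outliers = [s for s in expr.sample_ids if s not in outlier_map]
    if not outliers:
        raise ValidationError("no called outliers; run the outliers stage first")
    pool_o = esnp_mod.scaled_effects(
        records, outliers, p["most_significant_only"], source="outlier"
    )
    pool_b = esnp_mod.scaled_effects(
        records, non_outliers, p["most_significant_only"], source="non_outlier"
    )
    comp = esnp_mod.compare_pools(pool_o, pool_b)
    table = pd.DataFrame([comp])
    table.to_csv(wd / "esnp_comparison.tsv", sep="\t", index=False)
    report.tables["esnp"] = table
    report.params["esnp"] = p


def _stage_private_snps(config, report, wd):
    p = config.stage(
        "private_snps", window_bp=1_000_000, replicates=100,
        schemes=(1, 2, 3, 4), chrom_size=40_000_000,
    )
    gt = private_variants.read_vcf(wd / "genotypes.vcf")
    seg = private_variants.read_bed4(wd / "segmentation.bed")
    genes = pd.read_csv(wd / "genes.tsv", sep="\t")
    gene_coords = {
        r.gene_id: (str(r.chrom), int(r.tss), r.strand) for r in genes.itertuples()
    }
    outlier_map = _called_outlier_map(wd)
    outlier_map = {
        s: [g for g in gl if g in gene_coords] for s, gl in outlier_map.items()
    }
    outlier_map = {s: gl for s, gl in outlier_map.items() if gl}
    if not outlier_map:
        raise ValidationError("no called outliers with placed genes")
    genes_l, genes_s = _planted_gene_groups(wd)
    pool = [g for g in genes_l if g in gene_coords]
    s_pool = [g for g in genes_s if g in gene_coords]
    chrom_sizes = {"1": p["chrom_size"]}
    report.seeds["private_snps"] = config.seed
    rep = private_variants.private_snp_density_report(
        gt, seg, gene_coords, outlier_map, window_bp=p["window_bp"],
        schemes=tuple(p["schemes"]), replicates=p["replicates"],
        seed=config.seed, gene_pool=pool, s_gene_pool=s_pool,
        chrom_sizes=chrom_sizes,
    )
    out = rep.observed.join(rep.p_values)
    out.to_csv(wd / "private_snp_report.tsv", sep="\t")
    report.tables["private_snps"] = out
    report.params["private_snps"] = p


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "ssmd": _stage_ssmd,
    "outliers": _stage_outliers,
    "diffssmd": _stage_diffssmd,
    "twins": _stage_twins,
    "esnp": _stage_esnp,
    "private_snps": _stage_private_snps,
}


def run_full(config: fio.RunConfig, stages=None) -> PipelineReport:
    """Run the requested stages (default: all) in pipeline order."""
    stages = list(stages) if stages else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}")
    wd = _workdir(config)
    report = PipelineReport(params={"seed": config.seed})
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("pipeline stage: %s", stage)
        try:
            _STAGE_FUNCS[stage](config, report, wd)
        except FileNotFoundError as e:
            raise ValidationError(
                f"stage {stage!r} is missing an input: {e}"
            ) from e
    return report
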