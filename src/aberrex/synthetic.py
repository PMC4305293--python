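"""Synthetic-data generators emulating the statistical structure the
analyses assume, with ground-truth bookkeeping for recovery tests.

The expression generator draws gene-set blocks from a multivariate normal
with exchangeable within-set correlation ρ and plants three kinds of
structure:

* **Outlier individuals** for L-class sets — displaced along the
  minimal-variance eigendirection of the set covariance (any contrast
  orthogonal to the shared factor), so every per-gene z-score stays small
  while the Mahalanobis distance is large; the canonical way to realize
  "multivariately extreme, univariately normal" samples.  Displacement is
  parameterized in Mahalanobis units.
* **Sporadic per-gene aberrance** in ordinary transcriptome genes: a few
  individuals per gene carry large single-gene spikes, the empirical
  signature of population expression data that makes random gene sets
  accumulate excess SSMD.
* **Tightly regulated S-class blocks** — high ρ, no spikes — whose SSMD
  falls in the lower tail of the random-set null.

Twin, genotype/segmentation and eSNP generators follow the same
pure-function-of-(config, seed) contract.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import spawn
from .errors import ValidationError
from .formats_io import ExpressionMatrix, GeneSet, GeneSetCollection
from .private_variants import (
    CLASS_LABELS,
    MISSING,
    GenotypeTable,
    RegulatorySegmentation,
    Variant,
    cis_windows,
)
from .twins import TwinCohort


@dataclass
class SetSpec:
    """One planted gene-set block."""

    name: str
    size: int
    kind: str = "null"          # "L" | "S" | "null"
    rho: float = 0.9
    n_outliers: int = 0
    displacement: float = 12.0  # Mahalanobis units along the minor axis
    z_bound: float = 2.0        # planted per-gene z-scores must stay below
    pop_scale: dict = field(default_factory=dict)  # population -> residual SD ×


@dataclass
class SyntheticTruth:
    planted_outliers: dict = field(default_factory=dict)  # set -> {sample: MD}
    planted_spikes: dict = field(default_factory=dict)    # set -> {sample: |z|}
    planted_L_sets: list = field(default_factory=list)
    planted_S_sets: list = field(default_factory=list)
    population_scale: dict = field(default_factory=dict)
    twin_model: dict = field(default_factory=dict)
    esnp_truth: list = field(default_factory=list)  # (gene, snp, slope)
    private_enrichment: dict = field(default_factory=dict)
    private_singletons: dict = field(default_factory=dict)  # sample -> [(chrom,pos)]

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _displacement_vector(m: int, rho: float, delta: float, z_bound: float) -> np.ndarray:
    """Delta-Mahalanobis displacement along the minor eigendirection of the
    exchangeable-correlation covariance (eigenvalue 1 − ρ)."""
    v = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(m)])
    v -= v.mean()  # orthogonal to the shared-factor direction
    v /= np.linalg.norm(v)
    d = delta * np.sqrt(1.0 - rho) * v
    zmax = float(np.abs(d).max())
    if zmax >= z_bound:
        raise ValidationError(
            f"displacement {delta} at rho={rho} yields per-gene z {zmax:.2f} "
            f">= bound {z_bound}"
        )
    return d


def simulate_expression(
    populations: Sequence[tuple[str, int]] = (("EUR", 326),),
    sets: Sequence[SetSpec] = (),
    n_background_genes: int = 1000,
    spike_fraction: float = 1.0,
    spike_samples: int = 3,
    spike_mean: float = 6.0,
    spike_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GeneSetCollection, SyntheticTruth]:
    """Expression matrix + gene-set collection + truth manifest.

    Background genes are N(0,1) with sporadic aberrant spikes in
    ``spike_samples`` random individuals (``spike_fraction`` of genes);
    L/null set genes receive the same spikes, S sets stay clean.
    """
    sample_ids, labels = [], {}
    for pop, size in populations:
        for i in range(size):
            s = f"{pop}{i:04d}"
            sample_ids.append(s)
            labels[s] = pop
    n = len(sample_ids)
    pop_of = np.array([labels[s] for s in sample_ids])

    truth = SyntheticTruth()
    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []
    collection = GeneSetCollection()

    def add_spikes(block: np.ndarray, rng, record=None):
        m = block.shape[0]
        for j in range(m):
            if rng.random() < spike_fraction:
                picks = rng.choice(n, size=spike_samples, replace=False)
                mags = np.abs(rng.normal(spike_mean, spike_sd, size=spike_samples))
                signs = rng.choice([-1.0, 1.0], size=spike_samples)
                block[j, picks] += signs * mags
                if record is not None:
                    for p, mag in zip(picks, mags):
                        s = sample_ids[int(p)]
                        record[s] = max(record.get(s, 0.0), float(mag))

    for k, spec in enumerate(sets):
        rng = spawn(seed, "expr-set", spec.name)
        m = spec.size
        rho = 0.95 if spec.kind == "S" else spec.rho
        factor = rng.standard_normal(n)
        eps = rng.standard_normal((m, n))
        scale = np.ones(n)
        for pop, mult in spec.pop_scale.items():
            scale[pop_of == pop] = mult
        block = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * eps * scale
        if spec.kind == "L" and spec.n_outliers > 0:
            d = _displacement_vector(m, rho, spec.displacement, spec.z_bound)
            picks = rng.choice(n, size=spec.n_outliers, replace=False)
            block[:, picks] = d[:, None] + 0.1 * rng.standard_normal(
                (m, spec.n_outliers)
            )
            truth.planted_outliers[spec.name] = {
                sample_ids[int(p)]: float(spec.displacement) for p in picks
            }
        if spec.kind != "S":
            spiked: dict[str, float] = {}
            add_spikes(block, rng, record=spiked)
            if spiked:
                truth.planted_spikes[spec.name] = spiked
        names = [f"{spec.name}_g{j}" for j in range(m)]
        gene_ids.extend(names)
        blocks.append(block)
        collection.add(GeneSet(spec.name, f"planted {spec.kind} set", names))
        if spec.kind == "L":
            truth.planted_L_sets.append(spec.name)
        elif spec.kind == "S":
            truth.planted_S_sets.append(spec.name)
        if spec.pop_scale:
            truth.population_scale[spec.name] = dict(spec.pop_scale)

    rng_bg = spawn(seed, "expr-background")
    bg = rng_bg.standard_normal((n_background_genes, n))
    add_spikes(bg, rng_bg)
    bg_names = [f"BG_g{j}" for j in range(n_background_genes)]
    gene_ids.extend(bg_names)
    blocks.append(bg)

    values = np.vstack(blocks) if blocks else np.empty((0, n))
    expr = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, population=labels
    )
    return expr, collection, truth


def make_null_sets(
    expr: ExpressionMatrix,
    n_sets: int,
    size: int,
    seed: int = 0,
    pool_prefix: str = "BG_",
) -> GeneSetCollection:
    """Random gene sets drawn from the background pool (no planted structure)."""
    pool = [g for g in expr.gene_ids if g.startswith(pool_prefix)]
    coll = GeneSetCollection()
    for k in range(n_sets):
        rng = spawn(seed, "null-set", k)
        genes = list(rng.choice(pool, size=size, replace=False))
        coll.add(GeneSet(f"NULL_{k:04d}", "random background set", genes))
    return coll


def make_fig1_example(
    seed: int = 0, n: int = 100, rho: float = 0.9, displacement: float = 6.0
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two correlated genes with 3 individuals displaced against the
    correlation structure: multivariately extreme, univariately unremarkable."""
    expr, _, truth = simulate_expression(
        populations=(("POP", n),),
        sets=(
            SetSpec(
                name="FIG1", size=2, kind="L", rho=rho, n_outliers=3,
                displacement=displacement,
            ),
        ),
        n_background_genes=0,
        spike_fraction=0.0,
        seed=seed,
    )
    expr = expr.subset_genes(["FIG1_g0", "FIG1_g1"])
    return expr, truth


def simulate_twins(
    n_mz: int = 60,
    n_dz: int = 60,
    n_genes: int = 200,
    var_genetic: float = 1.0,
    var_shared_env: float = 0.5,
    var_unique_env: float = 0.25,
    env_sensitive_genes: Sequence[str] | int = 0,
    env_inflation: float = 3.0,
    baseline: float = 10.0,
    seed: int = 0,
) -> tuple[TwinCohort, SyntheticTruth]:
    """Twin cohort with additive genetic + shared-env + unique-env components.

    MZ co-twins share the genetic value fully, DZ co-twins with correlation
    one half.  Environment-sensitive genes have their unique-environment SD
    inflated by ``env_inflation`` — the generator's model of genes whose
    expression reacts to the individual environment.  ``baseline`` keeps
    values on a positive scale, as RMD presumes.
    """
    rng = spawn(seed, "twins")
    gene_ids = [f"TW_g{j}" for j in range(n_genes)]
    if isinstance(env_sensitive_genes, int):
        env_set = set(gene_ids[:env_sensitive_genes])
    else:
        env_set = set(env_sensitive_genes)
    sg, sc = np.sqrt(var_genetic), np.sqrt(var_shared_env)
    se = np.array(
        [
            np.sqrt(var_unique_env) * (env_inflation if g in env_set else 1.0)
            for g in gene_ids
        ]
    )[:, None]

    pairs, cols, ids = [], [], []
    for zyg, count in (("MZ", n_mz), ("DZ", n_dz)):
        g1 = rng.standard_normal((n_genes, count)) * sg
        if zyg == "MZ":
            g2 = g1
        else:
            g2 = 0.5 * g1 + np.sqrt(0.75) * rng.standard_normal((n_genes, count)) * sg
        c = rng.standard_normal((n_genes, count)) * sc
        e1 = rng.standard_normal((n_genes, count)) * se
        e2 = rng.standard_normal((n_genes, count)) * se
        y1 = baseline + g1 + c + e1
        y2 = baseline + g2 + c + e2
        for i in range(count):
            s1, s2 = f"{zyg}{i:03d}a", f"{zyg}{i:03d}b"
            pairs.append((s1, s2, zyg))
            ids.extend([s1, s2])
            cols.extend([y1[:, i], y2[:, i]])
    expr = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=ids, values=np.column_stack(cols),
        population={s: "TWIN" for s in ids},
    )
    truth = SyntheticTruth(
        twin_model={
            "var_genetic": var_genetic,
            "var_shared_env": var_shared_env,
            "var_unique_env": var_unique_env,
            "env_sensitive_genes": sorted(env_set),
            "env_inflation": env_inflation,
        }
    )
    return TwinCohort(pairs=pairs, expression=expr), truth


def make_segmentation(
    chrom_sizes: Mapping[str, int],
    tile_bp: int = 50_000,
    seed: int = 0,
) -> RegulatorySegmentation:
    """Tile each chromosome with fixed-size intervals labelled by randomly
    cycling chromatin-state classes (weights favouring T/R as in real
    segmentations)."""
    rng = spawn(seed, "segmentation")
    weights = {"E": 0.08, "TSS": 0.10, "CTCF": 0.06, "T": 0.25, "PF": 0.04,
               "R": 0.30, "WE": 0.05, "UNCL": 0.12}
    labels = list(weights)
    p = np.array([weights[x] for x in labels])
    intervals = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, tile_bp):
            end = min(start + tile_bp, size)
            label = labels[int(rng.choice(len(labels), p=p))]
            intervals.append((chrom, start, end, label))
    return RegulatorySegmentation(intervals=intervals)


def simulate_genotypes(
    sample_ids: Sequence[str],
    gene_coords: Mapping[str, tuple[str, int, str]],
    seg: RegulatorySegmentation,
    chrom_sizes: Mapping[str, int],
    outlier_genes: Mapping[str, list[str]] | None = None,
    class_multipliers: Mapping[str, float] | None = None,
    base_rate_per_mb: float = 0.5,
    hom_fraction: float = 0.1,
    esnp_spec: Sequence[tuple[str, float, float]] = (),  # (gene, maf, slope)
    window_bp: int = 1_000_000,
    seed: int = 0,
) -> tuple[GenotypeTable, pd.DataFrame, SyntheticTruth]:
    """Genotypes with singleton (private) variants at class-specific rates.

    Every individual carries genome-wide singletons at ``base_rate_per_mb``
    per segmentation class territory; outlier individuals get their rate
    multiplied by ``class_multipliers[label]`` inside the cis windows of
    their aberrant genes.  eSNPs are common variants (HWE at the given MAF)
    placed near their gene's TSS, with the planted slope recorded in the
    truth manifest and the returned eSNP table.
    """
    outlier_genes = outlier_genes or {}
    class_multipliers = class_multipliers or {}
    n = len(sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    truth = SyntheticTruth(
        private_enrichment={c: float(class_multipliers.get(c, 1.0))
                            for c in CLASS_LABELS},
    )

    windows_by_sample: dict[str, list[tuple[str, int, int]]] = {}
    for s, genes in outlier_genes.items():
        rows = [(g, *gene_coords[g]) for g in genes]
        windows_by_sample[s] = [
            (c, a, b) for _, c, a, b in cis_windows(rows, window_bp, chrom_sizes)
        ]

    used_positions: set[tuple[str, int]] = set()
    variants: list[Variant] = []
    singles: dict[str, list[tuple[str, int]]] = {s: [] for s in sample_ids}

    def draw_position(rng, chrom, start, end):
        for _ in range(100):
            pos = int(rng.integers(start + 1, end + 1))  # 1-based in (start, end]
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return pos
        raise ValidationError("could not place variant (interval saturated)")

    for chrom, start, end, label in seg.intervals:
        mb = (end - start) / 1e6
        rng = spawn(seed, "private", chrom, start)
        mid = (start + end) // 2
        for s in sample_ids:
            lam = base_rate_per_mb * mb
            if s in windows_by_sample:
                for wc, ws, we in windows_by_sample[s]:
                    if wc == chrom and ws <= mid < we:
                        lam *= class_multipliers.get(label, 1.0)
                        break
            k = rng.poisson(lam)
            for _ in range(k):
                pos = draw_position(rng, chrom, start, end)
                dosage = np.zeros(n, dtype=np.int8)
                dosage[sample_index[s]] = 2 if rng.random() < hom_fraction else 1
                variants.append(Variant(chrom, pos, "A", "G", dosage))
                singles[s].append((chrom, pos))

    esnp_rows = []
    for gene, maf, slope in esnp_spec:
        chrom, tss, _ = gene_coords[gene]
        rng = spawn(seed, "esnp", gene)
        pos = draw_position(rng, chrom, max(0, tss - 5000), tss + 5000)
        dosage = rng.binomial(2, maf, size=n).astype(np.int8)
        snp_id = f"rs_{gene}"
        variants.append(Variant(chrom, pos, "C", "T", dosage))
        esnp_rows.append(
            {"gene_id": gene, "snp_id": snp_id, "beta": slope, "p_value": 1e-8,
             "chrom": chrom, "pos": pos}
        )
        truth.esnp_truth.append((gene, snp_id, float(slope)))

    gt = GenotypeTable(sample_ids=list(sample_ids), variants=variants)
    truth.private_singletons = {s: sorted(v) for s, v in singles.items() if v}
    return gt, pd.DataFrame(esnp_rows), truth


def esnp_genotype_lookup(
    gt: GenotypeTable, esnp_table: pd.DataFrame
) -> dict[str, dict[str, int | None]]:
    """Genotype mapping per eSNP id, keyed for esnp.attach_genotypes."""
    by_pos = {(v.chrom, v.pos): v for v in gt.variants}
    out = {}
    for _, row in esnp_table.iterrows():
        v = by_pos[(str(row["chrom"]), int(row["pos"]))]
        out[row["snp_id"]] = {
            s: (None if v.genotypes[i] == MISSING else int(v.genotypes[i]))
            for i, s in enumerate(gt.sample_ids)
        }
    return out


def inject_esnp_effects(
    expr: ExpressionMatrix, gt: GenotypeTable, esnp_table: pd.DataFrame
) -> ExpressionMatrix:
    """Add slope × genotype-dosage to each eSNP's gene row (linear effect)."""
    by_pos = {(v.chrom, v.pos): v for v in gt.variants}
    values = expr.values.copy()
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    col = [gt.sample_ids.index(s) for s in expr.sample_ids]
    for _, row in esnp_table.iterrows():
        g = row["gene_id"]
        if g not in gene_index:
            continue
        v = by_pos[(str(row["chrom"]), int(row["pos"]))]
        dos = v.genotypes[col].astype(float)
        dos[dos == MISSING] = np.nan
        add = row["beta"] * np.nan_to_num(dos - np.nanmean(dos))
        values[gene_index[g], :] += add
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids), sample_ids=list(expr.sample_ids),
        values=values, population=dict(expr.population),
    )


# ---------------------------------------------------------------------------
# Benchmark preset
# ---------------------------------------------------------------------------

def benchmark_preset(seed: int = 0) -> dict:
    """The packaged recovery benchmark: one population of 160 individuals,
    15 planted L sets (6 hidden multivariate outliers each), 15 planted S
    sets, 50 random null sets, all of size 10, over a 1500-gene matrix.

    Sized so the Bonferroni-corrected permutation analysis over all 80 sets
    completes in minutes on one core.
    """
    specs = (
        [SetSpec(f"L_{k:02d}", 10, kind="L", rho=0.9, n_outliers=6,
                 displacement=12.0) for k in range(15)]
        + [SetSpec(f"S_{k:02d}", 10, kind="S") for k in range(15)]
    )
    expr, coll, truth = simulate_expression(
        populations=(("EUR", 160),),
        sets=specs,
        n_background_genes=1200,
        seed=seed,
    )
    nulls = make_null_sets(expr, n_sets=50, size=10, seed=seed)
    for gs in nulls:
        coll.add(gs)
    return {"expression": expr, "collection": coll, "truth": truth}
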