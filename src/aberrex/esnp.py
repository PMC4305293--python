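"""Genotype-scaled eSNP effect sizes and outlier vs non-outlier comparison.

An eSNP's effect size |β| is the absolute slope of expression (Z-scored
across individuals) on genotype dosage {0, 1, 2}.  The genotype-scaled
effect β* = |β| · genotype is zero exactly for homozygous-major carriers,
so comparing the zero fractions (2×2 χ² test) and the nonzero distributions
(two-sample K-S) between outlier and non-outlier individuals asks whether
common regulatory variants explain outlier status.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger("aberrex")


@dataclass
class ESNPRecord:
    gene_id: str
    snp_id: str
    abs_beta: float
    genotypes: dict[str, int | None]  # sample -> {0,1,2}, None = missing
    significance_rank: int = 1

    def __post_init__(self):
        if self.abs_beta < 0:
            raise ValidationError("abs_beta must be >= 0")
        for s, g in self.genotypes.items():
            if g is not None and g not in (0, 1, 2):
                raise ValidationError(f"genotype for {s} must be 0/1/2 or missing")


@dataclass
class ScaledEffectPool:
    values: np.ndarray
    source: str  # "outlier" | "non_outlier"
    n_pairs: int  # (individual, gene) pairs pooled


def effect_size_regression(genotype: np.ndarray, expression: np.ndarray) -> float:
    """|slope| of Z-scored expression regressed on genotype dosage."""
    genotype = np.asarray(genotype, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if genotype.shape != expression.shape:
        raise ValidationError("genotype and expression lengths differ")
    if np.ptp(genotype) == 0:
        raise DegenerateInputError("constant genotype")
    z = (expression - expression.mean()) / expression.std(ddof=0)
    slope = stats.linregress(genotype, z).slope
    return float(abs(slope))


def read_esnp_table(path) -> list[ESNPRecord]:
    """TSV with columns gene_id, snp_id, beta[, p_value]; significance rank
    within a gene follows p_value when present, otherwise file order."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "snp_id": str})
    required = {"gene_id", "snp_id", "beta"}
    if not required <= set(df.columns):
        raise ValidationError(f"eSNP table needs columns {sorted(required)}")
    records = []
    for gene, grp in df.groupby("gene_id", sort=False):
        if "p_value" in grp.columns:
            grp = grp.sort_values("p_value", kind="stable")
        for rank, (_, row) in enumerate(grp.iterrows(), start=1):
            records.append(
                ESNPRecord(
                    gene_id=str(gene),
                    snp_id=str(row["snp_id"]),
                    abs_beta=abs(float(row["beta"])),
                    genotypes={},
                    significance_rank=rank,
                )
            )
    return records


def attach_genotypes(records, genotype_lookup):
    """Fill each record's genotypes from ``genotype_lookup[snp_id]``."""
    for rec in records:
        if rec.snp_id in genotype_lookup:
            rec.genotypes = dict(genotype_lookup[rec.snp_id])
    return records


def scaled_effects(
    records: list[ESNPRecord],
    sample_ids: list[str],
    most_significant_only: bool = False,
    source: str = "pool",
) -> ScaledEffectPool:
    """Pool |β|·genotype over every (sample, gene, eSNP) triple.

    Multiple eSNPs of one gene are treated independently unless
    ``most_significant_only`` keeps rank-1 eSNPs only.  Missing genotypes
    are dropped with a logged count.
    """
    use = [r for r in records if not most_significant_only or r.significance_rank == 1]
    values = []
    n_missing = 0
    pairs = set()
    for rec in use:
        for s in sample_ids:
            g = rec.genotypes.get(s)
            if g is None:
                n_missing += 1
                continue
            values.append(rec.abs_beta * g)
            pairs.add((s, rec.gene_id))
    if n_missing:
        logger.info("scaled_effects: dropped %d missing genotypes", n_missing)
    return ScaledEffectPool(
        values=np.array(values, dtype=float), source=source, n_pairs=len(pairs)
    )


def compare_pools(outlier: ScaledEffectPool, background: ScaledEffectPool) -> dict:
    """Zero-fraction 2×2 χ² test plus two-sample K-S on the nonzero values.

    Returns a dict with zero fractions, the χ² p-value, and (D, p) for the
    nonzero comparison (None when a pool has no nonzero values).
    """
    if len(outlier.values) == 0 or len(background.values) == 0:
        raise DegenerateInputError("empty scaled-effect pool")
    zo = int(np.sum(outlier.values == 0))
    zb = int(np.sum(background.values == 0))
    no, nb = len(outlier.values), len(background.values)
    table = np.array([[zo, no - zo], [zb, nb - zb]])
    if table.sum(axis=0).min() == 0:
        chi2_p = 1.0  # both pools all-zero or all-nonzero: no difference testable
        chi2_stat = 0.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(table, correction=True)
    nz_o = outlier.values[outlier.values > 0]
    nz_b = background.values[background.values > 0]
    if len(nz_o) == 0 or len(nz_b) == 0:
        logger.warning("compare_pools: a pool has no nonzero values; K-S skipped")
        ks = None
    else:
        res = stats.ks_2samp(nz_o, nz_b)
        ks = (float(res.statistic), float(res.pvalue))
    return {
        "zero_fraction_outlier": zo / no,
        "zero_fraction_background": zb / nb,
        "chi2_stat": float(chi2_stat),
        "chi2_p": float(chi2_p),
        "ks_nonzero": ks,
    }
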