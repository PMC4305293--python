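"""Twin expression discordance: the relative mean difference (RMD) metric,
per-gene pooling over MZ/DZ pairs, permutation normalization, and group
comparisons between gene classes.

For a twin pair with expression y1, y2 of one gene,

    RMD = |y1 − y2| / (2 · (y1 + y2)/2)

is a scale-free discordance measure (half the range over the mean).  Mean
RMD per gene, pooled over all pairs of one zygosity, is normalized by the
same quantity computed under random re-pairings of the same individuals, so
values near 1 mean "no more discordant than strangers".
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._rng import spawn
from .errors import DegenerateInputError, ValidationError
from .formats_io import ExpressionMatrix
from .ssmd import compare_frequency_groups

logger = logging.getLogger("aberrex")

ZYGOSITIES = ("MZ", "DZ")


@dataclass
class TwinCohort:
    pairs: list[tuple[str, str, str]]  # (sample_1, sample_2, "MZ"|"DZ")
    expression: ExpressionMatrix

    def __post_init__(self):
        seen: set[str] = set()
        present = set(self.expression.sample_ids)
        for s1, s2, zyg in self.pairs:
            if zyg not in ZYGOSITIES:
                raise ValidationError(f"zygosity must be MZ or DZ, got {zyg!r}")
            for s in (s1, s2):
                if s in seen:
                    raise ValidationError(f"sample {s} appears in more than one pair")
                if s not in present:
                    raise ValidationError(f"pair member {s} missing from matrix")
                seen.add(s)

    def pairs_of(self, zygosity: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, z in self.pairs if z == zygosity]


def read_twin_pairs(path) -> list[tuple[str, str, str]]:
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(f"{path}:{ln}: expected 3 fields")
            pairs.append((parts[0], parts[1], parts[2]))
    return pairs


def rmd_pair(y1: float, y2: float) -> float:
    """|y1 − y2| / (2 · mean(y1, y2)); undefined at zero mean."""
    mean = (y1 + y2) / 2.0
    if mean == 0:
        raise DegenerateInputError("RMD undefined for zero pair mean")
    return abs(y1 - y2) / (2.0 * mean)


def _pair_matrices(cohort: TwinCohort, zygosity: str):
    pairs = cohort.pairs_of(zygosity)
    if not pairs:
        raise DegenerateInputError(f"no {zygosity} pairs in cohort")
    expr = cohort.expression
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    a = expr.values[:, [idx[p[0]] for p in pairs]]
    b = expr.values[:, [idx[p[1]] for p in pairs]]
    return a, b


def _mean_rmd(a: np.ndarray, b: np.ndarray, gene_ids: list[str]) -> dict[str, float]:
    """Mean RMD per gene over pair columns; genes with any nonpositive pair
    mean are dropped with a logged count (RMD presumes positive scale)."""
    means = (a + b) / 2.0
    valid = (means > 0).all(axis=1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("RMD: dropped %d genes with nonpositive pair means", n_dropped)
    rmd = np.abs(a - b) / (2.0 * np.where(means > 0, means, np.nan))
    out = {}
    for i, g in enumerate(gene_ids):
        if valid[i]:
            out[g] = float(rmd[i].mean())
    return out


def mean_rmd_per_gene(cohort: TwinCohort, zygosity: str) -> dict[str, float]:
    """Arithmetic mean of pair RMDs per gene for one zygosity."""
    a, b = _pair_matrices(cohort, zygosity)
    return _mean_rmd(a, b, cohort.expression.gene_ids)


def _random_pairing(samples: list[str], rng) -> list[tuple[str, str]]:
    order = list(rng.permutation(len(samples)))
    return [
        (samples[order[i]], samples[order[i + 1]]) for i in range(0, len(order) - 1, 2)
    ]


def normalize_rmd(
    cohort: TwinCohort,
    zygosity: str,
    n_reassign: int = 100,
    seed: int = 0,
    within_zygosity: bool = True,
) -> dict[str, float]:
    """Observed mean RMD per gene divided by its average under random
    re-pairings of the sample pool (uniform perfect matchings).

    ``within_zygosity`` re-pairs among the requested zygosity's samples
    only; otherwise the whole cohort pool is used.
    """
    pairs = cohort.pairs_of(zygosity)
    if len(pairs) < 2:
        raise DegenerateInputError("need at least 2 pairs to normalize")
    observed = mean_rmd_per_gene(cohort, zygosity)
    if within_zygosity:
        pool = [s for p in pairs for s in p]
    else:
        pool = [s for p in cohort.pairs for s in p[:2]]
    expr = cohort.expression
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    acc = {g: 0.0 for g in observed}
    cnt = {g: 0 for g in observed}
    for r in range(n_reassign):
        rng = spawn(seed, "rmd-reassign", zygosity, r)
        rnd_pairs = _random_pairing(pool, rng)
        a = expr.values[:, [idx[p[0]] for p in rnd_pairs]]
        b = expr.values[:, [idx[p[1]] for p in rnd_pairs]]
        rnd = _mean_rmd(a, b, expr.gene_ids)
        for g in acc:
            if g in rnd:
                acc[g] += rnd[g]
                cnt[g] += 1
    out = {}
    for g, obs in observed.items():
        if cnt[g] == 0 or acc[g] == 0:
            logger.info("RMD normalization undefined for gene %s; dropped", g)
            continue
        out[g] = obs / (acc[g] / cnt[g])
    return out


def rmd_table(
    cohort: TwinCohort, n_reassign: int = 100, seed: int = 0
):
    """Per-gene raw and normalized mean RMD for both zygosities."""
    import pandas as pd

    raw_mz = mean_rmd_per_gene(cohort, "MZ")
    raw_dz = mean_rmd_per_gene(cohort, "DZ")
    norm_mz = normalize_rmd(cohort, "MZ", n_reassign=n_reassign, seed=seed)
    norm_dz = normalize_rmd(cohort, "DZ", n_reassign=n_reassign, seed=seed)
    genes = [g for g in cohort.expression.gene_ids if g in raw_mz and g in raw_dz]
    return pd.DataFrame(
        {
            "gene_id": genes,
            "mean_rmd_MZ": [raw_mz[g] for g in genes],
            "mean_rmd_DZ": [raw_dz[g] for g in genes],
            "normalized_mean_rmd_MZ": [norm_mz.get(g, np.nan) for g in genes],
            "normalized_mean_rmd_DZ": [norm_dz.get(g, np.nan) for g in genes],
            "n_pairs_MZ": len(cohort.pairs_of("MZ")),
            "n_pairs_DZ": len(cohort.pairs_of("DZ")),
        }
    ).set_index("gene_id")


def compare_rmd_groups(
    table, genes_l: list[str], genes_s: list[str]
) -> dict[str, tuple[float, float]]:
    """K-S comparisons of normalized mean RMD:

    L vs S within each zygosity, and MZ vs DZ within each gene group.
    Returns {comparison: (D, p)}.
    """
    gl = [g for g in genes_l if g in table.index]
    gs = [g for g in genes_s if g in table.index]
    if not gl or not gs:
        raise DegenerateInputError("gene group absent from RMD table")
    mz_l = table.loc[gl, "normalized_mean_rmd_MZ"].dropna().to_numpy()
    mz_s = table.loc[gs, "normalized_mean_rmd_MZ"].dropna().to_numpy()
    dz_l = table.loc[gl, "normalized_mean_rmd_DZ"].dropna().to_numpy()
    dz_s = table.loc[gs, "normalized_mean_rmd_DZ"].dropna().to_numpy()
    return {
        "L_vs_S_MZ": compare_frequency_groups(mz_l, mz_s),
        "L_vs_S_DZ": compare_frequency_groups(dz_l, dz_s),
        "MZ_vs_DZ_L": compare_frequency_groups(mz_l, dz_l),
        "MZ_vs_DZ_S": compare_frequency_groups(mz_s, dz_s),
    }
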