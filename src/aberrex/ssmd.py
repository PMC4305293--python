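"""The SSMD statistic, its permutation null over random gene sets, L-/S-
classification with Bonferroni control, rank-frequency validation, and the
subsampling power analysis.

SSMD = Σ_i MD_i² over individuals summarises how far a gene set's expression
profiles spread around the robust population centre; the squaring weights
outlier individuals.  Its null distribution is built by repeatedly drawing m
random genes from the full matrix (which breaks the correlation structure
between set genes) and re-running the whole robust-distance pipeline.  A set
is called L (tends to be aberrantly expressed) when its SSMD exceeds the
null at the Bonferroni-corrected level, S when it falls below.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import spawn
from .errors import DegenerateInputError, ValidationError
from .formats_io import ExpressionMatrix, GeneSetCollection, restrict_set
from .robust_distance import (
    MDProfile,
    estimate_robust_covariance,
    mahalanobis_distances,
)

logger = logging.getLogger("aberrex")


@dataclass
class SSMDResult:
    set_name: str
    m: int
    ssmd_observed: float
    null_values: np.ndarray
    p_greater: float
    p_smaller: float
    n_perm: int
    verdict: str  # "L" | "S" | "neutral"


@dataclass
class PowerCurve:
    axis: str  # "sample_size" | "set_size"
    grid: np.ndarray
    power: np.ndarray
    replicates: int


def md_profile_for_set(
    expr: ExpressionMatrix,
    genes: list[str],
    seed: int | np.random.Generator = 0,
    support_fraction: float | None = None,
) -> MDProfile:
    """Robust model + Mahalanobis distances for one gene set."""
    X = expr.gene_submatrix(genes)
    model = estimate_robust_covariance(
        X, support_fraction=support_fraction, seed=seed, gene_names=list(genes)
    )
    return mahalanobis_distances(X, model, sample_ids=list(expr.sample_ids))


def compute_ssmd(profile: MDProfile) -> float:
    """Sum of squared Mahalanobis distances over individuals."""
    if len(profile) == 0:
        raise ValidationError("empty MD profile")
    return float(np.sum(profile.md_squared))


def ssmd_for_set(
    expr: ExpressionMatrix,
    genes: list[str],
    seed: int | np.random.Generator = 0,
    support_fraction: float | None = None,
) -> float:
    return compute_ssmd(md_profile_for_set(expr, genes, seed, support_fraction))


class SSMDNullCache:
    """Permutation nulls keyed by (matrix fingerprint, m).

    Thousands of gene sets share a handful of sizes, so the null for a size
    is generated once and extended in place when a set escalates its
    permutation count.  Permutation j for a given (matrix, m) is a pure
    function of the cache seed, so cached and uncached runs agree.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._store: dict[tuple[str, int], np.ndarray] = {}

    def get(self, expr: ExpressionMatrix, m: int, n_perm: int) -> np.ndarray:
        key = (expr.fingerprint(), m)
        have = self._store.get(key, np.empty(0))
        if len(have) < n_perm:
            extra = _generate_null(expr, m, start=len(have), stop=n_perm,
                                   seed=self.seed)
            have = np.concatenate([have, extra])
            self._store[key] = have
        return have[:n_perm]


def _generate_null(
    expr: ExpressionMatrix, m: int, start: int, stop: int, seed: int
) -> np.ndarray:
    if m > expr.n_genes:
        raise ValidationError(f"m={m} exceeds matrix gene count {expr.n_genes}")
    out = np.empty(stop - start)
    for j in range(start, stop):
        rng = spawn(seed, "ssmd-null", m, j)
        idx = rng.choice(expr.n_genes, size=m, replace=False)
        genes = [expr.gene_ids[i] for i in idx]
        out[j - start] = ssmd_for_set(expr, genes, seed=rng)
    return out


def permutation_null_ssmd(
    expr: ExpressionMatrix,
    m: int,
    n_perm: int = 1000,
    seed: int = 0,
    cache: SSMDNullCache | None = None,
) -> np.ndarray:
    """SSMD values for ``n_perm`` random m-gene sets (full pipeline each)."""
    if cache is not None:
        if cache.seed != seed:
            raise ValidationError("cache seed differs from requested seed")
        return cache.get(expr, m, n_perm)
    return _generate_null(expr, m, start=0, stop=n_perm, seed=seed)


def empirical_p(observed: float, null_values: np.ndarray) -> tuple[float, float]:
    """(p_greater, p_smaller) with the +1/(n+1) correction; never zero."""
    null_values = np.asarray(null_values)
    n = len(null_values)
    p_greater = (1 + int(np.sum(null_values >= observed))) / (n + 1)
    p_smaller = (1 + int(np.sum(null_values <= observed))) / (n + 1)
    return p_greater, p_smaller


def _clopper_pearson(k: int, n: int, level: float = 0.99) -> tuple[float, float]:
    a = 1 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return lo, hi


def classify_gene_set(
    observed: float,
    expr: ExpressionMatrix,
    m: int,
    alpha: float = 0.01,
    n_sets: int = 1,
    n_perm_start: int = 1000,
    max_perm: int = 100_000,
    seed: int = 0,
    cache: SSMDNullCache | None = None,
    set_name: str = "",
) -> SSMDResult:
    """Sequential permutation test against the Bonferroni level alpha/n_sets.

    Starts at ``n_perm_start`` permutations and multiplies by 10 while the
    Clopper–Pearson interval of either one-sided exceedance proportion still
    straddles the corrected level and ``max_perm`` has not been reached —
    i.e. until the Bonferroni level is either achieved or rejected.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    thr = alpha / n_sets
    n_perm = min(n_perm_start, max_perm)
    while True:
        null = permutation_null_ssmd(expr, m, n_perm, seed=seed, cache=cache)
        k_g = int(np.sum(null >= observed))
        k_s = int(np.sum(null <= observed))
        ci_g = _clopper_pearson(k_g, n_perm)
        ci_s = _clopper_pearson(k_s, n_perm)
        straddles = (ci_g[0] <= thr <= ci_g[1]) or (ci_s[0] <= thr <= ci_s[1])
        if not straddles or n_perm >= max_perm:
            break
        n_perm = min(n_perm * 10, max_perm)
    p_greater, p_smaller = empirical_p(observed, null)
    if p_greater <= thr:
        verdict = "L"
    elif p_smaller <= thr:
        verdict = "S"
    else:
        verdict = "neutral"
    if n_perm >= max_perm and straddles:
        logger.info(
            "set %s: permutation bound %d reached with p undecided "
            "(p_greater=%.3g, p_smaller=%.3g, level=%.3g)",
            set_name, n_perm, p_greater, p_smaller, thr,
        )
    return SSMDResult(
        set_name=set_name,
        m=m,
        ssmd_observed=observed,
        null_values=null,
        p_greater=p_greater,
        p_smaller=p_smaller,
        n_perm=n_perm,
        verdict=verdict,
    )


def classify_collection(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = 0.01,
    n_sets: int | None = None,
    n_perm_start: int = 1000,
    max_perm: int = 100_000,
    max_size: int = 150,
    seed: int = 0,
):
    """Classify every set in a collection; returns (results, table).

    ``n_sets`` defaults to the number of testable sets (the Bonferroni
    denominator).  Sets with ≥ ``max_size`` or < 2 expressed genes are
    skipped.  Null distributions are shared through one cache.
    """
    import pandas as pd

    restricted = []
    for gs in collection:
        rs = restrict_set(gs, expr, max_size=max_size)
        if 2 <= rs.size < max_size:
            restricted.append(rs)
        else:
            logger.info("skipping set %s (%d expressed genes)", gs.name, rs.size)
    if n_sets is None:
        n_sets = len(restricted)
    cache = SSMDNullCache(seed=seed)
    results: list[SSMDResult] = []
    rows = []
    for rs in restricted:
        rng = spawn(seed, "ssmd-observed", rs.name)
        observed = ssmd_for_set(expr, rs.genes, seed=rng)
        res = classify_gene_set(
            observed, expr, rs.size, alpha=alpha, n_sets=n_sets,
            n_perm_start=n_perm_start, max_perm=max_perm, seed=seed,
            cache=cache, set_name=rs.name,
        )
        results.append(res)
        rows.append(
            {
                "set_name": rs.name,
                "m": rs.size,
                "genes_expressed_total": rs.counts_label,
                "ssmd": res.ssmd_observed,
                "p_greater": res.p_greater,
                "p_smaller": res.p_smaller,
                "n_perm": res.n_perm,
                "verdict": res.verdict,
            }
        )
    return results, pd.DataFrame(rows)


def ssmd_rank_frequency(observed: float, null_values: np.ndarray) -> float:
    """Fraction of null SSMD values strictly below the observed SSMD."""
    null_values = np.asarray(null_values)
    if len(null_values) == 0:
        raise ValidationError("empty null")
    return float(np.mean(null_values < observed))


def compare_frequency_groups(
    freqs_a: np.ndarray, freqs_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test; returns (D, p)."""
    freqs_a, freqs_b = np.asarray(freqs_a), np.asarray(freqs_b)
    if len(freqs_a) == 0 or len(freqs_b) == 0:
        raise DegenerateInputError("empty group in K-S comparison")
    res = stats.ks_2samp(freqs_a, freqs_b, method="auto")
    return float(res.statistic), float(res.pvalue)


def power_analysis_subsample(
    expr: ExpressionMatrix,
    genes: list[str],
    axis: str,
    grid: list[int],
    replicates: int = 100,
    alpha: float = 0.05,
    n_sets: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> PowerCurve:
    """Power of the (one-sided, L-direction) SSMD test under subsampling.

    For each grid value, draw ``replicates`` random subsamples of the
    individuals (axis "sample_size") or of the set genes (axis "set_size"),
    rerun the SSMD significance test, and report the fraction significant.
    """
    if axis not in ("sample_size", "set_size"):
        raise ValidationError("axis must be 'sample_size' or 'set_size'")
    grid = sorted(int(g) for g in grid)
    limit = expr.n_samples if axis == "sample_size" else len(genes)
    if grid[-1] > limit:
        raise ValidationError(f"grid value {grid[-1]} exceeds available {limit}")
    thr = alpha / n_sets
    power = []
    cache = SSMDNullCache(seed=seed) if axis == "set_size" else None
    for g in grid:
        hits = 0
        for r in range(replicates):
            rng = spawn(seed, "power", axis, g, r)
            if axis == "sample_size":
                idx = sorted(rng.choice(expr.n_samples, size=g, replace=False))
                sub = expr.subset_samples([expr.sample_ids[i] for i in idx])
                observed = ssmd_for_set(sub, genes, seed=rng)
                null = permutation_null_ssmd(
                    sub, len(genes), n_perm, seed=int(rng.integers(2**31))
                )
            else:
                idx = sorted(rng.choice(len(genes), size=g, replace=False))
                sub_genes = [genes[i] for i in idx]
                observed = ssmd_for_set(expr, sub_genes, seed=rng)
                null = permutation_null_ssmd(expr, g, n_perm, seed=seed, cache=cache)
            p_greater, _ = empirical_p(observed, null)
            hits += p_greater <= thr
        power.append(hits / replicates)
    return PowerCurve(
        axis=axis, grid=np.array(grid), power=np.array(power), replicates=replicates
    )
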