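"""Population-difference statistic diffSSMD and its label-shuffling null.

Mahalanobis distances are computed once on the pooled two-population matrix
with a single robust model; diffSSMD = SSMD_A − SSMD_B is then a function of
the group labels only.  The null shuffles sample labels at the fixed group
ratio without recomputing distances, and a set is significant only when the
observed difference exceeds every null value (a strict all-exceedance rule,
p ≤ 1/(n_perm + 1)).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._rng import spawn
from .errors import DegenerateInputError, ValidationError
from .formats_io import ExpressionMatrix
from .robust_distance import MDProfile
from .ssmd import PowerCurve, md_profile_for_set


@dataclass
class DiffSSMDResult:
    set_name: str
    diff_observed: float
    null_values: np.ndarray
    n1: int
    n2: int
    verdict: str  # "larger" | "smaller" | "neutral"


def diff_ssmd(
    profile: MDProfile,
    labels: Mapping[str, str],
    group_a: str,
    group_b: str,
) -> float:
    """Σ MD² over group A minus Σ MD² over group B (pooled distances)."""
    missing = [s for s in profile.sample_ids if s not in labels]
    if missing:
        raise ValidationError(f"samples lack labels: {missing[:5]}")
    mask_a = np.array([labels[s] == group_a for s in profile.sample_ids])
    mask_b = np.array([labels[s] == group_b for s in profile.sample_ids])
    if not mask_a.any() or not mask_b.any():
        raise DegenerateInputError("empty group in diff_ssmd")
    if (mask_a & mask_b).any():
        raise ValidationError("groups overlap")
    return float(profile.md_squared[mask_a].sum() - profile.md_squared[mask_b].sum())


def permutation_null_diff(
    profile: MDProfile,
    n1: int,
    n2: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null diffSSMD from random partitions of the fixed MD² values.

    Each replicate shuffles the samples and splits them n1/n2; distances
    are not recomputed.
    """
    md2 = profile.md_squared
    if n1 + n2 != len(md2):
        raise ValidationError(
            f"n1 + n2 = {n1 + n2} does not match {len(md2)} samples"
        )
    if n1 < 1 or n2 < 1:
        raise DegenerateInputError("both groups must be nonempty")
    total = md2.sum()
    out = np.empty(n_perm)
    for j in range(n_perm):
        rng = spawn(seed, "diff-null", j)
        pick = rng.choice(len(md2), size=n1, replace=False)
        sa = md2[pick].sum()
        out[j] = sa - (total - sa)
    return out


def classify_diff(
    set_name: str, diff_observed: float, null_values: np.ndarray
) -> DiffSSMDResult:
    """Strict all-exceedance verdict: "larger" only if the observed value
    exceeds every null value, "smaller" only if below every null value."""
    null_values = np.asarray(null_values)
    if len(null_values) == 0:
        raise ValidationError("empty null")
    if diff_observed > null_values.max():
        verdict = "larger"
    elif diff_observed < null_values.min():
        verdict = "smaller"
    else:
        verdict = "neutral"
    n = len(null_values)
    # group sizes are unknown here; caller-facing result carries them
    return DiffSSMDResult(set_name, float(diff_observed), null_values, -1, -1, verdict)


def diff_ssmd_test(
    expr: ExpressionMatrix,
    genes: list[str],
    group_a: str,
    group_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "",
) -> DiffSSMDResult:
    """Full diffSSMD test for one gene set on a two-population matrix."""
    profile = md_profile_for_set(expr, genes, seed=spawn(seed, "diff-md", set_name))
    labels = expr.population
    n1 = sum(labels[s] == group_a for s in expr.sample_ids)
    n2 = sum(labels[s] == group_b for s in expr.sample_ids)
    observed = diff_ssmd(profile, labels, group_a, group_b)
    null = permutation_null_diff(profile, n1, n2, n_perm=n_perm, seed=seed)
    res = classify_diff(set_name, observed, null)
    res.n1, res.n2 = n1, n2
    return res


def diff_power_analysis(
    expr: ExpressionMatrix,
    genes: list[str],
    group_a: str,
    group_b: str,
    group_a_sizes: list[int],
    replicates: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> PowerCurve:
    """Power of the diffSSMD test as group A is subsampled.

    The full-data verdict is computed first; power at each grid size is the
    fraction of subsampled replicates whose verdict matches it.
    """
    full = diff_ssmd_test(expr, genes, group_a, group_b, n_perm=n_perm, seed=seed)
    a_ids = [s for s in expr.sample_ids if expr.population[s] == group_a]
    b_ids = [s for s in expr.sample_ids if expr.population[s] == group_b]
    grid = sorted(int(g) for g in group_a_sizes)
    if grid[-1] > len(a_ids):
        raise ValidationError(f"grid value {grid[-1]} exceeds group size {len(a_ids)}")
    power = []
    for g in grid:
        hits = 0
        for r in range(replicates):
            rng = spawn(seed, "diff-power", g, r)
            keep = [a_ids[i] for i in sorted(rng.choice(len(a_ids), g, replace=False))]
            sub = expr.subset_samples(keep + b_ids)
            res = diff_ssmd_test(
                sub, genes, group_a, group_b, n_perm=n_perm,
                seed=int(rng.integers(2**31)), set_name=full.set_name,
            )
            hits += res.verdict == full.verdict
        power.append(hits / replicates)
    return PowerCurve(
        axis="sample_size", grid=np.array(grid), power=np.array(power),
        replicates=replicates,
    )
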