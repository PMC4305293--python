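"""Robust covariance estimation, Mahalanobis distances, chi-square-plot
coordinates and outlier calling for a single gene set.

For a gene set of m genes observed in n individuals, the location vector and
m×m gene-gene scatter matrix are estimated robustly with the minimum
covariance determinant (MCD) estimator, so that a handful of aberrant
individuals cannot mask themselves by inflating the classical covariance.
Each individual's Mahalanobis distance

    MD_i = sqrt((x_i − μ)ᵀ Σ⁻¹ (x_i − μ))

is approximately χ²_m-distributed when squared (for multivariate-normal
data), which underlies both the chi-square diagnostic plot and the default
outlier cutoff at the χ²(q, m) quantile of squared distances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.covariance import MinCovDet

from ._rng import int_seed, rng_from
from .errors import DegenerateInputError, SingularCovarianceError, ValidationError

logger = logging.getLogger("aberrex")


@dataclass
class RobustCovarianceModel:
    location: np.ndarray          # length m
    scatter: np.ndarray           # m × m, symmetric positive definite
    support_fraction: float
    support_mask: np.ndarray      # per-sample bool, True = in MCD support
    method: str = "mcd"           # "mcd" or "classical"

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        self.scatter = np.asarray(self.scatter, dtype=float)
        if self.scatter.ndim != 2 or self.scatter.shape[0] != self.scatter.shape[1]:
            raise ValidationError("scatter must be square")
        if self.location.shape[0] != self.scatter.shape[0]:
            raise ValidationError("location length must equal scatter dimension")
        if not np.allclose(self.scatter, self.scatter.T, atol=1e-10):
            raise ValidationError("scatter must be symmetric")
        eigmin = linalg.eigvalsh(self.scatter)[0]
        if eigmin <= 0:
            raise SingularCovarianceError(
                f"scatter is singular (smallest eigenvalue {eigmin:.3g})"
            )

    @property
    def dim(self) -> int:
        return self.location.shape[0]


@dataclass
class MDProfile:
    md: np.ndarray
    md_squared: np.ndarray
    df: int
    sample_ids: list[str]

    def __post_init__(self):
        self.md = np.asarray(self.md, dtype=float)
        self.md_squared = np.asarray(self.md_squared, dtype=float)
        if self.df < 1:
            raise ValidationError("df must be >= 1")
        if not np.allclose(self.md_squared, self.md**2):
            raise ValidationError("md_squared must equal md**2")

    def __len__(self):
        return len(self.md)


@dataclass
class ChiSquarePlot:
    ranked_md_squared: np.ndarray
    quantile_probs: np.ndarray
    chisq_quantiles: np.ndarray
    df: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_md_squared) + 1),
                "p": self.quantile_probs,
                "chisq_quantile": self.chisq_quantiles,
                "md_squared": self.ranked_md_squared,
            }
        )


@dataclass
class OutlierCall:
    outlier_sample_ids: list[str]
    threshold_md_squared: float
    method: str  # "quantile" | "gap"


def _check_columns(X: np.ndarray, gene_names: list[str] | None):
    sd = X.std(axis=0)
    const = np.where(sd == 0)[0]
    if const.size:
        names = (
            [gene_names[i] for i in const]
            if gene_names
            else [f"column {i}" for i in const]
        )
        raise SingularCovarianceError(
            f"constant (zero-variance) gene(s): {names}", genes=names
        )


def estimate_robust_covariance(
    X: np.ndarray,
    support_fraction: float | None = None,
    seed: int | np.random.Generator = 0,
    gene_names: list[str] | None = None,
    allow_classical_fallback: bool = True,
) -> RobustCovarianceModel:
    """MCD location/scatter for an n × m gene-set matrix.

    ``support_fraction`` defaults to the standard (n + m + 1) / 2n.  With
    ``support_fraction = 1`` the classical mean/covariance is returned.
    When n ≤ 2m the MCD is unreliable, so the classical estimate is used
    with a logged warning (or an error if ``allow_classical_fallback`` is
    off) — small validation cohorts can still meet large gene sets.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-dimensional (samples x genes)")
    n, m = X.shape
    if n <= m:
        raise DegenerateInputError(f"need more samples than genes (n={n}, m={m})")
    _check_columns(X, gene_names)
    if support_fraction is None:
        support_fraction = (n + m + 1) / (2 * n)
    if not 0.5 < support_fraction <= 1:
        raise ValidationError("support_fraction must be in (0.5, 1]")

    classical = support_fraction >= 1.0
    if not classical and n <= 2 * m:
        if not allow_classical_fallback:
            raise DegenerateInputError(
                f"n={n} <= 2m={2*m}: too few samples for MCD"
            )
        logger.warning(
            "n=%d <= 2m=%d: falling back to classical covariance", n, 2 * m
        )
        classical = True

    if classical:
        location = X.mean(axis=0)
        scatter = np.cov(X, rowvar=False)
        if m == 1:
            scatter = scatter.reshape(1, 1)
        support = np.ones(n, dtype=bool)
        return RobustCovarianceModel(
            location, scatter, 1.0, support, method="classical"
        )

    mcd = MinCovDet(
        support_fraction=support_fraction, random_state=int_seed(rng_from(seed))
    ).fit(X)
    return RobustCovarianceModel(
        mcd.location_, mcd.covariance_, support_fraction, mcd.support_, method="mcd"
    )


def mahalanobis_distances(
    X: np.ndarray,
    model: RobustCovarianceModel,
    sample_ids: list[str] | None = None,
) -> MDProfile:
    """Per-individual Mahalanobis distances under ``model`` (df = m)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.dim:
        raise ValidationError(
            f"X has {X.shape[1]} columns but model dimension is {model.dim}"
        )
    dev = X - model.location
    cho = linalg.cho_factor(model.scatter, lower=True)
    sol = linalg.cho_solve(cho, dev.T)
    md2 = np.einsum("ij,ji->i", dev, sol)
    md2 = np.maximum(md2, 0.0)
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(md2))]
    return MDProfile(md=np.sqrt(md2), md_squared=md2, df=model.dim, sample_ids=ids)


def chi_square_plot_coordinates(profile: MDProfile) -> ChiSquarePlot:
    """Ranked squared distances against χ²_df quantiles at p = (i − 0.5)/I."""
    I = len(profile)
    if I == 0:
        raise ValidationError("empty MD profile")
    probs = (np.arange(1, I + 1) - 0.5) / I
    return ChiSquarePlot(
        ranked_md_squared=np.sort(profile.md_squared),
        quantile_probs=probs,
        chisq_quantiles=stats.chi2.ppf(probs, df=profile.df),
        df=profile.df,
    )


def call_outliers(
    profile: MDProfile, quantile: float = 0.975, method: str = "quantile"
) -> OutlierCall:
    """Flag individuals in the broken tail of the chi-square plot.

    ``quantile``: flag samples with MD² above the χ²(quantile, df) quantile.
    ``gap``: additionally require samples to lie beyond the largest
    consecutive gap among the ranked MD² values above that quantile — a
    conservative reading of a visual "break in the tail".
    """
    if not 0 < quantile < 1:
        raise ValidationError("quantile must be in (0, 1)")
    threshold = float(stats.chi2.ppf(quantile, df=profile.df))
    above = profile.md_squared > threshold
    if method == "quantile":
        ids = [s for s, a in zip(profile.sample_ids, above) if a]
        return OutlierCall(ids, threshold, "quantile")
    if method != "gap":
        raise ValidationError(f"unknown outlier method {method!r}")
    order = np.argsort(profile.md_squared)
    ranked = profile.md_squared[order]
    tail_start = np.searchsorted(ranked, threshold, side="right")
    if tail_start >= len(ranked):
        return OutlierCall([], threshold, "gap")
    # gaps between consecutive ranked values from the last below-threshold
    # point through the tail; outliers are everything past the largest gap
    lo = max(tail_start - 1, 0)
    seg = ranked[lo:]
    if len(seg) < 2:
        flagged_idx = order[tail_start:]
    else:
        gaps = np.diff(seg)
        cut = lo + int(np.argmax(gaps)) + 1
        cut = max(cut, tail_start)
        flagged_idx = order[cut:]
    ids = [profile.sample_ids[i] for i in flagged_idx]
    return OutlierCall(ids, threshold, "gap")
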