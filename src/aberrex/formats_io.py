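"""Readers and writers for the external formats, run configuration, and the
PCA-based sample QC applied before any analysis.

Expression comes in as a genes × samples TSV (first column gene ids, header
row sample ids) holding RPKM or normalized residuals; gene sets as GMT;
population labels and per-gene metrics as two-column TSVs.  All readers
validate identifiers and numeric content and raise typed errors instead of
silently truncating.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .errors import DuplicateIdError, FormatError, ValidationError

logger = logging.getLogger("aberrex")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with per-sample population labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)
    population: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateIdError("duplicate gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIdError("duplicate sample ids in expression matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if not self.population:
            self.population = {s: "ALL" for s in self.sample_ids}
        missing = [s for s in self.sample_ids if s not in self.population]
        if missing:
            raise ValidationError(f"samples lack population labels: {missing[:5]}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._fingerprint: str | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def fingerprint(self) -> str:
        """Stable content hash (used to key permutation-null caches)."""
        if self._fingerprint is None:
            h = hashlib.sha1()
            h.update("\t".join(self.gene_ids).encode())
            h.update("\t".join(self.sample_ids).encode())
            h.update(np.ascontiguousarray(self.values).tobytes())
            self._fingerprint = h.hexdigest()
        return self._fingerprint

    def gene_submatrix(self, genes: Sequence[str]) -> np.ndarray:
        """Samples × genes array for ``genes`` (the analysis orientation)."""
        try:
            idx = [self._gene_index[g] for g in genes]
        except KeyError as e:
            raise ValidationError(f"gene not in matrix: {e.args[0]}") from None
        return self.values[idx, :].T.copy()

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(samples),
            values=self.values[:, idx],
            population={s: self.population[s] for s in samples},
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
            population=dict(self.population),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValidationError(f"collection key {name!r} != set name {gs.name!r}")

    def add(self, gs: GeneSet):
        if gs.name in self.sets:
            raise DuplicateIdError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass
class RestrictedSet:
    """A gene set intersected with the genes present in an expression matrix."""

    name: str
    genes: list[str]
    n_expressed: int
    n_total: int
    empty: bool

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def counts_label(self) -> str:
        """Formatted like Table-style '# of genes' columns, e.g. '94 / 191'."""
        return f"{self.n_expressed} / {self.n_total}"


@dataclass
class RunConfig:
    """Master seed plus per-stage parameters; every randomized operation
    reads its seed from here."""

    seed: int = 0
    params: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config root must be a mapping: {path}")
        known = {"seed", "params", "paths"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}) or {},
            paths=raw.get("paths", {}) or {},
        )

    def to_yaml(self, path: str | Path):
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"seed": self.seed, "params": self.params, "paths": self.paths}, fh
            )

    def stage(self, name: str, **defaults):
        """Stage parameters with defaults overridden by the config."""
        merged = dict(defaults)
        merged.update(self.params.get(name, {}))
        return merged


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, population_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a genes × samples TSV (header = sample ids, column 1 = gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except FileNotFoundError:
        raise
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression TSV {path}: {e}") from e
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdError(f"duplicated gene id(s): {dups[:5]}")
    if df.columns.has_duplicates:
        raise DuplicateIdError("duplicated sample id(s) in header")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise FormatError(f"non-numeric cell in expression TSV {path}: {e}") from e
    population = read_population_labels(population_path) if population_path else {}
    if population:
        population = {s: population[s] for s in df.columns}
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        population=population,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path):
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_population_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            sample, label = parts
            if sample in labels:
                raise DuplicateIdError(f"{path}:{ln}: duplicate sample {sample!r}")
            labels[sample] = label
    return labels


def write_population_labels(labels: Mapping[str, str], path: str | Path):
    with open(path, "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: name TAB description TAB gene TAB gene ...

    Duplicated genes within a set are deduplicated (order kept) with a
    logged warning; a line with fewer than 3 fields is an error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("GMT set %s: duplicated gene %s dropped", name, g)
                else:
                    seen[g] = None
            coll.add(GeneSet(name=name, description=desc, genes=list(seen)))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path):
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description] + gs.genes) + "\n")


def restrict_set(
    gene_set: GeneSet, expr: ExpressionMatrix, max_size: int = 150
) -> RestrictedSet:
    """Intersect a set with the matrix genes, reporting expressed/total counts.

    ``max_size`` is informational for callers filtering collections (sets
    with ≥ max_size expressed genes are typically skipped upstream).
    """
    present = set(expr.gene_ids)
    genes = [g for g in gene_set.genes if g in present]
    rs = RestrictedSet(
        name=gene_set.name,
        genes=genes,
        n_expressed=len(genes),
        n_total=len(gene_set.genes),
        empty=not genes,
    )
    if rs.empty:
        logger.warning("gene set %s has no expressed genes", gene_set.name)
    if rs.n_expressed >= max_size:
        logger.info(
            "gene set %s has %d expressed genes (>= %d)", gene_set.name,
            rs.n_expressed, max_size,
        )
    return rs


# ---------------------------------------------------------------------------
# Per-gene metric tables (h2, single-cell CV, normalized mean RMD, ...)
# ---------------------------------------------------------------------------

def read_gene_metric_table(path: str | Path) -> dict[str, float]:
    metrics: dict[str, float] = {}
    with open(path) as fh:
        first = True
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 fields")
            gene, value = parts
            if first:
                first = False
                try:
                    float(value)
                except ValueError:
                    continue  # header row
            try:
                v = float(value)
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-numeric metric") from e
            if not np.isfinite(v):
                raise ValidationError(f"{path}:{ln}: non-finite metric for {gene}")
            if gene in metrics:
                raise DuplicateIdError(f"{path}:{ln}: duplicate gene {gene!r}")
            metrics[gene] = v
    return metrics


def write_gene_metric_table(metrics: Mapping[str, float], path: str | Path,
                            header: tuple[str, str] | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"{header[0]}\t{header[1]}\n")
        for gene, v in metrics.items():
            fh.write(f"{gene}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# PCA sample QC
# ---------------------------------------------------------------------------

def pca_sample_qc(
    expr: ExpressionMatrix, n_components: int = 2, sd_cutoff: float = 4.0
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove samples with unusual global expression profiles.

    PCA on the full matrix (samples as observations); a sample whose score
    on any of the first ``n_components`` components lies more than
    ``sd_cutoff`` standard deviations from that component's mean is
    excluded.  A single pass — exclusion is not recomputed on the reduced
    matrix — so the excluded list is exactly reproducible.
    """
    if n_components == 0:
        return expr, []
    if expr.n_samples < 3:
        raise ValidationError("PCA sample QC needs at least 3 samples")
    n_components = min(n_components, expr.n_samples - 1, expr.n_genes)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(
        expr.values.T
    )
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs(scores - mean) / sd
    bad = np.where((z > sd_cutoff).any(axis=1))[0]
    excluded = [expr.sample_ids[i] for i in bad]
    if len(excluded) == expr.n_samples:
        raise ValidationError("PCA QC excluded every sample")
    if excluded:
        logger.info("PCA QC excluded %d samples: %s", len(excluded), excluded)
        keep = [s for s in expr.sample_ids if s not in set(excluded)]
        return expr.subset_samples(keep), excluded
    return expr, excluded
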