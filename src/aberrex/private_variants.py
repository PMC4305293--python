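"""Private (singleton) SNP identification, cis windows around genes,
chromatin-state interval intersection, per-class SNP densities, and the
enrichment test against four control schemes.

A variant is private to individual s when s is the only cohort member
carrying the alternate allele (heterozygous, allele frequency 1/(2N), or
homozygous, 1/N).  Private SNPs of outlier individuals are pooled inside
the cis windows of their aberrantly expressed genes, split by chromatin
state class (E, TSS, CTCF, T, PF, R, WE, UNCL), and the per-class density
(SNPs per Mb of class territory) is compared with densities from control
constructions by a one-tailed t test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from ._rng import spawn
from .errors import DegenerateInputError, FormatError, ValidationError

logger = logging.getLogger("aberrex")

CLASS_LABELS = ("E", "TSS", "CTCF", "T", "PF", "R", "WE", "UNCL")

MISSING = -1


@dataclass
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: np.ndarray  # per-sample dosage {0,1,2}, MISSING for no-call

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


@dataclass
class GenotypeTable:
    sample_ids: list[str]
    variants: list[Variant]

    def __post_init__(self):
        n = len(self.sample_ids)
        for v in self.variants:
            if len(v.genotypes) != n:
                raise ValidationError(
                    f"variant {v.chrom}:{v.pos} has {len(v.genotypes)} genotypes, "
                    f"expected {n}"
                )
        self.variants.sort(key=lambda v: (v.chrom, v.pos))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class RegulatorySegmentation:
    intervals: list[tuple[str, int, int, str]]  # chrom, start, end (0-based half-open)

    def __post_init__(self):
        for chrom, start, end, label in self.intervals:
            if start >= end:
                raise ValidationError(f"empty interval {chrom}:{start}-{end}")
            if label not in CLASS_LABELS:
                raise ValidationError(f"unknown segmentation class {label!r}")

    def to_ranges(self) -> pr.PyRanges:
        df = pd.DataFrame(
            self.intervals, columns=["Chromosome", "Start", "End", "Label"]
        )
        return pr.PyRanges(df)


# ---------------------------------------------------------------------------
# VCF / BED IO (CHROM/POS/REF/ALT/GT subset; SNPs only)
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeTable:
    """Read genotypes from a VCF (plain or bgzipped).

    Multi-allelic records are split per alternate allele; non-SNP alleles
    are skipped with a counter.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[Variant] = []
    n_skipped = 0
    for rec in vf.fetch() if vf.index is not None else vf:
        for ai, alt in enumerate(rec.alts or (), start=1):
            if len(rec.ref) != 1 or alt is None or len(alt) != 1 or alt == "*":
                n_skipped += 1
                continue
            dosages = np.empty(len(samples), dtype=np.int8)
            for si, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages[si] = MISSING
                else:
                    dosages[si] = sum(1 for a in gt if a == ai)
            variants.append(
                Variant(str(rec.chrom), int(rec.pos), rec.ref, alt, dosages)
            )
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP alleles", n_skipped)
    return GenotypeTable(sample_ids=samples, variants=variants)


def write_vcf(gt: GenotypeTable, path, chrom_sizes: Mapping[str, int] | None = None):
    chroms = dict(chrom_sizes or {})
    for v in gt.variants:
        chroms.setdefault(v.chrom, max(v.pos + 1, chroms.get(v.chrom, 0)))
        chroms[v.chrom] = max(chroms[v.chrom], v.pos + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, size in sorted(chroms.items()):
            fh.write(f"##contig=<ID={c},length={size}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for v in gt.variants:
            calls = "\t".join(gt_codes[int(g)] for g in v.genotypes)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_bed4(path) -> RegulatorySegmentation:
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4 line has fewer than 4 fields")
            intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return RegulatorySegmentation(intervals=intervals)


def write_bed(intervals: Sequence[tuple], path):
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Private SNPs
# ---------------------------------------------------------------------------

def find_private_snps(gt: GenotypeTable) -> dict[str, list[Variant]]:
    """Variants whose alternate allele occurs in exactly one individual.

    Missing genotypes exclude a sample from carrying but do not disqualify
    a variant from being private to another sample.
    """
    if gt.n_samples < 2:
        raise DegenerateInputError("privacy needs at least 2 individuals")
    out: dict[str, list[Variant]] = {s: [] for s in gt.sample_ids}
    for v in gt.variants:
        carriers = np.where(v.genotypes >= 1)[0]
        if len(carriers) == 1:
            out[gt.sample_ids[carriers[0]]].append(v)
    return out


# ---------------------------------------------------------------------------
# Windows and territories
# ---------------------------------------------------------------------------

def cis_windows(
    genes: Sequence[tuple[str, str, int, str]],
    window_bp: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[tuple[str, str, int, int]]:
    """TSS-centred windows of total length ``window_bp`` per gene.

    Input rows are (gene_id, chrom, tss, strand); strand is ignored (the
    window is symmetric about the TSS).  Windows are clipped at chromosome
    bounds; coordinates are 0-based half-open.
    """
    half = window_bp // 2
    out = []
    for gene_id, chrom, tss, _strand in genes:
        start = max(0, tss - half)
        end = tss + half
        if chrom_sizes and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        if start >= end:
            raise ValidationError(f"empty window for gene {gene_id}")
        out.append((gene_id, chrom, start, end))
    return out


def _windows_to_ranges(windows) -> pr.PyRanges:
    df = pd.DataFrame(
        [(c, s, e) for _, c, s, e in windows],
        columns=["Chromosome", "Start", "End"],
    )
    return pr.PyRanges(df)


def class_territory(
    windows, seg: RegulatorySegmentation
) -> dict[str, tuple[list[tuple[str, int, int]], float]]:
    """Per class: segmentation ∩ union of windows, merged, with total Mb.

    Classes with empty intersection are reported with territory 0 and an
    empty interval list (flagged by the caller before densities).
    """
    merged_windows = _windows_to_ranges(windows).merge()
    seg_pr = seg.to_ranges()
    out: dict[str, tuple[list, float]] = {}
    for label in CLASS_LABELS:
        sub = seg_pr[seg_pr.Label == label]
        if len(sub) == 0:
            out[label] = ([], 0.0)
            continue
        inter = sub.intersect(merged_windows)
        if len(inter) == 0:
            out[label] = ([], 0.0)
            continue
        m = inter.merge()
        df = m.df
        ivals = list(zip(df.Chromosome.astype(str), df.Start, df.End))
        mb = float((df.End - df.Start).sum()) / 1e6
        out[label] = (ivals, mb)
    return out


def _count_in_intervals(
    positions: dict[str, np.ndarray], intervals: list[tuple[str, int, int]]
) -> int:
    """Count 1-based positions with start < pos <= end over interval lists."""
    count = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivals in by_chrom.items():
        pos = positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        # pos-1 in [start, end)  <=>  start < pos <= end
        p0 = pos - 1
        idx = np.searchsorted(np.sort(starts), p0, side="right") - 1
        order = np.argsort(starts)
        sorted_ends = ends[order]
        inside = (idx >= 0) & (p0 < sorted_ends[np.clip(idx, 0, None)])
        count += int(inside.sum())
    return count


@dataclass
class DensityReport:
    observed: pd.DataFrame  # index class: snp_count, territory_mb, density
    controls: dict[int, pd.DataFrame] = field(default_factory=dict)
    p_values: pd.DataFrame | None = None


def density_per_class(
    private_variants: Sequence[Variant],
    territory: Mapping[str, tuple[list, float]],
) -> pd.DataFrame:
    """Pooled SNP count per class divided by class territory in Mb.

    SNPs are deduplicated within a class by (chrom, pos); classes with zero
    territory are flagged with NaN density.
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    seen = set()
    for v in private_variants:
        key = (v.chrom, v.pos)
        if key in seen:
            continue
        seen.add(key)
        pos_by_chrom.setdefault(v.chrom, []).append(v.pos)
    pos_by_chrom = {c: np.array(sorted(p)) for c, p in pos_by_chrom.items()}
    rows = []
    for label in CLASS_LABELS:
        ivals, mb = territory.get(label, ([], 0.0))
        n = _count_in_intervals(pos_by_chrom, ivals) if ivals else 0
        if mb > 0:
            density = n / mb
        else:
            density = np.nan
            logger.warning("class %s has zero territory", label)
        rows.append({"class": label, "snp_count": n, "territory_mb": mb,
                     "density": density})
    return pd.DataFrame(rows).set_index("class")


def _observed_densities(
    private_by_sample: Mapping[str, list[Variant]],
    outlier_genes: Mapping[str, list[str]],
    gene_coords: Mapping[str, tuple[str, int, str]],
    seg: RegulatorySegmentation,
    window_bp: int,
    chrom_sizes: Mapping[str, int] | None,
    translate: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pool counts over (outlier, gene) pairs; one shared territory from the
    union of all aberrant genes' windows."""
    all_genes = sorted({g for gl in outlier_genes.values() for g in gl})
    if not all_genes:
        raise DegenerateInputError("no aberrant genes supplied")
    win_rows = [(g, *gene_coords[g]) for g in all_genes]
    windows = cis_windows(win_rows, window_bp=window_bp, chrom_sizes=chrom_sizes)
    if translate:
        windows = [
            (g, c, s + translate.get(g, 0), e + translate.get(g, 0))
            for g, c, s, e in windows
        ]
    territory = class_territory(windows, seg)
    win_by_gene = {g: (c, s, e) for g, c, s, e in windows}
    pooled: list[Variant] = []
    for sample, gene_list in outlier_genes.items():
        snps = private_by_sample.get(sample, [])
        if not snps:
            continue
        for v in snps:
            for g in gene_list:
                c, s, e = win_by_gene[g]
                if v.chrom == c and s < v.pos <= e:
                    pooled.append(v)
                    break
    return density_per_class(pooled, territory)


def control_densities(
    scheme: int,
    replicates: int,
    seed: int,
    *,
    private_by_sample: Mapping[str, list[Variant]],
    outlier_genes: Mapping[str, list[str]],
    gene_coords: Mapping[str, tuple[str, int, str]],
    seg: RegulatorySegmentation,
    window_bp: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
    all_samples: Sequence[str] | None = None,
    gene_pool: Sequence[str] | None = None,
    s_gene_pool: Sequence[str] | None = None,
    displacement_bp: int = 10_000_000,
) -> pd.DataFrame:
    """Replicate control densities for one of the four schemes.

    1 — outlier individuals replaced by equally many random non-outliers
        (the gene mapping is carried over to the substitutes);
    2 — windows rebuilt from loci ``displacement_bp`` away from the genes
        (sign drawn per gene per replicate, with chromosome-bound fallback);
    3 — each outlier's aberrant genes replaced by a random same-size set
        from the expressed-gene pool;
    4 — like 3 but drawn from the S-class gene pool.

    Returns a long DataFrame (replicate, class, density).
    """
    if scheme not in (1, 2, 3, 4):
        raise ValidationError("scheme must be 1, 2, 3 or 4")
    outliers = list(outlier_genes)
    rows = []
    for r in range(replicates):
        rng = spawn(seed, "private-control", scheme, r)
        if scheme == 1:
            if all_samples is None:
                raise ValidationError("scheme 1 needs all_samples")
            non_outliers = [s for s in all_samples if s not in outlier_genes]
            if len(non_outliers) < len(outliers):
                raise DegenerateInputError(
                    "not enough non-outlier individuals for scheme 1"
                )
            subs = list(rng.choice(non_outliers, size=len(outliers), replace=False))
            mapping = {sub: outlier_genes[o] for sub, o in zip(subs, outliers)}
            dens = _observed_densities(
                private_by_sample, mapping, gene_coords, seg, window_bp, chrom_sizes
            )
        elif scheme == 2:
            translate = {}
            all_genes = {g for gl in outlier_genes.values() for g in gl}
            for g in all_genes:
                chrom, tss, _ = gene_coords[g]
                sign = 1 if rng.random() < 0.5 else -1
                shift = sign * displacement_bp
                half = window_bp // 2
                size = chrom_sizes.get(chrom) if chrom_sizes else None
                lo_ok = tss - half + shift >= 0
                hi_ok = size is None or tss + half + shift <= size
                if not (lo_ok and hi_ok):
                    shift = -shift
                translate[g] = shift
            dens = _observed_densities(
                private_by_sample, outlier_genes, gene_coords, seg, window_bp,
                chrom_sizes, translate=translate,
            )
        else:
            pool = gene_pool if scheme == 3 else s_gene_pool
            if pool is None:
                raise ValidationError(f"scheme {scheme} needs a gene pool")
            pool = [g for g in pool if g in gene_coords]
            # outliers sharing a gene list (same aberrant set) keep sharing
            # the replacement draw, preserving the pooled window structure
            draws: dict[tuple, list[str]] = {}
            mapping = {}
            for o in outliers:
                key = tuple(sorted(outlier_genes[o]))
                if key not in draws:
                    if len(key) > len(pool):
                        raise DegenerateInputError(
                            f"gene pool too small for scheme {scheme}"
                        )
                    draws[key] = list(rng.choice(pool, size=len(key), replace=False))
                mapping[o] = draws[key]
            dens = _observed_densities(
                private_by_sample, mapping, gene_coords, seg, window_bp, chrom_sizes
            )
        for label, row in dens.iterrows():
            rows.append(
                {"replicate": r, "class": label, "density": row["density"]}
            )
    return pd.DataFrame(rows)


def enrichment_test(observed: float, control: np.ndarray) -> float:
    """One-tailed t test of the observed density against the control
    replicate sample (single-case form, Crawford–Howell):

        t = (observed − mean(control)) / (sd(control) · sqrt(1 + 1/n)),

    referred to t with n − 1 degrees of freedom.  Small p = observed
    density enriched over controls.  The sqrt(1 + 1/n) factor keeps the
    null p uniform: the observed density carries the same replicate-level
    sampling noise as each control draw.
    """
    control = np.asarray(control, dtype=float)
    control = control[np.isfinite(control)]
    n = len(control)
    if n < 2:
        raise DegenerateInputError("need >= 2 control replicates")
    if not np.isfinite(observed):
        raise ValidationError("observed density is not finite")
    sd = control.std(ddof=1)
    if sd == 0:
        if control.mean() < observed:
            return 0.0
        return 1.0 if control.mean() > observed else 0.5
    t = (observed - control.mean()) / (sd * np.sqrt(1.0 + 1.0 / n))
    return float(stats.t.sf(t, df=n - 1))


def private_snp_density_report(
    gt: GenotypeTable,
    seg: RegulatorySegmentation,
    gene_coords: Mapping[str, tuple[str, int, str]],
    outlier_genes: Mapping[str, list[str]],
    window_bp: int = 1_000_000,
    schemes: Sequence[int] = (1, 2, 3, 4),
    replicates: int = 100,
    seed: int = 0,
    gene_pool: Sequence[str] | None = None,
    s_gene_pool: Sequence[str] | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> DensityReport:
    """Observed per-class private-SNP densities plus the requested control
    schemes and their one-tailed enrichment p-values."""
    private = find_private_snps(gt)
    observed = _observed_densities(
        private, outlier_genes, gene_coords, seg, window_bp, chrom_sizes
    )
    report = DensityReport(observed=observed)
    pvals = {}
    for scheme in schemes:
        ctrl = control_densities(
            scheme, replicates, seed,
            private_by_sample=private, outlier_genes=outlier_genes,
            gene_coords=gene_coords, seg=seg, window_bp=window_bp,
            chrom_sizes=chrom_sizes, all_samples=gt.sample_ids,
            gene_pool=gene_pool, s_gene_pool=s_gene_pool,
        )
        report.controls[scheme] = ctrl
        col = {}
        for label in CLASS_LABELS:
            obs = observed.loc[label, "density"]
            vec = ctrl.loc[ctrl["class"] == label, "density"].to_numpy()
            if np.isfinite(obs) and np.isfinite(vec).sum() >= 2:
                col[label] = enrichment_test(float(obs), vec)
            else:
                col[label] = np.nan
        pvals[f"scheme_{scheme}"] = col
    report.p_values = pd.DataFrame(pvals)
    return report
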