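import numpy as np
import pytest

from aberrex import private_variants as pv
from aberrex.errors import (
    DegenerateInputError,
    FormatError,
    ValidationError,
)


def table(genotype_rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(genotype_rows[0]))]
    variants = [
        pv.Variant("1", 100 + i, "A", "G", np.array(row, dtype=np.int8))
        for i, row in enumerate(genotype_rows)
    ]
    return pv.GenotypeTable(sample_ids=samples, variants=variants)


class TestFindPrivateSNPs:
    @pytest.mark.parametrize(
        "row,owner",
        [
            ((0, 1, 0), "s1"),   # heterozygous private
            ((0, 2, 0), "s1"),   # homozygous private
            ((1, 1, 0), None),   # two carriers: not private
            ((0, 0, 0), None),
        ],
    )
    def test_privacy_definition(self, row, owner):
        gt = table([row])
        private = pv.find_private_snps(gt)
        carriers = [s for s, vs in private.items() if vs]
        assert carriers == ([owner] if owner else [])

    def test_missing_genotype_does_not_disqualify(self):
        gt = table([(0, 1, pv.MISSING)])
        private = pv.find_private_snps(gt)
        assert len(private["s1"]) == 1

    def test_single_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            pv.find_private_snps(table([(1,)]))

    def test_each_variant_private_to_at_most_one(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 3, size=(50, 6))
        gt = table(list(rows))
        private = pv.find_private_snps(gt)
        total = sum(len(v) for v in private.values())
        assert total <= len(gt.variants)


class TestCisWindows:
    def test_tss_centered(self):
        out = pv.cis_windows([("G", "1", 2_000_000, "+")])
        assert out == [("G", "1", 1_500_000, 2_500_000)]

    def test_clipped_at_chromosome_bounds(self):
        out = pv.cis_windows(
            [("G", "1", 100_000, "+")], chrom_sizes={"1": 10_000_000}
        )
        assert out == [("G", "1", 0, 600_000)]

    def test_strand_ignored(self):
        plus = pv.cis_windows([("G", "1", 5_000_000, "+")])
        minus = pv.cis_windows([("G", "1", 5_000_000, "-")])
        assert plus == minus


class TestClassTerritory:
    def seg(self, intervals):
        return pv.RegulatorySegmentation(intervals=intervals)

    def test_fully_covered_interval(self):
        seg = self.seg([("1", 10_000, 11_000, "E")])
        windows = [("G", "1", 0, 1_000_000)]
        out = pv.class_territory(windows, seg)
        assert out["E"][1] == pytest.approx(0.001)

    def test_overlapping_windows_counted_once(self):
        seg = self.seg([("1", 500, 1_500, "TSS")])
        windows = [("G1", "1", 0, 1_000), ("G2", "1", 800, 2_000)]
        out = pv.class_territory(windows, seg)
        assert out["TSS"][1] == pytest.approx(0.001)

    def test_empty_intersection_flagged_zero(self):
        seg = self.seg([("2", 0, 1_000, "R")])
        out = pv.class_territory([("G", "1", 0, 1_000)], seg)
        assert out["R"] == ([], 0.0)

    def test_unknown_class_label_rejected(self):
        with pytest.raises(ValidationError):
            self.seg([("1", 0, 10, "BOGUS")])


class TestDensity:
    def test_zero_snps_zero_density(self):
        territory = {"E": ([("1", 0, 1_000_000)], 1.0)}
        out = pv.density_per_class([], territory)
        assert out.loc["E", "density"] == 0.0

    def test_density_invariant_to_interval_split(self):
        snps = [
            pv.Variant("1", p, "A", "G", np.array([1, 0], dtype=np.int8))
            for p in (10, 500, 900, 1500)
        ]
        whole = {"T": ([("1", 0, 2_000)], 0.002)}
        split = {"T": ([("1", 0, 1_000), ("1", 1_000, 2_000)], 0.002)}
        d1 = pv.density_per_class(snps, whole).loc["T", "density"]
        d2 = pv.density_per_class(snps, split).loc["T", "density"]
        assert d1 == d2

    def test_coordinate_convention_boundaries(self):
        # BED [100, 200) holds 1-based positions 101..200
        territory = {"E": ([("1", 100, 200)], 0.0001)}

        def count(pos):
            v = pv.Variant("1", pos, "A", "G", np.array([1, 0], dtype=np.int8))
            return pv.density_per_class([v], territory).loc["E", "snp_count"]

        assert count(100) == 0
        assert count(101) == 1
        assert count(200) == 1
        assert count(201) == 0


class TestVCFAndBed:
    def test_vcf_round_trip(self, tmp_path):
        gt = table([(0, 1, 0), (2, 0, pv.MISSING), (1, 1, 0)])
        path = tmp_path / "x.vcf"
        pv.write_vcf(gt, path)
        back = pv.read_vcf(path)
        assert back.sample_ids == gt.sample_ids
        assert len(back.variants) == 3
        for a, b in zip(back.variants, gt.variants):
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
            np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_bed4_round_trip(self, tmp_path):
        seg = pv.RegulatorySegmentation(
            [("1", 0, 100, "E"), ("1", 100, 300, "R")]
        )
        pv.write_bed(seg.intervals, tmp_path / "x.bed")
        back = pv.read_bed4(tmp_path / "x.bed")
        assert back.intervals == seg.intervals

    def test_short_bed_line_rejected(self, tmp_path):
        (tmp_path / "x.bed").write_text("1\t0\t100\n")
        with pytest.raises(FormatError):
            pv.read_bed4(tmp_path / "x.bed")


class TestEnrichmentTest:
    def test_observed_far_above_controls(self):
        control = np.random.default_rng(0).normal(1.0, 0.05, size=50)
        assert pv.enrichment_test(5.0, control) < 0.001

    def test_observed_at_control_mean(self):
        control = np.random.default_rng(1).normal(2.0, 0.2, size=200)
        p = pv.enrichment_test(float(control.mean()), control)
        assert 0.4 < p < 0.6

    def test_degenerate_controls(self):
        same = np.full(10, 3.0)
        assert pv.enrichment_test(3.0, same) == 0.5
        assert pv.enrichment_test(9.0, same) == 0.0

    def test_too_few_controls_rejected(self):
        with pytest.raises(DegenerateInputError):
            pv.enrichment_test(1.0, np.array([1.0]))


class TestControlSchemes:
    def setup_inputs(self):
        from aberrex.synthetic import make_segmentation, simulate_genotypes

        chrom_sizes = {"1": 40_000_000}
        seg = make_segmentation(chrom_sizes, seed=0)
        coords = {
            f"G{i}": ("1", 1_000_000 + 2_000_000 * i, "+") for i in range(8)
        }
        outlier_map = {"s000": ["G0", "G1"], "s001": ["G0", "G1"]}
        samples = [f"s{k:03d}" for k in range(12)]
        gt, _, _ = simulate_genotypes(
            samples, coords, seg, chrom_sizes, outlier_genes=outlier_map,
            base_rate_per_mb=2.0, seed=0,
        )
        return gt, seg, coords, outlier_map, chrom_sizes

    def test_same_seed_identical_replicates(self):
        gt, seg, coords, omap, sizes = self.setup_inputs()
        private = pv.find_private_snps(gt)
        kwargs = dict(
            private_by_sample=private, outlier_genes=omap, gene_coords=coords,
            seg=seg, chrom_sizes=sizes, all_samples=gt.sample_ids,
        )
        a = pv.control_densities(1, 4, 7, **kwargs)
        b = pv.control_densities(1, 4, 7, **kwargs)
        assert a.equals(b)

    def test_scheme1_without_non_outliers_errors(self):
        gt, seg, coords, omap, sizes = self.setup_inputs()
        private = pv.find_private_snps(gt)
        everyone = {s: ["G0"] for s in gt.sample_ids}
        with pytest.raises(DegenerateInputError):
            pv.control_densities(
                1, 2, 0, private_by_sample=private, outlier_genes=everyone,
                gene_coords=coords, seg=seg, chrom_sizes=sizes,
                all_samples=gt.sample_ids,
            )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValidationError):
            pv.control_densities(
                9, 1, 0, private_by_sample={}, outlier_genes={},
                gene_coords={}, seg=pv.RegulatorySegmentation([]),
            )
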