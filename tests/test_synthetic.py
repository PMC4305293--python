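import numpy as np
import pytest

from aberrex import synthetic
from aberrex import private_variants as pv
from aberrex.errors import ValidationError


class TestSimulateExpression:
    def test_bookkeeping_matches_requested_structure(self):
        expr, coll, truth = synthetic.simulate_expression(
            populations=(("EUR", 326),),
            sets=(synthetic.SetSpec("GPCR", 94, kind="L", rho=0.9,
                                    n_outliers=3),),
            n_background_genes=0,
            seed=0,
        )
        assert expr.values.shape == (94, 326)
        assert len(truth.planted_outliers["GPCR"]) == 3
        assert coll.sets["GPCR"].size == 94

    def test_planted_outliers_univariately_unremarkable(self):
        expr, coll, truth = synthetic.simulate_expression(
            populations=(("EUR", 200),),
            sets=(synthetic.SetSpec("HID", 10, kind="L", rho=0.9,
                                    n_outliers=4, displacement=6.0),),
            n_background_genes=0,
            spike_fraction=0.0,
            seed=1,
        )
        X = expr.gene_submatrix(coll.sets["HID"].genes)
        z = np.abs((X - X.mean(0)) / X.std(0, ddof=1))
        rows = [expr.sample_ids.index(s) for s in truth.planted_outliers["HID"]]
        assert z[rows].max() < 2.0

    def test_excessive_displacement_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.simulate_expression(
                populations=(("EUR", 50),),
                sets=(synthetic.SetSpec("X", 4, kind="L", rho=0.1,
                                        n_outliers=1, displacement=20.0),),
                seed=0,
            )

    def test_same_seed_identical_matrix(self):
        kwargs = dict(
            populations=(("EUR", 40),),
            sets=(synthetic.SetSpec("A", 5, kind="L", rho=0.8, n_outliers=2,
                                    displacement=8.0),),
            n_background_genes=30,
            seed=9,
        )
        e1, _, _ = synthetic.simulate_expression(**kwargs)
        e2, _, _ = synthetic.simulate_expression(**kwargs)
        np.testing.assert_array_equal(e1.values, e2.values)


class TestFig1Example:
    def test_two_genes_three_outliers_deterministic(self):
        e1, t1 = synthetic.make_fig1_example(seed=4)
        e2, _ = synthetic.make_fig1_example(seed=4)
        assert e1.n_genes == 2
        assert len(t1.planted_outliers["FIG1"]) == 3
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_outliers_within_population_per_gene_range(self):
        expr, truth = synthetic.make_fig1_example(seed=2)
        X = expr.values  # genes x samples
        rows = [expr.sample_ids.index(s) for s in truth.planted_outliers["FIG1"]]
        others = [i for i in range(expr.n_samples) if i not in rows]
        for g in range(2):
            lo, hi = X[g, others].min(), X[g, others].max()
            assert all(lo <= X[g, r] <= hi for r in rows)


class TestSimulateTwins:
    def test_zero_unique_env_gives_zero_mz_rmd(self):
        from aberrex.twins import mean_rmd_per_gene

        cohort, _ = synthetic.simulate_twins(
            n_mz=10, n_dz=10, n_genes=12, var_unique_env=0.0, seed=0
        )
        rmd = mean_rmd_per_gene(cohort, "MZ")
        assert max(rmd.values()) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_per_seed(self):
        c1, _ = synthetic.simulate_twins(n_mz=5, n_dz=5, n_genes=6, seed=8)
        c2, _ = synthetic.simulate_twins(n_mz=5, n_dz=5, n_genes=6, seed=8)
        np.testing.assert_array_equal(
            c1.expression.values, c2.expression.values
        )


class TestSimulateGenotypes:
    def build(self, seed=0, multipliers=None):
        chrom_sizes = {"1": 30_000_000}
        seg = synthetic.make_segmentation(chrom_sizes, seed=seed)
        coords = {f"G{i}": ("1", 1_000_000 + 2_000_000 * i, "+")
                  for i in range(6)}
        outlier_map = {"s000": ["G0", "G1"]}
        samples = [f"s{k:03d}" for k in range(10)]
        gt, esnp_table, truth = synthetic.simulate_genotypes(
            samples, coords, seg, chrom_sizes, outlier_genes=outlier_map,
            class_multipliers=multipliers or {}, base_rate_per_mb=1.0,
            esnp_spec=[("G2", 0.4, 0.5)], seed=seed,
        )
        return gt, esnp_table, truth, chrom_sizes

    def test_vcf_round_trip_reproduces_planted_singletons(self, tmp_path):
        gt, _, truth, chrom_sizes = self.build(seed=3)
        pv.write_vcf(gt, tmp_path / "g.vcf", chrom_sizes)
        back = pv.read_vcf(tmp_path / "g.vcf")
        private = pv.find_private_snps(back)
        recovered = {
            s: sorted((v.chrom, v.pos) for v in vs)
            for s, vs in private.items() if vs
        }
        planted = {
            s: sorted((c, p) for c, p in pos)
            for s, pos in truth.private_singletons.items()
        }
        # planted singletons must all be recovered; the only extras allowed
        # are common eSNP variants that happen to be singletons by chance
        for s, pos in planted.items():
            assert set(pos) <= set(recovered.get(s, []))
        esnp_positions = {(v.chrom, v.pos) for v in gt.variants
                          if v.genotypes.sum() > 2}
        for s, pos in recovered.items():
            extras = set(pos) - set(planted.get(s, []))
            assert extras <= esnp_positions

    def test_deterministic_per_seed(self):
        g1, _, _, _ = self.build(seed=5)
        g2, _, _, _ = self.build(seed=5)
        assert len(g1.variants) == len(g2.variants)
        for a, b in zip(g1.variants, g2.variants):
            assert (a.chrom, a.pos) == (b.chrom, b.pos)
            np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_esnp_effect_injection_is_linear(self):
        gt, esnp_table, _, _ = self.build(seed=1)
        from aberrex.formats_io import ExpressionMatrix

        expr = ExpressionMatrix(
            ["G2"], gt.sample_ids, np.zeros((1, len(gt.sample_ids)))
        )
        out = synthetic.inject_esnp_effects(expr, gt, esnp_table)
        v = next(v for v in gt.variants
                 if (v.chrom, v.pos) == (esnp_table.iloc[0]["chrom"],
                                         esnp_table.iloc[0]["pos"]))
        dos = v.genotypes.astype(float)
        centered = 0.5 * (dos - dos.mean())
        np.testing.assert_allclose(out.values[0], centered, atol=1e-12)

    def test_neutral_multipliers_give_uniform_enrichment_p(self):
        # with no planted enrichment the one-tailed p-values over classes
        # and seeds should look uniform
        pvals = []
        for seed in range(4):
            chrom_sizes = {"1": 30_000_000}
            seg = synthetic.make_segmentation(chrom_sizes, seed=seed)
            coords = {f"G{i}": ("1", 1_000_000 + 2_000_000 * i, "+")
                      for i in range(10)}
            omap = {f"s{k:03d}": [f"G{i}" for i in range(5)] for k in range(4)}
            samples = [f"s{k:03d}" for k in range(30)]
            gt, _, _ = synthetic.simulate_genotypes(
                samples, coords, seg, chrom_sizes, outlier_genes=omap,
                base_rate_per_mb=3.0, seed=seed,
            )
            rep = pv.private_snp_density_report(
                gt, seg, coords, omap, schemes=(1,), replicates=20,
                seed=seed, chrom_sizes=chrom_sizes,
            )
            pvals.extend(rep.p_values["scheme_1"].dropna().tolist())
        from scipy import stats

        pvals = [p for p in pvals if 0.0 < p < 1.0]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBenchmarkPreset:
    def test_collection_composition(self):
        bench = synthetic.benchmark_preset(seed=0)
        coll = bench["collection"]
        truth = bench["truth"]
        assert len(truth.planted_L_sets) == 15
        assert len(truth.planted_S_sets) == 15
        assert len(coll) == 80
        assert bench["expression"].values.shape == (1500, 160)
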