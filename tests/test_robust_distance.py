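import numpy as np
import pytest
from scipy import linalg

from aberrex import robust_distance as rd
from aberrex.errors import (
    DegenerateInputError,
    SingularCovarianceError,
    ValidationError,
)
from aberrex.synthetic import make_fig1_example


def brute_force_md(X, location, scatter):
    """Independent oracle: explicit matrix inverse, row by row."""
    inv = linalg.inv(scatter)
    return np.array(
        [np.sqrt((x - location) @ inv @ (x - location)) for x in X]
    )


class TestEstimateRobustCovariance:
    def test_mcd_scatter_close_to_identity_on_clean_mvn(self):
        X = np.random.default_rng(0).standard_normal((1000, 5))
        model = rd.estimate_robust_covariance(X, seed=0)
        # oracle: sample covariance of the MCD support points
        support_cov = np.cov(X[model.support_mask], rowvar=False)
        assert np.linalg.norm(model.scatter - np.eye(5)) < 0.3
        assert np.linalg.norm(support_cov - np.eye(5)) < 0.3

    def test_robust_location_resists_gross_outlier(self):
        rng = np.random.default_rng(1)
        clean = rng.standard_normal((50, 2))
        X = np.vstack([clean, [[100.0, 100.0]]])
        model = rd.estimate_robust_covariance(X, seed=1)
        clean_mean = clean.mean(axis=0)
        classical_mean = X.mean(axis=0)
        assert np.linalg.norm(model.location - clean_mean) < np.linalg.norm(
            classical_mean - clean_mean
        )

    def test_zero_variance_column_error_names_gene(self):
        X = np.random.default_rng(2).standard_normal((40, 3))
        X[:, 1] = 5.0
        with pytest.raises(SingularCovarianceError, match="GENE_B"):
            rd.estimate_robust_covariance(
                X, gene_names=["GENE_A", "GENE_B", "GENE_C"]
            )

    def test_too_few_samples_error(self):
        with pytest.raises(DegenerateInputError):
            rd.estimate_robust_covariance(np.eye(3))

    def test_classical_fallback_when_n_below_2m(self, caplog):
        X = np.random.default_rng(3).standard_normal((25, 15))
        with caplog.at_level("WARNING", logger="aberrex"):
            model = rd.estimate_robust_covariance(X, support_fraction=0.8)
        assert model.method == "classical"
        assert any("falling back" in r.message for r in caplog.records)

    def test_full_support_equals_classical_moments(self):
        X = np.random.default_rng(4).standard_normal((30, 4))
        model = rd.estimate_robust_covariance(X, support_fraction=1.0)
        np.testing.assert_allclose(model.location, X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            model.scatter, np.cov(X, rowvar=False), atol=1e-12
        )


class TestMahalanobisDistances:
    @pytest.mark.parametrize(
        "location,scatter,x,expected",
        [
            ([0.0], [[1.0]], [3.0], 3.0),                      # |x-mu|/sigma
            ([0.0, 0.0], np.eye(2), [3.0, 4.0], 5.0),          # Euclidean
            (
                [0.0, 0.0],
                [[1.0, 0.9], [0.9, 1.0]],
                [1.0, 1.0],
                np.sqrt(0.2 / 0.19),                           # explicit 2x2 inverse
            ),
        ],
    )
    def test_closed_form_examples(self, location, scatter, x, expected):
        model = rd.RobustCovarianceModel(
            np.asarray(location), np.asarray(scatter), 1.0,
            np.ones(1, dtype=bool), "classical",
        )
        prof = rd.mahalanobis_distances(np.array([x]), model)
        assert prof.md[0] == pytest.approx(expected, abs=1e-10)
        assert prof.df == len(location)

    def test_matches_brute_force_oracle(self):
        X = np.random.default_rng(5).standard_normal((10, 3))
        model = rd.estimate_robust_covariance(X, support_fraction=1.0)
        prof = rd.mahalanobis_distances(X, model)
        np.testing.assert_allclose(
            prof.md, brute_force_md(X, model.location, model.scatter), atol=1e-8
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 3))
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        shift = rng.standard_normal(3)
        Y = X @ A.T + shift
        md_x = rd.mahalanobis_distances(
            X, rd.estimate_robust_covariance(X, support_fraction=1.0)
        ).md
        md_y = rd.mahalanobis_distances(
            Y, rd.estimate_robust_covariance(Y, support_fraction=1.0)
        ).md
        np.testing.assert_allclose(md_x, md_y, atol=1e-8)

    def test_dimension_mismatch(self):
        model = rd.RobustCovarianceModel(
            np.zeros(2), np.eye(2), 1.0, np.ones(1, dtype=bool)
        )
        with pytest.raises(ValidationError):
            rd.mahalanobis_distances(np.ones((3, 3)), model)


class TestChiSquarePlot:
    def test_probs_formula(self):
        prof = rd.MDProfile(
            md=np.array([1.0, 2.0, 0.5, 3.0]),
            md_squared=np.array([1.0, 4.0, 0.25, 9.0]),
            df=2,
            sample_ids=list("abcd"),
        )
        plot = rd.chi_square_plot_coordinates(prof)
        np.testing.assert_allclose(
            plot.quantile_probs, [0.125, 0.375, 0.625, 0.875]
        )
        np.testing.assert_array_equal(
            plot.ranked_md_squared, np.sort(prof.md_squared)
        )
        # chi2 with df=2 median is 2 ln 2
        assert rd.stats.chi2.ppf(0.5, 2) == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_empty_profile_rejected(self):
        prof = rd.MDProfile(np.empty(0), np.empty(0), 2, [])
        with pytest.raises(ValidationError):
            rd.chi_square_plot_coordinates(prof)


class TestCallOutliers:
    def test_planted_extreme_sample_flagged(self):
        md2 = np.ones(20)
        md2[3] = 10 * rd.stats.chi2.ppf(0.975, 5)
        prof = rd.MDProfile(np.sqrt(md2), md2, 5, [f"s{i}" for i in range(20)])
        call = rd.call_outliers(prof)
        assert call.outlier_sample_ids == ["s3"]
        assert all(
            prof.md_squared[prof.sample_ids.index(s)] > call.threshold_md_squared
            for s in call.outlier_sample_ids
        )

    def test_null_false_positive_rate_near_nominal(self):
        flagged = 0
        for seed in range(5):
            X = np.random.default_rng(200 + seed).standard_normal((400, 5))
            model = rd.estimate_robust_covariance(X, seed=seed)
            prof = rd.mahalanobis_distances(X, model)
            flagged += len(rd.call_outliers(prof, 0.975).outlier_sample_ids)
        rate = flagged / (5 * 400)
        sd = np.sqrt(0.025 * 0.975 / 400)
        assert abs(rate - 0.025) < 2 * sd

    def test_fig1_outliers_found_by_md_missed_univariately(self):
        expr, truth = make_fig1_example(seed=11)
        X = expr.gene_submatrix(expr.gene_ids)
        model = rd.estimate_robust_covariance(X, seed=11)
        prof = rd.mahalanobis_distances(X, model, sample_ids=expr.sample_ids)
        planted = set(truth.planted_outliers["FIG1"])
        assert planted <= set(rd.call_outliers(prof).outlier_sample_ids)
        # a per-gene |z| > 3 rule sees nothing unusual in the planted samples
        z = np.abs((X - X.mean(0)) / X.std(0, ddof=1))
        rows = [expr.sample_ids.index(s) for s in planted]
        assert z[rows].max() < 3

    def test_gap_method_flags_broken_tail_only(self):
        md2 = np.concatenate([np.linspace(0.5, 4, 30), [30.0, 31.0]])
        prof = rd.MDProfile(
            np.sqrt(md2), md2, 2, [f"s{i}" for i in range(32)]
        )
        call = rd.call_outliers(prof, 0.975, method="gap")
        assert sorted(call.outlier_sample_ids) == ["s30", "s31"]

    def test_invalid_quantile(self):
        prof = rd.MDProfile(np.ones(3), np.ones(3), 2, list("abc"))
        with pytest.raises(ValidationError):
            rd.call_outliers(prof, quantile=1.5)
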