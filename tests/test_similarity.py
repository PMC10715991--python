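"""Reference-model and Mahalanobis-distance tests with explicit-inverse oracles."""

import numpy as np
import pandas as pd
import pytest

import nirstab as ns
from conftest import make_spectrum


def standards_from_matrix(X, grid, brand="TT"):
    spectra = [
        make_spectrum(row, grid, sample_id=f"std{i}", brand=brand,
                      batch_id=f"S{i}", role="standard")
        for i, row in enumerate(X)
    ]
    return ns.SpectrumSet(grid=grid, spectra=spectra)


def grid_of(n):
    return ns.WavenumberGrid(4000.0, 8.0, n)


def brute_force_D(x, X):
    """Explicit-inverse oracle: (x-mu) S^-1 (x-mu)^T with S the n-1 covariance."""
    mu = X.mean(axis=0)
    S = np.cov(X, rowvar=False)
    return float((x - mu) @ np.linalg.inv(S) @ (x - mu))


class TestFitReference:
    def test_mixed_brands_rejected(self):
        grid = grid_of(4)
        rng = np.random.default_rng(0)
        spectra = [
            make_spectrum(rng.normal(size=4), grid, sample_id=f"s{i}",
                          brand=b, batch_id="S1", role="standard")
            for i, b in enumerate(["TT", "TT", "AA"])
        ]
        with pytest.raises(ns.ValidationError, match="brands"):
            ns.fit_reference(ns.SpectrumSet(grid=grid, spectra=spectra))

    def test_too_few_standards_rejected(self):
        grid = grid_of(4)
        X = np.random.default_rng(0).normal(size=(2, 4))
        with pytest.raises(ns.ValidationError, match="at least 3"):
            ns.fit_reference(standards_from_matrix(X, grid))

    def test_classical_rank_error_instructs_alternatives(self):
        grid = grid_of(10)
        X = np.random.default_rng(0).normal(size=(5, 10))
        with pytest.raises(ns.NumericalError, match="subspace"):
            ns.fit_reference(standards_from_matrix(X, grid), method="classical")

    def test_duplicated_standards_drop_rank_subspace_still_fits(self):
        grid = grid_of(8)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 8))
        X[5] = X[4]  # duplicate -> centered rank drops to n-2
        model = ns.fit_reference(
            standards_from_matrix(X, grid), method="pca_subspace", variance_retained=1.0
        )
        assert model.k <= 4  # k <= n_ref - 2
        assert np.all(model.eigenvalues > 0)


class TestMahalanobisD:
    def test_zero_at_the_mean(self):
        grid = grid_of(3)
        X = np.random.default_rng(2).normal(size=(10, 3))
        model = ns.fit_reference(standards_from_matrix(X, grid), method="classical")
        x = make_spectrum(model.mu, grid, sample_id="at_mean")
        assert ns.mahalanobis_D(x, model) == pytest.approx(0.0, abs=1e-18)

    def test_identity_covariance_quadratic_form(self):
        """mu=(0,0), C=I, x=(3,4) -> D = 25 (the squared distance, as defined)."""
        grid = grid_of(2)
        model = ns.ReferenceModel(
            mu=np.zeros(2), grid=grid, brand="TT", method="classical",
            n_ref=10, covariance=np.eye(2),
        )
        x = make_spectrum([3.0, 4.0], grid, sample_id="x")
        assert ns.mahalanobis_D(x, model) == pytest.approx(25.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_explicit_inverse_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        d = int(rng.integers(2, 21))
        n = d + int(rng.integers(5, 15))
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        model = ns.fit_reference(standards_from_matrix(X, grid), method="classical")
        x_vals = rng.normal(size=d)
        x = make_spectrum(x_vals, grid, sample_id="probe")
        expected = brute_force_D(x_vals, X)
        assert ns.mahalanobis_D(x, model) == pytest.approx(expected, rel=1e-8)

    def test_sum_over_reference_samples_identity(self):
        """Sum of D over the n_ref training spectra equals d*(n_ref-1)."""
        rng = np.random.default_rng(42)
        d, n = 6, 30
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        standards = standards_from_matrix(X, grid)
        model = ns.fit_reference(standards, method="classical")
        total = sum(ns.mahalanobis_D(s, model) for s in standards)
        assert total == pytest.approx(d * (n - 1), rel=1e-6)

    def test_affine_invariance_classical(self):
        """D is invariant under an invertible linear map of x and the standards."""
        rng = np.random.default_rng(17)
        d, n = 5, 40
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        A = rng.normal(size=(d, d)) + 3 * np.eye(d)
        x = rng.normal(size=d)
        m1 = ns.fit_reference(standards_from_matrix(X, grid), method="classical")
        m2 = ns.fit_reference(standards_from_matrix(X @ A.T, grid), method="classical")
        d1 = ns.mahalanobis_D(make_spectrum(x, grid, sample_id="p"), m1)
        d2 = ns.mahalanobis_D(make_spectrum(A @ x, grid, sample_id="p"), m2)
        assert d1 == pytest.approx(d2, rel=1e-8)

    def test_monotone_along_fixed_direction(self):
        rng = np.random.default_rng(23)
        d, n = 4, 25
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        model = ns.fit_reference(standards_from_matrix(X, grid), method="classical")
        direction = rng.normal(size=d)
        ds = [
            ns.mahalanobis_D(make_spectrum(model.mu + t * direction, grid, sample_id="p"), model)
            for t in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a <= b for a, b in zip(ds, ds[1:]))

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        model = ns.fit_reference(
            standards_from_matrix(rng.normal(size=(10, 4)), grid_of(4)), method="classical"
        )
        x = make_spectrum(np.ones(4), ns.WavenumberGrid(4000.0, 4.0, 4), sample_id="x")
        with pytest.raises(ns.ValidationError):
            ns.mahalanobis_D(x, model)


class TestSubspaceClassicalConsistency:
    @pytest.mark.parametrize("trial", range(3))
    def test_full_variance_subspace_equals_classical(self, trial):
        rng = np.random.default_rng(200 + trial)
        d, n = 8, 40
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        standards = standards_from_matrix(X, grid)
        classical = ns.fit_reference(standards, method="classical")
        subspace = ns.fit_reference(standards, method="pca_subspace", variance_retained=1.0)
        for _ in range(10):
            x = make_spectrum(rng.normal(size=d), grid, sample_id="p")
            assert ns.mahalanobis_D(x, subspace) == pytest.approx(
                ns.mahalanobis_D(x, classical), rel=1e-8
            )

    def test_shrinkage_interpolates_toward_classical(self):
        rng = np.random.default_rng(9)
        d, n = 5, 200
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        standards = standards_from_matrix(X, grid)
        shrunk = ns.fit_reference(standards, method="shrinkage")
        classical = ns.fit_reference(standards, method="classical")
        assert 0 <= shrunk.shrinkage_intensity <= 1
        x = make_spectrum(rng.normal(size=d), grid, sample_id="p")
        # with n >> d the shrinkage intensity is small, distances close
        assert ns.mahalanobis_D(x, shrunk) == pytest.approx(
            ns.mahalanobis_D(x, classical), rel=0.2
        )


class TestBatchAverage:
    def test_identical_batch_is_idempotent(self):
        grid = grid_of(4)
        v = np.array([1.0, 2.0, 3.0, 4.0])
        spectra = [
            make_spectrum(v, grid, sample_id=f"s{i}") for i in range(3)
        ]
        out = ns.batch_average(ns.SpectrumSet(grid=grid, spectra=spectra))
        assert len(out) == 1
        assert np.array_equal(out[0].values, v)

    def test_two_spectra_midpoint(self):
        grid = grid_of(3)
        a = make_spectrum([0.0, 0.0, 0.0], grid, sample_id="a")
        b = make_spectrum([2.0, 4.0, 6.0], grid, sample_id="b")
        out = ns.batch_average(ns.SpectrumSet(grid=grid, spectra=[a, b]))
        assert np.array_equal(out[0].values, [1.0, 2.0, 3.0])

    def test_random_batches_match_arithmetic_oracle(self):
        rng = np.random.default_rng(31)
        grid = grid_of(6)
        spectra = []
        for i in range(12):
            spectra.append(make_spectrum(
                rng.normal(size=6), grid, sample_id=f"s{i}", batch_id=f"B{i % 4}",
            ))
        spectrum_set = ns.SpectrumSet(grid=grid, spectra=spectra)
        out = ns.batch_average(spectrum_set)
        assert len(out) == 4
        for avg in out:
            members = [s.values for s in spectrum_set if s.meta.batch_id == avg.meta.batch_id]
            assert np.allclose(avg.values, np.mean(members, axis=0), atol=1e-15)

    def test_missing_batch_id_rejected(self):
        grid = grid_of(3)
        s = ns.Spectrum(
            meta=ns.SpectrumMeta(sample_id="e", role="empty_pad"),
            grid=grid, values=np.ones(3),
        )
        with pytest.raises(ns.ValidationError, match="batch_id"):
            ns.batch_average(ns.SpectrumSet.from_spectra([s]))


class TestStabilityTimeline:
    def test_products_at_the_mean_score_zero(self):
        rng = np.random.default_rng(37)
        d, n = 4, 20
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        model = ns.fit_reference(standards_from_matrix(X, grid), method="classical")
        products = ns.SpectrumSet(grid=grid, spectra=[
            make_spectrum(model.mu, grid, sample_id=f"p{i}", batch_id=f"B{i}",
                          date_index=i)
            for i in range(3)
        ])
        result = ns.stability_timeline(products, model)
        assert np.allclose(result.per_sample["D"], 0.0, atol=1e-18)

    def test_single_spectrum_batches_equal_per_sample(self):
        rng = np.random.default_rng(38)
        d, n = 4, 20
        grid = grid_of(d)
        model = ns.fit_reference(
            standards_from_matrix(rng.normal(size=(n, d)), grid), method="classical"
        )
        products = ns.SpectrumSet(grid=grid, spectra=[
            make_spectrum(rng.normal(size=d), grid, sample_id=f"p{i}",
                          batch_id=f"B{i}", date_index=i)
            for i in range(5)
        ])
        result = ns.stability_timeline(products, model)
        assert np.allclose(
            result.per_batch["D"].to_numpy(), result.per_sample["D"].to_numpy()
        )

    def test_entries_ordered_by_date_index(self, demo_report):
        di = demo_report.stability.per_sample["date_index"].to_numpy()
        assert np.all(np.diff(di) >= 0)
        assert demo_report.stability.per_batch["batch_id"].is_unique

    def test_interbrand_exceeds_intrabrand_exhaustively(self, demo_report):
        """On the simulated two-brand study every AA distance to the TT
        reference exceeds every TT sample distance."""
        inter = demo_report.inter_brand["D"].to_numpy()
        intra = demo_report.stability.per_sample["D"].to_numpy()
        assert inter.min() > intra.max()


class TestPcaScores:
    def test_collinear_data_explained_by_pc1(self):
        grid = grid_of(6)
        direction = np.linspace(1, 2, 6)
        spectra = [
            make_spectrum(t * direction, grid, sample_id=f"s{i}")
            for i, t in enumerate(np.linspace(-2, 2, 9))
        ]
        scores = ns.pca_scores(ns.SpectrumSet(grid=grid, spectra=spectra), n_components=2)
        ratios = scores.attrs["explained_variance_ratio"]
        assert ratios[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_preserve_pairwise_distances_at_full_rank(self):
        rng = np.random.default_rng(55)
        grid = grid_of(5)
        X = rng.normal(size=(8, 5))
        spectra = [
            make_spectrum(row, grid, sample_id=f"s{i}") for i, row in enumerate(X)
        ]
        scores = ns.pca_scores(
            ns.SpectrumSet(grid=grid, spectra=spectra), n_components=5
        )
        S = scores[[f"PC{j}" for j in range(1, 6)]].to_numpy()
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.linalg.norm(S[i] - S[j]) == pytest.approx(
                    np.linalg.norm(X[i] - X[j]), rel=1e-8
                )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(56)
        grid = grid_of(5)
        spectra = [
            make_spectrum(rng.normal(size=5), grid, sample_id=f"s{i}") for i in range(7)
        ]
        fwd = ns.pca_scores(ns.SpectrumSet(grid=grid, spectra=spectra), 2)
        rev = ns.pca_scores(ns.SpectrumSet(grid=grid, spectra=spectra[::-1]), 2)
        merged = fwd.merge(rev, on="sample_id", suffixes=("_f", "_r"))
        assert np.allclose(merged["PC1_f"], merged["PC1_r"], atol=1e-10)
        assert np.allclose(merged["PC2_f"], merged["PC2_r"], atol=1e-10)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(57)
        grid = grid_of(5)
        spectra = [
            make_spectrum(rng.normal(size=5), grid, sample_id=f"s{i}") for i in range(4)
        ]
        with pytest.raises(ns.ConfigError):
            ns.pca_scores(ns.SpectrumSet(grid=grid, spectra=spectra), n_components=4)


class TestModelSerialization:
    def test_json_round_trip_preserves_distances(self):
        rng = np.random.default_rng(60)
        d, n = 12, 8
        grid = grid_of(d)
        X = rng.normal(size=(n, d))
        model = ns.fit_reference(standards_from_matrix(X, grid))
        restored = ns.ReferenceModel.from_json_dict(model.to_json_dict())
        x = make_spectrum(rng.normal(size=d), grid, sample_id="p")
        assert ns.mahalanobis_D(x, restored) == pytest.approx(
            ns.mahalanobis_D(x, model), rel=1e-12
        )
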