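"""Per-window PCA: imputation, scaling, eigendecomposition, GL iteration."""

import numpy as np
import pytest

from winscan import variant_io, windowed_pca
from winscan.variant_io import ScanParams, VariantRecord, WindowSpec
from winscan.windowed_pca import (
    GenotypeMatrix,
    LikelihoodMatrix,
    expected_genotypes,
    gl_pca_window,
    mean_impute,
    pca_window,
    run_windowed_pca,
    standardize,
)

from conftest import pca_oracle


def _params(**kw):
    kw.setdefault("window_size", 100)
    kw.setdefault("step_size", 100)
    kw.setdefault("min_variants", 2)
    return ScanParams(**kw)


def _certain_likelihoods(genotypes):
    lik = np.zeros(genotypes.shape + (3,))
    for g in (0, 1, 2):
        lik[..., g] = genotypes == g
    return lik


class TestMeanImpute:
    def test_complete_matrix_unchanged(self):
        g = GenotypeMatrix(np.array([[0.0, 1], [2, 1]]))
        out, dropped = mean_impute(g)
        np.testing.assert_array_equal(out.values, g.values)
        assert dropped == 0

    def test_missing_becomes_column_mean(self):
        g = GenotypeMatrix(np.array([[0.0], [2.0], [np.nan]]))
        out, _ = mean_impute(g)
        assert out.values[2, 0] == 1.0

    def test_all_missing_column_dropped_and_counted(self):
        vals = np.ones((3, 4))
        vals[:, 2] = np.nan
        out, dropped = mean_impute(GenotypeMatrix(vals))
        assert out.values.shape == (3, 3)
        assert dropped == 1


class TestStandardize:
    def test_patterson_scaling_hand_computed(self):
        # column [0,1,2]: p = 0.5, centered (-1,0,1), / sqrt(0.25) = (-2,0,2)
        x, keep = standardize(np.array([[0.0], [1.0], [2.0]]), "patterson")
        np.testing.assert_allclose(x[:, 0], [-2.0, 0.0, 2.0])

    def test_centering_sums_to_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, size=(6, 8)).astype(float)
        x, keep = standardize(vals, "center")
        np.testing.assert_allclose(x.sum(axis=0), 0.0, atol=1e-12)

    def test_monomorphic_columns_dropped(self):
        vals = np.array([[2.0, 0.0], [2.0, 1.0], [2.0, 2.0]])
        x, keep = standardize(vals, "patterson")
        assert keep.tolist() == [False, True]
        assert x.shape == (3, 1)


class TestPcaWindow:
    def test_two_group_configuration(self):
        rng = np.random.default_rng(1)
        row_a = rng.integers(0, 3, 30).astype(float)
        row_b = rng.integers(0, 3, 30).astype(float)
        vals = np.vstack([np.tile(row_a, (3, 1)), np.tile(row_b, (3, 1))])
        res = pca_window(GenotypeMatrix(vals), _params())
        s = res.scores[1]
        assert np.allclose(s[:3], s[0]) and np.allclose(s[3:], s[3])
        assert np.sign(s[0]) == -np.sign(s[3])
        assert abs(s.sum()) < 1e-9 * np.abs(s).max()

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(3, 13)
            m = rng.integers(5, 41)
            vals = rng.integers(0, 3, size=(n, m)).astype(float)
            res = pca_window(GenotypeMatrix(vals), _params(pcs=(1, 2)))
            if not res.valid:
                continue
            oracle = pca_oracle(vals)
            for pc in (1, 2):
                a, b = res.scores[pc], oracle[:, pc - 1]
                assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_below_min_variants_invalid(self):
        vals = np.array([[0.0, 1], [1, 2], [2, 0]])
        res = pca_window(GenotypeMatrix(vals), _params(min_variants=3))
        # only 2 usable variants < min_variants
        assert not res.valid
        assert np.isnan(res.scores[1]).all()

    def test_fewer_than_two_samples_fatal(self):
        with pytest.raises(ValueError, match="2 samples"):
            pca_window(GenotypeMatrix(np.array([[0.0, 1, 2]])), _params())

    def test_var_explained_nonincreasing(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 3, size=(10, 30)).astype(float)
        res = pca_window(GenotypeMatrix(vals), _params(pcs=(1, 2, 3)))
        ve = [res.var_explained[pc] for pc in (1, 2, 3)]
        assert ve[0] >= ve[1] >= ve[2] >= 0

    def test_missingness_robustness_on_structured_matrix(self):
        rng = np.random.default_rng(3)
        p = np.where(np.arange(200) % 2 == 0, 0.9, 0.1)
        vals = np.vstack([rng.binomial(2, p, size=(8, 200)),
                          rng.binomial(2, p[::-1], size=(8, 200))]).astype(float)
        full = pca_window(GenotypeMatrix(vals), _params())
        masked = vals.copy()
        masked[rng.random(vals.shape) < 0.10] = np.nan
        part = pca_window(GenotypeMatrix(masked), _params())
        r = np.corrcoef(full.scores[1], part.scores[1])[0, 1]
        assert abs(r) > 0.95


class TestExpectedGenotypes:
    def test_certain_triplet_ignores_prior(self):
        lik = np.zeros((1, 1, 3))
        lik[0, 0, 2] = 1.0
        for p in (0.01, 0.5, 0.99):
            e = expected_genotypes(LikelihoodMatrix(lik), np.array([p]))
            assert np.allclose(e, 2.0)

    def test_flat_triplet_returns_hwe_mean(self):
        lik = np.full((1, 1, 3), 1 / 3)
        for p in (0.1, 0.5, 0.8):
            e = expected_genotypes(LikelihoodMatrix(lik), np.array([p]))
            assert np.allclose(e, 2 * p, atol=1e-12)

    def test_hand_bayes_computation(self):
        # (0.1, 0.8, 0.1) with p=0.5 prior (0.25, 0.5, 0.25):
        # posterior ~ (0.025, 0.4, 0.025) -> E[g] = (0.4 + 2*0.025)/0.45 = 1.0
        lik = np.array([[[0.1, 0.8, 0.1]]])
        e = expected_genotypes(LikelihoodMatrix(lik), np.array([0.5]))
        assert np.allclose(e, 1.0)

    def test_per_individual_frequencies(self):
        lik = np.full((2, 1, 3), 1 / 3)
        freqs = np.array([[0.2], [0.8]])
        e = expected_genotypes(LikelihoodMatrix(lik), freqs)
        np.testing.assert_allclose(e[:, 0], [0.4, 1.6])


class TestGlPcaWindow:
    def test_certain_likelihoods_equal_hard_call_path(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(12, 40)).astype(float)
        gt = pca_window(GenotypeMatrix(geno), _params())
        gl = gl_pca_window(LikelihoodMatrix(_certain_likelihoods(geno)), _params())
        assert gl.converged
        for pc in (1, 2):
            np.testing.assert_allclose(gl.scores[pc], gt.scores[pc], atol=1e-6)

    def test_depth_limit_correlation_nondecreasing(self, small_cohort):
        from winscan import synth
        g = small_cohort.genotypes
        inside = (small_cohort.positions >= 150_001) & (small_cohort.positions <= 350_000)
        g = g[:, ~inside][:, :300]  # structured, inversion-free block
        truth = pca_window(GenotypeMatrix(g), _params()).scores[1]
        rng = np.random.default_rng(5)
        cors = []
        for depth in (2, 8, 30):
            lik = synth.simulate_likelihoods(g.astype(int), depth, 0.01, rng)
            res = gl_pca_window(LikelihoodMatrix(lik), _params())
            cors.append(abs(np.corrcoef(res.scores[1], truth)[0, 1]))
        assert cors == sorted(cors)
        assert cors[-1] > 0.99

    def test_flat_sample_lands_between_population_means(self):
        rng = np.random.default_rng(6)
        p = np.where(np.arange(100) % 2 == 0, 0.95, 0.05)
        geno = np.vstack([rng.binomial(2, p, size=(5, 100)),
                          rng.binomial(2, p[::-1], size=(5, 100))])
        lik = _certain_likelihoods(geno)
        lik[0] = 1 / 3  # sample 0 carries no information
        res = gl_pca_window(LikelihoodMatrix(lik), _params())
        s = res.scores[1]
        lo, hi = sorted([s[1:5].mean(), s[5:].mean()])
        assert lo < s[0] < hi

    def test_nonconvergence_flag_not_error(self):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 3, size=(6, 30)).astype(float)
        lik = 0.4 * _certain_likelihoods(geno) + 0.2
        lik /= lik.sum(axis=-1, keepdims=True)
        res = gl_pca_window(LikelihoodMatrix(lik), _params(), max_iter=1, tol=1e-15)
        assert res.valid and not res.converged


class TestRunWindowedPca:
    def test_track_length_matches_window_count(self):
        rng = np.random.default_rng(9)
        recs = [VariantRecord("cX", p, "A", "C", rng.integers(0, 3, 8).astype(float))
                for p in sorted(rng.choice(5_000_000, 400, replace=False) + 1)]
        params = ScanParams(window_size=1_000_000, step_size=100_000, min_variants=2)
        wins = variant_io.window_stream(iter(recs), params, chrom_span=5_000_000,
                                        n_samples=8)
        track = run_windowed_pca(wins, params, [f"s{i}" for i in range(8)],
                                 polarize=False)
        assert len(track) == 41
        assert variant_io.window_count(5_000_000, 1_000_000, 100_000) == 41

    def test_windows_match_isolated_pca_up_to_sign(self, small_cohort_files,
                                                   small_cohort_cfg, small_params,
                                                   small_track):
        st = variant_io.open_variant_stream(small_cohort_files["vcf"], "vcf")
        wins = list(variant_io.window_stream(
            st, small_params, chrom_span=small_cohort_cfg.chrom_length,
            n_samples=len(st.samples)))
        for win, res in zip(wins, small_track.results):
            if not res.valid:
                continue
            solo = pca_window(GenotypeMatrix(win.values), small_params, spec=win.spec)
            a, b = res.scores[1], solo.scores[1]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_scores_sum_to_zero_on_every_window(self, small_track):
        for pc in small_track.pcs:
            m = small_track.scores_matrix(pc)
            for row in m:
                if np.isfinite(row).all():
                    assert abs(row.sum()) < 1e-6 * max(np.abs(row).max(), 1e-12)

    def test_all_invalid_track_warns(self, caplog):
        recs = [VariantRecord("c", p, "A", "C", np.array([0.0, 1, 2]))
                for p in (5, 6)]
        params = ScanParams(window_size=10, step_size=10, min_variants=10)
        wins = variant_io.window_stream(iter(recs), params, chrom_span=10, n_samples=3)
        track = run_windowed_pca(wins, params, ["a", "b", "c"])
        assert not any(r.valid for r in track.results)
        assert any("below min_variants" in r.message for r in caplog.records)

    def test_zero_windows_fatal(self):
        params = ScanParams(window_size=100, step_size=100, min_variants=2)
        with pytest.raises(ValueError, match="no windows"):
            run_windowed_pca(iter([]), params, ["a", "b"])


class TestTrackFiles:
    def test_write_read_round_trip(self, small_track, tmp_path):
        prefix = str(tmp_path / "trk")
        paths = windowed_pca.write_track(small_track, prefix)
        assert len(paths) == 3  # pc1, pc2, stats
        back = windowed_pca.read_track(prefix, pcs=(1, 2))
        assert back.sample_ids == small_track.sample_ids
        assert len(back) == len(small_track)
        for pc in (1, 2):
            a = small_track.scores_matrix(pc)
            b = back.scores_matrix(pc)
            # 6 significant digits in the files
            np.testing.assert_allclose(b, a, rtol=1e-5, atol=1e-5, equal_nan=True)

    def test_na_encoding_for_invalid_windows(self, tmp_path):
        from conftest import make_track
        scores = np.array([[1.0, -1.0], [np.nan, np.nan], [2.0, -2.0]])
        track = make_track(scores)
        prefix = str(tmp_path / "na")
        windowed_pca.write_track(track, prefix)
        import gzip
        lines = gzip.open(f"{prefix}.pc1.tsv.gz", "rt").read().splitlines()
        assert lines[2].split("\t")[4:] == ["NA", "NA"]
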