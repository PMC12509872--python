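import numpy as np
import pytest

from winscan import synth, variant_io, windowed_pca


@pytest.fixture(scope="session")
def small_cohort_cfg():
    """Two populations, 20 samples, 500 kb with a planted 200 kb inversion."""
    return synth.CohortConfig(
        n_samples=10, n_populations=2, divergence=0.2,
        chrom_length=500_000, variant_density=0.002,
        inversion=synth.InversionConfig(150_001, 350_000, 0.5, 4.0),
        depth=30.0, error_rate=0.01, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_cfg):
    return synth.simulate_cohort(small_cohort_cfg)


@pytest.fixture(scope="session")
def small_cohort_files(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    return synth.write_cohort(small_cohort, str(d / "fx"))


@pytest.fixture(scope="session")
def small_params():
    return variant_io.ScanParams(window_size=100_000, step_size=50_000,
                                 min_variants=10)


@pytest.fixture(scope="session")
def small_track(small_cohort_files, small_cohort_cfg, small_params):
    st = variant_io.open_variant_stream(small_cohort_files["vcf"], "vcf")
    wins = variant_io.window_stream(st, small_params,
                                    chrom_span=small_cohort_cfg.chrom_length,
                                    n_samples=len(st.samples))
    return windowed_pca.run_windowed_pca(wins, small_params, st.samples)


def make_track(scores, chrom="chr1", window_size=100, step=100, pcs=(1,)):
    """Build a PCTrack directly from a (windows x samples) score matrix.

    Rows that are entirely NaN become invalid windows. Helper for polarity
    and viz tests that do not need a real PCA behind the track.
    """
    scores = np.asarray(scores, dtype=float)
    n_win, n_samp = scores.shape
    params = variant_io.ScanParams(window_size=window_size, step_size=step,
                                   pcs=pcs, min_variants=2)
    results = []
    for i in range(n_win):
        start = 1 + i * step
        spec = variant_io.WindowSpec(chrom, start, start + window_size - 1)
        row = scores[i]
        valid = np.isfinite(row).any()
        results.append(windowed_pca.WindowResult(
            spec, {pc: row.copy() for pc in pcs},
            {pc: 0.5 for pc in pcs}, n_variants=50, pct_missing=0.0,
            valid=valid))
    sample_ids = [f"s{i}" for i in range(n_samp)]
    return windowed_pca.PCTrack(chrom, results, params, sample_ids)


def pca_oracle(values, scaler="patterson"):
    """Independent dense-SVD PCA on a dosage matrix (no missing entries).

    Mean-centers each variant column, optionally Patterson-scales, drops
    monomorphic columns, and returns sample scores U @ diag(S) from a full
    SVD — a separate numerical route from the covariance eigendecomposition
    under test.
    """
    x = np.asarray(values, dtype=float).copy()
    p = x.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    x, p = x[:, keep], p[keep]
    x = x - 2.0 * p
    if scaler == "patterson":
        x = x / np.sqrt(p * (1 - p))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u * s


def column_correlations(a, b):
    """Per-row |Pearson correlation| between two (windows x samples) matrices."""
    out = []
    for i in range(a.shape[0]):
        x, y = a[i], b[i]
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() > 2 and np.std(x[m]) > 0 and np.std(y[m]) > 0:
            out.append(abs(np.corrcoef(x[m], y[m])[0, 1]))
        else:
            out.append(np.nan)
    return np.asarray(out)
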