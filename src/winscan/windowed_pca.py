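"""Per-window principal component analysis of genotype data.

Hard genotypes are mean-imputed, centered and (by default) Patterson-scaled
— centered dosages divided by sqrt(p(1-p)) where p is half the mean dosage —
before a full symmetric eigendecomposition of the sample x sample covariance.
Sample scores for PC k are u_k * sqrt(lambda_k), i.e. the projection of each
sample onto the k-th axis, and variance explained is lambda_k over the trace.

Genotype likelihoods are handled with an iterative expected-genotype scheme:
posterior mean dosages under a Hardy-Weinberg prior are decomposed, the
low-rank fit yields per-individual allele frequencies which refine the prior,
and the loop repeats until the expected genotypes stabilize. With certain
likelihoods this degenerates exactly to the hard-call pipeline.

All eigendecompositions are deterministic (LAPACK ``eigh`` on the N x N
covariance); no randomized solver is involved, so identical input yields
bit-identical scores.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variant_io import ScanParams, Window, WindowSpec

logger = logging.getLogger("winscan")


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix; NaN marks missing calls."""

    values: np.ndarray
    sample_ids: List[str] = field(default_factory=list)
    positions: Optional[np.ndarray] = None


@dataclass
class LikelihoodMatrix:
    """Samples x variants x 3 genotype probability array (triplets sum to 1)."""

    values: np.ndarray
    sample_ids: List[str] = field(default_factory=list)
    positions: Optional[np.ndarray] = None


@dataclass
class WindowResult:
    """PC scores and metadata for one window.

    Scores are sign-ambiguous until polarized. Invalid windows (fewer than
    ``min_variants`` usable variants) carry NaN scores and ``valid=False``.
    """

    spec: WindowSpec
    scores: Dict[int, np.ndarray]
    var_explained: Dict[int, float]
    n_variants: int
    pct_missing: float
    valid: bool = True
    converged: bool = True


@dataclass
class PCTrack:
    """Ordered per-chromosome sequence of :class:`WindowResult`."""

    chrom: str
    results: List[WindowResult]
    params: ScanParams
    sample_ids: List[str]

    def __len__(self) -> int:
        return len(self.results)

    @property
    def pcs(self) -> Tuple[int, ...]:
        return tuple(self.params.pcs)

    def scores_matrix(self, pc: int) -> np.ndarray:
        """(windows x samples) score matrix for one PC; NaN rows are invalid."""
        n = len(self.sample_ids)
        out = np.full((len(self.results), n), np.nan)
        for i, r in enumerate(self.results):
            if r.valid and pc in r.scores:
                out[i] = r.scores[pc]
        return out

    def midpoints(self) -> np.ndarray:
        return np.asarray([r.spec.mid for r in self.results], dtype=int)


def mean_impute(g: GenotypeMatrix) -> Tuple[GenotypeMatrix, int]:
    """Replace each missing dosage by its variant-column mean.

    Columns with no observed entries cannot be imputed; they are dropped and
    counted, and the drop count is returned alongside the completed matrix.
    """
    values = np.asarray(g.values, dtype=float)
    if values.size == 0:
        return GenotypeMatrix(values.copy(), g.sample_ids, g.positions), 0
    observed = ~np.isnan(values)
    keep = observed.any(axis=0)
    n_dropped = int((~keep).sum())
    values = values[:, keep]
    observed = observed[:, keep]
    positions = g.positions[keep] if g.positions is not None else None
    if not observed.all():
        col_mean = np.nansum(values, axis=0) / observed.sum(axis=0)
        idx = np.where(~observed)
        values = values.copy()
        values[idx] = col_mean[idx[1]]
    return GenotypeMatrix(values, g.sample_ids, positions), n_dropped


def standardize(values: np.ndarray, scaler: str = "patterson") -> Tuple[np.ndarray, np.ndarray]:
    """Center (and optionally Patterson-scale) a complete dosage matrix.

    Monomorphic columns (allele frequency 0 or 1 after imputation) carry no
    information and are dropped first. Returns the standardized matrix and
    the boolean mask of retained columns.
    """
    if scaler not in ("none", "center", "patterson"):
        raise ValueError(f"unknown scaler {scaler!r}")
    values = np.asarray(values, dtype=float)
    if values.shape[1] == 0:
        return values, np.zeros(0, dtype=bool)
    p = values.mean(axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0)
    values = values[:, keep]
    p = p[keep]
    if scaler == "none":
        return values, keep
    out = values - 2.0 * p
    if scaler == "patterson":
        out = out / np.sqrt(p * (1.0 - p))
    return out, keep


def _decompose(x: np.ndarray, pcs: Sequence[int]) -> Tuple[Dict[int, np.ndarray], Dict[int, float], np.ndarray, np.ndarray]:
    """Eigendecompose the sample covariance of a standardized matrix.

    Returns per-PC scores and variance fractions plus the full eigenvector
    matrix and eigenvalues (descending) for callers that need the low-rank
    fit (the genotype-likelihood iteration).
    """
    cov = x @ x.T
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    scores: Dict[int, np.ndarray] = {}
    var_exp: Dict[int, float] = {}
    for pc in pcs:
        k = pc - 1
        if k < len(eigval):
            scores[pc] = eigvec[:, k] * np.sqrt(eigval[k])
            var_exp[pc] = float(eigval[k] / total) if total > 0 else 0.0
        else:
            scores[pc] = np.full(x.shape[0], np.nan)
            var_exp[pc] = 0.0
    return scores, var_exp, eigvec, eigval


def _invalid_result(spec: WindowSpec, pcs: Sequence[int], n_samples: int,
                    n_variants: int, pct_missing: float) -> WindowResult:
    nan = np.full(n_samples, np.nan)
    return WindowResult(spec, {pc: nan.copy() for pc in pcs},
                        {pc: float("nan") for pc in pcs},
                        n_variants, pct_missing, valid=False)


def pca_window(g: GenotypeMatrix, params: ScanParams,
               spec: Optional[WindowSpec] = None) -> WindowResult:
    """PCA of one window of hard genotypes (missing calls mean-imputed)."""
    n_samples = g.values.shape[0]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if spec is None:
        spec = _default_spec(g.positions)
    total = g.values.size
    pct_missing = float(np.isnan(g.values).sum() / total) if total else 0.0
    complete, _ = mean_impute(g)
    x, keep = standardize(complete.values, params.scaler)
    n_used = x.shape[1]
    if n_used < params.min_variants:
        return _invalid_result(spec, params.pcs, n_samples, n_used, pct_missing)
    scores, var_exp, _, _ = _decompose(x, params.pcs)
    return WindowResult(spec, scores, var_exp, n_used, pct_missing)


def _default_spec(positions: Optional[np.ndarray]) -> WindowSpec:
    if positions is not None and len(positions):
        return WindowSpec("", int(positions[0]), int(positions[-1]))
    return WindowSpec("", 1, 1)


def expected_genotypes(l: LikelihoodMatrix, freqs: np.ndarray) -> np.ndarray:
    """Posterior mean alt-allele dosage under a Hardy-Weinberg prior.

    ``freqs`` is either a per-variant vector (shared prior) or a
    samples x variants matrix of per-individual allele frequencies. The
    prior genotype probabilities at frequency p are ((1-p)^2, 2p(1-p), p^2);
    the posterior is proportional to likelihood x prior.
    """
    lik = np.asarray(l.values, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if p.ndim == 1:
        p = np.broadcast_to(p, lik.shape[:2])
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p ** 2], axis=-1)
    post = lik * prior
    norm = post.sum(axis=-1, keepdims=True)
    norm = np.where(norm <= 0, 1.0, norm)
    post = post / norm
    return post[..., 1] + 2.0 * post[..., 2]


def _flat_fraction(lik: np.ndarray) -> float:
    if lik.size == 0:
        return 0.0
    spread = lik.max(axis=-1) - lik.min(axis=-1)
    return float((spread < 1e-12).mean())


def gl_pca_window(l: LikelihoodMatrix, params: ScanParams,
                  max_iter: int = 100, tol: float = 1e-4,
                  spec: Optional[WindowSpec] = None) -> WindowResult:
    """PCA of one window of genotype likelihoods.

    Iterates: expected genotypes under the current prior -> eigendecomposition
    of the standardized matrix -> per-individual allele frequencies from the
    rank-K fit (K = largest requested PC), clamped to [1/(2N), 1-1/(2N)] ->
    refined expected genotypes; stops when their RMS change drops below
    ``tol`` or after ``max_iter`` rounds (then ``converged=False``).
    """
    lik = np.asarray(l.values, dtype=float)
    n_samples = lik.shape[0]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if spec is None:
        spec = _default_spec(l.positions)
    pct_missing = _flat_fraction(lik)

    # site frequencies from expected genotypes under a flat (uniform) prior
    e0 = lik[..., 1] + 2.0 * lik[..., 2]  # triplets are normalized
    f = e0.mean(axis=0) / 2.0
    keep = (f > 0.0) & (f < 1.0)
    lik = lik[:, keep]
    f = f[keep]
    n_used = lik.shape[1]
    if n_used < params.min_variants:
        return _invalid_result(spec, params.pcs, n_samples, n_used, pct_missing)

    sub = LikelihoodMatrix(lik, l.sample_ids)
    rank = max(params.pcs)
    clamp_lo = 1.0 / (2.0 * n_samples)
    scale = np.sqrt(f * (1.0 - f)) if params.scaler == "patterson" else None

    e = expected_genotypes(sub, f)
    converged = False
    scores: Dict[int, np.ndarray] = {}
    var_exp: Dict[int, float] = {}
    for _ in range(max_iter):
        x = e - e.mean(axis=0)
        if scale is not None:
            x = x / scale
        scores, var_exp, eigvec, eigval = _decompose(x, params.pcs)
        k = min(rank, len(eigval))
        u = eigvec[:, :k] * np.sqrt(eigval[:k])
        v = x.T @ eigvec[:, :k]
        v = np.divide(v, np.sqrt(eigval[:k]), out=np.zeros_like(v),
                      where=eigval[:k] > 0)
        x_hat = u @ v.T
        if scale is not None:
            x_hat = x_hat * scale
        pi = (x_hat + 2.0 * f) / 2.0
        pi = np.clip(pi, clamp_lo, 1.0 - clamp_lo)
        e_new = expected_genotypes(sub, pi)
        rms = float(np.sqrt(np.mean((e_new - e) ** 2)))
        e = e_new
        if rms < tol:
            converged = True
            break
    if not converged:
        logger.warning("GL-PCA did not converge in %d iterations at %s:%d-%d",
                       max_iter, spec.chrom, spec.start, spec.end)
    x = e - e.mean(axis=0)
    if scale is not None:
        x = x / scale
    scores, var_exp, _, _ = _decompose(x, params.pcs)
    return WindowResult(spec, scores, var_exp, n_used, pct_missing,
                        valid=True, converged=converged)


def run_windowed_pca(windows: Iterable[Window], params: ScanParams,
                     sample_ids: Sequence[str],
                     polarize: bool = True,
                     polarize_cfg=None) -> PCTrack:
    """Run per-window PCA over a window stream and return the polarized track."""
    results: List[WindowResult] = []
    chrom = ""
    for win in windows:
        chrom = win.spec.chrom or chrom
        if win.values.ndim == 3:
            res = gl_pca_window(LikelihoodMatrix(win.values, list(sample_ids),
                                                 win.positions),
                                params, spec=win.spec)
        else:
            res = pca_window(GenotypeMatrix(win.values, list(sample_ids),
                                            win.positions),
                             params, spec=win.spec)
        results.append(res)
    if not results:
        raise ValueError(f"no windows produced for region {chrom or '<unknown>'}")
    track = PCTrack(chrom, results, params, list(sample_ids))
    if not any(r.valid for r in results):
        logger.warning("all %d windows below min_variants=%d on %s",
                       len(results), params.min_variants, chrom)
    elif polarize:
        from . import polarity
        cfg = polarize_cfg or polarity.PolarizeConfig()
        for pc in params.pcs:
            track = polarity.polarize_track(track, cfg, pc)
    return track


# -- track files -------------------------------------------------------------

def _fmt(v: float) -> str:
    return "NA" if (v is None or (isinstance(v, float) and np.isnan(v))) else f"{v:.6g}"


def write_track(track: PCTrack, prefix: str) -> List[str]:
    """Write one gzipped TSV per PC plus a per-window stats file.

    ``<prefix>.pc<k>.tsv.gz`` holds chrom, start, end, mid and one score
    column per sample (``NA`` for invalid windows); ``<prefix>.stats.tsv.gz``
    holds variant counts, missingness and variance explained. Floats are
    written at 6 significant digits.
    """
    paths = []
    for pc in track.pcs:
        path = f"{prefix}.pc{pc}.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chrom\tstart\tend\tmid\t" + "\t".join(track.sample_ids) + "\n")
            for r in track.results:
                row = [track.chrom, str(r.spec.start), str(r.spec.end), str(r.spec.mid)]
                sc = r.scores.get(pc)
                if r.valid and sc is not None:
                    row += [_fmt(v) for v in sc]
                else:
                    row += ["NA"] * len(track.sample_ids)
                fh.write("\t".join(row) + "\n")
        paths.append(path)
    stats_path = f"{prefix}.stats.tsv.gz"
    with gzip.open(stats_path, "wt") as fh:
        ve_cols = [f"var_explained_pc{pc}" for pc in track.pcs]
        fh.write("chrom\tstart\tend\tmid\tn_variants\tpct_missing\t" + "\t".join(ve_cols) + "\n")
        for r in track.results:
            row = [track.chrom, str(r.spec.start), str(r.spec.end), str(r.spec.mid),
                   str(r.n_variants), _fmt(r.pct_missing)]
            row += [_fmt(r.var_explained.get(pc, float("nan"))) for pc in track.pcs]
            fh.write("\t".join(row) + "\n")
    paths.append(stats_path)
    return paths


def read_track(prefix: str, pcs: Sequence[int] = (1, 2)) -> PCTrack:
    """Reload a :class:`PCTrack` from the files written by :func:`write_track`."""
    frames = {}
    for pc in pcs:
        frames[pc] = pd.read_csv(f"{prefix}.pc{pc}.tsv.gz", sep="\t")
    first = frames[pcs[0]]
    sample_ids = list(first.columns[4:])
    try:
        stats = pd.read_csv(f"{prefix}.stats.tsv.gz", sep="\t")
    except FileNotFoundError:
        stats = None
    chrom = str(first["chrom"].iloc[0]) if len(first) else ""
    starts = first["start"].to_numpy()
    window_size = int(first["end"].iloc[0] - first["start"].iloc[0] + 1) if len(first) else 1
    step = int(starts[1] - starts[0]) if len(starts) > 1 else window_size
    params = ScanParams(window_size=window_size, step_size=min(step, window_size),
                        pcs=tuple(pcs))
    results = []
    for i in range(len(first)):
        spec = WindowSpec(chrom, int(first["start"].iloc[i]), int(first["end"].iloc[i]))
        scores, var_exp = {}, {}
        valid = False
        for pc in pcs:
            vals = pd.to_numeric(frames[pc].iloc[i, 4:], errors="coerce").to_numpy(dtype=float)
            scores[pc] = vals
            if np.isfinite(vals).any():
                valid = True
            if stats is not None and f"var_explained_pc{pc}" in stats.columns:
                var_exp[pc] = float(stats[f"var_explained_pc{pc}"].iloc[i])
            else:
                var_exp[pc] = float("nan")
        n_var = int(stats["n_variants"].iloc[i]) if stats is not None else 0
        pct_na = float(stats["pct_missing"].iloc[i]) if stats is not None else float("nan")
        results.append(WindowResult(spec, scores, var_exp, n_var, pct_na, valid=valid))
    return PCTrack(chrom, results, params, sample_ids)
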