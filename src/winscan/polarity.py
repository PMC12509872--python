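"""Sign harmonization of per-window principal components.

Each window's eigenvector carries an arbitrary +/- sign, so raw PC score
series jump between adjacent windows. Polarization walks the track left to
right: for every valid window it picks a reference signal — in adaptive mode
the sample with the largest absolute score in that window, in guided mode
the summed scores of user-chosen guide samples — and flips the whole window
when the reference's sign disagrees with the sign average of that reference
over the up-to-``n_prev`` previous, already polarized, valid windows.
Flips negate every sample's score uniformly, so relative geometry within a
window is never altered.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .windowed_pca import PCTrack, WindowResult


@dataclass
class PolarizeConfig:
    """Polarization settings: history depth and optional guide samples."""

    n_prev: int = 5
    guide_samples: Optional[List[str]] = None
    mode: str = "adaptive"

    def __post_init__(self):
        if self.n_prev < 1:
            raise ValueError("n_prev must be >= 1")
        if self.guide_samples:
            self.mode = "guided"


def _copy_track(track: PCTrack) -> PCTrack:
    results = [WindowResult(r.spec, {pc: np.array(s, dtype=float) for pc, s in r.scores.items()},
                            dict(r.var_explained), r.n_variants, r.pct_missing,
                            r.valid, r.converged)
               for r in track.results]
    return PCTrack(track.chrom, results, track.params, list(track.sample_ids))


def _guide_indices(track: PCTrack, cfg: PolarizeConfig) -> List[int]:
    idx = []
    for s in cfg.guide_samples or []:
        if s not in track.sample_ids:
            raise ValueError(
                f"unknown guide sample {s!r}; valid ids: {track.sample_ids}")
        idx.append(track.sample_ids.index(s))
    return idx


def polarize_track(track: PCTrack, cfg: PolarizeConfig, pc: int) -> PCTrack:
    """Harmonize the sign of ``pc`` across the track's windows.

    The first valid window is left unchanged and seeds the history. Invalid
    windows are passed through untouched and do not consume history. NaN
    reference scores in history windows are excluded from the sign average;
    a zero sign average (tie) keeps the window's current orientation. The
    operation is idempotent on its own output.
    """
    out = _copy_track(track)
    guided = cfg.mode == "guided" and cfg.guide_samples
    gidx = _guide_indices(track, cfg) if guided else None
    history: List[np.ndarray] = []  # polarized score vectors of valid windows

    for r in out.results:
        if not r.valid or pc not in r.scores:
            continue
        cur = r.scores[pc]
        if history:
            if guided:
                ref_cur = float(np.nansum(cur[gidx]))
                hist_vals = [float(np.nansum(h[gidx])) for h in history[-cfg.n_prev:]]
            else:
                finite = np.where(np.isfinite(cur), np.abs(cur), -np.inf)
                ref_i = int(np.argmax(finite))  # ties: lowest sample index
                ref_cur = float(cur[ref_i])
                hist_vals = [float(h[ref_i]) for h in history[-cfg.n_prev:]]
            signs = [np.sign(v) for v in hist_vals if np.isfinite(v) and v != 0]
            mean_sign = float(np.mean(signs)) if signs else 0.0
            if mean_sign != 0 and np.isfinite(ref_cur) and ref_cur != 0 \
                    and np.sign(ref_cur) != np.sign(mean_sign):
                r.scores[pc] = -cur
        history.append(r.scores[pc])
    return out


def flip_chromosome(track: PCTrack, pc: int) -> PCTrack:
    """Negate ``pc`` scores of every valid window (an involution)."""
    out = _copy_track(track)
    for r in out.results:
        if r.valid and pc in r.scores:
            r.scores[pc] = -r.scores[pc]
    return out


def flip_windows(track: PCTrack, intervals: Sequence[Tuple[str, int, int]],
                 pc: int) -> PCTrack:
    """Negate ``pc`` in windows whose midpoint falls in any closed interval.

    Overlapping or duplicate intervals flip a window at most once (set
    semantics).
    """
    for chrom, start, end in intervals:
        if end < start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end} (end < start)")
    out = _copy_track(track)
    for r in out.results:
        if not (r.valid and pc in r.scores):
            continue
        mid = r.spec.mid
        hit = any(c == out.chrom and s <= mid <= e for c, s, e in intervals)
        if hit:
            r.scores[pc] = -r.scores[pc]
    return out
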