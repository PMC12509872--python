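"""Genome-track plots of polarized PC score tracks.

Both plot entry points build a backend-neutral :class:`FigureSpec` — one
polyline per sample over window midpoints, with invalid (NA) windows
breaking the line — and render it to any of: self-contained interactive
HTML (hover metadata, toggleable legend groups, zoom), or static PDF / SVG
/ PNG via matplotlib. Trace data are identical across output formats, and
rendering never touches the track files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .variant_io import SampleMetadata, minmax_positions
from .windowed_pca import PCTrack

logger = logging.getLogger("winscan")

#: Fixed colorblind-safe categorical cycle; recycled (with a warning) past 12 groups.
PALETTE = [
    "#332288", "#117733", "#44AA99", "#88CCEE", "#DDCC77", "#CC6677",
    "#AA4499", "#882255", "#999933", "#661100", "#6699CC", "#888888",
]
DEFAULT_COLOR = "#555555"
SUPPORTED_FORMATS = ("html", "pdf", "svg", "png")


@dataclass
class PlotConfig:
    """Plot settings: PC, coloring column, order, interval and sizes."""

    pc: int = 1
    color_by: Optional[str] = None
    continuous: Optional[bool] = None   # None = auto-detect numeric columns
    group_order: Optional[List[str]] = None
    interval: Optional[Tuple[int, int]] = None
    width: int = 1400
    height: int = 500
    free_scale: bool = False            # per-panel y scale in genomeplot


@dataclass
class TraceSpec:
    sample_id: str
    group: Optional[str]
    color: str
    x: List[float]
    y: List[Optional[float]]   # None encodes an NA gap
    hover: str


@dataclass
class PanelSpec:
    label: str
    x_start: float
    x_end: float


@dataclass
class FigureSpec:
    title: str
    xlabel: str
    ylabel: str
    traces: List[TraceSpec]
    panels: List[PanelSpec]
    width: int = 1400
    height: int = 500


def _hover_text(sample: str, meta: Optional[SampleMetadata]) -> str:
    parts = [f"sample: {sample}"]
    if meta is not None and sample in meta.table.index:
        for col, val in meta.annotations(sample).items():
            parts.append(f"{col}: {val}")
    return "<br>".join(parts)


def _trace_styles(sample_ids: Sequence[str], meta: Optional[SampleMetadata],
                  cfg: PlotConfig) -> Tuple[Dict[str, str], Dict[str, Optional[str]], List[str]]:
    """Per-sample color and group plus the z-stacking draw order."""
    colors = {s: DEFAULT_COLOR for s in sample_ids}
    groups: Dict[str, Optional[str]] = {s: None for s in sample_ids}
    order = list(sample_ids)
    if cfg.color_by is None or meta is None:
        return colors, groups, order
    if cfg.color_by not in meta.columns:
        raise ValueError(
            f"unknown color_by column {cfg.color_by!r}; available: {meta.columns}")
    col = meta.table[cfg.color_by].reindex(sample_ids)
    continuous = cfg.continuous
    if continuous is None:
        continuous = pd.api.types.is_numeric_dtype(col)
    if continuous:
        from matplotlib import colormaps
        from matplotlib.colors import to_hex
        cmap = colormaps["viridis"]
        pos = minmax_positions(col.to_numpy(dtype=float))
        for s, p in zip(sample_ids, pos):
            colors[s] = to_hex(cmap(0.0 if np.isnan(p) else float(p)))
            groups[s] = None
        return colors, groups, order
    levels = [g for g in col.dropna().unique()]
    if cfg.group_order:
        ordered = [g for g in cfg.group_order if g in levels]
        ordered += [g for g in levels if g not in ordered]
    else:
        ordered = levels
    if len(ordered) > len(PALETTE):
        warnings.warn(f"{len(ordered)} groups exceed the {len(PALETTE)}-color "
                      "palette; colors will be recycled")
    level_color = {g: PALETTE[i % len(PALETTE)] for i, g in enumerate(ordered)}
    for s in sample_ids:
        g = col.get(s)
        if pd.notna(g):
            groups[s] = str(g)
            colors[s] = level_color[g]
    rank = {g: i for i, g in enumerate(ordered)}
    order = sorted(sample_ids,
                   key=lambda s: (rank.get(groups[s], len(rank)), sample_ids.index(s)))
    return colors, groups, order


def _track_traces(track: PCTrack, meta: Optional[SampleMetadata], cfg: PlotConfig,
                  x_offset: float = 0.0) -> List[TraceSpec]:
    scores = track.scores_matrix(cfg.pc)   # windows x samples
    mids = track.midpoints().astype(float)
    if cfg.interval is not None:
        lo, hi = cfg.interval
        keep = (mids >= lo) & (mids <= hi)
        scores, mids = scores[keep], mids[keep]
    colors, groups, order = _trace_styles(track.sample_ids, meta, cfg)
    traces = []
    for s in order:
        i = track.sample_ids.index(s)
        y = [None if np.isnan(v) else float(v) for v in scores[:, i]]
        traces.append(TraceSpec(s, groups[s], colors[s],
                                [float(m) + x_offset for m in mids], y,
                                _hover_text(s, meta)))
    return traces


def build_chrom_figure(track: PCTrack, meta: Optional[SampleMetadata],
                       cfg: PlotConfig) -> FigureSpec:
    """Figure over a single chromosome: one polyline per sample."""
    if not len(track.results) or not any(r.valid for r in track.results):
        raise ValueError(f"track on {track.chrom!r} is empty or all-invalid")
    traces = _track_traces(track, meta, cfg)
    span = (track.results[0].spec.start, track.results[-1].spec.end)
    return FigureSpec(
        title=f"PC{cfg.pc} along {track.chrom}",
        xlabel=f"{track.chrom} position (bp)", ylabel=f"PC{cfg.pc} score",
        traces=traces,
        panels=[PanelSpec(track.chrom, float(span[0]), float(span[1]))],
        width=cfg.width, height=cfg.height)


def build_genome_figure(tracks: Sequence[PCTrack], meta: Optional[SampleMetadata],
                        cfg: PlotConfig) -> FigureSpec:
    """Multi-chromosome figure: panels laid out left to right in input order."""
    if not tracks:
        raise ValueError("genomeplot needs at least one track")
    ref = sorted(tracks[0].sample_ids)
    for t in tracks[1:]:
        if sorted(t.sample_ids) != ref:
            diff = set(ref) ^ set(t.sample_ids)
            raise ValueError(
                f"inconsistent sample sets across tracks; first discrepancy: "
                f"{sorted(diff)[0]!r} (chromosome {t.chrom})")
    offset = 0.0
    panels: List[PanelSpec] = []
    per_sample: Dict[str, TraceSpec] = {}
    for t in tracks:
        if not any(r.valid for r in t.results):
            raise ValueError(f"track on {t.chrom!r} is all-invalid")
        span_end = float(t.results[-1].spec.end)
        for tr in _track_traces(t, meta, cfg, x_offset=offset):
            if tr.sample_id in per_sample:
                acc = per_sample[tr.sample_id]
                # break the line between chromosomes with an explicit gap
                acc.x.append(tr.x[0] if tr.x else acc.x[-1])
                acc.y.append(None)
                acc.x += tr.x
                acc.y += tr.y
            else:
                per_sample[tr.sample_id] = tr
        panels.append(PanelSpec(t.chrom, offset, offset + span_end))
        offset += span_end
    return FigureSpec(
        title=f"PC{cfg.pc} genome-wide", xlabel="genome position (bp, concatenated)",
        ylabel=f"PC{cfg.pc} score", traces=list(per_sample.values()),
        panels=panels, width=cfg.width, height=cfg.height)


# -- rendering ---------------------------------------------------------------

def render_static(fig: FigureSpec, path: str) -> None:
    """Render a FigureSpec to PDF/SVG/PNG through matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dpi = 100
    f, ax = plt.subplots(figsize=(fig.width / dpi, fig.height / dpi), dpi=dpi)
    seen_groups = set()
    for tr in fig.traces:
        y = np.asarray([np.nan if v is None else v for v in tr.y], dtype=float)
        label = None
        if tr.group is not None and tr.group not in seen_groups:
            label = tr.group
            seen_groups.add(tr.group)
        ax.plot(tr.x, y, color=tr.color, linewidth=0.8, label=label)
    for p in fig.panels[1:]:
        ax.axvline(p.x_start, color="#bbbbbb", linewidth=0.8, linestyle="--")
    if len(fig.panels) > 1:
        for p in fig.panels:
            ax.annotate(p.label, ((p.x_start + p.x_end) / 2, 1.02),
                        xycoords=("data", "axes fraction"), ha="center", fontsize=8)
    ax.set_title(fig.title)
    ax.set_xlabel(fig.xlabel)
    ax.set_ylabel(fig.ylabel)
    if seen_groups:
        ax.legend(loc="upper right", fontsize=8)
    f.tight_layout()
    f.savefig(path)
    plt.close(f)


def render(fig: FigureSpec, paths: Sequence[str]) -> List[str]:
    """Write the figure to every path; the format follows each extension."""
    written = []
    for path in paths:
        ext = str(path).rsplit(".", 1)[-1].lower()
        if ext not in SUPPORTED_FORMATS:
            raise ValueError(f"unsupported output format {ext!r} "
                             f"(supported: {SUPPORTED_FORMATS})")
        if ext == "html":
            from ._html import render_html
            render_html(fig, path)
        else:
            render_static(fig, path)
        written.append(str(path))
    return written


def chromplot(track: PCTrack, meta: Optional[SampleMetadata], cfg: PlotConfig,
              out_paths: Sequence[str]) -> FigureSpec:
    """Plot one PC along one chromosome; returns the figure description."""
    fig = build_chrom_figure(track, meta, cfg)
    render(fig, out_paths)
    return fig


def genomeplot(tracks: Sequence[PCTrack], meta: Optional[SampleMetadata],
               cfg: PlotConfig, out_paths: Sequence[str]) -> FigureSpec:
    """Plot one PC across several chromosomes on a shared score axis."""
    fig = build_genome_figure(tracks, meta, cfg)
    render(fig, out_paths)
    return fig
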