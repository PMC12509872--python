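"""Streaming readers for biallelic variant data and rolling-window assembly.

Three input dialects are supported:

* **VCF 4.x** (plain, gzip- or bgzip-compressed) with ``GT`` hard calls or
  ``GL``/``PL`` genotype likelihoods, read through :mod:`cyvcf2`.
* **BEAGLE** genotype-likelihood files as emitted by the ANGSD suite
  (header ``marker allele1 allele2`` followed by three likelihood columns
  per sample; the marker is ``chrom_pos``).
* **TSV** genotype matrices with columns ``CHROM``, ``POS`` and one
  alt-allele dosage column (``0``/``1``/``2``/``NA``) per sample.

Records are streamed in position order and assembled into overlapping
rolling windows so that memory stays bounded by a single window's span.
Coordinates are 1-based and fully closed, matching VCF convention; a
variant belongs to a window when ``start <= pos <= end``.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("winscan")

#: Sentinel for a missing hard-called dosage.
MISSING = float("nan")

_GZIP_MAGIC = b"\x1f\x8b"

_ALLELE_CODES = {"0": "A", "1": "C", "2": "G", "3": "T"}


class VariantFileError(RuntimeError):
    """Fatal input problem: unreadable file, unsorted records, bad field tag."""


@dataclass
class VariantRecord:
    """One biallelic site.

    ``payload`` is either a length-N float vector of alt-allele dosages
    (entries in {0, 1, 2, NaN}) or an (N, 3) array of normalized genotype
    probabilities ``(P(g=0), P(g=1), P(g=2))``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    payload: np.ndarray

    @property
    def is_likelihood(self) -> bool:
        return self.payload.ndim == 2


@dataclass(frozen=True)
class WindowSpec:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"window end {self.end} < start {self.start}")


@dataclass
class Window:
    """A window interval plus the (samples x variants[, 3]) payload matrix."""

    spec: WindowSpec
    values: np.ndarray
    positions: np.ndarray
    sample_ids: List[str]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


@dataclass
class ScanParams:
    """Parameters of a windowed scan.

    window_size and step_size are in bp. ``pcs`` lists the 1-based principal
    component indices to emit (at most PC10). Windows with fewer than
    ``min_variants`` usable variants yield invalid (NA) results. ``anchor``
    selects whether windows start at position 1 or at the first variant.
    """

    window_size: int = 1_000_000
    step_size: int = 100_000
    pcs: Tuple[int, ...] = (1, 2)
    min_variants: int = 20
    gl_field: Optional[str] = None
    format: str = "vcf"
    scaler: str = "patterson"
    anchor: str = "one"

    def __post_init__(self):
        self.pcs = tuple(int(p) for p in self.pcs)
        if not self.pcs or any(p < 1 or p > 10 for p in self.pcs):
            raise ValueError("pc indices must lie in 1..10")
        if self.step_size > self.window_size:
            raise ValueError("step_size must not exceed window_size")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")
        if self.min_variants < 2:
            raise ValueError("min_variants must be >= 2")
        if self.gl_field is not None and self.gl_field not in ("GT", "GL", "PL"):
            raise VariantFileError(f"unknown genotype field tag {self.gl_field!r}")
        if self.format not in ("vcf", "beagle", "tsv"):
            raise ValueError(f"unknown input format {self.format!r}")
        if self.anchor not in ("one", "first_variant"):
            raise ValueError(f"unknown window anchor {self.anchor!r}")


def is_gzip(path: str) -> bool:
    """True when the file starts with the gzip magic bytes (bgzip included)."""
    with open(path, "rb") as fh:
        return fh.read(2) == _GZIP_MAGIC


def _open_text(path: str) -> io.TextIOBase:
    if is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def parse_likelihood_triplet(raw: Union[str, Sequence[float]], encoding: str) -> np.ndarray:
    """Decode one genotype-likelihood triplet into normalized probabilities.

    ``PL`` values are phred-scaled (``10**(-PL/10)``). ``GL`` values are
    log10-scaled when every entry is <= 0 (the common VCF dialect) and
    plain probabilities otherwise. The result always sums to 1; an
    all-equal triplet normalizes to the flat (1/3, 1/3, 1/3) prior.

    Raises ``ValueError`` on wrong arity or non-numeric fields so callers
    can skip the record and count it.
    """
    if isinstance(raw, str):
        parts = raw.replace(";", ",").split(",")
    else:
        parts = list(raw)
    if len(parts) != 3:
        raise ValueError(f"expected 3 likelihood values, got {len(parts)}")
    vals = np.asarray([float(p) for p in parts], dtype=float)
    if np.isnan(vals).any():
        raise ValueError("non-numeric likelihood value")
    if encoding == "PL":
        probs = np.power(10.0, -vals / 10.0)
    elif encoding == "GL":
        if np.all(vals <= 0):
            probs = np.power(10.0, vals)
        else:
            if np.any(vals < 0):
                raise ValueError("mixed-sign GL values are neither log10 nor probabilities")
            probs = vals
    else:
        raise VariantFileError(f"unknown gl_field tag {encoding!r}")
    total = probs.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("likelihood triplet does not normalize")
    return probs / total


def _parse_region(region: Optional[str]) -> Tuple[Optional[str], int, float]:
    if region is None:
        return None, 1, math.inf
    if ":" in region:
        chrom, span = region.split(":", 1)
        lo, hi = span.replace(",", "").split("-")
        return chrom, int(lo), int(hi)
    return region, 1, math.inf


class VariantStream:
    """Ordered iterator of :class:`VariantRecord` with header metadata.

    Exposes ``samples`` (names from the header), ``n_skipped`` (multiallelic
    or unparseable records) and enforces nondecreasing position order.
    """

    def __init__(self, path: str, fmt: str, region: Optional[str] = None,
                 gl_field: Optional[str] = None):
        if fmt not in ("vcf", "beagle", "tsv"):
            raise VariantFileError(f"unknown format {fmt!r}")
        if gl_field is not None and gl_field not in ("GT", "GL", "PL"):
            raise VariantFileError(f"unknown gl_field tag {gl_field!r}")
        self.path = path
        self.format = fmt
        self.gl_field = gl_field if gl_field != "GT" else None
        self.region_chrom, self.region_start, self.region_end = _parse_region(region)
        self.n_skipped = 0
        self.samples: List[str] = []
        self._haploid_warned = False
        try:
            if fmt == "vcf":
                import cyvcf2
                self._vcf = cyvcf2.VCF(path)
                self.samples = list(self._vcf.samples)
            else:
                self._fh = _open_text(path)
                header = self._fh.readline().rstrip("\n")
                cols = header.split("\t") if "\t" in header else header.split()
                if fmt == "beagle":
                    if len(cols) < 3 or (len(cols) - 3) % 3:
                        raise VariantFileError(f"malformed BEAGLE header in {path}")
                    self.samples = cols[3::3]
                else:
                    if cols[:2] != ["CHROM", "POS"]:
                        raise VariantFileError(f"malformed TSV header in {path}")
                    self.samples = cols[2:]
        except VariantFileError:
            raise
        except Exception as exc:  # unreadable / not a variant file
            raise VariantFileError(f"cannot read variant file {path}: {exc}") from exc

    # -- iteration ---------------------------------------------------------

    def __iter__(self) -> Iterator[VariantRecord]:
        n_yielded = 0
        last_pos = {}
        produce = {"vcf": self._iter_vcf, "beagle": self._iter_beagle,
                   "tsv": self._iter_tsv}[self.format]
        for rec in produce():
            if self.region_chrom is not None and rec.chrom != self.region_chrom:
                continue
            if rec.pos < last_pos.get(rec.chrom, 0):
                raise VariantFileError(
                    f"{self.path}: record at {rec.chrom}:{rec.pos} out of position "
                    "order; input must be coordinate-sorted")
            last_pos[rec.chrom] = rec.pos
            if not (self.region_start <= rec.pos <= self.region_end):
                continue
            n_yielded += 1
            yield rec
        if self.region_chrom is not None and n_yielded == 0:
            warnings.warn(f"no records found for region {self.region_chrom!r} in {self.path}")

    def _iter_vcf(self) -> Iterator[VariantRecord]:
        for v in self._vcf:
            alts = v.ALT
            if len(alts) != 1 or v.POS < 1 or any(c in alts[0] for c in "<>[]*,"):
                self.n_skipped += 1
                continue
            if self.gl_field is None:
                payload = self._vcf_dosages(v)
            else:
                payload = self._vcf_likelihoods(v)
                if payload is None:
                    self.n_skipped += 1
                    continue
            yield VariantRecord(v.CHROM, v.POS, v.REF, alts[0], payload)

    def _vcf_dosages(self, v) -> np.ndarray:
        out = np.empty(len(self.samples), dtype=float)
        for i, call in enumerate(v.genotypes):
            alleles = [a for a in call[:-1]]  # last entry is the phase flag
            if len(alleles) == 1:  # haploid call: double it
                if not self._haploid_warned:
                    warnings.warn(f"{self.path}: haploid GT calls doubled to diploid dosage")
                    self._haploid_warned = True
                out[i] = MISSING if alleles[0] < 0 else 2.0 * alleles[0]
            elif any(a < 0 for a in alleles):  # missing or half-call
                out[i] = MISSING
            else:
                out[i] = float(sum(alleles))
        return out

    def _vcf_likelihoods(self, v) -> Optional[np.ndarray]:
        arr = v.format(self.gl_field)
        if arr is None or arr.shape[1] != 3:
            return None
        out = np.empty((len(self.samples), 3), dtype=float)
        for i in range(arr.shape[0]):
            row = np.asarray(arr[i], dtype=float)
            # htslib missing sentinels: INT32_MIN for PL, huge negatives for GL
            if not np.all(np.isfinite(row)) or np.any(row < -1e8):
                out[i] = 1.0 / 3.0
                continue
            try:
                out[i] = parse_likelihood_triplet(row, self.gl_field)
            except ValueError:
                out[i] = 1.0 / 3.0
        return out

    def _iter_beagle(self) -> Iterator[VariantRecord]:
        n = len(self.samples)
        for line in self._fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 + 3 * n:
                self.n_skipped += 1
                continue
            marker = parts[0]
            try:
                chrom, pos_s = marker.rsplit("_", 1)
                pos = int(pos_s)
                vals = np.asarray(parts[3:], dtype=float).reshape(n, 3)
            except ValueError:
                self.n_skipped += 1
                continue
            if pos < 1:
                self.n_skipped += 1
                continue
            triplets = np.empty_like(vals)
            ok = True
            for i in range(n):
                try:
                    triplets[i] = parse_likelihood_triplet(vals[i], "GL")
                except ValueError:
                    ok = False
                    break
            if not ok:
                self.n_skipped += 1
                continue
            ref = _ALLELE_CODES.get(parts[1], parts[1])
            alt = _ALLELE_CODES.get(parts[2], parts[2])
            yield VariantRecord(chrom, pos, ref, alt, triplets)

    def _iter_tsv(self) -> Iterator[VariantRecord]:
        n = len(self.samples)
        for line in self._fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) != 2 + n:
                self.n_skipped += 1
                continue
            try:
                pos = int(parts[1])
                payload = np.asarray(
                    [MISSING if p == "NA" else float(p) for p in parts[2:]], dtype=float)
            except ValueError:
                self.n_skipped += 1
                continue
            if pos < 1:
                self.n_skipped += 1
                continue
            yield VariantRecord(parts[0], pos, "N", "N", payload)


def open_variant_stream(path: str, fmt: str = "vcf", region: Optional[str] = None,
                        gl_field: Optional[str] = None) -> VariantStream:
    """Open ``path`` and stream biallelic records for ``region`` in order.

    Compression (gzip/bgzip) is auto-detected from magic bytes. Multiallelic
    and unparseable records are skipped and counted on the returned stream's
    ``n_skipped`` attribute; sample names are available as ``samples``.
    """
    return VariantStream(path, fmt, region=region, gl_field=gl_field)


def write_tsv(records: Iterable[VariantRecord], samples: Sequence[str], path: str) -> None:
    """Serialize dosage records to the canonical TSV dialect (CHROM, POS, samples)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("CHROM\tPOS\t" + "\t".join(samples) + "\n")
        for rec in records:
            vals = ["NA" if np.isnan(v) else str(int(v)) if v == int(v) else repr(v)
                    for v in rec.payload]
            fh.write(f"{rec.chrom}\t{rec.pos}\t" + "\t".join(vals) + "\n")


# -- windowing ---------------------------------------------------------------


def window_count(chrom_span: int, window_size: int, step_size: int) -> int:
    """Number of full-length windows anchored at 1 on a span of ``chrom_span`` bp."""
    if chrom_span < window_size:
        return 0
    return (chrom_span - window_size) // step_size + 1


def window_stream(records: Iterable[VariantRecord], params: ScanParams,
                  chrom_span: Optional[int] = None,
                  n_samples: Optional[int] = None) -> Iterator[Window]:
    """Assemble sorted records into overlapping rolling windows.

    Windows advance by ``params.step_size`` from the anchor (position 1, or
    the first variant when ``params.anchor == "first_variant"``) and only
    full-length windows (``end <= chrom_span``) are emitted. A variant may
    fall into several overlapping windows; empty windows carry a
    zero-column matrix. When ``chrom_span`` is ``None`` the records are
    buffered and the last variant position is used as the span.
    """
    w, s = params.window_size, params.step_size
    it = iter(records)
    pending: List[VariantRecord] = []

    if chrom_span is None:
        pending = list(it)
        if not pending:
            return
        chrom_span = pending[-1].pos
        it = iter(())

    anchor = 1
    chrom = None
    if params.anchor == "first_variant":
        if not pending:
            try:
                pending = [next(it)]
            except StopIteration:
                pending = []
        if pending:
            anchor = pending[0].pos

    from collections import deque
    from itertools import chain
    buf: deque = deque()
    src = chain(pending, it)
    exhausted = False

    def _pull(upto: int):
        nonlocal exhausted, chrom, n_samples
        while not exhausted:
            try:
                rec = next(src)
            except StopIteration:
                exhausted = True
                return
            if chrom is None:
                chrom = rec.chrom
            if n_samples is None:
                n_samples = rec.payload.shape[0]
            buf.append(rec)
            if rec.pos > upto:
                return

    emitted = False
    start = anchor
    while start + w - 1 <= chrom_span:
        end = start + w - 1
        _pull(end)
        while buf and buf[0].pos < start:
            buf.popleft()
        in_win = [r for r in buf if start <= r.pos <= end]
        if chrom is None and in_win:
            chrom = in_win[0].chrom
        ns = n_samples if n_samples is not None else 0
        if in_win:
            values = np.stack([r.payload for r in in_win], axis=1)
            positions = np.asarray([r.pos for r in in_win], dtype=int)
        else:
            values = np.zeros((ns, 0), dtype=float)
            positions = np.zeros(0, dtype=int)
        spec = WindowSpec(chrom or "", start, end)
        yield Window(spec, values, positions, [])
        emitted = True
        start += s
    if not emitted:
        logger.warning("span %d shorter than window size %d: no full windows", chrom_span, w)


# -- sample metadata ---------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample annotation table aligned to the cohort's sample order."""

    table: pd.DataFrame  # indexed by sample id, reindexed to the cohort

    @property
    def columns(self) -> List[str]:
        return list(self.table.columns)

    def annotations(self, sample_id: str) -> dict:
        return self.table.loc[sample_id].to_dict()


def read_metadata(path: str, sample_ids: Sequence[str],
                  quantitative: Optional[str] = None) -> SampleMetadata:
    """Read a metadata TSV (first column = sample id) and align it to the cohort.

    Metadata rows for unknown samples are dropped with a warning; cohort
    samples without metadata get NA annotations. When ``quantitative`` names
    a column it is validated as numeric.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise VariantFileError(f"duplicate sample ids in metadata: {dups}")
    df = df.set_index(id_col)
    extra = df.index.difference(sample_ids)
    if len(extra):
        warnings.warn(f"dropping {len(extra)} metadata rows with unknown sample ids")
    aligned = df.reindex(sample_ids)
    if quantitative is not None:
        if quantitative not in aligned.columns:
            raise VariantFileError(
                f"quantitative column {quantitative!r} not in metadata "
                f"(columns: {list(aligned.columns)})")
        vals = pd.to_numeric(aligned[quantitative], errors="coerce")
        if vals.isna().all() or (aligned[quantitative].notna() & vals.isna()).any():
            raise VariantFileError(f"column {quantitative!r} is not numeric")
        aligned[quantitative] = vals
    return SampleMetadata(aligned)


def minmax_positions(values: Sequence[float]) -> np.ndarray:
    """Min-max scale a quantitative column to [0, 1] color positions."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)
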