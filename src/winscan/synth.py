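"""Synthetic cohorts with known population structure and a planted inversion.

The generator draws per-variant ancestral allele frequencies uniformly on
(0.05, 0.95) and population frequencies from a Balding-Nichols Beta model
with divergence F (variance F * p * (1-p) around the ancestral frequency).
Genotypes are Hardy-Weinberg within population. Inside an optional inversion
locus each sample carries an inversion genotype drawn at haplotype frequency
q, and alleles there segregate between the inverted and standard haplotype
classes at an amplified divergence — the way a real non-recombining inversion
manifests to PCA as genotype correlation, producing the characteristic
tripartite (homozygote / heterozygote / homozygote) cluster pattern.

Genotype likelihoods are produced by a read-sampling model: read depth per
sample and site is Poisson, alt-read counts are binomial given the true
genotype and a per-base error rate, and the three genotype likelihoods are
the binomial probabilities of the observed read pair, normalized.

All three on-disk dialects (VCF with GT+PL, BEAGLE, TSV) are emitted from a
single genotype draw, so cross-format comparisons see the same cohort. A
fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class InversionConfig:
    """Planted inversion: closed interval, haplotype frequency, divergence boost."""

    start: int = 2_000_001
    end: int = 4_000_000
    freq: float = 0.5
    divergence_multiplier: float = 4.0


@dataclass
class CohortConfig:
    """Cohort simulation settings.

    ``divergence`` is the Balding-Nichols F between populations;
    ``variant_density`` is variants per bp; ``depth`` is the mean sequencing
    depth of the likelihood model and ``error_rate`` its per-base error.
    """

    n_samples: int = 50          # per population
    n_populations: int = 2
    divergence: float = 0.2
    chrom_length: int = 5_000_000
    chrom: str = "chr1"
    variant_density: float = 0.001
    inversion: Optional[InversionConfig] = field(default_factory=InversionConfig)
    missingness: float = 0.0
    depth: float = 30.0
    error_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence F must lie in (0, 1)")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must lie in [0, 1)")
        if self.inversion is not None:
            inv = self.inversion
            if not (1 <= inv.start <= inv.end <= self.chrom_length):
                raise ValueError("inversion interval must lie within the chromosome")
            if not (0.0 < inv.freq < 1.0):
                raise ValueError("inversion haplotype frequency must lie in (0, 1)")
        if self.depth < 0 or not (0.0 <= self.error_rate < 0.5):
            raise ValueError("depth must be >= 0 and error_rate in [0, 0.5)")


@dataclass
class Cohort:
    """In-memory realization of a simulated cohort."""

    config: CohortConfig
    sample_ids: List[str]
    populations: np.ndarray        # per-sample population label index
    inversion_genotypes: np.ndarray  # per-sample dosage of the inverted haplotype
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray          # samples x variants, NaN = missing
    likelihoods: np.ndarray        # samples x variants x 3, normalized
    qt: np.ndarray                 # quantitative metadata column

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_ids,
            "population": [f"pop{p}" for p in self.populations],
            "inversion_genotype": self.inversion_genotypes,
            "qt": np.round(self.qt, 4),
        })


def _balding_nichols(rng: np.random.Generator, ancestral: np.ndarray,
                     f: float) -> np.ndarray:
    """Draw descendant allele frequencies around ``ancestral`` at divergence f."""
    a = ancestral * (1.0 - f) / f
    b = (1.0 - ancestral) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def simulate_likelihoods(genotypes: np.ndarray, depth: float, error_rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Genotype likelihood triplets from Poisson read depth and binomial errors.

    Works elementwise on an integer dosage array; sites with zero sampled
    reads get the flat (1/3, 1/3, 1/3) triplet.
    """
    g = np.asarray(genotypes)
    n_reads = rng.poisson(depth, size=g.shape)
    p_alt = np.select([g == 0, g == 1], [error_rate, 0.5], default=1.0 - error_rate)
    k_alt = rng.binomial(n_reads, p_alt)
    lik = np.empty(g.shape + (3,), dtype=float)
    for gi, p in enumerate((error_rate, 0.5, 1.0 - error_rate)):
        lik[..., gi] = sps.binom.pmf(k_alt, n_reads, p)
    total = lik.sum(axis=-1, keepdims=True)
    flat = total <= 0
    lik = np.where(flat, 1.0 / 3.0, lik / np.where(flat, 1.0, total))
    return lik


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Draw a full cohort (genotypes, likelihoods, truth labels) from ``cfg``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_samples * cfg.n_populations
    n_var = int(round(cfg.chrom_length * cfg.variant_density))
    if n_var < 1:
        raise ValueError("variant_density too low: no variants")

    positions = np.sort(rng.choice(cfg.chrom_length, size=n_var, replace=False)) + 1
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_var)
    alt_i = (ref_i + rng.integers(1, 4, size=n_var)) % 4

    populations = np.repeat(np.arange(cfg.n_populations), cfg.n_samples)
    sample_ids = [f"pop{p}_s{i}" for p in range(cfg.n_populations)
                  for i in range(cfg.n_samples)]

    ancestral = rng.uniform(0.05, 0.95, size=n_var)
    pop_freqs = np.stack([_balding_nichols(rng, ancestral, cfg.divergence)
                          for _ in range(cfg.n_populations)])

    genotypes = np.empty((n_total, n_var), dtype=float)
    for s in range(n_total):
        genotypes[s] = rng.binomial(2, pop_freqs[populations[s]])

    inv_geno = np.zeros(n_total, dtype=int)
    if cfg.inversion is not None:
        inv = cfg.inversion
        inv_geno = rng.binomial(2, inv.freq, size=n_total)
        in_inv = (positions >= inv.start) & (positions <= inv.end)
        f_inv = min(0.9, cfg.divergence * inv.divergence_multiplier)
        # two haplotype classes replace population structure inside the locus
        p_std = _balding_nichols(rng, ancestral[in_inv], f_inv)
        p_invh = _balding_nichols(rng, ancestral[in_inv], f_inv)
        m = int(in_inv.sum())
        for s in range(n_total):
            d = inv_geno[s]
            genotypes[s, in_inv] = (rng.binomial(d, p_invh) if d else 0) + \
                (rng.binomial(2 - d, p_std) if d < 2 else 0)

    likelihoods = simulate_likelihoods(genotypes.astype(int), cfg.depth,
                                       cfg.error_rate, rng)
    if cfg.missingness > 0:
        mask = rng.random(genotypes.shape) < cfg.missingness
        genotypes[mask] = np.nan
        likelihoods[mask] = 1.0 / 3.0

    qt = inv_geno + rng.normal(0.0, 0.25, size=n_total)
    return Cohort(cfg, sample_ids, populations, inv_geno, positions,
                  bases[ref_i], bases[alt_i], genotypes, likelihoods, qt)


# -- writers (deterministic: gzip mtime pinned to 0) -------------------------

def _out(path: str, compression: Optional[str]):
    if compression == "gzip":
        # empty filename + zero mtime keep the byte stream seed-determined
        return gzip.GzipFile("", "wb", fileobj=open(path, "wb"), mtime=0)
    if compression == "bgzip":
        import pysam
        return pysam.BGZFile(path, "wb")
    return open(path, "wb")


def _write_lines(path: str, lines, compression: Optional[str]) -> None:
    with _out(path, compression) as fh:
        for line in lines:
            fh.write((line + "\n").encode())


def _pl_from_triplet(trip: np.ndarray) -> str:
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(np.maximum(trip, 1e-30))
    pl = np.round(pl - pl.min()).astype(int)
    return ",".join(str(min(v, 255)) for v in pl)


def vcf_lines(cohort: Cohort):
    cfg = cohort.config
    yield "##fileformat=VCFv4.2"
    yield f"##contig=<ID={cfg.chrom},length={cfg.chrom_length}>"
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    yield '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">'
    yield "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + \
        "\t".join(cohort.sample_ids)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j in range(len(cohort.positions)):
        fields = [cfg.chrom, str(int(cohort.positions[j])), ".",
                  str(cohort.ref[j]), str(cohort.alt[j]), ".", "PASS", ".", "GT:PL"]
        for i in range(len(cohort.sample_ids)):
            g = cohort.genotypes[i, j]
            gt = "./." if np.isnan(g) else gt_map[int(g)]
            fields.append(f"{gt}:{_pl_from_triplet(cohort.likelihoods[i, j])}")
        yield "\t".join(fields)


def beagle_lines(cohort: Cohort):
    base_code = {"A": "0", "C": "1", "G": "2", "T": "3"}
    head = ["marker", "allele1", "allele2"]
    for s in cohort.sample_ids:
        head += [s, s, s]
    yield "\t".join(head)
    for j in range(len(cohort.positions)):
        row = [f"{cohort.config.chrom}_{int(cohort.positions[j])}",
               base_code[str(cohort.ref[j])], base_code[str(cohort.alt[j])]]
        for i in range(len(cohort.sample_ids)):
            row += [f"{v:.6f}" for v in cohort.likelihoods[i, j]]
        yield "\t".join(row)


def tsv_lines(cohort: Cohort):
    yield "CHROM\tPOS\t" + "\t".join(cohort.sample_ids)
    for j in range(len(cohort.positions)):
        vals = ["NA" if np.isnan(g) else str(int(g)) for g in cohort.genotypes[:, j]]
        yield f"{cohort.config.chrom}\t{int(cohort.positions[j])}\t" + "\t".join(vals)


def write_vcf(cohort: Cohort, path: str, compression: Optional[str] = "gzip") -> None:
    _write_lines(path, vcf_lines(cohort), compression)


def write_beagle(cohort: Cohort, path: str, compression: Optional[str] = "gzip") -> None:
    _write_lines(path, beagle_lines(cohort), compression)


def write_tsv(cohort: Cohort, path: str, compression: Optional[str] = "gzip") -> None:
    _write_lines(path, tsv_lines(cohort), compression)


def write_cohort(cohort: Cohort, out_prefix: str) -> Dict[str, str]:
    """Emit the VCF, BEAGLE, TSV and truth files for a simulated cohort."""
    paths = {
        "vcf": f"{out_prefix}.vcf.gz",
        "beagle": f"{out_prefix}.beagle.gz",
        "tsv": f"{out_prefix}.tsv.gz",
        "truth": f"{out_prefix}.truth.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_beagle(cohort, paths["beagle"])
    write_tsv(cohort, paths["tsv"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
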