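"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout (the VCF/GFF
convention); conversion to BED's 0-based half-open intervals happens only
in :func:`write_bed`.  Genotypes are unphased: ``0/1`` and ``1/0`` are the
same genotype, and phase separators on input are accepted and discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import yaml

log = logging.getLogger("teapop")

#: INFO annotations consumed by the hard filter.
INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: Sentinel genotype for a missing call (``./.``).
MISSING = (-1, -1)


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class VariantSite:
    """One VCF record: site annotations plus per-sample diploid calls.

    ``genotypes`` holds one unordered allele-index pair per sample, with
    ``(-1, -1)`` marking a missing call; ``depths`` holds per-sample read
    depth with ``None`` for a missing DP.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    qual: Optional[float]
    info: dict[str, float]
    genotypes: list[tuple[int, int]]
    depths: list[Optional[int]]
    site_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        n_alleles = len(self.alts)
        for g in self.genotypes:
            for a in g:
                if a != -1 and not (0 <= a <= n_alleles):
                    raise ValueError(f"allele index {a} out of range at "
                                     f"{self.chrom}:{self.pos}")
        for d in self.depths:
            if d is not None and d < 0:
                raise ValueError("depths must be >= 0 when present")

    @property
    def is_indel(self) -> bool:
        """True when any allele has length != 1."""
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)

    @property
    def is_biallelic_snp(self) -> bool:
        return len(self.alts) == 1 and not self.is_indel

    def total_depth(self) -> int:
        """Sum of per-sample depths, treating missing DP as 0."""
        return sum(d for d in self.depths if d is not None)

    def missing_fraction(self) -> float:
        n = len(self.genotypes)
        if n == 0:
            return 0.0
        return sum(1 for g in self.genotypes if g == MISSING) / n

    def alt_dosages(self) -> np.ndarray:
        """Per-sample count of non-reference alleles; -1 where missing."""
        out = np.empty(len(self.genotypes), dtype=np.int8)
        for i, (a, b) in enumerate(self.genotypes):
            out[i] = -1 if (a, b) == MISSING else (a != 0) + (b != 0)
        return out


@dataclass
class PopulationSpec:
    """A named population and its ordered member samples."""

    name: str
    samples: list[str]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"population {self.name!r} has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError(f"population {self.name!r} has duplicate samples")


@dataclass
class GeneFeature:
    """A gene row from a GFF3 file (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-sites matrix of alternate-allele dosages.

    ``dosages`` is int8 with values {0, 1, 2} and -1 for missing; ``depths``
    (optional) is per-sample, per-site read depth.  Sites are columns and
    are sorted by position along one chromosome.
    """

    chrom: str
    positions: np.ndarray            # (n_sites,) int64, 1-based
    dosages: np.ndarray              # (n_samples, n_sites) int8
    samples: list[str]
    depths: Optional[np.ndarray] = None   # (n_samples, n_sites) int32
    ref: Optional[list[str]] = None
    alt: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), self.positions.size):
            raise ValueError("dosages shape does not match samples x sites")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def alt_allele_counts(self, sample_idx: Optional[np.ndarray] = None
                          ) -> tuple[np.ndarray, np.ndarray]:
        """Return (alt allele count, called allele count) per site."""
        d = self.dosages if sample_idx is None else self.dosages[sample_idx]
        called = d >= 0
        alt = np.where(called, d, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        return alt.astype(np.int64), n.astype(np.int64)

    @classmethod
    def from_sites(cls, sites: Iterable[VariantSite],
                   samples: list[str]) -> "GenotypeMatrix":
        """Build a matrix from biallelic SNP records on one chromosome."""
        pos, dos, dep, refs, alts = [], [], [], [], []
        chrom = None
        for s in sites:
            if not s.is_biallelic_snp:
                continue
            if chrom is None:
                chrom = s.chrom
            elif s.chrom != chrom:
                raise ValueError("from_sites expects a single chromosome")
            pos.append(s.pos)
            dos.append(s.alt_dosages())
            dep.append([0 if d is None else d for d in s.depths])
            refs.append(s.ref)
            alts.append(s.alts[0])
        if chrom is None:
            raise ValueError("no biallelic SNPs in input")
        return cls(chrom=chrom,
                   positions=np.array(pos),
                   dosages=np.array(dos, dtype=np.int8).T,
                   samples=list(samples),
                   depths=np.array(dep, dtype=np.int32).T,
                   ref=refs, alt=alts)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path,
             sample_subset: Optional[Sequence[str]] = None
             ) -> Iterator[VariantSite]:
    """Stream :class:`VariantSite` records from a VCF 4.x file.

    Absent INFO annotations are left out of ``info`` (never imputed to 0).
    Raises if a requested sample is not in the header, or with the record
    index if a record cannot be interpreted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in header_samples]
        if missing:
            raise VcfParseError(
                f"samples not in VCF header: {', '.join(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    for i, v in enumerate(vcf, start=1):
        try:
            info = {}
            for k in INFO_KEYS:
                val = v.INFO.get(k)
                if val is not None:
                    info[k] = float(val)
            gts = [(g[0], g[1]) if g[0] >= 0 and g[1] >= 0 else MISSING
                   for g in v.genotypes]
            dp = v.format("DP")
            if dp is None:
                depths: list[Optional[int]] = [None] * len(samples)
            else:
                depths = [None if d < 0 else int(d) for d in dp[:, 0]]
            yield VariantSite(
                chrom=v.CHROM, pos=v.POS, ref=v.REF,
                alts=list(v.ALT), qual=v.QUAL, info=info,
                genotypes=gts, depths=depths,
                site_id=v.ID or ".")
        except VcfParseError:
            raise
        except Exception as e:     # htslib gives no source line numbers
            raise VcfParseError(f"malformed VCF record #{i} in {path}: {e}"
                                ) from e


def write_vcf(sites: Iterable[VariantSite], samples: Sequence[str],
              path: str | Path) -> None:
    """Write sites as a minimal VCF 4.2 file (GT:DP format).

    Input must be sorted by (chrom, pos) — chromosomes grouped, positions
    non-decreasing — or a ``ValueError`` is raised.
    """
    sites = list(sites)
    seen_chroms: list[str] = []
    last: tuple[str, int] | None = None
    for s in sites:
        if last is None or s.chrom != last[0]:
            if s.chrom in seen_chroms:
                raise ValueError(f"unsorted input: chromosome {s.chrom} "
                                 "records are not contiguous")
            seen_chroms.append(s.chrom)
        elif s.pos < last[1]:
            raise ValueError(f"unsorted input at {s.chrom}:{s.pos}")
        last = (s.chrom, s.pos)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=teapop\n')
        for k in INFO_KEYS:
            fh.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in seen_chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in sites:
            if len(s.genotypes) != len(samples):
                raise ValueError(f"site {s.chrom}:{s.pos} has "
                                 f"{len(s.genotypes)} genotypes for "
                                 f"{len(samples)} samples")
            qual = "." if s.qual is None else f"{s.qual:.10g}"
            info = ";".join(f"{k}={s.info[k]:g}" for k in INFO_KEYS
                            if k in s.info) or "."
            cols = [s.chrom, str(s.pos), s.site_id, s.ref,
                    ",".join(s.alts) or ".", qual, ".", info, "GT:DP"]
            for (a, b), d in zip(s.genotypes, s.depths):
                gt = "./." if (a, b) == MISSING else f"{a}/{b}"
                dp = "." if d is None else str(d)
                cols.append(f"{gt}:{dp}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED / tables

def read_gff(path: str | Path) -> list[GeneFeature]:
    """Read gene rows from a GFF3 file, sorted by (chrom, start).

    Only rows with feature type ``gene`` are retained.  The gene id is the
    ``ID=`` attribute (``gene_id=`` accepted as fallback).
    """
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            start, end = int(fields[3]), int(fields[4])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            gene_id = "NA"
            for attr in fields[8].split(";"):
                k, _, v = attr.partition("=")
                if k.strip() in ("ID", "gene_id"):
                    gene_id = v.strip()
                    break
            genes.append(GeneFeature(chrom=fields[0], start=start, end=end,
                                     strand=fields[6], gene_id=gene_id))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff(genes: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tteapop\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write scored intervals as BED (0-based half-open).

    ``regions`` must carry chrom/start/end (1-based inclusive) and score;
    the conversion is start-1 / end-unchanged.
    """
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t.\t{r.score:g}\n")


def read_population_table(path: str | Path) -> list[PopulationSpec]:
    """Read a two-column (sample TAB population) assignment table."""
    by_pop: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sample, pop = parts
            by_pop.setdefault(pop, []).append(sample)
    return [PopulationSpec(name=p, samples=s) for p, s in by_pop.items()]


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a flat dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
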