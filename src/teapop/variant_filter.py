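"""Hard filtering and the five strict SNP criteria, as an ordered cascade.

The cascade applies, in order: the GATK-style hard filter on site
annotations, then (1) indel proximity (>= 5 bp from any indel record),
(2) consensus quality >= 40, (3) biallelic SNP only, (4) per-site total
depth inside the empirical 2.5th-97.5th percentiles of the candidate set,
and (5) minor allele frequency >= 0.01.  All comparison boundaries are
inclusive exactly as the operators are written.

Missing-data conventions: an absent INFO annotation never fails its
hard-filter condition (the annotation is a property of evidence that may
be undefined), while a missing QUAL fails the quality criterion (QUAL is
the criterion's subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import MISSING, VariantSite

HARD_FILTER_THRESHOLDS = {
    "QD": (">=", 2.0),
    "FS": ("<=", 60.0),
    "MQ": (">=", 40.0),
    "MQRankSum": (">=", -12.5),
    "ReadPosRankSum": (">=", -8.0),
}


@dataclass
class FilterReport:
    """Per-step accounting of the filter cascade."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int,
            removed_positions: Optional[list[int]] = None,
            **extra) -> None:
        if self.steps and n_in != self.steps[-1]["n_out"]:
            raise ValueError("cascade steps must chain: input of step "
                             f"{name!r} is not the previous step's output")
        if n_out > n_in:
            raise ValueError(f"step {name!r} increased the site count")
        rec = {"step": name, "n_in": n_in, "n_out": n_out, **extra}
        if removed_positions is not None:
            rec["removed_positions"] = removed_positions
        self.steps.append(rec)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in s.items()
                              if k != "removed_positions"}
                             for s in self.steps])

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def hard_filter(site: VariantSite) -> tuple[bool, list[str]]:
    """GATK-style hard filter on the five site annotations.

    Passes iff QD >= 2.0, FS <= 60.0, MQ >= 40.0, MQRankSum >= -12.5 and
    ReadPosRankSum >= -8.0; an absent annotation does not fail.
    """
    failing = []
    for key, (op, thr) in HARD_FILTER_THRESHOLDS.items():
        val = site.info.get(key)
        if val is None:
            continue
        ok = val >= thr if op == ">=" else val <= thr
        if not ok:
            failing.append(key)
    return (not failing), failing


def indel_proximity_filter(sites: Sequence[VariantSite], window: int = 5
                           ) -> list[VariantSite]:
    """Keep SNPs at least ``window`` bp from every indel record.

    A SNP survives iff no indel exists with |snp.pos - indel.pos| < window
    on the same chromosome (the indel's POS anchors its location).  Indel
    records themselves are dropped from the returned stream.  Input must
    be position-sorted per chromosome.
    """
    _check_sorted(sites)
    indel_pos: dict[str, list[int]] = {}
    for s in sites:
        if s.is_indel:
            indel_pos.setdefault(s.chrom, []).append(s.pos)
    indel_arr = {c: np.asarray(p, dtype=np.int64)
                 for c, p in indel_pos.items()}

    out = []
    for s in sites:
        if s.is_indel:
            continue
        arr = indel_arr.get(s.chrom)
        if arr is not None and arr.size:
            j = int(np.searchsorted(arr, s.pos))
            near = any(0 <= k < arr.size and abs(int(arr[k]) - s.pos) < window
                       for k in (j - 1, j))
            if near:
                continue
        out.append(s)
    return out


def quality_filter(site: VariantSite, min_qual: float = 40.0) -> bool:
    """Consensus quality criterion: QUAL >= 40 (missing QUAL fails)."""
    return site.qual is not None and site.qual >= min_qual


def biallelic_snp_filter(site: VariantSite) -> bool:
    """Exactly one alternate allele and all alleles of length 1."""
    return site.is_biallelic_snp


def depth_percentile_filter(sites: Sequence[VariantSite],
                            lo_pct: float = 2.5, hi_pct: float = 97.5
                            ) -> tuple[list[VariantSite], tuple[float, float]]:
    """Keep sites whose total depth lies inside the empirical percentiles.

    The bounds are the linear-interpolation percentiles of per-site total
    depth over the full candidate set passed in; a site survives iff
    lo <= depth <= hi.  Returns (survivors, (lo, hi)).
    """
    if not sites:
        raise ValueError("depth_percentile_filter requires a non-empty set")
    totals = np.array([s.total_depth() for s in sites], dtype=float)
    lo, hi = np.percentile(totals, [lo_pct, hi_pct])
    keep = (totals >= lo) & (totals <= hi)
    return [s for s, k in zip(sites, keep) if k], (float(lo), float(hi))


def maf_filter(site: VariantSite, min_maf: float = 0.01) -> bool:
    """Minor-allele-frequency criterion over non-missing genotypes.

    MAF = min(p, 1-p) with p = alt-dosage sum / (2 x called samples);
    passes iff MAF >= 0.01.  All-missing sites fail.
    """
    dos = site.alt_dosages()
    called = dos >= 0
    n_called = int(called.sum())
    if n_called == 0:
        return False
    p = float(np.where(called, dos, 0).sum()) / (2.0 * n_called)
    return min(p, 1.0 - p) >= min_maf


def filter_cascade(sites: Sequence[VariantSite], *,
                   indel_window: int = 5,
                   min_qual: float = 40.0,
                   depth_lo_pct: float = 2.5, depth_hi_pct: float = 97.5,
                   min_maf: float = 0.01,
                   ) -> tuple[list[VariantSite], FilterReport]:
    """Run the full strict-filter cascade and report per-step counts."""
    _check_sorted(sites)
    report = FilterReport()
    current = list(sites)

    survivors = [s for s in current if hard_filter(s)[0]]
    report.add("hard_filter", len(current), len(survivors))
    current = survivors

    survivors = indel_proximity_filter(current, window=indel_window)
    report.add("indel_proximity", len(current), len(survivors))
    current = survivors

    survivors = [s for s in current if quality_filter(s, min_qual)]
    report.add("quality", len(current), len(survivors))
    current = survivors

    survivors = [s for s in current if biallelic_snp_filter(s)]
    report.add("biallelic_snp", len(current), len(survivors))
    current = survivors

    if current:
        survivors, (lo, hi) = depth_percentile_filter(
            current, depth_lo_pct, depth_hi_pct)
        report.add("depth_percentile", len(current), len(survivors),
                   depth_lo=lo, depth_hi=hi)
        current = survivors
    else:
        report.add("depth_percentile", 0, 0)

    survivors = [s for s in current if maf_filter(s, min_maf)]
    report.add("maf", len(current), len(survivors))
    return survivors, report


def select_for_structure(sites: Sequence[VariantSite],
                         max_missing: float = 0.2,
                         thin_bp: int = 2000) -> list[VariantSite]:
    """Missingness filter plus greedy physical thinning.

    Drops sites with a missing-genotype fraction above ``max_missing``,
    then keeps the first site of each chromosome and every subsequent site
    at least ``thin_bp`` away from the last kept site (a deterministic
    left-to-right minimum-spacing walk).
    """
    _check_sorted(sites)
    kept: list[VariantSite] = []
    last: dict[str, int] = {}
    for s in sites:
        if s.missing_fraction() > max_missing:
            continue
        prev = last.get(s.chrom)
        if prev is None or s.pos - prev >= thin_bp:
            kept.append(s)
            last[s.chrom] = s.pos
    return kept


def select_for_structure_binned(sites: Sequence[VariantSite],
                                max_missing: float = 0.2,
                                bin_bp: int = 2000) -> list[VariantSite]:
    """Fixed-bin alternative: keep the first eligible site per 2-kb bin."""
    _check_sorted(sites)
    kept: list[VariantSite] = []
    seen: set[tuple[str, int]] = set()
    for s in sites:
        if s.missing_fraction() > max_missing:
            continue
        key = (s.chrom, (s.pos - 1) // bin_bp)
        if key not in seen:
            seen.add(key)
            kept.append(s)
    return kept


def _check_sorted(sites: Iterable[VariantSite]) -> None:
    last: Optional[tuple[str, int]] = None
    seen: set[str] = set()
    for s in sites:
        if last is None or s.chrom != last[0]:
            if s.chrom in seen:
                raise ValueError("input not sorted: chromosome "
                                 f"{s.chrom} not contiguous")
            seen.add(s.chrom)
        elif s.pos < last[1]:
            raise ValueError(f"input not sorted at {s.chrom}:{s.pos}")
        last = (s.chrom, s.pos)
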