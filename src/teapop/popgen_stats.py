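"""Windowed diversity statistics and linkage-disequilibrium decay.

Implements site/window/individual heterozygosity (40-kb windows, 20-kb
step, windows with mean per-sample depth < 1 removed), nucleotide
diversity pi with the 8-sample x 20-replicate subsampling protocol
(50-kb windows, 10-kb step), Tajima's D, the Weir & Cockerham (1984)
two-population Fst estimator, and r^2 decay with the half-decay-distance
summary.  All statistics are phase-free and operate on unphased
alternate-allele dosages; r^2 is the squared Pearson correlation of
dosages (Rogers-Huff style), the standard choice for unphased
resequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, PopulationSpec, VariantSite


@dataclass
class WindowStat:
    """One sliding-window value of a statistic."""

    chrom: str
    start: int       # 1-based inclusive
    end: int
    value: float
    n_sites: int
    mean_depth: float = float("nan")


@dataclass
class LDCurve:
    """Binned r^2-vs-distance curve with its half-decay summary."""

    bin_mid: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    half_decay_distance: Optional[float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_mid": self.bin_mid,
                             "mean_r2": self.mean_r2,
                             "n_pairs": self.n_pairs})


def windows_for(chrom_length: int, size: int, step: int
                ) -> list[tuple[int, int]]:
    """Tile [1, chrom_length] with sliding windows (1-based inclusive)."""
    if size < step:
        import warnings
        warnings.warn("window size < step leaves gaps between windows")
    out = []
    start = 1
    while start <= chrom_length:
        out.append((start, min(start + size - 1, chrom_length)))
        start += step
    return out


# ---------------------------------------------------------------------------
# Heterozygosity

def site_pop_heterozygosity(site: VariantSite,
                            sample_indices: Optional[Sequence[int]] = None
                            ) -> float:
    """Fraction of heterozygous individuals among called individuals.

    Returns NaN when no individual in the population is called (such
    sites are excluded from window means).
    """
    gts = (site.genotypes if sample_indices is None
           else [site.genotypes[i] for i in sample_indices])
    called = [g for g in gts if g != MISSING]
    if not called:
        return float("nan")
    het = sum(1 for a, b in called if a != b)
    return het / len(called)


def _pop_idx(matrix: GenotypeMatrix,
             pop: Optional[PopulationSpec]) -> np.ndarray:
    if pop is None:
        return np.arange(matrix.n_samples)
    return matrix.sample_indices(pop.samples)


def per_site_heterozygosity(matrix: GenotypeMatrix,
                            pop: Optional[PopulationSpec] = None
                            ) -> np.ndarray:
    """Vectorized per-site population heterozygosity (NaN = no calls)."""
    d = matrix.dosages[_pop_idx(matrix, pop)]
    called = (d >= 0).sum(axis=0)
    het = (d == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def window_heterozygosity(matrix: GenotypeMatrix,
                          pop: Optional[PopulationSpec] = None,
                          size: int = 40_000, step: int = 20_000,
                          chrom_length: Optional[int] = None,
                          min_mean_depth: float = 1.0) -> list[WindowStat]:
    """Mean site heterozygosity per sliding window.

    Windows whose mean per-sample, per-site depth is below
    ``min_mean_depth`` are removed, as are windows without any called
    site.
    """
    length = chrom_length or int(matrix.positions[-1]) if matrix.n_sites \
        else (chrom_length or 0)
    hets = per_site_heterozygosity(matrix, pop)
    out = []
    for start, end in windows_for(length, size, step):
        i0, i1 = np.searchsorted(matrix.positions, [start, end + 1])
        vals = hets[i0:i1]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        mean_depth = _window_mean_depth(matrix, i0, i1)
        if not np.isnan(mean_depth) and mean_depth < min_mean_depth:
            continue
        out.append(WindowStat(matrix.chrom, start, end,
                              float(vals.mean()), int(vals.size),
                              mean_depth))
    return out


def _window_mean_depth(matrix: GenotypeMatrix, i0: int, i1: int) -> float:
    if matrix.depths is None or i1 <= i0:
        return float("nan")
    return float(matrix.depths[:, i0:i1].mean())


def individual_heterozygosity(matrix: GenotypeMatrix, sample: str | int
                              ) -> float:
    """Fraction of an individual's called loci that are heterozygous."""
    i = (matrix.samples.index(sample) if isinstance(sample, str) else sample)
    d = matrix.dosages[i]
    called = d >= 0
    if not called.any():
        return float("nan")
    return float((d == 1).sum() / called.sum())


# ---------------------------------------------------------------------------
# Nucleotide diversity

def per_site_pi(matrix: GenotypeMatrix,
                pop: Optional[PopulationSpec] = None) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2*na*(nt-na)/(nt*(nt-1))."""
    alt, nt = matrix.alt_allele_counts(_pop_idx(matrix, pop))
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (nt - alt) / (nt * (nt - 1.0))
    pi[nt < 2] = 0.0
    return pi


def nucleotide_diversity_pi(matrix: GenotypeMatrix,
                            pop: Optional[PopulationSpec] = None,
                            size: int = 50_000, step: int = 10_000,
                            chrom_length: Optional[int] = None
                            ) -> list[WindowStat]:
    """Windowed pi: summed per-site diversity over the window length (bp)."""
    length = chrom_length or (int(matrix.positions[-1])
                              if matrix.n_sites else 0)
    pis = per_site_pi(matrix, pop)
    out = []
    for start, end in windows_for(length, size, step):
        i0, i1 = np.searchsorted(matrix.positions, [start, end + 1])
        span = end - start + 1
        out.append(WindowStat(matrix.chrom, start, end,
                              float(pis[i0:i1].sum()) / span,
                              int(i1 - i0),
                              _window_mean_depth(matrix, i0, i1)))
    return out


def subsampled_pi(matrix: GenotypeMatrix, pops: Sequence[PopulationSpec],
                  k: int = 8, reps: int = 20, seed: int = 0,
                  size: int = 50_000, step: int = 10_000,
                  chrom_length: Optional[int] = None) -> pd.DataFrame:
    """Replicated equal-size subsampling of windowed pi.

    For each population, ``reps`` draws of ``k`` samples without
    replacement; returns a long DataFrame (population, rep, chrom, start,
    end, pi) suitable for boxplotting.  Equal subsample sizes remove the
    sample-number dependence of diversity comparisons between
    populations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pop in pops:
        if len(pop.samples) < k:
            raise ValueError(f"population {pop.name!r} has fewer than "
                             f"{k} samples")
        for rep in range(reps):
            chosen = [pop.samples[i] for i in
                      rng.choice(len(pop.samples), size=k, replace=False)]
            sub = PopulationSpec(name=pop.name, samples=chosen)
            for w in nucleotide_diversity_pi(matrix, sub, size, step,
                                             chrom_length):
                rows.append({"population": pop.name, "rep": rep,
                             "chrom": w.chrom, "start": w.start,
                             "end": w.end, "pi": w.value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants(n: int) -> tuple[float, ...]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(matrix: GenotypeMatrix,
              pop: Optional[PopulationSpec] = None,
              size: int = 50_000, step: int = 10_000,
              chrom_length: Optional[int] = None) -> list[WindowStat]:
    """Windowed Tajima's D from segregating sites and pairwise diversity.

    The sample size entering the a1..e2 normalization constants is the
    rounded mean called-allele count over the window's segregating sites
    (missingness makes the count vary site to site).  Windows with no
    segregating site, or mean n < 4, get a NaN value.
    """
    length = chrom_length or (int(matrix.positions[-1])
                              if matrix.n_sites else 0)
    alt, nt = matrix.alt_allele_counts(_pop_idx(matrix, pop))
    seg = (alt > 0) & (alt < nt)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(nt > 1,
                           2.0 * alt * (nt - alt) / (nt * (nt - 1.0)), 0.0)
    out = []
    for start, end in windows_for(length, size, step):
        i0, i1 = np.searchsorted(matrix.positions, [start, end + 1])
        seg_w = seg[i0:i1]
        S = int(seg_w.sum())
        if S == 0:
            out.append(WindowStat(matrix.chrom, start, end, float("nan"),
                                  int(i1 - i0)))
            continue
        n_eff = int(round(nt[i0:i1][seg_w].mean()))
        if n_eff < 4:
            out.append(WindowStat(matrix.chrom, start, end, float("nan"),
                                  int(i1 - i0)))
            continue
        a1, e1, e2 = _tajima_constants(n_eff)
        pi_sum = float(pi_site[i0:i1].sum())
        var = e1 * S + e2 * S * (S - 1.0)
        d = (pi_sum - S / a1) / np.sqrt(var)
        out.append(WindowStat(matrix.chrom, start, end, float(d),
                              int(i1 - i0)))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst

def wc_fst_components(matrix: GenotypeMatrix, pop_a: PopulationSpec,
                      pop_b: PopulationSpec
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir & Cockerham (1984) variance components.

    Returns (a, a+b+c) per site, NaN where a population has no called
    genotypes or fewer than two samples are called overall.
    """
    comps = []
    for pop in (pop_a, pop_b):
        d = matrix.dosages[_pop_idx(matrix, pop)]
        called = d >= 0
        n = called.sum(axis=0).astype(float)               # individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, d, 0).sum(axis=0) / (2.0 * n)
            h = (d == 1).sum(axis=0) / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) \
            / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                 - (r - 1.0) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar)
                                     - (r - 1.0) / r * s2
                                     - (2.0 * nbar - 1.0)
                                     / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    denom = a + b + c
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(denom)
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)
    return a, denom


def weir_cockerham_fst(matrix: GenotypeMatrix, pop_a: PopulationSpec,
                       pop_b: PopulationSpec,
                       size: int = 50_000, step: int = 10_000,
                       chrom_length: Optional[int] = None
                       ) -> list[WindowStat]:
    """Windowed ratio-of-sums Weir & Cockerham Fst between two populations."""
    length = chrom_length or (int(matrix.positions[-1])
                              if matrix.n_sites else 0)
    a, denom = wc_fst_components(matrix, pop_a, pop_b)
    out = []
    for start, end in windows_for(length, size, step):
        i0, i1 = np.searchsorted(matrix.positions, [start, end + 1])
        aw, dw = a[i0:i1], denom[i0:i1]
        ok = np.isfinite(dw)
        dsum = float(dw[ok].sum())
        value = float(aw[ok].sum() / dsum) if ok.any() and dsum != 0 \
            else float("nan")
        out.append(WindowStat(matrix.chrom, start, end, value,
                              int(ok.sum())))
    return out


# ---------------------------------------------------------------------------
# LD decay

def ld_decay(matrix: GenotypeMatrix,
             pop: Optional[PopulationSpec] = None,
             max_dist: int = 300_000, bin_bp: int = 1000,
             maf_min: float = 0.05) -> LDCurve:
    """Distance-binned mean r^2 between genotype-dosage pairs.

    r^2 is the squared Pearson correlation of alternate-allele dosages
    over the samples called at both sites; pairs where either site is
    monomorphic in that sample subset are skipped.  The half-decay
    distance is the smallest bin midpoint whose mean r^2 falls to half
    the maximum bin mean.
    """
    idx = _pop_idx(matrix, pop)
    d = matrix.dosages[idx].astype(float)
    d[d < 0] = np.nan
    called = ~np.isnan(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(d, axis=0) / (2.0 * called.sum(axis=0))
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.isfinite(maf) & (maf >= maf_min)
    pos = matrix.positions[keep]
    d = d[:, keep]

    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    x_valid = ~np.isnan(d)
    x0 = np.where(x_valid, d, 0.0)
    for i in range(pos.size - 1):
        j1 = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        if j1 <= i + 1:
            continue
        sl = slice(i + 1, j1)
        v = x_valid[:, i][:, None] & x_valid[:, sl]
        n = v.sum(axis=0).astype(float)
        xi = np.where(v, x0[:, i][:, None], 0.0)
        yj = np.where(v, x0[:, sl], 0.0)
        sx = xi.sum(axis=0)
        sy = yj.sum(axis=0)
        sxx = (xi * xi).sum(axis=0)
        syy = (yj * yj).sum(axis=0)
        sxy = (xi * yj).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = n * sxy - sx * sy
            den = (n * sxx - sx ** 2) * (n * syy - sy ** 2)
            r2 = num ** 2 / den
        dist = (pos[sl] - pos[i]).astype(np.int64)
        bins = np.minimum((dist - 1) // bin_bp, n_bins - 1)
        ok = np.isfinite(r2) & (n >= 2)
        np.add.at(sums, bins[ok], r2[ok])
        np.add.at(counts, bins[ok], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    mids = (np.arange(n_bins) + 0.5) * bin_bp

    half = None
    finite = np.isfinite(means)
    if finite.any():
        target = 0.5 * np.nanmax(means)
        below = finite & (means <= target)
        if below.any():
            half = float(mids[np.argmax(below)])
    return LDCurve(bin_mid=mids, mean_r2=means, n_pairs=counts,
                   half_decay_distance=half)


def window_stats_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame([{"chrom": w.chrom, "start": w.start, "end": w.end,
                          "value": w.value, "n_sites": w.n_sites,
                          "mean_depth": w.mean_depth} for w in stats])
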