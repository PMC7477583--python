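"""Composite-likelihood selective-sweep scan and sweep-region calling.

The scan follows the classical hitchhiking composite-likelihood framework:
under a hard sweep centred at a test position, a lineage sampled at a site
a distance ``d`` away escaped the sweep with probability
``p_e = 1 - exp(-alpha * d)`` (``alpha`` measures sweep strength per bp).
Lineages that did not escape coalesce onto the sweeping haplotype, so the
post-sweep frequency spectrum at the site is a ``p_e``-dependent mixture
that displaces background-spectrum mass toward the extreme frequency
classes.  At each grid position the composite likelihood over nearby
sites is maximized over ``alpha`` and compared with the chromosome-wide
background ("neutral") spectrum:

    CLR = 2 * (max_alpha log CL(alpha) - log CL_background) >= 0.

Sites may be polarized against an outgroup (derived counts) or folded
(minor counts) when no ancestral state is available; substitutions
(derived fixed in the sample) occupy frequency class n.  Background
spectra are estimated per chromosome and population; missing genotypes
make the per-site allele count vary, which is handled exactly through
hypergeometric downsampling of the background spectrum.

Region calling reproduces the bespoke post-processing: contiguous
above-threshold grid points (threshold = top 1% of CLR scores) become
regions, nearby regions are gap-merged when the gap is at most 50% of the
adjacent regions' size (mean of the two by default; min/max/sum exposed),
scores are summed CLR, and regions shorter than 300 bp are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numba import njit
from scipy import stats

from .io_core import GeneFeature, GenotypeMatrix, PopulationSpec, VariantSite

#: default maximizer grid: log-spaced sweep strengths, per bp
DEFAULT_ALPHAS = np.logspace(-8, 0, 40)
#: probability floor replacing exact zeros before taking logs
_P_FLOOR = 1e-300


@dataclass
class PolarizedSite:
    """A site's frequency-class observation for the scan."""

    chrom: str
    pos: int
    derived_count: int     # minor count when folded
    n: int                 # called allele count
    folded: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.derived_count <= self.n:
            raise ValueError(f"derived_count out of range at "
                             f"{self.chrom}:{self.pos}")
        if self.folded and self.derived_count > self.n - self.derived_count:
            raise ValueError("folded sites must use the minor count")

    @property
    def is_substitution(self) -> bool:
        return not self.folded and self.derived_count == self.n


@dataclass
class SFS:
    """A site-frequency spectrum at reference sample size ``n``.

    ``counts`` is indexed by derived-allele class 0..n (class 0 is always
    zero for observable sites; class n holds substitutions).  ``probs``
    is the normalized spectrum over classes 1..n.
    """

    n: int
    counts: np.ndarray
    includes_substitutions: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n + 1,):
            raise ValueError("counts must have length n + 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def probs(self) -> np.ndarray:
        """Normalized spectrum over classes 0..n (class 0 mass is 0)."""
        total = self.counts[1:].sum()
        if total == 0:
            raise ValueError("empty spectrum")
        out = np.zeros(self.n + 1)
        out[1:] = self.counts[1:] / total
        return out


@dataclass
class CLRGridPoint:
    chrom: str
    pos: int
    clr: float
    alpha_hat: float       # NaN when clr == 0


@dataclass
class SweepRegion:
    """A merged interval of above-threshold scan points."""

    chrom: str
    start: int             # 1-based inclusive
    end: int
    score: float           # sum of member CLR scores
    n_points: int
    genes: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Polarization

def polarize(sites: Iterable[VariantSite],
             outgroup_alleles: Mapping[int, str],
             sample_indices: Optional[Sequence[int]] = None
             ) -> list[PolarizedSite]:
    """Polarize biallelic sites against outgroup alleles.

    If the outgroup carries one of the site's two alleles, that allele is
    ancestral and the other is counted as derived; otherwise the site is
    folded and the minor count is recorded.  Sites that are neither
    polymorphic nor substitutions (derived count 0, or folded minor count
    0) are excluded.
    """
    out = []
    for s in sites:
        if not s.is_biallelic_snp:
            continue
        dos = s.alt_dosages()
        if sample_indices is not None:
            dos = dos[list(sample_indices)]
        called = dos >= 0
        n = 2 * int(called.sum())
        if n == 0:
            continue
        alt_count = int(np.where(called, dos, 0).sum())
        anc = outgroup_alleles.get(s.pos)
        if anc == s.ref:
            derived, folded = alt_count, False
        elif anc == s.alts[0]:
            derived, folded = n - alt_count, False
        else:
            derived, folded = min(alt_count, n - alt_count), True
        if derived == 0:
            # neither polymorphic nor a substitution: excluded
            continue
        out.append(PolarizedSite(chrom=s.chrom, pos=s.pos,
                                 derived_count=derived, n=n, folded=folded))
    return out


def polarize_matrix(matrix: GenotypeMatrix,
                    pop: Optional[PopulationSpec] = None,
                    ancestral_is_ref: bool = True,
                    folded: bool = False) -> list[PolarizedSite]:
    """Polarize a genotype matrix whose reference allele is ancestral.

    Convenience for simulated data (allele 0 is ancestral by
    construction) and for pre-polarized VCFs.  With ``folded=True`` the
    minor count is recorded and no ancestral information is used.
    """
    idx = (np.arange(matrix.n_samples) if pop is None
           else matrix.sample_indices(pop.samples))
    alt, n = matrix.alt_allele_counts(idx)
    out = []
    for j in range(matrix.n_sites):
        nj, aj = int(n[j]), int(alt[j])
        if nj == 0:
            continue
        if folded:
            c = min(aj, nj - aj)
            if c == 0:
                continue
            out.append(PolarizedSite(matrix.chrom, int(matrix.positions[j]),
                                     c, nj, folded=True))
        else:
            d = aj if ancestral_is_ref else nj - aj
            if d == 0:
                continue
            out.append(PolarizedSite(matrix.chrom, int(matrix.positions[j]),
                                     d, nj, folded=False))
    return out


# ---------------------------------------------------------------------------
# Background spectrum

def _hyp_matrix(n_draw: int, n_pool: int) -> np.ndarray:
    """H[i, j] = P(i derived in n_draw draws | j derived among n_pool)."""
    i = np.arange(n_draw + 1)[:, None]
    j = np.arange(n_pool + 1)[None, :]
    return stats.hypergeom.pmf(i, n_pool, j, n_draw)


def background_sfs(sites: Sequence[PolarizedSite], n: Optional[int] = None,
                   includes_substitutions: bool = True,
                   em_iterations: int = 50) -> SFS:
    """Estimate the chromosome-wide background spectrum at size ``n``.

    With complete data (every site called at ``n`` alleles, no folding)
    this reduces to plain class tallying.  Sites with fewer called
    alleles enter through the hypergeometric projection likelihood, and
    folded sites through the two-class folded likelihood; both are
    handled with a short EM fit of the class probabilities.  Returns the
    spectrum as expected class counts.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("cannot build a background SFS from zero sites")
    if not includes_substitutions:
        sites = [s for s in sites if not s.is_substitution]
        if not sites:
            raise ValueError("no polymorphic sites for the background SFS")
    if n is None:
        n = max(s.n for s in sites)
    if any(s.n > n for s in sites):
        raise ValueError("site with more called alleles than SFS size n")

    # Per-site likelihood rows L[s, j] = P(obs_s | true class j at size n).
    hyp_cache: dict[int, np.ndarray] = {}
    L = np.zeros((len(sites), n + 1))
    for si, s in enumerate(sites):
        H = hyp_cache.get(s.n)
        if H is None:
            H = hyp_cache[s.n] = _hyp_matrix(s.n, n)
        row = H[s.derived_count].copy()
        if s.folded and s.derived_count != s.n - s.derived_count:
            row = row + H[s.n - s.derived_count]
        L[si] = row

    j_max = n if includes_substitutions else n - 1
    active = np.zeros(n + 1, dtype=bool)
    active[1:j_max + 1] = True
    p = np.zeros(n + 1)
    p[active] = 1.0 / np.arange(1, j_max + 1)      # neutral-shaped start
    p[active] /= p[active].sum()

    complete = all((not s.folded) and s.n == n for s in sites)
    if complete:
        counts = np.bincount([s.derived_count for s in sites],
                             minlength=n + 1).astype(float)
        counts[~active] = 0.0
        return SFS(n=n, counts=counts,
                   includes_substitutions=includes_substitutions)

    La = L[:, active]
    for _ in range(em_iterations):
        w = La * p[active][None, :]
        tot = w.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        w /= tot
        new = w.sum(axis=0)
        s_new = new.sum()
        if s_new == 0:
            break
        new /= s_new
        if np.max(np.abs(new - p[active])) < 1e-12:
            p[active] = new
            break
        p[active] = new
    counts = np.zeros(n + 1)
    counts[active] = p[active] * len(sites)
    return SFS(n=n, counts=counts,
               includes_substitutions=includes_substitutions)


# ---------------------------------------------------------------------------
# Sweep-model likelihood tables

def _downsampled_spectra(probs: np.ndarray, n_ref: int, m_max: int
                         ) -> list[np.ndarray]:
    """q[m][i]: background class probabilities downsampled to m draws."""
    out = [None] * (m_max + 1)
    for m in range(1, m_max + 1):
        out[m] = _hyp_matrix(m, n_ref) @ probs
    return out


def _sweep_mixture_matrix(n: int, q: list[np.ndarray]) -> np.ndarray:
    """M[k, c]: P(c derived of n | k lineages escaped), pe-independent.

    The k escapees plus one lineage representing the swept cluster are
    k+1 draws from the pre-sweep population; the cluster lineage's allele
    is copied onto the n-k collapsed lineages.  When all n lineages
    escape, the mixture is exactly the background spectrum at n.
    """
    M = np.zeros((n + 1, n + 1))
    for k in range(n):
        qk = q[k + 1]                       # classes 0..k+1
        for i in range(k + 2):
            p_cluster_derived = i / (k + 1.0)
            # cluster lineage derived: escapees carry i-1, collapsed n-k
            c = i - 1 + (n - k)
            if 0 <= c <= n:
                M[k, c] += qk[i] * p_cluster_derived
            # cluster lineage ancestral: total derived = i
            if i <= n:
                M[k, i] += qk[i] * (1.0 - p_cluster_derived)
    M[n] = q[n]
    return M


def _binom_weights(n: int, pe_grid: np.ndarray) -> np.ndarray:
    """B[g, k] = Binom(k; n, pe_grid[g])."""
    k = np.arange(n + 1)[None, :]
    return stats.binom.pmf(k, n, pe_grid[:, None])


class _ScanTables:
    """Precomputed log-likelihood tables for one background spectrum.

    One table per (site allele count, folded) combination present in the
    data, each of shape (n_pe, n+1): log P(class | p_e) under the sweep
    model, with p_e discretized uniformly on [0, 1].  Background log
    probabilities use the same observable-class conditioning.
    """

    def __init__(self, background: SFS, site_keys: set[tuple[int, bool]],
                 n_pe: int = 512):
        self.n_pe = n_pe
        self.pe_grid = np.linspace(0.0, 1.0, n_pe)
        phi = background.probs
        incl_sub = background.includes_substitutions
        n_ref = background.n
        self.table_ids: dict[tuple[int, bool], int] = {}
        max_classes = max(k[0] for k in site_keys) + 1
        tables = []
        self.bg_log: dict[tuple[int, bool], np.ndarray] = {}
        q_cache = _downsampled_spectra(phi, n_ref,
                                       max(k[0] for k in site_keys))
        for (n, folded) in sorted(site_keys):
            M = _sweep_mixture_matrix(n, q_cache)
            B = _binom_weights(n, self.pe_grid)
            T = B @ M                         # (n_pe, n+1), classes 0..n
            qn = q_cache[n].copy()            # background at this n
            lo, hi = 1, (n if incl_sub else n - 1)
            T = _condition(T, lo, hi)
            qn = _condition(qn[None, :], lo, hi)[0]
            if folded:
                # folded observable classes are minor counts 1..n/2;
                # mass folded onto class 0 (monomorphic/substitution)
                # is unobservable and renormalized away
                T = _condition(_fold_table(T, n), 1, n // 2)
                qn = _condition(_fold_table(qn[None, :], n), 1, n // 2)[0]
            logT = np.log(np.maximum(T, _P_FLOOR))
            padded = np.full((self.n_pe, max_classes), np.log(_P_FLOOR))
            padded[:, :logT.shape[1]] = logT
            self.table_ids[(n, folded)] = len(tables)
            tables.append(padded)
            self.bg_log[(n, folded)] = np.log(np.maximum(qn, _P_FLOOR))
        self.log_tables = np.stack(tables)    # (n_tables, n_pe, max_classes)


def _condition(T: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Restrict class probabilities to the observable range and renormalize."""
    out = T.copy()
    out[:, :lo] = 0.0
    out[:, hi + 1:] = 0.0
    norm = out.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return out / norm


def _fold_table(T: np.ndarray, n: int) -> np.ndarray:
    """Fold class probabilities: P_f(m) = P(m) + P(n - m) for m < n - m."""
    out = np.zeros_like(T)
    for m in range(0, n // 2 + 1):
        if m == n - m:
            out[:, m] = T[:, m]
        else:
            out[:, m] = T[:, m] + T[:, n - m]
    return out


@njit(cache=False)
def _scan_kernel(grid_pos, site_pos, site_lo, site_hi, tid, cls, bg_ll,
                 log_tables, alphas, n_pe, refine_iters):
    n_grid = grid_pos.size
    clr = np.zeros(n_grid)
    alpha_hat = np.full(n_grid, np.nan)
    n_alpha = alphas.size
    inv_phi = (np.sqrt(5.0) - 1.0) / 2.0
    for g in range(n_grid):
        lo, hi = site_lo[g], site_hi[g]
        if hi - lo < 2:
            continue
        bg = 0.0
        for s in range(lo, hi):
            bg += bg_ll[s]
        best_ll = -1e300
        best_ia = 0
        for ia in range(n_alpha):
            a = alphas[ia]
            ll = 0.0
            for s in range(lo, hi):
                d = abs(site_pos[s] - grid_pos[g])
                pe = 1.0 - np.exp(-a * d)
                idx = int(pe * (n_pe - 1) + 0.5)
                ll += log_tables[tid[s], idx, cls[s]]
            if ll > best_ll:
                best_ll = ll
                best_ia = ia
        best_a = alphas[best_ia]
        if refine_iters > 0 and best_ll > bg:
            la = np.log(alphas[best_ia - 1]) if best_ia > 0 \
                else np.log(alphas[0]) - 1.0
            lb = np.log(alphas[best_ia + 1]) if best_ia < n_alpha - 1 \
                else np.log(alphas[n_alpha - 1]) + 1.0
            x1 = lb - inv_phi * (lb - la)
            x2 = la + inv_phi * (lb - la)
            f1 = _loglik_at(np.exp(x1), g, lo, hi, grid_pos, site_pos,
                            tid, cls, log_tables, n_pe)
            f2 = _loglik_at(np.exp(x2), g, lo, hi, grid_pos, site_pos,
                            tid, cls, log_tables, n_pe)
            for _ in range(refine_iters):
                if f1 < f2:
                    la = x1
                    x1, f1 = x2, f2
                    x2 = la + inv_phi * (lb - la)
                    f2 = _loglik_at(np.exp(x2), g, lo, hi, grid_pos,
                                    site_pos, tid, cls, log_tables, n_pe)
                else:
                    lb = x2
                    x2, f2 = x1, f1
                    x1 = lb - inv_phi * (lb - la)
                    f1 = _loglik_at(np.exp(x1), g, lo, hi, grid_pos,
                                    site_pos, tid, cls, log_tables, n_pe)
            if f1 > best_ll:
                best_ll, best_a = f1, np.exp(x1)
            if f2 > best_ll:
                best_ll, best_a = f2, np.exp(x2)
        value = 2.0 * (best_ll - bg)
        if value > 0.0:
            clr[g] = value
            alpha_hat[g] = best_a
    return clr, alpha_hat


@njit(cache=False)
def _loglik_at(a, g, lo, hi, grid_pos, site_pos, tid, cls, log_tables, n_pe):
    ll = 0.0
    for s in range(lo, hi):
        d = abs(site_pos[s] - grid_pos[g])
        pe = 1.0 - np.exp(-a * d)
        idx = int(pe * (n_pe - 1) + 0.5)
        ll += log_tables[tid[s], idx, cls[s]]
    return ll


def clr_scan(sites: Sequence[PolarizedSite], background: SFS,
             grid_spacing: int = 100, *,
             alphas: Optional[np.ndarray] = None,
             max_dist: int = 200_000,
             n_pe: int = 512,
             refine: bool = True,
             span: Optional[tuple[int, int]] = None
             ) -> list[CLRGridPoint]:
    """Composite-likelihood-ratio scan across one chromosome.

    Test positions are placed every ``grid_spacing`` bp across the site
    span (or ``span``); at each, the sweep likelihood is maximized over
    ``alphas`` (log-spaced 1e-8..1 per bp by default) with a
    golden-section refinement around the best grid value.  Sites farther
    than ``max_dist`` from the test position contribute equally to both
    models and are omitted.  Returns one :class:`CLRGridPoint` per test
    position; ``clr`` is clamped at 0 (the null is nested at
    alpha -> infinity) and ``alpha_hat`` is NaN there.
    """
    sites = sorted(sites, key=lambda s: s.pos)
    if len(sites) < 2:
        return []
    chroms = {s.chrom for s in sites}
    if len(chroms) != 1:
        raise ValueError("clr_scan expects sites from a single chromosome")
    chrom = chroms.pop()
    if alphas is None:
        alphas = DEFAULT_ALPHAS

    if any(s.n > background.n for s in sites):
        raise ValueError("site with more called alleles than the "
                         "background SFS sample size")
    keys = {(s.n, s.folded) for s in sites}
    tables = _ScanTables(background, keys, n_pe=n_pe)

    pos = np.array([s.pos for s in sites], dtype=np.int64)
    tid = np.array([tables.table_ids[(s.n, s.folded)] for s in sites],
                   dtype=np.int64)
    cls = np.array([s.derived_count for s in sites], dtype=np.int64)
    bg_ll = np.array([tables.bg_log[(s.n, s.folded)][s.derived_count]
                      for s in sites])

    lo_pos, hi_pos = span if span is not None else (int(pos[0]), int(pos[-1]))
    grid = np.arange(lo_pos, hi_pos + 1, grid_spacing, dtype=np.int64)
    site_lo = np.searchsorted(pos, grid - max_dist).astype(np.int64)
    site_hi = np.searchsorted(pos, grid + max_dist, side="right"
                              ).astype(np.int64)

    clr, alpha_hat = _scan_kernel(
        grid, pos, site_lo, site_hi, tid, cls, bg_ll,
        tables.log_tables, np.asarray(alphas, dtype=float),
        n_pe, 12 if refine else 0)
    return [CLRGridPoint(chrom=chrom, pos=int(p), clr=float(c),
                         alpha_hat=float(a))
            for p, c, a in zip(grid, clr, alpha_hat)]


# ---------------------------------------------------------------------------
# Region building / merging / filtering

def clr_threshold(points: Sequence[CLRGridPoint] | np.ndarray,
                  top_fraction: float = 0.01) -> float:
    """The (1 - top_fraction) empirical quantile of CLR scores."""
    pts = list(points)
    if pts and isinstance(pts[0], CLRGridPoint):
        values = np.array([p.clr for p in pts], dtype=float)
    else:
        values = np.asarray(pts, dtype=float)
    if values.size == 0:
        raise ValueError("empty scan")
    return float(np.quantile(values, 1.0 - top_fraction))


def build_regions(points: Sequence[CLRGridPoint], threshold: float
                  ) -> list[SweepRegion]:
    """Maximal runs of consecutive grid points with clr >= threshold."""
    regions: list[SweepRegion] = []
    run: list[CLRGridPoint] = []

    def flush() -> None:
        if run:
            regions.append(SweepRegion(
                chrom=run[0].chrom, start=run[0].pos, end=run[-1].pos,
                score=float(sum(p.clr for p in run)), n_points=len(run)))
            run.clear()

    last_chrom = None
    for p in points:
        if p.chrom != last_chrom:
            flush()
            last_chrom = p.chrom
        if p.clr >= threshold:
            run.append(p)
        else:
            flush()
    flush()
    return regions


GAP_MODES = ("min", "max", "mean", "sum")


def _gap_limit(a: SweepRegion, b: SweepRegion, gap_rule: float,
               mode: str) -> float:
    sa, sb = a.size, b.size
    agg = {"min": min(sa, sb), "max": max(sa, sb),
           "mean": 0.5 * (sa + sb), "sum": sa + sb}[mode]
    return gap_rule * agg


def merge_regions(regions: Sequence[SweepRegion], gap_rule: float = 0.5,
                  mode: str = "mean") -> list[SweepRegion]:
    """Gap-merge adjacent regions, iterated to a fixpoint.

    Two neighbouring regions merge when the gap between them (bp strictly
    between the intervals) is at most ``gap_rule`` times the aggregate of
    their sizes (``mode``: mean of the two by default).  Merging is
    repeated left-to-right until no further merge applies; merged scores
    are summed and spans unioned.
    """
    if mode not in GAP_MODES:
        raise ValueError(f"mode must be one of {GAP_MODES}")
    current = sorted(regions, key=lambda r: (r.chrom, r.start))
    changed = True
    while changed:
        changed = False
        out: list[SweepRegion] = []
        for r in current:
            if (out and out[-1].chrom == r.chrom):
                prev = out[-1]
                gap = r.start - prev.end - 1
                if gap <= _gap_limit(prev, r, gap_rule, mode):
                    out[-1] = SweepRegion(
                        chrom=prev.chrom, start=prev.start,
                        end=max(prev.end, r.end),
                        score=prev.score + r.score,
                        n_points=prev.n_points + r.n_points)
                    changed = True
                    continue
            out.append(r)
        current = out
    return current


def finalize_regions(regions: Sequence[SweepRegion], min_size: int = 300
                     ) -> list[SweepRegion]:
    """Drop merged regions spanning fewer than ``min_size`` bp."""
    return [r for r in regions if r.size >= min_size]


def genes_in_regions(regions: Sequence[SweepRegion],
                     genes: Sequence[GeneFeature]) -> list[SweepRegion]:
    """Attach candidate genes: any >= 1 bp overlap with a final region."""
    out = []
    for r in regions:
        hits = [g.gene_id for g in genes
                if g.chrom == r.chrom and g.start <= r.end
                and g.end >= r.start]
        out.append(replace(r, genes=hits))
    return out


# ---------------------------------------------------------------------------
# Convenience pipeline

def scan_genotype_matrix(matrix: GenotypeMatrix,
                         pop: Optional[PopulationSpec] = None,
                         outgroup_alleles: Optional[Mapping[int, str]] = None,
                         grid_spacing: int = 100,
                         folded: bool = False,
                         **scan_kwargs) -> list[CLRGridPoint]:
    """Polarize, build the chromosome background, and run the CLR scan.

    With no outgroup table the matrix's reference allele is taken as
    ancestral (true for the simulators here); ``folded=True`` ignores
    ancestral information entirely.
    """
    if outgroup_alleles is None:
        polarized = polarize_matrix(matrix, pop, folded=folded)
    else:
        from .synthetic_data import to_variant_sites
        idx = (None if pop is None
               else list(matrix.sample_indices(pop.samples)))
        polarized = polarize(to_variant_sites(matrix), outgroup_alleles,
                             sample_indices=idx)
    background = background_sfs(polarized)
    return clr_scan(polarized, background, grid_spacing=grid_spacing,
                    **scan_kwargs)


def call_sweep_regions(points: Sequence[CLRGridPoint],
                       top_fraction: float = 0.01,
                       gap_rule: float = 0.5, mode: str = "mean",
                       min_size: int = 300,
                       genes: Optional[Sequence[GeneFeature]] = None
                       ) -> tuple[list[SweepRegion], float]:
    """Threshold, build, merge, size-filter and annotate sweep regions."""
    threshold = clr_threshold(points, top_fraction)
    regions = finalize_regions(
        merge_regions(build_regions(points, threshold), gap_rule, mode),
        min_size)
    if genes is not None:
        regions = genes_in_regions(regions, genes)
    return regions, threshold
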