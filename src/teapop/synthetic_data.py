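"""Synthetic genotype, annotation and sequence-pair generators.

These emulate the statistical structure of multi-population diploid
resequencing data: a neutral 1/k site-frequency-spectrum background,
Hardy-Weinberg genotype assembly, negative-binomial read depths, missing
calls, indels adjacent to SNPs, an implanted hard sweep under the
deterministic-escape (star-like hitchhiking) approximation, and
K2P-evolved long-terminal-repeat pairs of known divergence time.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .io_core import MISSING, GenotypeMatrix, GeneFeature, VariantSite

#: Default mean per-sample read depth; the emulated study design sequenced
#: accessions to roughly 14x.
DEFAULT_DEPTH_MEAN = 14.0


@dataclass
class SimConfig:
    """Parameters of the neutral-population simulator."""

    n_samples: int = 30              # diploid individuals per population
    n_sites: int = 4000
    chrom_length: int = 2_000_000    # bp
    chrom: str = "chr1"
    sweep_center: Optional[int] = None
    sweep_alpha: Optional[float] = None   # per-bp escape rate, > 0
    missing_rate: float = 0.0
    depth_mean: float = DEFAULT_DEPTH_MEAN
    depth_dispersion: float = 10.0   # negative-binomial size parameter
    indel_rate: float = 0.0          # fraction of SNPs adjacent to an indel
    ld_scale: Optional[float] = None  # haplotype-copying decay scale (bp)
    n_founders: int = 8              # founder haplotypes for the LD mode
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sites > self.chrom_length:
            raise ValueError("n_sites exceeds chrom_length")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside simulated data."""

    sweep_center: Optional[int] = None
    swept_sites: Optional[np.ndarray] = None   # positions whose genotypes changed
    true_k2p_time: Optional[float] = None      # years, for sequence pairs
    true_divergence: Optional[float] = None    # expected substitutions/site


def _neutral_counts(rng: np.random.Generator, n_hap: int,
                    n_sites: int) -> np.ndarray:
    """Draw derived-allele counts k in 1..n-1 with P(k) proportional to 1/k."""
    k = np.arange(1, n_hap)
    p = (1.0 / k) / np.sum(1.0 / k)
    return rng.choice(k, size=n_sites, p=p)


def simulate_neutral_population(config: SimConfig) -> GenotypeMatrix:
    """Simulate a neutral diploid genotype matrix.

    Site positions are uniform without replacement on [1, chrom_length];
    the derived-allele count per site follows the neutral 1/k law;
    genotypes pair haploid lineages at random (Hardy-Weinberg).  Allele 0
    is ancestral by construction, so downstream polarization against a
    truthful outgroup is exact.  With ``ld_scale`` set, haplotypes copy
    from a founder pool with an exponential switch process, inducing
    linkage disequilibrium that decays on that physical scale.
    """
    if config.sweep_center is not None:
        raise ValueError("simulate_neutral_population expects no sweep; "
                         "use implant_sweep afterwards")
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_samples
    positions = np.sort(rng.choice(config.chrom_length, size=config.n_sites,
                                   replace=False) + 1)

    if config.ld_scale is None:
        counts = _neutral_counts(rng, n_hap, config.n_sites)
        # For each site, mark `k` randomly chosen lineages as derived.
        u = rng.random((config.n_sites, n_hap))
        ranks = np.argsort(u, axis=1).argsort(axis=1)
        hap = (ranks < counts[:, None]).T.astype(np.int8)  # (n_hap, n_sites)
    else:
        hap = _copying_haplotypes(rng, n_hap, positions, config)

    dosages = (hap[0::2] + hap[1::2]).astype(np.int8)

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = -1

    p_nb = config.depth_dispersion / (config.depth_dispersion
                                      + config.depth_mean)
    depths = rng.negative_binomial(config.depth_dispersion, p_nb,
                                   size=dosages.shape).astype(np.int32)

    return GenotypeMatrix(
        chrom=config.chrom, positions=positions, dosages=dosages,
        samples=[f"S{i:03d}" for i in range(config.n_samples)],
        depths=depths,
        ref=["A"] * config.n_sites, alt=["T"] * config.n_sites)


def _copying_haplotypes(rng: np.random.Generator, n_hap: int,
                        positions: np.ndarray,
                        config: SimConfig) -> np.ndarray:
    """Haplotype-copying mode: LD decaying on scale ``ld_scale``."""
    n_sites = positions.size
    founder_counts = _neutral_counts(rng, config.n_founders + 1, n_sites)
    u = rng.random((n_sites, config.n_founders))
    ranks = np.argsort(u, axis=1).argsort(axis=1)
    founders = (ranks < founder_counts[:, None]).T  # (n_founders, n_sites)

    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-gaps / config.ld_scale)
    hap = np.empty((n_hap, n_sites), dtype=np.int8)
    for h in range(n_hap):
        fid = np.empty(n_sites, dtype=np.intp)
        fid[0] = rng.integers(config.n_founders)
        switches = rng.random(n_sites - 1) < p_switch
        new_ids = rng.integers(config.n_founders, size=n_sites - 1)
        for s in range(1, n_sites):
            fid[s] = new_ids[s - 1] if switches[s - 1] else fid[s - 1]
        hap[h] = founders[fid, np.arange(n_sites)]
    return hap


def implant_sweep(matrix: GenotypeMatrix, center: int, alpha: float,
                  seed: int = 0) -> tuple[GenotypeMatrix, TruthRecord]:
    """Overlay a hard selective sweep on a neutral matrix.

    Deterministic-escape approximation: at a site a distance ``d`` from
    ``center``, each haploid lineage independently escapes the sweep with
    probability ``p_e = 1 - exp(-alpha * d)``; lineages that do not escape
    are coalesced onto one sweeping haplotype and copy its allele, pushing
    frequencies toward 0 or n near the center.  Positions, sample count
    and site count are never altered — only genotype values.
    """
    if alpha <= 0:
        raise ValueError("sweep alpha must be > 0")
    rng = np.random.default_rng(seed)
    n_samples, n_sites = matrix.dosages.shape
    n_hap = 2 * n_samples

    # Expand dosages to pseudo-haplotypes (random phase; statistics here
    # are phase-free and genotypes were assembled by random pairing).
    hap = np.zeros((n_hap, n_sites), dtype=np.int8)
    miss = matrix.dosages < 0
    hap[0::2] = np.where(matrix.dosages >= 1, 1, 0)
    hap[1::2] = np.where(matrix.dosages == 2, 1, 0)
    flip = rng.random((n_samples, n_sites)) < 0.5
    het = matrix.dosages == 1
    swap = het & flip
    a = hap[0::2].copy()
    hap[0::2][swap] = hap[1::2][swap]
    hap[1::2][swap] = a[swap]

    d = np.abs(matrix.positions - center).astype(float)
    p_escape = 1.0 - np.exp(-alpha * d)
    sweep_hap = hap[0]                       # the sweeping haplotype
    escaped = rng.random((n_hap, n_sites)) < p_escape[None, :]
    escaped[0] = True                        # it carries itself
    new_hap = np.where(escaped, hap, sweep_hap[None, :]).astype(np.int8)

    new_dos = (new_hap[0::2] + new_hap[1::2]).astype(np.int8)
    new_dos[miss] = -1
    changed = np.any((new_dos != matrix.dosages) & ~miss, axis=0)
    truth = TruthRecord(sweep_center=center,
                        swept_sites=matrix.positions[changed].copy())
    out = replace(matrix, dosages=new_dos)
    return out, truth


# ---------------------------------------------------------------------------
# VariantSite materialization and filter-stress artifacts

def to_variant_sites(matrix: GenotypeMatrix,
                     qual: float = 1000.0,
                     info: Optional[dict] = None) -> Iterator[VariantSite]:
    """Materialize a genotype matrix as clean biallelic SNP records."""
    base_info = {"QD": 25.0, "FS": 1.0, "MQ": 60.0,
                 "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
    if info:
        base_info.update(info)
    refs = matrix.ref or ["A"] * matrix.n_sites
    alts = matrix.alt or ["T"] * matrix.n_sites
    for j in range(matrix.n_sites):
        gts = []
        for i in range(matrix.n_samples):
            dos = matrix.dosages[i, j]
            gts.append(MISSING if dos < 0 else
                       [(0, 0), (0, 1), (1, 1)][dos])
        depths = (list(map(int, matrix.depths[:, j]))
                  if matrix.depths is not None else [None] * matrix.n_samples)
        yield VariantSite(chrom=matrix.chrom, pos=int(matrix.positions[j]),
                          ref=refs[j], alts=[alts[j]], qual=qual,
                          info=dict(base_info), genotypes=gts, depths=depths)


@dataclass
class ArtifactConfig:
    """Rates of filter-stressing artifacts injected into a clean SNP set."""

    fraction_near_indel: float = 0.05   # SNPs placed within 4 bp of an indel
    n_far_indels: int = 20              # extra indels >= 5 bp from any SNP
    fraction_low_qual: float = 0.05     # QUAL drawn below 40
    fraction_boundary_qual: float = 0.01  # QUAL exactly 40 (must pass)
    fraction_triallelic: float = 0.03
    fraction_hard_fail: float = 0.05    # one hard-filter annotation failing
    fraction_info_absent: float = 0.02  # one annotation dropped (must pass)
    fraction_depth_outlier: float = 0.04  # depths pushed into the tails
    fraction_monomorphic: float = 0.02  # MAF forced to 0
    seed: int = 0


def inject_artifacts(sites: list[VariantSite], config: ArtifactConfig
                     ) -> tuple[list[VariantSite], "pd.DataFrame"]:
    """Stress a clean SNP stream with labelled filtering artifacts.

    Returns the perturbed, position-sorted record list (now containing
    indel records) and a per-SNP truth table with one boolean column per
    criterion the site should fail.  The depth labels replicate the
    cascade's semantics: percentile bounds are computed on the SNPs that
    survive the hard filter, indel-proximity, quality and biallelic steps.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    snps = [replace(s, alts=list(s.alts), info=dict(s.info),
                    genotypes=list(s.genotypes), depths=list(s.depths))
            for s in sites]
    n = len(snps)
    occupied = {s.pos for s in snps}
    chrom = snps[0].chrom

    def pick(fraction_or_count, exclude=frozenset()):
        k = (fraction_or_count if isinstance(fraction_or_count, int)
             else int(round(fraction_or_count * n)))
        avail = [i for i in range(n) if i not in exclude]
        return set(rng.choice(avail, size=min(k, len(avail)),
                              replace=False).tolist())

    # --- indels near a chosen fraction of SNPs --------------------------
    near_idx = pick(config.fraction_near_indel)
    indels: list[VariantSite] = []
    for i in sorted(near_idx):
        for off in rng.permutation([1, 2, 3, 4, -1, -2, -3, -4]):
            p = snps[i].pos + int(off)
            if p >= 1 and p not in occupied:
                occupied.add(p)
                indels.append(_make_indel(chrom, p, snps[i]))
                break

    # --- indels far from every SNP --------------------------------------
    lo, hi = 1, max(s.pos for s in snps) + 1000
    placed = 0
    while placed < config.n_far_indels:
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= 6 for q in occupied):
            occupied.add(p)
            indels.append(_make_indel(chrom, p, snps[0]))
            placed += 1

    # --- QUAL straddling 40 ---------------------------------------------
    low_q = pick(config.fraction_low_qual)
    boundary_q = pick(config.fraction_boundary_qual, exclude=low_q)
    for i in range(n):
        if i in low_q:
            snps[i].qual = float(rng.uniform(5.0, 39.9))
        elif i in boundary_q:
            snps[i].qual = 40.0
        else:
            snps[i].qual = float(rng.uniform(40.5, 2000.0))

    # --- triallelic sites -------------------------------------------------
    tri = pick(config.fraction_triallelic)
    for i in tri:
        site = snps[i]
        extra = {"A", "C", "G", "T"} - {site.ref, *site.alts}
        site.alts.append(sorted(extra)[0])
        called = [j for j, g in enumerate(site.genotypes) if g != MISSING]
        j = called[int(rng.integers(len(called)))]
        site.genotypes[j] = (site.genotypes[j][0], 2)

    # --- hard-filter annotation failures / absences ----------------------
    hard_fail = pick(config.fraction_hard_fail)
    info_absent = pick(config.fraction_info_absent, exclude=hard_fail)
    fail_values = {"QD": 1.0, "FS": 80.0, "MQ": 20.0,
                   "MQRankSum": -20.0, "ReadPosRankSum": -12.0}
    keys = list(fail_values)
    for i in hard_fail:
        k = keys[int(rng.integers(len(keys)))]
        snps[i].info[k] = fail_values[k]
    for i in info_absent:
        k = keys[int(rng.integers(len(keys)))]
        snps[i].info.pop(k, None)

    # --- depth outliers ---------------------------------------------------
    outlier = pick(config.fraction_depth_outlier)
    for idx, i in enumerate(sorted(outlier)):
        factor = 8.0 if idx % 2 == 0 else 0.0
        snps[i].depths = [None if d is None else int(round(d * factor))
                          for d in snps[i].depths]

    # --- monomorphic (MAF = 0) sites -------------------------------------
    mono = pick(config.fraction_monomorphic, exclude=tri)
    for i in mono:
        snps[i].genotypes = [g if g == MISSING else (0, 0)
                             for g in snps[i].genotypes]

    # --- truth labels -----------------------------------------------------
    indel_pos = np.array(sorted(s.pos for s in indels), dtype=np.int64)

    def near_indel(pos: int) -> bool:
        j = np.searchsorted(indel_pos, pos)
        for k in (j - 1, j):
            if 0 <= k < indel_pos.size and abs(int(indel_pos[k]) - pos) < 5:
                return True
        return False

    rows = []
    for i, s in enumerate(snps):
        p_alt = _alt_frequency(s)
        rows.append({
            "pos": s.pos,
            "fails_hard": i in hard_fail,
            "fails_indel_proximity": near_indel(s.pos),
            "fails_quality": s.qual is None or s.qual < 40.0,
            "fails_biallelic": not s.is_biallelic_snp,
            "fails_maf": p_alt is None or min(p_alt, 1 - p_alt) < 0.01,
        })
    labels = pd.DataFrame(rows)

    # Depth bounds from the survivors of the steps preceding the depth step.
    pre_depth = ~(labels.fails_hard | labels.fails_indel_proximity
                  | labels.fails_quality | labels.fails_biallelic)
    cand = np.array([snps[i].total_depth()
                     for i in range(n)])[pre_depth.to_numpy()]
    lo_b, hi_b = np.percentile(cand, [2.5, 97.5])
    depth_fail = np.full(n, False)
    totals = np.array([s.total_depth() for s in snps])
    depth_fail[pre_depth.to_numpy()] = (
        (totals[pre_depth.to_numpy()] < lo_b)
        | (totals[pre_depth.to_numpy()] > hi_b))
    labels["fails_depth"] = depth_fail
    labels["total_depth"] = totals

    out = sorted(snps + indels, key=lambda s: (s.chrom, s.pos))
    return out, labels


def _make_indel(chrom: str, pos: int, template: VariantSite) -> VariantSite:
    return VariantSite(
        chrom=chrom, pos=pos, ref="AT", alts=["A"], qual=500.0,
        info={"QD": 20.0, "FS": 2.0, "MQ": 55.0},
        genotypes=[(0, 0)] * len(template.genotypes),
        depths=[14] * len(template.depths))


def _alt_frequency(site: VariantSite) -> Optional[float]:
    dos = site.alt_dosages()
    called = dos >= 0
    if not called.any():
        return None
    return float(np.where(called, dos, 0).sum()) / (2.0 * called.sum())


def tiled_genes(chrom: str, chrom_length: int, spacing: int = 10_000,
                gene_length: int = 4000) -> list[GeneFeature]:
    """Synthetic gene annotation: one gene every ``spacing`` bp."""
    genes = []
    gid = 0
    for start in range(1, chrom_length - gene_length + 1, spacing):
        genes.append(GeneFeature(chrom=chrom, start=start,
                                 end=start + gene_length - 1,
                                 strand="+" if gid % 2 == 0 else "-",
                                 gene_id=f"gene{gid:05d}"))
        gid += 1
    return genes


# ---------------------------------------------------------------------------
# K2P sequence-pair evolution

_BASES = np.array(list("ACGT"))
#: transition partner of each base (A<->G, C<->T), indexed A,C,G,T
_TS_PARTNER = np.array([2, 3, 0, 1])


def _k2p_substitution_matrix(divergence: float, tstv: float) -> np.ndarray:
    """Per-branch 4x4 base-change probabilities for a K2P process.

    ``divergence`` is the expected substitutions/site on the branch and
    ``tstv`` the expected transition:transversion ratio R = alpha/(2 beta).
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    # alpha*t + 2*beta*t = divergence, alpha/(2 beta) = tstv
    beta_t = divergence / (2.0 * (tstv + 1.0))
    alpha_t = divergence * tstv / (tstv + 1.0)
    e4 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2        # to the transition partner
    p_tv = 0.25 - 0.25 * e4                   # to each transversion partner
    p_same = 1.0 - p_ts - 2.0 * p_tv
    P = np.full((4, 4), p_tv)
    np.fill_diagonal(P, p_same)
    P[np.arange(4), _TS_PARTNER] = p_ts
    return P


def _evolve(seq_idx: np.ndarray, P: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(seq_idx.size)
    return (u[:, None] > cum[seq_idx]).sum(axis=1).astype(np.int8)


def simulate_ltr_pair(time: float, mu: float = 6.5e-9, tstv: float = 2.0,
                      length: int = 5000, seed: int = 0):
    """Evolve the two terminal repeats of one LTR element.

    Both copies descend from a random ancestral sequence and accumulate a
    total expected divergence of ``2 * mu * time`` between them (each
    branch carries half).  Returns the gapless :class:`AlignedPair` and a
    :class:`TruthRecord` with the true time and divergence.
    """
    from .molecular_dating import AlignedPair

    if time < 0:
        raise ValueError("time must be >= 0")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    rng = np.random.default_rng(seed)
    divergence = 2.0 * mu * time
    anc = rng.integers(4, size=length).astype(np.int8)
    P = _k2p_substitution_matrix(divergence / 2.0, tstv)
    a = _evolve(anc, P, rng)
    b = _evolve(anc, P, rng)
    pair = AlignedPair(seq_a="".join(_BASES[a]), seq_b="".join(_BASES[b]),
                       label_a="ltr5", label_b="ltr3")
    return pair, TruthRecord(true_k2p_time=time, true_divergence=divergence)
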