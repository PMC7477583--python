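import itertools

import numpy as np
import pytest

from teapop import popgen_stats as ps, synthetic_data as sd
from teapop.io_core import GenotypeMatrix, MISSING, PopulationSpec, VariantSite


def matrix_from(dosages, positions=None, chrom="chr1", depths=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    positions = (np.asarray(positions) if positions is not None
                 else np.arange(1, n_sites + 1) * 100)
    return GenotypeMatrix(chrom=chrom, positions=positions, dosages=dosages,
                          samples=[f"S{i}" for i in range(n_samples)],
                          depths=depths)


def brute_force_pi(dosages, which):
    """Mean pairwise difference over all haploid allele pairs at one site."""
    alleles = []
    for d in dosages:
        if d >= 0:
            alleles += [1] * d + [0] * (2 - d)
    pairs = list(itertools.combinations(alleles, 2))
    if not pairs:
        return 0.0
    return sum(a != b for a, b in pairs) / len(pairs)


class TestHeterozygosity:
    def test_site_fraction(self):
        s = VariantSite("chr1", 100, "A", ["T"], 50.0, {},
                        [(0, 1), (1, 0), (0, 0), (1, 1)], [10] * 4)
        assert ps.site_pop_heterozygosity(s) == 0.5

    def test_all_hom_and_all_missing(self):
        s = VariantSite("chr1", 100, "A", ["T"], 50.0, {},
                        [(0, 0), (1, 1)], [10, 10])
        assert ps.site_pop_heterozygosity(s) == 0.0
        s2 = VariantSite("chr1", 100, "A", ["T"], 50.0, {},
                        [MISSING, MISSING], [10, 10])
        assert np.isnan(ps.site_pop_heterozygosity(s2))

    def test_vectorized_matches_per_genotype_count(self, small_matrix):
        hets = ps.per_site_heterozygosity(small_matrix)
        for j in range(0, small_matrix.n_sites, 30):
            d = small_matrix.dosages[:, j]
            called = d[d >= 0]
            expected = (np.nan if called.size == 0
                        else (called == 1).sum() / called.size)
            if np.isnan(expected):
                assert np.isnan(hets[j])
            else:
                assert hets[j] == pytest.approx(expected)

    def test_window_boundaries_and_means(self):
        """40-kb/20-kb windows on a 100-kb toy chromosome."""
        rng = np.random.default_rng(1)
        dosages = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        positions = np.sort(rng.choice(100_000, 50, replace=False) + 1)
        m = matrix_from(dosages, positions)
        wins = ps.window_heterozygosity(m, chrom_length=100_000)
        spans = [(w.start, w.end) for w in wins]
        assert set(spans) <= {(1, 40_000), (20_001, 60_000),
                              (40_001, 80_000), (60_001, 100_000),
                              (80_001, 100_000)}
        hets = ps.per_site_heterozygosity(m)
        for w in wins:
            in_w = (positions >= w.start) & (positions <= w.end)
            assert w.value == pytest.approx(np.nanmean(hets[in_w]))

    def test_single_site_window_value(self):
        m = matrix_from([[1], [0], [0], [0]], positions=[10])
        (w,) = ps.window_heterozygosity(m, size=40_000, step=20_000,
                                        chrom_length=30_000)
        assert w.value == 0.25

    def test_low_depth_window_removed(self):
        depths = np.zeros((4, 1), dtype=np.int32)  # mean depth 0 < 1
        m = matrix_from([[1], [0], [0], [1]], positions=[10], depths=depths)
        assert ps.window_heterozygosity(m, chrom_length=1000) == []

    def test_individual_heterozygosity(self):
        d = np.array([[1] * 3 + [0] * 9 + [-1] * 4], dtype=np.int8)
        m = matrix_from(d.reshape(1, -1))
        assert ps.individual_heterozygosity(m, 0) == pytest.approx(3 / 12)
        m_all_missing = matrix_from(np.full((1, 5), -1, dtype=np.int8))
        assert np.isnan(ps.individual_heterozygosity(m_all_missing, 0))

    def test_hwe_expectation(self):
        rng = np.random.default_rng(3)
        p = 0.3
        dosages = rng.binomial(2, p, size=(40, 4000)).astype(np.int8)
        m = matrix_from(dosages, positions=np.arange(1, 4001))
        hets = [ps.individual_heterozygosity(m, i) for i in range(40)]
        assert np.mean(hets) == pytest.approx(2 * p * (1 - p), rel=0.02)


class TestPi:
    def test_single_site_closed_form(self):
        # 4 called alleles, alt count 2 -> 2*2*2/(4*3) = 2/3
        m = matrix_from([[1], [1]], positions=[10])
        assert ps.per_site_pi(m)[0] == pytest.approx(2 / 3)

    def test_monomorphic_window_zero(self):
        m = matrix_from(np.zeros((5, 10), dtype=np.int8))
        wins = ps.nucleotide_diversity_pi(m, chrom_length=5000)
        assert all(w.value == 0 for w in wins)

    def test_matches_brute_force_pairwise_oracle(self, small_matrix):
        pi = ps.per_site_pi(small_matrix)
        for j in range(small_matrix.n_sites):
            expected = brute_force_pi(small_matrix.dosages[:, j], j)
            assert pi[j] == pytest.approx(expected, abs=1e-12)

    def test_windowed_value_is_sum_over_length(self, small_matrix):
        wins = ps.nucleotide_diversity_pi(small_matrix, size=50_000,
                                          step=10_000, chrom_length=100_000)
        pi = ps.per_site_pi(small_matrix)
        w = wins[0]
        in_w = (small_matrix.positions >= w.start) & \
            (small_matrix.positions <= w.end)
        assert w.value == pytest.approx(pi[in_w].sum() / 50_000, abs=1e-15)


class TestSubsampledPi:
    @pytest.fixture(scope="class")
    def pops_matrix(self):
        rng = np.random.default_rng(7)
        # pop A simulated at higher diversity than pop B
        a = rng.binomial(2, 0.4, size=(20, 400))
        b = rng.binomial(2, rng.uniform(0.01, 0.08, size=400),
                         size=(20, 400))
        m = matrix_from(np.vstack([a, b]).astype(np.int8),
                        positions=np.sort(rng.choice(200_000, 400,
                                                     replace=False) + 1))
        pa = PopulationSpec("A", m.samples[:20])
        pb = PopulationSpec("B", m.samples[20:])
        return m, pa, pb

    def test_seed_reproducible(self, pops_matrix):
        m, pa, pb = pops_matrix
        df1 = ps.subsampled_pi(m, [pa, pb], reps=3, seed=5)
        df2 = ps.subsampled_pi(m, [pa, pb], reps=3, seed=5)
        assert df1.equals(df2)

    def test_full_population_subsample_degenerate(self, pops_matrix):
        m, pa, _ = pops_matrix
        df = ps.subsampled_pi(m, [pa], k=20, reps=4, seed=1)
        per_rep = df.groupby("rep").pi.mean()
        assert per_rep.nunique() == 1

    def test_diversity_ordering_recovered(self, pops_matrix):
        m, pa, pb = pops_matrix
        df = ps.subsampled_pi(m, [pa, pb], k=8, reps=20, seed=2)
        means = df.groupby(["population", "rep"]).pi.mean().unstack(0)
        assert (means["A"] > means["B"]).sum() >= 19

    def test_variance_shrinks_with_subsample_size(self, pops_matrix):
        m, pa, _ = pops_matrix
        spreads = []
        for k in (4, 8, 16):
            df = ps.subsampled_pi(m, [pa], k=k, reps=20, seed=3)
            spreads.append(df.groupby("rep").pi.mean().var())
        assert spreads[0] > spreads[2]

    def test_small_population_rejected(self, pops_matrix):
        m, pa, _ = pops_matrix
        with pytest.raises(ValueError):
            ps.subsampled_pi(m, [PopulationSpec("tiny", m.samples[:3])],
                             k=8)


def textbook_tajimas_d(n, S, pi_sum):
    """Independent transcription of the classic D formula."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        dosages = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        m = matrix_from(dosages, positions=np.arange(1, 41) * 10)
        (w,) = ps.tajimas_d(m, size=1000, step=1000, chrom_length=500)
        alt = dosages.sum(axis=0)
        seg = (alt > 0) & (alt < 10)
        pi_sum = sum(2 * a * (10 - a) / (10 * 9) for a in alt[seg])
        expected = textbook_tajimas_d(10, int(seg.sum()), pi_sum)
        assert w.value == pytest.approx(expected, abs=1e-12)

    def test_neutral_simulation_mean_near_zero(self):
        """Window D pooled over replicate genomes is unbiased around 0."""
        d = []
        for seed in range(5):
            cfg = sd.SimConfig(n_samples=15, n_sites=5000,
                               chrom_length=2_000_000, seed=seed)
            m = sd.simulate_neutral_population(cfg)
            wins = ps.tajimas_d(m, size=20_000, step=20_000,
                                chrom_length=2_000_000)
            d += [w.value for w in wins if np.isfinite(w.value)]
        d = np.asarray(d)
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) < 2 * se

    def test_sweep_window_depressed_below_flanks(self):
        alpha = np.log(2) / 10_000
        centre_vals, flank_vals = [], []
        for seed in range(50):
            cfg = sd.SimConfig(n_samples=10, n_sites=400,
                               chrom_length=200_000, seed=seed + 100)
            m = sd.simulate_neutral_population(cfg)
            swept, _ = sd.implant_sweep(m, 100_000, alpha, seed=seed)
            wins = ps.tajimas_d(swept, size=20_000, step=20_000,
                                chrom_length=200_000)
            for w in wins:
                if not np.isfinite(w.value):
                    continue
                if w.start <= 100_000 <= w.end:
                    centre_vals.append(w.value)
                elif w.end < 40_000 or w.start > 160_000:
                    flank_vals.append(w.value)
        se_diff = np.sqrt(np.var(centre_vals, ddof=1) / len(centre_vals)
                          + np.var(flank_vals, ddof=1) / len(flank_vals))
        assert np.mean(centre_vals) < np.mean(flank_vals) - 2 * se_diff

    def test_no_segregating_sites_sentinel(self):
        m = matrix_from(np.zeros((5, 3), dtype=np.int8))
        (w,) = ps.tajimas_d(m, size=1000, step=1000, chrom_length=400)
        assert np.isnan(w.value)


def wc84_per_site(d1, d2):
    """Independent per-site transcription of Weir & Cockerham (1984)."""
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    n1 = (d1 >= 0).sum()
    n2 = (d2 >= 0).sum()
    if n1 < 1 or n2 < 1 or n1 + n2 < 3:
        return np.nan, np.nan
    p1 = d1[d1 >= 0].sum() / (2 * n1)
    p2 = d2[d2 >= 0].sum() / (2 * n2)
    h1 = (d1 == 1).sum() / n1
    h2 = (d2 == 1).sum() / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar)**2 + n2 * (p2 - pbar)**2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, a + b + c


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(17)
        base = rng.binomial(2, rng.uniform(0.1, 0.9, 300),
                            size=(60, 300)).astype(np.int8)
        m = matrix_from(base, positions=np.arange(1, 301) * 10)
        pa = PopulationSpec("A", m.samples[:30])
        pb = PopulationSpec("B", m.samples[30:])
        (w,) = ps.weir_cockerham_fst(m, pa, pb, size=5000, step=5000,
                                     chrom_length=3000)
        assert abs(w.value) < 0.05

    def test_fixed_difference_is_one(self):
        d = np.vstack([np.full((10, 5), 2), np.zeros((10, 5))]
                      ).astype(np.int8)
        m = matrix_from(d, positions=np.arange(1, 6) * 10)
        pa = PopulationSpec("A", m.samples[:10])
        pb = PopulationSpec("B", m.samples[10:])
        (w,) = ps.weir_cockerham_fst(m, pa, pb, size=100, step=100,
                                     chrom_length=50)
        assert w.value == pytest.approx(1.0)

    def test_matches_independent_1984_transcription(self):
        rng = np.random.default_rng(19)
        d = rng.integers(-1, 3, size=(25, 120)).astype(np.int8)
        m = matrix_from(d, positions=np.arange(1, 121) * 7)
        pa = PopulationSpec("A", m.samples[:12])
        pb = PopulationSpec("B", m.samples[12:])
        a_vec, denom_vec = ps.wc_fst_components(m, pa, pb)
        a_sum = d_sum = 0.0
        for j in range(120):
            a, denom = wc84_per_site(d[:12, j], d[12:, j])
            if np.isfinite(denom):
                a_sum += a
                d_sum += denom
                assert a_vec[j] == pytest.approx(a, abs=1e-12)
                assert denom_vec[j] == pytest.approx(denom, abs=1e-12)
        (w,) = ps.weir_cockerham_fst(m, pa, pb, size=1000, step=1000,
                                     chrom_length=900)
        assert w.value == pytest.approx(a_sum / d_sum, abs=1e-12)

    def test_same_population_split_low_fst(self, small_matrix):
        pa = PopulationSpec("A", small_matrix.samples[:5])
        pb = PopulationSpec("B", small_matrix.samples[5:])
        wins = ps.weir_cockerham_fst(small_matrix, pa, pb,
                                     size=100_000, step=100_000,
                                     chrom_length=100_000)
        assert abs(wins[0].value) < 0.05


class TestLdDecay:
    def test_identical_adjacent_sites_r2_one(self):
        rng = np.random.default_rng(23)
        col = rng.integers(0, 3, size=20).astype(np.int8)
        m = matrix_from(np.column_stack([col, col]), positions=[100, 101])
        curve = ps.ld_decay(m, max_dist=1000, bin_bp=1000, maf_min=0.0)
        assert curve.mean_r2[0] == pytest.approx(1.0)

    def test_independent_sites_flat_near_sampling_floor(self):
        rng = np.random.default_rng(29)
        n = 50
        d = rng.binomial(2, 0.4, size=(n, 500)).astype(np.int8)
        m = matrix_from(d, positions=np.sort(
            rng.choice(100_000, 500, replace=False) + 1))
        curve = ps.ld_decay(m, max_dist=50_000, bin_bp=10_000)
        vals = curve.mean_r2[np.isfinite(curve.mean_r2)]
        # E[r^2] ~ 1/n under independence, flat in distance
        assert np.all(vals < 3 / n)
        assert vals.max() - vals.min() < 2 / n

    def test_half_decay_recovers_copying_scale(self):
        scale = 10_000
        estimates = []
        for seed in range(20):
            cfg = sd.SimConfig(n_samples=30, n_sites=800,
                               chrom_length=200_000, ld_scale=scale,
                               seed=seed)
            m = sd.simulate_neutral_population(cfg)
            curve = ps.ld_decay(m, max_dist=60_000, bin_bp=2000)
            if curve.half_decay_distance is not None:
                estimates.append(curve.half_decay_distance)
        assert len(estimates) >= 15
        med = np.median(estimates)
        assert scale / 2 <= med <= scale * 2

    def test_r2_bounds(self, small_matrix):
        curve = ps.ld_decay(small_matrix, max_dist=50_000, bin_bp=5000)
        vals = curve.mean_r2[np.isfinite(curve.mean_r2)]
        assert np.all((vals >= 0) & (vals <= 1))
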