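# Methods

This note documents the models implemented in `teapop`, the choices made
where a published description leaves room, and what the synthetic-data
tests do and do not demonstrate.

## Variant filtering

The cascade applies the hard filter first, then the five strict
criteria in their stated order: indel proximity, quality, biallelic SNP,
depth percentile, MAF. Decisions that required interpretation:

- **Missing annotations.** An absent INFO annotation (QD, FS, MQ,
  MQRankSum, ReadPosRankSum) never fails its hard-filter condition —
  these annotations are undefined for some sites (e.g. rank sums need
  heterozygous carriers), and failing on absence would discard sites for
  lack of evidence rather than evidence of badness. A missing QUAL does
  fail the quality criterion, because QUAL is the quantity the criterion
  tests. All comparison boundaries are inclusive exactly as the
  operators read (QUAL = 40 passes; an indel at distance exactly 5 bp
  leaves its neighbour SNP in).
- **Depth bounds.** "Depth from 2.5 to 97.5%" is read as the empirical
  2.5th–97.5th percentiles (linear interpolation, the numpy default) of
  per-site total depth across the candidate set entering that step,
  computed genome-wide. A per-chromosome variant would be a small change
  behind the same function; the bounds used are returned in the report.
- **Indel anchoring.** Indel proximity is measured from the indel's POS.
  Span-aware distance would differ only for multi-bp deletions
  overlapping the 5-bp window edge.
- **Thinning.** "No two sites within the same 2000-bp region" is
  implemented as a deterministic left-to-right minimum-spacing walk
  (keep the first site, then every site ≥ 2 kb from the last kept).
  A fixed-bin alternative (`select_for_structure_binned`) is provided;
  the two differ only in phase at bin edges.

## Diversity statistics

- Per-site π uses the unbiased pairwise estimator
  2·n_alt(n_tot−n_alt)/(n_tot(n_tot−1)) over called alleles; window π
  divides the summed per-site values by the window length in bp (no
  accessible-length correction — callable fraction is not modelled).
- Windows tile each chromosome from position 1 (40 kb/20 kb for
  heterozygosity, 50 kb/10 kb for π, Fst and Tajima's D); the last
  window is clipped at the chromosome end. Heterozygosity windows with
  mean per-sample depth < 1 are removed.
- Tajima's D needs a single sample size n for its normalization
  constants while missingness makes the called-allele count vary by
  site; the rounded mean count over the window's segregating sites is
  used. The alternative (minimum count) changes D by < 1% at the
  missingness levels simulated here.
- Fst is the Weir & Cockerham (1984) two-population estimator with the
  observed-heterozygosity term, windowed as a ratio of sums (Σa/Σ(a+b+c)),
  which is the standard way to aggregate the per-site components.
- r² is the squared Pearson correlation of unphased genotype dosages
  (0/1/2) over samples called at both sites (Rogers–Huff style): the
  data are unphased and no phasing step is modelled. Pairs are binned
  by distance (1-kb bins by default); the half-decay distance is the
  smallest bin midpoint whose mean r² ≤ 50% of the maximum bin mean.
  Sites are pre-filtered at MAF ≥ 0.05 by default; the floor, binning
  and maximum distance are all arguments. Under independence the curve
  sits at the ~1/n sampling floor, so half-decay is only meaningful
  when LD actually decays from a elevated short-range value.
- The subsampling protocol draws k = 8 samples per population, 20
  times, without replacement, from a single seeded generator, and
  recomputes window π per draw; equal subsample sizes remove the
  dependence of diversity comparisons on panel size.

## Sweep scan

The scan is a composite-likelihood ratio in the classical hitchhiking
framework. Ingredients:

- **Observations.** Each biallelic site contributes its frequency class:
  derived count when polarized against the outgroup allele, minor count
  when folded (outgroup missing or carrying a third state). Sites that
  are neither polymorphic nor substitutions are excluded; substitutions
  (derived fixed in the sample) occupy class n.
- **Background.** The chromosome-wide spectrum is the null model,
  estimated per population. With complete data this is a plain tally.
  Sites with missing genotypes enter through the hypergeometric
  projection likelihood and folded sites through the two-class folded
  likelihood, combined in a short EM fit; with no missingness and no
  folding the EM is exact at its starting tally. Estimation ignores the
  observability conditioning (a second-order effect at these
  missingness levels).
- **Sweep model.** A lineage at distance d from the swept site escapes
  with probability p_e = 1 − exp(−α·d). Conditional on k of n lineages
  escaping (binomial), the k escapees plus one lineage representing the
  swept cluster are k+1 draws from the pre-sweep population (the
  background spectrum hypergeometrically downsampled to k+1); the
  cluster lineage's allele is copied onto the n−k collapsed lineages.
  With k = n the mixture reduces exactly to the background. Class
  probabilities are conditioned on the observable classes (1..n
  unfolded, 1..⌊n/2⌋ folded).
- **Numerics.** p_e is discretized on a uniform 512-point grid (the
  spectrum is smooth in p_e; finer grids change CLR by < 0.1%). α is
  maximized on a 40-point log grid spanning 1e-8..1 per bp, then
  refined by 12 golden-section iterations around the best grid point.
  CLR is clamped at 0 (the null is nested at α → ∞) and α̂ is reported
  as NaN there. Sites farther than 200 kb from the test position are
  omitted — they contribute equally to both models at the α values of
  interest. Probabilities are floored at 1e-300 before logs so that a
  polymorphic site exactly at a putative sweep center scores
  "effectively impossible" rather than producing non-finite arithmetic.
  The inner loop is numba-compiled.
- **Regions.** The threshold is the top 1% of CLR scores (computed over
  the whole scan per population; the per-chromosome background does not
  change this). Contiguous above-threshold grid points form regions;
  adjacent regions merge when the gap (bp strictly between them) is at
  most 50% of the mean of the two regions' sizes, iterated to a
  fixpoint. "Size of the adjacent sweep regions" admits min/max/mean/sum
  readings; the mean is the symmetric, intermediate choice and all four
  are exposed (`mode=`). The merge relation is monotone — merging only
  grows sizes, never gaps — so the fixpoint is independent of merge
  order; the tests verify this against exhaustive enumeration. Regions
  under 300 bp are dropped; scores are summed CLR; genes overlapping a
  final region by ≥ 1 bp are the candidates.
- **Ancestral states.** Outgroup-allele polarization replaces tree-based
  ML reconstruction; the folded likelihood covers sites where the
  outgroup is uninformative, so no phylogenetic machinery is needed.

## Synthetic data

The generators emulate the statistical structure the analysis consumes,
not the sequencing process:

- Neutral sites are independent given their frequencies, with derived
  counts drawn from the equilibrium 1/k law and genotypes assembled by
  random pairing (Hardy–Weinberg). There is no recombination-explicit
  coalescent, no mutation-rate heterogeneity, and (by default) no
  linkage: LD-dependent results use the optional haplotype-copying mode,
  in which haplotypes copy from a founder pool with exponential founder
  switching on a configurable physical scale.
- Read depths are negative-binomial with mean 14 (the panel emulated
  here averaged ~13.7×) and size 10, giving realistic percentile tails
  for the depth filter. Missing genotypes are independent Bernoulli.
- The implanted sweep is the deterministic-escape (star-like)
  approximation — the same signal class the CLR likelihood models. This
  makes parameter recovery a self-consistent test of the scan machinery;
  it does not test robustness to demography, background selection or
  recombination-rate variation, which real data contain.
- The artifact injector perturbs a clean SNP stream with indels placed
  within 4 bp of chosen SNPs, far indels, QUAL values straddling 40
  (including exact-40 boundary cases), triallelic conversions, failing
  or absent hard-filter annotations, depth outliers and forced
  monomorphism, and emits per-site truth labels computed with the same
  cascade semantics (depth bounds from the sites surviving the prior
  steps). Cascade-vs-labels agreement is therefore an end-to-end oracle
  for the filter, not a tautology: labels come from the generator's
  bookkeeping, survivors from parsing and filtering a real VCF.
- LTR pairs evolve from a random ancestor along two branches of a
  Kimura two-parameter process (closed-form transition matrix) with
  total divergence 2μt and transition:transversion ratio 2 by default.
  Alignments are gapless; indel evolution in repeats is not modelled.

Problem sizes used by the test suite and acceptance script (chosen to
exercise the statistics at meaningful sample sizes): sweep-recovery
replicates use a 2-Mb chromosome, 30 diploids and 4,000 segregating
sites with the sweep at midpoint and α = ln2/15000 (escape probability
½ at 15 kb); the filter oracle uses 10,000 SNPs for 30 diploids;
diversity oracles use ≤ 20 samples × 200 sites where O(n²) enumeration
is exact.

## Dating

K2P distances exclude alignment columns with a gap or N in either
sequence (the EMBOSS distmat convention). The "Ks" used for LTR
insertion dating is this K2P distance on the terminal-repeat alignment —
a neutral non-coding distance, deliberately not a codon-model Ks.
Codon-aware Ks values for paralog/ortholog pairs are accepted
precomputed (two-column table); no alignment or synonymous-site
counting is performed here. Time = Ks/(2μ) is exactly linear in Ks;
saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises an error rather than
returning a clamped value. Histograms of Ks or age are emitted for peak
inspection; peak calling (kernel/bin choices) is left to the user.

## Known limitations

- The scan's p_e discretization and 200-kb site window trade < 0.1%
  CLR accuracy for tractable runtime; both are arguments.
- Background-spectrum estimation ignores observability conditioning
  and, under heavy missingness (≫ 20%), would benefit from the full
  conditional EM.
- Windowed statistics use physical window length, not callable length;
  π is therefore downward-biased in poorly callable regions of real
  data.
- The simulators produce a single chromosome per call; multi-chromosome
  inputs are handled by the I/O and filtering layers but the scan is
  run per chromosome by design (chromosome-wide backgrounds).
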