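# Methods

This note records the statistical models, the default parameters and the
reasons for them, the scope of the synthetic-data generators, and the
numerical choices made in `subgenomics`. It makes no empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Setting

The toolkit targets resequencing and expression analyses of an
allohexaploid crucifer genome organized into three subgenomes, labelled
SG1, SG2 and SG3, with a fixed chromosome→subgenome map (20 chromosomes:
6 + 7 + 7). All statistics are computed genome-wide and per subgenome.

## SNP filter cascade

Sites pass through four stages in a fixed pipeline order, and the
survivor count is logged after every stage:

1. **Depth outliers** — drop sites whose mean depth across samples
   exceeds `depth_factor` (default 10) times the overall mean site depth.
   Excess depth flags collapsed repeats and paralog pile-ups. The stage
   is skipped, and logged as a pass-through, when the input carries no
   per-genotype depths.
2. **Site filters** — keep biallelic SNPs with observed heterozygosity
   strictly below `max_site_het` (default 0.5) and missingness strictly
   below `max_missing` (default 0.10). High within-site heterozygosity in
   a selfing species is a homeolog-collapse signature, not biology.
3. **LD pruning** — greedy windowed pruning on genotypic r²
   (`r2_max` 0.4, `window_sites` 50, `step_sites` 5). Within each window
   the later site of any offending pair is dropped and the window is
   re-scanned to a fixed point, so the result is order-deterministic.
   r² is the squared Pearson correlation of dosage vectors over samples
   non-missing at both sites; monomorphic or length-<2 overlaps are
   treated as undefined and never trigger a drop.
4. **MAF filter** — threshold 0.1 with an explicit `mode`:
   `drop_above` removes sites whose minor-allele frequency exceeds the
   threshold, `drop_below` removes rare variants (the conventional
   direction). Both directions appear in practice, so the CLI refuses to
   guess and requires `--maf-mode`; the manifest default is `drop_above`.

Genotypes are coded 0/1/2 dosages with −1 for missing; half-calls are
treated as missing.

## Diversity and differentiation

- **Site π** is the mean pairwise haplotype difference,
  π = n_ref·n_alt / (N(N−1)/2) over the N non-missing haplotypes. The
  numerator and denominator are kept as exact integers before a single
  float division, so the value equals a brute-force enumeration of all
  haplotype pairs bit-for-bit. Sites with fewer than two haplotypes are
  undefined and excluded.
- **Windowed π** tiles each chromosome with fixed windows from
  position 1 and reports the per-bp sum of site π over each window.
  Subgenome and genome aggregates are bp-weighted by default
  (site-weighted available), matching per-bp window summaries.
- **Individual heterozygosity** is the fraction of heterozygous calls
  among an individual's non-missing calls, genome-wide and per subgenome.
- **F_ST** is the Weir & Cockerham (1984) estimator for diploids with the
  two-population variance components a (among populations), b (among
  individuals within populations) and c (within individuals); the
  weighted multi-site estimate is Σa / Σ(a+b+c) over sites with a
  non-zero denominator (ratio-of-sums form). Pairwise tables over >2
  populations reuse the two-population estimator per pair.
- **PCA** runs on mean-imputed dosages (per-site mean fills missing)
  with a fixed random state for reproducibility.

## Homoeolog bias and expression dominance

Only strict 1:1:1 syntelog triplets are analysed; rows with missing
members or with any gene id reused across rows are removed up front.

- **TPM**: rate = count/length, TPM = 10⁶ · rate / Σrate, so each
  library sums to exactly one million and per-gene values are invariant
  to library-size rescaling.
- **Pairwise bias**: r = log2(TPM_a + c) − log2(TPM_b + c) with
  pseudocount c = 0.5. |r| > 2 (strictly) calls a biased pair; pairs in
  which both members fall below `min_tpm` = 1 TPM are `not-testable`.
  Computing r as a difference of logs (rather than the log of a ratio)
  makes the antisymmetry r(a,b) = −r(b,a) bit-exact. The 4-fold
  threshold and the testability floor are the customary homoeolog-bias
  conventions for triplicated genomes.
- **Dominance**: per organ, pairwise two-sample rank-sum tests
  (Mann–Whitney; exact p for small samples, continuity-corrected normal
  approximation otherwise; a signed-rank variant is available for
  triplet-paired designs) compare subgenome TPM distributions. Medians
  are reported on log(TPM+1) (natural log; monotone, so it does not
  affect the rank tests). A subgenome is called dominant in an organ iff
  its median is strictly the highest and both of its pairwise tests are
  significant after Holm adjustment of the three p-values at α = 0.05.
  Holm control keeps the family-wise false-flag rate at α while the raw
  per-pair p-values remain calibrated (verified in the null-calibration
  checks).
- **Composition χ²**: `equal_proportion_chisq` tests observed
  per-subgenome counts against equal expected proportions
  (Pearson χ², df = k−1).

## Assembly summaries

- **Telomeres**: the plant telomeric repeat TTTAGGG (or its reverse
  complement CCCTAAA) is searched, case-insensitively, within the first
  and last 10 kb of each chromosome. An end is telomere-positive iff the
  longest tandem run strictly exceeds `min_repeats` = 10 copies; ends are
  summarized as both / start-only / end-only / neither. The strict
  boundary (exactly 10 copies → negative) is pinned by tests.
- **Gaps**: maximal runs of N (case-insensitive) counted per chromosome
  and aggregated per subgenome; fractions are per-bp.
- **Feature composition**: BED (0-based half-open) or GFF3 (1-based
  inclusive) intervals are normalized to 1-based inclusive coordinates,
  tallied per subgenome, and tested with the equal-proportion χ²;
  per-subgenome occupancy is feature-bp divided by subgenome-bp.

## Synthetic-data generators

The generators produce fixtures with known truth for testing and
calibration; they are not fitted to any real data set.

- **Genotypes** (`simulate_structured_genotypes`): ancestral allele
  frequencies uniform on (0.05, 0.95); population frequencies from the
  Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F), with per-population
  F (defaults 0.05–0.20 across four populations of 56/56/55/55, i.e. a
  222-accession panel); Hardy–Weinberg diploid draws; optional uniform
  missingness (default 2%) and constant depths. Subgenome diversity
  ratios (default SG1 1.00 : SG2 1.22 : SG3 0.79) are imposed by thinning
  polymorphic sites per subgenome with probability scale/max(scale). The
  truth record stores ancestral and population frequencies and the
  expected per-bp π computed from the pooled-frequency pairwise
  difference probability 2·q̄(1−q̄).
- **Expression** (`simulate_expression`): per-triplet baseline
  log-means ~ Normal(3.5, 1.0) shared across the three homoeologs;
  counts are negative-binomial via the Gamma–Poisson mixture
  (Gamma shape 1/φ, scale μφ, then Poisson; dispersion φ = 0.1 — a typical RNA-seq
  overdispersion); gene lengths uniform on 500–5000 bp; libraries scaled
  to 5·10⁶ expected counts. A bias plan plants a chosen fraction of
  triplets (default 10% in the three reproductive organs) with a fixed
  log2 fold change (default 3) on one subgenome (default SG3); planted
  anchors are recorded as truth.
- **Genome** (`simulate_genome_fasta`): random A/C/G/T sequence with
  exact tandem telomere plants at chromosome ends (forward motif at the
  start, reverse complement at the end; the flanking base is forced
  off-motif so planted run lengths are exact) and N-runs at planned
  positions; overlapping plants are rejected. The default plan has 20
  chromosomes of 30 kb with a 7 both / 5 start-only / 5 end-only /
  3 neither telomere layout and a 100-bp gap on every fourth chromosome.

All generators take a single integer seed (NumPy `default_rng`), write
plain-text outputs plus a JSON truth record, and are byte-deterministic.

## Numerical choices

- Exact integer arithmetic before the final division in site π; difference
  of logs for bias antisymmetry; ratio-of-sums for weighted F_ST (more
  stable than averaging per-site ratios, which are noisy at low-variance
  sites).
- Undefined quantities (π with <2 haplotypes, r² of monomorphic sites,
  F_ST components with zero denominator, aggregates over empty sets) are
  excluded or reported as NaN rather than coerced to 0.
- Fixed seeds/random states everywhere randomness appears (PCA,
  generators); workflows serialize their manifest so runs replay
  byte-identically.

## Limitations

- The F_ST estimator is the two-population diploid form; no small-sample
  bias correction beyond Weir–Cockerham's own, and no confidence
  intervals (no block jackknife).
- The Balding–Nichols generator draws sites independently, so LD-pruning
  behaviour on realistic haplotype structure is only exercised by the
  constructed fixtures, not the simulator.
- The expression generator shares one baseline per triplet and plants a
  single shift per organ; it does not model sample replicates, batch
  effects, or length biases, so dominance tests here compare homoeolog
  populations within single libraries.
- Dominance calls treat triplets as independent; shared regulation among
  syntelogs violates this and would make p-values anticonservative.
- The telomere scan counts exact tandem motif copies only; degenerate
  repeat variants are not matched.
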