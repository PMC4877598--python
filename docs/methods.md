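# Methods

This note records the statistical models, algorithmic choices and defaults
behind each module, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make printed figures reproduce
bit-exactly.

## Bayesian pileup scoring

At a candidate site with `alt` supporting reads out of `depth`, the variant
fraction X is given a conjugate beta model: prior Beta(a₀, b₀), posterior
Beta(a₀ + alt, b₀ + depth − alt). The score is the posterior survival
probability Pr(X ≥ θ), computed with the regularized incomplete beta
function; θ = 0.05 separates real variants (germline fractions near 0.5 or
1) from sequencing error (per-base rates ≤ 1%). A site is called when the
score strictly exceeds 0.9.

Choices worth stating:

- *Prior.* "Non-informative" is read as the uniform Beta(1, 1); Jeffreys
  Beta(½, ½) is available via `CallerConfig.from_prior_name("jeffreys")` for
  sensitivity analysis. The two differ materially only at depths below ~10.
- *Depth floor.* With a uniform prior an empty column already scores
  0.95^… > 0.9 (the prior itself puts 95% of its mass above 0.05), so calling
  requires `depth ≥ min_depth`, default 8 reads. Without a floor every
  no-coverage position would be "called".
- *Per-allele scoring.* Each column's strongest non-reference allele is
  scored alone rather than pooling all non-reference reads; pooling would let
  three different error bases masquerade as one variant. Ties on count break
  lexicographically for determinism. Indel alleles (keys like `+AG`, `-T` in
  the counts map) are scored by the same rule as SNVs.
- *Operating characteristics.* At 30× and 1% error the strongest error allele
  needs 3 reads to clear 0.9 (score 0.93 at 3/30 vs 0.80 at 2/30), giving a
  per-position false-call rate of about 5×10⁻⁴ — measured, not assumed, in
  the test suite — while heterozygous sites at balanced depth score ≈ 1.

Triage applies knowledge in strict precedence: curated database status
(non-pathologic / pathologic) decides outright; otherwise nonsynonymous
variants are compared against a per-gene population-frequency cutoff with a
strict `>` (0.01 for the dominant-acting genes *APC*, *BMPR1A*, *STK11*;
0.05 for the recessive *MUTYH*, *NTHL1*, where carriers are common);
remaining nonsynonymous variants are VUS, and a missing frequency yields VUS
with a `no-AF` flag rather than a silent pass. Synonymous uncharacterized
variants are treated as non-pathologic; the package does not model splice
effects of synonymous changes.

## Circular binary segmentation

`cbs_segment` re-implements CBS rather than wrapping an existing package:
the current interval is treated as a circle, every arc (i, j] with both arc
and complement spanning at least `min_width` = 2 bins is evaluated with the
pooled-variance two-sample t statistic, and the best arc is accepted when a
permutation test on the maximal statistic gives p < α (default α = 0.01,
1000 permutations). Accepted splits cut at both arc boundaries and the
pieces recurse; the emitted segments always partition the input.

Implementation details:

- *Search statistic.* At fixed total sum of squares, t² is strictly
  increasing in the between-group sum of squares
  B = m(n−m)/n · (mean_arc − mean_rest)², and permutation preserves the total
  SS, so both the arc search and the permutation comparison use B. This
  reduces each permutation to prefix sums and lets the whole reference
  distribution be evaluated with vectorized arithmetic. The test suite holds
  an independent oracle that enumerates arcs exhaustively and computes t
  directly.
- *Permutation protocol.* Every segment test draws from
  `default_rng([seed, k])`, k being a depth-first test counter, and builds
  permutations by argsort of uniform draws. Once the exceedance count
  already implies p ≥ α the remaining permutations are skipped; this cannot
  change any split decision, and because each test owns its child stream it
  does not perturb later tests either. Results are exactly reproducible for
  a given seed.
- *Ratio track.* `compute_ratios` forms log₂((d + c)/(e + c)) with
  pseudocount c = 0.5 against either a scalar diploid expectation or a
  bin-matched control profile; the pseudocount keeps zero-coverage bins
  finite. Using a matched control doubles the Poisson noise, which in
  practice moves breakpoint resolution from ±1 to about ±2 bins.
- *Defaults.* 250 bp bins resolve a ~10 kb event with ~40 bins while keeping
  per-bin counts high enough (~30 reads) for a roughly Gaussian log-ratio.
  No pruning/"undo" pass is applied after splitting; at the event sizes and
  noise levels targeted here recursive splitting alone is sufficient, and
  the omission is deliberate scope control, not an oversight.

`detect_deletion` turns segments with mean log₂ ratio ≤ −0.6 (midpoint
guard between the diploid 0 and the one-copy −1) spanning ≥ 3 bins into
deletion calls, merging adjacent qualifying segments; breakpoint resolution
is one bin, and lengths are 1-based inclusive (end − start + 1), the
convention under which the case study's sequenced breakpoints
112,035,925–112,045,512 span 9,588 bp.

## Allele-specific expression

With mutant-allele reads k out of n total at a transcribed heterozygous SNP,
the package reports k/n (as a percent, rounded half-away-from-zero to one
decimal), the percent reduction relative to the wild allele
100·(1 − mutant/wild) (nearest integer), an exact Clopper–Pearson
1 − α interval on the fraction (via `scipy.stats.binomtest`), and a
two-sided exact binomial p-value against 0.5. Which SNP allele rides the
mutant haplotype is a declared input — in the motivating case the phase
follows from the deletion being in cis with one allele — never an inference.
Haplotype aggregation across multiple SNPs is out of scope.

## CAGE promoter activity

Tag counts are normalized to TPM by the library's **total mapped tags**, not
by the tags in the analyzed window, so activities are comparable across
samples. Clustering is single-linkage and strand-aware with a 20 bp maximum
gap — the one free choice in this stage, as tag-cluster pipelines differ;
20 bp is standard practice and config-exposed. Clusters strictly below
0.1 TPM per base of width are discarded. Promoter activity sums the TPM of
same-strand clusters overlapping a named window; when windows overlap one
another, a cluster is credited only to the window containing its peak
position so no tag is double counted. Activities below 0.1 TPM are reported
as a `<0.1` floor — a flag, never a zero — and any ratio against a floored
denominator is refused (`BelowFloorError`) instead of returning a
meaningless magnitude.

Two numerical conventions matter:

- Fold ratios round half-away-from-zero to one decimal and sample percent
  ratios to the nearest integer; under these conventions the measured blood
  activities (patient 11.70, controls 30.28 / 26.18 TPM at promoter 1B;
  0.68 TPM at 1A) reproduce 44.5-fold and 39% / 45% exactly.
- The `< 0.1` comparisons carry a 10⁻⁹ relative guard so a quantity that
  equals the floor in exact arithmetic (one 0.1-TPM tag per base of width)
  is not dropped by binary-float rounding.

## Breakpoint flank homology

`flank_identity` aligns the two windows flanking a deletion globally
(Needleman–Wunsch via Biopython's `PairwiseAligner`; match +1, mismatch −1,
linear gap −2 by default) and reports 100 · matches / alignment columns,
rounded to one decimal. Gap columns stay in the denominator — conservative,
and stated explicitly because identity conventions differ — while columns
containing N are excluded from numerator and denominator both. Deterministic
global alignment was chosen over heuristic local search so results are
exactly reproducible. Two context numbers from simulation: a pair built with
155 matching and 45 scattered mismatching columns over 200 bp aligns gapless
at 77.5% (the Alu-flank regime; on some random backgrounds the optimizer
finds a gapped alignment a fraction of a point higher), while unrelated
200-mers land near 44–53% under this scoring — well above the 25% ungapped
per-column expectation, because gaps are allowed to chase coincidental
matches — so observed flank identities must be judged against the gapped
null, not against 25%.

## The synthetic study

`SimConfig` defaults encode the study conditions end to end: a 50 kb region
at 250 bp bins with diploid mean 30 reads/bin and a heterozygous deletion at
20,001–30,000 (bins 81–120); per-base error 0.5% (1% in the stress tests);
four heterozygous SNPs at balanced allelic depth; 28,437 deep-cDNA reads
with mutant fraction 0.112; and CAGE promoter rates of 300 (APC-1B), 7
(APC-1A) and 25,000 (ACTB) expected tags in a 10⁷-tag library — i.e. ~30,
~0.7 and ~2,500 TPM, the scale of the measured blood libraries — with the
patient condition halving the 1B rate.

What the generator emulates: Poisson bin depths with a copy-number step;
pileup columns whose reads err uniformly to the three other bases;
hemizygous het sites inside the deletion retaining only the allele not in
cis with it; binomial allele sampling of cDNA reads; Poisson promoter tag
totals with sharp TSS peaks (rounded normal, sd 1 bp — real CAGE promoter
peaks concentrate most tags on a few dominant start positions, and a broad
peak would spuriously fail the density filter) plus sparse uniform
background tags over the surrounding ±20 kb.

What it does not emulate — and hence what passing tests do not demonstrate
about real data: alignment and mapping artifacts, GC and amplification bias,
overdispersed (non-Poisson) coverage, base-quality structure, PCR bias in
the deep cDNA assay, multi-promoter tag position structure beyond a single
peak, and real genomic repeat context. Homozygous deletions are not
simulated (the target event is heterozygous by construction).

All simulators draw from `numpy.random.default_rng` seeded as
`[seed, crc32(stream-name)]`, so each product (depth, pileup, each CAGE
sample) has an independent, reproducible stream: changing CAGE parameters
cannot perturb the depth draw, and identical seeds give byte-identical
output files.

## Problem sizes used in the checks

The bundled verification runs use the study-scale defaults: 200-bin tracks
(500 seeded replicates for the boundary-localization rate), 10⁵-position
pileups for the false-call rate, 10⁴ simulated runs for interval coverage,
and the full 28,437-read depth for ASE recovery. These sizes were chosen to
make the Monte-Carlo tolerances (3 standard errors) meaningful for each
quantity.

## Known limitations

- The caller scores one alternate allele per site; true multi-allelic sites
  emit only the strongest allele.
- CBS here has no undo/pruning step and no per-bin weights; very short or
  shallow events (e.g. two low bins in thirty) are intentionally not
  significant under the permutation test at α = 0.01.
- The AF-based triage is only as good as the supplied population tables; the
  package never queries databases.
- Promoter-level decomposition of residual mutant transcription (how much of
  the minor allele's 11.2% flows through each alternative promoter) is not
  computable from single-SNP allele counts and is not attempted.
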