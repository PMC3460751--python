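# Methods

## The protocol being modelled

DGE tag profiling sequences one short tag per cDNA molecule, anchored at
the 3′-most DpnII restriction site (`GATC`). Reads are 18 bases: 16
biological bases immediately 3′ of the cut plus two protocol-appended junk
bases. Processing clips the junk bases and prepends `GATC`, giving 20-base
tags. Because digestion is incomplete and transcripts may have several
polyadenylation sites, a gene usually produces tags from more than one
GATC position; all of a gene's unambiguous tags are summed into one locus
count per lane, regardless of position.

The species pair under study is allopolyploid: a locus may be represented
by two homeologous copies (one per parental subgenome, here labelled A and
B) and occasionally a third, more diverged paralogous copy (C). Tags that
match both copies of a locus ("locus-specific") measure the locus; tags
matching exactly one copy ("copy-specific") additionally measure that
copy; tags matching two different loci are ambiguous and discarded
entirely.

## Mapping semantics

Tags are matched against full reference sequences under pure Hamming
(ungapped, position-wise) distance with a 0–2 mismatch budget, on both
strands, with `N` never matching. Hits on the reverse strand are reported
at the forward-strand start coordinate of the matched window, so forward
and reverse hits at one physical site share a position key. The index uses
pigeonhole seeding (three segments of the 20-mer; any ≤2-mismatch match is
exact in at least one segment) with full verification, and is tested for
exact equality against a naive quadratic scan. Mismatches are allowed
anywhere in the 20-mer including the GATC prefix, since mapping is over
whole reference sequences rather than only digestion-anchored positions;
GATC-anchored sites dominate exact matches by construction.

The mismatch budget is configurable per species. The motivating use-case
is a conspecific reference for one species: the other species' tags carry
fixed interspecific SNPs (~2% per site), so an asymmetric policy (0
mismatches for the conspecific species, 1 for the other) compensates for
reference bias. The pipeline exposes both knobs and
`pipeline.compare_datasets` measures how the DEG list moves when they
change.

## Differential expression model

Counts for gene *g* in lane *j* are modelled as negative binomial with
mean N<sub>j</sub>·p<sub>gj</sub> (N<sub>j</sub> = lane library size, the
column sum of locus counts) and a single **common dispersion** φ shared by
all genes: Var = μ + φμ². Two-group comparison (3 lanes per species by
default) proceeds as:

1. **Library-size equalization.** Counts are quantile-mapped onto the
   geometric-mean library size using a moment-matched gamma transform:
   each count is placed on the CDF of a gamma with its own lane's NB
   mean/variance and read off at the same quantile of the gamma matching
   the common size. The transform is the identity when sizes already
   agree and maps zeros to zeros.
2. **Conditional ML dispersion.** Within a group with equalized sizes the
   likelihood of the lane counts conditional on their sum depends only on
   φ. The summed per-gene conditional log-likelihoods are maximized over
   δ = φ/(1+φ) ∈ [0, 0.95] by bounded scalar search, alternating with
   step 1 until φ changes by less than 1e-4 (at most 20 iterations).
   Genes with zero counts everywhere are excluded; at least one group
   must have replicate lanes or the estimate is refused.
3. **Exact conditional test.** For each gene the group pseudo-count sums
   (rounded to integers) s_A, s_B are conditioned on t = s_A + s_B. Under
   the null, each group sum is NB with mean n_i·t/(n_A+n_B) and size
   n_i/φ; the two-sided p-value sums the conditional probabilities of all
   splits no more probable than the observed one (ties included; p = 1
   when t = 0). At φ = 0 this reduces exactly to the conditional binomial
   test, and it is verified against full enumeration for small totals.
4. **Effect size and calls.** propE and propF are pseudo-count lane
   averages over the equalized library size with a prior of 0.5 added to
   both numerators, so a gene absent in one species gets a large but
   finite |M| (M = log₂ propE − log₂ propF). Calls: up_E iff M > 0.58 and
   BH-adjusted p < 0.05; up_F symmetrically. The 0.58 cutoff is
   log₂(1.5) rounded to two decimals; BH is the standard step-up
   procedure with enforced monotonicity.

The 0.5 prior is a design choice: the sentinel |M| magnitudes it produces
for zero-count groups depend on library size and are reported as-is, not
calibrated to any external value.

## Homeolog copy analysis

Copy-specific and copy-unspecific counts are split per locus. A locus is
analysable when, summed over lanes and copies, copy-specific tags are
**greater than five** and **at least fivefold** ("≥", inclusive) the
copy-unspecific tags. The aggregation level (locus vs per-copy) is
configurable because either reading of the rule is defensible; locus-level
summation is the default. Per-copy DE uses copy-specific counts only —
shared tags cannot discriminate copies — and runs through the same exact
test. Loci are then classified by their copy calls: all copies up in one
species, exactly one copy up with the rest flat, reciprocal (at least one
copy up in each species), or no signal.

Copy relationships are classified from global pairwise identity (unit
match/mismatch scoring, free end gaps, identity = matches over aligned
columns excluding end gaps): the most similar pair below 95% identity is
the homeolog pair, a further copy below 90% to both is a putative paralog,
and copies at ≥95% are flagged as possible alleles or assembly artifacts
rather than homeologs.

## Concordance between DEG lists

Two analyses of the same contrast rarely survey the same genes, so before
intersecting lists each DEG count is survey-corrected: genes invisible to
the other analysis are removed. The overlap percentage divides by the
smaller corrected count (integer percent for agreements, one decimal for
disagreements, which intersect opposite-direction lists). Significance is
assessed by resampling: n- and m-subsets are drawn independently without
replacement from the Y genes surveyed by both analyses, 10,000 times, and
the one-sided p-value is (#{null ≥ z} + 1)/(reps + 1). Since this null is
exactly Hypergeometric(Y, n, m), the analytic tail probability is emitted
alongside the resampled one; the resampler remains the primary path and
its null is tested against the exact pmf (total-variation distance) in the
suite.

## Enrichment

Per term, a one-sided Fisher exact test on the 2×2 table (membership in
the up-regulated set × carrying the term) over the background of
surveyable genes (those with at least one DpnII site and a mapped tag).
Term-cluster memberships are taken as input; the cluster score is
−log₁₀ of the geometric mean of member p-values, significant at ≥ 1.3
(equivalent to a geometric-mean p of 0.05). No kappa-statistic clustering
is implemented, and no GO-graph propagation is performed.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with defaults
chosen as the study conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 300 | gene loci in the conspecific reference |
| `homeolog_fraction` | 700/6428 | loci carrying a second (homeologous) copy |
| `triplet_fraction` | 5/700 | homeolog loci carrying a third, paralogous copy |
| `homeolog_divergence` | 0.10 | per-site divergence between copies (~90% identity) |
| `paralog_divergence` | 0.15 | divergence of the third copy (~85% identity) |
| `heterospecific_divergence` | 0.10 | divergence of the ortholog reference |
| `interspecies_snp_rate` | 0.02 | fixed SNPs of species E vs the conspecific reference (~98% identity) |
| `mean_length` | 500 | transcript length (uniform ±30%) |
| `dispersion` | 0.1 | NB overdispersion φ of lane counts |
| `de_fraction`, `log2_fc` | 0.10, 2.0 | truly DE loci and their effect size |
| `lanes_per_species` | 3 | flow-cell lanes per species |
| `library_size` | 50,000 | tags per lane (desk scale; real lanes run millions) |
| `digestion_completeness` | 0.5 | probability an upstream GATC site is cut |
| `error_rate` | 0.002 | per-base substitution error |
| `bad_read_fraction` | 0.08 | reads given a sub-Q20 position for the filter to catch |

Design notes:

* **Exact copy counts.** The homeolog/triplet fractions select exact
  numbers of loci (rounded), so sequence bookkeeping is deterministic:
  6,428 loci with 700 second copies yield exactly 7,128 sequences.
* **Expression truth.** Species-F locus proportions are Dirichlet; DE
  loci get their species-E proportion multiplied by 2^(±log2_fc) with
  directions assigned greedily so up- and down-moved mass nearly cancel,
  and the non-DE block is rescaled so proportions sum to one. Every DE
  locus therefore has |log₂ fold change| exactly log2_fc while non-DE
  loci absorb only a negligible common composition shift.
* **Copy shares** within a multi-copy locus are independent Dirichlet
  draws per species, so reciprocal homeolog patterns arise naturally.
* **Lane counts** are Gamma-Poisson per copy (NB with the configured φ).
  A lane always yields ~`library_size` tags: copies whose transcript has
  no usable GATC site — including species-E transcripts whose only site
  was destroyed by a SNP — drop out of the pool and the rest fill the
  lane, as with a real sequencer running to fixed depth.
* **Tag positions.** Each copy's count is spread by multinomial over its
  eligible GATC sites (the 3′-most always eligible, upstream sites with
  probability `digestion_completeness`) with geometrically decaying
  weight (ratio 0.6) toward 5′. The true positional distribution of tags
  under incomplete digestion is unknown; this decay is a stand-in, not an
  inference, and nothing downstream depends on its exact shape.
* **Reads** are the 16 bases 3′ of a site plus two random junk bases,
  with substitution errors; qualities are Phred+33 with Q30–40
  everywhere except one sub-Q20 position planted in a `bad_read_fraction`
  of reads.
* **Platform lists** for the concordance analysis are noisy DEG lists
  over partially overlapping surveyed universes, parameterized by
  sensitivity and a false-positive rate.
* `simulate_count_matrix` exposes the statistical layer alone (NB counts
  straight from the truth table, no sequencing), which the calibration
  and power tests use so that mapping effects cannot confound them.

What the generator does **not** emulate: realistic Illumina error
profiles (errors are uniform substitutions), adapter or poly-A chemistry,
gene families beyond the per-locus copies (so cross-locus ambiguous tags
are essentially absent, unlike the ~2% seen with real transcriptomes),
variable transcript GC or length biases, and correlated biological
replicates. Passing tests therefore demonstrate the correctness of the
algorithms and the statistical calibration of the tests under the stated
model, not performance on real libraries.

## Numerical choices and degenerate inputs

* Dispersion search bounds δ ∈ [1e-9, 0.95]; estimates below 1e-6 are
  reported as exactly 0 (Poisson).
* The exact test computes the full conditional probability vector per
  gene (O(t) work) in log space; ties with the observed probability count
  as extreme, with a 1e-10 relative tolerance.
* p-values of exactly 0 cannot occur in the resampler (add-one rule).
* Genes with all-zero counts are excluded from testing and returned as
  `not_tested`; a t = 0 gene in the exact test gets p = 1.
* Sequences shorter than a site plus 16 bases are rejected at config
  validation; GATC sites with fewer than 16 downstream bases are counted
  in the site distribution but yield no candidate tag.
* Simulation problem sizes in the test suite (40–1,000 loci, lanes of
  4,000–100,000 tags) are the package's chosen desk scale; all results in
  the README and the acceptance script come from these sizes.

## Known limitations

* Common dispersion only — no tagwise/trended dispersion, no GLM layer,
  no TMM normalization; library sizes are locus-count column sums, which
  is the model this analysis specifies.
* The Hamming mapper targets short fixed-length tags; it does not do
  gapped alignment and is not meant for genome-scale references.
* The enzyme site is pluggable in the reference/digestion layer but only
  GATC (DpnII) is exercised by the tests.
* Copy assignment trusts the reference labels; the package does not phase
  homeolog copies de novo from reads.
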