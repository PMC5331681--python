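# Methods

## Coordinate conventions

All coordinates are 0-based half-open (BED convention).  GTF input is
converted at parse time.  The TSS of a plus-strand gene is `span.start`; of
a minus-strand gene, `span.end - 1` (the biological 5′ base).  Chromosome
names are taken verbatim; no "chr" normalization is applied.  Downstream
modules operate only on validated in-memory types — no stage re-parses
text.

## Replicate-reproducible peaks

Peak calling is noisy, so only regions supported by both replicates enter
the analysis.  Peaks from the two replicates are pooled and grouped into
maximal components under transitive ≥ `min_overlap` bp overlap (default
1 bp; half-open abutment is zero overlap).  A component containing peaks
from both replicates is reported once, as the merged union span.  The union
(rather than the intersection span) preserves the full evidence extent for
downstream width and assignment analyses; an intersection-span mode is
available via `span='intersection'`.  The one-sweep grouping is exact
because, with records sorted by start, the running maximum end determines
the best achievable overlap with any earlier member.

Temporal dynamics pool the reproducible sets of all timepoints, merge them
into regions the same way, and report each region's membership class (the
seven non-empty subsets of {t1, t2, t3}).  Class counts sum to the number
of merged regions by construction.

## Nearest-gene assignment

A peak overlapping a gene span is assigned to it at signed distance 0;
otherwise the gene minimizing the edge-to-edge gap wins.  Ties break by the
smaller distance to the TSS, then lexicographic gene_id, making assignment
fully deterministic.  Distances are signed negative upstream / positive
downstream relative to gene strand.  When the genes of a chromosome are
pairwise disjoint the implementation uses a bisection fast path (the
candidates are the genes overlapping the query plus its two flanks); with
overlapping gene models it falls back to a dense scan.  Both paths are
checked against an exhaustive oracle in the tests.

## Monte Carlo peaks-per-gene null

The question "are binding sites clustered on genes more than chance?" is
answered by re-placing the same number of intervals with the observed width
multiset uniformly at random: the chromosome is drawn with probability
proportional to its length, the start uniformly so the interval fits, and
overlaps among placed intervals are allowed.  No mappability mask is
applied (an exclusion list can be supplied); this is the simplest null
consistent with "random placement", and the synthetic genome has no
unmappable regions.  Each iteration recomputes the mean peaks per
associated gene through the same nearest-gene assignment as the observed
data.  The add-one estimator `(r + 1)/(n + 1)` never reports zero.

The self-calibration test feeds the null one of its own draws and checks
that p-values are KS-uniform.  Because the statistic is a ratio of small
integers, a tiny instance produces heavy ties and the `≥` count then makes
the p-value conservative; the calibration instance therefore includes a
gene-free chromosome so that both the numerator (assigned peaks) and the
denominator (distinct genes) vary, which brings the tie probability below
0.5% and makes the estimator effectively continuous.

## Occupancy score

Parameters (`ScoringParameters`): steepness k = 5e-4 /bp, half-distance
15 bp, inside-gene score 1, epsilon 0.01, distance convention d0 = 1.

Per-base scores are summed exactly (vectorized over integer distances,
evaluated through `expit` for stability) and divided by peak width — no
sampling.  Two conventions are deliberately explicit because the formula
alone does not fix them:

* **d0** — the base immediately adjacent to the gene is at distance 1
  (d0 = 1, default) or 0.  Both are supported; the difference per base is
  below 4e-6 at the default steepness.
* **Peak inclusion** — a peak is counted for a gene iff its nearest base is
  within `max_distance`, the distance where the per-base score falls to
  epsilon (≈ 9.2 kb at defaults).  Peaks beyond contribute less than
  epsilon each; `epsilon = 0` disables the cutoff and forces every
  same-chromosome peak into the sum.

Scoring is per gene, **not** an exclusive assignment: one peak may
contribute to several nearby genes, which is the natural reading of a
distance-weighted sum (exclusive assignment would reintroduce the hard
nearest-gene boundary the decay is meant to soften).  The gene span (not
the exon union) defines "inside the gene".  The indexed whole-genome path
pre-selects candidate peaks with sorted-array bisection and sums in a fixed
order, so it is bit-identical to scoring genes one at a time.

## DE classification and target calling

Down/up sets use |log₂FC| ≥ 0.5 (inclusive) and padj < 0.05 (strict);
genes with missing padj are excluded.  The response curve uses every
distinct positive score as a cutoff, so it is exact; the randomized
baseline samples gene sets of matched size uniformly without replacement
from the scored universe and averages 100 repetitions (mean and SD per
cutoff).  Its per-cutoff mean converges to the hypergeometric expectation
`set_size × n_above / N`, which the tests verify at 10,000 repetitions.

Inflection detection fits `y = a + bx + c·max(0, x − k)` over the cutoff
rank index by exhaustive breakpoint search (≥ 3 points per segment),
mirroring the plotting space in which such thresholds are judged by eye.
"Clearly evident" is encoded as two guards: the two-segment fit must
improve the single-line SSE by ≥ 20%, and the experimental count at the
breakpoint must be ≥ 2× the baseline mean there.  Either failure returns
"none detected" — the expected outcome for up-regulated or
score-independent expression changes.  A numerically perfect line
(SSE ≤ 1e-9 of the signal scale) is also "none detected".

The final target set is the union over timepoints of genes at or above
that timepoint's threshold that are DE in the chosen direction
(default: down-regulated under overexpression, the direction with usable
dynamic range).

## Pausing analysis

The proximal window is the first 300 bp downstream of the TSS (the
conventional pausing-region scale), the body is the remainder of the span,
and genes shorter than 600 bp are excluded; all three are configurable.
Densities are integrated coverage over window length, so ratios are
invariant to global rescaling.  Genes with zero body density (undefined
ratio) are excluded from set comparisons and counted separately.

Set enrichment for the continuous ratio uses label permutation with the
difference of **mean** log₂ ratio as the default statistic.  The median
difference is available but not the default: under heavily tied ratios a
permuted half-half split reproduces the observed median difference with
high probability (for two constant groups of 50, ≈ 41% of permutations),
so the median p-value cannot saturate even under perfect separation,
whereas the mean difference is reproduced only by the original labeling.
Categorical Pol II classes use the exact one-sided hypergeometric tail,
with helper support for top-quartile classes derived from a numeric
pausing index.

Metagene profiles resample each gene's coverage to `n_bins` by linear
interpolation of the cumulative coverage — exact area-preserving binning
for per-base step functions — normalize per gene to sum 1, strand-flip
minus genes, and average.  Per-gene normalization is the default (a gene
contributes its shape, not its expression level); zero-coverage genes are
skipped because they have no shape to contribute.

## Synthetic data

The generator emulates the full study at desk scale.  Defaults define the
standard simulated conditions:

* 2000 genes on 5 × 3 Mb chromosomes, non-overlapping, strands 1:1,
  lengths log-normal (median 2 kb, σ_log 0.6, minimum 700 bp), 2–5 exons.
* 50 true targets; peaks per target `max(1, Poisson(2.5))` (most bound
  genes carry ≥ 2 sites); widths log-normal with median 600 bp; centers at
  a gene edge or uniformly inside (50/50, so both the unit-score and the
  logistic branch of the formula are exercised) with 200 bp placement
  noise; 300 uniform noise peaks.
* Temporal membership sampled per region from class weights in which a
  majority of sites are unique to one timepoint (58%), few are
  constitutive (9%), and the t1∩t2-only and t1∩t3-only classes are rare.
* Replicates re-emit each region with 10 bp edge jitter, so replicate
  intersection recovers essentially all planted regions.
* DE: targets draw log₂FC ~ N(−1.5, 0.4) with padj ~ Beta(0.5, 200)
  (skewed to zero); null genes draw log₂FC ~ N(0, 0.4) with uniform padj,
  except a 5% spuriously significant fraction.  padj is simulated directly
  rather than derived from counts — the pipeline consumes the DE table's
  shape, not the DE model.
* Coverage: per-gene two-level profiles with proximal/body ratio 5 for
  targets and 1 for background, scaled to 10⁶ total reads, with Poisson
  noise per 25 bp step.  Intergenic background is zero.

What the generator does **not** emulate: mappability and GC artifacts,
replicate-specific biases, correlated DE errors, overdispersed coverage,
overlapping or nested gene models, and realistic chromosome-scale
heterogeneity.  Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated generative model, not
robustness to every artifact of real sequencing data.

All randomness derives from one integer seed via named, indexed streams
(`SeedSequence([seed, crc32(name), index])`), so operations are
reproducible independently and in parallel, and identical configurations
produce byte-identical output files.

## Problem sizes used in the checks

The automated checks run at sizes chosen to exercise every code path while
keeping the suite quick: formula exactness on 200 random peak/gene
instances (≤ 2 kb peaks) at 1e-12 relative tolerance; interval operations
against quadratic oracles on ~100 instances of up to 500 intervals; null
calibration over 200 repetitions of 99 iterations; baseline convergence at
10,000 repetitions on a 500-gene universe; target recovery over 20
simulated studies at the standard conditions (the acceptance script uses
10); pausing calibration over 200 null simulations at 199 permutations.

## Known limitations

* The breakpoint fit assumes a single change of slope; staircase-like
  response curves with several regimes will return the dominant one.
* The scored-gene universe for baselines is the full score table; callers
  who want an expressed-only universe should pre-filter the table.
* `epsilon > 0` truncates genuinely ultra-distal contributions; set
  `epsilon = 0` to force exhaustive same-chromosome sums at quadratic
  cost.
* The Monte Carlo null models placement, not peak calling: width
  distributions are preserved, but signal-dependent peak-width biases are
  not.
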