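# Methods

## The index and the filtering cascade

At a variant site, a bulk's SNP/Indel-index is the fraction of covering
reads that carry the mutant (ALT) allele, computed at full floating
precision; two-decimal values appear only in printed output. An index is
*undefined* when the bulk's total depth falls below `min_depth` (default 1,
i.e. only zero-coverage sites are undefined; no depth floor is imposed
beyond that, but `min_depth` is exposed for stricter calling).

The cascade applies three per-site predicates in order:

1. **Low-index removal** — a site is removed iff its index is strictly
   below `low_index_cutoff` (default 0.3) in *both* bulks. The reading is
   conjunctive, matching established MutMap practice. Sites with an
   undefined index in either bulk are also removed here: an uncovered
   mutant bulk cannot certify a fixed mutant allele, so such sites cannot
   satisfy the downstream criteria in any case.
2. **Mutant-index requirement** — keep iff the mutant-bulk index is at
   least `mut_index_required` (default 1.0). At the default this is an
   exact equality `alt_depth == total_depth` with no epsilon; a recessive
   phenotype scored without ambiguity admits no wild-type read in the
   mutant bulk if sequencing is error-free. The threshold is configurable
   for users who want to tolerate miscalls.
3. **Wild-type-index bound** — keep iff the wild-type-bulk index is
   *strictly* below `wt_index_max` (default 0.5). Strictness matters: a
   wild-type-phenotype bulk composed purely of heterozygotes has expected
   index exactly 0.5 and must be excludable.

Stages 2 and 3 are pure per-variant predicates, so their order cannot
change the survivor set (verified by property test); the funnel counts do
depend on order, and the reported order is low-index → mutant-fixed →
wild-type-bounded. SNPs and indels flow through one cascade jointly but
are tallied separately at every stage.

A site fixed in the parent before the causal mutation arose (homozygous
background) has index ≈ 1 in *both* bulks and is always rejected at stage 3
— this is why the wild-type bound, not the mutant requirement, is what
protects against phenotype-uncorrelated fixed mutations.

## Variant I/O conventions

Coordinates are 1-based point positions in both dialects (VCF convention;
the TSV dialect uses the same convention so the two agree). The mutant
allele is always the VCF ALT allele, assuming calling against the wild-type
reference. Multi-allelic VCF records are split per ALT allele, each split
inheriting the record's site coverage (the sum of all AD entries) as its
denominator, which keeps the index denominator equal to site coverage.
Whether upstream callers split or drop multi-allelic sites varies; the
split convention here is a documented choice. Sites absent from the table
are treated as absent, not as zero-depth; zero depth is representable and
handled by the undefined-index rule. No genotype-likelihood interpretation,
INFO parsing or indel normalization is attempted.

## The simulator

The generator emulates a MutMap+-style experiment end to end:

* **Genome.** Default 12 chromosomes of 30 Mb / 125 cM each (a rice-like
  genome size and map length, kept uniform for simplicity). Genetic
  position is linear in physical position within a chromosome; nonuniform
  recombination maps are out of scope.
* **Mutation load.** One recessive causal site (always a C→T transition,
  default chr1:2,771,134) heterozygous in the parent, plus `n_background`
  heterozygous and `n_fixed` homozygous background mutations placed
  uniformly at random without collisions. Each background ref/alt pair is
  a transition (C→T or G→A) with probability `transition_fraction`
  (default 0.9, the canonical EMS bias), otherwise a random transversion.
  The default background load (2,000 heterozygous + 100 fixed) is an
  order-of-magnitude convention for a mutagenized line carried through
  several selfed generations, not a measured value.
* **Meiosis.** Each selfed progeny receives two independent gametes.
  Within a gamete, alleles at heterozygous sites on one chromosome follow
  a linear Markov walk along the genetic map with crossover probability
  `r = (1 − exp(−2d/100))/2` (Haldane, no interference) between adjacent
  sites; chromosomes assort independently; fixed sites always transmit the
  mutant allele. All heterozygous mutations are modelled in coupling phase
  (every mutant allele on the same homolog). For unlinked sites phase is
  irrelevant, and for the tightly linked neighborhood of the causal site
  coupling is the conservative choice (it maximizes hitch-hiking
  survivors). `linkage=False` switches to free assortment at every site,
  the textbook idealization of an unlinked background.
* **Phenotype and bulking.** Phenotype is recessive on the causal genotype,
  optionally flipped with `misphenotyping_rate` (default 0). From a cohort
  of `n_progeny` (default 240, comfortably above the 120 plants needed to
  fill 30+30 bulks at a 3:1 ratio), the two bulks are drawn uniformly
  without replacement and pooled in equal proportion: the bulk allele
  frequency at a site is the summed genotype over selected plants divided
  by twice the bulk size.
* **Sequencing.** Per site and bulk, total depth is Poisson at the bulk's
  mean coverage (defaults 18.06× wild-type, 20.90× mutant) and the
  mutant-read count is binomial at `f(1−ε) + (1−f)ε`, with `f` the bulk
  allele frequency and `ε` the per-read miscall rate (default 0). Reads
  are sampled from the pooled frequency (infinite-template pooling) rather
  than by resampling individual plants per read: this matches
  equal-proportion DNA pooling, and plant-level stochasticity enters
  through bulk composition. Zero-depth outcomes are kept; they exercise
  the undefined-index path. Default `ε = 0` mirrors the idealization under
  which the exact index-1 criterion is justified; nonzero values let users
  quantify that criterion's fragility.

Everything is deterministic given `seed` (one `numpy` Generator drives the
whole run; no hidden global state).

### What the simulator does and does not capture

It emulates the post-variant-calling allele-depth table. It does not model
read mapping, caller errors, coverage biases (GC, repeats), a realistic
per-chromosome mutation landscape, crossover interference, or segregation
distortion. Passing tests therefore certify the *genetics and sampling
arithmetic* of the pipeline — segregation ratios, linkage decay, expected
indices, filter operating characteristics under the stated model — not its
behaviour on any particular real read set. Real-study scale quantities
(e.g. tens of thousands of called variants and the specific candidate
coordinate) depend on raw reads and a calling pipeline and are carried here
only as design inputs and defaults.

## Phenotype statistics

The segregation test is a Pearson chi-square goodness-of-fit with 1 df and
**no Yates continuity correction**: for 102:30 against 3:1 the uncorrected
statistic is (3²/99 + 3²/33) = 0.3636 (printed 0.36), while Yates would
give ≈ 0.2525; the uncorrected convention is the one that reproduces
standard reporting and is adopted throughout. Expected counts come from
the stated ratio and the observed total; the p-value is the chi-square
survival function.

The pigment formulas are evaluated literally, in order (Chl a and Chl b
feed the carotenoid formula), including the bare `104` coefficient:

```
Chl a = (12.21·OD665 − 2.81·OD649) · V/W
Chl b = (20.13·OD649 − 5.03·OD665) · V/W
Caro  = (1000·OD470·V/W − 3.27·Chl a − 104·Chl b) / 198
```

with V the extract volume (mL) and W the fresh weight (g). The formulas'
native output scale under the standard ethanol/acetone calibration is
µg-scale concentration per gram fresh weight, but published tables built on
them are sometimes labelled mg/g without an explicit conversion; the
package emits formula units and leaves unit conversion to the user rather
than guessing a factor. Negative outputs (absorbances outside the
calibration range) are returned as computed but flagged and warned about.

## Power evaluation

`evaluate` runs simulate → cascade over replicates, each replicate drawing
its random stream from a deterministic function of `(seed, i)`
(`SeedSequence(seed, spawn_key=(i,))`), so results are reproducible and
independent of execution order. It reports sensitivity (causal site in the
survivor set), mean false positives split by background class — unlinked,
linked (heterozygous background within `linked_window_cm`, default 10 cM,
of the causal site on its chromosome) and fixed, whose failure modes
differ — the low median of the survivor-set size (an actual replicate
value, hence an integer), and per-stage mean counts. `sweep` evaluates a
grid over mean depth, bulk size or error rate with common random numbers
across grid points for low-variance paired comparisons; when bulk size
grows, the progeny cohort is grown to 8× the bulk size so phenotype classes
fill with near certainty.

A useful closed form: at a site fixed for the mutant allele and covered by
exactly `d` reads with miscall rate ε, P(index = 1) = (1−ε)^d —
`mut_index_one_rate` is its Monte-Carlo counterpart using the same binomial
read model, and tests require the two to agree within the 99% interval.

## Numerical and design choices

* Index comparisons always use unrounded values; `index = 1` is an exact
  integer condition, immune to floating-point representation issues.
* Funnel/report problem sizes used by the test suite (hundreds to a few
  thousand simulated sites, up to ~200 replicates) were chosen as the
  smallest sizes at which the Monte-Carlo intervals in the assertions are
  decisive.
* The low median is used for the survivor-count summary so the reported
  value is always a realized replicate outcome.
* Ties and degenerate inputs: empty variant tables produce an all-zero
  funnel; a bulk with zero coverage yields an undefined index (never a
  division error); `compute_index` rejects `alt_depth > total_depth`.

## Known limitations

* Coupling-phase heterozygous background is an approximation; repulsion
  linkage between background sites is not modelled.
* The exact index-1 criterion is brittle under sequencing error by design;
  the power module quantifies the decay but the package does not pick a
  relaxed threshold for the user.
* No sliding-window index plots or delta-index confidence intervals
  (classical QTL-seq machinery): the method implemented is per-site
  filtering only, and no variant-consequence annotation is attempted.
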