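# Methods

This note documents the models, parameter choices and numerical conventions
behind `dietbarcode`, and what the synthetic validation does and does not
demonstrate about real data.

## The false-assignment filter

The filter assumes that the dominant source of false-positive occurrences is
run-level cross-assignment of reads between PCR products (tag jumping /
mixed clusters), that the number of misassigned reads of a variant scales
with that variant's run total, and that an alien-control haplotype —
handled separately from every study sample — measures the process: any of
its reads observed outside its own product must be cross-assigned.

* `R_FA = max_over_non-source_products(count_alien) / N_alien`. Using the
  maximum rather than the mean makes the per-product threshold conservative:
  it over-states the typical per-product leak (the mean leak per product is
  roughly `R_FA_true / n_products`), which is the intended direction for a
  false-positive filter. As an estimator of the aggregate jump rate it is
  conversely biased low once jumps spread over many products, because
  `max <= total`. The parameter-recovery experiment characterises exactly
  this: medians land near half the true rate when the control depth is
  matched to the rate (see below).
* `T_FA_i = ceil(N_i * R_FA)`. The ceiling is conservative for non-integer
  products (never admits a count the real-valued threshold would reject);
  a small epsilon (1e-9) guards against floating-point inflation of exact
  integer products. Positivity uses strict inequality (`count > T_FA_i`):
  with a threshold of 5, a count of 5 is negative. This is the reading that
  reconciles "the read number above which the product is positive" with the
  documented 5-reads-at-threshold-5 false negative.
* R_FA is estimated per sequencing run and never shared across runs.
* Replicate rule: an occurrence needs positives in at least `min_fraction`
  (default 0.5) of the replicate set. Both groupings are exposed because
  the design is genuinely ambiguous: within-platform (2 replicates, where a
  single positive out of two already passes 50 %) for the per-platform
  tables, and pooled over all four replicates (needing at least two) for the
  final occurrence calls. The pooled grouping is the default for final
  tables.
* Variant-to-taxon collapse happens after thresholding (thresholds are
  defined per variant); a product is positive for a taxon when any of the
  taxon's variants is positive.

## Taxonomic assignment

Percent identity is computed by end-gap-free global alignment with unit
match/mismatch/gap scores; the denominator is the number of alignment
columns spanned by the aligned region, so internal gaps count against
identity while terminal overhangs do not, and `N` matches nothing. A
BLAST-style local identity would inflate scores for truncated variants.

Assignment walks per-category tier lists (prey-type references 100/98 %,
processed-food references 98/95 %; the tier class is chosen from the best
hit's reference category, ties resolved to the stricter prey tiers). At the
highest tier with hits, the call is the lowest common ancestor of the hits:
species if unique, else genus, family, order, superorder. When even the
superorders disagree the call falls back to the shared class (or
"Vertebrata"), still labelled superorder rank, so that "unidentified" is
reserved exactly for best identity below the lowest tier. A deliberate
consequence of the 98 % top tier for processed food: an exact match to a
reference with a congener within 2 % resolves at *genus* level — matching
how processed-food taxa are reported in practice (e.g. *Sus* sp., *Bos*
sp.). Occurrence-vs-truth comparisons therefore match taxa through the
reference lineage (an occurrence at genus rank matches a truth species of
that genus), implemented in `occurrence.reconcile_with_truth`.

## Detection metrics

A feeding event is one distinct (feeding day, taxon) pair; its DNA is
expected in the earliest scat emitted at least 12 h after the day's first
meal of that taxon (lag window 12-24 h, configurable). Events with no
following scat are excluded from the denominator with a warning. Detection
rate is `100 x observed / expected` per food category, reported as integer
percent; carry-over detections in later scats count as observed without
enlarging the denominator, so overshoot past 100 % is possible. Sample
fractions are reported to one decimal. For category-level comparisons,
anthropogenic food counts once per sample (its taxa cannot be tied to
independent ingestion events) with the taxon-level multiplicity reported
separately; prey taxa and game species count per (sample, taxon).

## Statistics

The two-sided 2x2 Fisher test sums hypergeometric probabilities of all
margin-fixed tables at most as probable as the observed one (relative tie
tolerance 1e-7); degenerate margins give p = 1 with a warning. r x c tables
use margin-preserving Monte-Carlo permutation with the plus-one correction
`(b+1)/(n+1)`, deterministic under a fixed seed. The binomial GLM of
detectability (platform x food item) is deliberately not reimplemented —
the module exports the model-ready long-format detection table instead.

## The synthetic-data generator

The generator emulates the study design the filter was built for: a feeding
trial with one scat per day, each DNA extract amplified twice per platform
on two platform profiles, negative extraction/PCR controls, and one alien
control product per run.

Defaults (the study conditions, chosen once):

| parameter | default | rationale |
|---|---|---|
| `n_samples` | 41 | scats in the calibration feeding trial |
| `replicates_per_platform` | 2 | two independent PCRs per platform |
| `tagjump_rate` | 5e-4 | the 0.05 % run false-assignment rate |
| `predator_read_fraction` | 0.85 | host reads dominate (87.5-98.5 % observed) |
| `category_detect_prob` | 0.82 / 0.54 / 0.31 | per-scat detectability anchored to the calibration rates (prey / pet food / raw) |
| integrity scaling | 1.0 / 0.35 / 0.12 | relative read abundance of present food taxa; free parameters expressing the DNA-integrity gradient (no quantitative model exists) |
| platform profiles | 2500 reads/product, no truncation; 500 reads/product, 30 % truncation | deep clean platform vs shallow platform losing truncated amplicons without reverse tags |
| `alien_control_total_reads` | 10,000 | about 5 expected jumped reads at the default rate, so the max/total estimator virtually never returns 0; the study-scale control (~2,000 reads, ~1 expected jump) is explored separately in the recovery experiment |
| `contamination_rate` | 0.002 | low-level human/predator reads in negative controls |

Tag jumps are modelled as independent uniform re-assignment of each read to
any other PCR product; category detectability is a single per-scat Bernoulli
on presence (shared by all replicates and platforms) plus the integrity
abundance scaling. Reference sequences are 136-bp with block-disjoint
between-genus substitutions (guaranteeing the within < between divergence
ordering) and 1-2 within-genus substitutions. Read-level FASTQ emission
(inline 7-bp tags, degenerate-primer instantiations) exists for round-trip
exercises; the default output is count tables, since filtering operates on
counts.

What the simulator does **not** model: PCR chemistry, chimeras, polymerase
error beyond a uniform rate, homopolymer mechanics (only their net
truncation effect), carry-over DNA across consecutive scats, and
platform-specific detectability differences. Passing validation therefore
shows the filter chain is sound against the tag-jumping mechanism it
targets, not that it removes every artefact class in real libraries.

## Validation experiment sizes

* R_FA recovery: 3 rates x 20 seeded runs, 10 samples, one 2000-read
  platform, control depth `2 / rate` (about two expected jumps — the regime
  where a max-based estimator is informative; at fixed depth the estimator
  degrades as `1/E[jumps]` for rarer rates). Median estimates land at about
  half the true rate, within the factor-3 band asserted.
* False-positive soundness: 20 seeded full-default runs (41 scats, both
  platforms); the count of retained food occurrences incompatible with the
  truth table is asserted zero in at least 19 of 20.
* Detectability ordering: 20 seeded runs of a 120-day trial — the trial is
  lengthened so per-category event counts resolve the 0.82/0.54/0.31
  ordering above Monte-Carlo noise; strict ordering asserted in >= 18 of 20.
* Fisher exactness: all 2x2 tables with margins up to 8 against exact
  rational-arithmetic enumeration.

## Known limitations

* The merge/demultiplex stage handles the inline-tag dialect natively and
  represents dual-index layouts abstractly as tag-pair labels; index
  location is irrelevant to counting.
* Tags must match exactly (no one-mismatch rescue): residual cross-talk is
  exactly what the T_FA model corrects, and rescuing tags would change the
  estimated rate.
* Primer matching allows 1 mismatch by default (IUPAC degeneracy aside);
  the merge overlap minimum (20 bp) and identity threshold (80 %) are
  package choices, exposed as configuration.
* `R_FA` is stored as a fraction and printed as percent.
* Occurrence tables derived from published summary counts
  (`dietbarcode.studydata`) expand aggregate counts into synthetic
  per-sample rows; sample identities there are arbitrary and only the
  counts are meaningful.
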