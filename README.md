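# dietbarcode

A diet-metabarcoding analysis pipeline for faecal samples, built around the
**alien-control false-assignment filter**. It turns demultiplexed amplicon
reads (or pre-dereplicated per-PCR-product variant count tables) from a
cytochrome-*b* 136-bp mini-barcode into filtered food-item occurrence
tables, and ships a forward simulator of the whole study design so every
stage can be exercised and validated without any sequencing data.

It is aimed at molecular ecologists analysing predator diet (the motivating
system is the domestic cat, whose scats mix intact prey DNA with heavily
processed pet-food and raw fish/meat DNA) on benchtop sequencing platforms
with technical PCR replicates.

## The filtering model

Tag jumping (index hopping, mixed clusters) re-assigns a small fraction of
reads to the wrong PCR product, producing false-positive occurrences. The
pipeline corrects this with one non-arbitrary threshold per sequencing run:

* **R_FA** — the run false-assignment rate. An *alien control* is a
  haplotype handled separately from all study samples, so any of its reads
  found in a study product can only be cross-assignment. With N_alien total
  alien reads in the run,

      R_FA = max over non-source products of count(alien) / N_alien

* **T_FA_i** — the positivity threshold for variant *i*. Misassignment
  scales with a variant's abundance, so with run total N_i,

      T_FA_i = ceil(N_i x R_FA)

  A PCR product is positive for variant *i* only when its count **strictly
  exceeds** T_FA_i (e.g. 34,000 reads at R_FA = 0.05 % give T_FA = 17; a
  count of 17 is negative, 18 is positive).

* **Replicate concordance** — a (sample, taxon) occurrence is retained only
  when it is positive in at least 50 % of the technical PCR replicates
  (configurable; within-platform pairs or all replicates pooled).

Variants are assigned to taxa by end-gap-free global percent identity
against the reference library using sliding similarity tiers — 100/98 % for
prey-type taxa, 98/95 % for processed-food taxa — with lowest-common-ancestor
resolution when several references tie (processed-food taxa therefore often
resolve at genus level, e.g. *Sus* sp.). Detection is summarised as
occurrence counts against the *minimum expected occurrences* implied by a
known feeding schedule and a >= 12 h gut-transit window, frequency of
occurrence, and Fisher exact comparisons of biomass vs read proportions.

## Worked example

```bash
dietbarcode run --seed 1 --out demo_out
```

simulates a 41-scat feeding trial sequenced twice on each of two platform
profiles, estimates R_FA from the alien control, filters, and prints the
pooled detection summary:

```json
{
  "prey": {"expected": 16, "observed": 13, "rate_percent": 81},
  "pet_food": {"expected": 37, "observed": 22, "rate_percent": 59},
  "raw_fish_meat": {"expected": 13, "observed": 6, "rate_percent": 46}
}
```

Reading this: the trial schedule implied 16 expected prey occurrences
(distinct feeding-day x taxon events mapped to the first scat >= 12 h
later), of which 13 survived thresholding and replicate filtering — intact
prey DNA is detected far more reliably than processed pet food or stored raw
fish/meat, the ordering the category detectabilities encode. `demo_out/`
contains every intermediate artifact (counts per run, thresholds with each
T_FA_i >= 1, per-platform and pooled occurrence tables, control screen,
`report.md`). The same library is importable directly; see
`dietbarcode.experiments` for ready-made validation experiments.

The equivalent stage-by-stage commands are `dietbarcode simulate`, `demux`,
`merge`, `derep`, `assign`, `filter`, `occurrences` and `compare`.

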