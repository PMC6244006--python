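"""Forward simulator of the diet-metabarcoding study design.

Generates a synthetic 136-bp cytochrome-b mini-barcode reference library, a
calibration feeding trial (known meal schedule, daily scats, ground-truth
expected occurrences) and per-platform sequencing runs as PCR-product x
variant count tables, with the statistical structure the filtering pipeline
assumes:

* predator reads dominate each faecal PCR product (default 85 % of reads);
* food taxa present in a scat are detected per-category with probabilities
  anchored to the observed calibration rates (prey 0.82, pet food 0.54, raw
  fish/meat 0.31) and, when present, carry abundance scaled by a
  DNA-integrity factor (prey > pet food > raw);
* every read is independently re-assigned to a uniformly random other PCR
  product with probability ``tagjump_rate`` (the tag-jumping / mixed-cluster
  mechanism the T_FA filter corrects);
* one alien-control product carries a fixed number of reads of a haplotype
  foreign to the study, from which R_FA is estimable;
* negative extraction/PCR controls carry only low-level human/predator
  contamination;
* one platform profile loses a fraction of its reads as truncated amplicons
  (no valid reverse tag), recorded in the run log.

Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import occurrence as occ_mod
from .seqio import ConfigError, ReadCountTable, variant_id, write_fastq
from .taxassign import MiniBarcodeReference, RefEntry

BARCODE_LENGTH = 136
BASES = np.array(list("ACGT"))

#: relative read abundance of a present food taxon, by category ("DNA
#: integrity" scaling: intact prey carcasses > processed pet food > stored
#: raw fish/meat)
INTEGRITY = {"prey": 1.0, "pet_food": 0.35, "raw_fish_meat": 0.12}

#: fraction of a sample product's reads drawn as human background
HUMAN_READ_FRACTION = 0.005

FWD_PRIMER = "GAYAAARTYCCVTTYCAYC"
REV_PRIMER = "AARTAYCAYTCDGGYTTRAT"


@dataclass(frozen=True)
class PlatformProfile:
    """Net sequencing behaviour of one platform.

    ``truncation_prob`` is the probability that a read is emitted without a
    valid reverse tag and must be discarded (the net effect of homopolymer /
    short-read failure modes, not their mechanics).
    """

    name: str
    reads_per_product: int
    truncation_prob: float = 0.0
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        if self.reads_per_product <= 0:
            raise ConfigError("reads_per_product must be > 0")
        for f in (self.truncation_prob, self.per_base_error):
            if not 0.0 <= f <= 1.0:
                raise ConfigError("platform fractions must be in [0, 1]")


def default_platforms() -> list[PlatformProfile]:
    # depths scaled to the study's per-product order of magnitude: the
    # short-read platform is shallower and loses ~30 % truncated amplicons
    return [
        PlatformProfile("IonPGM", reads_per_product=500, truncation_prob=0.30, per_base_error=0.01),
        PlatformProfile("MiSeq", reads_per_product=2500, truncation_prob=0.0, per_base_error=0.001),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_samples: int = 41  # daily scats of the feeding trial
    replicates_per_platform: int = 2
    platforms: list[PlatformProfile] = field(default_factory=default_platforms)
    tagjump_rate: float = 0.0005
    predator_read_fraction: float = 0.85
    category_detect_prob: dict[str, float] = field(
        default_factory=lambda: {"prey": 0.82, "pet_food": 0.54, "raw_fish_meat": 0.31}
    )
    contamination_rate: float = 0.002
    alien_control_total_reads: int = 10_000

    def __post_init__(self) -> None:
        fracs = [self.tagjump_rate, self.predator_read_fraction, self.contamination_rate]
        fracs += list(self.category_detect_prob.values())
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigError("all fractions must be in [0, 1]")
        if self.replicates_per_platform < 1:
            raise ConfigError("replicates_per_platform must be >= 1")
        if self.n_samples < 0 or self.alien_control_total_reads < 0:
            raise ConfigError("sizes must be non-negative")
        if not self.platforms:
            raise ConfigError("at least one platform profile required")


# ---------------------------------------------------------------------------
# reference generation

_MANDATORY = [
    # species, genus, family, order, superorder, class, category
    ("Felis silvestris catus", "Felis", "Felidae", "Carnivora", "Laurasiatheria", "Mammalia", "predator"),
    ("Homo sapiens", "Homo", "Hominidae", "Primates", "Euarchontoglires", "Mammalia", "human"),
    ("Myodes glareolus", "Myodes", "Cricetidae", "Rodentia", "Euarchontoglires", "Mammalia", "alien_control"),
]

_CATEGORY_LINEAGE = {
    "prey": ("Simomyidae", "Rodentia", "Euarchontoglires", "Mammalia", "prey_candidate"),
    "pet_food": ("Simobovidae", "Artiodactyla", "Laurasiatheria", "Mammalia", "human_linked_candidate"),
    "raw_fish_meat": ("Simosalmonidae", "Salmoniformes", "Protacanthopterygii", "Actinopterygii", "human_linked_candidate"),
}


def generate_reference(
    n_species_per_category: Mapping[str, int] | None = None,
    divergence_spec: Mapping[str, float] | None = None,
    seed: int = 0,
) -> MiniBarcodeReference:
    """Build a synthetic mini-barcode library with controlled divergence.

    ``divergence_spec`` gives within-genus and between-genus substitution
    fractions (within < between).  Species are grouped into genera of two
    where counts allow, so congeneric ambiguity is exercised downstream.  A
    predator, a human and an alien-control taxon are always included.
    """
    n_species_per_category = dict(n_species_per_category or {"prey": 6, "pet_food": 6, "raw_fish_meat": 3})
    divergence_spec = dict(divergence_spec or {"within_genus": 0.02, "between_genus": 0.08})
    within = divergence_spec["within_genus"]
    between = divergence_spec["between_genus"]
    if not 0.0 < within < between <= 0.5:
        raise ConfigError("need 0 < within_genus < between_genus <= 0.5")
    for cat, n in n_species_per_category.items():
        if n < 0:
            raise ConfigError("species counts must be >= 0")
        if cat not in _CATEGORY_LINEAGE:
            raise ConfigError(f"unknown category {cat!r}")

    rng = np.random.default_rng(seed)
    base = rng.choice(BASES, size=BARCODE_LENGTH)
    k_between = max(1, round(between * BARCODE_LENGTH))
    k_within_max = max(1, int(within * BARCODE_LENGTH))

    # genus plan: mandatory taxa first (each its own genus), then per-category
    # genera of up to two congeneric species
    plan: list[tuple[str, list[str], tuple]] = []  # (genus, species list, lineage+cat)
    for sp, genus, fam, order, sup, cls, cat in _MANDATORY:
        plan.append((genus, [sp], (fam, order, sup, cls, cat)))
    for cat in sorted(n_species_per_category):
        fam, order, sup, cls, refcat = _CATEGORY_LINEAGE[cat]
        n = n_species_per_category[cat]
        gi = 0
        while n > 0:
            gi += 1
            genus = f"{cat.replace('_', '').capitalize()}omys{gi}"
            n_in_genus = min(2, n)
            species = [f"{genus} species{j + 1}" for j in range(n_in_genus)]
            plan.append((genus, species, (fam, order, sup, cls, refcat)))
            n -= n_in_genus

    def mutate(seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
        out = seq.copy()
        for p in positions:
            choices = [b for b in "ACGT" if b != out[p]]
            out[p] = choices[rng.integers(len(choices))]
        return out

    # genus ancestors: disjoint mutated position blocks where possible, so
    # between-genus divergence is guaranteed; falls back to random positions
    all_pos = rng.permutation(BARCODE_LENGTH)
    entries: list[RefEntry] = []
    for g_idx, (genus, species_list, (fam, order, sup, cls, refcat)) in enumerate(plan):
        start = (g_idx * k_between) % BARCODE_LENGTH
        if (g_idx + 1) * k_between <= BARCODE_LENGTH:
            positions = all_pos[start:start + k_between]
        else:
            positions = rng.choice(BARCODE_LENGTH, size=k_between, replace=False)
        ancestor = mutate(base, positions)
        for s_idx, sp in enumerate(species_list):
            if s_idx == 0:
                seq = ancestor
            else:
                d = int(rng.integers(1, k_within_max + 1))
                pos = rng.choice(BARCODE_LENGTH, size=d, replace=False)
                seq = mutate(ancestor, pos)
            ref_id = "ref_" + sp.lower().replace(" ", "_")
            entries.append(
                RefEntry(
                    ref_id=ref_id,
                    species=sp,
                    genus=genus,
                    family=fam,
                    order=order,
                    superorder=sup,
                    class_=cls,
                    category=refcat,
                    sequence="".join(seq),
                )
            )
    return MiniBarcodeReference(entries)


# ---------------------------------------------------------------------------
# calibration trial

def generate_calibration_trial(
    config: SimulationConfig,
    reference: MiniBarcodeReference,
    start_date: str = "2012-05-01",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the feeding trial: schedule, scat records and ground truth.

    One feeding day per scat.  The daily ration has constant total mass but
    varying composition: pet food on most days, plus either a prey item or a
    raw fish/meat item on some days, split evenly over three meals.  Scats
    are emitted daily; the truth table is computed with the same >= 12 h
    transit-window rule the occurrence module applies.
    """
    cats_available = {
        "prey": [e.species for e in reference.by_category("prey_candidate")],
        "pet_food": [e for e in _food_species(reference, "pet_food")],
        "raw_fish_meat": [e for e in _food_species(reference, "raw_fish_meat")],
    }
    for cat, taxa in cats_available.items():
        if not taxa:
            raise ConfigError(f"reference lacks taxa for category {cat}")
    rng = np.random.default_rng(_substream(config.seed, "trial"))
    n_days = config.n_samples
    day0 = pd.Timestamp(start_date)
    meal_hours = (8, 12, 17)
    daily_mass = 200.0

    sched_rows = []
    for d in range(n_days):
        items: list[tuple[str, str]] = []
        if rng.random() < 0.9:
            items.append(("pet_food", cats_available["pet_food"][rng.integers(len(cats_available["pet_food"]))]))
        if rng.random() < 0.3:
            items.append(("prey", cats_available["prey"][rng.integers(len(cats_available["prey"]))]))
        elif rng.random() < 0.43:  # raw items on ~30 % of days overall
            items.append(("raw_fish_meat", cats_available["raw_fish_meat"][rng.integers(len(cats_available["raw_fish_meat"]))]))
        if not items:
            items.append(("pet_food", cats_available["pet_food"][rng.integers(len(cats_available["pet_food"]))]))
        mass_per_serving = daily_mass / (len(items) * len(meal_hours))
        for hour in meal_hours:
            for cat, taxon in items:
                sched_rows.append(
                    {
                        "meal_time": day0 + pd.Timedelta(days=d, hours=hour),
                        "taxon": taxon,
                        "category": cat,
                        "mass_g": mass_per_serving,
                    }
                )
    schedule = pd.DataFrame(sched_rows, columns=["meal_time", "taxon", "category", "mass_g"])

    scats = pd.DataFrame(
        {
            "sample_id": [f"S{d + 1:03d}" for d in range(n_days)],
            "emission_time": [day0 + pd.Timedelta(days=d + 1, hours=7) for d in range(n_days)],
        }
    )
    truth = occ_mod.expected_occurrences(schedule, scats)
    return schedule, scats, truth


def _food_species(reference: MiniBarcodeReference, category: str) -> list[str]:
    lineage_order = _CATEGORY_LINEAGE[category][1]
    return [
        e.species
        for e in reference.by_category("human_linked_candidate")
        if e.order == lineage_order
    ]


def food_category_map(reference: MiniBarcodeReference) -> dict[str, str]:
    """taxon name (species or genus) -> schedule food category.

    Prey candidates map to "prey"; human-linked candidates are split into
    pet food vs raw fish/meat by the lineage the generator gave them.
    """
    order_to_cat = {
        lineage[1]: cat for cat, lineage in _CATEGORY_LINEAGE.items()
    }
    out: dict[str, str] = {}
    for e in reference.entries:
        if e.category == "prey_candidate":
            cat = "prey"
        elif e.category == "human_linked_candidate":
            cat = order_to_cat.get(e.order)
            if cat is None:
                continue
        else:
            continue
        out[e.species] = cat
        out.setdefault(e.genus, cat)
    return out


def _substream(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# sequencing-run simulation

@dataclass
class SimulatedRuns:
    runs: dict[str, ReadCountTable]
    sheet: pd.DataFrame
    run_log: dict[str, dict]
    alien_variant: str
    variant_to_taxon: dict[str, str]


def simulate_run(
    config: SimulationConfig,
    reference: MiniBarcodeReference,
    truth: pd.DataFrame,
) -> SimulatedRuns:
    """Draw one sequencing run per platform profile.

    Presence of an expected food taxon in a scat is a single per-scat
    Bernoulli draw (category detection probability) shared by all platforms
    and replicates; read counts are multinomial given presence, with
    integrity-scaled food abundances.  Tag jumps then re-assign each read to
    a uniformly random other PCR product with probability ``tagjump_rate``.
    """
    alien = [e for e in reference.entries if e.category == "alien_control"]
    if not alien:
        raise ConfigError("reference lacks an alien-control taxon")
    alien = alien[0]
    predator = next(e for e in reference.entries if e.category == "predator")
    human = next(e for e in reference.entries if e.category == "human")

    species_entry = reference.species_map()
    vid_of = {sp: variant_id(e.sequence) for sp, e in species_entry.items()}
    variant_to_taxon = {v: sp for sp, v in vid_of.items()}

    samples = sorted(truth["sample_id"].unique()) if len(truth) else [
        f"S{d + 1:03d}" for d in range(config.n_samples)
    ]
    rng_presence = np.random.default_rng(_substream(config.seed, "presence"))
    # per-scat Bernoulli on presence, shared across platforms and replicates
    present: dict[str, list[tuple[str, str]]] = {s: [] for s in samples}
    for row in truth.itertuples(index=False):
        p = config.category_detect_prob.get(row.category, 1.0)
        if rng_presence.random() < p:
            present[row.sample_id].append((row.taxon, row.category))

    runs: dict[str, ReadCountTable] = {}
    sheet_rows: list[dict] = []
    run_log: dict[str, dict] = {}
    tag_rng = np.random.default_rng(_substream(config.seed, "tags"))

    for platform in config.platforms:
        rng = np.random.default_rng(_substream(config.seed, f"run:{platform.name}"))
        product_rows: list[dict] = []
        for s in samples:
            for rep in range(1, config.replicates_per_platform + 1):
                product_rows.append(
                    {"product_id": f"{s}_{platform.name}_r{rep}", "sample_id": s,
                     "platform": platform.name, "replicate": rep, "role": "sample"}
                )
        product_rows.append(
            {"product_id": f"ALIEN_{platform.name}", "sample_id": "ALIEN",
             "platform": platform.name, "replicate": 1, "role": "alien_control"}
        )
        for rep in (1, 2):
            product_rows.append(
                {"product_id": f"NEGEXT_{platform.name}_r{rep}", "sample_id": "NEG_EXT",
                 "platform": platform.name, "replicate": rep, "role": "negative_extraction"}
            )
            product_rows.append(
                {"product_id": f"NEGPCR_{platform.name}_r{rep}", "sample_id": "NEG_PCR",
                 "platform": platform.name, "replicate": rep, "role": "negative_pcr"}
            )
        products = [r["product_id"] for r in product_rows]
        variants = sorted(variant_to_taxon)
        counts = np.zeros((len(products), len(variants)), dtype=np.int64)
        v_index = {v: j for j, v in enumerate(variants)}
        p_index = {p: i for i, p in enumerate(products)}

        reads_generated = 0
        truncated_dropped = 0
        for row in product_rows:
            i = p_index[row["product_id"]]
            if row["role"] == "sample":
                depth = platform.reads_per_product
                reads_generated += depth
                kept = int(rng.binomial(depth, 1.0 - platform.truncation_prob))
                truncated_dropped += depth - kept
                taxa = present[row["sample_id"]]
                weights = [config.predator_read_fraction, HUMAN_READ_FRACTION]
                cols = [v_index[vid_of[predator.species]], v_index[vid_of[human.species]]]
                if taxa:
                    food_mass = 1.0 - config.predator_read_fraction - HUMAN_READ_FRACTION
                    integ = np.array([INTEGRITY[c] for _, c in taxa])
                    integ = integ / integ.sum() * food_mass
                    for (taxon, _), w in zip(taxa, integ):
                        weights.append(w)
                        cols.append(v_index[vid_of[taxon]])
                w = np.array(weights) / np.sum(weights)
                draw = rng.multinomial(kept, w)
                for col, n in zip(cols, draw):
                    counts[i, col] += n
            elif row["role"] == "alien_control":
                counts[i, v_index[vid_of[alien.species]]] += config.alien_control_total_reads
                reads_generated += config.alien_control_total_reads
            else:  # negative controls: low-level human/predator contamination
                lam = config.contamination_rate * platform.reads_per_product
                for sp in (human.species, predator.species):
                    n = int(rng.poisson(lam))
                    counts[i, v_index[vid_of[sp]]] += n
                    reads_generated += n

        jumped_total = _apply_tag_jumps(counts, config.tagjump_rate, rng)

        df = pd.DataFrame(counts, index=products, columns=variants)
        df.index.name = "product_id"
        runs[platform.name] = ReadCountTable(
            df,
            run_id=platform.name,
            variant_sequences={v: species_entry[t].sequence for v, t in variant_to_taxon.items()},
        )
        assigned = int(counts.sum())
        run_log[platform.name] = {
            "reads_generated": reads_generated,
            "reads_assigned": assigned,
            "reads_truncated": truncated_dropped,
            "reads_jumped": int(jumped_total),
        }
        seen_pairs: set[tuple[str, str]] = set()
        for r in product_rows:
            while True:
                fwd = "".join(tag_rng.choice(BASES, size=7))
                rev = "".join(tag_rng.choice(BASES, size=7))
                if (fwd, rev) not in seen_pairs:
                    seen_pairs.add((fwd, rev))
                    break
            sheet_rows.append({**r, "fwd_tag": fwd, "rev_tag": rev})

    sheet = pd.DataFrame(sheet_rows)
    return SimulatedRuns(
        runs=runs,
        sheet=sheet,
        run_log=run_log,
        alien_variant=vid_of[alien.species],
        variant_to_taxon=variant_to_taxon,
    )


def _apply_tag_jumps(counts: np.ndarray, rate: float, rng: np.random.Generator) -> int:
    """Re-assign each read to a uniformly random other product w.p. ``rate``."""
    if rate <= 0:
        return 0
    n_products = counts.shape[0]
    if n_products < 2:
        return 0
    total = 0
    for j in range(counts.shape[1]):
        col = counts[:, j]
        jumps = rng.binomial(col, rate)
        if jumps.sum() == 0:
            continue
        total += int(jumps.sum())
        col -= jumps
        for src in np.nonzero(jumps)[0]:
            others = np.ones(n_products) / (n_products - 1)
            others[src] = 0.0
            col += rng.multinomial(jumps[src], others)
    return total


# ---------------------------------------------------------------------------
# optional read-level (FASTQ) emission

def _concrete(primer: str, rng: np.random.Generator) -> str:
    from .seqio import IUPAC

    return "".join(b if b in "ACGT" else IUPAC[b][rng.integers(len(IUPAC[b]))] for b in primer)


def emit_fastq(
    table: ReadCountTable,
    sheet: pd.DataFrame,
    out_path: str | Path,
    seed: int = 0,
    quality: int = 35,
) -> None:
    """Write the count table as single-end reads with inline tags and primers.

    Each read is fwd_tag + fwd_primer + variant + revcomp(rev_primer) +
    revcomp(rev_tag), so `seqio.demultiplex` + `seqio.dereplicate` recover
    the table exactly.  Intended for small-scale round-trip exercises, not
    full-depth runs.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    tags = sheet.set_index("product_id")[["fwd_tag", "rev_tag"]]
    records = []
    k = 0
    for product in table.products:
        fwd_tag, rev_tag = tags.loc[product]
        for v in table.variants:
            n = int(table.counts.at[product, v])
            if n == 0:
                continue
            insert = table.variant_sequences[v]
            for _ in range(n):
                read = (
                    fwd_tag
                    + _concrete(FWD_PRIMER, rng)
                    + insert
                    + str(Seq(_concrete(REV_PRIMER, rng)).reverse_complement())
                    + str(Seq(rev_tag).reverse_complement())
                )
                k += 1
                records.append((f"read{k}", read, [quality] * len(read)))
    write_fastq(records, out_path)
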