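"""Tiered percent-identity taxonomic assignment against a mini-barcode library.

Each sequence variant is compared to every entry of a 136-bp cytochrome-b
reference library by end-gap-free global alignment.  Assignment walks a
per-category list of sliding similarity tiers (100/98 % for prey-type
references, 98/95 % for processed-food references): at the highest tier with
hits, the variant is assigned to the lowest common ancestor of the hits
(species if unique, else genus, family, order, superorder).  Variants whose
best identity falls below the lowest tier stay unidentified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .seqio import ConfigError, read_fasta, variant_id, write_fasta

RANKS = ("species", "genus", "family", "order", "superorder")

#: reference category -> which tier list applies
REF_CATEGORIES = (
    "prey_candidate",
    "human_linked_candidate",
    "predator",
    "human",
    "alien_control",
)

DEFAULT_TIERS: dict[str, list[float]] = {
    "prey": [100.0, 98.0],
    "processed": [98.0, 95.0],
}

_TIER_CLASS = {
    "prey_candidate": "prey",
    "predator": "prey",
    "human": "prey",
    "alien_control": "prey",
    "human_linked_candidate": "processed",
}

_EPS = 1e-9


@dataclass(frozen=True)
class RefEntry:
    ref_id: str
    species: str
    genus: str
    family: str
    order: str
    superorder: str
    class_: str
    category: str
    sequence: str

    def lineage(self) -> dict[str, str]:
        return {
            "species": self.species,
            "genus": self.genus,
            "family": self.family,
            "order": self.order,
            "superorder": self.superorder,
        }


@dataclass
class MiniBarcodeReference:
    """Taxon-labelled barcode library with food-category map."""

    entries: list[RefEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate ref_ids in reference")
        for e in self.entries:
            if not e.sequence:
                raise ConfigError(f"empty sequence for {e.ref_id}")
            if not e.species or not e.genus:
                raise ConfigError(f"lineage incomplete for {e.ref_id}")
            if e.category not in REF_CATEGORIES:
                raise ConfigError(f"unknown reference category {e.category!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_category(self, category: str) -> list[RefEntry]:
        return [e for e in self.entries if e.category == category]

    def species_map(self) -> dict[str, RefEntry]:
        return {e.species: e for e in self.entries}

    def to_files(self, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
        write_fasta({e.ref_id: e.sequence for e in self.entries}, fasta_path)
        pd.DataFrame(
            [
                {
                    "ref_id": e.ref_id,
                    "species": e.species,
                    "genus": e.genus,
                    "family": e.family,
                    "order": e.order,
                    "superorder": e.superorder,
                    "class": e.class_,
                    "category": e.category,
                }
                for e in self.entries
            ]
        ).to_csv(taxonomy_path, index=False)

    @classmethod
    def from_files(cls, fasta_path: str | Path, taxonomy_path: str | Path) -> "MiniBarcodeReference":
        seqs = read_fasta(fasta_path)
        tax = pd.read_csv(taxonomy_path)
        entries = []
        for row in tax.to_dict("records"):
            if row["ref_id"] not in seqs:
                raise ConfigError(f"taxonomy entry {row['ref_id']} missing from FASTA")
            entries.append(
                RefEntry(
                    ref_id=row["ref_id"],
                    species=row["species"],
                    genus=row["genus"],
                    family=row["family"],
                    order=row["order"],
                    superorder=row["superorder"],
                    class_=row["class"],
                    category=row["category"],
                    sequence=seqs[row["ref_id"]],
                )
            )
        return cls(entries)


@dataclass
class VariantAssignment:
    variant_id: str
    best_identity: float
    assigned_taxon: str
    assigned_rank: str  # one of RANKS or "unidentified"
    tier_used: float | None
    ambiguous: bool
    category: str = "uncategorised"


# ---------------------------------------------------------------------------
# alignment

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # unit match/mismatch/gap scores; terminal gaps are free (end-free global)
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aligner.open_end_insertion_score = 0
    aligner.extend_end_insertion_score = 0
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(query: str, reference: str) -> float:
    """Percent identity under end-gap-free global alignment, unit scoring.

    The denominator is the number of alignment columns spanned by the aligned
    region (internal gaps count against identity, terminal overhangs do not).
    ``N`` matches nothing.  Co-optimal alignments can place gaps differently;
    the arguments are ordered canonically before aligning so the reported
    identity is symmetric by construction.
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    q = query.upper()
    r = reference.upper()
    bad = set(q + r) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)}")
    if q == r and "N" not in q:
        return 100.0
    if q > r:  # symmetry: score ties resolve identically for (a, b) and (b, a)
        q, r = r, q
    aln = _ALIGNER.align(r, q)[0]
    segs_t, segs_q = aln.aligned
    if len(segs_t) == 0:
        return 0.0
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(segs_t, segs_q):
        if prev_t_end is not None:
            columns += (t0 - prev_t_end) + (q0 - prev_q_end)  # internal gaps
        for i in range(t1 - t0):
            bt, bq = r[t0 + i], q[q0 + i]
            columns += 1
            if bt == bq and bt != "N":
                matches += 1
        prev_t_end, prev_q_end = t1, q1
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# tiered assignment

def _lca(entries: Sequence[RefEntry]) -> tuple[str, str]:
    """(taxon, rank) of the lowest common ancestor of reference hits."""
    for rank in RANKS:
        values = {e.lineage()[rank] for e in entries}
        if len(values) == 1:
            return values.pop(), rank
    # different superorders: fall back to the shared class, or the subphylum
    classes = {e.class_ for e in entries}
    taxon = classes.pop() if len(classes) == 1 else "Vertebrata"
    return taxon, "superorder"


def assign_variant(
    variant: str,
    reference: MiniBarcodeReference,
    tiers: Mapping[str, Sequence[float]] | None = None,
    vid: str | None = None,
) -> VariantAssignment:
    """Assign one variant sequence by tier descent with LCA tie-breaking.

    The tier list (prey vs processed) is chosen from the best hit's reference
    category; ties across categories use the stricter prey tiers.
    """
    if len(reference) == 0:
        raise ConfigError("empty reference")
    tiers = tiers or DEFAULT_TIERS
    vid = vid or variant_id(variant)

    idents = [(percent_identity(variant, e.sequence), e) for e in reference.entries]
    best_identity = max(i for i, _ in idents)
    best_entries = [e for i, e in idents if i >= best_identity - _EPS]
    tier_classes = {_TIER_CLASS[e.category] for e in best_entries}
    tier_class = "prey" if "prey" in tier_classes else "processed"
    tier_list = sorted(tiers[tier_class], reverse=True)

    for tier in tier_list:
        hits = [e for i, e in idents if i >= tier - _EPS]
        if not hits:
            continue
        taxon, rank = _lca(hits)
        return VariantAssignment(
            variant_id=vid,
            best_identity=best_identity,
            assigned_taxon=taxon,
            assigned_rank=rank,
            tier_used=tier,
            ambiguous=len({e.species for e in hits}) > 1,
        )
    return VariantAssignment(
        variant_id=vid,
        best_identity=best_identity,
        assigned_taxon="",
        assigned_rank="unidentified",
        tier_used=None,
        ambiguous=False,
    )


def classify_category(
    assignment: VariantAssignment,
    category_map: Mapping[str, str],
) -> str:
    """Map an assigned taxon (at its rank) to a food-item category.

    ``category_map`` covers taxon names at every rank that can be assigned
    (e.g. both "Sus scrofa" and "Sus"); game species are mapped to
    human_linked by the map itself when the study design calls for it.
    Unknown taxa go to an explicit "uncategorised" bucket, never silently.
    """
    if assignment.assigned_rank == "unidentified":
        return "unidentified"
    category = category_map.get(assignment.assigned_taxon)
    if category is None:
        return "uncategorised"
    return category


def default_category_map(reference: MiniBarcodeReference) -> dict[str, str]:
    """Category lookup derived from the reference library.

    Species map to their reference category (recoded to occurrence-level
    labels) and every ancestral taxon inherits a category when all its
    descendant references agree.
    """
    recode = {
        "prey_candidate": "prey_item",
        "human_linked_candidate": "human_linked",
        "predator": "predator",
        "human": "human",
        "alien_control": "alien_control",
    }
    by_taxon: dict[str, set[str]] = {}
    for e in reference.entries:
        for rank in RANKS:
            by_taxon.setdefault(e.lineage()[rank], set()).add(recode[e.category])
        by_taxon.setdefault(e.class_, set()).add(recode[e.category])
    return {t: cats.pop() for t, cats in by_taxon.items() if len(cats) == 1}


def ancestor_sets(reference: MiniBarcodeReference) -> dict[str, set]:
    """species -> the set of its ancestral taxon names (genus .. class)."""
    out: dict[str, set] = {}
    for e in reference.entries:
        out[e.species] = {e.genus, e.family, e.order, e.superorder, e.class_}
    return out


def assign_table(
    variant_sequences: Mapping[str, str],
    reference: MiniBarcodeReference,
    tiers: Mapping[str, Sequence[float]] | None = None,
    category_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Assign every variant; returns the assignments table (one row each)."""
    category_map = category_map if category_map is not None else default_category_map(reference)
    rows = []
    for vid, seq in variant_sequences.items():
        a = assign_variant(seq, reference, tiers=tiers, vid=vid)
        a.category = classify_category(a, category_map)
        rows.append(
            {
                "variant_id": a.variant_id,
                "identity": round(a.best_identity, 4),
                "taxon": a.assigned_taxon,
                "rank": a.assigned_rank,
                "tier": a.tier_used,
                "ambiguous": a.ambiguous,
                "category": a.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "identity", "taxon", "rank", "tier", "ambiguous", "category"],
    )
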