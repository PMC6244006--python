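"""Read-level and table-level input/output.

Reduces raw amplicon reads to per-PCR-product variant count tables:
quality-aware merging of read pairs, demultiplexing on inline 7-bp tags with
IUPAC-degenerate primer matching, and exact-sequence dereplication.  Variants
are exact sequences (haplotype-level analysis); no OTU/ASV clustering is
performed here.
"""

from __future__ import annotations

import gzip
import hashlib
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

ROLES = ("sample", "alien_control", "negative_extraction", "negative_pcr")

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class FormatError(ValueError):
    """Malformed sequence/quality input."""


class ConfigError(ValueError):
    """Inconsistent run configuration (duplicate tags, bad thresholds...)."""


@dataclass(frozen=True)
class PCRProduct:
    """One PCR reaction: a sample x platform x replicate cell of the design.

    ``tag_pair`` is the (forward, reverse) 7-mer multiplex identifier pair;
    it may be None for count-table inputs where demultiplexing already
    happened upstream (e.g. dual-index dialects, where the pair is abstract).
    """

    product_id: str
    sample_id: str
    platform: str
    replicate_index: int = 1
    role: str = "sample"
    tag_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown role {self.role!r}")
        if self.replicate_index < 1:
            raise ConfigError("replicate_index must be >= 1")


def variant_id(sequence: str) -> str:
    """Stable identifier for an exact sequence variant (hash-derived)."""
    return "v" + hashlib.sha1(sequence.upper().encode()).hexdigest()[:10]


@dataclass
class ReadCountTable:
    """PCR-product x variant matrix of non-negative integer read counts.

    ``counts`` is indexed by product_id with variant ids as columns.  The
    per-variant run total N_i (the quantity the T_FA threshold scales with)
    is the column sum.
    """

    counts: pd.DataFrame
    run_id: str = "run"
    variant_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise FormatError("negative counts")
        self.counts = self.counts.astype(int)

    @property
    def variant_run_totals(self) -> pd.Series:
        """N_i: total reads in the run for each variant."""
        return self.counts.sum(axis=0)

    @property
    def products(self) -> list[str]:
        return list(self.counts.index)

    @property
    def variants(self) -> list[str]:
        return list(self.counts.columns)

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "product_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, run_id: str = "run",
                 variant_sequences: dict[str, str] | None = None) -> "ReadCountTable":
        df = pd.read_csv(path, sep="\t", index_col="product_id")
        return cls(df, run_id=run_id, variant_sequences=variant_sequences or {})


# ---------------------------------------------------------------------------
# read-pair merging

def merge_read_pair(
    seq1: str,
    qual1: Sequence[int],
    seq2: str,
    qual2: Sequence[int],
    min_overlap: int = 20,
    min_identity: float = 0.8,
) -> tuple[str, list[int]] | None:
    """Merge a read pair into a quality-corrected consensus.

    The reverse mate is reverse-complemented, the best ungapped overlap with
    the forward mate is located, and at each disagreeing overlap position the
    base with the higher quality score is kept (equal qualities give ``N``).
    Returns None when no overlap of at least ``min_overlap`` bases reaches
    ``min_identity``.
    """
    if len(seq1) != len(qual1) or len(seq2) != len(qual2):
        raise FormatError("sequence/quality length mismatch")
    if not seq1 or not seq2:
        raise FormatError("empty mate")
    s1 = seq1.upper()
    s2 = str(Seq(seq2.upper()).reverse_complement())
    q2 = list(qual2)[::-1]
    q1 = list(qual1)

    best = None  # (matches, overlap_len, offset)
    # offset = start position of s2 within s1 coordinates (may exceed len(s1)-len(s2))
    for offset in range(len(s1) - min_overlap, -1, -1):
        ov = min(len(s1) - offset, len(s2))
        if ov < min_overlap:
            continue
        matches = sum(1 for i in range(ov) if s1[offset + i] == s2[i])
        key = (matches, ov, -offset)
        if best is None or key > best[0]:
            best = (key, offset, ov, matches)
    if best is None:
        return None
    _, offset, ov, matches = best
    if matches / ov < min_identity:
        return None

    cons, quals = list(s1[:offset]), q1[:offset]
    for i in range(ov):
        b1, b2 = s1[offset + i], s2[i]
        p1, p2 = q1[offset + i], q2[i]
        if b1 == b2:
            cons.append(b1)
            quals.append(max(p1, p2))
        elif p1 > p2:
            cons.append(b1)
            quals.append(p1)
        elif p2 > p1:
            cons.append(b2)
            quals.append(p2)
        else:
            cons.append("N")
            quals.append(min(p1, p2))
    cons.append(s2[ov:])
    quals.extend(q2[ov:])
    return "".join(cons), quals


# ---------------------------------------------------------------------------
# demultiplexing

def iupac_mismatches(pattern: str, window: str) -> int:
    """Number of positions where ``window`` violates the degenerate pattern."""
    if len(pattern) != len(window):
        raise FormatError("pattern/window length mismatch")
    return sum(1 for p, b in zip(pattern, window) if b not in IUPAC.get(p, ""))


def demultiplex(
    reads: Iterable[str],
    products: Sequence[PCRProduct],
    primer_pair: tuple[str, str],
    max_primer_mismatch: int = 1,
    max_spacer: int = 3,
) -> tuple[dict[str, list[str]], Counter]:
    """Assign reads to PCR products by exact inline tag match.

    A read is assigned iff both the forward and the (reverse-complemented)
    reverse 7-bp tag match exactly and both primers match their degenerate
    pattern with at most ``max_primer_mismatch`` mismatches; 0-3 bp
    heterogeneity spacers between tag and primer are consumed.  Reads lacking
    a valid reverse tag are truncated amplicons and are tallied, not assigned.
    Tags are deliberately matched without mismatch rescue: the residual
    cross-assignment is what the downstream T_FA model corrects.

    Returns (product_id -> trimmed inserts, discard log by reason).
    """
    tag_map: dict[tuple[str, str], str] = {}
    for p in products:
        if p.tag_pair is None:
            raise ConfigError(f"product {p.product_id} has no tag pair")
        if p.tag_pair in tag_map:
            raise ConfigError(f"duplicate tag pair {p.tag_pair}")
        tag_map[p.tag_pair] = p.product_id

    fwd_primer, rev_primer = (pr.upper() for pr in primer_pair)
    rev_primer_rc = str(Seq(rev_primer).reverse_complement())
    tag_len = len(next(iter(tag_map))[0])
    fwd_tags = {t for t, _ in tag_map}
    rev_tags = {t for _, t in tag_map}

    assigned: dict[str, list[str]] = {p.product_id: [] for p in products}
    log: Counter = Counter()

    for read in reads:
        read = read.upper()
        fwd_tag = read[:tag_len]
        if fwd_tag not in fwd_tags:
            log["no_forward_tag"] += 1
            continue
        # locate forward primer after an optional heterogeneity spacer
        f_end = None
        f_mm = None
        for spacer in range(max_spacer + 1):
            start = tag_len + spacer
            window = read[start:start + len(fwd_primer)]
            if len(window) < len(fwd_primer):
                break
            mm = iupac_mismatches(fwd_primer, window)
            if f_mm is None or mm < f_mm:
                f_mm, f_end = mm, start + len(fwd_primer)
            if mm == 0:
                break
        if f_mm is None or f_mm > max_primer_mismatch:
            log["primer_mismatch"] += 1
            continue
        # reverse tag sits reverse-complemented at the very end of the read
        rev_tag = str(Seq(read[-tag_len:]).reverse_complement())
        if rev_tag not in rev_tags:
            log["truncated"] += 1
            continue
        if (fwd_tag, rev_tag) not in tag_map:
            log["unknown_tag_combination"] += 1
            continue
        # reverse primer (reverse-complemented) just before the reverse tag,
        # again with an optional spacer
        r_start = None
        r_mm = None
        for spacer in range(max_spacer + 1):
            end = len(read) - tag_len - spacer
            window = read[end - len(rev_primer_rc):end]
            if len(window) < len(rev_primer_rc):
                break
            mm = _rc_pattern_mismatches(rev_primer, window)
            if r_mm is None or mm < r_mm:
                r_mm, r_start = mm, end - len(rev_primer_rc)
            if mm == 0:
                break
        if r_mm is None or r_mm > max_primer_mismatch:
            log["primer_mismatch"] += 1
            continue
        insert = read[f_end:r_start]
        if not insert:
            log["empty_insert"] += 1
            continue
        assigned[tag_map[(fwd_tag, rev_tag)]].append(insert)
        log["assigned"] += 1
    return assigned, log


_RC = {"A": "T", "C": "G", "G": "C", "T": "A",
       "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
       "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


def _rc_pattern_mismatches(pattern: str, window: str) -> int:
    rc_pattern = "".join(_RC[c] for c in reversed(pattern))
    return iupac_mismatches(rc_pattern, window)


# ---------------------------------------------------------------------------
# dereplication

def dereplicate(
    reads_by_product: Mapping[str, Sequence[str]],
    run_id: str = "run",
) -> ReadCountTable:
    """Collapse identical trimmed sequences into variants.

    Variant ids are sequence-hash derived, so they are stable across runs and
    across input orderings; column sums reproduce the input read counts.
    Empty input yields an empty table.
    """
    rows: dict[str, Counter] = {}
    seqs: dict[str, str] = {}
    for product, reads in reads_by_product.items():
        c: Counter = Counter()
        for r in reads:
            vid = variant_id(r)
            seqs[vid] = r.upper()
            c[vid] += 1
        rows[product] = c
    variants = sorted(seqs)
    df = pd.DataFrame(
        [[rows[p].get(v, 0) for v in variants] for p in rows],
        index=list(rows),
        columns=variants,
        dtype=int,
    )
    df.index.name = "product_id"
    return ReadCountTable(df, run_id=run_id, variant_sequences=seqs)


# ---------------------------------------------------------------------------
# file formats

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read (id, sequence, phred qualities) records; gzip accepted."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [
            (rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{name}\n{seq}\n+\n{qstr}\n")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = {"product_id", "sample_id", "platform", "replicate", "role"}
    missing = required - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(sheet["role"]) - set(ROLES)
    if bad:
        raise FormatError(f"unknown roles in sample sheet: {sorted(bad)}")
    return sheet


def products_from_sheet(sheet: pd.DataFrame) -> list[PCRProduct]:
    out = []
    for row in sheet.itertuples(index=False):
        tag_pair = None
        if "fwd_tag" in sheet.columns and isinstance(row.fwd_tag, str):
            tag_pair = (row.fwd_tag, row.rev_tag)
        out.append(
            PCRProduct(
                product_id=row.product_id,
                sample_id=row.sample_id,
                platform=row.platform,
                replicate_index=int(row.replicate),
                role=row.role,
                tag_pair=tag_pair,
            )
        )
    return out
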