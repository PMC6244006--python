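"""False-assignment thresholds and replicate-concordance filtering.

Tag jumping (index hopping / mixed clusters) moves a small fraction of reads
between PCR products of the same sequencing run, creating false positive
occurrences.  An alien control — a haplotype handled separately from the
study samples, whose reads can only appear in them through cross-assignment —
lets that rate be measured per run:

    R_FA  = max over non-source products of the alien variant's count
            / the alien variant's run total

Because misassignment scales with a variant's abundance, the positivity
threshold for variant i with run total N_i is

    T_FA_i = ceil(N_i * R_FA)

and a PCR product is positive for i only when its count strictly exceeds
T_FA_i.  Surviving positives must then be concordant across technical PCR
replicates (>= min_fraction of the replicate set) to become occurrences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .seqio import ConfigError, ReadCountTable

_CEIL_EPS = 1e-9


class EstimationError(ValueError):
    """The alien control carries no signal (zero run total)."""


@dataclass
class FilterThresholds:
    """Run-level false-assignment rate and the per-variant thresholds."""

    run_id: str
    r_fa: float  # stored as a fraction; printed as percent in reports
    t_fa: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_fa <= 1.0:
            raise ConfigError("R_FA must be in [0, 1]")
        if any(v < 0 for v in self.t_fa.values()):
            raise ConfigError("T_FA thresholds must be non-negative")

    def to_frame(self, run_totals: Mapping[str, int] | None = None) -> pd.DataFrame:
        rows = [
            {
                "variant_id": v,
                "N_i": int(run_totals[v]) if run_totals is not None else None,
                "T_FA": t,
            }
            for v, t in self.t_fa.items()
        ]
        return pd.DataFrame(rows, columns=["variant_id", "N_i", "T_FA"])


@dataclass
class PositivityMatrix:
    """Product x variant boolean calls, with the inputs that produced them."""

    matrix: pd.DataFrame
    thresholds: FilterThresholds

    @property
    def products(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def variants(self) -> list[str]:
        return list(self.matrix.columns)


def estimate_rfa(
    counts: ReadCountTable,
    alien_variant: str,
    alien_source_products: Iterable[str],
) -> float:
    """Estimate the run false-assignment rate from the alien control.

    R_FA = (maximal alien count in any product that is not an alien source)
    divided by the alien variant's run total; 0 when the alien never leaks.
    """
    if alien_variant not in counts.counts.columns:
        raise EstimationError(f"alien variant {alien_variant} absent from run")
    sources = set(alien_source_products)
    unknown = sources - set(counts.counts.index)
    if unknown:
        raise ConfigError(f"alien source products not in table: {sorted(unknown)}")
    col = counts.counts[alien_variant]
    n_alien = int(col.sum())
    if n_alien == 0:
        raise EstimationError("alien variant has zero reads in the run")
    outside = col[~col.index.isin(sources)]
    max_misassigned = int(outside.max()) if len(outside) else 0
    return max_misassigned / n_alien


def compute_tfa(counts: ReadCountTable, r_fa: float) -> FilterThresholds:
    """T_FA_i = ceil(N_i * R_FA) for every variant i in the run.

    Ceiling is the conservative choice for non-integer products: it never
    admits a count that the exact (real-valued) threshold would reject.
    """
    if not 0.0 <= r_fa <= 1.0:
        raise ConfigError("R_FA must be in [0, 1]")
    totals = counts.variant_run_totals
    t_fa = {
        v: int(math.ceil(int(n) * r_fa - _CEIL_EPS)) if n > 0 else 0
        for v, n in totals.items()
    }
    return FilterThresholds(run_id=counts.run_id, r_fa=r_fa, t_fa=t_fa)


def call_positives(counts: ReadCountTable, thresholds: FilterThresholds) -> PositivityMatrix:
    """Positive iff count strictly exceeds T_FA_i.

    The strict inequality reconciles the threshold definition ("the read
    number above which the product is positive") with the documented case of
    5 reads at T_FA = 5 being a (false) negative.  As a masking operation on
    counts the call is idempotent.
    """
    missing = set(counts.counts.columns) - set(thresholds.t_fa)
    if missing:
        raise ConfigError(f"variants without thresholds: {sorted(missing)[:5]}")
    thr = pd.Series(
        {v: thresholds.t_fa[v] for v in counts.counts.columns}, dtype=int
    )
    matrix = counts.counts.gt(thr, axis=1)
    return PositivityMatrix(matrix=matrix, thresholds=thresholds)


def replicate_filter(
    positives: PositivityMatrix,
    sheet: pd.DataFrame,
    min_fraction: float = 0.5,
    variant_to_taxon: Mapping[str, str] | None = None,
    within_platform: bool = False,
    roles: Iterable[str] = ("sample",),
) -> pd.DataFrame:
    """Collapse replicate-level positives into occurrence calls.

    Product-level variant positives are OR-ed per taxon (thresholds are
    defined per variant, so filtering precedes the taxon collapse), then a
    (sample, taxon) occurrence is retained iff the fraction of positive
    replicates in the grouping unit reaches ``min_fraction``.  With
    ``within_platform`` the unit is (sample, platform) — the per-platform
    tables; otherwise all replicates of a sample are pooled.

    Returns a long table: sample_id [, platform], taxon, n_positive,
    n_replicates, retained.  Per-replicate support is preserved so reports
    can show one-replicate vs two-replicate columns.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ConfigError("min_fraction must be in (0, 1]")
    sheet = sheet[sheet["role"].isin(set(roles))]
    if sheet.empty:
        raise ConfigError("empty replicate set: no products with requested roles")
    mat = positives.matrix.loc[positives.matrix.index.intersection(sheet["product_id"])]
    if variant_to_taxon:
        taxa = pd.Index([variant_to_taxon.get(v, v) for v in mat.columns])
        mat = mat.T.groupby(taxa).any().T
    taxa_cols = list(mat.columns)
    mat.columns.name = "taxon"
    meta = sheet.set_index("product_id")[["sample_id", "platform"]]
    joined = mat.join(meta, how="left")
    keys = ["sample_id", "platform"] if within_platform else ["sample_id"]
    grouped = joined.groupby(keys)
    n_pos = grouped[taxa_cols].sum()
    n_pos.columns.name = "taxon"
    n_rep = grouped.size()
    long = n_pos.stack().rename("n_positive").reset_index()
    long["n_positive"] = long["n_positive"].astype(int)
    long = long.merge(n_rep.rename("n_replicates").reset_index(), on=keys)
    long["retained"] = long["n_positive"] / long["n_replicates"] >= min_fraction - 1e-12
    long = long[long["n_positive"] > 0].reset_index(drop=True)
    return long[keys + ["taxon", "n_positive", "n_replicates", "retained"]]


def screen_controls(
    occurrences: pd.DataFrame,
    sheet: pd.DataFrame,
    taxon_categories: Mapping[str, str],
    food_categories: Iterable[str] = ("prey_item", "human_linked"),
) -> dict:
    """Check that no food taxon survives filtering in a negative control.

    Negative extraction/PCR controls legitimately carry low-level human and
    predator contamination; any retained *food* occurrence there indicates a
    filtering failure and is flagged (with a warning, not a hard stop).
    """
    control_samples = set(
        sheet.loc[sheet["role"].isin({"negative_extraction", "negative_pcr"}), "sample_id"]
    )
    if not control_samples:
        return {"status": "no_controls", "flagged": occurrences.iloc[0:0]}
    occ = occurrences[
        occurrences["sample_id"].isin(control_samples) & occurrences["retained"]
    ]
    food = set(food_categories)
    flagged = occ[
        occ["taxon"].map(lambda t: taxon_categories.get(t, "uncategorised")).isin(food)
    ]
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} food-taxon occurrence(s) survive in negative controls",
            stacklevel=2,
        )
        return {"status": "flagged", "flagged": flagged.reset_index(drop=True)}
    return {"status": "ok", "flagged": flagged.reset_index(drop=True)}
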