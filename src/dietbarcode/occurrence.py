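"""Expected vs observed occurrences and the diet detection metrics.

The calibration study feeds a housebound cat a known, weighed diet and
collects one scat per day.  Given a >= 12 h gut transit time, each distinct
(meal-day, taxon) event is expected to appear in the earliest scat emitted at
least 12 h after ingestion — the "minimum expected occurrence".  Observed
occurrences come from the filtered occurrence tables; detection rates,
frequency of occurrence, per-sample success fractions and read-vs-biomass
proportions are the study's summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FOOD_CATEGORIES = ("prey", "pet_food", "raw_fish_meat")

#: occurrence categories whose taxa cannot be tied to independent ingestion
#: events (pet food mixes several taxa), so category-level comparisons count
#: them once per sample with the taxon-level multiplicity reported in brackets
MULTI_TAXON_CATEGORIES = ("human_linked", "pet_food", "raw_fish_meat", "anthropogenic")


@dataclass
class DetectionSummary:
    """Expected vs observed occurrence counts for one food category."""

    category: str
    expected: int
    observed_total: int
    observed_by_support: dict[int, int] = field(default_factory=dict)
    detection_rate: float | None = None  # integer percent, None when expected == 0


# ---------------------------------------------------------------------------
# expected occurrences (truth table)

def expected_occurrences(
    schedule: pd.DataFrame,
    scats: pd.DataFrame,
    lag_window: tuple[float, float] = (12.0, 24.0),
) -> pd.DataFrame:
    """Map feeding events onto the scats where their DNA is expected.

    ``schedule`` columns: meal_time (datetime), taxon, category, mass_g.
    ``scats`` columns: sample_id, emission_time (datetime).

    One event per distinct (meal-day, taxon); the event's reference time is
    the first meal of that taxon that day, and it maps to the earliest scat
    emitted >= min_h hours later.  Events with no such scat are undetectable
    and excluded (with a warning).  Returns one row per event: sample_id,
    taxon, category, meal_date.
    """
    min_h, max_h = lag_window
    if not min_h < max_h:
        raise ValueError("lag window must satisfy min < max")
    if schedule.empty:
        return pd.DataFrame(columns=["sample_id", "taxon", "category", "meal_date"])
    sched = schedule.copy()
    sched["meal_time"] = pd.to_datetime(sched["meal_time"])
    sched["meal_date"] = sched["meal_time"].dt.date
    events = (
        sched.sort_values("meal_time")
        .groupby(["meal_date", "taxon"], as_index=False)
        .first()[["meal_date", "taxon", "category", "meal_time"]]
    )
    sc = scats.copy()
    sc["emission_time"] = pd.to_datetime(sc["emission_time"])
    sc = sc.sort_values("emission_time")

    rows = []
    undetectable = 0
    for ev in events.itertuples(index=False):
        earliest = ev.meal_time + pd.Timedelta(hours=min_h)
        after = sc[sc["emission_time"] >= earliest]
        if after.empty:
            undetectable += 1
            continue
        rows.append(
            {
                "sample_id": after.iloc[0]["sample_id"],
                "taxon": ev.taxon,
                "category": ev.category,
                "meal_date": ev.meal_date,
            }
        )
    if undetectable:
        warnings.warn(
            f"{undetectable} feeding event(s) had no scat >= {min_h} h later; "
            "excluded from the expected-occurrence denominator",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["sample_id", "taxon", "category", "meal_date"])


# ---------------------------------------------------------------------------
# observed-occurrence summaries

def detection_rate(
    truth: pd.DataFrame,
    occurrences: pd.DataFrame,
    category: str,
) -> DetectionSummary:
    """Observed / minimum-expected occurrences for one food category.

    The numerator counts retained (sample, taxon) occurrences of the
    category, so carry-over detections in later scats are counted as observed
    without inflating the expected denominator; overshoot past 100 % is
    therefore possible.  Rates are reported as integer percent.
    """
    expected = int((truth["category"] == category).sum()) if len(truth) else 0
    occ = occurrences[occurrences["category"] == category] if len(occurrences) else occurrences
    if len(occ) and "retained" in occ.columns:
        occ = occ[occ["retained"]]
    observed = int(len(occ))
    by_support: dict[int, int] = {}
    if len(occ) and "n_positive" in occ.columns:
        by_support = occ["n_positive"].value_counts().astype(int).to_dict()
    rate = None if expected == 0 else round(100.0 * observed / expected)
    return DetectionSummary(
        category=category,
        expected=expected,
        observed_total=observed,
        observed_by_support=by_support,
        detection_rate=rate,
    )


def tabulate(
    occurrences: pd.DataFrame,
    platforms: Sequence[str] | None = None,
) -> dict:
    """Occurrence counts in the calibration/field report layout.

    ``occurrences`` is a long per-platform table with columns sample_id,
    taxon, category, platform, n_positive (replicates supporting the call),
    retained, and optionally pooled_retained (the pooled cross-platform
    call for the (sample, taxon) pair).

    Returns ``by_taxon`` (per platform: occurrences seen in exactly one and
    in two replicates, and their total, plus the pooled column) and
    ``by_category``: prey taxa and game species count one occurrence per
    (sample, taxon) whereas anthropogenic food counts one occurrence per
    sample — credited to the two-replicate column when any of its taxa
    replicated — with the taxon-level multiplicity reported separately.
    """
    if occurrences.empty:
        empty = pd.DataFrame()
        return {"by_taxon": empty, "by_category": empty, "multiplicity": {}}
    occ = occurrences[occurrences["retained"]].copy()
    platforms = list(platforms or sorted(occ["platform"].unique()))

    # per-taxon layout
    by_taxon_rows = []
    for (category, taxon), df_t in occ.groupby(["category", "taxon"]):
        row: dict = {"category": category, "taxon": taxon}
        for plat in platforms:
            sub = df_t[df_t["platform"] == plat]
            support = sub.groupby("sample_id")["n_positive"].max()
            row[f"{plat}_one"] = int((support == 1).sum())
            row[f"{plat}_two"] = int((support >= 2).sum())
            row[f"{plat}_total"] = int(len(support))
        row["pooled_total"] = int(df_t["sample_id"].nunique())
        by_taxon_rows.append(row)
    by_taxon = pd.DataFrame(by_taxon_rows)

    # per-category layout with the anthropogenic multiplicity rule
    by_cat_rows = []
    multiplicity: dict[str, int] = {}
    for category, df_c in occ.groupby("category"):
        row = {"category": category}
        per_sample = category in MULTI_TAXON_CATEGORIES
        for plat in platforms:
            sub = df_c[df_c["platform"] == plat]
            if per_sample:
                support = sub.groupby("sample_id")["n_positive"].max()
            else:
                support = sub.groupby(["sample_id", "taxon"])["n_positive"].max()
            row[f"{plat}_one"] = int((support == 1).sum())
            row[f"{plat}_two"] = int((support >= 2).sum())
            row[f"{plat}_total"] = int(len(support))
        if per_sample:
            row["pooled_total"] = int(df_c["sample_id"].nunique())
            multiplicity[category] = int(
                df_c.groupby(["sample_id", "taxon"]).ngroups
            )
        else:
            row["pooled_total"] = int(df_c.groupby(["sample_id", "taxon"]).ngroups)
        by_cat_rows.append(row)
    by_category = pd.DataFrame(by_cat_rows)
    return {"by_taxon": by_taxon, "by_category": by_category, "multiplicity": multiplicity}


def pool_union(per_platform: pd.DataFrame) -> pd.DataFrame:
    """Pooled occurrence set as the union of per-platform retained calls.

    Input is the long per-platform table (sample_id, taxon, platform,
    n_positive, retained, ...); output has one row per (sample, taxon) with
    ``<platform>_retained`` flags and a ``pooled_retained`` column that is
    their logical OR.
    """
    occ = per_platform.copy()
    flags = (
        occ.assign(retained=occ["retained"].astype(bool))
        .pivot_table(index=["sample_id", "taxon"], columns="platform",
                     values="retained", aggfunc="any", fill_value=False)
    )
    flags.columns = [f"{p}_retained" for p in flags.columns]
    flags["pooled_retained"] = flags.any(axis=1)
    return flags.reset_index()


def samples_with_any_item(
    occurrences: pd.DataFrame,
    sample_universe: Iterable[str],
    food_categories: Iterable[str] = ("prey_item", "human_linked", "prey", "pet_food", "raw_fish_meat"),
) -> tuple[int, float | None]:
    """(count, percent) of samples containing at least one identified food item.

    The universe excludes samples not attributable to the target predator.
    Percent reported to 1 decimal; None for an empty universe.
    """
    universe = list(dict.fromkeys(sample_universe))
    if not universe:
        return 0, None
    occ = occurrences
    if len(occ) and "retained" in occ.columns:
        occ = occ[occ["retained"]]
    if len(occ) and "category" in occ.columns:
        occ = occ[occ["category"].isin(set(food_categories))]
    positive = set(occ["sample_id"]) & set(universe) if len(occ) else set()
    count = len(positive)
    return count, round(100.0 * count / len(universe), 1)


def frequency_of_occurrence(
    occurrences: pd.DataFrame,
    sample_universe: Iterable[str],
) -> pd.DataFrame:
    """Per-taxon frequency of occurrence: % of universe samples with the taxon."""
    universe = list(dict.fromkeys(sample_universe))
    occ = occurrences
    if len(occ) and "retained" in occ.columns:
        occ = occ[occ["retained"]]
    if not universe:
        return pd.DataFrame(columns=["taxon", "n_samples", "fo_percent"])
    counts = (
        occ[occ["sample_id"].isin(set(universe))]
        .groupby("taxon")["sample_id"]
        .nunique()
        if len(occ)
        else pd.Series(dtype=int)
    )
    return pd.DataFrame(
        {
            "taxon": counts.index,
            "n_samples": counts.values.astype(int) if len(counts) else [],
            "fo_percent": (
                np.round(100.0 * counts.values / len(universe), 1) if len(counts) else []
            ),
        }
    ).reset_index(drop=True)


def platform_agreement(occurrences: pd.DataFrame) -> tuple[int, int, float | None]:
    """(jointly confirmed, total, percent) of occurrences seen by both platforms.

    ``occurrences`` needs one row per (sample, taxon) with boolean columns for
    each platform's retained call (any column ending in ``_retained``).
    """
    flag_cols = [c for c in occurrences.columns if c.endswith("_retained")]
    if not flag_cols:
        raise ValueError("no *_retained platform columns")
    any_p = occurrences[flag_cols].any(axis=1)
    both = occurrences[flag_cols].all(axis=1)
    total = int(any_p.sum())
    joint = int((both & any_p).sum())
    return joint, total, (round(100.0 * joint / total, 1) if total else None)


def rank_share(occurrences: pd.DataFrame, rank: str = "species") -> tuple[int, int, float | None]:
    """(count, total, percent) of occurrences identified at the given rank."""
    if "rank" not in occurrences.columns:
        raise ValueError("occurrence table has no rank column")
    total = int(len(occurrences))
    count = int((occurrences["rank"] == rank).sum())
    return count, total, (round(100.0 * count / total) if total else None)


def read_vs_biomass(
    counts,
    assignments: pd.DataFrame,
    schedule: pd.DataFrame,
    categories: Sequence[str] = FOOD_CATEGORIES,
) -> tuple[pd.Series, pd.Series]:
    """Paired (biomass, read) proportion vectors over the food categories.

    Only reads assigned to food taxa enter the read denominator (predator,
    human, alien-control and unidentified reads are excluded).  Returns
    (biomass proportions, read proportions); the read vector is all-NaN when
    no food reads remain.
    """
    biomass = schedule.groupby("category")["mass_g"].sum()
    biomass = biomass.reindex(categories, fill_value=0.0)
    total_mass = biomass.sum()
    biomass_prop = biomass / total_mass if total_mass > 0 else biomass * np.nan

    cat_of = assignments.set_index("variant_id")["category"]
    totals = counts.variant_run_totals
    read_counts = pd.Series(0.0, index=list(categories))
    for v, n in totals.items():
        c = cat_of.get(v)
        if c in read_counts.index:
            read_counts[c] += n
    total_reads = read_counts.sum()
    read_prop = read_counts / total_reads if total_reads > 0 else read_counts * np.nan
    return biomass_prop, read_prop


def reconcile_with_truth(
    occurrences: pd.DataFrame,
    truth: pd.DataFrame,
    ancestors: Mapping[str, set],
    fallback_category: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Match occurrence taxa (at any rank) against the truth's species.

    Assignments can legitimately land above species rank (e.g. processed-food
    taxa resolve to genus under the 98/95 tiers), so occurrence/truth
    comparison goes through each truth species' ancestor set: an occurrence
    taxon is compatible with a truth species when it equals the species or
    one of its ancestors.  Each occurrence row gets the food category of the
    truth species it is compatible with (``fallback_category`` covers taxa
    never fed, e.g. reference-derived prey labels); the second return value
    counts retained food occurrences with no compatible truth row in the
    same sample — the false positives that survived filtering.
    """
    fallback_category = fallback_category or {}
    truth_species = list(truth["taxon"].unique()) if len(truth) else []
    cat_of_species = (
        dict(zip(truth["taxon"], truth["category"])) if len(truth) else {}
    )
    expected_pairs = (
        set(zip(truth["sample_id"], truth["taxon"])) if len(truth) else set()
    )

    def compatible_species(taxon: str) -> list[str]:
        return [
            sp for sp in truth_species
            if taxon == sp or taxon in ancestors.get(sp, set())
        ]

    occ = occurrences.copy()
    categories = []
    fp = 0
    for row in occ.itertuples(index=False):
        matches = compatible_species(row.taxon)
        if matches:
            categories.append(cat_of_species[matches[0]])
        else:
            categories.append(fallback_category.get(row.taxon, "uncategorised"))
        if getattr(row, "retained", True) and categories[-1] in FOOD_CATEGORIES:
            in_sample = any((row.sample_id, sp) in expected_pairs for sp in matches)
            if not in_sample:
                fp += 1
    occ["category"] = categories
    return occ, fp


def identify_predator(
    predator_support: pd.DataFrame,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Call each sample's predator from fully replicated predator taxa.

    ``predator_support`` columns: sample_id, taxon, n_positive, n_replicates
    (predator-category taxa only).  A sample's predator is the taxon positive
    in all replicates; no such taxon -> "unresolved", more than one ->
    "ambiguous" (excluded from diet universes either way).
    """
    rows = []
    for sample, df in predator_support.groupby("sample_id"):
        reps = df["n_replicates"] if n_replicates is None else n_replicates
        full = df[df["n_positive"] >= reps]
        if len(full) == 1:
            rows.append({"sample_id": sample, "predator": full.iloc[0]["taxon"], "status": "confirmed"})
        elif len(full) == 0:
            rows.append({"sample_id": sample, "predator": None, "status": "unresolved"})
        else:
            rows.append({"sample_id": sample, "predator": None, "status": "ambiguous"})
    return pd.DataFrame(rows, columns=["sample_id", "predator", "status"])
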