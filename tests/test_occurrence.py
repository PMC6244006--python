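"""Expected-occurrence mapping, report layouts and detection metrics."""

import numpy as np
import pandas as pd
import pytest

from dietbarcode import studydata
from dietbarcode.occurrence import (
    detection_rate,
    expected_occurrences,
    frequency_of_occurrence,
    identify_predator,
    platform_agreement,
    pool_union,
    rank_share,
    read_vs_biomass,
    samples_with_any_item,
    tabulate,
)
from dietbarcode.seqio import ReadCountTable


def scats(times):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(times))],
        "emission_time": pd.to_datetime(times),
    })


def schedule(rows):
    return pd.DataFrame(rows, columns=["meal_time", "taxon", "category", "mass_g"])


class TestExpectedOccurrences:
    def test_twelve_hour_rule_skips_same_day_scat(self):
        sched = schedule([("2012-05-01 08:00", "vole", "prey", 30.0)])
        sc = scats(["2012-05-01 09:00", "2012-05-02 10:00"])
        truth = expected_occurrences(sched, sc)
        assert list(truth["sample_id"]) == ["S1"]

    def test_three_feeding_days_give_three_expected(self):
        rows = [(f"2012-05-0{d} 08:00", "Arvicola terrestris", "prey", 30.0)
                for d in (1, 3, 5)]
        sc = scats([f"2012-05-0{d} 07:00" for d in (2, 4, 6)])
        truth = expected_occurrences(schedule(rows), sc)
        assert len(truth) == 3
        assert set(truth["taxon"]) == {"Arvicola terrestris"}

    def test_multiple_meals_one_day_count_once(self):
        rows = [("2012-05-01 08:00", "vole", "prey", 10.0),
                ("2012-05-01 12:00", "vole", "prey", 10.0),
                ("2012-05-01 17:00", "vole", "prey", 10.0)]
        sc = scats(["2012-05-02 07:00"])
        assert len(expected_occurrences(schedule(rows), sc)) == 1

    def test_event_without_later_scat_excluded_with_warning(self):
        sched = schedule([("2012-05-01 08:00", "vole", "prey", 30.0)])
        sc = scats(["2012-05-01 09:00"])
        with pytest.warns(UserWarning):
            truth = expected_occurrences(sched, sc)
        assert truth.empty

    def test_empty_schedule_gives_empty_truth(self):
        truth = expected_occurrences(schedule([]), scats(["2012-05-02 07:00"]))
        assert truth.empty


class TestDetectionRate:
    def test_calibration_prey_vector(self):
        truth = studydata.calibration_truth()
        occ = studydata.calibration_occurrences()
        s = detection_rate(truth, occ, "prey")
        assert (s.expected, s.observed_total) == (11, 9)
        assert s.detection_rate == 82

    def test_pet_food_and_raw(self):
        truth = studydata.calibration_truth()
        occ = studydata.calibration_occurrences()
        assert detection_rate(truth, occ, "pet_food").detection_rate == 54
        assert detection_rate(truth, occ, "raw_fish_meat").detection_rate == 31

    def test_full_detection_is_100(self):
        truth = pd.DataFrame({"sample_id": ["S1"], "taxon": ["t"],
                              "category": ["prey"], "meal_date": [None]})
        occ = pd.DataFrame({"sample_id": ["S1"], "taxon": ["t"],
                            "category": ["prey"], "retained": [True]})
        assert detection_rate(truth, occ, "prey").detection_rate == 100

    def test_zero_expected_is_na(self):
        truth = pd.DataFrame(columns=["sample_id", "taxon", "category"])
        occ = pd.DataFrame(columns=["sample_id", "taxon", "category", "retained"])
        assert detection_rate(truth, occ, "prey").detection_rate is None

    def test_invariant_to_relabelling(self, rng):
        truth = studydata.calibration_truth()
        occ = studydata.calibration_occurrences()
        relabel = {s: f"Z{i}" for i, s in enumerate(occ["sample_id"].unique())}
        occ2 = occ.assign(sample_id=occ["sample_id"].map(relabel))
        occ2 = occ2.sample(frac=1.0, random_state=0)
        assert (detection_rate(truth, occ2, "prey").detection_rate
                == detection_rate(truth, occ, "prey").detection_rate)


class TestTabulate:
    def test_field_table_reconstruction(self):
        occ = studydata.field_occurrences_long()
        result = tabulate(occ, platforms=["IonPGM", "MiSeq"])
        by_taxon = result["by_taxon"].set_index("taxon")
        rod = by_taxon.loc["Small/medium-sized rodents"]
        assert (rod.MiSeq_one, rod.MiSeq_two, rod.MiSeq_total) == (119, 111, 230)
        prey = by_taxon[by_taxon["category"] == "prey_item"]
        assert prey["MiSeq_total"].sum() == 150 + 126  # == 276
        # layout identity: total = one-replicate + two-replicate counts
        for plat in ("IonPGM", "MiSeq"):
            assert (by_taxon[f"{plat}_total"]
                    == by_taxon[f"{plat}_one"] + by_taxon[f"{plat}_two"]).all()

    def test_anthropogenic_multiplicity_rule(self):
        # one sample: two anthropogenic taxa (one in 2 reps, one in 1) and two
        # prey taxa both replicated -> 1 anthropogenic category occurrence
        # credited to the two-replicate column, multiplicity 2; 2 prey occurrences
        occ = pd.DataFrame([
            ("S1", "Sus sp.", "human_linked", "MiSeq", 2, True),
            ("S1", "Gallus sp.", "human_linked", "MiSeq", 1, True),
            ("S1", "Microtus agrestis", "prey_item", "MiSeq", 2, True),
            ("S1", "Arvicola terrestris", "prey_item", "MiSeq", 2, True),
        ], columns=["sample_id", "taxon", "category", "platform", "n_positive", "retained"])
        result = tabulate(occ, platforms=["MiSeq"])
        by_cat = result["by_category"].set_index("category")
        assert by_cat.loc["human_linked", "MiSeq_total"] == 1
        assert by_cat.loc["human_linked", "MiSeq_two"] == 1
        assert by_cat.loc["prey_item", "MiSeq_total"] == 2
        assert result["multiplicity"]["human_linked"] == 2

    def test_empty_table(self):
        result = tabulate(pd.DataFrame())
        assert result["by_taxon"].empty and result["by_category"].empty


class TestSampleFractions:
    def test_field_pooled_fraction(self):
        occ, universe = studydata.field_sample_outcomes()
        n, pct = samples_with_any_item(occ, universe)
        assert (n, pct) == (285, 87.4)

    def test_per_platform_fractions(self):
        occ, universe = studydata.field_sample_outcomes()
        n_pgm, pct_pgm = samples_with_any_item(occ[occ.platform == "IonPGM"], universe)
        assert (n_pgm, pct_pgm) == (240, 73.6)
        n_ms, pct_ms = samples_with_any_item(occ[occ.platform == "MiSeq"], universe)
        assert (n_ms, pct_ms) == (271, 83.1)

    def test_zero_positive(self):
        occ = pd.DataFrame(columns=["sample_id", "taxon", "category", "retained"])
        assert samples_with_any_item(occ, ["a", "b"]) == (0, 0.0)

    def test_empty_universe_is_na(self):
        occ = pd.DataFrame(columns=["sample_id", "taxon", "category", "retained"])
        assert samples_with_any_item(occ, [])[1] is None


class TestFrequencyAndShares:
    def test_fo_extremes(self):
        occ = pd.DataFrame({
            "sample_id": ["S1", "S2"], "taxon": ["t", "t"], "retained": [True, True],
        })
        fo = frequency_of_occurrence(occ, ["S1", "S2"]).set_index("taxon")
        assert fo.loc["t", "fo_percent"] == 100.0
        fo2 = frequency_of_occurrence(occ.iloc[0:0], ["S1", "S2"])
        assert fo2.empty

    def test_platform_agreement(self):
        flags = studydata.field_prey_platform_flags()
        joint, total, pct = platform_agreement(flags)
        assert (joint, total, pct) == (143, 198, 72.2)

    def test_species_rank_share(self):
        ranks = studydata.field_prey_ranks()
        count, total, pct = rank_share(ranks, "species")
        assert (count, total, pct) == (287, 319, 90)


class TestPoolUnion:
    def test_pooled_set_is_union_of_platform_retained(self, rng):
        rows = []
        for i in range(60):
            rows.append({
                "sample_id": f"S{rng.integers(1, 10)}",
                "taxon": rng.choice(["a", "b", "c"]),
                "platform": rng.choice(["IonPGM", "MiSeq"]),
                "n_positive": int(rng.integers(1, 3)),
                "retained": bool(rng.random() < 0.7),
            })
        occ = pd.DataFrame(rows).drop_duplicates(["sample_id", "taxon", "platform"])
        pooled = pool_union(occ)
        expected_union = set(
            map(tuple, occ.loc[occ["retained"], ["sample_id", "taxon"]].values)
        )
        got = set(
            map(tuple, pooled.loc[pooled["pooled_retained"],
                                  ["sample_id", "taxon"]].values)
        )
        assert got == expected_union
        flag_cols = [c for c in pooled.columns if c.endswith("_retained")
                     and c != "pooled_retained"]
        assert (pooled[flag_cols].any(axis=1) == pooled["pooled_retained"]).all()


class TestReadVsBiomass:
    def _counts(self, values):
        df = pd.DataFrame({v: [n] for v, n in values.items()}, index=["P1"])
        df.index.name = "product_id"
        return ReadCountTable(df, run_id="r")

    def _assign(self, cats):
        return pd.DataFrame({"variant_id": list(cats), "category": list(cats.values())})

    def _sched(self, masses):
        return pd.DataFrame({
            "meal_time": pd.to_datetime(["2012-05-01 08:00"] * len(masses)),
            "taxon": [f"t{i}" for i in range(len(masses))],
            "category": list(masses),
            "mass_g": list(masses.values()),
        })

    def test_single_category_reads_give_indicator(self):
        b, r = read_vs_biomass(
            self._counts({"v1": 100}), self._assign({"v1": "prey"}),
            self._sched({"prey": 10, "pet_food": 10, "raw_fish_meat": 10}),
        )
        assert r["prey"] == 1.0 and r["pet_food"] == 0.0

    def test_equal_reads_and_masses_match(self):
        b, r = read_vs_biomass(
            self._counts({"v1": 50, "v2": 50, "v3": 50}),
            self._assign({"v1": "prey", "v2": "pet_food", "v3": "raw_fish_meat"}),
            self._sched({"prey": 10, "pet_food": 10, "raw_fish_meat": 10}),
        )
        assert np.allclose(b.values, r.values)

    def test_non_food_reads_excluded(self):
        b, r = read_vs_biomass(
            self._counts({"v1": 660, "v2": 330, "v3": 5, "v4": 5}),
            self._assign({"v1": "prey", "v2": "pet_food", "v3": "raw_fish_meat",
                          "v4": "predator"}),
            self._sched({"prey": 10, "pet_food": 10, "raw_fish_meat": 10}),
        )
        assert r["prey"] == pytest.approx(660 / 995)
        assert r.sum() == pytest.approx(1.0)


class TestIdentifyPredator:
    def support(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "taxon", "n_positive", "n_replicates"])

    def test_fully_replicated_cat(self):
        calls = identify_predator(self.support([("S1", "Felis silvestris catus", 4, 4)]))
        assert calls.iloc[0].predator == "Felis silvestris catus"
        assert calls.iloc[0].status == "confirmed"

    def test_dog_sample_confirmed_as_dog(self):
        calls = identify_predator(self.support([
            ("S1", "Canis lupus familiaris", 4, 4),
            ("S1", "Felis silvestris catus", 1, 4),
        ]))
        assert calls.iloc[0].predator == "Canis lupus familiaris"

    def test_tie_is_ambiguous(self):
        calls = identify_predator(self.support([
            ("S1", "Canis lupus familiaris", 4, 4),
            ("S1", "Felis silvestris catus", 4, 4),
        ]))
        assert calls.iloc[0].status == "ambiguous"

    def test_none_replicated_is_unresolved(self):
        calls = identify_predator(self.support([("S1", "Felis silvestris catus", 2, 4)]))
        assert calls.iloc[0].status == "unresolved"

    def test_study_breakdown_fraction(self):
        calls = identify_predator(studydata.field_predator_support())
        frac = (calls["predator"] == "Felis silvestris catus").mean()
        assert round(100 * frac, 1) == 90.8
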