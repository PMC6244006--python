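"""Synthetic reference, feeding trial and sequencing-run generator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dietbarcode import simdata
from dietbarcode.seqio import ConfigError
from dietbarcode.taxassign import percent_identity


def hamming_identity(a, b):
    assert len(a) == len(b)
    return 100 * sum(x == y for x, y in zip(a, b)) / len(a)


class TestGenerateReference:
    def test_zero_counts_leave_only_mandatory_taxa(self):
        ref = simdata.generate_reference(
            {"prey": 0, "pet_food": 0, "raw_fish_meat": 0}, seed=1
        )
        assert len(ref) == 3
        assert {e.category for e in ref.entries} == {"predator", "human", "alien_control"}

    def test_same_seed_same_fasta_bytes(self, tmp_path):
        paths = []
        for i in (1, 2):
            ref = simdata.generate_reference(seed=99)
            p = tmp_path / f"ref{i}.fasta"
            ref.to_files(p, tmp_path / f"tax{i}.csv")
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_divergence_structure_by_exhaustive_pairwise_identity(self):
        ref = simdata.generate_reference(
            {"prey": 2, "pet_food": 0, "raw_fish_meat": 0},
            {"within_genus": 0.02, "between_genus": 0.08},
            seed=5,
        )
        by_genus = {}
        for e in ref.entries:
            by_genus.setdefault(e.genus, []).append(e)
        for a, b in itertools.combinations(ref.entries, 2):
            ident = hamming_identity(a.sequence, b.sequence)
            if a.genus == b.genus:
                assert ident >= 98.0
                assert a.sequence != b.sequence
            else:
                assert ident <= 95.0

    def test_sequences_are_136bp_acgt(self):
        ref = simdata.generate_reference(seed=3)
        for e in ref.entries:
            assert len(e.sequence) == 136
            assert set(e.sequence) <= set("ACGT")

    def test_inconsistent_divergence_bounds_raise(self):
        with pytest.raises(ConfigError):
            simdata.generate_reference(divergence_spec={"within_genus": 0.1,
                                                        "between_genus": 0.05})


class TestCalibrationTrial:
    def test_single_meal_maps_to_first_scat_after_twelve_hours(self, default_sim):
        cfg, ref, schedule, scats, truth, _ = default_sim
        # every truth row's scat is >= 12 h after the first meal of the event day
        sched = schedule.copy()
        sched["meal_time"] = pd.to_datetime(sched["meal_time"])
        first_meal = sched.groupby([sched["meal_time"].dt.date, "taxon"])["meal_time"].min()
        emission = scats.set_index("sample_id")["emission_time"]
        for row in truth.itertuples(index=False):
            t0 = first_meal.loc[(row.meal_date, row.taxon)]
            assert pd.Timestamp(emission.loc[row.sample_id]) - t0 >= pd.Timedelta(hours=12)

    def test_daily_mass_constant_composition_varies(self, default_sim):
        cfg, ref, schedule, *_ = default_sim
        sched = schedule.copy()
        sched["day"] = pd.to_datetime(sched["meal_time"]).dt.date
        daily = sched.groupby("day")["mass_g"].sum()
        assert np.allclose(daily.values, daily.values[0])
        compositions = sched.groupby("day")["taxon"].apply(frozenset)
        assert compositions.nunique() > 1

    def test_zero_days_gives_empty_truth(self):
        cfg = simdata.SimulationConfig(seed=1, n_samples=0)
        ref = simdata.generate_reference(seed=1)
        schedule, scats, truth = simdata.generate_calibration_trial(cfg, ref)
        assert schedule.empty and truth.empty


class TestSimulateRun:
    def test_no_tag_jumps_means_no_alien_leak(self):
        cfg = simdata.SimulationConfig(seed=2, n_samples=6, tagjump_rate=0.0)
        ref = simdata.generate_reference(seed=2)
        _, _, truth = simdata.generate_calibration_trial(cfg, ref)
        sim = simdata.simulate_run(cfg, ref, truth)
        for platform, table in sim.runs.items():
            col = table.counts[sim.alien_variant]
            outside = col[col.index != f"ALIEN_{platform}"]
            assert int(outside.sum()) == 0

    def test_jumped_alien_reads_binomially_distributed(self):
        # 100k alien reads at rate 5e-4 -> ~50 expected jumps, sd ~ 7.07
        cfg = simdata.SimulationConfig(
            seed=4, n_samples=50, tagjump_rate=0.0005,
            alien_control_total_reads=100_000,
            platforms=[simdata.PlatformProfile("MiSeq", reads_per_product=200)],
        )
        ref = simdata.generate_reference(seed=4)
        _, _, truth = simdata.generate_calibration_trial(cfg, ref)
        sim = simdata.simulate_run(cfg, ref, truth)
        table = sim.runs["MiSeq"]
        col = table.counts[sim.alien_variant]
        jumped = int(col[col.index != "ALIEN_MiSeq"].sum())
        mean, sd = 50.0, np.sqrt(100_000 * 0.0005 * 0.9995)
        assert abs(jumped - mean) <= 3 * sd

    def test_predator_share_concentrates_at_requested_fraction(self):
        cfg = simdata.SimulationConfig(
            seed=6, n_samples=10, predator_read_fraction=0.98,
            platforms=[simdata.PlatformProfile("MiSeq", reads_per_product=10_000)],
        )
        ref = simdata.generate_reference(seed=6)
        _, _, truth = simdata.generate_calibration_trial(cfg, ref)
        sim = simdata.simulate_run(cfg, ref, truth)
        table = sim.runs["MiSeq"]
        sheet = sim.sheet
        sample_products = sheet.loc[sheet["role"] == "sample", "product_id"]
        predator_vid = next(
            v for v, t in sim.variant_to_taxon.items() if t == "Felis silvestris catus"
        )
        sub = table.counts.loc[sample_products]
        share = (sub[predator_vid] / sub.sum(axis=1)).mean()
        assert 0.97 <= share <= 0.99

    def test_read_conservation(self, default_sim):
        *_, sim = default_sim
        for platform, log in sim.run_log.items():
            assert log["reads_generated"] == log["reads_assigned"] + log["reads_truncated"]
            assert log["reads_assigned"] == int(sim.runs[platform].counts.values.sum())

    def test_negative_controls_contain_no_food_taxa(self, default_sim):
        cfg, ref, *_, sim = default_sim
        food = {e.species for e in ref.entries
                if e.category in ("prey_candidate", "human_linked_candidate")}
        for platform, table in sim.runs.items():
            sheet = sim.sheet
            neg = sheet.loc[sheet["role"].isin({"negative_extraction", "negative_pcr"})
                            & (sheet["platform"] == platform), "product_id"]
            sub = table.counts.loc[table.counts.index.intersection(neg)]
            for v in sub.columns:
                if sim.variant_to_taxon[v] in food:
                    # only tag-jumped reads may appear; with the default rate that
                    # is a handful at most
                    assert int(sub[v].sum()) <= 3

    def test_determinism_same_seed_identical_tables(self):
        cfg = simdata.SimulationConfig(seed=11, n_samples=8)
        ref = simdata.generate_reference(seed=11)
        _, _, truth = simdata.generate_calibration_trial(cfg, ref)
        sims = [simdata.simulate_run(cfg, ref, truth) for _ in range(2)]
        for platform in sims[0].runs:
            pd.testing.assert_frame_equal(
                sims[0].runs[platform].counts, sims[1].runs[platform].counts
            )
        pd.testing.assert_frame_equal(sims[0].sheet, sims[1].sheet)

    def test_missing_alien_taxon_is_configuration_error(self, default_sim):
        cfg, ref, *_ , sim = default_sim
        from dietbarcode.taxassign import MiniBarcodeReference
        no_alien = MiniBarcodeReference(
            [e for e in ref.entries if e.category != "alien_control"]
        )
        _, _, truth = simdata.generate_calibration_trial(cfg, no_alien)
        with pytest.raises(ConfigError):
            simdata.simulate_run(cfg, no_alien, truth)


class TestFastqRoundTrip:
    def test_counts_recoverable_by_demultiplexing(self, tmp_path):
        from dietbarcode.seqio import demultiplex, dereplicate, products_from_sheet, read_fastq

        cfg = simdata.SimulationConfig(
            seed=9, n_samples=2,
            platforms=[simdata.PlatformProfile("MiSeq", reads_per_product=40)],
            tagjump_rate=0.0, alien_control_total_reads=30,
        )
        ref = simdata.generate_reference({"prey": 1, "pet_food": 1, "raw_fish_meat": 1}, seed=9)
        _, _, truth = simdata.generate_calibration_trial(cfg, ref)
        sim = simdata.simulate_run(cfg, ref, truth)
        table = sim.runs["MiSeq"]
        fq = tmp_path / "run.fastq"
        simdata.emit_fastq(table, sim.sheet, fq, seed=9)
        reads = [seq for _, seq, _ in read_fastq(fq)]
        products = products_from_sheet(sim.sheet)
        assigned, log = demultiplex(
            reads, products, (simdata.FWD_PRIMER, simdata.REV_PRIMER)
        )
        assert log.get("truncated", 0) == 0
        rebuilt = dereplicate({p: r for p, r in assigned.items() if r}, run_id="MiSeq")
        nonzero = table.counts.loc[(table.counts != 0).any(axis=1),
                                   (table.counts != 0).any(axis=0)]
        rebuilt_aligned = rebuilt.counts.reindex(
            index=nonzero.index, columns=nonzero.columns
        ).fillna(0).astype(int)
        pd.testing.assert_frame_equal(rebuilt_aligned, nonzero)
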