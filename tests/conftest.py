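import numpy as np
import pandas as pd
import pytest

from dietbarcode import simdata
from dietbarcode.seqio import ReadCountTable
from dietbarcode.taxassign import MiniBarcodeReference, RefEntry


def make_entry(species, genus, sequence, category="prey_candidate",
               family="Famidae", order="Ordinales", superorder="Superordo",
               class_="Mammalia", ref_id=None):
    return RefEntry(
        ref_id=ref_id or "ref_" + species.lower().replace(" ", "_").replace(".", ""),
        species=species, genus=genus, family=family, order=order,
        superorder=superorder, class_=class_, category=category,
        sequence=sequence,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120501)


@pytest.fixture(scope="session")
def barcode(rng):
    return "".join(rng.choice(list("ACGT"), size=136))


def mutate(seq, positions, rng):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


@pytest.fixture(scope="session")
def small_reference(barcode, rng):
    """Two congeneric prey species, one processed-food taxon, predator/human/alien."""
    seq_a = barcode
    seq_b = mutate(barcode, [5], rng)                    # congener, ~99.3 % identity
    seq_pet = mutate(barcode, list(range(0, 136, 9)), rng)   # distant taxon
    seq_cat = mutate(barcode, list(range(3, 136, 7)), rng)
    seq_hum = mutate(barcode, list(range(1, 136, 6)), rng)
    seq_vole = mutate(barcode, list(range(2, 136, 5)), rng)
    return MiniBarcodeReference([
        make_entry("Arvicola terrestris", "Arvicola", seq_a),
        make_entry("Arvicola sapidus", "Arvicola", seq_b),
        make_entry("Sus scrofa", "Sus", seq_pet, category="human_linked_candidate",
                   family="Suidae", order="Artiodactyla"),
        make_entry("Felis silvestris catus", "Felis", seq_cat, category="predator",
                   family="Felidae", order="Carnivora"),
        make_entry("Homo sapiens", "Homo", seq_hum, category="human",
                   family="Hominidae", order="Primates"),
        make_entry("Myodes glareolus", "Myodes", seq_vole, category="alien_control",
                   family="Cricetidae", order="Rodentia"),
    ])


@pytest.fixture
def count_table():
    """Tiny run: 4 sample products (2 samples x 2 reps) + alien + neg control."""
    counts = pd.DataFrame(
        {
            "v_alien": [1, 0, 0, 0, 1934 - 1, 0],
            "v_prey": [120, 90, 0, 0, 0, 0],
            "v_pet": [10, 6, 30, 40, 0, 0],
        },
        index=["S1_r1", "S1_r2", "S2_r1", "S2_r2", "ALIEN", "NEG"],
    )
    counts.index.name = "product_id"
    return ReadCountTable(counts, run_id="toy")


@pytest.fixture
def toy_sheet():
    return pd.DataFrame(
        {
            "product_id": ["S1_r1", "S1_r2", "S2_r1", "S2_r2", "ALIEN", "NEG"],
            "sample_id": ["S1", "S1", "S2", "S2", "ALIEN", "NEG"],
            "platform": ["MiSeq"] * 6,
            "replicate": [1, 2, 1, 2, 1, 1],
            "role": ["sample"] * 4 + ["alien_control", "negative_pcr"],
        }
    )


@pytest.fixture(scope="session")
def default_sim():
    """One small simulated pair of runs shared across tests."""
    cfg = simdata.SimulationConfig(seed=7, n_samples=12)
    ref = simdata.generate_reference(seed=7)
    schedule, scats, truth = simdata.generate_calibration_trial(cfg, ref)
    sim = simdata.simulate_run(cfg, ref, truth)
    return cfg, ref, schedule, scats, truth, sim
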