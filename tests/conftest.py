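import numpy as np
import pytest

from metacaz import synthetic_data as sd
from metacaz.search import ScoringParams


@pytest.fixture(scope="session")
def db3():
    """Three-family protein database (two members each)."""
    db, consensus = sd.build_family_db(
        ["GH13", "GH5", "LO2"], per_family=2, aa_len_range=(80, 140), seed=11)
    return db, consensus


@pytest.fixture(scope="session")
def scoring():
    return ScoringParams()


@pytest.fixture(scope="session")
def planted_metagenome(db3):
    """A 120 kb single-population metagenome with planted genes + truth."""
    db, _ = db3
    spec = sd.make_population_spec("popA", 0.52, 120_000, seed=3)
    genome, truth = sd.simulate_population_genome(
        spec, [("GH13", 4), ("GH5", 3), ("LO2", 3)], db, seed=4)
    contigs, lifted, windows = sd.shred_to_contigs(genome, truth, seed=5)
    return {"db": db, "genome": genome, "truth": truth,
            "contigs": contigs, "lifted": lifted, "windows": windows}
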