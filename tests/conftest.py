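import numpy as np
import pytest

from mrnalang import (
    KineticClass,
    MrnaRecord,
    StructuralClass,
    StudyDataset,
    write_dataset,
)


def random_framed_sequence(rng, n_codons):
    return "".join(rng.choice(list("ACGU"), size=3 * n_codons))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Six hand-built records spanning both kinetic and all structural classes."""
    rows = [
        ("P1", "AUGGCCUUUACG", StructuralClass.ALL_ALPHA, KineticClass.TWO_STATE, 2.5),
        ("P2", "AUGCGCGCGAAA", StructuralClass.ALL_ALPHA, KineticClass.MULTI_STATE, -1.0),
        ("P3", "AUGAAUGGUCCA", StructuralClass.ALL_BETA, KineticClass.TWO_STATE, 4.75),
        ("P4", "AUGGGGCCCAAA", StructuralClass.ALL_BETA, KineticClass.MULTI_STATE, 0.125),
        ("P5", "AUGACGUACGUA", StructuralClass.ALPHA_BETA, KineticClass.TWO_STATE, 7.0),
        ("P6", "AUGUUUAAACCC", StructuralClass.ALPHA_BETA, KineticClass.MULTI_STATE, -3.25),
    ]
    records = tuple(
        MrnaRecord(id=i, sequence=s, structural_class=sc, kinetic_class=kc, ln_kf=y)
        for i, s, sc, kc, y in rows
    )
    return StudyDataset(records=records, provenance="fixture")


@pytest.fixture
def dataset_files(tmp_path, small_dataset):
    fasta = tmp_path / "seqs.fasta"
    ann = tmp_path / "ann.csv"
    write_dataset(small_dataset, fasta, ann)
    return fasta, ann
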