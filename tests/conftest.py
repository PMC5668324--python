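import pytest

from barcodekit.seqio import BarcodeDataset, LocusAlignment, SequenceRecord
from barcodekit.synthetic import simulate_dataset, study_like_config


def make_alignment(locus, rows, species=None):
    """rows: list of (individual_id, seq) or (individual_id, species, seq)."""
    records = []
    for row in rows:
        if len(row) == 3:
            indiv, sp, seq = row
        else:
            indiv, seq = row
            sp = species[indiv] if species else f"sp_{indiv}"
        records.append(SequenceRecord(indiv, sp, locus, seq))
    return LocusAlignment(locus, records)


@pytest.fixture(scope="session")
def study_dataset():
    """The default study-analogue dataset: 17 individuals, 5 loci."""
    ds, truth = simulate_dataset(study_like_config(seed=42))
    return ds, truth


@pytest.fixture()
def two_species_toy():
    """Two well-separated species, 3+3 individuals, no intra variation."""
    rows = [
        ("a1", "X one", "ACGTACGTAC"),
        ("a2", "X one", "ACGTACGTAC"),
        ("a3", "X one", "ACGTACGTAC"),
        ("b1", "X two", "ACGTTTTTAC"),
        ("b2", "X two", "ACGTTTTTAC"),
        ("b3", "X two", "ACGTTTTTAC"),
    ]
    return make_alignment("toy", rows)


@pytest.fixture()
def toy_dataset(two_species_toy):
    second = make_alignment(
        "toy2",
        [
            ("a1", "X one", "GGGGCCCC"),
            ("a2", "X one", "GGGGCCCC"),
            ("a3", "X one", "GGGGCCCC"),
            ("b1", "X two", "GGGGCCAA"),
            ("b2", "X two", "GGGGCCAA"),
            ("b3", "X two", "GGGGCCAA"),
        ],
    )
    ds = BarcodeDataset()
    ds.add(two_species_toy)
    ds.add(second)
    return ds
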