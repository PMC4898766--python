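import numpy as np
import pytest

from gradcomm.data_model import SpecimenRecord, SpecimenTable


def make_record(i, species, locality="L1", path=None, elevation=100.0,
                lat=11.7, lon=109.2, hypothesis="h1", haplotype=None, **extra_labels):
    labels = {hypothesis: species}
    labels.update(extra_labels)
    return SpecimenRecord(
        specimen_id=f"s{i:04d}",
        path=path if path is not None else locality.rstrip("0123456789'"),
        locality=locality,
        latitude=lat,
        longitude=lon,
        elevation=elevation,
        species_labels=labels,
        haplotype=haplotype,
    )


def make_table(rows, hypotheses=("h1",)):
    """rows: iterable of dicts forwarded to make_record."""
    records = [make_record(i, **row) for i, row in enumerate(rows)]
    return SpecimenTable(records, list(hypotheses))


@pytest.fixture
def simple_table():
    return make_table(
        [
            dict(species="A", locality="L1", elevation=50),
            dict(species="A", locality="L1", elevation=60),
            dict(species="B", locality="L2", elevation=350),
            dict(species="B", locality="L1", elevation=80),
            dict(species="C", locality="L2", elevation=400),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_incidence(rng, n_species=8, n_units=5, p=0.4):
    """Random 0/1 matrix with no all-zero species row."""
    from gradcomm.data_model import IncidenceMatrix

    while True:
        cells = (rng.random((n_species, n_units)) < p).astype(np.int8)
        if (cells.sum(axis=1) > 0).all() and cells.any():
            return IncidenceMatrix(
                [f"sp{i}" for i in range(n_species)],
                [f"u{j}" for j in range(n_units)],
                cells,
            )
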