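import numpy as np
import pytest

from barcodegap.alignment import AlignedDataset, SequenceRecord, parse_taxon_label
from barcodegap.distances import build_distance_matrix
from barcodegap.simulate import SimulationSpec, simulate_dataset


def make_dataset(entries):
    """Build an AlignedDataset from (header, residues) pairs."""
    records = []
    for k, (header, residues) in enumerate(entries):
        label = parse_taxon_label(header)
        tokens = [t for t in header.split() if any(c.isdigit() for c in t)]
        rec_id = tokens[0] if tokens else f"{label.full.replace(' ', '_')}"
        records.append(SequenceRecord(id=rec_id, label=label, residues=residues.upper()))
    return AlignedDataset(records=records)


def random_dataset(rng, n_species=4, per_species=3, length=60, d_intra=0.01, d_inter=0.2):
    spec = SimulationSpec(
        n_species=n_species, per_species=per_species, length=length,
        d_intra=d_intra, d_inter=d_inter, seed=int(rng.integers(2**31)),
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160512)


@pytest.fixture(scope="session")
def small_sim():
    """A clean, well-separated 5-species dataset with its distance matrix."""
    ds, truth = simulate_dataset(
        SimulationSpec(n_species=5, per_species=6, length=400,
                       d_intra=0.005, d_inter=0.2, seed=7)
    )
    return ds, truth, build_distance_matrix(ds)
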