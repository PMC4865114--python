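"""Generate the study datasets.

Produces, under scratch/data/ (regenerable intermediates):

* ``clean``      — 20 species x 10 sequences, 500 columns, expected
                   p-distances 0.01 within and 0.15 between species;
* ``mislabeled`` — the same sequences with two specimens relabelled to a
                   wrong species (database-misidentification scenario);
* ``cryptic``    — the clean data with one species split into two
                   lineages separated by an extra ~10% divergence.

Each variant is written as FASTA plus a ground-truth TSV; a taxonomy map
for subsetting accompanies the clean data.
"""

import copy
from pathlib import Path

from barcodegap.alignment import write_fasta
from barcodegap.simulate import (
    SimulationSpec,
    inject_cryptic_lineages,
    inject_mislabels,
    simulate_dataset,
    write_taxonomy_tsv,
    write_truth_tsv,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
SEED = 20160512

spec = SimulationSpec(n_species=20, per_species=10, length=500,
                      d_intra=0.01, d_inter=0.15, seed=SEED)

OUT.mkdir(parents=True, exist_ok=True)
ds, truth = simulate_dataset(spec)
write_fasta(ds, OUT / "clean.fasta")
write_truth_tsv(ds, truth, OUT / "clean.truth.tsv")
write_taxonomy_tsv(spec, OUT / "taxonomy.tsv")
print(f"clean: {len(ds)} sequences x {ds.length} columns "
      f"({spec.n_species} species)")

ds_mis, truth_mis = inject_mislabels(ds, copy.deepcopy(truth),
                                     rate=2 / len(ds), seed=SEED + 1)
write_fasta(ds_mis, OUT / "mislabeled.fasta")
write_truth_tsv(ds_mis, truth_mis, OUT / "mislabeled.truth.tsv")
print(f"mislabeled: relabelled {sorted(truth_mis.mislabeled_ids)}")

ds_cry, truth_cry = inject_cryptic_lineages(ds, copy.deepcopy(truth),
                                            species_index=1, depth=0.10,
                                            seed=SEED + 2)
write_fasta(ds_cry, OUT / "cryptic.fasta")
write_truth_tsv(ds_cry, truth_cry, OUT / "cryptic.truth.tsv")
moved = [i for i, l in truth_cry.true_lineage.items()
         if truth_cry.true_species[i] == 1 and l == 1]
print(f"cryptic: split species 1, lineage B = {len(moved)} sequences "
      f"at extra depth 0.10")
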