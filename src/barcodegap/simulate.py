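"""Synthetic aligned barcode datasets with known species structure.

The generator emulates the shape of a curated single-locus barcode
alignment: K species, each a tight cluster of sequences around its own
ancestor, with much larger divergence between species than within them.
Sequences evolve under a Jukes–Cantor model (site-independent, equal-rate
substitutions, no indels) on a two-level star genealogy: a root ancestor
spawns one ancestor per species, which spawns the individuals.  Branch
lengths are chosen through the Jukes–Cantor relation

    p = 3/4 * (1 - exp(-4*mu/3))

so that the *expected* pairwise p-distance is ``d_intra`` within species
and approximately ``d_inter`` between species.  Defaults (20 species of
10 sequences, 500 columns, d_intra = 0.01, d_inter = 0.15) reflect a
well-separated barcode locus with roughly an order of magnitude between
the intra- and interspecific scales.

Confounders seen in real repositories can be injected with known ground
truth: mislabelled specimens, deep cryptic lineages inside one nominal
species, imprecise "Genus sp." labels, and planted clade-private
diagnostic nucleotides.  Every injection records its victims in a
:class:`SimulatedTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import AlignedDataset, SequenceRecord, TaxonLabel
from .errors import SimulationError

_BASES = "ACGT"


def _alpha_suffix(k: int) -> str:
    """1 -> 'a', 2 -> 'b', ..., 27 -> 'aa' (bijective base-26)."""
    out = []
    while k > 0:
        k, rem = divmod(k - 1, 26)
        out.append(chr(ord("a") + rem))
    return "".join(reversed(out))


def species_label(k: int) -> TaxonLabel:
    """Deterministic binomial label for simulated species ``k`` (1-based)."""
    suf = _alpha_suffix(k)
    genus, epithet = f"Genus{suf}", f"species{suf}"
    return TaxonLabel(genus=genus, epithet=epithet, precise=True, full=f"{genus} {epithet}")


def jc_branch_length(p: float) -> float:
    """Jukes–Cantor branch length mu giving expected p-distance ``p``."""
    if not 0 <= p < 0.75:
        raise SimulationError(f"expected p-distance must be in [0, 0.75): {p}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_p(mu: float) -> float:
    """Expected p-distance across a Jukes–Cantor branch of length mu."""
    return 0.75 * (1.0 - math.exp(-4.0 * mu / 3.0))


def _evolve(codes: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """One JC branch: substitute each site w.p. jc_p(mu), uniform over the
    three alternative bases."""
    out = codes.copy()
    hit = rng.random(codes.size) < jc_p(mu)
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


@dataclass
class SimulationSpec:
    """Conditions of a simulated barcode study.

    ``per_species`` may be a single int or one count per species.
    ``cryptic_splits`` holds (species_index, split_depth) pairs where the
    depth is the extra expected p-distance between the two lineages;
    ``planted_diagnostics`` holds (species_index, lineage_index, column,
    state) with 1-based columns and 0-based lineage indices.
    """

    n_species: int = 20
    per_species: object = 10
    length: int = 500
    d_intra: float = 0.01
    d_inter: float = 0.15
    mislabel_rate: float = 0.0
    cryptic_splits: tuple = ()
    imprecise_rate: float = 0.0
    planted_diagnostics: tuple = ()
    seed: int = 0

    def counts(self) -> list:
        if isinstance(self.per_species, int):
            return [self.per_species] * self.n_species
        counts = list(self.per_species)
        if len(counts) != self.n_species:
            raise SimulationError("per_species list length != n_species")
        return counts

    def validate(self):
        if self.n_species < 1 or self.length < 1:
            raise SimulationError("n_species and length must be >= 1")
        if not 0 <= self.d_intra < self.d_inter <= 0.75:
            raise SimulationError("require 0 <= d_intra < d_inter <= 0.75")
        for rate in (self.mislabel_rate, self.imprecise_rate):
            if not 0 <= rate <= 1:
                raise SimulationError("rates must be in [0, 1]")
        if any(c < 1 for c in self.counts()):
            raise SimulationError("per_species counts must be >= 1")


@dataclass
class SimulatedTruth:
    """Ground truth of a simulated dataset, keyed by sequence id."""

    true_species: dict = field(default_factory=dict)  # id -> species index (1-based)
    true_lineage: dict = field(default_factory=dict)  # id -> lineage index (0-based)
    mislabeled_ids: set = field(default_factory=set)
    imprecise_ids: set = field(default_factory=set)
    planted: list = field(default_factory=list)


def simulate_dataset(spec: SimulationSpec) -> tuple:
    """Generate an aligned dataset plus its ground truth.

    Deterministic for a fixed spec (including seed): two calls produce
    byte-identical sequences, labels and truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts()
    splits = dict(spec.cryptic_splits)
    bad = set(splits) - set(range(1, spec.n_species + 1))
    if bad:
        raise SimulationError(f"cryptic split for unknown species: {sorted(bad)}")

    mu_half_inter = jc_branch_length(spec.d_inter) / 2.0
    mu_half_intra = jc_branch_length(spec.d_intra) / 2.0

    root = rng.integers(0, 4, size=spec.length)
    records, truth = [], SimulatedTruth()
    seq_no = 0
    for k in range(1, spec.n_species + 1):
        ancestor = _evolve(root, mu_half_inter, rng)
        n_k = counts[k - 1]
        if k in splits:
            if n_k < 2:
                raise SimulationError(f"species {k} has < 2 members; cannot split")
            mu_half_depth = jc_branch_length(splits[k]) / 2.0
            lineage_ancestors = [
                _evolve(ancestor, mu_half_depth, rng),
                _evolve(ancestor, mu_half_depth, rng),
            ]
            lineage_of = [0] * ((n_k + 1) // 2) + [1] * (n_k // 2)
        else:
            lineage_ancestors = [ancestor]
            lineage_of = [0] * n_k
        label = species_label(k)
        for i in range(n_k):
            seq_no += 1
            codes = _evolve(lineage_ancestors[lineage_of[i]], mu_half_intra, rng)
            rec_id = f"SIM{seq_no:04d}"
            records.append(
                SequenceRecord(
                    id=rec_id,
                    label=label,
                    residues="".join(_BASES[c] for c in codes),
                )
            )
            truth.true_species[rec_id] = k
            truth.true_lineage[rec_id] = lineage_of[i]

    ds = AlignedDataset(records=records)

    for plant in spec.planted_diagnostics:
        ds = _plant_diagnostic(ds, truth, plant, rng)
        truth.planted.append(tuple(plant))

    if spec.imprecise_rate > 0:
        ds, truth = _inject_imprecise(ds, truth, spec.imprecise_rate, rng)
    if spec.mislabel_rate > 0:
        ds, truth = inject_mislabels(
            ds, truth, spec.mislabel_rate, seed=int(rng.integers(2**31))
        )
    return ds, truth


def _plant_diagnostic(ds, truth, plant, rng):
    """Fix (state, column) in the target lineage, purge it elsewhere."""
    species_index, lineage_index, column, state = plant
    state = state.upper()
    if state not in _BASES:
        raise SimulationError(f"planted state must be one of ACGT: {state!r}")
    if not 1 <= column <= ds.length:
        raise SimulationError(f"planted column {column} outside alignment (1..{ds.length})")
    in_group = {
        rec_id
        for rec_id in truth.true_species
        if truth.true_species[rec_id] == species_index
        and truth.true_lineage[rec_id] == lineage_index
    }
    if not in_group:
        raise SimulationError(
            f"no members in species {species_index} lineage {lineage_index}"
        )
    col = column - 1
    others = [b for b in _BASES if b != state]
    new_records = []
    for r in ds.records:
        res = list(r.residues)
        if r.id in in_group:
            res[col] = state
        elif res[col] == state:
            res[col] = others[int(rng.integers(3))]
        new_records.append(SequenceRecord(r.id, r.label, "".join(res)))
    return AlignedDataset(records=new_records)


def _inject_imprecise(ds, truth, rate, rng):
    n_flip = math.ceil(rate * len(ds))
    chosen = {str(i) for i in rng.choice(ds.ids, size=n_flip, replace=False)}
    new_records = []
    for r in ds.records:
        if r.id in chosen:
            lab = TaxonLabel(
                genus=r.label.genus,
                epithet="sp.",
                precise=False,
                full=f"{r.label.genus} sp.",
            )
            new_records.append(SequenceRecord(r.id, lab, r.residues))
        else:
            new_records.append(r)
    truth.imprecise_ids |= chosen
    return AlignedDataset(records=new_records), truth


def inject_mislabels(
    ds: AlignedDataset, truth: SimulatedTruth, rate: float, seed: int
) -> tuple:
    """Relabel ceil(rate*n) random records with a different species' label.

    Deterministic under ``seed``; the victims are added to
    ``truth.mislabeled_ids``.  Requires at least two species.
    """
    species_present = sorted(set(truth.true_species.values()))
    if len(species_present) < 2:
        raise SimulationError("mislabel injection needs >= 2 species")
    if rate == 0:
        return ds, truth
    rng = np.random.default_rng(seed)
    n_flip = math.ceil(rate * len(ds))
    chosen = {str(i) for i in rng.choice(ds.ids, size=n_flip, replace=False)}
    new_records = []
    for r in ds.records:
        if r.id in chosen:
            own = truth.true_species[r.id]
            candidates = [k for k in species_present if k != own]
            wrong = candidates[int(rng.integers(len(candidates)))]
            new_records.append(SequenceRecord(r.id, species_label(wrong), r.residues))
        else:
            new_records.append(r)
    truth.mislabeled_ids |= chosen
    return AlignedDataset(records=new_records), truth


def inject_cryptic_lineages(
    ds: AlignedDataset,
    truth: SimulatedTruth,
    species_index: int,
    depth: float,
    seed: int,
) -> tuple:
    """Split one species into two lineages separated by extra divergence.

    The second half of the species' members receives one shared set of
    Jukes–Cantor substitutions (branch length matching expected
    p-distance ``depth``), so divergence appears *between* the two
    lineages while the within-lineage spread is untouched.  Labels are
    unchanged; ``truth.true_lineage`` records the split.
    """
    members = [r.id for r in ds.records if truth.true_species.get(r.id) == species_index]
    if len(members) < 2:
        raise SimulationError(f"species {species_index} has < 2 members; cannot split")
    rng = np.random.default_rng(seed)
    moved = set(members[(len(members) + 1) // 2 :])
    mu = jc_branch_length(depth)
    length = ds.length
    hit = rng.random(length) < jc_p(mu)
    offsets = rng.integers(1, 4, size=int(hit.sum()))
    new_lineage = max(truth.true_lineage[m] for m in members) + 1
    new_records = []
    for r in ds.records:
        if r.id in moved:
            codes = np.frombuffer(r.residues.encode(), dtype=np.uint8)
            idx = np.array([_BASES.index(chr(c)) for c in codes])
            idx[hit] = (idx[hit] + offsets) % 4
            new_records.append(
                SequenceRecord(r.id, r.label, "".join(_BASES[c] for c in idx))
            )
            truth.true_lineage[r.id] = new_lineage
        else:
            new_records.append(r)
    return AlignedDataset(records=new_records), truth


def taxonomy_rows(spec: SimulationSpec, genera_per_family: int = 4) -> list:
    """Taxonomy-map rows for the simulated genera (one genus per species).

    Families group ``genera_per_family`` consecutive genera; subclasses
    alternate between two names; the phylum is constant.  Gives a nested
    hierarchy for subset tests.
    """
    rows = []
    for k in range(1, spec.n_species + 1):
        lab = species_label(k)
        fam_idx = (k - 1) // genera_per_family + 1
        rows.append(
            {
                "label": lab.genus,
                "genus": lab.genus,
                "family": f"Family{_alpha_suffix(fam_idx)}",
                "subclass": "Alphanemertea" if fam_idx % 2 else "Betanemertea",
                "phylum": "Simulata",
            }
        )
    return rows


def write_taxonomy_tsv(spec: SimulationSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tgenus\tfamily\tsubclass\tphylum\n")
        for row in taxonomy_rows(spec):
            fh.write(
                f"{row['label']}\t{row['genus']}\t{row['family']}\t"
                f"{row['subclass']}\t{row['phylum']}\n"
            )


def write_truth_tsv(ds: AlignedDataset, truth: SimulatedTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\ttrue_species\ttrue_lineage\tmislabeled\timprecise\n")
        for r in ds.records:
            fh.write(
                f"{r.id}\t{r.label.full}\t{truth.true_species[r.id]}\t"
                f"{truth.true_lineage[r.id]}\t"
                f"{int(r.id in truth.mislabeled_ids)}\t"
                f"{int(r.id in truth.imprecise_ids)}\n"
            )
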