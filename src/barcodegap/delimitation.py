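"""Threshold-based OTU delimitation and OTU-relabelled gap re-analysis.

OTUs are formed by single-linkage clustering: two sequences belong to the
same OTU when they are connected by a chain of pairwise p-distances each
at most the threshold (default 3%, the heuristic upper bound on
intraspecific COI variation).  Single linkage mirrors the connectivity
logic of statistical-parsimony networks.  The partition can then stand in
for the taxonomic labels in a second gap analysis — the key experiment
being that mislabelled specimens which destroy the barcoding gap under
nominal labels no longer do so under an objective partition.

Externally computed partitions (e.g. from a tree-based delimitation tool)
can be imported from a two-column TSV and re-analysed the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .alignment import AlignedDataset, TaxonLabel
from .distances import AnalysisConfig, DistanceMatrix, GapReport, bin_by_partition, detect_gap


@dataclass
class OTUPartition:
    """Total assignment of sequence ids to dense 1-based OTU integers."""

    assignment: dict  # id -> int
    threshold: float
    n_otus: int

    def groups(self) -> dict:
        """OTU -> member id list."""
        out: dict = {}
        for rec_id, otu in self.assignment.items():
            out.setdefault(otu, []).append(rec_id)
        return out


@dataclass
class HaplotypeTable:
    """Exact-sequence groups; keys are the residue strings."""

    groups: dict  # residues -> [ids]

    @property
    def n_haplotypes(self) -> int:
        return len(self.groups)


def collapse_haplotypes(ds: AlignedDataset) -> HaplotypeTable:
    """Group records by exact residue-string identity."""
    groups: dict = {}
    for r in ds.records:
        groups.setdefault(r.residues, []).append(r.id)
    return HaplotypeTable(groups=groups)


def cluster_otus(dm: DistanceMatrix, threshold: float) -> OTUPartition:
    """Single-linkage OTUs: connected components of the <=threshold graph.

    OTU numbers are dense 1..n_otus, ordered by each component's smallest
    member index in ``dm.ids``.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    adj = dm.values <= threshold
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    # renumber components by first occurrence, i.e. smallest member index
    order: dict = {}
    for label in comp:
        if label not in order:
            order[label] = len(order) + 1
    assignment = {rec_id: order[comp[k]] for k, rec_id in enumerate(dm.ids)}
    return OTUPartition(assignment=assignment, threshold=threshold, n_otus=n_comp)


def read_partition_tsv(path) -> dict:
    """Read an externally computed id -> group partition (two-column TSV)."""
    assignment = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or (line_no == 1 and line.lower().startswith("id\t")):
                continue
            rec_id, group = line.split("\t")[:2]
            assignment[rec_id] = group
    return assignment


@dataclass
class PartitionComparison:
    n_otus: int
    n_labels: int
    n_split_labels: int  # nominal species spanning more than one OTU
    n_lumped_otus: int  # OTUs spanning more than one nominal species


def compare_partition_to_labels(
    p: OTUPartition, labels: Mapping[str, TaxonLabel]
) -> PartitionComparison:
    """Contrast the OTU count and structure with the taxonomic labels."""
    otus_per_label: dict = {}
    labels_per_otu: dict = {}
    for rec_id, otu in p.assignment.items():
        key = labels[rec_id].species_key()
        otus_per_label.setdefault(key, set()).add(otu)
        labels_per_otu.setdefault(otu, set()).add(key)
    return PartitionComparison(
        n_otus=p.n_otus,
        n_labels=len(otus_per_label),
        n_split_labels=sum(1 for v in otus_per_label.values() if len(v) > 1),
        n_lumped_otus=sum(1 for v in labels_per_otu.values() if len(v) > 1),
    )


def regap_with_otus(
    dm: DistanceMatrix, p: OTUPartition, cfg: AnalysisConfig = AnalysisConfig()
) -> GapReport:
    """Re-run the gap analysis with OTU membership in place of species labels."""
    return detect_gap(bin_by_partition(dm, p.assignment), cfg)
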