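"""Character-based barcoding: pure diagnostic nucleotides per lineage.

A *pure* (private) characteristic attribute of a group of sequences is a
nucleotide state fixed at one alignment column in every group member and
absent from every background sequence at that column.  Positions are
1-based on the analysis alignment and reported in "STATE:POS" notation.

Two screens are run per lineage: a *local* screen against the other
lineages carrying the same nominal-species label (can this lineage be
told apart from its conspecific clusters?), and a *global* screen against
every other sequence in the dataset.  Group-side gaps or ambiguity codes
disqualify a column (the state is not fixed); a background ambiguity code
whose IUPAC expansion includes the candidate state counts as presence, so
diagnostics are never claimed over uncertain evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment import BASES, IUPAC_EXPANSION, AlignedDataset, SequenceRecord
from .errors import AlignmentError, BarcodeGapError


@dataclass(frozen=True)
class DiagnosticAttribute:
    state: str  # one of A, C, G, T
    position: int  # 1-based alignment column

    def __str__(self) -> str:
        return f"{self.state}:{self.position}"


@dataclass
class DiagnosticReport:
    clade_number: int
    scope: str  # "local" | "global"
    attributes: list
    group_size: int

    def attribute_string(self) -> str:
        return ", ".join(str(a) for a in self.attributes)


def pure_attributes(
    group: Sequence[SequenceRecord], background: Sequence[SequenceRecord]
) -> list:
    """All (state, position) fixed in ``group`` and absent from ``background``.

    Raises on overlapping id sets or alignment-length mismatch.
    """
    group, background = list(group), list(background)
    if not group or not background:
        raise BarcodeGapError("group and background must both be non-empty")
    overlap = {r.id for r in group} & {r.id for r in background}
    if overlap:
        raise BarcodeGapError(f"group/background overlap: {sorted(overlap)[:5]}")
    lengths = {len(r.residues) for r in group} | {len(r.residues) for r in background}
    if len(lengths) != 1:
        raise AlignmentError(f"alignment length mismatch: {sorted(lengths)}")
    (length,) = lengths

    out = []
    for col in range(length):
        states = {r.residues[col] for r in group}
        if len(states) != 1:
            continue
        (state,) = states
        if state not in BASES:
            continue  # gap or ambiguity in group: not a fixed state
        present = False
        for r in background:
            bg = r.residues[col]
            if bg == state or (
                bg in IUPAC_EXPANSION and state in IUPAC_EXPANSION[bg]
            ):
                present = True
                break
        if not present:
            out.append(DiagnosticAttribute(state=state, position=col + 1))
    return out


def run_diagnostic_screen(
    lineages: Iterable, ds: AlignedDataset, min_group_size: int = 1
) -> list:
    """Local and global diagnostic screens for each sufficiently large lineage.

    For every lineage with at least ``min_group_size`` members, emits a
    local report (background = members of the other lineages sharing the
    focal lineage's majority species label) when conspecific background
    exists, and a global report (background = all other sequences).
    """
    by_id = {r.id: r for r in ds.records}
    lineages = list(lineages)
    reports = []
    for lin in lineages:
        if len(lin.member_ids) < min_group_size:
            continue
        group = [by_id[m] for m in lin.member_ids]
        member_set = set(lin.member_ids)
        maj_key = lin.majority_label.species_key()

        local_bg = [
            by_id[m]
            for other in lineages
            if other is not lin and other.majority_label.species_key() == maj_key
            for m in other.member_ids
        ]
        if local_bg:
            reports.append(
                DiagnosticReport(
                    clade_number=lin.clade_number,
                    scope="local",
                    attributes=pure_attributes(group, local_bg),
                    group_size=len(group),
                )
            )

        global_bg = [r for r in ds.records if r.id not in member_set]
        if global_bg:
            reports.append(
                DiagnosticReport(
                    clade_number=lin.clade_number,
                    scope="global",
                    attributes=pure_attributes(group, global_bg),
                    group_size=len(group),
                )
            )
    return reports
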