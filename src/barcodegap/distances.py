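"""Uncorrected p-distances, intra/inter binning, histograms and gap detection.

The distance used throughout is the uncorrected *p*-distance: the
proportion of differing sites among *comparable* sites, where a site is
comparable only when both sequences carry an unambiguous base (A, C, G or
T) there.  Gaps and IUPAC ambiguity codes exclude the site from the
comparison; no substitution-model correction is applied.

All unordered pairs of records are funnelled into an intraspecific bin
(both labels name the same species) or an interspecific bin, and the two
distributions are compared.  A *strict* barcoding gap exists when the
largest intraspecific distance is smaller than the smallest interspecific
distance; in real datasets the interesting object is usually the widest
empty interval of the pooled distance distribution together with the
counts of interspecific distances below a low threshold (default 2%) and
intraspecific distances above a high threshold (default 5%).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import BASES, AlignedDataset, TaxonLabel
from .errors import (
    AlignmentError,
    EmptyBinError,
    ImpreciseLabelError,
    UndefinedDistanceError,
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the gap analysis.

    bin_width is in percentage points; the thresholds are proportions.
    low_threshold is the "interspecific distances of 2% or below" overlap
    cut, high_threshold the "intraspecific distances above 5%" cut, and
    species_rule_threshold the 3%-rule used for OTU clustering.
    """

    bin_width: float = 0.5
    low_threshold: float = 0.02
    high_threshold: float = 0.05
    species_rule_threshold: float = 0.03

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not (0 <= self.low_threshold <= self.high_threshold <= 1):
            raise ValueError("require 0 <= low_threshold <= high_threshold <= 1")


# ---------------------------------------------------------------------------
# p-distance


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8)


_BASE_CODES = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)


def _valid_mask(codes: np.ndarray) -> np.ndarray:
    return np.isin(codes, _BASE_CODES)


def p_distance(a: str, b: str) -> tuple:
    """Uncorrected p-distance and number of comparable sites.

    Raises :class:`UndefinedDistanceError` when no site has unambiguous
    bases in both sequences.
    """
    if len(a) != len(b):
        raise AlignmentError(f"length mismatch: {len(a)} vs {len(b)}")
    ca, cb = _encode(a.upper()), _encode(b.upper())
    comparable = _valid_mask(ca) & _valid_mask(cb)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedDistanceError("no comparable (unambiguous) sites")
    n_diff = int(((ca != cb) & comparable).sum())
    return n_diff / n_comp, n_comp


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair comparable-site counts."""

    ids: list
    values: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")

    def __len__(self):
        return len(self.ids)

    def index(self, rec_id: str) -> int:
        return self.ids.index(rec_id)

    def between(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in keep_ids]
        return DistanceMatrix(
            ids=list(keep_ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)].copy(),
        )


def build_distance_matrix(ds: AlignedDataset) -> DistanceMatrix:
    """All-pairs uncorrected p-distance over the dataset.

    Vectorised row-against-rest comparison; raises
    :class:`UndefinedDistanceError` naming the first pair with zero
    comparable sites.
    """
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    codes = np.vstack([_encode(r.residues) for r in ds.records])
    valid = _valid_mask(codes)
    values = np.zeros((n, n), dtype=float)
    comp = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(comp, valid.sum(axis=1))
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        n_comp = both.sum(axis=1)
        if (n_comp == 0).any():
            j = int(np.nonzero(n_comp == 0)[0][0]) + i + 1
            raise UndefinedDistanceError(
                f"no comparable sites between {ds.records[i].id!r} "
                f"and {ds.records[j].id!r}"
            )
        n_diff = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        row = n_diff / n_comp
        values[i, i + 1 :] = row
        values[i + 1 :, i] = row
        comp[i, i + 1 :] = n_comp
        comp[i + 1 :, i] = n_comp
    return DistanceMatrix(ids=ds.ids, values=values, comparable_sites=comp)


# ---------------------------------------------------------------------------
# binning


@dataclass
class ComparisonBins:
    """All unordered pairs split into intraspecific and interspecific."""

    intraspecific: list  # (id_a, id_b, distance)
    interspecific: list

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.intraspecific], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([d for _, _, d in self.interspecific], dtype=float)

    @property
    def n_total(self) -> int:
        return len(self.intraspecific) + len(self.interspecific)


def bin_comparisons(dm: DistanceMatrix, labels: Mapping[str, TaxonLabel]) -> ComparisonBins:
    """Split all pairs into intra/interspecific bins by label identity.

    A pair is intraspecific iff genus and epithet both match
    (case-insensitive).  All labels must be precise; purge first.
    """
    imprecise = [i for i in dm.ids if not labels[i].precise]
    if imprecise:
        raise ImpreciseLabelError(
            f"imprecise labels present (purge first): {imprecise[:5]}"
        )
    keys = [labels[i].species_key() for i in dm.ids]
    intra, inter = [], []
    n = len(dm.ids)
    for i in range(n - 1):
        for j in range(i + 1, n):
            entry = (dm.ids[i], dm.ids[j], float(dm.values[i, j]))
            (intra if keys[i] == keys[j] else inter).append(entry)
    return ComparisonBins(intraspecific=intra, interspecific=inter)


def bin_by_partition(dm: DistanceMatrix, groups: Mapping[str, object]) -> ComparisonBins:
    """Like :func:`bin_comparisons` but with arbitrary group ids (e.g. OTUs)."""
    keys = [groups[i] for i in dm.ids]
    intra, inter = [], []
    n = len(dm.ids)
    for i in range(n - 1):
        for j in range(i + 1, n):
            entry = (dm.ids[i], dm.ids[j], float(dm.values[i, j]))
            (intra if keys[i] == keys[j] else inter).append(entry)
    return ComparisonBins(intraspecific=intra, interspecific=inter)


# ---------------------------------------------------------------------------
# histogram


@dataclass
class DistanceHistogram:
    """Counts of intra/interspecific distances in half-open percent bins."""

    bin_edges: list  # (lo, hi) in percentage points
    intra_counts: list
    inter_counts: list

    def to_rows(self):
        for (lo, hi), a, b in zip(self.bin_edges, self.intra_counts, self.inter_counts):
            yield {"bin_lo": lo, "bin_hi": hi, "intra_count": a, "inter_count": b}


def build_histogram(bins: ComparisonBins, cfg: AnalysisConfig = AnalysisConfig()) -> DistanceHistogram:
    """Histogram both bins into [k*w, (k+1)*w) percent intervals covering [0, 100]."""
    w = cfg.bin_width
    n_bins = int(np.floor(100.0 / w)) + 1  # final bin starts at/beyond 100
    edges = [(k * w, (k + 1) * w) for k in range(n_bins)]

    def count(values):
        counts = [0] * n_bins
        for v in values:
            k = int(np.floor(v * 100.0 / w))
            counts[min(k, n_bins - 1)] += 1
        return counts

    return DistanceHistogram(
        bin_edges=edges,
        intra_counts=count(v for _, _, v in bins.intraspecific),
        inter_counts=count(v for _, _, v in bins.interspecific),
    )


# ---------------------------------------------------------------------------
# gap report


def format_percent(count: int, total: int) -> str:
    """Percentage at one decimal, rounded half away from zero, e.g. '24.9%'."""
    if total < 1:
        raise ZeroDivisionError("total must be >= 1")
    if not 0 <= count <= total:
        raise ValueError("require 0 <= count <= total")
    pct = decimal.Decimal(100 * count) / decimal.Decimal(total)
    return f"{pct.quantize(decimal.Decimal('0.1'), rounding=decimal.ROUND_HALF_UP)}%"


@dataclass
class OverlapCount:
    count: int
    total: int
    percent: str = field(init=False)

    def __post_init__(self):
        self.percent = format_percent(self.count, self.total)


@dataclass
class GapReport:
    """Summary of the (non-)separation of intra- and interspecific distances."""

    strict_gap: bool
    strict_gap_interval: tuple | None  # (max intra, min inter) when strict
    widest_empty_interval: tuple  # (lo, hi) over the pooled distances
    lower_flank: set  # bins with a value equal to widest interval's lo
    upper_flank: set  # bins with a value equal to widest interval's hi
    inter_below_low: OverlapCount
    intra_above_high: OverlapCount

    @property
    def gap_width(self) -> float:
        lo, hi = self.widest_empty_interval
        return hi - lo


def widest_empty_interval(pooled: np.ndarray) -> tuple:
    """Widest open interval between consecutive pooled distance values.

    Returns a zero-width interval at the common value when all pooled
    values coincide.
    """
    vals = np.unique(pooled)
    if len(vals) == 1:
        return (float(vals[0]), float(vals[0]))
    diffs = np.diff(vals)
    k = int(np.argmax(diffs))  # first maximal gap on ties
    return (float(vals[k]), float(vals[k + 1]))


def overlap_summary(bins: ComparisonBins, cfg: AnalysisConfig = AnalysisConfig()) -> tuple:
    """Counts of interspecific <= low threshold and intraspecific > high threshold."""
    intra, inter = bins.intra_values, bins.inter_values
    if len(intra) == 0:
        raise EmptyBinError("intraspecific bin is empty")
    if len(inter) == 0:
        raise EmptyBinError("interspecific bin is empty")
    inter_below = OverlapCount(int((inter <= cfg.low_threshold).sum()), len(inter))
    intra_above = OverlapCount(int((intra > cfg.high_threshold).sum()), len(intra))
    return inter_below, intra_above


def detect_gap(bins: ComparisonBins, cfg: AnalysisConfig = AnalysisConfig()) -> GapReport:
    """Detect a barcoding gap and summarise the intra/inter overlap.

    strict_gap holds iff max(intra) < min(inter).  The widest empty
    interval is computed category-blind on the pooled distances; the
    report records which bins contribute the values flanking it.
    """
    intra, inter = bins.intra_values, bins.inter_values
    if len(intra) == 0:
        raise EmptyBinError("intraspecific bin is empty")
    if len(inter) == 0:
        raise EmptyBinError("interspecific bin is empty")
    max_intra, min_inter = float(intra.max()), float(inter.min())
    strict = max_intra < min_inter
    pooled = np.concatenate([intra, inter])
    lo, hi = widest_empty_interval(pooled)

    def flank(value):
        cats = set()
        if np.isclose(intra, value).any():
            cats.add("intra")
        if np.isclose(inter, value).any():
            cats.add("inter")
        return cats

    inter_below, intra_above = overlap_summary(bins, cfg)
    return GapReport(
        strict_gap=strict,
        strict_gap_interval=(max_intra, min_inter) if strict else None,
        widest_empty_interval=(lo, hi),
        lower_flank=flank(lo),
        upper_flank=flank(hi),
        inter_below_low=inter_below,
        intra_above_high=intra_above,
    )
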