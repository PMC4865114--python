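"""p-distance, binning, histogram and gap-detection behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.distances import (
    AnalysisConfig,
    ComparisonBins,
    bin_comparisons,
    build_distance_matrix,
    build_histogram,
    detect_gap,
    format_percent,
    overlap_summary,
    p_distance,
    widest_empty_interval,
)
from barcodegap.errors import (
    AlignmentError,
    EmptyBinError,
    ImpreciseLabelError,
    UndefinedDistanceError,
)
from barcodegap.simulate import SimulationSpec, simulate_dataset

from conftest import make_dataset


def brute_p_distance(a, b):
    """Site-by-site reference: comparable iff both unambiguous bases."""
    diff = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            diff += x != y
    return diff / comp, comp


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ("ACGT", "ACGT", (0.0, 4)),
            ("AAAA", "TTTT", (1.0, 4)),
            ("ACG-TA", "ACGATA", (0.0, 5)),
            ("ACGTTA", "ACGATA", (1 / 6, 6)),  # one mismatch over six sites
            ("ACNT", "ACGT", (0.0, 3)),  # ambiguity excludes the site
            ("ARGT", "AAGT", (0.0, 3)),  # R never counts as match or mismatch
        ],
    )
    def test_hand_counts(self, a, b, expect):
        d, n = p_distance(a, b)
        assert n == expect[1]
        assert d == pytest.approx(expect[0])

    def test_no_comparable_sites_errors(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NN--", "ACGT")

    def test_length_mismatch_errors(self):
        with pytest.raises(AlignmentError):
            p_distance("ACG", "ACGT")

    def test_matches_brute_force_on_random_pairs(self, rng):
        alphabet = np.array(list("ACGTN-RY"))
        for _ in range(50):
            a = "".join(rng.choice(alphabet, size=40))
            b = "".join(rng.choice(alphabet, size=40))
            try:
                expected = brute_p_distance(a, b)
            except ZeroDivisionError:
                continue
            assert p_distance(a, b) == pytest.approx(expected)

    def test_symmetry_and_self_distance(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=30))
            assert p_distance(a, b) == p_distance(b, a)
            assert p_distance(a, a)[0] == 0.0


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        ds = make_dataset([("Aus bus X1", "ACGT"), ("Aus bus X2", "ACGT")])
        dm = build_distance_matrix(ds)
        assert np.all(dm.values == 0)

    def test_elementwise_matches_p_distance(self, small_sim):
        ds, _, dm = small_sim
        idx = [(0, 5), (3, 17), (10, 29), (1, 2)]
        for i, j in idx:
            d, n = p_distance(ds.records[i].residues, ds.records[j].residues)
            assert dm.values[i, j] == pytest.approx(d)
            assert dm.comparable_sites[i, j] == n
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_permutation_relabels_consistently(self, small_sim, rng):
        ds, _, dm = small_sim
        perm = rng.permutation(len(ds))
        shuffled = make_dataset(
            [(f"{ds.records[k].label.full} {ds.records[k].id}", ds.records[k].residues)
             for k in perm]
        )
        dm2 = build_distance_matrix(shuffled)
        assert np.allclose(dm2.values, dm.values[np.ix_(perm, perm)])

    def test_undefined_pair_names_sequences(self):
        ds = make_dataset([("Aus bus X1", "NN"), ("Aus bus X2", "AC")])
        with pytest.raises(UndefinedDistanceError, match="X1"):
            build_distance_matrix(ds)


class TestBinComparisons:
    def test_three_record_enumeration(self):
        ds = make_dataset(
            [("Lineus ruber X1", "ACGT"), ("Lineus ruber X2", "ACGA"),
             ("Lineus bilineatus X3", "AAAA")]
        )
        bins = bin_comparisons(build_distance_matrix(ds), ds.labels())
        assert len(bins.intraspecific) == 1
        assert len(bins.interspecific) == 2

    def test_single_species_all_intra(self):
        ds = make_dataset([(f"Aus bus X{i}", "ACGT") for i in range(5)])
        bins = bin_comparisons(build_distance_matrix(ds), ds.labels())
        assert len(bins.intraspecific) == 10 and not bins.interspecific

    def test_bin_sizes_match_closed_form(self):
        counts = [3, 5, 2, 4]
        ds, _ = simulate_dataset(
            SimulationSpec(n_species=4, per_species=counts, length=50, seed=2)
        )
        bins = bin_comparisons(build_distance_matrix(ds), ds.labels())
        n = sum(counts)
        expect_intra = sum(c * (c - 1) // 2 for c in counts)
        assert len(bins.intraspecific) == expect_intra
        assert len(bins.interspecific) == n * (n - 1) // 2 - expect_intra

    def test_imprecise_labels_rejected(self):
        ds = make_dataset([("Aus sp. X1", "ACGT"), ("Aus bus X2", "ACGT")])
        with pytest.raises(ImpreciseLabelError):
            bin_comparisons(build_distance_matrix(ds), ds.labels())


class TestHistogram:
    def test_empty_intra_all_zero(self):
        bins = ComparisonBins(intraspecific=[], interspecific=[("a", "b", 0.1)])
        hist = build_histogram(bins)
        assert sum(hist.intra_counts) == 0 and sum(hist.inter_counts) == 1

    def test_placement_half_open(self):
        bins = ComparisonBins(intraspecific=[], interspecific=[("a", "b", 0.043)])
        hist = build_histogram(bins, AnalysisConfig(bin_width=0.5))
        k = hist.inter_counts.index(1)
        assert hist.bin_edges[k] == (4.0, 4.5)

    def test_conservation_across_bin_widths(self, small_sim):
        ds, _, dm = small_sim
        bins = bin_comparisons(dm, ds.labels())
        for w in (0.1, 0.5, 2.0, 7.0):
            hist = build_histogram(bins, AnalysisConfig(bin_width=w))
            assert sum(hist.intra_counts) == len(bins.intraspecific)
            assert sum(hist.inter_counts) == len(bins.interspecific)

    def test_saturated_distance_binned(self):
        bins = ComparisonBins(intraspecific=[("a", "b", 1.0)], interspecific=[])
        hist = build_histogram(bins)
        assert sum(hist.intra_counts) == 1


def brute_widest_interval(values):
    vals = sorted(set(values))
    if len(vals) == 1:
        return (vals[0], vals[0])
    best = (vals[0], vals[1])
    for lo, hi in zip(vals, vals[1:]):
        if hi - lo > best[1] - best[0]:
            best = (lo, hi)
    return best


class TestGapDetection:
    def test_forced_strict_gap(self, rng):
        intra = [("a", "b", d) for d in rng.uniform(0, 0.02, 10)]
        inter = [("a", "c", d) for d in rng.uniform(0.10, 0.25, 10)]
        rep = detect_gap(ComparisonBins(intra, inter))
        assert rep.strict_gap
        lo, hi = rep.strict_gap_interval
        assert lo == pytest.approx(max(d for _, _, d in intra))
        assert hi == pytest.approx(min(d for _, _, d in inter))

    def test_interleaved_bins_not_strict(self):
        intra = [("a", "b", 0.01), ("a", "c", 0.12)]
        inter = [("b", "c", 0.05), ("b", "d", 0.20)]
        rep = detect_gap(ComparisonBins(intra, inter))
        assert not rep.strict_gap and rep.strict_gap_interval is None
        assert rep.widest_empty_interval == (0.12, 0.20)
        assert rep.lower_flank == {"intra"} and rep.upper_flank == {"inter"}

    def test_widest_interval_is_category_blind(self):
        intra = [("a", "b", 0.01), ("a", "c", 0.12)]
        inter = [("b", "c", 0.05), ("b", "d", 0.20)]
        swapped = detect_gap(ComparisonBins(inter, intra))
        assert swapped.widest_empty_interval == (0.12, 0.20)

    def test_widest_interval_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 50))
            vals = np.round(rng.uniform(0, 0.3, n), 3)
            assert widest_empty_interval(vals) == pytest.approx(
                brute_widest_interval(vals.tolist())
            )

    def test_empty_bin_named_in_error(self):
        with pytest.raises(EmptyBinError, match="inter"):
            detect_gap(ComparisonBins([("a", "b", 0.1)], []))
        with pytest.raises(EmptyBinError, match="intra"):
            detect_gap(ComparisonBins([], [("a", "b", 0.1)]))


class TestOverlapSummary:
    def test_threshold_conventions(self):
        # inter counted at <= low; intra counted strictly above high
        intra = [("a", "b", 0.05), ("a", "c", 0.051)]
        inter = [("b", "c", 0.02), ("b", "d", 0.021)]
        below, above = overlap_summary(ComparisonBins(intra, inter))
        assert below.count == 1 and above.count == 1

    def test_counts_match_brute_force(self, small_sim, rng):
        ds, _, dm = small_sim
        bins = bin_comparisons(dm, ds.labels())
        cfg = AnalysisConfig(low_threshold=0.05, high_threshold=0.08)
        below, above = overlap_summary(bins, cfg)
        assert below.count == sum(d <= 0.05 for _, _, d in bins.interspecific)
        assert above.count == sum(d > 0.08 for _, _, d in bins.intraspecific)

    def test_no_overlap_percent_string(self):
        intra = [("a", "b", 0.01)]
        inter = [("b", "c", 0.10), ("b", "d", 0.30)]
        below, above = overlap_summary(ComparisonBins(intra, inter))
        assert below.count == 0 and below.percent == "0.0%"


class TestFormatPercent:
    @pytest.mark.parametrize(
        "count,total,expect",
        [(4784, 19200, "24.9%"), (738, 3885, "19.0%"), (0, 7, "0.0%"),
         (15, 10000, "0.2%"), (1, 8, "12.5%"), (7, 7, "100.0%")],
    )
    def test_examples(self, count, total, expect):
        assert format_percent(count, total) == expect

    def test_zero_total_errors(self):
        with pytest.raises(ZeroDivisionError):
            format_percent(0, 0)

    @given(st.integers(1, 10**6), st.integers(0, 10**6))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_rounding_within_half_unit(self, total, count):
        count = min(count, total)
        value = float(format_percent(count, total)[:-1])
        assert abs(value - 100 * count / total) <= 0.05 + 1e-9
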