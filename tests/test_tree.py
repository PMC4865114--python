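"""Neighbor joining, midpoint rooting, lineage extraction, misid flagging."""

from collections import Counter

import numpy as np
import pytest
from skbio import TreeNode
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from barcodegap.alignment import parse_taxon_label
from barcodegap.distances import DistanceMatrix, build_distance_matrix
from barcodegap.errors import TreeSizeError
from barcodegap.tree import (
    extract_lineages,
    flag_misidentifications,
    majority_label,
    midpoint_root,
    neighbor_joining,
)

from conftest import make_dataset


def dm_from_array(values, ids):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        ids=list(ids), values=values,
        comparable_sites=np.full_like(values, 100, dtype=np.int64),
    )


def random_additive_matrix(rng, n_leaves):
    """Random binary tree with positive branch lengths -> tip distances."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 0.5))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 0.5)))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    for n in nodes:
        root.append(n)
    tipdm = root.tip_tip_distances()
    ids = list(tipdm.ids)
    return root, dm_from_array(tipdm.data, ids)


def tip_distance_map(tree):
    tipdm = tree.tip_tip_distances()
    return {
        tuple(sorted((a, b))): float(tipdm[a, b])
        for i, a in enumerate(tipdm.ids)
        for b in tipdm.ids[i + 1:]
    }


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = dm_from_array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]], "abc")
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.3)

    def test_four_taxon_split_recovered(self):
        # additive ((A,B),(C,D)) distances
        dm = dm_from_array(
            [[0, 0.2, 0.7, 0.8], [0.2, 0, 0.7, 0.8],
             [0.7, 0.7, 0, 0.3], [0.8, 0.8, 0.3, 0]],
            "ABCD",
        )
        tree = neighbor_joining(dm)
        # A and B must form a cherry
        a = tree.find("A")
        sibling_tips = {t.name for t in a.parent.tips()}
        assert sibling_tips == {"A", "B"}
        assert tip_distance_map(tree)[("A", "B")] == pytest.approx(0.2)

    def test_consistency_on_additive_inputs(self, rng):
        for _ in range(8):
            n = int(rng.integers(6, 11))
            true_tree, dm = random_additive_matrix(rng, n)
            ours = neighbor_joining(dm)
            # additive input: NJ reproduces every pairwise path length
            got = tip_distance_map(ours)
            for (a, b), d in tip_distance_map(true_tree).items():
                assert got[(a, b)] == pytest.approx(d, abs=1e-9)

    def test_agrees_with_skbio_on_additive_inputs(self, rng):
        _, dm = random_additive_matrix(rng, 8)
        ours = tip_distance_map(neighbor_joining(dm))
        ref = tip_distance_map(skbio_nj(SkbioDM(dm.values, dm.ids)))
        for pair, d in ref.items():
            assert ours[pair] == pytest.approx(d, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        _, dm = random_additive_matrix(rng, 7)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix(
            ids=[dm.ids[k] for k in perm],
            values=dm.values[np.ix_(perm, perm)],
            comparable_sites=dm.comparable_sites[np.ix_(perm, perm)],
        )
        assert tip_distance_map(neighbor_joining(dm)) == pytest.approx(
            tip_distance_map(neighbor_joining(dm2))
        )

    def test_too_few_sequences(self):
        dm = dm_from_array([[0, 0.1], [0.1, 0]], "ab")
        with pytest.raises(TreeSizeError):
            neighbor_joining(dm)

    def test_negative_branch_estimates_clamped(self, rng):
        # a strongly non-additive matrix that provokes negative estimates
        values = rng.uniform(0.01, 0.2, size=(6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0)
        tree = neighbor_joining(dm_from_array(values, "abcdef"))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        tree = TreeNode.read(["(A:1,B:3);"])
        rooted = midpoint_root(tree)
        depths = {t.name: t.accumulate_to_ancestor(rooted) for t in rooted.tips()}
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_root_splits_longest_path_brute_force(self, rng):
        for _ in range(6):
            _, dm = random_additive_matrix(rng, int(rng.integers(5, 9)))
            tree = neighbor_joining(dm)
            pairs = tip_distance_map(tree)
            longest = max(pairs.values())
            rooted = midpoint_root(tree)
            depths = [t.accumulate_to_ancestor(rooted) for t in rooted.tips()]
            assert max(depths) == pytest.approx(longest / 2)

    def test_rerooting_preserves_tip_distances(self, rng):
        _, dm = random_additive_matrix(rng, 7)
        tree = neighbor_joining(dm)
        assert tip_distance_map(midpoint_root(tree)) == pytest.approx(
            tip_distance_map(tree)
        )


def label(s):
    return parse_taxon_label(s)


class TestMajorityLabel:
    def test_nineteen_versus_twenty(self):
        counts = Counter({label("Aus speciesa"): 19, label("Aus speciesb"): 20})
        maj, tie = majority_label(counts)
        assert maj.full == "Aus speciesb" and not tie

    def test_singleton(self):
        maj, tie = majority_label(Counter({label("Aus bus"): 1}))
        assert maj.full == "Aus bus" and not tie

    def test_even_split_breaks_lexicographically(self):
        counts = Counter({label("Zus zeta"): 5, label("Aus alpha"): 5})
        maj, tie = majority_label(counts)
        assert maj.full == "Aus alpha" and tie


class TestLineages:
    def test_identical_sequences_single_lineage(self):
        ds = make_dataset([(f"Aus bus X{i}", "ACGTACGT") for i in range(4)])
        dm = build_distance_matrix(ds)
        tree = midpoint_root(neighbor_joining(dm))
        lineages = extract_lineages(tree, dm, ds.labels(), cutoff=0.01)
        assert len(lineages) == 1
        assert sorted(lineages[0].member_ids) == sorted(ds.ids)

    def test_two_tight_clusters_two_lineages(self, small_sim):
        ds, truth, dm = small_sim
        sub_ids = [i for i in ds.ids if truth.true_species[i] in (1, 2)]
        sub = dm.submatrix(sub_ids)
        labels = {i: ds.labels()[i] for i in sub_ids}
        tree = midpoint_root(neighbor_joining(sub))
        lineages = extract_lineages(tree, sub, labels, cutoff=0.05)
        assert len(lineages) == 2
        got = {frozenset(l.member_ids) for l in lineages}
        want = {
            frozenset(i for i in sub_ids if truth.true_species[i] == k)
            for k in (1, 2)
        }
        assert got == want

    def test_lineages_partition_tips(self, small_sim):
        ds, _, dm = small_sim
        tree = midpoint_root(neighbor_joining(dm))
        for cutoff in (0.002, 0.05, 0.5):
            lineages = extract_lineages(tree, dm, ds.labels(), cutoff)
            members = [i for l in lineages for i in l.member_ids]
            assert sorted(members) == sorted(ds.ids)

    def test_lineages_are_maximal_clades(self, small_sim):
        ds, _, dm = small_sim
        tree = midpoint_root(neighbor_joining(dm))
        cutoff = 0.05
        lineages = extract_lineages(tree, dm, ds.labels(), cutoff)
        index = {i: k for k, i in enumerate(dm.ids)}
        for lin in lineages:
            assert lin.max_internal_distance < cutoff
            if len(lin.member_ids) == len(ds.ids):
                continue
            # the enclosing clade (here: any union with another lineage's
            # members) must violate the cutoff, else extraction stopped early
            node = tree.lca([tree.find(m) for m in lin.member_ids]) \
                if len(lin.member_ids) > 1 else tree.find(lin.member_ids[0])
            parent_tips = [t.name for t in node.parent.tips()]
            idx = [index[t] for t in parent_tips]
            assert dm.values[np.ix_(idx, idx)].max() >= cutoff


class TestMisidFlags:
    def intruder_fixture(self):
        base = "ACGTACGTACGTACGTACGA"
        far = "TGCATGCATGCATGCATGCC"
        entries = [(f"Cephalothrix rufifrons C{i}", base) for i in range(1, 11)]
        entries.append(("Hubrechtella dubia H1", base))  # zero distance intruder
        entries += [(f"Hubrechtella dubia H{i}", far) for i in range(2, 6)]
        return make_dataset(entries)

    def test_zero_distance_intruder_flagged(self):
        ds = self.intruder_fixture()
        dm = build_distance_matrix(ds)
        tree = midpoint_root(neighbor_joining(dm))
        lineages = extract_lineages(tree, dm, ds.labels(), cutoff=0.01)
        flags = flag_misidentifications(lineages, dm, max_dist=0.01)
        assert len(flags) == 1
        flag = flags[0]
        assert flag.sequence_id == "H1"
        assert flag.own_label.full == "Hubrechtella dubia"
        assert flag.clade_majority_label.full == "Cephalothrix rufifrons"
        assert flag.min_distance_to_majority == 0.0

    def test_label_pure_clades_unflagged(self, small_sim):
        ds, _, dm = small_sim
        tree = midpoint_root(neighbor_joining(dm))
        lineages = extract_lineages(tree, dm, ds.labels(), cutoff=0.05)
        assert flag_misidentifications(lineages, dm, max_dist=0.05) == []
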