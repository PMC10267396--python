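"""Marker matrix, shared sets, Fitch parsimony vs brute force, bootstrap."""

import itertools

import numpy as np
import pytest

from svarda.genomic_core import GenomicInterval, IntervalSet
from svarda.mosaic_phylogeny import (
    MarkerMatrix,
    build_reference_positions,
    bootstrap_support,
    count_informative_positions,
    enumerate_topologies,
    fitch_length,
    internal_bipartitions,
    matrix_to_sequences,
    mp_search,
    presence_absence_matrix,
    sequences_to_matrix,
    shared_set_counts,
    to_newick,
)

REGIONS = ["Bulb", "Calca", "Cereb", "Hippo", "Pfc"]
PLANTED = ("Cereb", ("Bulb", ("Hippo", ("Pfc", "Calca"))))


def matrix_from_columns(columns, regions=None):
    regions = regions or REGIONS
    states = np.array(columns, dtype=np.uint8).T
    loci = [GenomicInterval("chrX", i * 10, i * 10 + 5) for i in range(len(columns))]
    return MarkerMatrix(list(regions), loci, states)


def simulate_matrix(branch_chars, regions=None):
    """Homoplasy-free matrix: one column per (branch, copy)."""
    regions = regions or REGIONS
    cols = []
    for branch, n in branch_chars.items():
        col = [1 if r in branch else 0 for r in regions]
        cols.extend([col] * n)
    return matrix_from_columns(cols, regions)


DEFAULT_BRANCH_CHARS = {
    ("Bulb",): 30, ("Calca",): 30, ("Cereb",): 30, ("Hippo",): 30, ("Pfc",): 30,
    ("Pfc", "Calca"): 25, ("Hippo", "Pfc", "Calca"): 25,
    ("Bulb", "Hippo", "Pfc", "Calca"): 25,
    tuple(REGIONS): 10,
}


class TestMatrixConstruction:
    def test_reference_merges_across_regions(self):
        sets = {
            "A": IntervalSet([GenomicInterval("chr1", 100, 200)]),
            "B": IntervalSet([GenomicInterval("chr1", 150, 250)]),
        }
        ref = build_reference_positions(sets)
        assert list(ref) == [GenomicInterval("chr1", 100, 250)]
        m = presence_absence_matrix(ref, sets)
        assert m.states.tolist() == [[1], [1]]

    def test_disjoint_events_concatenate(self):
        sets = {
            "A": IntervalSet([GenomicInterval("chr1", 0, 50)]),
            "B": IntervalSet([GenomicInterval("chr2", 0, 50)]),
        }
        ref = build_reference_positions(sets)
        assert len(ref) == 2
        m = presence_absence_matrix(ref, sets)
        assert m.states.sum() == 2 and (m.states.sum(axis=0) == 1).all()

    def test_row_sums_match_overlap_counts(self, default_run):
        dres = default_run.donors["D1"]
        m = dres.matrix
        from svarda.genomic_core import intersect

        for i, region in enumerate(m.regions):
            evs = IntervalSet(e.interval for e in dres.events[region])
            ref = IntervalSet(m.loci)
            assert m.states[i].sum() == len(intersect(ref, evs))


class TestSharedSets:
    def test_exact_subset_counts(self):
        m = matrix_from_columns(
            [[1, 0, 0], [1, 1, 0], [1, 1, 1]], regions=["A", "B", "C"]
        )
        sc = shared_set_counts(m)
        assert sc.exact == {
            frozenset({"A"}): 1,
            frozenset({"A", "B"}): 1,
            frozenset({"A", "B", "C"}): 1,
        }
        assert sc.n_all_regions == 1 and sc.n_shared_multi == 2
        assert sum(sc.exact.values()) == m.n_loci

    def test_simulated_branch_counts_recovered(self):
        m = simulate_matrix(DEFAULT_BRANCH_CHARS)
        sc = shared_set_counts(m)
        for branch, n in DEFAULT_BRANCH_CHARS.items():
            assert sc.exact[frozenset(branch)] == n


class TestFitch:
    def test_trivial_characters(self):
        single = matrix_from_columns([[1, 0, 0, 0, 0]])
        for topo in enumerate_topologies(REGIONS):
            assert fitch_length(topo, single)[0] == 1
        allones = matrix_from_columns([[1, 1, 1, 1, 1]])
        topo = next(enumerate_topologies(REGIONS))
        assert fitch_length(topo, allones)[0] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_state_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from_columns(rng.integers(0, 2, size=(12, 5)).tolist())
        topo = list(enumerate_topologies(REGIONS))[int(rng.integers(0, 15))]

        def brute_force(col):
            leaf_state = dict(zip(REGIONS, col))
            # collect internal nodes (subtrees) of the rooted representation
            internals = []

            def walk(node):
                if isinstance(node, str):
                    return
                internals.append(node)
                walk(node[0])
                walk(node[1])

            walk(topo)
            best = None
            for assign in itertools.product([0, 1], repeat=len(internals)):
                state = dict(zip(map(id, internals), assign))

                def s(node):
                    return leaf_state[node] if isinstance(node, str) else state[id(node)]

                cost = 0

                def edges(node):
                    nonlocal cost
                    if isinstance(node, str):
                        return
                    for child in node:
                        cost += s(node) != s(child)
                        edges(child)

                edges(topo)
                best = cost if best is None else min(best, cost)
            return best

        total, per_char = fitch_length(topo, m)
        expected = [brute_force(col) for col in m.states.T.tolist()]
        assert per_char.tolist() == expected
        assert total == sum(expected)

    def test_matches_dendropy_fitch(self):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.model.parsimony import fitch_down_pass

        rng = np.random.default_rng(3)
        m = matrix_from_columns(rng.integers(0, 2, size=(60, 5)).tolist())
        topo = list(enumerate_topologies(REGIONS))[7]

        def newick(node):
            return node if isinstance(node, str) else f"({newick(node[0])},{newick(node[1])})"

        nwk = f"({newick(topo[0])},{newick(topo[1])});"
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=taxa)
        fasta = "".join(
            f">{r}\n{''.join(map(str, m.states[i]))}\n" for i, r in enumerate(m.regions)
        )
        chars = dendropy.StandardCharacterMatrix.get(
            data=fasta, schema="fasta", taxon_namespace=taxa
        )
        score = fitch_down_pass(
            tree.postorder_node_iter(),
            taxon_state_sets_map=chars.taxon_state_sets_map(gaps_as_missing=True),
        )
        assert fitch_length(topo, m)[0] == score


class TestMpSearch:
    def test_planted_topology_uniquely_recovered(self):
        m = simulate_matrix(DEFAULT_BRANCH_CHARS)
        res = mp_search(m, outgroup="Cereb")
        assert len(res.co_optimal) == 1
        assert set(internal_bipartitions(res.topology)) == {
            frozenset({"Pfc", "Calca"}),
            frozenset({"Hippo", "Pfc", "Calca"}),
        }
        # perfect phylogeny: one step per character
        assert res.tree_length == m.n_loci - DEFAULT_BRANCH_CHARS[tuple(REGIONS)]

    def test_singleton_only_matrix_is_a_star(self):
        m = simulate_matrix({(r,): 5 for r in REGIONS})
        res = mp_search(m, outgroup="Cereb")
        assert len(res.co_optimal) == 15

    def test_best_length_not_exceeded_by_any_topology(self):
        rng = np.random.default_rng(11)
        m = matrix_from_columns(rng.integers(0, 2, size=(40, 5)).tolist())
        res = mp_search(m, outgroup="Cereb")
        lengths = [fitch_length(t, m)[0] for t in enumerate_topologies(REGIONS, "Cereb")]
        assert res.tree_length == min(lengths)

    @pytest.mark.parametrize("seed", range(20))
    def test_tree_length_invariant_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(5, 40))
        m = matrix_from_columns(rng.integers(0, 2, size=(L, 5)).tolist())
        if (m.states.sum(axis=0) == 0).any():
            m.states[0, m.states.sum(axis=0) == 0] = 1
        res = mp_search(m, outgroup="Cereb")
        res.check_invariants()  # total == sum(branches) == sum(per-char minima)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        m = simulate_matrix(DEFAULT_BRANCH_CHARS)
        s1 = bootstrap_support(m, "Cereb", replicates=200, seed=5)
        s2 = bootstrap_support(m, "Cereb", replicates=200, seed=5)
        assert s1 == s2

    def test_strong_matrix_full_support(self):
        m = simulate_matrix(DEFAULT_BRANCH_CHARS)
        supp = bootstrap_support(m, "Cereb", replicates=300, seed=1)
        assert supp[frozenset({"Pfc", "Calca"})] == 100.0
        assert supp[frozenset({"Hippo", "Pfc", "Calca"})] == 100.0

    def test_monte_carlo_stability_across_seeds(self):
        m = simulate_matrix(DEFAULT_BRANCH_CHARS)
        a = bootstrap_support(m, "Cereb", replicates=1_000, seed=1)
        b = bootstrap_support(m, "Cereb", replicates=1_000, seed=2)
        for bp in (frozenset({"Pfc", "Calca"}), frozenset({"Hippo", "Pfc", "Calca"})):
            assert abs(a[bp] - b[bp]) <= 3.0


class TestInformativeSites:
    def test_definitions_diverge_on_four_region_pattern(self):
        pair = matrix_from_columns([[1, 1, 0, 0, 0]])
        assert count_informative_positions(pair) == (1, 1)
        four = matrix_from_columns([[1, 1, 1, 1, 0]])
        # present in 4 of 5: lineage-informative but not standard-informative
        assert count_informative_positions(four) == (1, 0)
        boring = matrix_from_columns([[1, 0, 0, 0, 0], [1, 1, 1, 1, 1]])
        assert count_informative_positions(boring) == (0, 0)


class TestEncodingAndExport:
    def test_at_encoding_roundtrip(self):
        rng = np.random.default_rng(2)
        m = matrix_from_columns(rng.integers(0, 2, size=(30, 5)).tolist())
        m.states[0, m.states.sum(axis=0) == 0] = 1
        seqs = matrix_to_sequences(m)
        assert set("".join(seqs.values())) <= {"A", "T"}
        back = sequences_to_matrix(seqs, loci=m.loci)
        assert (back.states == m.states).all() and back.regions == m.regions

    def test_newick_is_parseable_and_lengths_sum(self):
        dendropy = pytest.importorskip("dendropy")
        m = simulate_matrix(DEFAULT_BRANCH_CHARS)
        res = mp_search(m, "Cereb")
        res.bootstrap = bootstrap_support(m, "Cereb", replicates=50, seed=0)
        tree = dendropy.Tree.get(data=to_newick(res), schema="newick")
        leaves = {t.taxon.label for t in tree.leaf_node_iter()}
        assert leaves == set(REGIONS)
        total = sum(
            e.length for e in tree.preorder_edge_iter() if e.length is not None
        )
        assert total == res.tree_length
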