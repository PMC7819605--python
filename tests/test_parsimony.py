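"""Exact parsimony engine: Fitch scoring, search, indices, branch maps."""

import itertools
import random

import pytest

from hybridtrace import (
    CapacityError,
    CharacterMatrix,
    SiteMatrix,
    collapse_zero_change_branches,
    consistency_index,
    dedupe,
    distinct_mp_trees,
    enumerate_topologies,
    fitch_length,
    from_newick,
    is_perfectly_compatible,
    map_changes_to_branches,
    mp_search,
    retention_index,
    to_newick,
)
from hybridtrace.datasets import its_parental_matrix


def brute_force_length(tree, chars):
    """Independent oracle: minimize changes over ALL internal-node state
    assignments, per character."""
    adj = tree.neighbors()
    internal = sorted(u for u in adj if u >= tree.n_leaves)
    total = 0
    per_char = []
    for j in range(chars.n_characters):
        leaf_state = {
            i: chars.haplotype_states[chars.haplotype_names.index(lab)][j]
            for i, lab in enumerate(tree.leaf_labels)
        }
        states = sorted({s[j] for s in chars.haplotype_states})
        best = None
        for assignment in itertools.product(states, repeat=len(internal)):
            lab = dict(zip(internal, assignment))
            lab.update(leaf_state)
            cost = sum(1 for u, v in tree.edges if lab[u] != lab[v])
            best = cost if best is None else min(best, cost)
        per_char.append(best)
        total += best
    return total, per_char


def random_character_matrix(rng, n_hap, n_char, alphabet="ACGT-"):
    while True:
        cols = []
        for _ in range(n_char):
            col = [rng.choice(alphabet) for _ in range(n_hap)]
            if len(set(col)) >= 2:
                cols.append(col)
        if len(cols) == n_char:
            rows = ["".join(c[i] for c in cols) for i in range(n_hap)]
            if len(set(rows)) == n_hap:
                return CharacterMatrix(
                    tuple(range(1, n_char + 1)),
                    tuple(f"t{i}" for i in range(n_hap)),
                    tuple(rows),
                )


class TestDedupe:
    def test_cp_matrix_collapses_to_seven_haplotypes(self, cp_matrix):
        chars = dedupe(cp_matrix)
        assert chars.n_haplotypes == 7
        assert chars.n_taxa == 21
        assert set(chars.members[chars.haplotype_names[0]]) == {
            "PI", "KJ", "PK", "ST", "BS"
        }

    def test_parental_its_collapses_to_two(self):
        chars = dedupe(its_parental_matrix())
        assert chars.n_haplotypes == 2
        assert chars.n_characters == 12  # the fixed differences

    def test_all_distinct_rows_identity(self):
        m = SiteMatrix.from_rows(
            (1, 2), [("a", "", "AC"), ("b", "", "AG"), ("c", "", "TC")]
        )
        chars = dedupe(m)
        assert chars.n_haplotypes == 3
        assert chars.haplotype_names == ("a", "b", "c")


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_double_factorial_counts(self, n, count):
        labels = [f"t{i}" for i in range(n)]
        trees = list(enumerate_topologies(labels))
        assert len(trees) == count
        assert len(set(trees)) == count  # pairwise distinct topologies


class TestFitch:
    def test_two_haplotype_parental_matrix_scores_12(self):
        chars = dedupe(its_parental_matrix())
        tree = next(enumerate_topologies(chars.haplotype_names))
        total, per_char = fitch_length(tree, chars)
        assert total == 12
        assert set(per_char) == {1}

    def test_matches_brute_force_on_random_trees(self):
        rng = random.Random(19)
        for n in (4, 5, 6):
            chars = random_character_matrix(rng, n, 4)
            trees = list(enumerate_topologies(chars.haplotype_names))
            for tree in rng.sample(trees, min(6, len(trees))):
                got_total, got_per = fitch_length(tree, chars)
                exp_total, exp_per = brute_force_length(tree, chars)
                assert got_total == exp_total
                assert list(got_per) == exp_per

    def test_matches_dendropy_fitch_on_cp_tree(self, cp_matrix):
        """Independent cross-check of the scorer against dendropy's
        Fitch down-pass on the optimal cp tree."""
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        chars = dedupe(cp_matrix)
        result = mp_search(chars)
        newick = to_newick(result.trees[0])
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=taxa
        )
        # gap as fifth state: encode states over a 5-symbol alphabet
        alphabet = "ACGT-"
        mat = dendropy.StandardCharacterMatrix.from_dict(
            {
                name: "".join(str(alphabet.index(c)) for c in states)
                for name, states in zip(
                    chars.haplotype_names, chars.haplotype_states
                )
            },
            taxon_namespace=taxa,
        )
        taxon_states = mat.taxon_state_sets_map(gaps_as_missing=False)
        score = fitch_down_pass(dtree.postorder_node_iter(), taxon_state_sets_map=taxon_states)
        assert score == result.length == 20

    def test_duplicate_haplotype_adds_no_steps(self):
        rng = random.Random(23)
        chars = random_character_matrix(rng, 5, 4)
        res = mp_search(chars)
        dup = CharacterMatrix(
            chars.positions,
            chars.haplotype_names + ("t0b",),
            chars.haplotype_states + (chars.haplotype_states[0],),
        )
        res_dup = mp_search(dup)
        assert res_dup.length == res.length


class TestSearch:
    def test_parental_its_single_tree_12_steps_ci_ri_1(self):
        result = mp_search(dedupe(its_parental_matrix()))
        assert result.length == 12
        assert result.ci == 1.0
        assert result.ri == 1.0
        assert len(distinct_mp_trees(result)) == 1

    def test_cp_matrix_20_steps_ci_ri_1(self, cp_matrix):
        result = mp_search(dedupe(cp_matrix))
        assert result.length == 20
        assert result.ci == 1.0
        assert result.ri == 1.0
        assert not result.ri_degenerate
        # binary resolutions of one polytomy collapse to a single MP tree
        assert len(distinct_mp_trees(result)) == 1

    def test_four_taxon_conflict(self):
        """Two incompatible binary splits on 4 taxa: the best trees fit
        one character (1 step) and pay 2 on the other; CI = 2/3."""
        chars = CharacterMatrix(
            (1, 2),
            ("t1", "t2", "t3", "t4"),
            ("AA", "AC", "CA", "CC"),
        )
        result = mp_search(chars, mode="exhaustive")
        assert result.length == 3
        assert result.n_trees == 2
        assert result.ci == pytest.approx(2 / 3)
        assert not is_perfectly_compatible(chars)

    def test_branch_and_bound_equals_exhaustive(self):
        rng = random.Random(31)
        for n in (5, 6, 7, 8):
            chars = random_character_matrix(rng, n, 5)
            ex = mp_search(chars, mode="exhaustive")
            bb = mp_search(chars, mode="branch_and_bound")
            assert ex.length == bb.length
            assert set(ex.trees) == set(bb.trees)

    def test_capacity_cap(self):
        chars = CharacterMatrix(
            (1,),
            tuple(f"t{i}" for i in range(17)),
            tuple("A" if i else "C" for i in range(17)),
        )
        with pytest.raises(CapacityError):
            mp_search(chars)

    def test_length_at_least_sum_m_and_equality_iff_ci_1(self):
        rng = random.Random(37)
        for _ in range(8):
            chars = random_character_matrix(rng, 6, 4)
            result = mp_search(chars)
            m = sum(
                len({s[j] for s in chars.haplotype_states}) - 1
                for j in range(chars.n_characters)
            )
            assert result.length >= m
            assert (result.length == m) == (result.ci == 1.0)

    def test_compatible_implies_length_equals_characters(self, cp_matrix):
        chars = dedupe(cp_matrix)
        assert is_perfectly_compatible(chars)
        result = mp_search(chars)
        # all 20 cp characters are binary, so sum(m_i) = 20
        assert result.length == chars.n_characters


class TestIndices:
    def test_homoplasy_free_ci_1(self, cp_matrix):
        chars = dedupe(cp_matrix)
        result = mp_search(chars)
        assert consistency_index(result.per_character_steps, chars) == 1.0

    def test_autapomorphy_only_ri_degenerate(self):
        chars = CharacterMatrix(
            (1, 2),
            ("t1", "t2", "t3", "t4"),
            ("AA", "CA", "GC", "GA"),
        )
        # char 1: A/C/G with singletons; char 2: single C autapomorphy
        result = mp_search(chars)
        ri = retention_index(result.per_character_steps, chars)
        assert ri.degenerate and ri.value == 1.0

    def test_parental_its_ri_uses_taxon_counts(self):
        """RI is defined over the 10 accessions (5 per species), not the
        2 distinct haplotypes: g_i = 10 - 5 = 5 per character."""
        chars = dedupe(its_parental_matrix())
        result = mp_search(chars)
        ri = retention_index(result.per_character_steps, chars)
        assert ri.value == 1.0 and not ri.degenerate


class TestBranchMapping:
    def test_parental_tree_carries_all_12_changes_on_single_branch(self):
        chars = dedupe(its_parental_matrix())
        result = mp_search(chars)
        changes = map_changes_to_branches(result.trees[0], chars)
        non_empty = [ch for ch in changes.values() if ch]
        assert len(non_empty) == 1 and len(non_empty[0]) == 12

    def test_cp_tree_indels_map_to_griffithii_bin_branch(self, cp_matrix):
        """The six single-base indel characters 164-169 change on the
        branch separating the griffithii-type haplotypes (incl. the BIN
        accession's) from everything else."""
        chars = dedupe(cp_matrix)
        result = mp_search(chars)
        tree = result.trees[0]
        griffithii_side = frozenset({"SL", "MT"})  # haplotype representatives
        changes = map_changes_to_branches(tree, chars)
        for edge, ch in changes.items():
            side = tree.split_for_edge(edge)
            if side in (griffithii_side,
                        frozenset(chars.haplotype_names) - griffithii_side):
                positions = {p for p, _, _ in ch}
                assert {164, 165, 166, 167, 168, 169} <= positions
                break
        else:
            pytest.fail("griffithii split not found in MP tree")

    def test_change_counts_sum_to_length(self):
        rng = random.Random(41)
        for _ in range(5):
            chars = random_character_matrix(rng, 6, 5)
            result = mp_search(chars)
            for tree in result.trees:
                changes = map_changes_to_branches(tree, chars)
                assert sum(len(c) for c in changes.values()) == result.length

    def test_constant_character_never_changes(self):
        chars = CharacterMatrix(
            (1, 2), ("a", "b", "c", "d"), ("AA", "AC", "AC", "AA")
        )
        result = mp_search(chars)
        changes = map_changes_to_branches(result.trees[0], chars)
        assert all(p != 1 for ch in changes.values() for p, _, _ in ch)


class TestNewick:
    def test_three_leaf_form(self):
        tree = next(enumerate_topologies(("A", "B", "C")))
        assert to_newick(tree) == "(A,B,C);"

    def test_roundtrip_random_topologies(self):
        rng = random.Random(43)
        labels = tuple(f"t{i}" for i in range(8))
        trees = []
        for tree in enumerate_topologies(labels):
            trees.append(tree)
            if len(trees) == 200:
                break
        for tree in rng.sample(trees, 20):
            assert from_newick(to_newick(tree)) == tree

    def test_member_expansion(self):
        chars = dedupe(its_parental_matrix())
        result = mp_search(chars)
        nwk = to_newick(result.trees[0], members=chars.members)
        assert "CORDATA_1|CORDATA_2" in nwk

    def test_parental_tree_two_clusters(self):
        """The parental ITS MP tree separates the two species."""
        chars = dedupe(its_parental_matrix())
        result = mp_search(chars)
        tree = collapse_zero_change_branches(result.trees[0], chars)
        assert tree.n_leaves == 2  # one haplotype per species


class TestCollapse:
    def test_zero_change_collapse_is_stable_under_resolution(self, cp_matrix):
        chars = dedupe(cp_matrix)
        result = mp_search(chars)
        collapsed = {
            collapse_zero_change_branches(t, chars) for t in result.trees
        }
        assert len(collapsed) == 1
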