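"""Compact prefix tree construction, both orders, and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sof.io_cli import generate_overlapping_reads, random_reads_with_lengths
from sof.prefix_trie import (
    MatchCursor,
    NotSortedError,
    TrieNode,
    build,
    build_sorted,
    build_unsorted,
    dump,
    resolve_char,
    sort_reads,
    tries_equal,
    validate,
)
from sof.readset import BASE_TO_CODE

from .conftest import EXAMPLE_SEQS, make_readset

read_sets = st.lists(
    st.text(alphabet="ACGT", min_size=1, max_size=12), min_size=1, max_size=25
)


def _child(node, base):
    return node.children[BASE_TO_CODE[base]]


class TestSortReads:
    def test_already_sorted_example(self, example_reads):
        ordered, perm = sort_reads(example_reads)
        assert [r.sequence for r in ordered.reads] == EXAMPLE_SEQS
        assert [r.id for r in ordered.reads] == [1, 2, 3, 4, 5]
        assert list(perm) == [1, 2, 3, 4, 5]

    def test_two_element_swap(self):
        ordered, perm = sort_reads(make_readset(["T", "A"]))
        assert [r.sequence for r in ordered.reads] == ["A", "T"]
        assert list(perm) == [2, 1]

    def test_matches_builtin_sort_and_is_stable(self):
        rng = np.random.default_rng(7)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=rng.integers(1, 15)))
            for _ in range(100)
        ]
        seqs += seqs[:10]  # force duplicates
        rs = make_readset(seqs)
        ordered, perm = sort_reads(rs)
        assert [r.sequence for r in ordered.reads] == sorted(seqs)
        # stability: duplicates keep file order
        for a, b in zip(ordered.reads, ordered.reads[1:]):
            if a.sequence == b.sequence:
                assert a.original_index < b.original_index


class TestBuildSorted:
    def test_first_insertion_state(self):
        trie, _ = build(make_readset(["AAGGG"]))
        node = _child(trie.root, "A")
        assert (node.chain_len, node.r1, node.r2) == (4, 1, 1)
        assert node.is_leaf()

    def test_split_after_second_string(self):
        trie, _ = build(make_readset(["AAGGG", "ACTTT"]))
        v1 = _child(trie.root, "A")
        assert (v1.chain_len, v1.r1, v1.r2) == (0, 1, 2)
        v2, v3 = _child(v1, "A"), _child(v1, "C")
        assert (v2.chain_len, v2.r1, v2.r2) == (3, 1, 1)
        assert (v3.chain_len, v3.r1, v3.r2) == (3, 2, 2)

    def test_third_string_new_branch(self):
        trie, _ = build(make_readset(["AAGGG", "ACTTT", "AGGCT"]))
        v3 = _child(_child(trie.root, "A"), "G")
        assert (v3.chain_len, v3.r1, v3.r2) == (3, 3, 3)

    def test_full_example_tree(self, example_trie):
        assert example_trie.leaf_count() == 5
        a = _child(example_trie.root, "A")
        assert (a.chain_len, a.r1, a.r2) == (0, 1, 3)
        assert validate(example_trie) == []

    def test_duplicates_share_one_leaf(self):
        trie, _ = build(make_readset(["AC", "AC"]))
        leaf = _child(trie.root, "A")
        assert leaf.is_leaf()
        assert (leaf.r1, leaf.r2, leaf.n_terminal) == (1, 2, 2)

    def test_unsorted_input_rejected(self):
        rs = make_readset(["T", "A"])
        for i, r in enumerate(rs.reads, 1):
            r.id = i
        with pytest.raises(NotSortedError):
            build_sorted(rs)

    def test_shredded_reads_valid_and_bounded(self):
        rs, _truth = generate_overlapping_reads(4000, 500, (30, 80), seed=5, with_truth=False)
        trie, _ = build(rs, sort=True)
        assert validate(trie) == []
        distinct = len({r.sequence for r in rs.reads})
        assert trie.node_count <= 2 * distinct - 1


class TestBuildUnsorted:
    def test_reverse_file_order_same_tree(self, example_trie):
        rs = make_readset(list(reversed(EXAMPLE_SEQS)))
        trie, perm = build_unsorted(rs)
        assert tries_equal(trie, example_trie)
        assert list(perm) == [5, 4, 3, 2, 1]

    def test_single_read(self):
        trie, perm = build_unsorted(make_readset(["GATTA"]))
        node = _child(trie.root, "G")
        assert (node.r1, node.r2) == (1, 1)
        assert list(perm) == [1]

    def test_triplicate_read_registry(self):
        trie, _ = build_unsorted(make_readset(["TGA", "TGA", "TGA"]))
        leaf = _child(trie.root, "T")
        assert (leaf.r1, leaf.r2) == (1, 3)
        assert trie.duplicate_lists() == [[1, 2, 3]]

    def test_relabel_permutation_equals_sort_rank(self):
        rs = random_reads_with_lengths(80, (5, 40), seed=11)
        _trie, perm = build_unsorted(rs)
        rs2 = random_reads_with_lengths(80, (5, 40), seed=11)
        _ordered, sort_perm = sort_reads(rs2)
        assert list(perm) == list(sort_perm)

    @given(read_sets)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_structural_equivalence_property(self, seqs):
        """Unsorted construction always builds the tree sorted
        construction would, including prefix/duplicate pathologies."""
        sorted_trie, _ = build(make_readset(seqs), sort=True)
        unsorted_trie, _ = build_unsorted(make_readset(seqs))
        assert tries_equal(unsorted_trie, sorted_trie)
        assert validate(unsorted_trie) == []


class TestResolveChar:
    def test_example_node_g(self, example_trie):
        node = _child(example_trie.root, "G")  # chain GCCAC, chain_len 4
        cursor = MatchCursor(current_node=node, local_position=1, path_len=1)
        assert resolve_char(example_trie, cursor) == "C"  # position 2 of GCCAC

    def test_interval_reads_agree_everywhere(self):
        rs, _ = generate_overlapping_reads(600, 80, (10, 40), seed=3, with_truth=False)
        trie, _ = build(rs, sort=True)
        stack = [(trie.root, 0)]
        while stack:
            node, plen = stack.pop()
            for local in range(1, node.chain_len + 1):
                cursor = MatchCursor(node, local, plen)
                want = resolve_char(trie, cursor)
                for rid in range(node.r1, node.r2 + 1):
                    seq = trie.read_by_id(rid).sequence
                    assert seq[plen + local - 1] == want
            for child in node.child_nodes():
                stack.append((child, plen + 1 + node.chain_len if node is not trie.root else plen + 0))

    def test_cursor_past_chain_rejected(self, example_trie):
        node = _child(example_trie.root, "G")
        with pytest.raises(ValueError):
            resolve_char(example_trie, MatchCursor(node, node.chain_len + 2, 1))


class TestInvariants:
    def test_path_soundness_leaves_spell_reads(self, example_trie):
        """Decoding every root-to-leaf path reproduces the read."""
        stack = [(example_trie.root, "")]
        spelled = []
        while stack:
            node, prefix = stack.pop()
            if node is not example_trie.root:
                cursor_chars = [
                    resolve_char(
                        example_trie, MatchCursor(node, local, len(prefix) + 1)
                    )
                    for local in range(1, node.chain_len + 1)
                ]
                label = "ACGT"[node.label]
                prefix = prefix + label + "".join(cursor_chars)
            if node.is_leaf():
                spelled.append(prefix)
            for child in node.child_nodes():
                stack.append((child, prefix))
        assert sorted(spelled) == sorted({r.sequence for r in example_trie.read_set.reads})

    def test_linear_construction_work(self):
        rs = random_reads_with_lengths(400, (20, 120), seed=19)
        trie, _ = build(rs, sort=True)
        assert trie.comparisons <= 2 * rs.n

    @given(read_sets)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_fuzzed_tries_always_validate(self, seqs):
        trie, _ = build(make_readset(seqs), sort=True)
        assert validate(trie) == []

    def test_validate_flags_single_child_internal_node(self, example_trie):
        # negative control: graft a 1-child chain above an existing leaf
        g = _child(example_trie.root, "G")
        fake = TrieNode(label=BASE_TO_CODE["G"], chain_len=0, rep=g.rep)
        fake.r1, fake.r2 = g.r1, g.r2
        idx = BASE_TO_CODE["C"]
        g2 = TrieNode(label=idx, chain_len=g.chain_len - 1, rep=g.rep)
        g2.r1, g2.r2, g2.n_terminal = g.r1, g.r2, g.n_terminal
        fake.children[idx] = g2
        example_trie.root.children[BASE_TO_CODE["G"]] = fake
        example_trie.node_count += 1
        assert any("single-child" in v for v in validate(example_trie))

    def test_dump_format(self, example_trie):
        lines = dump(example_trie).strip().split("\n")
        assert lines[0] == "0\t.\t0\t1\t5"
        assert len(lines) == example_trie.node_count + 1
        assert all(len(line.split("\t")) == 5 for line in lines)
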