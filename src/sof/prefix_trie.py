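"""Compact prefix tree (radix trie) over a set of DNA reads.

The tree stores one node per maximal shared-prefix group.  Instead of
materialising edge strings it keeps, per node, a one-character edge
``label`` and a ``chain_len``: the number of further characters that are
implicit in the node and are recovered on demand from the original text
via a representative read.  Each node also carries a ``(r1, r2)``
interval over the lexicographic identification numbers 1..k of the
reads: exactly the reads whose sequence starts with the prefix spelled
by the root-to-node path.

Two constructions are provided and produce structurally identical
trees:

* :func:`build_sorted` — reads are inserted in lexicographic order and
  intervals are maintained on the fly (the upper bound of every node on
  the insertion path is simply extended to the new id).
* :func:`build_unsorted` — reads are inserted in file order ignoring
  internal intervals; a depth-first relabelling pass
  (:func:`relabel_intervals_dfs`) then assigns identification numbers
  to leaves with a counter and folds them up into the internal nodes.

Reads that are exact duplicates of one another share a single path and
a single node; the node records how many reads terminate in it
(``n_terminal``) and which ones (``terminal_origs``, the duplicate
lists used by the unsorted construction).  A read that is a proper
prefix of another read likewise terminates in the middle of the tree;
such nodes are the only ones allowed to have a single child.

Both constructions process each input character exactly once, so
construction runs in O(n) character comparisons for n total bases
(tracked in ``Trie.comparisons``) and the tree has at most 2k - 1
nodes for k distinct prefix-free reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .readset import CODE_TO_BASE, Read, ReadSet, ReadSetError

_BASES = "ACGT"


class NotSortedError(ValueError):
    """build_sorted was handed reads that are not in lexicographic order."""


class TrieNode:
    """One node of the compact prefix tree.

    ``label`` is the 2-bit code (0..3) of the edge character from the
    parent, or -1 for the root.  ``chain_len`` counts the implicit
    characters stored beyond the edge label.  ``children`` is a fixed
    4-slot list indexed by base code, so iteration is always in
    A < C < G < T order.  ``rep`` is the insertion number of a read
    whose sequence spells this node's path (used to resolve chain
    characters during construction); after construction the read with
    id ``r1`` serves the same purpose.
    """

    __slots__ = (
        "label",
        "chain_len",
        "r1",
        "r2",
        "children",
        "rep",
        "n_terminal",
        "terminal_origs",
    )

    def __init__(self, label: int, chain_len: int, rep: int):
        self.label = label
        self.chain_len = chain_len
        self.r1 = 0
        self.r2 = 0
        self.children: list[TrieNode | None] = [None, None, None, None]
        self.rep = rep
        self.n_terminal = 0
        self.terminal_origs: list[int] | None = None

    def child_nodes(self):
        return [c for c in self.children if c is not None]

    def is_leaf(self) -> bool:
        return all(c is None for c in self.children)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        lab = _BASES[self.label] if 0 <= self.label <= 3 else "."
        return f"TrieNode({lab}, chain={self.chain_len}, [{self.r1},{self.r2}])"


@dataclass
class MatchCursor:
    """Traversal state shared by construction and suffix matching.

    ``local_position`` is the 1-based position inside the current
    node's chain that the next input character will be compared
    against; ``path_len`` is the total number of characters consumed
    above that chain (all edge labels, each of length 1, plus every
    fully traversed chain).  The character under the cursor sits at
    1-based position ``path_len + local_position`` of the node's
    representative read.
    """

    current_node: TrieNode
    local_position: int = 1
    path_len: int = 0


class Trie:
    """Compact prefix tree bound to the :class:`ReadSet` it indexes."""

    def __init__(self, read_set: ReadSet):
        self.read_set = read_set
        self.root = TrieNode(label=-1, chain_len=0, rep=1)
        self.root.r1 = 1
        self.root.r2 = read_set.k
        self.node_count = 0  # nodes excluding the root
        self.comparisons = 0  # character comparisons during construction
        #: codes of the read with each id, index id-1 (filled once ids exist)
        self.codes_by_id: list[bytes] = []

    # -- plumbing ---------------------------------------------------------

    def read_by_id(self, read_id: int) -> Read:
        return self.read_set.reads[self._pos_by_id[read_id - 1]]

    def _finish(self, ordered_reads: list[Read]) -> None:
        """Record id -> read bookkeeping once every read has its id."""
        self.codes_by_id = [b""] * self.read_set.k
        self._pos_by_id = [0] * self.read_set.k
        for pos, r in enumerate(self.read_set.reads):
            self.codes_by_id[r.id - 1] = r.codes
            self._pos_by_id[r.id - 1] = pos

    def iter_nodes(self, include_root: bool = False):
        """Preorder traversal (children in A<C<G<T order), iterative."""
        stack = [(self.root, 0)]
        while stack:
            node, depth = stack.pop()
            if include_root or node is not self.root:
                yield node, depth
            for child in reversed(node.child_nodes()):
                stack.append((child, depth + 1))

    def duplicate_lists(self) -> list[list[int]]:
        """Per distinct sequence, the original indices of identical reads."""
        return [
            list(node.terminal_origs)
            for node, _ in self.iter_nodes()
            if node.terminal_origs
        ]

    def leaf_count(self) -> int:
        return sum(1 for node, _ in self.iter_nodes() if node.is_leaf())


def sort_reads(read_set: ReadSet) -> tuple[ReadSet, np.ndarray]:
    """Sort reads lexicographically and assign identification numbers.

    Returns a new :class:`ReadSet` in id order plus the permutation
    array ``perm`` with ``perm[original_index - 1] == id``.  The sort is
    stable: equal sequences keep their input order, so duplicates get
    consecutive ids in file order.
    """
    if read_set is None or read_set.k == 0:
        raise ReadSetError("cannot sort an empty read set")
    ordered = sorted(read_set.reads, key=lambda r: r.sequence)
    perm = np.zeros(read_set.k, dtype=np.int64)
    for rank, read in enumerate(ordered, start=1):
        read.id = rank
        perm[read.original_index - 1] = rank
    return ReadSet(ordered), perm


def resolve_char(trie: Trie, cursor: MatchCursor) -> str:
    """Character the cursor points at, recovered from the original text.

    The representative read is the one with id equal to the node's
    interval lower bound; every read in the interval agrees on this
    position because they share the node's path prefix.
    """
    node = cursor.current_node
    if cursor.local_position > node.chain_len + 1:
        raise ValueError("cursor past the end of the node's chain")
    codes = trie.codes_by_id[node.r1 - 1]
    pos = cursor.path_len + cursor.local_position - 1  # 0-based
    if pos >= len(codes):
        raise RuntimeError("cursor position beyond representative read")
    return CODE_TO_BASE[codes[pos]]


# -- construction ---------------------------------------------------------


def _insert(trie: Trie, codes_of: list[bytes], s: bytes, i: int, sorted_mode: bool) -> None:
    """Insert read number ``i`` (codes ``s``) into the tree.

    ``i`` is the read id under sorted construction and the original
    file index under unsorted construction; ``codes_of[i-1]`` must be
    ``s``.  Every input character is consumed by exactly one
    comparison: against a chain character or against the branch table.
    """
    L = len(s)
    cur = trie.root
    local = 1
    path_len = 0
    comp = 0
    while True:
        pos = path_len + local - 1  # 0-based position of the next character
        if pos == L:
            _insert_exhausted(trie, codes_of, cur, local, path_len, i, sorted_mode)
            break
        c = s[pos]
        if local <= cur.chain_len:
            comp += 1
            if c == codes_of[cur.rep - 1][pos]:
                local += 1
                continue
            _split_mismatch(trie, codes_of, cur, local, path_len, c, i, L, sorted_mode)
            break
        comp += 1
        child = cur.children[c]
        if child is None:
            # pos characters are already consumed by the path and the
            # current node's (fully matched) chain; the branch label c
            # consumes one more
            leaf = TrieNode(label=c, chain_len=L - pos - 1, rep=i)
            leaf.r1 = leaf.r2 = i
            leaf.n_terminal = 1
            leaf.terminal_origs = [i]
            cur.children[c] = leaf
            trie.node_count += 1
            break
        path_len += cur.chain_len + 1
        cur = child
        local = 1
        if sorted_mode:
            cur.r2 = i
    trie.comparisons += comp


def _split_mismatch(
    trie: Trie,
    codes_of: list[bytes],
    v: TrieNode,
    local: int,
    path_len: int,
    c: int,
    i: int,
    L: int,
    sorted_mode: bool,
) -> None:
    """Mismatch inside a chain: split v into v1 (upper, reusing v) and v2
    (lower, keeping v's children and terminal reads), and hang a new
    leaf v3 for the incoming read off v1."""
    d = codes_of[v.rep - 1][path_len + local - 1]
    v2 = TrieNode(label=d, chain_len=v.chain_len - local, rep=v.rep)
    v2.children = v.children
    v2.n_terminal = v.n_terminal
    v2.terminal_origs = v.terminal_origs
    if sorted_mode:
        v2.r1 = v.r1
        v2.r2 = v.r2 - 1  # v's upper bound was already extended to i on entry
    v3 = TrieNode(label=c, chain_len=L - path_len - local, rep=i)
    v3.r1 = v3.r2 = i
    v3.n_terminal = 1
    v3.terminal_origs = [i]
    v.chain_len = local - 1
    v.children = [None, None, None, None]
    v.children[d] = v2
    v.children[c] = v3
    v.n_terminal = 0
    v.terminal_origs = None
    trie.node_count += 2


def _insert_exhausted(
    trie: Trie,
    codes_of: list[bytes],
    v: TrieNode,
    local: int,
    path_len: int,
    i: int,
    sorted_mode: bool,
) -> None:
    """The read ran out of characters: it duplicates, or is a prefix of,
    material already in the tree."""
    if local == v.chain_len + 1:
        # ends exactly at the node boundary
        if v.n_terminal > 0:
            v.n_terminal += 1
            v.terminal_origs.append(i)
            return
        if sorted_mode:
            # under lexicographic order every extension of this read would
            # have been inserted after it
            raise NotSortedError("read is a prefix of an earlier read")
        v.n_terminal = 1
        v.terminal_origs = [i]
        return
    if sorted_mode:
        raise NotSortedError("read is a prefix of an earlier read")
    # ends mid-chain: split v into v1 (terminal for i) and v2 (the rest)
    d = codes_of[v.rep - 1][path_len + local - 1]
    v2 = TrieNode(label=d, chain_len=v.chain_len - local, rep=v.rep)
    v2.children = v.children
    v2.n_terminal = v.n_terminal
    v2.terminal_origs = v.terminal_origs
    v.chain_len = local - 1
    v.children = [None, None, None, None]
    v.children[d] = v2
    v.n_terminal = 1
    v.terminal_origs = [i]
    trie.node_count += 1


def build_sorted(read_set: ReadSet) -> Trie:
    """Build the tree from reads already in lexicographic order.

    Reads must carry ids 1..k matching their list order (as produced by
    :func:`sort_reads`); a violated order raises :class:`NotSortedError`.
    """
    reads = read_set.reads
    for j, r in enumerate(reads):
        if r.id != j + 1:
            raise NotSortedError("reads are not numbered 1..k in list order")
        if j and reads[j - 1].sequence > r.sequence:
            raise NotSortedError("reads are not in lexicographic order")
    trie = Trie(read_set)
    codes_of = [r.codes for r in reads]
    for j, r in enumerate(reads):
        _insert(trie, codes_of, r.codes, j + 1, sorted_mode=True)
    trie._finish(reads)
    return trie


def build_unsorted(read_set: ReadSet) -> tuple[Trie, np.ndarray]:
    """Build the tree from reads in file order, without sorting.

    Stage 1 inserts every read ignoring internal intervals (leaves are
    provisionally tagged with file indices, duplicates collected into
    per-sequence lists).  Stage 2 is :func:`relabel_intervals_dfs`.
    Returns the tree and the permutation original_index -> id, which
    equals the lexicographic-rank permutation.
    """
    trie = Trie(read_set)
    reads = read_set.reads
    codes_of = [r.codes for r in reads]
    for j, r in enumerate(reads):
        _insert(trie, codes_of, r.codes, j + 1, sorted_mode=False)
    perm = relabel_intervals_dfs(trie)
    for r in reads:
        r.id = int(perm[r.original_index - 1])
    trie._finish(reads)
    return trie, perm


def relabel_intervals_dfs(trie: Trie) -> np.ndarray:
    """Assign identification numbers by depth-first traversal.

    Children are visited in A < C < G < T order; a counter hands out
    consecutive ids to the reads terminating in each node (duplicate
    lists keep file order, so equal reads get sequential numbers), and
    each internal node's interval is set once its children are done.
    Iterative so path depth is not limited by the recursion limit.
    """
    k = trie.read_set.k
    perm = np.zeros(k, dtype=np.int64)
    counter = 1
    # stack holds (node, entered) pairs
    stack: list[tuple[TrieNode, bool]] = [(trie.root, False)]
    while stack:
        node, entered = stack.pop()
        if not entered:
            node.r1 = counter
            if node.n_terminal:
                for orig in node.terminal_origs:
                    perm[orig - 1] = counter
                    counter += 1
            stack.append((node, True))
            for child in reversed(node.child_nodes()):
                stack.append((child, False))
        else:
            node.r2 = counter - 1
    return perm


def build(read_set: ReadSet, sort: bool = True) -> tuple[Trie, np.ndarray]:
    """Convenience wrapper: sort-and-build or build-unsorted."""
    if sort:
        ordered, perm = sort_reads(read_set)
        return build_sorted(ordered), perm
    return build_unsorted(read_set)


# -- introspection --------------------------------------------------------


def node_path_len(trie: Trie, target: TrieNode) -> int:
    """Total characters spelled by the root-to-node path (labels + chains)."""
    # DFS carrying accumulated length; fine for diagnostics
    stack = [(trie.root, 0)]
    while stack:
        node, plen = stack.pop()
        total = plen if node is trie.root else plen + 1 + node.chain_len
        if node is target:
            return total
        for child in node.child_nodes():
            stack.append((child, total))
    raise ValueError("node not in trie")


def validate(trie: Trie) -> list[str]:
    """Check every structural invariant; returns violations (empty = valid).

    Checks: interval bounds and contiguity, child ordering by base,
    chain lengths, terminal multiplicities, the >= 2 children rule for
    non-terminal internal nodes, that every read in a node's interval
    shares the node's path prefix, and global leaf/node counts.
    """
    errs: list[str] = []
    k = trie.read_set.k
    root = trie.root
    if root.r1 != 1 or root.r2 != k:
        errs.append(f"root interval [{root.r1},{root.r2}] != [1,{k}]")

    n_nodes = 0
    n_leaves = 0
    n_terminal_nodes = 0
    total_terminal = 0
    stack: list[tuple[TrieNode, int]] = [(root, 0)]
    while stack:
        node, plen = stack.pop()
        is_root = node is root
        if not is_root:
            n_nodes += 1
            if not 0 <= node.label <= 3:
                errs.append(f"{node!r}: bad label")
            if node.chain_len < 0:
                errs.append(f"{node!r}: negative chain_len")
        if not (1 <= node.r1 <= node.r2 <= k):
            errs.append(f"{node!r}: interval out of bounds")
        prefix_len = plen if is_root else plen + 1 + node.chain_len
        children = node.child_nodes()
        if not children and not is_root:
            n_leaves += 1
            if node.n_terminal != node.r2 - node.r1 + 1:
                errs.append(f"{node!r}: leaf multiplicity != interval width")
        elif not is_root and len(children) < 2 and node.n_terminal == 0:
            errs.append(f"{node!r}: single-child internal node is not a word end")
        if node.n_terminal:
            n_terminal_nodes += 1
            total_terminal += node.n_terminal
        # children tile the interval after the terminal block, in base order
        next_id = node.r1 + node.n_terminal
        for slot in range(4):
            child = node.children[slot]
            if child is None:
                continue
            if child.label != slot:
                errs.append(f"{child!r}: label does not match child slot")
            if child.r1 != next_id:
                errs.append(
                    f"{node!r}: child {child!r} starts at {child.r1}, expected {next_id}"
                )
            next_id = child.r2 + 1
            stack.append((child, prefix_len))
        if children and next_id - 1 != node.r2:
            errs.append(f"{node!r}: children do not cover interval")
        # prefix agreement over the interval
        if not is_root and trie.codes_by_id:
            rep = trie.codes_by_id[node.r1 - 1]
            if len(rep) < prefix_len:
                errs.append(f"{node!r}: representative shorter than path")
            else:
                want = rep[:prefix_len]
                for rid in range(node.r1, node.r2 + 1):
                    codes = trie.codes_by_id[rid - 1]
                    if codes[:prefix_len] != want:
                        errs.append(f"{node!r}: read id {rid} disagrees with path")
                        break
                for t in range(node.n_terminal):
                    if len(trie.codes_by_id[node.r1 + t - 1]) != prefix_len:
                        errs.append(f"{node!r}: terminal read length != path length")
                        break

    if n_nodes != trie.node_count:
        errs.append(f"node_count {trie.node_count} != traversed {n_nodes}")
    distinct = len({r.sequence for r in trie.read_set.reads})
    if n_terminal_nodes != distinct:
        errs.append(f"{n_terminal_nodes} word-end nodes != {distinct} distinct reads")
    if total_terminal != k:
        errs.append(f"terminal multiplicities sum to {total_terminal}, not k={k}")
    return errs


def dump(trie: Trie) -> str:
    """Plain-text preorder dump, one node per line, for debugging/diffing.

    Format: ``depth<TAB>label<TAB>chain_len<TAB>r1<TAB>r2`` with ``.``
    for the root's label.
    """
    lines = []
    for node, depth in trie.iter_nodes(include_root=True):
        lab = _BASES[node.label] if 0 <= node.label <= 3 else "."
        lines.append(f"{depth}\t{lab}\t{node.chain_len}\t{node.r1}\t{node.r2}")
    return "\n".join(lines) + "\n"


def tries_equal(a: Trie, b: Trie) -> bool:
    """Node-for-node structural equality (labels, chains, intervals,
    terminal multiplicities, child layout)."""
    stack = [(a.root, b.root)]
    while stack:
        x, y = stack.pop()
        if (
            x.label != y.label
            or x.chain_len != y.chain_len
            or x.r1 != y.r1
            or x.r2 != y.r2
            or x.n_terminal != y.n_terminal
        ):
            return False
        for slot in range(4):
            cx, cy = x.children[slot], y.children[slot]
            if (cx is None) != (cy is None):
                return False
            if cx is not None:
                stack.append((cx, cy))
    return True
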