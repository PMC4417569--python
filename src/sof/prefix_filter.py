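"""Containment prefiltering: drop reads contained in other reads.

In the assembly context a read that equals a prefix or a suffix of
another read carries no extra overlap information and is usually
removed before the overlap stage.  The compact prefix tree makes both
cases cheap to detect:

* prefix containment — a read that is a proper prefix of (or equal to)
  another read terminates in a node that has children; all reads
  terminating in such a node are contained.  Exact duplicates
  terminate together in a leaf: exactly one copy (the smallest
  original file index, which the stable ordering puts first) survives.
* suffix containment — walking a proper suffix of any read down the
  tree and exhausting it exactly at a node boundary where reads
  terminate means those terminal reads equal that suffix.

Removal is recorded in a k-bit vector (:class:`RemovedMask`); the
overlap stage consults the mask at emission time instead of rebuilding
the tree, which yields the same records over the surviving reads.
Containment at interior offsets (substring but neither prefix nor
suffix) is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apsp import _walk
from .prefix_trie import Trie
from .readset import ReadSet

REASONS = ("prefix_contained", "suffix_contained", "duplicate")


@dataclass
class RemovedMask:
    """k boolean flags (index id-1) plus the reason for each removal."""

    bits: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    @classmethod
    def empty(cls, k: int) -> "RemovedMask":
        return cls(bits=np.zeros(k, dtype=bool))

    def mark(self, read_id: int, reason: str) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown removal reason {reason!r}")
        if not self.bits[read_id - 1]:
            self.bits[read_id - 1] = True
            self.reasons[read_id] = reason

    def removed_ids(self) -> list[int]:
        return [int(i) + 1 for i in np.flatnonzero(self.bits)]

    def count(self) -> int:
        return int(self.bits.sum())


def filter_prefix_contained(trie: Trie, mask: RemovedMask | None = None) -> RemovedMask:
    """Mark reads that are proper prefixes of other reads.

    Terminal reads of any node that has children are contained
    regardless of insertion order (both the read-inserted-first and the
    read-inserted-later cases of the two constructions land in the same
    tree shape).  Duplicate handling is deferred to
    :func:`filter_duplicates` so that reason precedence is
    prefix > suffix > duplicate.
    """
    if mask is None:
        mask = RemovedMask.empty(trie.read_set.k)
    for node, _depth in trie.iter_nodes():
        if node.n_terminal and not node.is_leaf():
            for rid in range(node.r1, node.r1 + node.n_terminal):
                mask.mark(rid, "prefix_contained")
    return mask


def filter_suffix_contained(
    trie: Trie, read_set: ReadSet, mask: RemovedMask | None = None
) -> RemovedMask:
    """Mark reads equal to a proper suffix of another read.

    Every proper suffix of every read (removed or not — containment is
    judged against the full input) is walked down the tree; exhaustion
    exactly at a node boundary where reads terminate identifies those
    terminal reads as suffix-contained.  Reuses the same walk as
    overlap matching.
    """
    if mask is None:
        mask = RemovedMask.empty(read_set.k)
    codes_by_id = trie.codes_by_id
    for i in range(1, read_set.k + 1):
        s = codes_by_id[i - 1]
        L = len(s)
        for start0 in range(1, L):
            node, local, _ = _walk(trie, s, start0)
            if node is None or node.n_terminal == 0:
                continue
            if local != node.chain_len + 1:
                continue  # exhausted mid-chain: nothing terminates here
            for rid in range(node.r1, node.r1 + node.n_terminal):
                mask.mark(rid, "suffix_contained")
    return mask


def filter_duplicates(trie: Trie, mask: RemovedMask | None = None) -> RemovedMask:
    """Among exact duplicates, keep only the smallest original index.

    The surviving copy is the terminal read with the lowest id, which
    under the stable lexicographic numbering is also the one earliest
    in the input file.
    """
    if mask is None:
        mask = RemovedMask.empty(trie.read_set.k)
    for node, _depth in trie.iter_nodes():
        if node.n_terminal > 1:
            for rid in range(node.r1 + 1, node.r1 + node.n_terminal):
                mask.mark(rid, "duplicate")
    return mask


def filter_contained(trie: Trie, read_set: ReadSet) -> RemovedMask:
    """Full prefilter: prefix containment, then suffix containment,
    then duplicate pruning.  Idempotent by construction (the mask only
    ever grows, and a second pass finds the same nodes)."""
    mask = RemovedMask.empty(read_set.k)
    filter_prefix_contained(trie, mask)
    filter_suffix_contained(trie, read_set, mask)
    filter_duplicates(trie, mask)
    return mask


def removal_report(mask: RemovedMask, trie: Trie) -> str:
    """TSV ``read_header<TAB>reason`` for every removed read."""
    lines = []
    for rid in mask.removed_ids():
        read = trie.read_by_id(rid)
        lines.append(f"{read.header}\t{mask.reasons[rid]}")
    return "\n".join(lines) + ("\n" if lines else "")
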