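"""All-pairs suffix-prefix matching over the compact prefix tree.

Every proper suffix of every read (longest first, i.e. starting at
position 2) is walked down the tree.  A suffix that is exhausted on a
path ends in some node whose interval [r1, r2] lists exactly the reads
having that suffix as a prefix: one suffix-prefix match per read in the
interval.  A mismatch inside a chain, or an absent branch, ends the
walk with no match.  Per read of length l this tests O(l) suffixes of
total length O(l^2), giving the O(k l^2) overall bound for k reads.

Three output modes mirror a classic overlap-finder interface:

* ``all_matches`` — one record per (query, suffix position, target)
  that matches, not only the longest;
* ``longest_only`` — a k x k table of longest match lengths (0 = no
  overlap); because suffixes are visited longest first, the first match
  for an ordered pair is its longest;
* ``none`` — matches are counted but not materialised (for runs where
  the O(k^2) output itself is the bottleneck).

Note on whole reads: suffix enumeration starts at position 2, so a read
that equals a *prefix* of another read is never reported here — that is
containment, handled by :mod:`sof.prefix_filter`.  A suffix that equals
an entire other read *is* reported (the shorter read's whole sequence
is a prefix of itself), which is likewise the suffix-containment case
the filter can remove beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .prefix_trie import MatchCursor, Trie
from .readset import Read, ReadSet

MODES = ("none", "longest_only", "all_matches")

#: refuse to allocate the longest_only k x k table above this many reads
DEFAULT_MATRIX_CAP = 20000


class Overlap(NamedTuple):
    """One suffix-prefix match: suffix of ``query_id`` starting at
    1-based ``start_pos`` equals a prefix of ``target_id``."""

    query_id: int
    target_id: int
    length: int
    start_pos: int


@dataclass
class OverlapResult:
    """Outcome of one :func:`find_overlaps` run."""

    mode: str
    min_len: int
    k: int
    counts: int = 0
    records: Optional[list[Overlap]] = None
    matrix: Optional[np.ndarray] = None
    #: character comparisons spent per query id (index id-1)
    comparisons: list[int] = field(default_factory=list)

    def longest(self, query_id: int, target_id: int) -> int:
        """Longest overlap for an ordered pair (0 if none)."""
        if self.matrix is not None:
            return int(self.matrix[query_id - 1, target_id - 1])
        if self.records is None:
            raise ValueError("mode 'none' retains no per-pair results")
        best = 0
        for rec in self.records:
            if rec.query_id == query_id and rec.target_id == target_id:
                best = max(best, rec.length)
        return best


def _walk(trie: Trie, s: bytes, start: int):
    """Walk the suffix ``s[start:]`` down the tree.

    Returns ``(node, local, consumed)`` where ``node`` is the node in
    which the suffix was exhausted (None on mismatch/absent branch),
    ``local`` the final 1-based chain position, and ``consumed`` the
    number of character comparisons spent.
    """
    m = len(s) - start
    cur = trie.root
    local = 1
    path_len = 0
    codes_by_id = trie.codes_by_id
    while True:
        pos = path_len + local - 1
        if pos == m:
            return cur, local, pos
        c = s[start + pos]
        if local <= cur.chain_len:
            if c == codes_by_id[cur.r1 - 1][pos]:
                local += 1
                continue
            return None, local, pos + 1
        child = cur.children[c]
        if child is None:
            return None, local, pos + 1
        path_len += cur.chain_len + 1
        cur = child
        local = 1


def match_suffix(trie: Trie, read: Read, start_pos: int) -> Optional[tuple[int, int]]:
    """Interval of reads whose prefix equals ``read``'s suffix at
    1-based ``start_pos`` (>= 2), or None when no path matches.

    Exhaustion mid-chain also counts: every read below the current node
    shares the path walked so far.
    """
    if not 2 <= start_pos <= len(read):
        raise ValueError(f"start_pos {start_pos} outside 2..{len(read)}")
    node, _local, _consumed = _walk(trie, read.codes, start_pos - 1)
    if node is None:
        return None
    return node.r1, node.r2


def cursor_after(trie: Trie, read: Read, start_pos: int) -> Optional[MatchCursor]:
    """Like :func:`match_suffix` but returning the final traversal state."""
    node, local, _ = _walk(trie, read.codes, start_pos - 1)
    if node is None:
        return None
    plen = len(read) - start_pos + 1 - (local - 1)
    return MatchCursor(current_node=node, local_position=local, path_len=plen)


def find_overlaps(
    trie: Trie,
    read_set: ReadSet,
    min_len: int = 30,
    mode: str = "all_matches",
    include_self: bool = False,
    removed: Optional[np.ndarray] = None,
    matrix_cap: int = DEFAULT_MATRIX_CAP,
    queries: Optional[Iterable[int]] = None,
) -> OverlapResult:
    """Enumerate suffix-prefix overlaps of length >= ``min_len``.

    Parameters
    ----------
    trie:
        Tree built over ``read_set`` (ids assigned).
    min_len:
        Minimum overlap length; suffixes shorter than this are skipped.
    mode:
        One of ``none`` / ``longest_only`` / ``all_matches``.
    include_self:
        Report pairs with target == query (off by default).
    removed:
        Optional boolean vector indexed by id-1; removed reads are
        excluded both as queries and as targets (containment filter).
    queries:
        Restrict to these query ids (used by work plans); default all.
        Records come out in (query position, start_pos, target) order.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    k = read_set.k
    if trie.read_set is not read_set:
        raise ValueError("trie was not built over this read set")
    if not trie.codes_by_id:
        raise ValueError("trie has no identification numbers assigned")

    matrix = None
    records = None
    if mode == "longest_only":
        if k > matrix_cap:
            raise ValueError(
                f"longest_only needs a {k}x{k} table; above cap {matrix_cap}"
            )
        matrix = np.zeros((k, k), dtype=np.int32)
    elif mode == "all_matches":
        records = []

    comparisons = [0] * k
    counts = 0
    codes_by_id = trie.codes_by_id
    query_ids = range(1, k + 1) if queries is None else queries
    for i in query_ids:
        if removed is not None and removed[i - 1]:
            continue
        s = codes_by_id[i - 1]
        L = len(s)
        comp = 0
        # start positions 2..L (1-based); suffix length L-start+1 >= min_len
        for start0 in range(1, L - min_len + 1):
            node, _local, consumed = _walk(trie, s, start0)
            comp += consumed
            if node is None:
                continue
            r1, r2 = node.r1, node.r2
            length = L - start0
            if mode == "all_matches":
                for t in range(r1, r2 + 1):
                    if t == i and not include_self:
                        continue
                    if removed is not None and removed[t - 1]:
                        continue
                    records.append(Overlap(i, t, length, start0 + 1))
                    counts += 1
            elif mode == "longest_only":
                row = matrix[i - 1]
                for t in range(r1, r2 + 1):
                    if t == i and not include_self:
                        continue
                    if removed is not None and removed[t - 1]:
                        continue
                    if row[t - 1] == 0:
                        row[t - 1] = length
                        counts += 1
            else:
                hits = r2 - r1 + 1
                if removed is not None:
                    hits = int(np.count_nonzero(~removed[r1 - 1 : r2]))
                if r1 <= i <= r2 and not include_self:
                    if removed is None or not removed[i - 1]:
                        hits -= 1
                counts += hits
        comparisons[i - 1] = comp
    return OverlapResult(
        mode=mode,
        min_len=min_len,
        k=k,
        counts=counts,
        records=records,
        matrix=matrix,
        comparisons=comparisons,
    )
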