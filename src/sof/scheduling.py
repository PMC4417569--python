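"""Partitioning APSP work across workers, and parallel tree construction.

Processing one read of length l means walking every proper suffix, so
its cost is well estimated by W_S = l(l+1)/2 character comparisons.
Four strategies assign reads (never parts of a read) to p workers:

* ``equal_count`` — contiguous blocks of (almost) equal read counts;
* ``share`` — each worker takes consecutive reads until its
  accumulated W_S reaches the optimal share (total work / p);
* ``dynamic`` — a shared pointer hands out fixed-size chunks of reads
  to whichever worker is free (mutual exclusion on the pointer);
* ``greedy`` — reads are assigned one by one to the currently
  least-loaded worker.

Construction itself parallelises by first characters: reads grouped by
their first one (4 groups) or two (16 groups) characters build disjoint
subtrees that merge trivially under a shared root, giving the same tree
as a single-threaded build.

All strategies are pure functions of their inputs: identical plans on
every run, and the overlap output is independent of the strategy and of
p.  Actual concurrency is an execution concern layered on top
(:func:`run_plan` executes any plan serially, worker by worker, which
is how the correctness guarantees are stated and tested).
"""

from __future__ import annotations

import threading
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from . import apsp
from .prefix_trie import Trie, TrieNode, _insert, sort_reads
from .readset import BASE_TO_CODE, Read, ReadSet

STRATEGIES = ("equal_count", "share", "dynamic", "greedy")

DEFAULT_CHUNK_SIZE = 1024


@dataclass
class WorkPlan:
    """Assignment of the reads (by position 1..k in the read set's
    current order) to workers 0..p-1.

    ``r[i-1]`` is the worker handling read i; ``y[q]`` is worker q's
    total estimated work; ``start_p[q]`` is the first read of worker q
    for the contiguous strategies (None entries for empty workers).
    """

    strategy: str
    p: int
    r: list[int]
    y: list[int]
    start_p: Optional[list[Optional[int]]] = None

    @property
    def k(self) -> int:
        return len(self.r)

    def worker_reads(self) -> list[list[int]]:
        """Read positions (1-based) per worker, in processing order."""
        out: list[list[int]] = [[] for _ in range(self.p)]
        for i, q in enumerate(self.r, start=1):
            out[q].append(i)
        return out

    def dump(self) -> str:
        """TSV ``read_index<TAB>worker`` for tests and debugging."""
        return "\n".join(f"{i}\t{q}" for i, q in enumerate(self.r, start=1)) + "\n"


def estimate_work(read: Read) -> int:
    """W_S = |S| (|S|+1) / 2, the suffix-walk comparison estimate."""
    l = len(read)
    return l * (l + 1) // 2


def total_work(read_set: ReadSet) -> int:
    return sum(estimate_work(r) for r in read_set.reads)


def optimal_share(read_set: ReadSet, p: int) -> Fraction:
    """Total estimated work divided by the number of workers (exact)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return Fraction(total_work(read_set), p)


def _contiguous_plan(strategy: str, sizes: list[int], works: list[int], p: int) -> WorkPlan:
    r: list[int] = []
    y = [0] * p
    start_p: list[Optional[int]] = [None] * p
    pos = 0
    for q, size in enumerate(sizes):
        if size:
            start_p[q] = pos + 1
        for _ in range(size):
            r.append(q)
            y[q] += works[pos]
            pos += 1
    return WorkPlan(strategy=strategy, p=p, r=r, y=y, start_p=start_p)


def partition_equal_count(read_set: ReadSet, p: int) -> WorkPlan:
    """Contiguous blocks whose sizes differ by at most one read."""
    if p < 1:
        raise ValueError("p must be >= 1")
    k = read_set.k
    base, rem = divmod(k, p)
    sizes = [base + (1 if q < rem else 0) for q in range(p)]
    works = [estimate_work(r) for r in read_set.reads]
    return _contiguous_plan("equal_count", sizes, works, p)


def partition_by_share(read_set: ReadSet, p: int) -> WorkPlan:
    """Assign consecutive reads to a worker until its load reaches the
    optimal share, then move on; the last worker takes the remainder.

    The boundary is "accumulate until load >= share": with works
    6,10,10,6,6,10 and p=3 (share 16) this yields the 2/2/2 split in
    which every worker lands exactly on 16.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    works = [estimate_work(r) for r in read_set.reads]
    share = optimal_share(read_set, p)
    sizes = [0] * p
    q = 0
    acc = 0
    for w in works:
        sizes[q] += 1
        acc += w
        if acc >= share and q < p - 1:
            q += 1
            acc = 0
    return _contiguous_plan("share", sizes, works, p)


def greedy_assign(read_set: ReadSet, p: int) -> WorkPlan:
    """Least-loaded-first assignment, ties broken by lowest worker index."""
    if p < 1:
        raise ValueError("p must be >= 1")
    import heapq

    works = [estimate_work(r) for r in read_set.reads]
    heap = [(0, q) for q in range(p)]
    r: list[int] = []
    y = [0] * p
    for w in works:
        load, q = heapq.heappop(heap)
        r.append(q)
        y[q] = load + w
        heapq.heappush(heap, (load + w, q))
    return WorkPlan(strategy="greedy", p=p, r=r, y=y)


class ChunkDispenser:
    """Shared-pointer chunk dispenser for the dynamic strategy.

    ``next_chunk`` atomically hands out the next range of reads
    (1-based inclusive) or None when exhausted; concurrent consumers
    never receive overlapping ranges and no read is skipped.
    """

    def __init__(self, k: int, chunk_size: int = DEFAULT_CHUNK_SIZE):
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        self.k = k
        self.chunk_size = chunk_size
        self._next = 1
        self._lock = threading.Lock()

    def next_chunk(self) -> Optional[tuple[int, int]]:
        with self._lock:
            if self._next > self.k:
                return None
            start = self._next
            end = min(start + self.chunk_size - 1, self.k)
            self._next = end + 1
            return start, end


def dynamic_chunks(read_set: ReadSet, chunk_size: int = DEFAULT_CHUNK_SIZE) -> ChunkDispenser:
    """Dispenser over the read set's current order."""
    return ChunkDispenser(read_set.k, chunk_size)


def dynamic_plan(read_set: ReadSet, p: int, chunk_size: int = DEFAULT_CHUNK_SIZE) -> WorkPlan:
    """Deterministic serial materialisation of the dynamic strategy:
    chunk j goes to worker j mod p (the round-robin draw order a set of
    equally fast consumers would produce)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    works = [estimate_work(r) for r in read_set.reads]
    disp = dynamic_chunks(read_set, chunk_size)
    r = [0] * read_set.k
    y = [0] * p
    j = 0
    while True:
        chunk = disp.next_chunk()
        if chunk is None:
            break
        q = j % p
        for i in range(chunk[0], chunk[1] + 1):
            r[i - 1] = q
            y[q] += works[i - 1]
        j += 1
    return WorkPlan(strategy="dynamic", p=p, r=r, y=y)


def make_plan(
    strategy: str,
    read_set: ReadSet,
    p: int,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> WorkPlan:
    if strategy == "equal_count":
        return partition_equal_count(read_set, p)
    if strategy == "share":
        return partition_by_share(read_set, p)
    if strategy == "greedy":
        return greedy_assign(read_set, p)
    if strategy == "dynamic":
        return dynamic_plan(read_set, p, chunk_size)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def run_plan(
    trie: Trie,
    read_set: ReadSet,
    plan: WorkPlan,
    **find_kwargs,
) -> apsp.OverlapResult:
    """Execute a plan serially, worker by worker, and merge the results.

    Queries are the reads each worker owns (positions mapped to ids);
    the merged result equals a single-worker :func:`sof.apsp.find_overlaps`
    run up to record order.
    """
    reads = read_set.reads
    merged: Optional[apsp.OverlapResult] = None
    for positions in plan.worker_reads():
        ids = [reads[i - 1].id or i for i in positions]
        part = apsp.find_overlaps(trie, read_set, queries=ids, **find_kwargs)
        if merged is None:
            merged = part
            continue
        merged.counts += part.counts
        if merged.records is not None:
            merged.records.extend(part.records)
        if merged.matrix is not None:
            merged.matrix += part.matrix  # disjoint query rows
        merged.comparisons = [
            a + b for a, b in zip(merged.comparisons, part.comparisons)
        ]
    assert merged is not None
    return merged


# -- parallel construction by first characters ----------------------------


def partition_construction_by_prefix(
    read_set: ReadSet, depth: int = 1
) -> dict[str, list[Read]]:
    """Group reads by their first ``depth`` characters (depth 1 or 2).

    A read shorter than ``depth`` is grouped under its first character
    alone, so depth-2 keys may be one or two characters long.
    """
    if depth not in (1, 2):
        raise ValueError("depth must be 1 or 2")
    groups: dict[str, list[Read]] = {}
    for read in read_set.reads:
        key = read.sequence[:depth] if len(read) >= depth else read.sequence[:1]
        groups.setdefault(key, []).append(read)
    return groups


def build_partitioned(read_set: ReadSet, depth: int = 1) -> tuple[Trie, np.ndarray]:
    """Build the tree as independent per-prefix subtrees and merge them.

    Reads are sorted once (ids 1..k); each prefix group, a contiguous
    id block, is inserted into its own subtree, and the subtrees hang
    under a shared root.  At depth 2 the four XY subtrees sharing a
    first character X meet in an X node with chain_len 0 (their second
    characters differ by construction); length-1 reads terminate in
    that node.  The merged tree is node-for-node identical to
    :func:`sof.prefix_trie.build_sorted` on the full set.
    """
    ordered, perm = sort_reads(read_set)
    groups = partition_construction_by_prefix(ordered, depth)
    codes_of = [r.codes for r in ordered.reads]

    merged = Trie(ordered)
    sub_tries: dict[str, Trie] = {}
    for key, members in groups.items():
        sub = Trie(ordered)
        for read in members:
            _insert(sub, codes_of, read.codes, read.id, sorted_mode=True)
        sub_tries[key] = sub
        merged.comparisons += sub.comparisons

    for x_char in "ACGT":
        x = BASE_TO_CODE[x_char]
        sub_keys = sorted(key for key in sub_tries if key[0] == x_char)
        if not sub_keys:
            continue
        short_key = x_char if x_char in sub_tries and depth == 2 else None
        long_keys = [key for key in sub_keys if len(key) == depth or depth == 1]
        if depth == 1 or (len(sub_keys) == 1 and short_key is None):
            only = sub_tries[sub_keys[0]]
            merged.root.children[x] = only.root.children[x]
            merged.node_count += only.node_count
            continue
        # depth 2, several groups under X: they meet in an X node
        if short_key is not None:
            xnode = sub_tries[short_key].root.children[x]
            merged.node_count += sub_tries[short_key].node_count
        else:
            first_sub = sub_tries[long_keys[0]].root.children[x]
            xnode = TrieNode(label=x, chain_len=0, rep=first_sub.rep)
            merged.node_count += 1
        for key in long_keys:
            if key == short_key:
                continue
            child = sub_tries[key].root.children[x]
            # re-root one level down: the edge consumes the second character
            child.label = BASE_TO_CODE[key[1]]
            child.chain_len -= 1
            xnode.children[child.label] = child
            merged.node_count += sub_tries[key].node_count
        bounds = [xnode.r1, xnode.r2] if xnode.n_terminal else []
        for child in xnode.child_nodes():
            bounds.extend((child.r1, child.r2))
        xnode.r1, xnode.r2 = min(bounds), max(bounds)
        merged.root.children[x] = xnode

    merged._finish(ordered.reads)
    return merged, perm
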