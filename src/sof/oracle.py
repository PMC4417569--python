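"""Brute-force reference implementations for differential testing.

These deliberately avoid the prefix tree entirely: suffix-prefix
matching is done by hashing every prefix of every read and looking up
every proper suffix, and containment by direct string tests over all
pairs.  Quadratic space/time, obviously correct, and usable from the
command line (``sof verify``) to spot-check the tree-based results on
small inputs.
"""

from __future__ import annotations

import numpy as np

from .readset import ReadSet

Triple = tuple[int, int, int]  # (query_id, target_id, length)


def brute_force_apsp(
    read_set: ReadSet, min_len: int = 1, include_self: bool = False
) -> set[Triple]:
    """All suffix-prefix matches of length >= min_len, by definition.

    Reads are identified by their ids when assigned, else by position.
    Every prefix of every read is indexed in a dictionary; every proper
    suffix of every read of admissible length is looked up.  Returns
    the set of (query, target, length) triples; per-pair maxima follow
    by taking the max over lengths.
    """
    ids = [r.id if r.id is not None else j + 1 for j, r in enumerate(read_set.reads)]
    by_prefix: dict[str, list[int]] = {}
    for rid, read in zip(ids, read_set.reads):
        seq = read.sequence
        for plen in range(min_len, len(seq) + 1):
            by_prefix.setdefault(seq[:plen], []).append(rid)
    out: set[Triple] = set()
    for rid, read in zip(ids, read_set.reads):
        seq = read.sequence
        for start in range(1, len(seq) - min_len + 1):  # proper suffixes
            suffix = seq[start:]
            for tid in by_prefix.get(suffix, ()):
                if tid == rid and not include_self:
                    continue
                out.add((rid, tid, len(suffix)))
    return out


def longest_overlap_map(
    read_set: ReadSet, min_len: int = 1, include_self: bool = False
) -> dict[tuple[int, int], int]:
    """Longest overlap per ordered pair, from :func:`brute_force_apsp`."""
    best: dict[tuple[int, int], int] = {}
    for q, t, length in brute_force_apsp(read_set, min_len, include_self):
        key = (q, t)
        if length > best.get(key, 0):
            best[key] = length
    return best


def brute_force_containment(read_set: ReadSet) -> tuple[np.ndarray, dict[int, str]]:
    """Reference containment mask over ids, with reasons.

    A read is removed iff another read (any other read, removed or
    not) has it as a prefix or suffix.  Reason precedence is
    prefix_contained > suffix_contained > duplicate; among exact
    duplicates with no other containment the copy with the smallest
    original index survives.
    """
    reads = read_set.reads
    ids = [r.id if r.id is not None else j + 1 for j, r in enumerate(reads)]
    k = read_set.k
    bits = np.zeros(k, dtype=bool)
    reasons: dict[int, str] = {}
    seqs = [r.sequence for r in reads]
    distinct = set(seqs)
    first_orig: dict[str, int] = {}
    for r in reads:
        if r.sequence not in first_orig or r.original_index < first_orig[r.sequence]:
            first_orig[r.sequence] = r.original_index

    for rid, read in zip(ids, reads):
        s = read.sequence
        if any(v != s and v.startswith(s) for v in distinct):
            bits[rid - 1] = True
            reasons[rid] = "prefix_contained"
        elif any(v != s and v.endswith(s) for v in distinct):
            bits[rid - 1] = True
            reasons[rid] = "suffix_contained"
        elif first_orig[s] != read.original_index:
            bits[rid - 1] = True
            reasons[rid] = "duplicate"
    return bits, reasons
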