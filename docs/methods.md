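# Methods

## Problem

Given k DNA reads over Σ = {A, C, G, T} with total length n, the
all-pairs suffix-prefix (APSP) problem asks, for every ordered pair
(S_i, S_j), for the longest proper suffix of S_i that equals a prefix
of S_j. APSP is the overlap stage of overlap-layout-consensus
assembly: its output is the edge set of the overlap graph.

## Data structure

`sof` answers APSP with a compact prefix tree (radix trie) of the
reads. Each node stores a one-character edge label, a `chain_len`
(the number of further characters implicit in the node, recovered on
demand from the original text through a representative read), and an
interval [r1, r2] over the lexicographic ranks 1..k of the reads: the
reads whose sequences start with the node's path string. Reads equal
to each other share one path; the node where reads end records their
multiplicity (`n_terminal`). The text itself is kept packed at two
bits per base, so total memory is 2n bits for the text plus O(k) nodes
(at most 2k − 1 for k distinct prefix-free reads).

### Construction

Two equivalent constructions are provided:

* **sorted** — reads are sorted lexicographically (stable sort; any
  O(n log n) sort is fine, radix sorting would recover the O(n)
  bound but is not needed for correctness) and inserted in rank
  order. Intervals are maintained on the fly: entering a node extends
  its upper bound to the new rank. A mismatch inside a chain splits
  the node in two and adds a leaf; a mismatch at an absent branch adds
  a leaf whose `chain_len` is the read length minus all characters
  consumed so far minus one (the branch label). The "minus consumed"
  accounting matters when the branch is taken after fully matching a
  non-empty chain.
* **unsorted** — reads are inserted in file order with internal
  intervals left unset; duplicates are collected into per-sequence
  lists. A depth-first pass (children always in A < C < G < T order)
  then assigns consecutive identification numbers to the reads ending
  in each node — equal reads get sequential numbers in file order —
  and folds child intervals into parents. The resulting permutation
  equals the stable lexicographic rank, and the tree is node-for-node
  identical to the sorted construction.

Construction consumes each input character at most once, so character
comparisons are ≤ n (the test suite asserts ≤ 2n); on random input
comparisons are far fewer because insertion stops at the first
mismatch and the remainder of the read becomes an implicit chain.

Prefix-contained reads (read = proper prefix of another) are
representable: they terminate at an internal node, which is then
allowed to have a single child. Only for prefix-free input does the
classic bound "every internal node has ≥ 2 children, hence ≤ k − 1
internal nodes" hold verbatim; the validator enforces the generalised
rule.

### Matching

Every proper suffix of every read (position 2 onward, longest first,
skipping suffixes shorter than the minimum overlap ℓ) is walked down
the tree. Exhausting the suffix — mid-chain or at a node boundary —
yields one overlap per read in the current node's interval; a chain
mismatch or absent branch yields none. Per read of length l this is
at most l(l+1)/2 + l character comparisons (asserted per read in the
tests), O(k·l²) overall. Because suffixes are visited longest first,
the first match for an ordered pair is its longest, which is what the
`longest_only` mode records in its k×k table (capped at k ≤ 20 000 by
default; the table is the output-size bottleneck, not the tree). The
`all_matches` mode emits every matching (query, start position,
target) triple; `none` only counts.

Self pairs are suppressed by default (`include_self` re-enables
them). A suffix equal to an entire other read is reported — and is
exactly the suffix-containment case the prefilter can remove first.

## Containment prefiltering

Optionally, reads contained in other reads are removed before
matching, recorded in a k-bit mask with reasons:

* prefix containment: reads terminating at a node with children;
* suffix containment: a proper-suffix walk that exhausts exactly at a
  node boundary where reads terminate marks those reads;
* duplicates: among identical reads the smallest original file index
  survives (reason precedence: prefix > suffix > duplicate).

Removal is applied at emission time (mask consulted for queries and
targets) rather than by rebuilding the tree; the test suite checks
this equals APSP on the surviving reads built from scratch, and that
the mask equals a brute-force all-pairs containment test. Substring
containment at interior offsets is deliberately out of scope.

## Work partitioning

Processing read S costs about W_S = |S|(|S|+1)/2 comparisons. Four
strategies assign whole reads to p workers: `equal_count` (contiguous
blocks, sizes within 1), `share` (consecutive reads until the
accumulated W_S reaches the optimal share ΣW_S/p — "reaches" is ≥,
the reading under which the worked 6-string example gives each of 3
workers exactly 16), `dynamic` (a lock-protected shared pointer hands
out fixed-size chunks, default 1024 reads), and `greedy` (least-loaded
worker, ties to the lowest index; max−min load never exceeds the
largest single W_S). Construction parallelises by first characters:
per-prefix groups (4 at depth 1, 16 at depth 2) build disjoint
subtrees merged under a shared root; at depth 2 sibling groups meet in
a zero-chain node and length-1 reads terminate there.

Plans are pure functions of their inputs and are executed serially,
worker by worker; the overlap set is identical under every strategy,
any p, and the single-worker run. Actual concurrency is left to the
deployment layer: fan-out over OS processes would have to ship the
node structure to each worker, and in-process threads serialise on the
interpreter lock, so neither would change the correctness story the
plans themselves carry.

## Synthetic data

Two generators drive the tests:

* `generate_random_reads(n, k, seed)` — k reads of i.i.d. uniform
  bases whose lengths are a uniform random composition of n into k
  positive parts. This emulates uniform random test data; note that
  two uniform reads share a length-m overlap with probability 4^−m,
  so at ℓ = 30 such instances have essentially zero true overlaps —
  they exercise the sparse regime and scaling, not hit enumeration.
* `generate_overlapping_reads(genome_len, k, read_len_range, seed)` —
  shreds a uniform random genome into substrings at random offsets,
  so true overlaps exist, and returns the full ground-truth table of
  longest overlaps per ordered pair computed by direct string
  comparison (chance matches included).

Neither generator models sequencing error, reverse-complement strands,
non-uniform genome composition, or repeat structure, so passing tests
demonstrate exact-match correctness and scaling behaviour, not
robustness to noisy reads (inexact overlap is out of scope for the
method itself).

## Numerical and design choices

* Alphabet is strictly {A, C, G, T}; lowercase is uppercased, anything
  else (including U and N) cannot be 2-bit encoded and is skipped with
  a warning (strict mode errors).
* All ids, positions, and intervals are 1-based inclusive at the API
  surface; children iterate A < C < G < T everywhere, making DFS
  relabelling and record order deterministic.
* Default minimum overlap ℓ = 30; output modes 0/1/2 = none /
  longest-only / all matches.
* Equal reads: stable ordering gives duplicates consecutive ids in
  file order; one leaf, interval width = multiplicity.
* The brute-force oracle indexes every prefix of every read in a hash
  map and looks up every proper suffix — definitionally correct,
  quadratic space, no code shared with the tree path.
* Differential test sizes: a hundred seeded instances (k mostly
  5–80, one in eight at 200–500; read lengths within 20–200; ℓ
  cycling 1/5/15/30), plus one uniform instance at n = 10⁷, k = 10⁵
  run in count-only mode as a scale check.

## Known limitations

* Exact matching only; no mismatches/indels, no reverse-complement
  overlaps.
* `longest_only` allocates a dense k×k table; use `all_matches` or
  `none` beyond the cap.
* Work estimates ignore that walks terminate early on mismatches, so
  per-worker wall times are conservative estimates of comparisons, not
  measured times.
* The pure-Python inner loops favour clarity; throughput is roughly
  10⁷ construction characters and ~10⁶ suffix walks per second on one
  core, ample for the tested sizes but far from an optimised native
  implementation.
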