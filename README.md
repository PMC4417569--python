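# sof — String Overlap Finder

All-pairs suffix-prefix (APSP) overlap detection for DNA reads, built
on a compact prefix tree.

Given k reads over {A, C, G, T} with total length n, APSP asks for the
longest proper suffix of each read that equals a prefix of each other
read — the overlap stage of an overlap-layout-consensus assembler, and
the edge set of the overlap graph. `sof` indexes the reads in a radix
trie whose nodes store, instead of edge strings, a one-character label,
a chain length pointing back into the 2-bit-packed original text, and
an interval [r1, r2] of the lexicographic ranks of all reads sharing
that prefix. Construction is O(n) (with or without pre-sorting the
reads — both orders build the identical tree), the tree has at most
2k − 1 nodes, and matching walks every proper suffix of every read
down the tree in O(k·l²) for maximum read length l: each exhausted
suffix reports one overlap per read in the final node's interval.

The package also provides containment prefiltering (reads equal to a
prefix or suffix of another read are removed before matching, tracked
in a k-bit mask), four strategies for partitioning matching work
across workers (equal counts, estimated-work shares W_S = |S|(|S|+1)/2,
dynamic chunks from a shared pointer, greedy least-loaded), parallel
construction by first one or two characters, synthetic read
generators, and a deliberately naive brute-force oracle for
differential testing.

## Worked example

The five reads S1=AAGGG, S2=ACTTT, S3=AGGCT, S4=GCCAC, S5=TCCGC:

```sh
$ printf '>S1\nAAGGG\n>S2\nACTTT\n>S3\nAGGCT\n>S4\nGCCAC\n>S5\nTCCGC\n' > fig.fa
$ sof run fig.fa --min-len 1 --output-mode 1
k=5 n=25 nodes=6 matches=5 removed=0
# sof overlaps	mode=longest_only	min_len=1	k=5	n=25	matches=5
S1	S4	1
S2	S5	1
S3	S5	1
S4	S2	2
S5	S4	2
```

The tree has 5 leaves and one internal node besides the root (the
three A-reads branch at their second character). Five ordered pairs
overlap: e.g. S4 = GCCAC ends in "AC", which is the 2-character prefix
of S2 = ACTTT, so the assembler may lay S2 after S4 with a 2 bp
overlap; no pair overlaps by 3 or more, so `--min-len 3` reports
nothing. `--output-mode 2` lists *all* matches per pair rather than
the longest, `--output-mode 0` only counts, `--filter-contained`
removes contained reads first, and `--workers/--strategy` select a
work partition (the overlap set is identical under every strategy).

The same functionality is available as a library:

```python
from sof import ReadSet, build, find_overlaps
rs = ReadSet.from_sequences([("S1", "AAGGG"), ("S2", "ACTTT")])
trie, perm = build(rs, sort=True)
result = find_overlaps(trie, trie.read_set, min_len=1, mode="all_matches")
```

`sof simulate` writes synthetic FASTA (uniform random reads of exact
total length, or reads shredded from a random genome so real overlaps
exist), and `sof verify` re-checks any FASTA against the brute-force
oracle, exiting non-zero on the first discrepancy.

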