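# Methods

## Index

The reference (one or more FASTA contigs, case-insensitive, wrapped or not)
is concatenated into a single text over {A,C,G,T}. Packing is 2 bits/base;
because a fifth symbol does not fit, every IUPAC base outside ACGT is
replaced by `A` and its position stored as a run in an ambiguity mask, which
coordinate translation reports per placement (placements are flagged, not
dropped). A single sentinel, lexicographically before `A`, terminates the
text; there is no per-contig sentinel, so a match can straddle a contig
junction in index space — such placements are removed during coordinate
translation instead.

The suffix array is built by prefix-doubling over numpy sorts
(O(n log² n)); index construction speed is explicitly not a goal of this
package. The FM-index stores the BWT, C, occurrence checkpoints every
`occ_stride` positions (default 64) and suffix-array samples every
`sa_stride` rows (default 8). Checkpointed answers are exact and
stride-invariant; the strides only trade memory for scan length. `sa_lookup`
walks the LF-mapping to the nearest sampled row; with row-stride sampling
the expected walk is (stride−1)/2 steps and row 0 is always sampled, so the
walk terminates. Index files `{.pac,.ann,.bwt,.sa,.rbwt,.rsa}` use a small
versioned little-endian binary dialect with per-file magic bytes; the
reverse-text index (`.rbwt/.rsa`) exists to compute the difference lower
bound below. Hit files (`.sai`) carry a CRC-32 fingerprint of the BWT so the
SAM stages can refuse hits produced against a different index.

## Inexact search

Backward search is extended to an edit tree: at each step the consumed query
base may match, be substituted (3 ways), be skipped (insertion in the read),
or one of four reference bases may be interposed (deletion). Counting model:
one *difference* per mismatch, per gap open and per gap extension; a gap of
length g costs 1 + (g−1) differences and `pen_gap_open + (g−1)·pen_gap_extend`
score. Defaults — mismatch 3, gap open 11, gap extension 4, at most 1 gap
open and 6 extensions — are this package's declared convention, chosen to
match widely used BWT aligners so that "default options" runs are
comparable. Gap opens are only allowed from the match state (a gap cannot
immediately follow the opposite gap type), and no gap operation may touch
the first or last `end_clip` (default 5) bases of the read: terminal gaps
are indistinguishable from soft boundary noise and the brute-force oracle
enforces the identical rule. An `N` in a read matches no reference base, so
any path through it costs one mismatch (substituting all four bases is
allowed, skipping it with a gap as well).

The difference bound z is either given (`-n <int>`) or derived from read
length as the smallest z with P(X > z) < 0.01 for X ~ Binomial(read_len,
0.04) — e.g. z = 5 at 37 bp, z = 7 at 70 bp. The bound tightens during the
search: once a full alignment with b differences exists, nodes above
min(z, b+1) are pruned (b when suboptimal reporting is off), and the final
hit set is re-filtered against the global best so that the reported set is
independent of traversal order. A prefix lower bound d(i) — the minimum
differences any occurrence of the query prefix q[0..i] needs, computed by
the standard restart scan on the reversed-text index — prunes nodes with
n_diff + d(i−1) > bound.

Three traversals of this node set are implemented and tested equal:

* `dfs_inexact` — depth-first, children visited in best-first order
  (ascending added penalty; ties: match first, insertions before deletions,
  then A<C<G<T). Memory is the current branch only: at most read_len + 1
  frames plus one frame per deletion on the branch (deletions do not consume
  a query base), i.e. read_len + 1 + z in the worst gapped case.
* `bfs_inexact_reference` — best-first frontier traversal that retains every
  generated node, modelling the memory-hungry strategy the DFS replaces;
  it reports both the widest frontier and the total nodes stored, and
  raises once the frontier exceeds a configurable cap.
* `align_multiphase` — the read is cut into seed-length fragments (default
  32 bp, 3' fragment first, the 5'-most fragment may be short) and each
  phase extends the ranked stack of partial hits through one fragment.
  Gap state is carried across fragment boundaries, so a gap may span two
  fragments; without this the phased result would not equal the single-pass
  search. The stack ranks by (n_diff, score, position) and discards entries
  above min(z, best+1) as soon as any full alignment is known. The per-read
  best is tracked per read id, so a shared stack over many reads never lets
  one read prune another.

`batch_align` packs a batch of reads into one contiguous code buffer and
runs a compiled (numba) implementation of the same bounded DFS per read —
identical rules, identical hit sets (asserted against both pure-Python
traversals in the tests) — which is what makes the 20,000-read protocol
runs feasible. Reads are independent, so results do not depend on batch
order or size. In the read-alignment driver both strands are searched; the
best difference count found on the first strand seeds the bound of the
second strand's search, which prunes only hits that the cross-strand
suboptimal filter would discard anyway. A per-read visit cap (default 2×10⁶
nodes per strand) aborts pathological searches; such reads are reported
unmapped. Caps this large are hit by roughly one read in several thousand at
the default error rate.

The independent test oracle (`brute_force_hits`) never touches the index:
for every reference start it enumerates the alignment directly. With at
most one gap open, an alignment is (prefix match run, optional gap of
length g at an interior offset, suffix match run), so the minimum
difference count per start is an exact minimum over (gap type, offset,
length) of gap cost plus Hamming mismatches — a closed-form enumeration
rather than a general DP, which keeps the oracle simple and obviously
independent. It refuses configurations with more than one gap open.

## Mapping quality and SAM

Coordinate translation resolves up to `max_occurrences` (default 10) SA rows
per hit, drops contig-spanning placements, and reconstructs the CIGAR from
the recorded operation counts by scanning the single gap placement that
reproduces the recorded mismatch count (smallest offset on ties). Mapping
quality is a declared, version-pinned convention: 0 if the best difference
count is shared by several placements; 37 for a unique placement with no
suboptimal competitor; otherwise max(0, 23 − 8·(n_subopt − 1)), forced to 0
if a "suboptimal" placement is actually as good as the best. It is monotone
non-increasing in the number of suboptimal hits. The `NM` tag reports the
difference count (mismatches + gap opens + gap extensions) of the chosen
placement — note this deviates from the SAM convention of counting edited
bases when a gap is longer than one.

Paired-end selection considers up to 32 placements per mate and picks the
opposite-strand, same-contig combination with the smallest combined
difference count whose insert size lies within limits; limits default to
mean ± 4 sd of the insert sizes of the first 10,000 unique proper
candidates (a permissive 0–10 kb when fewer than 8 are available), and are
flag-overridable. Pairs with no qualifying combination fall back to their
independent best placements with the proper-pair flag unset; a mate whose
placement was overridden by pairing keeps at most mapping quality 3. TLEN is
signed positive on the leftmost mate.

## Simulator and evaluation

The simulator emulates the wgsim protocol: a uniform-composition random
genome (GC configurable), a haplotype with SNPs and short indels, and
paired reads with independent per-base errors. Parameter defaults are the
study conditions: base error 0.02; mutation rate 0.001 with indel fraction
0.1 (values the protocol leaves unstated; chosen once, near wgsim's own
defaults) and indel extension probability 0.3 (wgsim's default); insert
N(500, 50) truncated to [read_len, haplotype]; constant base quality `I`
because the aligner is quality-blind. Mate 1 is always the forward-strand
mate. Truth is encoded losslessly in the read name —
`sim:<contig>:<pos1>:<strand1>:<pos2>:<strand2>:<serial>` — carrying both
mates because paired SAM records share one query name; the evaluator picks
the mate's truth from FLAG bits (or the `/1`/`/2` suffix in single-end
output). Inserted haplotype bases project to the reference base they
precede, so a read starting inside an insertion gets the attachment
coordinate as truth.

The evaluator reports `pct_mapped` (reads with mapq ≥ threshold, default 10,
over all reads) and `pct_error` (confident placements on the wrong contig or
strand, or more than `pos_tolerance` bp — default 5, allowing indel wobble —
from truth, over confident placements). Paired output is scored per read,
mates independently.

What the synthetic data does *not* emulate: repeat structure and low
complexity regions of real genomes (a uniform random 100 kb genome is almost
everywhere unique, so mapped percentages run higher and mapping-quality
filtering is rarely exercised by true repeats), quality-value structure,
indel hotspots, and coverage biases. Passing the protocol here demonstrates
the correctness of the search/reporting machinery, not real-genome accuracy
figures.

## Problem sizes and numerical choices

The packaged protocol uses a 100 kb genome and 10,000 pairs of 70 bp reads —
the protocol's shape at a desk scale the library handles in minutes on one
CPU. Randomized equivalence suites use references of 0.1–2 kb, reads of
8–100 bp and z ≤ 3, several hundred cases per property. All randomness is
seeded; the full simulate→index→align→pair→evaluate pipeline is
byte-reproducible for a fixed seed (ties everywhere are broken
deterministically: symbol order, position order, insertion before deletion).

## Orchestration

`multi-se` splits a library into near-equal contiguous partitions (sizes
differ by at most one read), aligns each independently and merges the
records back in input order under a single header; `multi-pe` runs exactly
two alignment units, one per mate file, then a single pairing pass. Both
are record-identical to the serial paths — the point being modelled is the
split/merge contract, not machine parallelism, so partitions execute
in-process.

## Known limitations

* Quality-aware scoring, soft-clipping and local rescue alignment are out of
  scope; every read is aligned end-to-end or not at all.
* The brute-force oracle and CIGAR reconstruction assume at most one gap
  open (the default limit); raising `max_gap_opens` works in the search but
  is not covered by the oracle.
* Mapping quality is a package convention, not a calibrated error
  probability; only its ordering properties should be relied on.
* Suffix-array construction is O(n log² n) with numpy sorting — fine for
  megabase references, not for mammalian genomes.
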