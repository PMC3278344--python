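# fmalign

`fmalign` is a BWT/FM-index short-read aligner written as a CPU library and
command-line tool. It maps Illumina-style reads (tens to a few hundred bp)
onto a reference genome, allowing mismatches and a short gap, and emits SAM.
It is aimed at people studying the *algorithmic* side of BWT read mapping —
the search-space traversal, the seed-phased scheduling, and the evaluation
protocol — at desk scale, with every stage exposed as a testable Python
function.

## The method

The reference is packed 2 bits/base (ambiguous bases become `A` and are
recorded in a mask), concatenated, and indexed: suffix array *SA*, BWT
*B[i] = T[SA[i]−1]*, cumulative counts *C(a)* and occurrence counts
*Occ(a, i)*. Backward search maps a query suffix to an SA interval in
*O(|q|)* — appending a symbol *a* to the left of a matched string *W* turns
the interval *[l, h)* of *W* into

```
l' = C(a) + Occ(a, l),   h' = C(a) + Occ(a, h)
```

Inexact alignment explores, right to left over the read, a tree whose edges
are: exact extension, the 3 base substitutions, an insertion (query base
skipped) and a deletion (each of the 4 reference bases inserted) — an
*O(9^n)* space, *O(4^n)* when gap opening is disabled. Every mismatch, gap
open and gap extension is one **difference**; nodes exceeding the bound *z*
are pruned, a per-prefix lower bound *d(i)* (computed on an index of the
reversed text) prunes hopeless branches, and once a best alignment with *b*
differences is known only nodes with ≤ min(z, b+1) differences survive, so
suboptimal hits one difference worse than the best are still reported.

The production traversal is a **difference-bound depth-first search** that
keeps only the current branch in memory (≤ |q|+1 nodes plus one per
deletion); a best-first breadth-first reference implementation, which
retains every generated node, documents the memory trade-off and serves as a
cross-check. Long reads can also be processed as seed-length fragments
(default 32 bp) in consecutive phases with a ranked host-side stack of
partial hits — provably the same hit set, with a bounded per-phase working
set. Hits are SA intervals plus difference compositions; `samse`/`sampe`
translate them to linear coordinates through a sampled suffix array, assign
a Phred-scale mapping quality, pair mates by orientation and insert size,
and write SAM.

A wgsim-style simulator (mutated haplotype, error-bearing read pairs, truth
encoded in read names) and an evaluator (% reads mapped at mapq ≥ 10,
% of those mapped wrongly) reproduce the standard accuracy protocol on
synthetic genomes.

## Worked example

```
$ fmalign simulate sim --length 50000 --pairs 1000 --seed 7
[INFO] simulated 1000 pairs (44 variants) -> sim{.fasta,_1.fq,_2.fq}
$ fmalign index sim.fasta -p sim
[INFO] indexed 50000 bp in 1 contig(s) -> sim.{pac,ann,bwt,sa,rbwt,rsa}
$ fmalign aln sim sim_1.fq -f sim_1.sai
$ fmalign aln sim sim_2.fq -f sim_2.sai
$ fmalign sampe sim sim_1.sai sim_2.sai sim_1.fq sim_2.fq -o pe.sam
$ fmalign evaluate pe.sam
n_reads=2000
pct_mapped=99.9000
pct_error=0.0000
```

`pct_mapped` is the fraction of reads placed with mapping quality ≥ 10;
`pct_error` is the fraction of those that landed on the wrong contig or
strand or more than 5 bp from their simulated origin. A SAM record looks
like:

```
sim:chrS:47611:+:48001:-:0  99  chrS  47612  37  70M  =  48002  460  ACGG...  III...  NM:i:3
```

— a proper pair (flag 99) at 1-based position 47612 with mapping quality 37
and 3 differences (`NM`); the read name encodes both mates' true origins.

The same machinery is available as a library:

```python
from fmalign import GenomeIndex, AlnOptions, dfs_inexact, pack_reference

gi = GenomeIndex.build(pack_reference([("chr1", "ACAACG...")]))
res = dfs_inexact(gi.fm, gi.rfm, "ACG", AlnOptions(max_diff=1))
```

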