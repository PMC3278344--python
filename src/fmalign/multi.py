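"""Split/align/merge orchestration for multiple alignment workers.

Models the multi-device convenience scripts of GPU aligners with CPU data
partitions: the single-end path splits the library into near-equal chunks
(sizes differ by at most one read), aligns each independently, and merges
the per-chunk records back into one SAM stream preserving input order.  The
paired-end path runs exactly two alignment units (one per mate file) and a
single pairing stage.  Both are record-identical to the serial path by
construction, which the test suite asserts.
"""

from __future__ import annotations

import numpy as np

from .align import AlnOptions
from .fmindex import GenomeIndex
from .pipeline import align_reads
from .postprocess import samse, sampe


def split_balanced(items: list, workers: int) -> list[list]:
    """Contiguous chunks whose sizes differ by at most one."""
    if workers < 1:
        raise ValueError("worker count must be >= 1")
    return [list(part) for part in np.array_split(np.array(items, dtype=object),
                                                  workers)]


def multi_se(gindex: GenomeIndex, fastq_records, opts: AlnOptions,
             workers: int = 1, max_occurrences: int = 10) -> list[str]:
    """Single-end align+convert over ``workers`` partitions; merged SAM lines."""
    chunks = split_balanced(fastq_records, workers)
    header: list[str] = []
    body: list[str] = []
    for chunk in chunks:
        if not chunk:
            continue
        recs = align_reads(gindex, [s for _n, s, _q in chunk], opts)
        lines = list(samse(gindex, recs, [tuple(r) for r in chunk], opts,
                           max_occurrences=max_occurrences,
                           command_line="fmalign multi-se"))
        hdr = [ln for ln in lines if ln.startswith("@")]
        if not header:
            header = hdr
        body.extend(ln for ln in lines if not ln.startswith("@"))
    if not header:
        from .postprocess import sam_header
        header = sam_header(gindex, "fmalign multi-se")
    return header + body


def multi_pe(gindex: GenomeIndex, fastq_1, fastq_2, opts: AlnOptions,
             insert_limits=None, max_occurrences: int = 10) -> list[str]:
    """Paired-end: two alignment units (never more), then one pairing pass."""
    if len(fastq_1) != len(fastq_2):
        raise ValueError(f"mate files differ in length: {len(fastq_1)} vs {len(fastq_2)}")
    recs1 = align_reads(gindex, [s for _n, s, _q in fastq_1], opts)
    recs2 = align_reads(gindex, [s for _n, s, _q in fastq_2], opts)
    return list(sampe(gindex, recs1, recs2, [tuple(r) for r in fastq_1],
                      [tuple(r) for r in fastq_2], opts,
                      insert_limits=insert_limits,
                      max_occurrences=max_occurrences,
                      command_line="fmalign multi-pe"))
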