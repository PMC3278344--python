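"""Read-to-hit-file alignment driver (the ``aln`` stage).

Each read and its reverse complement are searched against the forward index
with the compiled difference-bound DFS; hits carry a strand flag.  Reads in a
batch are packed into one contiguous buffer and processed independently, so
results do not depend on batch order or size.
"""

from __future__ import annotations

import numpy as np

from .align import AlnOptions
from .fmindex import GenomeIndex
from ._kernels import KernelIndex
from .postprocess import HitFileRecord, StrandHit, write_hit_file
from .refpack import codes_from_string, revcomp_codes


def align_read_codes(kidx: KernelIndex, codes: np.ndarray, opts: AlnOptions
                     ) -> tuple[list[StrandHit], bool]:
    """Hits of one read on both strands; returns (hits, dropped)."""
    m = len(codes)
    if m == 0:
        return [], False
    z = opts.resolve_z(m)
    hits: list[StrandHit] = []
    dropped = False
    best_seen = z + 1  # carried across strands; prunes only what the final
    for strand, q in ((0, codes), (1, revcomp_codes(codes))):  # filter drops
        rows, truncated, overflow = kidx.search(np.ascontiguousarray(q), opts, z,
                                                best_init=best_seen)
        if len(rows):
            best_seen = min(best_seen,
                            int((rows[:, 2] + rows[:, 3] + rows[:, 4]).min()))
        if truncated or overflow:
            dropped = True
        hits.extend(StrandHit(low=int(r[0]), high=int(r[1]), n_mm=int(r[2]),
                              n_gapo=int(r[3]), n_gape=int(r[4]),
                              n_ins=int(r[5]), n_del=int(r[6]),
                              score=int(r[7]), strand=strand)
                    for r in rows)
    if dropped:
        return [], True
    # keep only hits within one difference of the cross-strand best
    if hits:
        best = min(h.n_diff for h in hits)
        cap = min(z, best + 1) if opts.report_suboptimal else best
        hits = [h for h in hits if h.n_diff <= cap]
    return hits, False


def align_reads(gindex: GenomeIndex, seqs: list[str], opts: AlnOptions,
                batch_size: int = 0x40000) -> list[HitFileRecord]:
    """Align a list of read sequences; returns one record per read, in order."""
    kidx = KernelIndex(gindex)
    records: list[HitFileRecord] = []
    for start in range(0, len(seqs), batch_size):
        chunk = seqs[start:start + batch_size]
        codes = [codes_from_string(s) for s in chunk]
        buf = np.concatenate(codes) if codes else np.empty(0, np.uint8)
        offsets = np.cumsum([0] + [len(c) for c in codes])
        for k in range(len(chunk)):
            q = buf[offsets[k]:offsets[k + 1]]
            hits, dropped = align_read_codes(kidx, q, opts)
            records.append(HitFileRecord(read_id=start + k, hits=hits,
                                         dropped=dropped))
    return records


def align_fastq_to_sai(gindex: GenomeIndex, fastq_records, sai_path,
                       opts: AlnOptions) -> list[HitFileRecord]:
    records = align_reads(gindex, [seq for _n, seq, _q in fastq_records], opts)
    write_hit_file(sai_path, records, gindex.fingerprint, opts)
    return records
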