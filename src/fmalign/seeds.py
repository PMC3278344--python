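"""Seed-fragmented multi-phase search scheduling.

Long reads are cut into seed-length fragments (default 32 bp) which are
searched one per phase, in backward-search order (the 3' fragment first).
Between phases, incomplete alignments live in a host-side stack ranked by
their number of differences, best first; once any full alignment with b
differences exists, stacked partials worse than min(z, b+1) are discarded.
The final hit set is provably identical to a single-pass search of the whole
read — the phases only bound the per-launch working set, mirroring the
multiple-kernel execution model the scheduler is derived from.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from . import align as _al
from .align import AlignmentHit, AlnOptions, SearchResult, compute_lower_bound
from .fmindex import FMIndex
from .refpack import codes_from_string


def fragment_read(read, seed_len: int):
    """Cut a read into fragments in processing order (3' fragment first).

    Fragments are contiguous, cover the read, and all but the last-processed
    (5'-most) fragment have length ``seed_len``.
    """
    codes = codes_from_string(read) if isinstance(read, str) else np.asarray(read)
    m = len(codes)
    if m < 1 or seed_len < 1:
        raise ValueError("read length and seed_len must be >= 1")
    out = []
    hi = m
    while hi > 0:
        lo = max(0, hi - seed_len)
        out.append(codes[lo:hi])
        hi = lo
    return out


@dataclass(frozen=True)
class PartialHit:
    """An alignment covering only the first ``phase`` fragments of a read."""

    read_id: int
    phase: int  # fragments completed so far
    i: int  # query bases still unconsumed
    low: int
    high: int
    n_mm: int
    n_gapo: int
    n_gape: int
    n_ins: int
    n_del: int
    state: int
    score: int

    @property
    def n_diff(self) -> int:
        return self.n_mm + self.n_gapo + self.n_gape

    def sort_key(self):
        return (self.n_diff, self.score, self.read_id, self.phase, self.i,
                self.low, self.high, self.state)


class HitStack:
    """Ranked host-side store of partial hits between phases.

    The best completed-alignment difference count is tracked per read so that
    a full alignment of one read never prunes another read's partials.
    """

    def __init__(self):
        self._entries: set[PartialHit] = set()
        self._best_full: dict[int, int] = {}

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def entries(self) -> list[PartialHit]:
        return sorted(self._entries, key=PartialHit.sort_key)

    def best_full_diff(self, read_id: int = 0) -> int | None:
        return self._best_full.get(read_id)

    def push(self, ph: PartialHit) -> None:
        self._entries.add(ph)

    def extract_all(self) -> list[PartialHit]:
        out = self.entries
        self._entries.clear()
        return out

    def note_full(self, read_id: int, n_diff: int, z: int, opts: AlnOptions) -> None:
        cur = self._best_full.get(read_id)
        if cur is None or n_diff < cur:
            self._best_full[read_id] = n_diff
        self.prune_read(read_id, self.cap(read_id, z, opts))

    def cap(self, read_id: int, z: int, opts: AlnOptions) -> int:
        best = self._best_full.get(read_id)
        if best is None:
            return z
        if opts.report_suboptimal:
            return min(z, best + 1)
        return min(z, best)

    def prune_read(self, read_id: int, cap: int) -> None:
        self._entries = {e for e in self._entries
                         if e.read_id != read_id or e.n_diff <= cap}


def _extend_segment(index: FMIndex, codes, d, opts: AlnOptions, cap: int,
                    start: PartialHit, i_target: int):
    """Bounded DFS from a partial state down to query position i_target.

    Returns (end nodes at i_target, min full-alignment diff found or None).
    The ``cap`` is re-tightened locally when i_target == 0 and full
    alignments complete during the walk.
    """
    m = len(codes)
    root = _al._Node(i=start.i, low=start.low, high=start.high,
                     n_mm=start.n_mm, n_gapo=start.n_gapo, n_gape=start.n_gape,
                     n_ins=start.n_ins, n_del=start.n_del, state=start.state,
                     score=start.score)
    ends: list[_al._Node] = []
    stack = [root]
    peak = 1
    while stack:
        node = stack[-1]
        if node.i == i_target:
            if node.n_diff <= cap:
                ends.append(node)
                if i_target == 0 and opts.report_suboptimal:
                    cap = min(cap, node.n_diff + 1)
                elif i_target == 0:
                    cap = min(cap, node.n_diff)
            stack.pop()
            continue
        if not node.children and node.next_child == 0:
            node.children = _al._ordered_children(
                node.state, int(codes[node.i - 1]), opts, node.i, m,
                node.n_gapo, node.n_gape)
        if node.next_child >= len(node.children):
            stack.pop()
            continue
        pen, _cls, sym, kind = node.children[node.next_child]
        node.next_child += 1
        added = 1 if (pen or kind != _al.K_EXT) else 0
        nd = node.n_diff + added
        if nd > cap:
            continue
        ci = node.i - (0 if kind == _al.K_DEL else 1)
        if ci > 0 and nd + int(d[ci - 1]) > cap:
            continue
        child = _al._apply(index, node, pen, sym, kind)
        if child is None:
            continue
        stack.append(child)
        peak = max(peak, len(stack))
    return ends, peak


def _boundaries(fragments) -> list[int]:
    m = sum(len(f) for f in fragments)
    out = []
    consumed = 0
    for f in fragments:
        consumed += len(f)
        out.append(m - consumed)
    return out  # i-value after completing each fragment; last is 0


def run_phase(index: FMIndex, reverse_index: FMIndex, stack: HitStack,
              reads, opts: AlnOptions, z: int | None = None):
    """Extend every stacked partial through its next fragment.

    ``reads`` maps read_id to its sequence/codes (a list or dict).  Partials
    at mixed phases are allowed; each resumes from its own phase.  Returns
    (stack, completed AlignmentHits keyed by read_id).
    """
    completed: dict[int, set[AlignmentHit]] = {}
    lb_cache: dict[int, np.ndarray] = {}
    z_by_read: dict[int, int] = {}
    for ph in stack.extract_all():
        seq = reads[ph.read_id]
        codes = codes_from_string(seq) if isinstance(seq, str) else np.asarray(seq)
        if ph.read_id not in lb_cache:
            lb_cache[ph.read_id] = compute_lower_bound(reverse_index, codes)
            z_by_read[ph.read_id] = z if z is not None else opts.resolve_z(len(codes))
        d = lb_cache[ph.read_id]
        zz = z_by_read[ph.read_id]
        bounds = _boundaries(fragment_read(codes, opts.seed_len))
        i_target = bounds[ph.phase]
        cap = stack.cap(ph.read_id, zz, opts)
        if ph.n_diff > cap:
            continue
        ends, _ = _extend_segment(index, codes, d, opts, cap, ph, i_target)
        for node in ends:
            if i_target == 0:
                hit = _al._hit_from(node)
                completed.setdefault(ph.read_id, set()).add(hit)
                stack.note_full(ph.read_id, hit.n_diff, zz, opts)
            else:
                stack.push(PartialHit(
                    read_id=ph.read_id, phase=ph.phase + 1, i=node.i,
                    low=node.low, high=node.high, n_mm=node.n_mm,
                    n_gapo=node.n_gapo, n_gape=node.n_gape, n_ins=node.n_ins,
                    n_del=node.n_del, state=node.state, score=node.score))
    for rid, zz in z_by_read.items():
        stack.prune_read(rid, stack.cap(rid, zz, opts))
    return stack, completed


def align_multiphase(index: FMIndex, reverse_index: FMIndex, read,
                     opts: AlnOptions, z: int | None = None) -> SearchResult:
    """Whole-read alignment via the phased scheduler; equals dfs_inexact."""
    codes = codes_from_string(read) if isinstance(read, str) else np.asarray(read)
    m = len(codes)
    if m > opts.max_query_len:
        raise ValueError(f"query length {m} exceeds maximum {opts.max_query_len}")
    if z is None:
        z = opts.resolve_z(m)
    if m == 0:
        return _al.dfs_inexact(index, reverse_index, codes, opts, z=z)
    stack = HitStack()
    stack.push(PartialHit(read_id=0, phase=0, i=m, low=0, high=index.n + 1,
                          n_mm=0, n_gapo=0, n_gape=0, n_ins=0, n_del=0,
                          state=_al.ST_MATCH, score=0))
    hits: set[AlignmentHit] = set()
    peak_entries = 1
    while len(stack):
        stack, completed = run_phase(index, reverse_index, stack, [codes], opts, z=z)
        hits |= completed.get(0, set())
        peak_entries = max(peak_entries, len(stack))
    final, best = _al._final_filter({h: None for h in hits}, z, opts)
    return SearchResult(hits=final, peak_stored_nodes=peak_entries, visits=0,
                        best_diff=best)


def batch_align(index: FMIndex, reverse_index: FMIndex, reads,
                opts: AlnOptions) -> list[frozenset]:
    """Per-read hit sets for a batch, via the compiled kernel.

    Reads are packed into one contiguous code buffer before processing; the
    result is independent of read order and batch size.  Hit sets equal
    ``align_multiphase``/``dfs_inexact`` on each read individually.
    """
    from ._kernels import KernelIndex

    if len(reads) == 0:
        raise ValueError("batch must be non-empty")
    code_list = [codes_from_string(r) if isinstance(r, str) else np.asarray(r, dtype=np.uint8)
                 for r in reads]
    buf = np.concatenate(code_list) if code_list else np.empty(0, np.uint8)
    offsets = np.cumsum([0] + [len(c) for c in code_list])
    kidx = KernelIndex(SimpleNamespace(fm=index, rfm=reverse_index))
    out = []
    for k in range(len(code_list)):
        q = buf[offsets[k]:offsets[k + 1]]
        z = opts.resolve_z(len(q)) if len(q) else 0
        rows, _trunc, _ovfl = kidx.search(q, opts, z)
        out.append(frozenset(
            AlignmentHit(low=int(r[0]), high=int(r[1]), n_mm=int(r[2]),
                         n_gapo=int(r[3]), n_gape=int(r[4]), n_ins=int(r[5]),
                         n_del=int(r[6]), score=int(r[7]))
            for r in rows))
    return out
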