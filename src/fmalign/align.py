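"""Difference-bound inexact search over the FM-index.

The search explores, right-to-left over the query, the branch set of the
backward-search tree: exact extension, the three base substitutions, an
insertion (a query base absent from the reference) and a deletion (one of the
four reference bases inserted into the query).  Every mismatch, gap open and
gap extension counts as one *difference*; nodes are abandoned once their
difference count exceeds the bound z, and once a best alignment with b
differences is known the bound tightens to min(z, b+1) so suboptimal hits one
difference worse than the best are still reported.

A per-position lower bound d[] on the differences needed by each query
prefix, computed on the reverse-text index, prunes hopeless branches early.

Two traversals of the same node set are provided: a depth-first search that
keeps only the current branch in memory (the production strategy) and a
best-first breadth-first reference that retains every generated node, used to
document the memory trade-off and as a cross-implementation oracle.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .fmindex import FMIndex, SAInterval
from .refpack import codes_from_string

# alignment states
ST_MATCH = 0
ST_INS = 1
ST_DEL = 2

# child kinds
K_EXT = 0  # consume query base, extend interval with a symbol (match/mismatch)
K_INS = 1  # consume query base, no interval extension
K_DEL = 2  # extend interval with a symbol, no query base consumed


def auto_max_diff(read_length: int, error_rate: float = 0.04,
                  tail_threshold: float = 0.01) -> int:
    """Smallest z with P(X > z) < tail_threshold for X ~ Binomial(L, rate)."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    lp, lq = math.log(error_rate), math.log1p(-error_rate)
    cdf = 0.0
    for k in range(read_length + 1):
        lpmf = (math.lgamma(read_length + 1) - math.lgamma(k + 1)
                - math.lgamma(read_length - k + 1) + k * lp + (read_length - k) * lq)
        cdf += math.exp(lpmf)
        if 1.0 - cdf < tail_threshold:
            return k
    return read_length


@dataclass(frozen=True)
class AlnOptions:
    """Search options; the CLI exposes these as -n/-o/-e/-M/-O/-E/-l flags."""

    max_diff: int | str = "auto"  # z, or "auto" for the binomial formula
    error_rate: float = 0.04
    tail_threshold: float = 0.01
    gap_open_allowed: bool = True  # the '-o' control; False disables gaps entirely
    max_gap_opens: int = 1
    max_gap_extensions: int = 6
    pen_mismatch: int = 3
    pen_gap_open: int = 11
    pen_gap_extend: int = 4
    seed_len: int = 32
    end_clip: int = 5  # gaps banned within this many bases of either read end
    report_suboptimal: bool = True
    max_query_len: int = 512
    max_visits: int = 2_000_000
    bfs_frontier_cap: int = 2_000_000

    def __post_init__(self):
        if self.max_diff != "auto" and int(self.max_diff) < 0:
            raise ValueError("max_diff must be >= 0")
        if min(self.pen_mismatch, self.pen_gap_open, self.pen_gap_extend) <= 0:
            raise ValueError("penalties must be positive")
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")

    def resolve_z(self, read_length: int) -> int:
        if self.max_diff == "auto":
            return auto_max_diff(read_length, self.error_rate, self.tail_threshold)
        return int(self.max_diff)


@dataclass(frozen=True)
class AlignmentHit:
    """An SA interval with its difference composition."""

    low: int
    high: int
    n_mm: int
    n_gapo: int
    n_gape: int
    n_ins: int  # query bases inserted (skipped); n_ins + n_del == n_gapo + n_gape
    n_del: int  # reference bases deleted from the query (ref span grows)
    score: int

    @property
    def interval(self) -> SAInterval:
        return SAInterval(self.low, self.high)

    @property
    def n_diff(self) -> int:
        return self.n_mm + self.n_gapo + self.n_gape


@dataclass
class SearchResult:
    hits: frozenset
    peak_stored_nodes: int
    visits: int
    truncated: bool = False
    best_diff: int | None = None
    peak_frontier: int = 0  # BFS only: widest simultaneous frontier


def compute_lower_bound(reverse_index: FMIndex, query) -> np.ndarray:
    """d[i]: minimum differences for the query prefix q[0..i] to occur.

    Standard prefix scan on the reversed-text index: extend left-to-right;
    whenever the interval empties, bank one difference and restart from the
    full interval.  Non-decreasing by construction; an N base always empties
    the interval (it matches no reference base).
    """
    codes = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
    m = len(codes)
    d = np.zeros(m, dtype=np.int32)
    iv = reverse_index.full_interval()
    bound = 0
    for j in range(m):
        c = int(codes[j])
        if c > 3:
            iv = SAInterval(0, 0)
        else:
            iv = reverse_index.backward_ext(iv, c)
        if iv.empty:
            bound += 1
            iv = reverse_index.full_interval()
        d[j] = bound
    return d


def _ordered_children(state: int, qc: int, opts: AlnOptions, i: int, m: int,
                      n_gapo: int, n_gape: int):
    """Children of a node in best-first order.

    Order: ascending added penalty; ties broken match-first, then insertions
    before deletions, then symbol order A<C<G<T.  Gap opens are allowed only
    from the match state; extensions only continue the open gap.
    """
    cands = []  # (penalty, class_rank, symbol, kind)
    if state == ST_MATCH:
        if qc <= 3:
            cands.append((0, 0, qc, K_EXT))
        for c in range(4):
            if c != qc:
                cands.append((opts.pen_mismatch, 1, c, K_EXT))
        if opts.gap_open_allowed and n_gapo < opts.max_gap_opens:
            if opts.end_clip <= i - 1 < m - opts.end_clip:
                cands.append((opts.pen_gap_open, 2, -1, K_INS))
            if opts.end_clip <= i <= m - opts.end_clip:
                for c in range(4):
                    cands.append((opts.pen_gap_open, 3, c, K_DEL))
    else:
        if qc <= 3:
            cands.append((0, 0, qc, K_EXT))
        for c in range(4):
            if c != qc:
                cands.append((opts.pen_mismatch, 1, c, K_EXT))
        if opts.gap_open_allowed and n_gape < opts.max_gap_extensions:
            if state == ST_INS and opts.end_clip <= i - 1 < m - opts.end_clip:
                cands.append((opts.pen_gap_extend, 2, -1, K_INS))
            if state == ST_DEL and opts.end_clip <= i <= m - opts.end_clip:
                for c in range(4):
                    cands.append((opts.pen_gap_extend, 3, c, K_DEL))
    cands.sort()
    return cands


@dataclass
class _Node:
    i: int
    low: int
    high: int
    n_mm: int = 0
    n_gapo: int = 0
    n_gape: int = 0
    n_ins: int = 0
    n_del: int = 0
    state: int = ST_MATCH
    score: int = 0
    children: list = field(default_factory=list)
    next_child: int = 0

    @property
    def n_diff(self) -> int:
        return self.n_mm + self.n_gapo + self.n_gape


def _apply(index: FMIndex, node: _Node, pen: int, sym: int, kind: int):
    """Child node for one edge, or None when its interval is empty."""
    if kind == K_INS:
        low, high = node.low, node.high
    else:
        iv = index.backward_ext(SAInterval(node.low, node.high), sym)
        if iv.empty:
            return None
        low, high = iv.low, iv.high
    child = _Node(i=node.i - (0 if kind == K_DEL else 1), low=low, high=high,
                  n_mm=node.n_mm, n_gapo=node.n_gapo, n_gape=node.n_gape,
                  n_ins=node.n_ins, n_del=node.n_del,
                  state=node.state, score=node.score + pen)
    if kind == K_EXT:
        if pen:
            child.n_mm += 1
        child.state = ST_MATCH
    elif kind == K_INS:
        if node.state == ST_INS:
            child.n_gape += 1
        else:
            child.n_gapo += 1
        child.n_ins += 1
        child.state = ST_INS
    else:
        if node.state == ST_DEL:
            child.n_gape += 1
        else:
            child.n_gapo += 1
        child.n_del += 1
        child.state = ST_DEL
    return child


def _final_filter(raw_hits: dict, z: int, opts: AlnOptions) -> tuple[frozenset, int | None]:
    if not raw_hits:
        return frozenset(), None
    best = min(h.n_diff for h in raw_hits)
    cap = min(z, best + 1) if opts.report_suboptimal else best
    return frozenset(h for h in raw_hits if h.n_diff <= cap), best


def _hit_from(node: _Node) -> AlignmentHit:
    return AlignmentHit(low=node.low, high=node.high, n_mm=node.n_mm,
                        n_gapo=node.n_gapo, n_gape=node.n_gape,
                        n_ins=node.n_ins, n_del=node.n_del, score=node.score)


def dfs_inexact(index: FMIndex, reverse_index: FMIndex, query, opts: AlnOptions,
                z: int | None = None) -> SearchResult:
    """Difference-bound DFS; memory holds only the current branch of nodes."""
    codes = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
    m = len(codes)
    if m > opts.max_query_len:
        raise ValueError(f"query length {m} exceeds maximum {opts.max_query_len}")
    if z is None:
        z = opts.resolve_z(m)
    d = compute_lower_bound(reverse_index, codes) if m else np.zeros(0, np.int32)

    hits: set[AlignmentHit] = set()
    best = z + 1  # differences of the best full alignment seen so far
    cap = z
    visits = 0
    truncated = False

    root = _Node(i=m, low=0, high=index.n + 1)
    stack = [root]
    peak = 1
    while stack:
        node = stack[-1]
        if node.i == 0:
            if node.n_diff <= cap:
                hits.add(_hit_from(node))
                if node.n_diff < best:
                    best = node.n_diff
                    cap = min(z, best + 1) if opts.report_suboptimal else best
            stack.pop()
            continue
        if not node.children and node.next_child == 0:
            node.children = _ordered_children(node.state, int(codes[node.i - 1]),
                                              opts, node.i, m, node.n_gapo, node.n_gape)
        if node.next_child >= len(node.children):
            stack.pop()
            continue
        pen, _cls, sym, kind = node.children[node.next_child]
        node.next_child += 1
        added = 1 if (pen or kind != K_EXT) else 0
        nd = node.n_diff + added
        if nd > cap:
            continue
        ci = node.i - (0 if kind == K_DEL else 1)
        if ci > 0 and nd + int(d[ci - 1]) > cap:
            continue
        child = _apply(index, node, pen, sym, kind)
        if child is None:
            continue
        visits += 1
        if visits > opts.max_visits:
            truncated = True
            break
        stack.append(child)
        peak = max(peak, len(stack))

    final, best_diff = _final_filter(hits, z, opts)
    return SearchResult(hits=final, peak_stored_nodes=peak, visits=visits,
                        truncated=truncated, best_diff=best_diff)


def bfs_inexact_reference(index: FMIndex, reverse_index: FMIndex, query,
                          opts: AlnOptions, z: int | None = None) -> SearchResult:
    """Best-first BFS over the same node set; every generated node is retained.

    Mirrors the breadth-first strategy of CPU aligners: all daughter nodes go
    to a ranked store and the best is expanded next.  ``peak_stored_nodes``
    counts every node ever generated (the store only grows), which is what
    makes this traversal memory-hungry.  Intended for tests and small inputs;
    raises ``MemoryError`` when the frontier exceeds the configured cap.
    """
    codes = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
    m = len(codes)
    if m > opts.max_query_len:
        raise ValueError(f"query length {m} exceeds maximum {opts.max_query_len}")
    if z is None:
        z = opts.resolve_z(m)
    d = compute_lower_bound(reverse_index, codes) if m else np.zeros(0, np.int32)

    hits: set[AlignmentHit] = set()
    best = z + 1
    cap = z
    visits = 0
    truncated = False

    root = _Node(i=m, low=0, high=index.n + 1)
    seq = 0
    frontier = [(0, 0, root)]  # (score, insertion order, node)
    stored = 1  # total nodes generated and retained
    peak_frontier = 1
    while frontier:
        peak_frontier = max(peak_frontier, len(frontier))
        if len(frontier) > opts.bfs_frontier_cap:
            raise MemoryError(
                f"BFS frontier exceeded {opts.bfs_frontier_cap} nodes "
                f"(query length {m}, z={z})")
        _, _, node = heapq.heappop(frontier)
        if node.n_diff > cap:
            continue
        if node.i == 0:
            hits.add(_hit_from(node))
            if node.n_diff < best:
                best = node.n_diff
                cap = min(z, best + 1) if opts.report_suboptimal else best
            continue
        for pen, _cls, sym, kind in _ordered_children(
                node.state, int(codes[node.i - 1]), opts, node.i, m,
                node.n_gapo, node.n_gape):
            added = 1 if (pen or kind != K_EXT) else 0
            nd = node.n_diff + added
            if nd > cap:
                continue
            ci = node.i - (0 if kind == K_DEL else 1)
            if ci > 0 and nd + int(d[ci - 1]) > cap:
                continue
            child = _apply(index, node, pen, sym, kind)
            if child is None:
                continue
            visits += 1
            if visits > opts.max_visits:
                truncated = True
                frontier = []
                break
            seq += 1
            heapq.heappush(frontier, (child.score, seq, child))
            stored += 1

    final, best_diff = _final_filter(hits, z, opts)
    return SearchResult(hits=final, peak_stored_nodes=stored, visits=visits,
                        truncated=truncated, best_diff=best_diff,
                        peak_frontier=peak_frontier)
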