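"""Text-space brute-force oracle for the inexact search.

Independent of the FM-index path: for every reference start position it
computes the minimal number of differences of a full-query alignment
anchored there, by direct enumeration over gap type, gap placement and gap
length.  With the default limit of one gap open per alignment an alignment
contains at most a single contiguous gap, so the enumeration is exhaustive.
Each mismatch, gap open and gap extension counts as one difference; a gap of
length g costs g differences (one open plus g-1 extensions).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .align import AlnOptions
from .refpack import codes_from_string

_BIG = 1 << 30


@njit(cache=True)
def _ham(q, ref, qs, qe, rs):
    """Mismatches of q[qs:qe] vs ref[rs:rs+(qe-qs)]; N (code>3) never matches."""
    d = 0
    for k in range(qe - qs):
        qc = q[qs + k]
        if qc > 3 or qc != ref[rs + k]:
            d += 1
    return d


@njit(cache=True)
def _min_diff_all_starts(ref, q, gaps_on, g_max, clip, out):
    n = len(ref)
    m = len(q)
    for p in range(n):
        best = _BIG
        if p + m <= n:
            best = _ham(q, ref, 0, m, p)
        if gaps_on:
            for g in range(1, g_max + 1):
                # insertion: query bases j..j+g-1 skipped, ref span m-g
                if p + m - g <= n:
                    for j in range(clip, m - clip - g + 1):
                        d = g + _ham(q, ref, 0, j, p) + _ham(q, ref, j + g, m, p + j)
                        if d < best:
                            best = d
                # deletion: g extra reference bases between q[j-1] and q[j]
                if p + m + g <= n:
                    for j in range(clip, m - clip + 1):
                        d = g + _ham(q, ref, 0, j, p) + _ham(q, ref, j, m, p + j + g)
                        if d < best:
                            best = d
        out[p] = best


def brute_force_hits(reference, query, opts: AlnOptions,
                     z: int | None = None) -> set[tuple[int, int]]:
    """All (start position, minimal differences) occurrences of the query.

    Applies the same reporting rule as the index search: occurrences with
    more than min(z, best+1) differences (best when suboptimal reporting is
    off) are dropped.  Desk-scale inputs only.
    """
    if opts.max_gap_opens > 1 and opts.gap_open_allowed:
        raise NotImplementedError("oracle enumeration assumes max_gap_opens <= 1")
    ref = codes_from_string(reference) if isinstance(reference, str) else np.asarray(reference)
    q = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
    m = len(q)
    if z is None:
        z = opts.resolve_z(m)
    if m == 0:
        return {(p, 0) for p in range(len(ref) + 1)}
    g_max = 1 + opts.max_gap_extensions
    out = np.empty(len(ref), dtype=np.int64)
    _min_diff_all_starts(ref.astype(np.uint8), q.astype(np.uint8),
                         opts.gap_open_allowed, g_max, opts.end_clip, out)
    reachable = out[out <= z]
    if reachable.size == 0:
        return set()
    best = int(reachable.min())
    cap = min(z, best + 1) if opts.report_suboptimal else best
    return {(int(p), int(d)) for p, d in enumerate(out) if d <= cap}


def hamming_hits(reference, query, z: int) -> set[tuple[int, int]]:
    """Simple mismatch-only scan (the gap-disabled reduction), for tests."""
    ref = codes_from_string(reference) if isinstance(reference, str) else np.asarray(reference)
    q = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
    m = len(q)
    out = {}
    for p in range(len(ref) - m + 1):
        d = sum(1 for k in range(m) if q[k] > 3 or q[k] != ref[p + k])
        if d <= z:
            out[p] = d
    if not out:
        return set()
    best = min(out.values())
    cap = min(z, best + 1)
    return {(p, d) for p, d in out.items() if d <= cap}


def validate_hit(reference, query, position: int, n_mm: int, n_ins: int,
                 n_del: int, opts: AlnOptions) -> bool:
    """Check that an alignment with the claimed composition exists at position."""
    ref = codes_from_string(reference) if isinstance(reference, str) else np.asarray(reference)
    q = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
    m = len(q)
    p = position
    clip = opts.end_clip
    if n_ins == 0 and n_del == 0:
        return p + m <= len(ref) and _ham(q, ref, 0, m, p) == n_mm
    if n_ins and n_del:
        return False  # one gap only under the default limits
    g = n_ins or n_del
    if n_ins:
        if p + m - g > len(ref):
            return False
        return any(_ham(q, ref, 0, j, p) + _ham(q, ref, j + g, m, p + j) == n_mm
                   for j in range(clip, m - clip - g + 1))
    if p + m + g > len(ref):
        return False
    return any(_ham(q, ref, 0, j, p) + _ham(q, ref, j, m, p + j + g) == n_mm
               for j in range(clip, m - clip + 1))
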