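"""Compiled alignment kernels.

The per-read search kernel mirrors ``align.dfs_inexact`` exactly (same child
ordering, pruning and reporting rules) but runs as a single compiled function
over flat index arrays, which is what makes whole-library alignment feasible
at the simulated-protocol scale.  Equality with the pure-Python search and
with the phased scheduler is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# child kinds (match align.py)
K_EXT = 0
K_INS = 1
K_DEL = 2

HIT_FIELDS = 8  # low, high, n_mm, n_gapo, n_gape, n_ins, n_del, score


@njit(cache=True)
def _occ(bwt, ck, stride, c, p):
    k = p // stride
    cnt = ck[k, c]
    for j in range(k * stride, p):
        if bwt[j] == c:
            cnt += 1
    return cnt


@njit(cache=True)
def lower_bound_kernel(rbwt, rck, rstride, rC, n, q, d):
    low = np.int64(0)
    high = np.int64(n + 1)
    bound = 0
    for j in range(len(q)):
        c = q[j]
        if c > 3:
            low, high = np.int64(1), np.int64(0)
        else:
            low = rC[c] + _occ(rbwt, rck, rstride, c, low)
            high = rC[c] + _occ(rbwt, rck, rstride, c, high)
        if high <= low:
            bound += 1
            low, high = np.int64(0), np.int64(n + 1)
        d[j] = bound


@njit(cache=True)
def _occ4(bwt, ck, stride, p, out):
    """Occurrence counts of all four symbols in bwt[0:p) in one scan."""
    k = p // stride
    for c in range(4):
        out[c] = ck[k, c]
    for j in range(k * stride, p):
        b = bwt[j]
        if b < 4:
            out[b] += 1


@njit(cache=True)
def _gen_children(state, qc, i, m, ngo, nge, gaps_on, max_gapo, max_gape,
                  pen_mm, pen_go, pen_ge, clip, low, high, bwt, ck, stride, C,
                  keys, syms, kinds, pens, clows, chighs):
    """Fill the per-frame child arrays, best-first; returns the child count.

    Interval extensions for the four symbols are computed once (shared by the
    match/mismatch and deletion children); children whose interval is empty
    are not emitted.
    """
    o_lo = np.empty(4, np.int64)
    o_hi = np.empty(4, np.int64)
    _occ4(bwt, ck, stride, low, o_lo)
    _occ4(bwt, ck, stride, high, o_hi)
    cnt = 0
    for c in range(4):
        clo = C[c] + o_lo[c]
        chi = C[c] + o_hi[c]
        if chi <= clo:
            continue
        if c == qc:
            keys[cnt] = 0 * 64 + 0 * 8 + (c + 1)
            pens[cnt] = 0
        else:
            keys[cnt] = pen_mm * 64 + 1 * 8 + (c + 1)
            pens[cnt] = pen_mm
        syms[cnt] = c
        kinds[cnt] = K_EXT
        clows[cnt] = clo
        chighs[cnt] = chi
        cnt += 1
        if gaps_on:
            pen_d = -1
            if state == 0 and ngo < max_gapo:
                pen_d = pen_go
            elif state == 2 and nge < max_gape:
                pen_d = pen_ge
            if pen_d >= 0 and clip <= i <= m - clip:
                keys[cnt] = pen_d * 64 + 3 * 8 + (c + 1)
                syms[cnt] = c
                kinds[cnt] = K_DEL
                pens[cnt] = pen_d
                clows[cnt] = clo
                chighs[cnt] = chi
                cnt += 1
    if gaps_on and clip <= i - 1 < m - clip:
        pen_i = -1
        if state == 0 and ngo < max_gapo:
            pen_i = pen_go
        elif state == 1 and nge < max_gape:
            pen_i = pen_ge
        if pen_i >= 0:
            keys[cnt] = pen_i * 64 + 2 * 8
            syms[cnt] = -1
            kinds[cnt] = K_INS
            pens[cnt] = pen_i
            clows[cnt] = low
            chighs[cnt] = high
            cnt += 1
    # insertion sort by key: ascending (penalty, class, symbol)
    for a in range(1, cnt):
        ka, sa_, da, pa = keys[a], syms[a], kinds[a], pens[a]
        la, ha = clows[a], chighs[a]
        b = a - 1
        while b >= 0 and keys[b] > ka:
            keys[b + 1] = keys[b]
            syms[b + 1] = syms[b]
            kinds[b + 1] = kinds[b]
            pens[b + 1] = pens[b]
            clows[b + 1] = clows[b]
            chighs[b + 1] = chighs[b]
            b -= 1
        keys[b + 1] = ka
        syms[b + 1] = sa_
        kinds[b + 1] = da
        pens[b + 1] = pa
        clows[b + 1] = la
        chighs[b + 1] = ha
    return cnt


@njit(cache=True)
def dfs_kernel(bwt, ck, stride, C, n, q, d, z,
               gaps_on, max_gapo, max_gape, pen_mm, pen_go, pen_ge,
               clip, report_sub, max_visits, hits, best_init):
    """Iterative difference-bound DFS; returns (nhits, visits, truncated, overflow).

    ``best_init`` seeds the best-known difference count (z+1 when nothing is
    known); the caller may pass the best from a previous search whose hits
    compete in the same final filter (e.g. the other strand).
    """
    m = len(q)
    hcap = hits.shape[0]
    S = m + z + 8
    fi = np.empty(S, np.int64)
    flow = np.empty(S, np.int64)
    fhigh = np.empty(S, np.int64)
    fmm = np.empty(S, np.int64)
    fgo = np.empty(S, np.int64)
    fge = np.empty(S, np.int64)
    fins = np.empty(S, np.int64)
    fdel = np.empty(S, np.int64)
    fstate = np.empty(S, np.int64)
    fscore = np.empty(S, np.int64)
    fcidx = np.empty(S, np.int64)
    fnch = np.empty(S, np.int64)
    ckeys = np.empty((S, 9), np.int64)
    csyms = np.empty((S, 9), np.int64)
    ckinds = np.empty((S, 9), np.int64)
    cpens = np.empty((S, 9), np.int64)
    clows = np.empty((S, 9), np.int64)
    chighs = np.empty((S, 9), np.int64)

    sp = 0
    fi[0] = m
    flow[0] = 0
    fhigh[0] = n + 1
    fmm[0] = fgo[0] = fge[0] = fins[0] = fdel[0] = 0
    fstate[0] = 0
    fscore[0] = 0
    fcidx[0] = 0
    fnch[0] = -1

    nhits = 0
    overflow = 0
    truncated = 0
    visits = 0
    best = min(z + 1, best_init)
    if best > z:
        cap = z
    elif report_sub:
        cap = min(z, best + 1)
    else:
        cap = best
    while sp >= 0:
        if fi[sp] == 0:
            nd = fmm[sp] + fgo[sp] + fge[sp]
            if nd <= cap:
                if nhits < hcap:
                    hits[nhits, 0] = flow[sp]
                    hits[nhits, 1] = fhigh[sp]
                    hits[nhits, 2] = fmm[sp]
                    hits[nhits, 3] = fgo[sp]
                    hits[nhits, 4] = fge[sp]
                    hits[nhits, 5] = fins[sp]
                    hits[nhits, 6] = fdel[sp]
                    hits[nhits, 7] = fscore[sp]
                    nhits += 1
                else:
                    overflow = 1
                if nd < best:
                    best = nd
                    if report_sub:
                        cap = min(z, best + 1)
                    else:
                        cap = best
            sp -= 1
            continue
        if fnch[sp] < 0:
            fnch[sp] = _gen_children(fstate[sp], q[fi[sp] - 1], fi[sp], m,
                                     fgo[sp], fge[sp], gaps_on, max_gapo,
                                     max_gape, pen_mm, pen_go, pen_ge, clip,
                                     flow[sp], fhigh[sp], bwt, ck, stride, C,
                                     ckeys[sp], csyms[sp], ckinds[sp], cpens[sp],
                                     clows[sp], chighs[sp])
        if fcidx[sp] >= fnch[sp]:
            sp -= 1
            continue
        j = fcidx[sp]
        fcidx[sp] += 1
        pen = cpens[sp, j]
        kind = ckinds[sp, j]
        added = 1 if (pen > 0 or kind != K_EXT) else 0
        nd = fmm[sp] + fgo[sp] + fge[sp] + added
        if nd > cap:
            continue
        ci = fi[sp] if kind == K_DEL else fi[sp] - 1
        if ci > 0 and nd + d[ci - 1] > cap:
            continue
        clow = clows[sp, j]
        chigh = chighs[sp, j]
        visits += 1
        if visits > max_visits:
            truncated = 1
            break
        t = sp + 1
        fi[t] = ci
        flow[t] = clow
        fhigh[t] = chigh
        fmm[t] = fmm[sp]
        fgo[t] = fgo[sp]
        fge[t] = fge[sp]
        fins[t] = fins[sp]
        fdel[t] = fdel[sp]
        fscore[t] = fscore[sp] + pen
        if kind == K_EXT:
            if pen > 0:
                fmm[t] += 1
            fstate[t] = 0
        elif kind == K_INS:
            if fstate[sp] == 1:
                fge[t] += 1
            else:
                fgo[t] += 1
            fins[t] += 1
            fstate[t] = 1
        else:
            if fstate[sp] == 2:
                fge[t] += 1
            else:
                fgo[t] += 1
            fdel[t] += 1
            fstate[t] = 2
        fcidx[t] = 0
        fnch[t] = -1
        sp = t
    return nhits, visits, truncated, overflow


@njit(cache=True)
def sa_lookup_rows(bwt, ck, stride, C, sa_samp, sa_stride, n, rows, out):
    for idx in range(len(rows)):
        row = rows[idx]
        steps = 0
        while row % sa_stride != 0:
            c = bwt[row]
            if c > 3:
                row = 0
            else:
                row = C[c] + _occ(bwt, ck, stride, c, row)
            steps += 1
        out[idx] = (sa_samp[row // sa_stride] + steps) % (n + 1)


class KernelIndex:
    """Flat-array view of a GenomeIndex for the compiled kernels."""

    def __init__(self, gindex):
        fm, rfm = gindex.fm, gindex.rfm
        self.n = fm.n
        self.bwt = fm.bwt
        self.ck = fm.occ_ck
        self.stride = fm.occ_stride
        self.C = fm.C
        self.sa_samp = fm.sa_samples
        self.sa_stride = fm.sa_stride
        self.rbwt = rfm.bwt
        self.rck = rfm.occ_ck
        self.rstride = rfm.occ_stride
        self.rC = rfm.C

    def lower_bound(self, q_codes: np.ndarray) -> np.ndarray:
        d = np.empty(len(q_codes), dtype=np.int64)
        lower_bound_kernel(self.rbwt, self.rck, self.rstride, self.rC,
                           self.n, q_codes, d)
        return d

    def search(self, q_codes: np.ndarray, opts, z: int,
               hit_cap: int = 8192, best_init: int | None = None):
        """Run the DFS kernel; returns (unique hit rows, truncated, overflow).

        Hit rows are int64[k, 8]: low, high, n_mm, n_gapo, n_gape, n_ins,
        n_del, score — already post-filtered to min(z, best+1).
        """
        m = len(q_codes)
        d = self.lower_bound(q_codes) if m else np.empty(0, dtype=np.int64)
        hits = np.empty((hit_cap, HIT_FIELDS), dtype=np.int64)
        nhits, _visits, truncated, overflow = dfs_kernel(
            self.bwt, self.ck, self.stride, self.C, self.n,
            q_codes.astype(np.uint8), d, z,
            opts.gap_open_allowed, opts.max_gap_opens, opts.max_gap_extensions,
            opts.pen_mismatch, opts.pen_gap_open, opts.pen_gap_extend,
            opts.end_clip, opts.report_suboptimal, opts.max_visits, hits,
            z + 1 if best_init is None else best_init)
        raw = hits[:nhits]
        if nhits == 0:
            return raw.copy(), bool(truncated), bool(overflow)
        diffs = raw[:, 2] + raw[:, 3] + raw[:, 4]
        best = int(diffs.min())
        cap = min(z, best + 1) if opts.report_suboptimal else best
        raw = raw[diffs <= cap]
        raw = np.unique(raw, axis=0)
        return raw, bool(truncated), bool(overflow)

    def resolve_rows(self, low: int, high: int, cap: int | None = None) -> np.ndarray:
        """Text positions for BWT rows [low, high), optionally capped."""
        rows = np.arange(low, high, dtype=np.int64)
        if cap is not None:
            rows = rows[:cap]
        out = np.empty(len(rows), dtype=np.int64)
        sa_lookup_rows(self.bwt, self.ck, self.stride, self.C,
                       self.sa_samp, self.sa_stride, self.n, rows, out)
        return out
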