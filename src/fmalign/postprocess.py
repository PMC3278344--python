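"""SA-interval resolution, hit files, mapping quality and SAM emission.

The alignment stage writes per-read hits — SA intervals plus difference
compositions — to a versioned binary ``.sai`` file tied to its index by a
fingerprint.  The ``samse``/``sampe`` stages translate the intervals to
linear coordinates through the sampled suffix array, drop placements that
span a contig boundary, reconstruct CIGAR strings, assign a mapping quality
and emit SAM text.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .align import AlnOptions
from .fmindex import GenomeIndex
from ._kernels import KernelIndex
from .refpack import codes_from_string, revcomp

_SAI_MAGIC = b"FMSH"
_SAI_VERSION = 1

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80


@dataclass(frozen=True)
class StrandHit:
    """One hit of a read (or of its reverse complement, strand=1)."""

    low: int
    high: int
    n_mm: int
    n_gapo: int
    n_gape: int
    n_ins: int
    n_del: int
    score: int
    strand: int

    @property
    def n_diff(self) -> int:
        return self.n_mm + self.n_gapo + self.n_gape


@dataclass
class HitFileRecord:
    read_id: int
    hits: list[StrandHit] = field(default_factory=list)
    dropped: bool = False  # search aborted (visit cap) -> reported unmapped


@dataclass(frozen=True)
class MappedPosition:
    """A hit translated to linear space."""

    contig: str
    offset: int  # 0-based within contig
    strand: int
    n_diff: int
    ref_span: int
    hit: StrandHit
    global_pos: int
    in_ambiguous: bool = False


# --- hit files -------------------------------------------------------------


def write_hit_file(path, records: list[HitFileRecord], index_fingerprint: int,
                   opts: AlnOptions) -> None:
    """Binary per-read hit store (the ``.sai`` intermediate)."""
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4sII", _SAI_MAGIC, _SAI_VERSION, index_fingerprint))
        md = int(-1 if opts.max_diff == "auto" else opts.max_diff)
        fh.write(struct.pack("<iBiiiiiii", md, int(opts.gap_open_allowed),
                             opts.max_gap_opens, opts.max_gap_extensions,
                             opts.pen_mismatch, opts.pen_gap_open,
                             opts.pen_gap_extend, opts.seed_len, opts.end_clip))
        fh.write(struct.pack("<Q", len(records)))
        for rec in records:
            fh.write(struct.pack("<IIB", rec.read_id, len(rec.hits), int(rec.dropped)))
            if rec.hits:
                arr = np.array([[h.low, h.high, h.n_mm, h.n_gapo, h.n_gape,
                                 h.n_ins, h.n_del, h.score, h.strand]
                                for h in rec.hits], dtype="<i8")
                fh.write(arr.tobytes())


def read_hit_file(path) -> tuple[list[HitFileRecord], int, dict]:
    """Returns (records, index fingerprint, header options)."""
    with open(path, "rb") as fh:
        head = fh.read(12)
        if len(head) < 12:
            raise ValueError(f"truncated hit file {path}")
        magic, version, fp = struct.unpack("<4sII", head)
        if magic != _SAI_MAGIC:
            raise ValueError(f"{path} is not a hit (.sai) file")
        if version != _SAI_VERSION:
            raise ValueError(f"unsupported hit file version {version}")
        ob = fh.read(struct.calcsize("<iBiiiiiii"))
        md, gaps, mgo, mge, pm, pgo, pge, seed, clip = struct.unpack("<iBiiiiiii", ob)
        hdr = {"max_diff": ("auto" if md < 0 else md), "gap_open_allowed": bool(gaps),
               "max_gap_opens": mgo, "max_gap_extensions": mge,
               "pen_mismatch": pm, "pen_gap_open": pgo, "pen_gap_extend": pge,
               "seed_len": seed, "end_clip": clip}
        (n_reads,) = struct.unpack("<Q", fh.read(8))
        records = []
        for _ in range(n_reads):
            rb = fh.read(9)
            if len(rb) < 9:
                raise ValueError(f"truncated hit file {path}")
            rid, nh, dropped = struct.unpack("<IIB", rb)
            rec = HitFileRecord(read_id=rid, dropped=bool(dropped))
            if nh:
                raw = np.frombuffer(fh.read(nh * 9 * 8), dtype="<i8").reshape(nh, 9)
                rec.hits = [StrandHit(*(int(x) for x in row)) for row in raw]
            records.append(rec)
    return records, fp, hdr


# --- coordinate translation ------------------------------------------------


def interval_to_positions(gindex: GenomeIndex, hit: StrandHit, read_len: int,
                          max_occurrences: int = 10,
                          kidx: KernelIndex | None = None
                          ) -> tuple[list[MappedPosition], bool]:
    """Translate a hit's SA rows to (contig, offset) placements.

    At most ``max_occurrences`` rows are resolved; the flag reports whether
    the interval was truncated ("too many hits").  Placements whose reference
    span crosses a contig boundary are dropped; placements overlapping the
    ambiguity mask are flagged, not dropped.
    """
    if hit.high <= hit.low:
        raise ValueError("cannot resolve an empty SA interval")
    kidx = kidx or KernelIndex(gindex)
    too_many = hit.high - hit.low > max_occurrences
    positions = kidx.resolve_rows(hit.low, hit.high, cap=max_occurrences)
    ref_span = read_len - hit.n_ins + hit.n_del
    out = []
    for pos in sorted(int(p) for p in positions):
        contig, off = gindex.packed.contig_of(pos)
        cstart = pos - off
        clen = next(ln for nm, st, ln in gindex.packed.contig_table if nm == contig)
        if off + ref_span > clen:
            continue  # spans into the next contig: not a real genomic locus
        out.append(MappedPosition(
            contig=contig, offset=off, strand=hit.strand, n_diff=hit.n_diff,
            ref_span=ref_span, hit=hit, global_pos=pos,
            in_ambiguous=gindex.packed.overlaps_ambiguity(pos, pos + ref_span)))
    return out, too_many


def compute_mapq(best_hits: int, suboptimal_hits: int, n_diff_gap: int) -> int:
    """Phred-scale confidence of the chosen placement (declared convention).

    0 for a repetitive best hit; 37 for a unique hit with no suboptimal
    competitors; otherwise decays with the number of suboptimal hits and
    collapses to 0 when the suboptimal hits are as good as the best.
    """
    if best_hits < 1 or suboptimal_hits < 0:
        raise ValueError("hit counts must be non-negative (>=1 best)")
    if best_hits > 1:
        return 0
    if suboptimal_hits == 0:
        return 37
    if n_diff_gap == 0:
        return 0
    return max(0, 23 - 8 * (suboptimal_hits - 1))


# --- CIGAR reconstruction --------------------------------------------------


def cigar_for(query: np.ndarray, ref_window: np.ndarray, hit: StrandHit,
              end_clip: int) -> str:
    """Rebuild the CIGAR from the recorded operation counts.

    The search stores counts, not paths; with at most one gap the placement
    is recovered by scanning the gap position that reproduces the recorded
    mismatch count (smallest position on ties).
    """
    m = len(query)
    if hit.n_ins == 0 and hit.n_del == 0:
        return f"{m}M"

    def ham(qs, qe, rs):
        return sum(1 for k in range(qe - qs)
                   if query[qs + k] > 3 or query[qs + k] != ref_window[rs + k])

    if hit.n_ins:
        g = hit.n_ins
        best_j, best_mm = end_clip, None
        for j in range(end_clip, m - end_clip - g + 1):
            mm = ham(0, j, 0) + ham(j + g, m, j)
            if mm == hit.n_mm:
                return f"{j}M{g}I{m - j - g}M"
            if best_mm is None or mm < best_mm:
                best_j, best_mm = j, mm
        return f"{best_j}M{g}I{m - best_j - g}M"
    g = hit.n_del
    best_j, best_mm = end_clip, None
    for j in range(end_clip, m - end_clip + 1):
        mm = ham(0, j, 0) + ham(j, m, j + g)
        if mm == hit.n_mm:
            return f"{j}M{g}D{m - j}M"
        if best_mm is None or mm < best_mm:
            best_j, best_mm = j, mm
    return f"{best_j}M{g}D{m - best_j}M"


# --- SAM emission ----------------------------------------------------------


def sam_header(gindex: GenomeIndex, command_line: str = "") -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, _off, ln in gindex.packed.contig_table:
        lines.append(f"@SQ\tSN:{name}\tLN:{ln}")
    pg = f"@PG\tID:fmalign\tPN:fmalign\tVN:{_pkg_version}"
    if command_line:
        pg += f"\tCL:{command_line}"
    lines.append(pg)
    return lines


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


@dataclass
class _Chosen:
    primary: MappedPosition | None
    mapq: int
    alternates: list[MappedPosition]
    n_best: int
    n_subopt: int
    placements: list[MappedPosition]


def _choose(placements: list[MappedPosition], max_alternates: int) -> _Chosen:
    if not placements:
        return _Chosen(None, 0, [], 0, 0, [])
    ranked = sorted(placements, key=lambda p: (p.n_diff, p.hit.score, p.strand,
                                               p.global_pos))
    best = ranked[0]
    n_best = sum(1 for p in ranked if p.n_diff == best.n_diff)
    n_subopt = sum(1 for p in ranked if p.n_diff > best.n_diff)
    gap = min((p.n_diff - best.n_diff for p in ranked[1:]), default=None)
    mapq = compute_mapq(n_best, n_subopt, 1 if gap is None else gap)
    return _Chosen(best, mapq, ranked[1:1 + max_alternates], n_best, n_subopt, ranked)


def _resolve_read(gindex, kidx, rec: HitFileRecord, read_len: int,
                  max_occurrences: int) -> list[MappedPosition]:
    if rec.dropped:
        return []
    placements: list[MappedPosition] = []
    for h in rec.hits:
        pos, _trunc = interval_to_positions(gindex, h, read_len,
                                            max_occurrences, kidx=kidx)
        placements.extend(pos)
    return placements


def _sam_fields(name, seq, qual, chosen: _Chosen, ref_codes, end_clip,
                flag_extra: int = 0):
    """Common SAM columns for a single-end-style record."""
    qname = _strip_mate_suffix(name)
    if chosen.primary is None:
        flag = FLAG_UNMAPPED | flag_extra
        return [qname, str(flag), "*", "0", "0", "*", "*", "0", "0", seq, qual], None
    p = chosen.primary
    oriented = codes_from_string(seq if p.strand == 0 else revcomp(seq))
    window = ref_codes[p.global_pos:p.global_pos + p.ref_span]
    cigar = cigar_for(oriented, window, p.hit, end_clip)
    flag = (FLAG_REVERSE if p.strand else 0) | flag_extra
    out_seq = seq if p.strand == 0 else revcomp(seq)
    out_qual = qual if p.strand == 0 else qual[::-1]
    fields = [qname, str(flag), p.contig, str(p.offset + 1), str(chosen.mapq),
              cigar, "*", "0", "0", out_seq, out_qual]
    tags = [f"NM:i:{p.n_diff}"]
    if chosen.alternates:
        alts = []
        for a in chosen.alternates:
            strand_ch = "-" if a.strand else "+"
            alts.append(f"{a.contig},{strand_ch}{a.offset + 1},{len(seq)}M,{a.n_diff}")
        tags.append("XA:Z:" + ";".join(alts) + ";")
    return fields, tags


def samse(gindex: GenomeIndex, hit_records: list[HitFileRecord],
          reads: list[tuple[str, str, str]], opts: AlnOptions,
          max_occurrences: int = 10, command_line: str = "fmalign samse"):
    """Single-end SAM generation; yields header then one record per read."""
    if len(hit_records) != len(reads):
        raise ValueError(
            f"hit file has {len(hit_records)} records but {len(reads)} reads given")
    kidx = KernelIndex(gindex)
    ref_codes = gindex.packed.codes()
    yield from sam_header(gindex, command_line)
    for rec, (name, seq, qual) in zip(hit_records, reads):
        placements = _resolve_read(gindex, kidx, rec, len(seq), max_occurrences)
        chosen = _choose(placements, max_occurrences)
        fields, tags = _sam_fields(name, seq, qual, chosen, ref_codes, opts.end_clip)
        yield "\t".join(fields + (tags or []))


def _infer_insert_limits(pairs, cap: int = 10000):
    """Insert-size limits from unique proper candidates: mean +/- 4 sd."""
    sizes = []
    for c1, c2 in pairs:
        if c1.primary is None or c2.primary is None:
            continue
        if c1.n_best != 1 or c2.n_best != 1:
            continue
        size = _proper_insert(c1.primary, c2.primary)
        if size is not None:
            sizes.append(size)
        if len(sizes) >= cap:
            break
    if len(sizes) < 8:
        return (0, 10000)  # not enough evidence; permissive default
    arr = np.array(sizes, dtype=np.float64)
    mean, sd = arr.mean(), arr.std()
    return (max(0, int(mean - 4 * sd)), int(np.ceil(mean + 4 * sd)))


def _proper_insert(a: MappedPosition, b: MappedPosition):
    """Insert size if (a, b) are in proper orientation on one contig."""
    if a.contig != b.contig or a.strand == b.strand:
        return None
    fwd, rev = (a, b) if a.strand == 0 else (b, a)
    if fwd.offset > rev.offset:
        return None
    return rev.offset + rev.ref_span - fwd.offset


def sampe(gindex: GenomeIndex, hit_records_1, hit_records_2, reads_1, reads_2,
          opts: AlnOptions, insert_limits: tuple[int, int] | None = None,
          max_occurrences: int = 10, pair_candidates: int = 32,
          command_line: str = "fmalign sampe"):
    """Paired-end SAM generation.

    For each pair the opposite-strand placement combination with the smallest
    combined difference count and an insert size within limits is chosen;
    otherwise both mates fall back to their independent best placements with
    the proper-pair flag unset.  Limits default to mean +/- 4 sd of the first
    unique proper candidates.
    """
    if len(hit_records_1) != len(reads_1) or len(hit_records_2) != len(reads_2):
        raise ValueError("hit file / read count mismatch")
    if len(reads_1) != len(reads_2):
        raise ValueError(f"mate files differ in length: {len(reads_1)} vs {len(reads_2)}")
    kidx = KernelIndex(gindex)
    ref_codes = gindex.packed.codes()

    chosen_pairs = []
    for r1, r2, (n1, s1, q1), (n2, s2, q2) in zip(hit_records_1, hit_records_2,
                                                  reads_1, reads_2):
        p1 = _resolve_read(gindex, kidx, r1, len(s1), pair_candidates)
        p2 = _resolve_read(gindex, kidx, r2, len(s2), pair_candidates)
        chosen_pairs.append((_choose(p1, max_occurrences), _choose(p2, max_occurrences)))

    if insert_limits is None:
        insert_limits = _infer_insert_limits(chosen_pairs)
    lo, hi = insert_limits

    yield from sam_header(gindex, command_line)
    for (c1, c2), (n1, s1, q1), (n2, s2, q2) in zip(chosen_pairs, reads_1, reads_2):
        best_combo = None
        for a in c1.placements[:pair_candidates]:
            for b in c2.placements[:pair_candidates]:
                size = _proper_insert(a, b)
                if size is None or not lo <= size <= hi:
                    continue
                key = (a.n_diff + b.n_diff, a.hit.score + b.hit.score,
                       a.global_pos, b.global_pos, a.strand)
                if best_combo is None or key < best_combo[0]:
                    best_combo = (key, a, b, size)
        proper = best_combo is not None
        if proper:
            _, a, b, size = best_combo
            sel1 = _Chosen(a, _mapq_for(c1, a), c1.alternates, c1.n_best,
                           c1.n_subopt, c1.placements)
            sel2 = _Chosen(b, _mapq_for(c2, b), c2.alternates, c2.n_best,
                           c2.n_subopt, c2.placements)
        else:
            sel1, sel2, size = c1, c2, None
        yield _pe_record(n1, s1, q1, sel1, sel2, True, proper, size, ref_codes, opts)
        yield _pe_record(n2, s2, q2, sel2, sel1, False, proper, size, ref_codes, opts)


def _mapq_for(chosen: _Chosen, placement: MappedPosition) -> int:
    if chosen.primary is not None and placement.global_pos == chosen.primary.global_pos \
            and placement.strand == chosen.primary.strand:
        return chosen.mapq
    # the paired selection overrode the single-end best: low confidence alone
    return min(chosen.mapq, 3)


def _pe_record(name, seq, qual, mine: _Chosen, mate: _Chosen, is_first: bool,
               proper: bool, insert: int | None, ref_codes, opts) -> str:
    flag = FLAG_PAIRED | (FLAG_FIRST if is_first else FLAG_SECOND)
    if proper:
        flag |= FLAG_PROPER
    if mate.primary is None:
        flag |= FLAG_MATE_UNMAPPED
    elif mate.primary.strand:
        flag |= FLAG_MATE_REVERSE
    fields, tags = _sam_fields(name, seq, qual, mine, ref_codes, opts.end_clip,
                               flag_extra=flag)
    if mine.primary is not None and mate.primary is not None:
        rnext = "=" if mate.primary.contig == mine.primary.contig else mate.primary.contig
        fields[6] = rnext
        fields[7] = str(mate.primary.offset + 1)
        if proper and insert is not None and rnext == "=":
            if mine.primary.offset < mate.primary.offset or (
                    mine.primary.offset == mate.primary.offset and mine.primary.strand == 0):
                fields[8] = str(insert)
            else:
                fields[8] = str(-insert)
    elif mine.primary is None and mate.primary is not None:
        # unmapped mate placed at its partner's coordinates per convention
        fields[2] = mate.primary.contig
        fields[3] = str(mate.primary.offset + 1)
        fields[6] = "="
        fields[7] = str(mate.primary.offset + 1)
    return "\t".join(fields + (tags or []))
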