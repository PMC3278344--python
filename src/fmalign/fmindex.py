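"""BWT/FM-index construction and exact backward search.

The index covers the concatenated packed reference plus a single sentinel
that sorts before every base (there is no per-contig sentinel; hits spanning
a contig boundary are filtered during postprocessing).  Occurrence counts are
checkpointed at a fixed stride and suffix-array values sampled at a fixed row
stride; queries against the checkpointed structures are exact, the strides
trade memory for scan length.

Suffix-array construction is a plain prefix-doubling sort — adequate at the
scales this package targets; linear-time construction is out of scope.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .refpack import PackedReference, codes_from_string, pack_codes

SENTINEL = 4  # code used for the end-of-text symbol inside the BWT array

_MAGIC = {
    "pac": b"FMPK",
    "ann": b"FMAN",
    "bwt": b"FMBW",
    "sa": b"FMSA",
}
_VERSION = 1


class SAInterval(NamedTuple):
    """Half-open range [low, high) of BWT rows sharing a query suffix."""

    low: int
    high: int

    @property
    def size(self) -> int:
        return self.high - self.low

    @property
    def empty(self) -> bool:
        return self.high <= self.low


def build_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of codes + sentinel via prefix doubling (O(n log^2 n)).

    Returns a permutation of 0..n where n = len(codes); the sentinel suffix
    (position n) always sorts first.
    """
    n = len(codes)
    if n < 1:
        raise ValueError("reference must contain at least one base")
    rank = np.zeros(n + 1, dtype=np.int64)
    rank[:n] = codes.astype(np.int64) + 1  # sentinel keeps rank 0
    k = 1
    while True:
        key2 = np.full(n + 1, -1, dtype=np.int64)
        if k <= n:
            key2[: n + 1 - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord = rank[order]
        k_ord = key2[order]
        changed = np.empty(n + 1, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank = np.empty(n + 1, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n:
            return order.astype(np.int64)
        k *= 2


def bwt_from_sa(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Burrows-Wheeler transform: bwt[i] = text[sa[i]-1], sentinel where sa[i]==0."""
    n = len(codes)
    bwt = np.empty(n + 1, dtype=np.uint8)
    prev = sa - 1
    sent = sa == 0
    bwt[sent] = SENTINEL
    bwt[~sent] = codes[prev[~sent]]
    return bwt


def invert_bwt(bwt) -> np.ndarray | str:
    """Recover the unique text whose BWT (with one sentinel) is the input.

    Accepts either a uint8 code array (sentinel = 4) or a string using '$';
    returns the same kind.  Raises ``ValueError`` unless exactly one sentinel
    is present.
    """
    as_str = isinstance(bwt, str)
    if as_str:
        codes = np.frombuffer(bwt.encode("ascii"), dtype=np.uint8)
        arr = np.full(codes.shape, 255, dtype=np.uint8)
        for i, b in enumerate("ACGT"):
            arr[codes == ord(b)] = i
        arr[codes == ord("$")] = SENTINEL
        if (arr == 255).any():
            raise ValueError("BWT string may contain only A/C/G/T/$")
    else:
        arr = np.asarray(bwt, dtype=np.uint8)
    n_sent = int((arr == SENTINEL).sum())
    if n_sent != 1:
        raise ValueError(f"BWT must contain exactly one sentinel, found {n_sent}")
    n = len(arr) - 1
    counts = np.bincount(arr, minlength=5)
    starts = np.zeros(6, dtype=np.int64)
    # column-F order: sentinel first, then A..T
    starts[1] = counts[SENTINEL]
    for c in range(4):
        starts[c + 2] = starts[c + 1] + counts[c]
    seen = np.zeros(5, dtype=np.int64)
    lf = np.empty(n + 1, dtype=np.int64)
    for i, c in enumerate(arr):
        if c == SENTINEL:
            lf[i] = 0
        else:
            lf[i] = starts[c + 1] + seen[c]
        seen[c] += 1
    out = np.empty(n, dtype=np.uint8)
    row = 0
    for j in range(n - 1, -1, -1):
        out[j] = arr[row]
        row = lf[row]
    if as_str:
        return "".join("ACGT"[c] for c in out)
    return out


@dataclass
class FMIndex:
    """BWT with checkpointed occurrence counts and a sampled suffix array."""

    bwt: np.ndarray  # uint8, length n+1, one SENTINEL
    n: int  # text length (without sentinel)
    C: np.ndarray  # int64[4]; first BWT row of suffixes starting with symbol c
    occ_stride: int
    occ_ck: np.ndarray  # int64[(n+1)//stride + 1, 4]
    sa_stride: int
    sa_samples: np.ndarray  # int64; sa value at every sa_stride-th row
    sentinel_row: int

    @classmethod
    def from_bwt(cls, bwt: np.ndarray, occ_stride: int = 64, sa_stride: int = 8,
                 sa: np.ndarray | None = None) -> "FMIndex":
        if occ_stride < 1 or sa_stride < 1:
            raise ValueError("strides must be >= 1")
        n = len(bwt) - 1
        counts = np.bincount(bwt, minlength=5)[:4]
        C = np.empty(4, dtype=np.int64)
        C[0] = 1  # row 0 is the sentinel suffix
        for c in range(1, 4):
            C[c] = C[c - 1] + counts[c - 1]
        onehot = (bwt[:, None] == np.arange(4, dtype=np.uint8)[None, :])
        cum = np.zeros((n + 2, 4), dtype=np.int64)
        np.cumsum(onehot, axis=0, out=cum[1:])
        occ_ck = cum[::occ_stride].copy()
        sentinel_row = int(np.flatnonzero(bwt == SENTINEL)[0])
        if sa is None:
            sa_samples = np.empty(0, dtype=np.int64)
        else:
            sa_samples = sa[::sa_stride].astype(np.int64).copy()
        return cls(bwt=bwt.astype(np.uint8), n=n, C=C, occ_stride=occ_stride,
                   occ_ck=occ_ck, sa_stride=sa_stride, sa_samples=sa_samples,
                   sentinel_row=sentinel_row)

    @classmethod
    def build(cls, codes: np.ndarray, occ_stride: int = 64, sa_stride: int = 8) -> "FMIndex":
        sa = build_suffix_array(codes)
        return cls.from_bwt(bwt_from_sa(codes, sa), occ_stride, sa_stride, sa=sa)

    # --- queries -----------------------------------------------------------

    def occ(self, symbol: int, position: int) -> int:
        """Occurrences of symbol (0..3) in bwt[0:position)."""
        if not 0 <= position <= self.n + 1:
            raise ValueError(f"occ position {position} outside [0, {self.n + 1}]")
        k = position // self.occ_stride
        base = int(self.occ_ck[k, symbol])
        start = k * self.occ_stride
        if start == position:
            return base
        return base + int(np.count_nonzero(self.bwt[start:position] == symbol))

    def full_interval(self) -> SAInterval:
        return SAInterval(0, self.n + 1)

    def backward_ext(self, interval: SAInterval, symbol: int) -> SAInterval:
        low = int(self.C[symbol]) + self.occ(symbol, interval.low)
        high = int(self.C[symbol]) + self.occ(symbol, interval.high)
        return SAInterval(low, high)

    def exact_search(self, query) -> SAInterval:
        """Backward search of an ACGT query; empty query gives the full interval."""
        codes = codes_from_string(query) if isinstance(query, str) else np.asarray(query)
        iv = self.full_interval()
        for c in codes[::-1]:
            if c > 3:
                return SAInterval(0, 0)
            iv = self.backward_ext(iv, int(c))
            if iv.empty:
                return SAInterval(iv.low, iv.low)
        return iv

    def lf(self, row: int) -> int:
        c = int(self.bwt[row])
        if c == SENTINEL:
            return 0
        return int(self.C[c]) + self.occ(c, row)

    def sa_lookup(self, row: int) -> int:
        """Suffix-array value for a BWT row, recovered by LF-walking."""
        if not 0 <= row <= self.n:
            raise ValueError(f"row {row} outside [0, {self.n}]")
        steps = 0
        while row % self.sa_stride != 0:
            row = self.lf(row)
            steps += 1
        return int((self.sa_samples[row // self.sa_stride] + steps) % (self.n + 1))


def fingerprint(bwt: np.ndarray) -> int:
    """Stable 32-bit identifier of an index (used to pair hit files with it)."""
    return zlib.crc32(bwt.tobytes()) & 0xFFFFFFFF


# --- on-disk index bundle --------------------------------------------------


def _write_chunk(path, kind: str, header: bytes, payload: bytes) -> None:
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4sI", _MAGIC[kind], _VERSION))
        fh.write(header)
        fh.write(payload)


def _read_header(fh, kind: str, path) -> None:
    head = fh.read(8)
    if len(head) < 8:
        raise ValueError(f"truncated index file {path}")
    magic, version = struct.unpack("<4sI", head)
    if magic != _MAGIC[kind]:
        raise ValueError(f"bad magic in {path}: not a {kind} file")
    if version != _VERSION:
        raise ValueError(f"unsupported {kind} format version {version} in {path}")


def _read_exact(fh, nbytes: int, path):
    data = fh.read(nbytes)
    if len(data) != nbytes:
        raise ValueError(f"truncated index file {path}")
    return data


@dataclass
class GenomeIndex:
    """Packed reference plus forward and reverse-text FM-indices."""

    packed: PackedReference
    fm: FMIndex  # index of the forward text
    rfm: FMIndex  # index of the reversed text (for the difference lower bound)

    @classmethod
    def build(cls, packed: PackedReference, occ_stride: int = 64, sa_stride: int = 8) -> "GenomeIndex":
        codes = packed.codes()
        fm = FMIndex.build(codes, occ_stride, sa_stride)
        rfm = FMIndex.build(codes[::-1].copy(), occ_stride, sa_stride)
        return cls(packed=packed, fm=fm, rfm=rfm)

    @property
    def fingerprint(self) -> int:
        return fingerprint(self.fm.bwt)

    # file set mirrors the classic roles: .pac/.ann for the packed genome and
    # annotation, .bwt/.sa for the forward index, .rbwt/.rsa for the reverse
    def save(self, prefix) -> None:
        prefix = str(prefix)
        p = self.packed
        _write_chunk(prefix + ".pac", "pac", struct.pack("<Q", p.length), pack_codes(p.codes()).tobytes())
        ann = bytearray(struct.pack("<I", len(p.contig_table)))
        for name, off, ln in p.contig_table:
            nb = name.encode("utf-8")
            ann += struct.pack("<H", len(nb)) + nb + struct.pack("<QQ", off, ln)
        ann += struct.pack("<Q", len(p.ambiguity_runs))
        for start, ln in p.ambiguity_runs:
            ann += struct.pack("<QQ", start, ln)
        _write_chunk(prefix + ".ann", "ann", b"", bytes(ann))
        for ext, fm in ((".bwt", self.fm), (".rbwt", self.rfm)):
            head = struct.pack("<QIQ", fm.n, fm.occ_stride, fm.sentinel_row)
            _write_chunk(prefix + ext, "bwt", head, fm.bwt.tobytes())
        for ext, fm in ((".sa", self.fm), (".rsa", self.rfm)):
            head = struct.pack("<QI", fm.n, fm.sa_stride)
            _write_chunk(prefix + ext, "sa", head, fm.sa_samples.astype("<i8").tobytes())

    @classmethod
    def load(cls, prefix) -> "GenomeIndex":
        prefix = str(prefix)
        with open(prefix + ".pac", "rb") as fh:
            _read_header(fh, "pac", prefix + ".pac")
            (length,) = struct.unpack("<Q", _read_exact(fh, 8, prefix + ".pac"))
            payload = np.frombuffer(_read_exact(fh, (length + 3) // 4, prefix + ".pac"), dtype=np.uint8)
        with open(prefix + ".ann", "rb") as fh:
            _read_header(fh, "ann", prefix + ".ann")
            (nc,) = struct.unpack("<I", _read_exact(fh, 4, prefix + ".ann"))
            table = []
            for _ in range(nc):
                (nl,) = struct.unpack("<H", _read_exact(fh, 2, prefix + ".ann"))
                name = _read_exact(fh, nl, prefix + ".ann").decode("utf-8")
                off, ln = struct.unpack("<QQ", _read_exact(fh, 16, prefix + ".ann"))
                table.append((name, off, ln))
            (nr,) = struct.unpack("<Q", _read_exact(fh, 8, prefix + ".ann"))
            runs = []
            for _ in range(nr):
                start, ln = struct.unpack("<QQ", _read_exact(fh, 16, prefix + ".ann"))
                runs.append((start, ln))
        packed = PackedReference(payload=payload.copy(), length=int(length),
                                 contig_table=table, ambiguity_runs=runs)

        def load_fm(bwt_path, sa_path):
            with open(bwt_path, "rb") as fh:
                _read_header(fh, "bwt", bwt_path)
                n, occ_stride, sentinel_row = struct.unpack("<QIQ", _read_exact(fh, 20, bwt_path))
                bwt = np.frombuffer(_read_exact(fh, n + 1, bwt_path), dtype=np.uint8).copy()
            with open(sa_path, "rb") as fh:
                _read_header(fh, "sa", sa_path)
                n2, sa_stride = struct.unpack("<QI", _read_exact(fh, 12, sa_path))
                if n2 != n:
                    raise ValueError(f"{sa_path} does not match {bwt_path} (text length)")
                n_samp = (n + 1 + sa_stride - 1) // sa_stride
                sa_samples = np.frombuffer(_read_exact(fh, 8 * n_samp, sa_path), dtype="<i8").astype(np.int64)
            fm = FMIndex.from_bwt(bwt, occ_stride=int(occ_stride), sa_stride=int(sa_stride))
            fm.sa_samples = sa_samples
            if fm.sentinel_row != sentinel_row:
                raise ValueError(f"corrupt BWT in {bwt_path}: sentinel row mismatch")
            return fm

        fm = load_fm(prefix + ".bwt", prefix + ".sa")
        rfm = load_fm(prefix + ".rbwt", prefix + ".rsa")
        return cls(packed=packed, fm=fm, rfm=rfm)


def save_index(index: GenomeIndex, prefix) -> None:
    index.save(prefix)


def load_index(prefix) -> GenomeIndex:
    return GenomeIndex.load(prefix)
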