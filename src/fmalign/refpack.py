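"""2-bit packed reference sequences.

The aligner works on a single concatenated code sequence (A=0, C=1, G=2, T=3)
covering every contig of the input FASTA, with a contig table mapping offsets
back to the source records.  Two bits per base admit no fifth symbol, so any
IUPAC base outside ACGT is deterministically replaced by ``A`` and the
position recorded in an ambiguity mask; postprocessing can flag hits that
overlap masked regions.  The payload is stored packed four bases per byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
# full IUPAC nucleotide alphabet (U handled like any other ambiguity: -> A)
_IUPAC = set("ACGTURYSWKMBDHVN")

AMBIG_SUBSTITUTE = "A"


def _encode(seq: str, contig: str) -> tuple[np.ndarray, np.ndarray]:
    """Encode one contig; returns (codes uint8, ambiguous-position indices)."""
    up = seq.upper()
    arr = np.frombuffer(up.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    ambig = np.flatnonzero(codes == 255)
    if ambig.size:
        bad = [i for i in ambig if up[i] not in _IUPAC]
        if bad:
            i = bad[0]
            raise ValueError(
                f"non-IUPAC character {up[i]!r} in contig {contig!r} at position {i}"
            )
        codes[ambig] = _CODE[AMBIG_SUBSTITUTE]
    return codes, ambig.astype(np.int64)


def _positions_to_runs(pos: np.ndarray) -> list[tuple[int, int]]:
    if pos.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))
    return [(int(pos[s]), int(pos[e] - pos[s] + 1)) for s, e in zip(starts, ends)]


def pack_codes(codes: np.ndarray) -> np.ndarray:
    """Pack an array of 2-bit codes into bytes, 4 bases/byte, LSB first."""
    n = len(codes)
    padded = np.zeros((n + 3) // 4 * 4, dtype=np.uint8)
    padded[:n] = codes
    quads = padded.reshape(-1, 4).astype(np.uint16)
    packed = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    return packed.astype(np.uint8)


def unpack_codes(packed: np.ndarray, length: int) -> np.ndarray:
    quads = np.empty((len(packed), 4), dtype=np.uint8)
    quads[:, 0] = packed & 3
    quads[:, 1] = (packed >> 2) & 3
    quads[:, 2] = (packed >> 4) & 3
    quads[:, 3] = (packed >> 6) & 3
    return quads.reshape(-1)[:length].copy()


@dataclass
class PackedReference:
    """Concatenated 2-bit packed genome with contig table and ambiguity runs.

    ``payload`` holds ceil(length/4) bytes; ``ambiguity_runs`` is a list of
    (start, run_length) in concatenated coordinates.
    """

    payload: np.ndarray
    length: int
    contig_table: list[tuple[str, int, int]]
    ambiguity_runs: list[tuple[int, int]] = field(default_factory=list)

    def codes(self) -> np.ndarray:
        """Materialise the uint8 code array (one byte per base)."""
        return unpack_codes(self.payload, self.length)

    def unpack(self) -> str:
        """Decode to an ACGT string (ambiguous bases appear substituted)."""
        return "".join(_BASES[c] for c in self.codes())

    @property
    def ambiguity_mask(self) -> set[int]:
        out: set[int] = set()
        for start, ln in self.ambiguity_runs:
            out.update(range(start, start + ln))
        return out

    @property
    def payload_nbytes(self) -> int:
        return int(self.payload.nbytes)

    def contig_of(self, offset: int) -> tuple[str, int]:
        """Map a concatenated offset to (contig name, offset within contig)."""
        if not 0 <= offset < self.length:
            raise ValueError(f"offset {offset} outside reference of length {self.length}")
        for name, start, ln in self.contig_table:
            if start <= offset < start + ln:
                return name, offset - start
        raise AssertionError("contig table does not cover reference")

    def overlaps_ambiguity(self, start: int, end: int) -> bool:
        """True when [start, end) intersects any masked run."""
        return any(start < s + ln and s < end for s, ln in self.ambiguity_runs)


def pack_reference(fasta_records: list[tuple[str, str]]) -> PackedReference:
    """Pack FASTA records into one concatenated 2-bit reference.

    Contigs are concatenated in input order; bases outside ACGT are replaced
    by ``A`` and recorded in the ambiguity mask.  Raises ``ValueError`` for an
    empty record list or a character outside the IUPAC alphabet.
    """
    if not fasta_records:
        raise ValueError("cannot pack an empty reference")
    parts: list[np.ndarray] = []
    table: list[tuple[str, int, int]] = []
    ambig: list[np.ndarray] = []
    offset = 0
    for name, seq in fasta_records:
        codes, apos = _encode(seq, name)
        parts.append(codes)
        table.append((name, offset, len(seq)))
        if apos.size:
            ambig.append(apos + offset)
        offset += len(seq)
    codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    apos = np.concatenate(ambig) if ambig else np.empty(0, dtype=np.int64)
    return PackedReference(
        payload=pack_codes(codes),
        length=offset,
        contig_table=table,
        ambiguity_runs=_positions_to_runs(apos),
    )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly multi-contig, wrapped, mixed-case) FASTA file."""
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def codes_from_string(seq: str) -> np.ndarray:
    """Encode a read/query string; N (or any ambiguity) becomes code 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def string_from_codes(codes) -> str:
    return "".join("ACGTN"[c] for c in codes)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a 4-line FASTQ file into (name, sequence, quality) tuples."""
    out = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not head.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record in {path}")
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch in {path}")
            out.append((head[1:].rstrip("\n").split()[0], seq, qual))
    return out


def write_fastq(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1].copy()


def revcomp(seq: str) -> str:
    return string_from_codes(revcomp_codes(codes_from_string(seq)))
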