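"""wgsim-style read simulation and mapping-accuracy evaluation.

A synthetic genome is mutated into a haplotype (SNPs and short indels), and
error-bearing paired-end reads are sampled from the haplotype with their true
reference coordinates encoded losslessly in the read names.  The evaluator
scores a SAM stream against that truth: the percentage of reads confidently
mapped (mapping quality at or above a Phred-scale threshold, 10 by default)
and, among those, the percentage placed on the wrong contig or strand or
more than a small tolerance away from the true position.

Read names carry both mates' truth, because paired SAM records share their
query name: ``sim:<contig>:<pos1>:<strand1>:<pos2>:<strand2>:<serial>`` with
a ``/1``/``/2`` mate suffix in FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .refpack import revcomp_codes, string_from_codes

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    n_pairs: int
    read_len: int = 70
    base_error_rate: float = 0.02
    mutation_rate: float = 0.001
    indel_fraction: float = 0.1
    indel_extend: float = 0.3
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    rng_seed: int = 1

    def __post_init__(self):
        for r in (self.base_error_rate, self.mutation_rate, self.indel_fraction,
                  self.indel_extend):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.insert_mean <= self.read_len:
            raise ValueError("insert_mean must exceed read_len")


@dataclass(frozen=True)
class TruthRecord:
    contig: str
    pos: int  # 0-based leftmost reference coordinate
    strand: int  # 0 forward, 1 reverse


def simulate_genome(length: int, gc_content: float = 0.5,
                    rng_seed: int = 1, name: str = "chrS") -> tuple[str, str]:
    """Reproducible random genome with the requested GC composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    p = np.array([(1 - gc_content) / 2, gc_content / 2,
                  gc_content / 2, (1 - gc_content) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return name, string_from_codes(codes)


def mutate_haplotype(genome: str, mutation_rate: float, indel_fraction: float,
                     rng_seed: int = 1, indel_extend: float = 0.3):
    """Introduce SNPs and short indels; returns (haplotype codes, projection,
    variants).

    ``projection[h]`` is the reference coordinate of haplotype position h
    (inserted bases project to the reference base they precede).  Variants
    are (ref_pos, kind, payload) with kind in {"snp", "ins", "del"}.
    """
    from .refpack import codes_from_string

    ref = codes_from_string(genome)
    n = len(ref)
    rng = np.random.default_rng(rng_seed)
    hap: list[int] = []
    proj: list[int] = []
    variants: list[tuple[int, str, str]] = []
    i = 0
    while i < n:
        if mutation_rate > 0 and rng.random() < mutation_rate:
            if rng.random() < indel_fraction:
                g = 1
                while rng.random() < indel_extend:
                    g += 1
                if rng.random() < 0.5:  # deletion of reference bases
                    g = min(g, n - i)
                    variants.append((i, "del", str(g)))
                    i += g
                    continue
                ins = rng.integers(0, 4, size=g)
                for b in ins:
                    hap.append(int(b))
                    proj.append(i)
                variants.append((i, "ins", "".join(_BASES[b] for b in ins)))
                hap.append(int(ref[i]))
                proj.append(i)
                i += 1
                continue
            alt = (int(ref[i]) + int(rng.integers(1, 4))) % 4
            variants.append((i, "snp", _BASES[alt]))
            hap.append(alt)
            proj.append(i)
            i += 1
        else:
            hap.append(int(ref[i]))
            proj.append(i)
            i += 1
    return (np.array(hap, dtype=np.uint8), np.array(proj, dtype=np.int64),
            variants)


def _inject_errors(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    if rate <= 0:
        return codes
    out = codes.copy()
    errs = np.flatnonzero(rng.random(len(codes)) < rate)
    if errs.size:
        shifts = rng.integers(1, 4, size=errs.size)
        out[errs] = (out[errs] + shifts) % 4
    return out


def sample_read_pairs(haplotype: np.ndarray, projection: np.ndarray,
                      params: SimParams, contig: str = "chrS"):
    """Sample paired reads from a haplotype.

    Returns (reads_1, reads_2, truth) where reads are FASTQ tuples
    (name, sequence, quality) and truth maps the shared core name to the
    (mate1, mate2) TruthRecord pair.  Mate 1 is the forward-strand mate;
    mate 2 is reverse-complemented.  Base qualities are constant 'I'.
    """
    rng = np.random.default_rng(params.rng_seed)
    hlen = len(haplotype)
    L = params.read_len
    if hlen < params.insert_mean:
        raise ValueError("haplotype shorter than the mean insert size")
    reads_1, reads_2 = [], []
    truth: dict[str, tuple[TruthRecord, TruthRecord]] = {}
    qual = "I" * L
    for serial in range(params.n_pairs):
        while True:
            insert = int(round(rng.normal(params.insert_mean, params.insert_sd)))
            if L <= insert <= hlen:
                break
        pos = int(rng.integers(0, hlen - insert + 1))
        end = pos + insert
        m1 = haplotype[pos:pos + L]
        m2 = revcomp_codes(haplotype[end - L:end])
        p1, p2 = int(projection[pos]), int(projection[end - L])
        core = f"sim:{contig}:{p1}:+:{p2}:-:{serial}"
        e1 = _inject_errors(m1, params.base_error_rate, rng)
        e2 = _inject_errors(m2, params.base_error_rate, rng)
        reads_1.append((core + "/1", string_from_codes(e1), qual))
        reads_2.append((core + "/2", string_from_codes(e2), qual))
        truth[core] = (TruthRecord(contig, p1, 0), TruthRecord(contig, p2, 1))
    return reads_1, reads_2, truth


@dataclass
class EvalResult:
    n_reads: int = 0
    n_confident: int = 0  # mapped with mapq >= threshold
    n_wrong: int = 0  # confident but misplaced

    @property
    def pct_mapped(self) -> float:
        return 100.0 * self.n_confident / self.n_reads if self.n_reads else 0.0

    @property
    def pct_error(self) -> float:
        return 100.0 * self.n_wrong / self.n_confident if self.n_confident else 0.0

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.n_reads + other.n_reads,
                          self.n_confident + other.n_confident,
                          self.n_wrong + other.n_wrong)

    def report(self) -> str:
        lines = ["metric\tvalue",
                 f"reads\t{self.n_reads}",
                 f"confident\t{self.n_confident}",
                 f"wrong\t{self.n_wrong}",
                 "",
                 f"n_reads={self.n_reads}",
                 f"pct_mapped={self.pct_mapped:.4f}",
                 f"pct_error={self.pct_error:.4f}"]
        return "\n".join(lines)


def truth_from_name(core: str) -> tuple[TruthRecord, TruthRecord]:
    """Decode the truth pair from a simulated read's core name."""
    parts = core.split(":")
    if len(parts) != 7 or parts[0] != "sim":
        raise ValueError(f"not a simulated read name: {core!r}")
    _, contig, p1, s1, p2, s2, _serial = parts
    return (TruthRecord(contig, int(p1), 0 if s1 == "+" else 1),
            TruthRecord(contig, int(p2), 0 if s2 == "+" else 1))


def evaluate(sam_lines, truth: dict, mapq_threshold: int = 10,
             pos_tolerance: int = 5, default_mate: int = 1) -> EvalResult:
    """Score SAM records against the simulator's truth.

    ``pct_mapped`` is computed over all records (one per read);
    ``pct_error`` over the confidently mapped ones.  A read is wrong when
    its contig or strand differs from truth or its 0-based position is more
    than ``pos_tolerance`` away.  Unknown read names raise ``ValueError``.
    """
    res = EvalResult()
    for line in sam_lines:
        if not line or line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        qname, flag, rname, pos, mapq = f[0], int(f[1]), f[2], int(f[3]), int(f[4])
        core = qname[:-2] if qname.endswith(("/1", "/2")) else qname
        if core not in truth:
            raise ValueError(f"read name {qname!r} not found in truth table")
        if flag & 0x40:
            mate = 1
        elif flag & 0x80:
            mate = 2
        elif qname.endswith("/2"):
            mate = 2
        elif qname.endswith("/1"):
            mate = 1
        else:
            mate = default_mate
        t = truth[core][mate - 1]
        res.n_reads += 1
        if flag & 0x4 or mapq < mapq_threshold:
            continue
        res.n_confident += 1
        strand = 1 if flag & 0x10 else 0
        if (rname != t.contig or strand != t.strand
                or abs((pos - 1) - t.pos) > pos_tolerance):
            res.n_wrong += 1
    return res
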