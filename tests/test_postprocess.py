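import random

import numpy as np
import pytest

from conftest import random_dna
from fmalign.align import AlnOptions
from fmalign.fmindex import GenomeIndex
from fmalign.pipeline import align_reads
from fmalign.postprocess import (
    HitFileRecord,
    StrandHit,
    cigar_for,
    compute_mapq,
    interval_to_positions,
    read_hit_file,
    samse,
    sampe,
    write_hit_file,
)
from fmalign.refpack import codes_from_string, pack_reference, revcomp
from fmalign.simulate import (
    SimParams,
    evaluate,
    mutate_haplotype,
    sample_read_pairs,
    simulate_genome,
)


def _hit(low, high, n_mm=0, strand=0, n_ins=0, n_del=0):
    n_gapo = 1 if (n_ins or n_del) else 0
    n_gape = max(n_ins + n_del - 1, 0)
    return StrandHit(low=low, high=high, n_mm=n_mm, n_gapo=n_gapo,
                     n_gape=n_gape, n_ins=n_ins, n_del=n_del,
                     score=3 * n_mm + 11 * n_gapo + 4 * n_gape, strand=strand)


class TestHitFile:
    def test_roundtrip(self, tmp_path):
        records = [
            HitFileRecord(read_id=0, hits=[_hit(3, 5, 1), _hit(7, 8, 0, strand=1)]),
            HitFileRecord(read_id=1, hits=[]),
            HitFileRecord(read_id=2, hits=[], dropped=True),
        ]
        path = tmp_path / "x.sai"
        write_hit_file(path, records, 0xDEAD, AlnOptions(max_diff=2))
        got, fp, hdr = read_hit_file(path)
        assert fp == 0xDEAD
        assert hdr["max_diff"] == 2 and hdr["seed_len"] == 32
        assert [r.hits for r in got] == [records[0].hits, [], []]
        assert got[2].dropped

    def test_rejects_non_sai(self, tmp_path):
        path = tmp_path / "bad.sai"
        path.write_bytes(b"NOTASAI!" + b"\0" * 40)
        with pytest.raises(ValueError):
            read_hit_file(path)

    def test_samse_refuses_foreign_fingerprint(self, toy_genome_index, tmp_path):
        gi, c1, c2 = toy_genome_index
        path = tmp_path / "x.sai"
        write_hit_file(path, [HitFileRecord(0)], gi.fingerprint + 1,
                       AlnOptions(max_diff=1))
        _recs, fp, _ = read_hit_file(path)
        assert fp != gi.fingerprint  # the CLI rejects on this comparison


class TestIntervalToPositions:
    def test_toy_positions(self):
        packed = pack_reference([("c1", "ACAACG")])
        gi = GenomeIndex.build(packed, occ_stride=4, sa_stride=2)
        iv = gi.fm.exact_search("AC")
        pos, too_many = interval_to_positions(gi, _hit(iv.low, iv.high), 2)
        assert not too_many
        assert sorted((p.contig, p.offset) for p in pos) == [("c1", 0), ("c1", 3)]

    def test_truncation_flag(self):
        packed = pack_reference([("c1", "A" * 40)])
        gi = GenomeIndex.build(packed, occ_stride=4, sa_stride=2)
        iv = gi.fm.exact_search("AAAA")
        pos, too_many = interval_to_positions(gi, _hit(iv.low, iv.high), 4,
                                              max_occurrences=5)
        assert too_many and len(pos) <= 5

    def test_contig_boundary_hits_dropped(self):
        # "GGTT" exists only across the c1/c2 junction
        packed = pack_reference([("c1", "AAAGG"), ("c2", "TTCCC")])
        gi = GenomeIndex.build(packed, occ_stride=4, sa_stride=2)
        iv = gi.fm.exact_search("GGTT")
        assert iv.size == 1
        pos, _ = interval_to_positions(gi, _hit(iv.low, iv.high), 4)
        assert pos == []

    def test_empty_interval_rejected(self, toy_genome_index):
        gi, _c1, _c2 = toy_genome_index
        with pytest.raises(ValueError):
            interval_to_positions(gi, _hit(5, 5), 10)


class TestComputeMapq:
    def test_unique_hit_ceiling(self):
        assert compute_mapq(1, 0, 1) == 37

    def test_repetitive_hit_zero(self):
        assert compute_mapq(2, 0, 1) == 0
        assert compute_mapq(5, 3, 1) == 0

    def test_suboptimal_decay_and_monotonicity(self):
        grid = [compute_mapq(1, s, 1) for s in range(0, 8)]
        assert grid[0] == 37
        assert all(b <= a for a, b in zip(grid[1:], grid[2:]))
        assert compute_mapq(1, 1, 0) == 0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            compute_mapq(0, 0, 1)


class TestCigar:
    def test_ungapped(self):
        q = codes_from_string("ACGTACGTAC")
        assert cigar_for(q, q, _hit(0, 1, 0), 5) == "10M"

    def test_insertion_placement(self):
        ref = codes_from_string("AAAACCTTTTGGGG")
        # read = ref with 'G' inserted after position 6
        q = codes_from_string("AAAACCGTTTTGGG")
        h = _hit(0, 1, 0, n_ins=1)
        assert cigar_for(q, ref[:13], h, 5) == "6M1I7M"

    def test_deletion_placement(self):
        ref = codes_from_string("AAAACCTTTTGGGG")
        q = codes_from_string("AAAACCTTTGGGG")  # one T deleted
        h = _hit(0, 1, 0, n_del=1)
        cig = cigar_for(q, ref, h, 5)
        assert cig in {"6M1D7M", "7M1D6M", "8M1D5M", "9M1D4M"}


def _reads_of(pairs):
    return [tuple(r) for r in pairs]


@pytest.fixture(scope="module")
def aligned(compiled_kernels):
    rng = random.Random(31)
    genome = random_dna(rng, 4000)
    packed = pack_reference([("cX", genome)])
    gi = GenomeIndex.build(packed, occ_stride=16, sa_stride=4)
    opts = AlnOptions(max_diff=2)
    reads = []
    truth_pos = []
    for k in range(30):
        p = rng.randrange(0, 3960)
        seq = genome[p:p + 36]
        strand = rng.random() < 0.5
        if strand:
            seq = revcomp(seq)
        reads.append((f"r{k}", seq, "I" * 36))
        truth_pos.append((p, int(strand)))
    reads.append(("junk", "".join(rng.choice("ACGT") for _ in range(36)), "I" * 36))
    recs = align_reads(gi, [s for _n, s, _q in reads], opts)
    lines = list(samse(gi, recs, reads, opts))
    return gi, reads, truth_pos, lines


class TestSamse:
    def test_record_count_matches_read_count(self, aligned):
        _gi, reads, _tp, lines = aligned
        body = [ln for ln in lines if not ln.startswith("@")]
        assert len(body) == len(reads)

    def test_unique_hits_recover_truth(self, aligned):
        _gi, reads, truth_pos, lines = aligned
        body = [ln for ln in lines if not ln.startswith("@")]
        checked = 0
        for ln, (p, strand) in zip(body, truth_pos):
            f = ln.split("\t")
            flag, mapq = int(f[1]), int(f[4])
            if flag & 4 or mapq == 0:
                continue
            assert f[2] == "cX"
            assert int(f[3]) - 1 == p
            assert (1 if flag & 16 else 0) == strand
            checked += 1
        assert checked >= 25

    def test_nm_tag_equals_n_diff_and_strand_seq(self, aligned):
        gi, reads, _tp, lines = aligned
        body = [ln for ln in lines if not ln.startswith("@")]
        for ln, (_n, seq, _q) in zip(body, reads):
            f = ln.split("\t")
            flag = int(f[1])
            if flag & 4:
                assert f[2] == "*" and f[5] == "*"
                continue
            assert any(t.startswith("NM:i:") for t in f[11:])
            assert f[9] in (seq, revcomp(seq))
            if flag & 16:
                assert f[9] == revcomp(seq)

    def test_sam_parses_with_pysam(self, aligned, tmp_path):
        import pysam

        _gi, _reads, _tp, lines = aligned
        path = tmp_path / "out.sam"
        path.write_text("\n".join(lines) + "\n")
        with pysam.AlignmentFile(str(path)) as fh:
            n = sum(1 for _ in fh)
        assert n == len(_reads)

    def test_read_count_mismatch_raises(self, aligned):
        gi, reads, _tp, _lines = aligned
        with pytest.raises(ValueError):
            list(samse(gi, [HitFileRecord(0)], reads, AlnOptions(max_diff=1)))


@pytest.fixture(scope="module")
def pe_setup(compiled_kernels):
    name, genome = simulate_genome(30_000, rng_seed=41)
    hap, proj, _ = mutate_haplotype(genome, 0.0, 0.0, rng_seed=42)
    params = SimParams(n_pairs=150, read_len=50, base_error_rate=0.01,
                       insert_mean=300, insert_sd=30, rng_seed=43)
    r1, r2, truth = sample_read_pairs(hap, proj, params, contig=name)
    gi = GenomeIndex.build(pack_reference([(name, genome)]),
                           occ_stride=32, sa_stride=8)
    opts = AlnOptions(max_diff=3)
    recs1 = align_reads(gi, [s for _n, s, _q in r1], opts)
    recs2 = align_reads(gi, [s for _n, s, _q in r2], opts)
    lines = list(sampe(gi, recs1, recs2, _reads_of(r1), _reads_of(r2), opts))
    return gi, r1, r2, truth, lines, params


class TestSampe:

    def test_proper_pairs_and_insert_sizes(self, pe_setup):
        _gi, _r1, _r2, _truth, lines, params = pe_setup
        body = [ln for ln in lines if not ln.startswith("@")]
        assert len(body) == 300
        tlens = []
        for ln in body:
            f = ln.split("\t")
            flag, tlen = int(f[1]), int(f[8])
            assert flag & 0x1
            if flag & 0x2 and tlen > 0:
                tlens.append(tlen)
        assert len(tlens) >= 100
        mean = np.mean(tlens)
        # simulator inserts are N(300, 30): the recovered mean must agree
        assert abs(mean - params.insert_mean) <= 2 * params.insert_sd / np.sqrt(len(tlens)) + 1

    def test_pair_flags_are_consistent(self, pe_setup):
        _gi, _r1, _r2, _truth, lines, _params = pe_setup
        body = [ln for ln in lines if not ln.startswith("@")]
        for a, b in zip(body[0::2], body[1::2]):
            fa, fb = int(a.split("\t")[1]), int(b.split("\t")[1])
            assert bool(fa & 0x40) and bool(fb & 0x80)
            assert bool(fa & 0x2) == bool(fb & 0x2)
            assert bool(fa & 0x10) == bool(fb & 0x20)
            assert bool(fa & 0x4) == bool(fb & 0x8)

    def test_paired_truth_recovery(self, pe_setup):
        _gi, _r1, _r2, truth, lines, _params = pe_setup
        res = evaluate(lines, truth, mapq_threshold=10)
        assert res.pct_error <= 1.0
        assert res.pct_mapped >= 90.0

    def test_mate_count_mismatch_raises(self, pe_setup):
        gi, r1, r2, _truth, _lines, _params = pe_setup
        opts = AlnOptions(max_diff=1)
        with pytest.raises(ValueError):
            list(sampe(gi, [], [], _reads_of(r1), _reads_of(r2), opts))

    def test_same_strand_mates_not_proper(self, compiled_kernels):
        rng = random.Random(44)
        genome = random_dna(rng, 5000)
        gi = GenomeIndex.build(pack_reference([("c", genome)]),
                               occ_stride=16, sa_stride=4)
        opts = AlnOptions(max_diff=1)
        # both mates on the forward strand: orientation rule must reject
        r1 = [("p/1", genome[100:140], "I" * 40)]
        r2 = [("p/2", genome[400:440], "I" * 40)]
        recs1 = align_reads(gi, [r1[0][1]], opts)
        recs2 = align_reads(gi, [r2[0][1]], opts)
        lines = [ln for ln in sampe(gi, recs1, recs2, r1, r2, opts,
                                    insert_limits=(0, 1000))
                 if not ln.startswith("@")]
        for ln in lines:
            assert not int(ln.split("\t")[1]) & 0x2

    def test_one_mate_unmapped_flags_partner(self, compiled_kernels):
        rng = random.Random(45)
        genome = random_dna(rng, 5000)
        gi = GenomeIndex.build(pack_reference([("c", genome)]),
                               occ_stride=16, sa_stride=4)
        opts = AlnOptions(max_diff=0)
        r1 = [("p/1", genome[100:140], "I" * 40)]
        r2 = [("p/2", "T" * 40 if "T" * 40 not in genome else "A" * 40, "I" * 40)]
        recs1 = align_reads(gi, [r1[0][1]], opts)
        recs2 = align_reads(gi, [r2[0][1]], opts)
        lines = [ln for ln in sampe(gi, recs1, recs2, r1, r2, opts,
                                    insert_limits=(0, 1000))
                 if not ln.startswith("@")]
        f1, f2 = (int(ln.split("\t")[1]) for ln in lines)
        assert f2 & 0x4 and f1 & 0x8
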