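import math
import random

import pytest

from conftest import build_pair, mutate_query, random_dna, resolve_positions
from fmalign.align import (
    AlnOptions,
    auto_max_diff,
    bfs_inexact_reference,
    compute_lower_bound,
    dfs_inexact,
)
from fmalign.oracle import brute_force_hits, hamming_hits, validate_hit


def binom_tail(n, p, z):
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(z + 1, n + 1))


class TestAutoMaxDiff:
    def test_matches_direct_binomial_tail(self):
        for length in (1, 10, 37, 70, 150):
            z = auto_max_diff(length)
            assert binom_tail(length, 0.04, z) < 0.01
            if z > 0:
                assert binom_tail(length, 0.04, z - 1) >= 0.01

    def test_single_base_read(self):
        # P(X > 0) = 0.04 >= 0.01, P(X > 1) = 0 < 0.01
        assert auto_max_diff(1) == 1

    def test_monotone_in_read_length(self):
        zs = [auto_max_diff(n) for n in range(1, 200)]
        assert all(b >= a for a, b in zip(zs, zs[1:]))

    def test_vanishing_rate_gives_zero(self):
        assert auto_max_diff(100, error_rate=1e-9) == 0


class TestLowerBound:
    def test_exact_substring_gives_zero_bound(self, toy_pair):
        _, rfm = toy_pair
        assert compute_lower_bound(rfm, "ACAACG").tolist() == [0] * 6

    def test_tt_needs_two_differences(self, toy_pair):
        _, rfm = toy_pair
        assert compute_lower_bound(rfm, "TT").tolist() == [1, 2]

    def test_non_decreasing_random(self):
        rng = random.Random(13)
        for _ in range(50):
            text = random_dna(rng, rng.randrange(50, 400))
            _, rfm = build_pair(text)
            q = random_dna(rng, rng.randrange(1, 25))
            d = compute_lower_bound(rfm, q).tolist()
            assert d == sorted(d)

    def test_bound_never_exceeds_true_minimum(self):
        """d[i] must lower-bound the oracle's minimal differences of each prefix."""
        rng = random.Random(14)
        opts = AlnOptions(max_diff=3, gap_open_allowed=False)
        for _ in range(30):
            text = random_dna(rng, 200)
            _, rfm = build_pair(text)
            q = random_dna(rng, 12)
            d = compute_lower_bound(rfm, q)
            for i in (len(q) - 1,):
                hits = hamming_hits(text, q, 3)
                if hits:
                    true_min = min(nd for _p, nd in hits)
                    assert d[i] <= true_min


class TestDfsExamples:
    def test_exact_hit(self, toy_pair):
        fm, rfm = toy_pair
        res = dfs_inexact(fm, rfm, "ACG", AlnOptions(max_diff=0))
        assert resolve_positions(fm, res.hits) == {(3, 0)}
        (hit,) = res.hits
        assert hit.high - hit.low == 1 and hit.n_diff == 0

    def test_one_mismatch(self, toy_pair):
        fm, rfm = toy_pair
        res = dfs_inexact(fm, rfm, "ACG", AlnOptions(max_diff=1, gap_open_allowed=False))
        assert resolve_positions(fm, res.hits) == {(0, 1), (3, 0)}

    def test_absent_query_empty(self, toy_pair):
        fm, rfm = toy_pair
        res = dfs_inexact(fm, rfm, "TTT", AlnOptions(max_diff=0))
        assert res.hits == frozenset()

    def test_all_mismatch_path_exists(self, toy_pair):
        fm, rfm = toy_pair
        res = dfs_inexact(fm, rfm, "TTT", AlnOptions(max_diff=3, gap_open_allowed=False))
        assert len(res.hits) >= 1

    def test_query_too_long_raises(self, toy_pair):
        fm, rfm = toy_pair
        with pytest.raises(ValueError, match="length"):
            dfs_inexact(fm, rfm, "A" * 600, AlnOptions(max_diff=0))

    def test_n_costs_one_mismatch(self):
        fm, rfm = build_pair("ACGTACGTAAACCC")
        opts = AlnOptions(max_diff=1, gap_open_allowed=False)
        res = dfs_inexact(fm, rfm, "ACNT", opts)
        assert {(p, d) for p, d in resolve_positions(fm, res.hits)} == {(0, 1), (4, 1)}
        res0 = dfs_inexact(fm, rfm, "ACNT", AlnOptions(max_diff=0))
        assert res0.hits == frozenset()

    def test_gap_disabled_never_emits_gaps(self):
        rng = random.Random(15)
        opts = AlnOptions(max_diff=3, gap_open_allowed=False)
        for _ in range(30):
            text = random_dna(rng, 300)
            fm, rfm = build_pair(text)
            q = mutate_query(rng, text[20:40], 2, do_indel=False)
            res = dfs_inexact(fm, rfm, q, opts)
            assert all(h.n_gapo == h.n_gape == 0 for h in res.hits)


class TestBfs:
    def test_empty_query_full_interval(self, toy_pair):
        fm, rfm = toy_pair
        res = bfs_inexact_reference(fm, rfm, "", AlnOptions(max_diff=1))
        (hit,) = res.hits
        assert (hit.low, hit.high, hit.n_diff) == (0, fm.n + 1, 0)

    def test_frontier_cap_raises(self):
        fm, rfm = build_pair("ACGT" * 100)
        opts = AlnOptions(max_diff=3, bfs_frontier_cap=2)
        with pytest.raises(MemoryError):
            bfs_inexact_reference(fm, rfm, "ACGTACGT", opts)


class TestOracle:
    def test_exact_substring(self):
        opts = AlnOptions(max_diff=0)
        hits = brute_force_hits("ACAACG", "AC", opts)
        assert hits == {(0, 0), (3, 0)}

    def test_gap_disabled_equals_hamming_scan(self):
        rng = random.Random(16)
        for _ in range(25):
            text = random_dna(rng, 250)
            q = mutate_query(rng, text[30:52], 2, do_indel=False)
            z = rng.randrange(4)
            opts = AlnOptions(max_diff=z, gap_open_allowed=False)
            assert brute_force_hits(text, q, opts) == hamming_hits(text, q, z)

    def test_validate_hit_positive_and_negative(self):
        opts = AlnOptions(max_diff=2)
        assert validate_hit("ACAACG", "ACG", 3, 0, 0, 0, opts)
        assert not validate_hit("ACAACG", "ACG", 3, 1, 0, 0, opts)


def _random_case(rng):
    n = rng.randrange(100, 800)
    text = random_dna(rng, n)
    m = rng.randrange(8, 36)
    if rng.random() < 0.75:
        p = rng.randrange(0, n - m)
        q = mutate_query(rng, text[p:p + m], rng.randrange(0, 3),
                         do_indel=rng.random() < 0.4)
    else:
        q = random_dna(rng, m)
    z = rng.randrange(0, 4)
    gaps = rng.random() < 0.5
    return text, q, AlnOptions(max_diff=z, gap_open_allowed=gaps)


def test_dfs_matches_oracle_randomized(compiled_kernels):
    rng = random.Random(17)
    for _ in range(60):
        text, q, opts = _random_case(rng)
        fm, rfm = build_pair(text)
        res = dfs_inexact(fm, rfm, q, opts)
        assert resolve_positions(fm, res.hits) == brute_force_hits(text, q, opts)


def test_dfs_equals_bfs_and_uses_less_memory(compiled_kernels):
    rng = random.Random(18)
    for _ in range(40):
        text, q, opts = _random_case(rng)
        fm, rfm = build_pair(text)
        dres = dfs_inexact(fm, rfm, q, opts)
        bres = bfs_inexact_reference(fm, rfm, q, opts)
        assert dres.hits == bres.hits
        assert bres.peak_stored_nodes >= dres.peak_stored_nodes


def test_every_emitted_hit_revalidates(compiled_kernels):
    rng = random.Random(19)
    for _ in range(30):
        text, q, opts = _random_case(rng)
        fm, rfm = build_pair(text)
        for h in dfs_inexact(fm, rfm, q, opts).hits:
            for row in range(h.low, h.high):
                p = fm.sa_lookup(row)
                assert validate_hit(text, q, p, h.n_mm, h.n_ins, h.n_del, opts)
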