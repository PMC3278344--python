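import random

import pytest

from fmalign.fmindex import FMIndex, GenomeIndex
from fmalign.refpack import pack_reference


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def naive_occurrences(text: str, query: str) -> list[int]:
    """All start positions of query in text by direct scanning."""
    if not query:
        return list(range(len(text) + 1))
    out = []
    start = 0
    while True:
        p = text.find(query, start)
        if p < 0:
            return out
        out.append(p)
        start = p + 1


def build_pair(text: str, occ_stride: int = 16, sa_stride: int = 4):
    """Forward and reverse-text FM indices for a raw text string."""
    from fmalign.refpack import codes_from_string

    codes = codes_from_string(text)
    fm = FMIndex.build(codes, occ_stride, sa_stride)
    rfm = FMIndex.build(codes[::-1].copy(), occ_stride, sa_stride)
    return fm, rfm


def resolve_positions(fm: FMIndex, hits) -> set[tuple[int, int]]:
    """SA-resolve a hit set to {(position, minimal n_diff)}."""
    best: dict[int, int] = {}
    for h in hits:
        for row in range(h.low, h.high):
            p = fm.sa_lookup(row)
            if p not in best or h.n_diff < best[p]:
                best[p] = h.n_diff
    return set(best.items())


def mutate_query(rng: random.Random, q: str, n_sub: int, do_indel: bool) -> str:
    out = list(q)
    for _ in range(n_sub):
        j = rng.randrange(len(out))
        out[j] = rng.choice("ACGT")
    if do_indel and len(out) > 14:
        j = rng.randrange(6, len(out) - 6)
        if rng.random() < 0.5:
            del out[j]
        else:
            out.insert(j, rng.choice("ACGT"))
    return "".join(out)


@pytest.fixture(scope="session")
def toy_text():
    return "ACAACG"


@pytest.fixture(scope="session")
def toy_pair(toy_text):
    return build_pair(toy_text, occ_stride=4, sa_stride=2)


@pytest.fixture(scope="session")
def toy_genome_index():
    rng = random.Random(20240901)
    c1 = random_dna(rng, 400)
    c2 = random_dna(rng, 250)
    packed = pack_reference([("c1", c1), ("c2", c2)])
    return GenomeIndex.build(packed, occ_stride=16, sa_stride=4), c1, c2


@pytest.fixture(scope="session")
def compiled_kernels():
    """Warm the numba kernels once per session on a tiny case."""
    from fmalign.align import AlnOptions
    from fmalign.seeds import batch_align
    from fmalign.oracle import brute_force_hits

    fm, rfm = build_pair("ACGTACGTACGTAAACCCGGG")
    batch_align(fm, rfm, ["ACGT"], AlnOptions(max_diff=1))
    brute_force_hits("ACGTACGTACGT", "ACGT", AlnOptions(max_diff=1))
    return True
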