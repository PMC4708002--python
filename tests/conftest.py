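import random

import numpy as np
import pytest

from bwtsv import dna
from bwtsv.genome_index import GenomeIndex, GlobalGenome
from bwtsv.read_index import ReadCollection, ReadIndex
from bwtsv.simulate import ReadSimParams, make_genome, simulate_reads


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def brute_count(pattern: str, reads) -> int:
    """Occurrences of pattern over reads and their reverse complements."""
    total = 0
    for r in reads:
        for s in (r, dna.revcomp_str(r)):
            i = s.find(pattern)
            while i >= 0:
                total += 1
                i = s.find(pattern, i + 1)
    return total


def brute_left_contexts(seed: str, reads, e: int) -> dict[str, int]:
    """All left contexts (up to e bases) of seed over reads + revcomps."""
    ctx: dict[str, int] = {}
    for r in reads:
        for s in (r, dna.revcomp_str(r)):
            i = s.find(seed)
            while i >= 0:
                ctx[s[max(0, i - e) : i]] = ctx.get(s[max(0, i - e) : i], 0) + 1
                i = s.find(seed, i + 1)
    return ctx


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_915)


@pytest.fixture(scope="session")
def random_reads(rng):
    return [random_dna(rng, 40) for _ in range(30)]


@pytest.fixture(scope="session")
def small_index(random_reads):
    return ReadIndex.build(ReadCollection.from_iter(random_reads))


@pytest.fixture(scope="session")
def small_genome(rng):
    seq = random_dna(rng, 2000)
    return GlobalGenome.from_records([("chr1", seq)]), seq


@pytest.fixture(scope="session")
def toy_deletion():
    """Error-free tumor/normal toy with one deletion junction at (s-1, t)."""
    ref = make_genome(1, [40_000], seed=7)
    name, seq = ref[0]
    s, t = 15_000, 18_000
    cancer = [(name, np.concatenate([seq[:s], seq[t:]]))]
    params = ReadSimParams(coverage=40.0, error_rate=0.0)
    tumor = simulate_reads(cancer, params, seed=8, sample_label="tumor")
    normal = simulate_reads(ref, params, seed=9, sample_label="normal")
    gidx = GenomeIndex(GlobalGenome([name], [seq]))
    rit = ReadIndex.build_from_matrices([tumor.r1, tumor.r2], "tumor")
    rin = ReadIndex.build_from_matrices([normal.r1, normal.r2], "normal")
    return dict(gidx=gidx, ridx_tumor=rit, ridx_normal=rin, s=s, t=t, seq=seq)


@pytest.fixture(scope="session")
def toy_inversion():
    """Error-free toy with one inversion of [s, t): junctions (s-1, t-1) and (s, t)."""
    ref = make_genome(1, [40_000], seed=17)
    name, seq = ref[0]
    s, t = 15_000, 18_000
    cancer = [(name, np.concatenate([seq[:s], dna.revcomp(seq[s:t]), seq[t:]]))]
    params = ReadSimParams(coverage=40.0, error_rate=0.0)
    tumor = simulate_reads(cancer, params, seed=18, sample_label="tumor")
    normal = simulate_reads(ref, params, seed=19, sample_label="normal")
    gidx = GenomeIndex(GlobalGenome([name], [seq]))
    rit = ReadIndex.build_from_matrices([tumor.r1, tumor.r2], "tumor")
    rin = ReadIndex.build_from_matrices([normal.r1, normal.r2], "normal")
    return dict(gidx=gidx, ridx_tumor=rit, ridx_normal=rin, s=s, t=t, seq=seq)
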