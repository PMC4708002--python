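"""Lossless dictionary of reads: BWT over a read collection with rank
structures, backward search, occurrence counting and recursive leftward
extension enumeration.

Each read is indexed together with its reverse complement, both terminated by
their own ``$``, so that fragments sequenced from either strand — including
junction-spanning fragments — are found by a single forward-pattern search.
The index is exact: occurrence counting over the index equals brute-force
substring counting over the reads and their reverse complements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from . import dna
from ._kernels import (
    backward_step_kernel,
    build_checkpoints,
    count_pattern_kernel,
    enumerate_left_kernel,
    match_interval_kernel,
)
from .suffix import bwt_from_sa, suffix_array

logger = logging.getLogger(__name__)

INDEX_FORMAT_VERSION = 1
DEFAULT_MIN_READ_LEN = 30


@dataclass
class ReadCollection:
    """Validated read set for one sample.

    Reads containing non-ACGT characters (typically N) are dropped at
    construction with a logged count; exact-match semantics over the index
    would otherwise be ill-defined.
    """

    reads: list[str]
    sample_label: str = "tumor"
    min_read_len: int = DEFAULT_MIN_READ_LEN
    n_dropped: int = field(default=0, init=False)

    @classmethod
    def from_iter(
        cls,
        reads: Iterable[str],
        sample_label: str = "tumor",
        min_read_len: int = DEFAULT_MIN_READ_LEN,
    ) -> "ReadCollection":
        kept, dropped = [], 0
        for r in reads:
            if len(r) >= min_read_len and dna.is_valid_read(r):
                kept.append(r.upper())
            else:
                dropped += 1
        rc = cls(kept, sample_label=sample_label, min_read_len=min_read_len)
        rc.n_dropped = dropped
        if dropped:
            logger.info("dropped %d reads (non-ACGT or < %d bp)", dropped, min_read_len)
        return rc

    @classmethod
    def from_fastq(cls, *paths, sample_label="tumor", min_read_len=DEFAULT_MIN_READ_LEN):
        """Read one or more FASTQ files (quality scores ignored)."""
        import pysam

        def gen():
            for p in paths:
                with pysam.FastxFile(str(p)) as fh:
                    for rec in fh:
                        yield rec.sequence

        return cls.from_iter(gen(), sample_label=sample_label, min_read_len=min_read_len)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SearchInterval:
    """Half-open suffix-rank interval; width = occurrences of the pattern."""

    lo: int
    hi: int

    @property
    def width(self) -> int:
        return self.hi - self.lo

    @property
    def empty(self) -> bool:
        return self.lo >= self.hi


class ReadIndex:
    """BWT of a read collection (both strands) with occurrence checkpoints."""

    def __init__(self, bwt: np.ndarray, n_entries: int, sample_label: str = "tumor"):
        self.bwt = np.asarray(bwt, dtype=np.uint8)
        self.n_entries = int(n_entries)
        self.sample_label = sample_label
        counts = np.bincount(self.bwt, minlength=5).astype(np.int64)
        # cbase[c] = number of symbols < c in the text (bucket starts)
        self.char_counts = counts
        self.cbase = np.concatenate(([0], np.cumsum(counts)))[:5]
        self.occ = build_checkpoints(self.bwt)
        if int(counts[dna.SENTINEL]) != self.n_entries:
            raise ValueError("sentinel count does not match number of entries")

    # -- construction --------------------------------------------------

    @classmethod
    def build(cls, reads: ReadCollection) -> "ReadIndex":
        """Index each read and its reverse complement, '$'-terminated."""
        if len(reads) == 0:
            raise ValueError("cannot index an empty read collection")
        chunks = []
        term = np.array([dna.SENTINEL], dtype=np.uint8)
        for r in reads.reads:
            arr = dna.encode(r)
            chunks.append(arr)
            chunks.append(term)
            chunks.append(dna.revcomp(arr))
            chunks.append(term)
        text = np.concatenate(chunks)
        sa = suffix_array(text)
        bwt = bwt_from_sa(text, sa)
        return cls(bwt, n_entries=2 * len(reads), sample_label=reads.sample_label)

    @classmethod
    def build_from_matrices(cls, matrices, sample_label: str = "tumor") -> "ReadIndex":
        """Build from (n, read_len) uint8 code matrices (codes 1..4 only).

        Equivalent to :meth:`build` on the decoded strings but skips string
        round-trips; used by the pipeline on simulator/mapper output."""
        blocks = []
        n_entries = 0
        for mat in matrices:
            n, L = mat.shape
            if n == 0:
                continue
            n_entries += 2 * n
            # per read: read $ revcomp $ — the same entry order as build()
            block = np.zeros((n, 2 * (L + 1)), dtype=np.uint8)
            block[:, :L] = mat
            block[:, L + 1 : 2 * L + 1] = dna._COMPLEMENT[mat[:, ::-1]]
            blocks.append(block.reshape(-1))
        if not n_entries:
            raise ValueError("cannot index an empty read collection")
        text = np.concatenate(blocks)
        sa = suffix_array(text)
        bwt = bwt_from_sa(text, sa)
        return cls(bwt, n_entries=n_entries, sample_label=sample_label)

    # -- queries -------------------------------------------------------

    def full_interval(self) -> SearchInterval:
        return SearchInterval(0, self.bwt.size)

    def backward_step(self, interval: SearchInterval, c: str | int) -> SearchInterval:
        """Extend the matched pattern by one character on the left."""
        code = dna.encode(c)[0] if isinstance(c, str) else int(c)
        if not 1 <= code <= 4:
            raise ValueError("backward step character must be one of A, C, G, T")
        lo, hi = backward_step_kernel(
            self.bwt, self.occ, self.cbase, interval.lo, interval.hi, code
        )
        return SearchInterval(int(lo), int(hi))

    def match_interval(self, pattern: str | np.ndarray) -> SearchInterval:
        pat = dna.encode(pattern) if isinstance(pattern, str) else np.asarray(pattern, np.uint8)
        lo, hi = match_interval_kernel(self.bwt, self.occ, self.cbase, pat)
        return SearchInterval(int(lo), int(hi))

    def count_occurrences(self, pattern: str | np.ndarray) -> int:
        """Exact substring occurrence count over all indexed entries."""
        pat = dna.encode(pattern) if isinstance(pattern, str) else np.asarray(pattern, np.uint8)
        if pat.size == 0:
            raise ValueError("pattern must be non-empty")
        return int(count_pattern_kernel(self.bwt, self.occ, self.cbase, pat))

    def enumerate_left_extensions(
        self, seed: str | np.ndarray, ext_len: int = 20, max_branches: int = 1024
    ) -> list[tuple[str, int]]:
        """All maximal left extensions s (|s| <= ext_len) with s+seed indexed.

        support = occurrence count of s+seed.  An extension is maximal when it
        reaches ext_len or no further base extends it.  Seed absent -> []."""
        if ext_len < 1:
            raise ValueError("ext_len must be >= 1")
        iv = self.match_interval(seed)
        if iv.empty:
            return []
        out_ext = np.empty((max_branches, ext_len), dtype=np.uint8)
        out_len = np.empty(max_branches, dtype=np.int64)
        out_sup = np.empty(max_branches, dtype=np.int64)
        n = enumerate_left_kernel(
            self.bwt, self.occ, self.cbase, iv.lo, iv.hi, ext_len, out_ext, out_len, out_sup
        )
        return [
            (dna.decode(out_ext[i, : out_len[i]]), int(out_sup[i])) for i in range(n)
        ]

    # -- reconstruction / serialization --------------------------------

    def invert(self) -> list[str]:
        """Recover the indexed multiset of strings from the BWT alone."""
        bwt = self.bwt
        n = bwt.size
        counts = np.bincount(bwt, minlength=5).astype(np.int64)
        cbase = np.concatenate(([0], np.cumsum(counts)))[:5]
        # LF mapping via stable per-symbol numbering
        occ_before = np.zeros(n, dtype=np.int64)
        seen = np.zeros(5, dtype=np.int64)
        for i in range(n):
            occ_before[i] = seen[bwt[i]]
            seen[bwt[i]] += 1
        lf = cbase[bwt] + occ_before
        out = []
        # each '$' in the first column corresponds to one entry; walk backwards
        for k in range(int(counts[dna.SENTINEL])):
            chars = []
            i = k  # rows [0, n_entries) of the first column are '$'
            while True:
                c = bwt[i]
                if c == dna.SENTINEL:
                    break
                chars.append(c)
                i = int(lf[i])
            out.append(dna.decode(np.array(chars[::-1], dtype=np.uint8)))
        return sorted(out)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            version=np.int64(INDEX_FORMAT_VERSION),
            bwt=self.bwt,
            n_entries=np.int64(self.n_entries),
            sample_label=np.frombuffer(self.sample_label.encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "ReadIndex":
        with np.load(path) as z:
            if int(z["version"]) != INDEX_FORMAT_VERSION:
                raise ValueError("unsupported read-index format version")
            return cls(
                z["bwt"],
                int(z["n_entries"]),
                sample_label=z["sample_label"].tobytes().decode(),
            )


def build_read_index(reads: ReadCollection) -> ReadIndex:
    """Functional alias for :meth:`ReadIndex.build`."""
    return ReadIndex.build(reads)
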