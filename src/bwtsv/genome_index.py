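"""Concatenated reference genome with global coordinates and MLU windows.

All chromosomes are joined into one sequence with a ``$`` separator between
them, so every chromosomal position maps to a single global coordinate and
positions on different chromosomes are mutually comparable.  On top of the
concatenation (plus its reverse complement) a table of MLU values — the
minimum length for uniqueness, i.e. the shortest substring starting at a
position, in a given direction, that occurs exactly once in both strands of
the genome — is computed from a suffix array and its LCP array.  Anchor
queries for the breakpoint scan are MLU-sized windows padded by a small
slack ``alpha`` so that matching read fragments are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dna
from .suffix import lcp_array, suffix_array

UNDEFINED = -1
DEFAULT_ALPHA = 3


class GlobalGenome:
    """Reference chromosomes concatenated with '$' separators.

    Coordinates are 0-based; global coordinate = chromosome offset + position.
    N bases are encoded as the separator code and therefore never match reads
    nor participate in unique windows.
    """

    def __init__(self, names: list[str], seqs: list[np.ndarray]):
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        if not names:
            raise ValueError("at least one chromosome required")
        self.names = list(names)
        sep = np.array([dna.SENTINEL], dtype=np.uint8)
        parts, offsets, pos = [], {}, 0
        self.starts = np.empty(len(names), dtype=np.int64)
        self.ends = np.empty(len(names), dtype=np.int64)
        for i, (name, s) in enumerate(zip(names, seqs)):
            if i:
                parts.append(sep)
                pos += 1
            offsets[name] = pos
            self.starts[i] = pos
            pos += s.size
            self.ends[i] = pos
            parts.append(s)
        self.sequence = np.concatenate(parts)
        self.offsets = offsets
        self.total_length = int(self.sequence.size)

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "GlobalGenome":
        """Build from (name, sequence) pairs; N/lowercase tolerated."""
        names, seqs = [], []
        for name, seq in records:
            names.append(name)
            b = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            arr = np.zeros(b.size, dtype=np.uint8)
            for ch, code in zip("ACGT", (dna.A, dna.C, dna.G, dna.T)):
                arr[b == ord(ch)] = code
            seqs.append(arr)
        return cls(names, seqs)

    @classmethod
    def from_fasta(cls, path) -> "GlobalGenome":
        import pysam

        recs = []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                recs.append((rec.name, rec.sequence))
        return cls.from_records(recs)

    # -- coordinates ---------------------------------------------------

    def chrom_to_global(self, chrom: str, pos: int) -> int:
        off = self.offsets[chrom]
        i = self.names.index(chrom)
        if not 0 <= pos < self.ends[i] - self.starts[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return off + pos

    def global_to_chrom(self, g: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.ends, g, side="right"))
        if not (0 <= g < self.total_length) or g < self.starts[i]:
            raise ValueError(f"global coordinate {g} is a separator or out of range")
        return self.names[i], int(g - self.starts[i])

    def chrom_index(self, g: int) -> int:
        """Index of the chromosome containing global position g (-1 if separator)."""
        i = int(np.searchsorted(self.ends, g, side="right"))
        if 0 <= g < self.total_length and i < len(self.names) and g >= self.starts[i]:
            return i
        return -1

    def slice(self, lo: int, hi: int) -> np.ndarray:
        return self.sequence[lo:hi]


@dataclass
class MLUTable:
    """Per-position MLU values over both strands of the concatenation.

    ``mlu_plus[i]`` is stored over the doubled text ``S $ revcomp(S)``:
    indices < n are rightward MLUs on the forward strand; index ``n+1+j``
    is the rightward MLU at position j of the reverse complement, i.e. the
    leftward MLU at forward position ``n-1-j``.  ``UNDEFINED`` marks
    positions with no unique extension inside their chromosome.
    """

    mlu_plus: np.ndarray
    n_forward: int

    def forward(self, x: int) -> int:
        return int(self.mlu_plus[x])

    def reverse(self, x: int) -> int:
        """Leftward MLU anchored at forward-strand position x."""
        return int(self.mlu_plus[self.n_forward + 1 + (self.n_forward - 1 - x)])


def concatenate_genome(records: list[tuple[str, str]]) -> GlobalGenome:
    return GlobalGenome.from_records(records)


def compute_mlu_plus(genome: GlobalGenome) -> MLUTable:
    """MLU table from the suffix/LCP arrays of genome + reverse complement.

    The minimal unique length at position i is 1 + the longest prefix shared
    with any other suffix of the doubled text (both strands); it is undefined
    when that length would run past the chromosome end or cover an N.
    """
    seq = genome.sequence
    n = seq.size
    doubled = np.concatenate(
        [seq, np.array([dna.SENTINEL], dtype=np.uint8), dna.revcomp(seq)]
    )
    m = doubled.size
    sa = suffix_array(doubled)
    lcp = lcp_array(doubled, sa)
    rank = np.empty(m, dtype=np.int64)
    rank[sa.astype(np.int64)] = np.arange(m)
    # longest prefix shared with any lexicographic neighbour
    lcp_next = np.zeros(m, dtype=np.int64)
    lcp_next[:-1] = lcp[1:]
    shared = np.maximum(lcp[rank], lcp_next[rank])
    mlu = shared + 1
    # next separator/N (code 0) at or after each position
    sep_pos = np.flatnonzero(doubled == dna.SENTINEL)
    idx = np.searchsorted(sep_pos, np.arange(m), side="left")
    nxt_sep = np.where(idx < sep_pos.size, sep_pos[np.minimum(idx, sep_pos.size - 1)], m)
    room = nxt_sep - np.arange(m)
    mlu = np.where((mlu <= room) & (doubled != dna.SENTINEL), mlu, UNDEFINED)
    return MLUTable(mlu_plus=mlu.astype(np.int32), n_forward=n)


class GenomeIndex:
    """GlobalGenome plus its MLU table and window-query construction."""

    def __init__(self, genome: GlobalGenome, mlu: MLUTable | None = None):
        self.genome = genome
        self.mlu = mlu if mlu is not None else compute_mlu_plus(genome)

    def make_window_query(
        self, x: int, alpha: int = DEFAULT_ALPHA, strand: str = "+"
    ) -> np.ndarray | None:
        """Unique anchor window of length MLU(x) + alpha starting at x.

        '+' extends rightward on the forward strand; '-' returns the reverse
        complement window extending leftward from x (used by the swapped
        scan).  Returns None (skip signal) when the MLU is undefined or the
        window would cross a chromosome boundary.
        """
        g = self.genome
        if not 0 <= x < g.total_length:
            return None
        ci = g.chrom_index(x)
        if ci < 0:
            return None
        if strand == "+":
            ml = self.mlu.forward(x)
            if ml == UNDEFINED or x + ml + alpha > g.ends[ci]:
                return None
            return g.sequence[x : x + ml + alpha]
        ml = self.mlu.reverse(x)
        if ml == UNDEFINED or x - (ml + alpha) + 1 < g.starts[ci]:
            return None
        return dna.revcomp(g.sequence[x - (ml + alpha) + 1 : x + 1])

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            version=np.int64(1),
            names="\x00".join(self.genome.names).encode(),
            starts=self.genome.starts,
            ends=self.genome.ends,
            sequence=self.genome.sequence,
            mlu=self.mlu.mlu_plus,
            n_forward=np.int64(self.mlu.n_forward),
        )

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        with np.load(path) as z:
            names = bytes(z["names"]).decode().split("\x00")
            seq = z["sequence"]
            starts, ends = z["starts"], z["ends"]
            seqs = [seq[s:e] for s, e in zip(starts, ends)]
            genome = GlobalGenome(names, seqs)
            mlu = MLUTable(z["mlu"], int(z["n_forward"]))
            return cls(genome, mlu)
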