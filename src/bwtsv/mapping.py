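"""Internal exact-seed paired-end mapper.

Places each read by a unique exact (or, as a fallback, one-mismatch) match of
its first 30 bases against the reference, verified by full-length mismatch
counting, so the pipeline's simulations need no external aligner.  MAPQ is 60
for uniquely placed reads and 0 otherwise; a pair is flagged proper when both
ends map to the same chromosome in inward orientation with a template length
within mean +- 4 sd of the insert model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dna
from .genome_index import GlobalGenome
from .simulate import ReadSet

SEED_LEN = 30
MAX_NM = 10
PROPER_SD_RANGE = 4.0


class MapperIndex:
    """Sorted table of the reference's 30-mers (forward strand)."""

    def __init__(self, genome: GlobalGenome, seed_len: int = SEED_LEN):
        self.genome = genome
        self.seed_len = seed_len
        seq = genome.sequence
        n = seq.size
        k = seed_len
        if n < k:
            raise ValueError("genome shorter than the seed length")
        keys = np.zeros(n - k + 1, dtype=np.uint64)
        valid = np.ones(n - k + 1, dtype=bool)
        for j in range(k):
            win = seq[j : j + n - k + 1]
            keys = (keys << np.uint64(2)) | (win.astype(np.uint64) - 1)
            valid &= win != dna.SENTINEL
        # windows containing a separator/N would wrap (code 0 - 1); drop them
        pos = np.flatnonzero(valid).astype(np.int64)
        keys = keys[pos]
        order = np.argsort(keys, kind="stable")
        self.keys = keys[order]
        self.pos = pos[order]

    def lookup(self, query_keys: np.ndarray):
        """(count, first-hit position) for each query key."""
        lo = np.searchsorted(self.keys, query_keys, side="left")
        hi = np.searchsorted(self.keys, query_keys, side="right")
        count = hi - lo
        first = self.pos[np.minimum(lo, self.pos.size - 1)]
        first = np.where(count > 0, first, -1)
        return count, first


@dataclass
class MappingResult:
    """Per-read placements for a paired read set (2 * n_pairs reads).

    Read order: all r1 then all r2.  ``pos`` is the 0-based global coordinate
    of the leftmost aligned base (-1 = unmapped); ``strand`` 0 forward /
    1 reverse; ``proper`` is per pair."""

    pos: np.ndarray
    strand: np.ndarray
    mapq: np.ndarray
    nm: np.ndarray
    n_pairs: int
    read_len: int
    sample_label: str
    proper: np.ndarray = None
    tlen: np.ndarray = None

    def five_prime(self, i: int) -> int:
        return int(self.pos[i] + (self.read_len - 1 if self.strand[i] else 0))


def _pack_keys(mat: np.ndarray) -> np.ndarray:
    keys = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(mat.shape[1]):
        keys = (keys << np.uint64(2)) | (mat[:, j].astype(np.uint64) - 1)
    return keys


def _one_mismatch_variants(keys: np.ndarray, k: int) -> np.ndarray:
    """(n, 3k) matrix of all single-base substitutions of each packed key."""
    n = keys.size
    out = np.empty((n, 3 * k), dtype=np.uint64)
    col = 0
    for j in range(k):
        shift = np.uint64(2 * (k - 1 - j))
        cur = (keys >> shift) & np.uint64(3)
        for d in (1, 2, 3):
            nb = (cur + np.uint64(d)) & np.uint64(3)
            out[:, col] = (keys & ~(np.uint64(3) << shift)) | (nb << shift)
            col += 1
    return out


def map_reads(
    reads: ReadSet,
    index: MapperIndex,
    insert_mean: float,
    insert_sd: float,
    one_mismatch_rescue: bool = True,
) -> MappingResult:
    genome = index.genome
    rl = reads.read_len
    k = index.seed_len
    mat = np.concatenate([reads.r1, reads.r2])
    n = mat.shape[0]
    rc_mat = dna._COMPLEMENT[mat[:, ::-1]]

    key_f = _pack_keys(mat[:, :k])
    key_r = _pack_keys(rc_mat[:, :k])
    cf, pf = index.lookup(key_f)
    cr, pr = index.lookup(key_r)

    pos = np.full(n, -1, dtype=np.int64)
    strand = np.zeros(n, dtype=np.uint8)
    mapq = np.zeros(n, dtype=np.uint8)

    total = cf + cr
    uniq = total == 1
    fwd = uniq & (cf == 1)
    rev = uniq & (cr == 1)
    pos[fwd] = pf[fwd]
    # reverse placement: seed is the first 30 bases of the reverse complement,
    # i.e. the leftmost aligned bases on the reference
    pos[rev] = pr[rev]
    strand[rev] = 1
    mapq[uniq] = 60
    ambiguous = total > 1

    if one_mismatch_rescue:
        miss = np.flatnonzero(total == 0)
        if miss.size:
            var_f = _one_mismatch_variants(key_f[miss], k)
            var_r = _one_mismatch_variants(key_r[miss], k)
            cf2, ff2 = index.lookup(var_f.ravel())
            cr2, fr2 = index.lookup(var_r.ravel())
            cf2, ff2 = cf2.reshape(var_f.shape), ff2.reshape(var_f.shape)
            cr2, fr2 = cr2.reshape(var_r.shape), fr2.reshape(var_r.shape)
            tf, tr = cf2.sum(axis=1), cr2.sum(axis=1)
            one = (tf + tr) == 1  # rescued iff a single hit over both strands
            fsel = one & (tf == 1)
            rsel = one & (tr == 1)
            wf = np.argmax(cf2 > 0, axis=1)
            wr = np.argmax(cr2 > 0, axis=1)
            pos[miss[fsel]] = ff2[fsel, wf[fsel]]
            pos[miss[rsel]] = fr2[rsel, wr[rsel]]
            strand[miss[rsel]] = 1
            mapq[miss[one]] = 60

    # full-length verification
    placed = np.flatnonzero(pos >= 0)
    if placed.size:
        off = np.arange(rl, dtype=np.int64)
        # clamp gather to valid range; out-of-range counts as mismatch
        gpos = pos[placed][:, None] + off[None, :]
        in_range = gpos < genome.total_length
        gseq = genome.sequence[np.clip(gpos, 0, genome.total_length - 1)]
        fwd_reads = mat[placed]
        rev_reads = rc_mat[placed]
        read_oriented = np.where(strand[placed][:, None].astype(bool), rev_reads, fwd_reads)
        nm_arr = ((gseq != read_oriented) | ~in_range | (gseq == dna.SENTINEL)).sum(axis=1)
        bad = nm_arr > MAX_NM
        nm_full = np.zeros(n, dtype=np.int32)
        nm_full[placed] = nm_arr.astype(np.int32)
        drop = placed[bad]
        pos[drop] = -1
        mapq[drop] = 0
    else:
        nm_full = np.zeros(n, dtype=np.int32)

    # ambiguous reads: leave unmapped with MAPQ 0 (position not trusted)
    pos[ambiguous] = -1
    mapq[ambiguous] = 0

    npairs = reads.n_pairs
    p1, p2 = pos[:npairs], pos[npairs:]
    s1, s2 = strand[:npairs], strand[npairs:]
    both = (p1 >= 0) & (p2 >= 0)
    left = np.minimum(p1, p2)
    right = np.maximum(p1 + rl, p2 + rl)
    span = right - left
    # inward orientation: the leftmost read forward, the rightmost reverse
    left_is_1 = p1 <= p2
    left_strand = np.where(left_is_1, s1, s2)
    right_strand = np.where(left_is_1, s2, s1)
    inward = (left_strand == 0) & (right_strand == 1)
    same_chrom = np.zeros(npairs, dtype=bool)
    ends = index.genome.ends
    c1 = np.searchsorted(ends, p1, side="right")
    c2 = np.searchsorted(ends, p2, side="right")
    same_chrom[both] = c1[both] == c2[both]
    lo_span = insert_mean - PROPER_SD_RANGE * insert_sd
    hi_span = insert_mean + PROPER_SD_RANGE * insert_sd
    proper = both & same_chrom & inward & (span >= lo_span) & (span <= hi_span)
    tlen = np.where(proper, span, 0)
    return MappingResult(
        pos=pos,
        strand=strand,
        mapq=mapq,
        nm=nm_full,
        n_pairs=npairs,
        read_len=rl,
        sample_label=reads.sample_label,
        proper=proper,
        tlen=tlen,
    )


def write_sam(result: MappingResult, reads: ReadSet, genome: GlobalGenome, path):
    """Emit the mapping as plain SAM (flags, RNEXT/PNEXT/TLEN per the SAM standard)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": int(genome.ends[i] - genome.starts[i])}
            for i, name in enumerate(genome.names)
        ],
    }
    rl = result.read_len
    npairs = result.n_pairs
    with pysam.AlignmentFile(str(path), "wh", header=dict(header)) as out:
        for i in range(2 * npairs):
            pair = i % npairs
            is_r2 = i >= npairs
            mate = pair if is_r2 else pair + npairs
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{reads.sample_label}_{pair}"
            mat = reads.r2 if is_r2 else reads.r1
            seq = dna.decode(mat[pair])
            flag = 0x1 | (0x80 if is_r2 else 0x40)
            mapped = result.pos[i] >= 0
            mate_mapped = result.pos[mate] >= 0
            if not mapped:
                flag |= 0x4
            if not mate_mapped:
                flag |= 0x8
            if mapped and result.strand[i]:
                flag |= 0x10
            if mate_mapped and result.strand[mate]:
                flag |= 0x20
            if result.proper[pair]:
                flag |= 0x2
            a.flag = flag
            if mapped:
                ci = genome.chrom_index(int(result.pos[i]))
                a.reference_id = ci
                a.reference_start = int(result.pos[i] - genome.starts[ci])
                a.mapping_quality = int(result.mapq[i])
                a.cigarstring = f"{rl}M"
                a.set_tag("NM", int(result.nm[i]))
            if result.strand[i] and mapped:
                # SEQ is stored on the forward reference strand
                seq = dna.revcomp_str(seq)
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            if mate_mapped:
                cm = genome.chrom_index(int(result.pos[mate]))
                a.next_reference_id = cm
                a.next_reference_start = int(result.pos[mate] - genome.starts[cm])
            if result.proper[pair]:
                sign = 1 if result.pos[i] <= result.pos[mate] else -1
                a.template_length = sign * int(result.tlen[pair])
            out.write(a)


def discordant_points_from_mapping(
    result: MappingResult, genome: GlobalGenome, mapq_min: int = 30
):
    """Array fast path: MAPQ-filtered discordant pairs as DiscordantPoints."""
    from .discordant import DiscordantPoint, OrientationClass

    npairs = result.n_pairs
    rl = result.read_len
    p1, p2 = result.pos[:npairs], result.pos[npairs:]
    s1, s2 = result.strand[:npairs], result.strand[npairs:]
    q1, q2 = result.mapq[:npairs], result.mapq[npairs:]
    keep = (
        (p1 >= 0)
        & (p2 >= 0)
        & ~result.proper
        & (np.minimum(q1, q2) >= mapq_min)
    )
    idx = np.flatnonzero(keep)
    g1 = p1[idx] + np.where(s1[idx] == 1, rl - 1, 0)
    g2 = p2[idx] + np.where(s2[idx] == 1, rl - 1, 0)
    out = []
    for a, b, sa, sb in zip(g1, g2, s1[idx], s2[idx]):
        if a == b:
            continue  # degenerate pair: no junction geometry
        if a <= b:
            x, y, sx, sy = int(a), int(b), sa, sb
        else:
            x, y, sx, sy = int(b), int(a), sb, sa
        out.append(
            DiscordantPoint(
                x=x,
                y=y,
                orientation_class=OrientationClass.from_strands(
                    "-" if sx else "+", "-" if sy else "+"
                ),
                sample_label=result.sample_label,
            )
        )
    return out
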