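"""Discordant read pairs as points in G x G, their orientation classes,
2D clustering, and somatic/germline labelling of clusters.

A read pair violating the paired-end mapping condition (inward orientation,
separation about one insert length) is mapped to a point (x, y), x < y, where
x and y are the global coordinates of the first (5') bases of the two reads.
The pair's strand combination fixes one of four orientation classes, which
determines on which side of each read the junction must lie:

* a forward-strand read precedes its junction (breakpoint to the right),
* a reverse-strand read follows it (breakpoint to the left).

After the x < y swap the four strand combinations correspond to the four
orderings of pair coordinates around the junction (x0, y0):

=============  ==========================  =======================
strands (x,y)  coordinate ordering          typical rearrangement
=============  ==========================  =======================
(+, -)         x_i < x0 < y0 < y_i          deletion-like
(-, +)         x0 < x_i < y_i < y0          tandem-duplication-like
(+, +)         x_i < x0,  y_i < y0          inversion (head side)
(-, -)         x0 < x_i,  y0 < y_i          inversion (tail side)
=============  ==========================  =======================
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_index import GlobalGenome

logger = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 30
DEFAULT_TUMOR_RATE = 0.90
DEFAULT_MIN_CLUSTER_SUPPORT = 3

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class OrientationClass(enum.Enum):
    """Junction geometry inferred from the strand pair after the x<y swap."""

    DELETION_LIKE = "+-"
    DUPLICATION_LIKE = "-+"
    INVERSION_HEAD = "++"
    INVERSION_TAIL = "--"

    @classmethod
    def from_strands(cls, strand_x: str, strand_y: str) -> "OrientationClass":
        return cls(strand_x + strand_y)

    @property
    def strand_x(self) -> str:
        return self.value[0]

    @property
    def strand_y(self) -> str:
        return self.value[1]

    @property
    def diagonal_spread(self) -> bool:
        """True when associated pairs spread along the main diagonal (the
        deletion/duplication-like classes); inversion classes spread along
        the anti-diagonal."""
        return self.value in ("+-", "-+")


@dataclass(frozen=True)
class AlignedPairRecord:
    """One mapped read pair (both ends primary and mapped)."""

    chrom1: str
    pos1: int  # 0-based leftmost aligned base
    strand1: str
    mapq1: int
    len1: int
    chrom2: str
    pos2: int
    strand2: str
    mapq2: int
    len2: int
    flag_proper: bool
    sample_label: str = "tumor"
    qname: str = ""


@dataclass(frozen=True)
class DiscordantPoint:
    x: int
    y: int
    orientation_class: OrientationClass
    sample_label: str

    def __post_init__(self):
        if not self.x < self.y:
            raise ValueError("discordant point requires x < y")


@dataclass
class Cluster:
    points: list[DiscordantPoint]
    orientation_class: OrientationClass
    somatic_flag: bool | None = field(default=None)

    @property
    def n_tumor(self) -> int:
        return sum(1 for p in self.points if p.sample_label == "tumor")

    @property
    def n_normal(self) -> int:
        return len(self.points) - self.n_tumor

    @property
    def tumor_fraction(self) -> float:
        return self.n_tumor / len(self.points)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        xs = [p.x for p in self.points]
        ys = [p.y for p in self.points]
        return min(xs), max(xs), min(ys), max(ys)

    def __len__(self) -> int:
        return len(self.points)


def extract_discordant(records, mapq_min: int = DEFAULT_MAPQ_MIN, sample_label="tumor"):
    """Filter a SAM stream down to usable discordant pairs.

    ``records`` is an iterable of :class:`pysam.AlignedSegment` (or a path /
    pysam.AlignmentFile).  Keeps primary records of pairs with both ends
    mapped, proper-pair flag unset and min(MAPQ) >= mapq_min; everything
    else is skipped with a counter.  Returns (pairs, n_skipped).
    """
    import pysam

    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        with pysam.AlignmentFile(str(records), check_sq=False) as fh:
            return extract_discordant(list(fh), mapq_min, sample_label)

    pending: dict[str, object] = {}
    pairs: list[AlignedPairRecord] = []
    n_skipped = 0
    for rec in records:
        if (
            rec.is_secondary
            or rec.is_supplementary
            or not rec.is_paired
            or rec.is_unmapped
            or rec.mate_is_unmapped
        ):
            n_skipped += 1
            continue
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
            continue
        r1, r2 = (mate, rec)
        if r1.is_proper_pair or min(r1.mapping_quality, r2.mapping_quality) < mapq_min:
            n_skipped += 2
            continue
        pairs.append(
            AlignedPairRecord(
                chrom1=r1.reference_name,
                pos1=r1.reference_start,
                strand1="-" if r1.is_reverse else "+",
                mapq1=r1.mapping_quality,
                len1=r1.query_length or r1.infer_query_length() or 0,
                chrom2=r2.reference_name,
                pos2=r2.reference_start,
                strand2="-" if r2.is_reverse else "+",
                mapq2=r2.mapping_quality,
                len2=r2.query_length or r2.infer_query_length() or 0,
                flag_proper=False,
                sample_label=sample_label,
                qname=r1.query_name,
            )
        )
    n_skipped += len(pending)
    if n_skipped:
        logger.info("extract_discordant: skipped %d records", n_skipped)
    return pairs, n_skipped


def pair_to_point(rec: AlignedPairRecord, genome: GlobalGenome) -> DiscordantPoint:
    """Map a discordant pair to its point in G x G with orientation class."""

    def five_prime(chrom, pos, strand, rlen):
        p = pos if strand == "+" else pos + rlen - 1
        return genome.chrom_to_global(chrom, p)

    g1 = five_prime(rec.chrom1, rec.pos1, rec.strand1, rec.len1)
    g2 = five_prime(rec.chrom2, rec.pos2, rec.strand2, rec.len2)
    if g1 <= g2:
        x, y, sx, sy = g1, g2, rec.strand1, rec.strand2
    else:
        x, y, sx, sy = g2, g1, rec.strand2, rec.strand1
    return DiscordantPoint(
        x=x,
        y=y,
        orientation_class=OrientationClass.from_strands(sx, sy),
        sample_label=rec.sample_label,
    )


def points_from_pairs(pairs, genome: GlobalGenome) -> list[DiscordantPoint]:
    """pair_to_point over a batch, skipping degenerate pairs (x == y)."""
    out = []
    for rec in pairs:
        try:
            out.append(pair_to_point(rec, genome))
        except ValueError:
            continue
    return out


def _refine_axis(xs: np.ndarray, labels: np.ndarray, insert_len: int) -> np.ndarray:
    """Split every current group at sorted-coordinate gaps >= insert_len."""
    new_labels = np.empty_like(labels)
    next_label = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        order = idx[np.argsort(xs[idx], kind="stable")]
        splits = np.flatnonzero(np.diff(xs[order]) >= insert_len)
        bounds = np.concatenate(([0], splits + 1, [order.size]))
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            new_labels[order[b0:b1]] = next_label
            next_label += 1
    return new_labels


def cluster_points(
    points: list[DiscordantPoint],
    insert_len: int,
    min_support: int = 1,
    max_iter: int = 50,
) -> list[Cluster]:
    """Alternating sort-and-partition clustering, iterated to a fixed point.

    Points are grouped per orientation class; within a class the x axis and
    then the y axis are repeatedly partitioned at gaps of at least the insert
    length until the partition stops changing.  Clusters with fewer than
    ``min_support`` points are discarded.
    """
    clusters: list[Cluster] = []
    by_class: dict[OrientationClass, list[DiscordantPoint]] = {}
    for p in points:
        by_class.setdefault(p.orientation_class, []).append(p)
    for oc, pts in by_class.items():
        xs = np.array([p.x for p in pts], dtype=np.int64)
        ys = np.array([p.y for p in pts], dtype=np.int64)
        labels = np.zeros(len(pts), dtype=np.int64)
        def canonical(lab):
            # first-occurrence renumbering so partitions compare by shape
            seen: dict[int, int] = {}
            return np.array([seen.setdefault(int(v), len(seen)) for v in lab])

        for _ in range(max_iter):
            before = canonical(labels)
            labels = _refine_axis(xs, labels, insert_len)
            labels = _refine_axis(ys, labels, insert_len)
            if np.array_equal(before, canonical(labels)):
                break
        for lab in np.unique(labels):
            members = [pts[i] for i in np.flatnonzero(labels == lab)]
            if len(members) >= min_support:
                clusters.append(Cluster(points=members, orientation_class=oc))
    clusters.sort(key=lambda c: (min(p.x for p in c.points), min(p.y for p in c.points)))
    return clusters


def label_somatic(cluster: Cluster, tumor_rate: float = DEFAULT_TUMOR_RATE) -> str:
    """Cluster-level somatic call: somatic iff tumor fraction >= tumor_rate."""
    somatic = cluster.tumor_fraction >= tumor_rate
    cluster.somatic_flag = somatic
    return "somatic" if somatic else "germline"
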