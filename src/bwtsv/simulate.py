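"""Fully synthetic, ground-truthed inputs for the breakpoint pipeline.

The generator reproduces the evaluation protocol the package is designed
around: a random reference genome, a matched "normal" genome carrying random
SNPs at 0.1%, and a "cancer" genome derived from the normal one by
non-overlapping rearrangements of six types (insertion, deletion, inversion,
tandem duplication, intra- and inter-chromosomal translocation) with event
lengths uniform over a configured range.  Paired-end reads of 90 bp with
insert lengths N(760, 45) are drawn uniformly over each genome, and tumor
samples of arbitrary purity are produced by mixing cancer-genome and
normal-genome read pairs.

Every novel adjacency created by an event is recorded in a TruthSet with
reference coordinates, so detection output can be scored exactly.  Junction
counts per event follow the convention: insertion 2, deletion 1, inversion 2,
tandem duplication 1, intra-/inter-chromosomal translocation 3 (cut-and-paste:
one junction at the excision site, two at the integration site).

Insertions copy a segment of the normal genome to the insertion point
(copy-and-paste).  Inserted material therefore maps to its source locus,
which is what makes insertion junctions visible to a discordant-pair
predictor at all: fully novel sequence longer than (insert length - 2 x read
length) can never produce a pair with both ends mapped, and its junctions
would be undetectable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna
from .discordant import OrientationClass
from .genome_index import GlobalGenome

EVENT_TYPES = (
    "insertion",
    "deletion",
    "inversion",
    "tandem_duplication",
    "intra_translocation",
    "inter_translocation",
)

JUNCTIONS_PER_EVENT = {
    "insertion": 2,
    "deletion": 1,
    "inversion": 2,
    "tandem_duplication": 1,
    "intra_translocation": 3,
    "inter_translocation": 3,
}


@dataclass(frozen=True)
class RearrangementSpec:
    """Event counts and the common event-length range (bp)."""

    events_per_type: int = 40
    length_range: tuple[int, int] = (300, 30_000)
    min_gap: int = 3_000  # between reserved intervals and to chromosome ends
    max_tries: int = 10_000


@dataclass(frozen=True)
class ReadSimParams:
    read_len: int = 90
    insert_mean: float = 760.0
    insert_sd: float = 45.0
    coverage: float = 40.0
    error_rate: float = 0.001

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert mean must exceed twice the read length")


@dataclass(frozen=True)
class Junction:
    """One novel adjacency, in reference coordinates (global, x < y)."""

    x: int
    y: int
    orientation_class: OrientationClass
    event_type: str
    event_id: int


@dataclass
class TruthSet:
    junctions: list[Junction]

    def __len__(self):
        return len(self.junctions)

    def match_calls(self, calls, tol: int = 10):
        """Greedy one-to-one matching of calls to truth junctions.

        A call matches a junction iff both coordinates are within tol.
        Returns (matched_junction_indices, matched_call_indices)."""
        matched_j: set[int] = set()
        matched_c: set[int] = set()
        for ci, call in enumerate(calls):
            for ji, j in enumerate(self.junctions):
                if ji in matched_j:
                    continue
                if abs(call.x0 - j.x) <= tol and abs(call.y0 - j.y) <= tol:
                    matched_j.add(ji)
                    matched_c.add(ci)
                    break
        return matched_j, matched_c


# -- genome ------------------------------------------------------------


def make_genome(n_chrom: int, lengths, seed: int) -> list[tuple[str, np.ndarray]]:
    """Random i.i.d. uniform ACGT chromosomes, reproducible from the seed."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_chrom):
        seq = rng.integers(1, 5, size=int(lengths[i]), dtype=np.uint8)
        out.append((f"chr{i + 1}", seq))
    return out


def add_snps(genome, rate: float, seed: int):
    """Independent per-base substitutions to a uniformly chosen other base.

    Returns (new genome, list of (chrom_name, positions array))."""
    if not 0 <= rate <= 0.05:
        raise ValueError("SNP rate outside [0, 0.05]")
    rng = np.random.default_rng(seed)
    out, logs = [], []
    for name, seq in genome:
        new = seq.copy()
        pos = np.flatnonzero(rng.random(seq.size) < rate)
        if pos.size:
            # shift by 1..3 in 0-based base space: always a different base
            shift = rng.integers(1, 4, size=pos.size, dtype=np.uint8)
            new[pos] = (new[pos] - 1 + shift) % 4 + 1
        out.append((name, new))
        logs.append((name, pos))
    return out, logs


# -- rearrangement planning -------------------------------------------


@dataclass
class _Event:
    kind: str
    event_id: int
    chrom: int  # affected (source) chromosome index
    start: int = 0
    end: int = 0
    target_chrom: int = -1
    target_pos: int = -1
    source: tuple[int, int, int] = (-1, -1, -1)  # insertion copy: chrom, u, v


def _flank_strand(direction: str) -> str:
    # 'L' flank (reference continues up to the coordinate) faces its junction
    # rightward, so reads on it are forward-stranded; 'R' flank the opposite.
    return "+" if direction == "L" else "-"


def _junction(flank1, flank2, event_type, event_id, offsets) -> Junction:
    (c1, p1, d1), (c2, p2, d2) = flank1, flank2
    g1 = offsets[c1] + p1
    g2 = offsets[c2] + p2
    (gx, dx_), (gy, dy_) = sorted([(g1, d1), (g2, d2)])
    oc = OrientationClass.from_strands(_flank_strand(dx_), _flank_strand(dy_))
    return Junction(gx, gy, oc, event_type, event_id)


def plan_rearrangements(
    genome, spec: RearrangementSpec, seed: int
) -> tuple[list[_Event], TruthSet]:
    """Place non-overlapping events and derive their truth junctions."""
    rng = np.random.default_rng(seed)
    lengths = [seq.size for _, seq in genome]
    n_chrom = len(lengths)
    if spec.events_per_type > 0 and n_chrom < 2:
        raise ValueError("inter-chromosomal translocations need >= 2 chromosomes")
    reserved: list[list[tuple[int, int]]] = [[] for _ in range(n_chrom)]

    def reserve(ci, lo, hi) -> bool:
        lo_m, hi_m = lo - spec.min_gap, hi + spec.min_gap
        if lo_m < spec.min_gap or hi_m > lengths[ci] - spec.min_gap:
            return False
        for a, b in reserved[ci]:
            if lo_m < b and a < hi_m:
                return False
        reserved[ci].append((lo_m, hi_m))
        return True

    def sample_interval(ci=None):
        for _ in range(spec.max_tries):
            c = int(rng.integers(0, n_chrom)) if ci is None else ci
            ln = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            if lengths[c] < ln + 4 * spec.min_gap:
                continue
            s = int(rng.integers(spec.min_gap, lengths[c] - ln - spec.min_gap))
            if reserve(c, s, s + ln):
                return c, s, s + ln
        raise RuntimeError("could not place event without overlap")

    def sample_point(exclude_chrom=None, require_chrom=None):
        for _ in range(spec.max_tries):
            if require_chrom is not None:
                c = require_chrom
            else:
                c = int(rng.integers(0, n_chrom))
                if exclude_chrom is not None and c == exclude_chrom and n_chrom > 1:
                    continue
            p = int(rng.integers(spec.min_gap, lengths[c] - spec.min_gap))
            if reserve(c, p, p + 1):
                return c, p
        raise RuntimeError("could not place insertion point")

    offsets = np.zeros(n_chrom, dtype=np.int64)
    gg = GlobalGenome([n for n, _ in genome], [s for _, s in genome])
    for i, (name, _) in enumerate(genome):
        offsets[i] = gg.offsets[name]

    events: list[_Event] = []
    junctions: list[Junction] = []
    eid = 0
    for kind in EVENT_TYPES:
        for _ in range(spec.events_per_type):
            if kind == "deletion":
                c, s, t = sample_interval()
                events.append(_Event(kind, eid, c, s, t))
                junctions.append(
                    _junction((c, s - 1, "L"), (c, t, "R"), kind, eid, offsets)
                )
            elif kind == "inversion":
                c, s, t = sample_interval()
                events.append(_Event(kind, eid, c, s, t))
                junctions.append(
                    _junction((c, s - 1, "L"), (c, t - 1, "L"), kind, eid, offsets)
                )
                junctions.append(
                    _junction((c, s, "R"), (c, t, "R"), kind, eid, offsets)
                )
            elif kind == "tandem_duplication":
                c, s, t = sample_interval()
                events.append(_Event(kind, eid, c, s, t))
                junctions.append(
                    _junction((c, t - 1, "L"), (c, s, "R"), kind, eid, offsets)
                )
            elif kind == "insertion":
                cs, u, v = sample_interval()
                ct, p = sample_point()
                events.append(
                    _Event(kind, eid, ct, target_chrom=ct, target_pos=p, source=(cs, u, v))
                )
                junctions.append(
                    _junction((ct, p - 1, "L"), (cs, u, "R"), kind, eid, offsets)
                )
                junctions.append(
                    _junction((cs, v - 1, "L"), (ct, p, "R"), kind, eid, offsets)
                )
            elif kind == "intra_translocation":
                c, s, t = sample_interval()
                _, p = sample_point(require_chrom=c)
                events.append(_Event(kind, eid, c, s, t, target_chrom=c, target_pos=p))
                junctions.append(
                    _junction((c, s - 1, "L"), (c, t, "R"), kind, eid, offsets)
                )
                junctions.append(
                    _junction((c, p - 1, "L"), (c, s, "R"), kind, eid, offsets)
                )
                junctions.append(
                    _junction((c, t - 1, "L"), (c, p, "R"), kind, eid, offsets)
                )
            elif kind == "inter_translocation":
                c, s, t = sample_interval()
                ct, p = sample_point(exclude_chrom=c)
                events.append(_Event(kind, eid, c, s, t, target_chrom=ct, target_pos=p))
                junctions.append(
                    _junction((c, s - 1, "L"), (c, t, "R"), kind, eid, offsets)
                )
                junctions.append(
                    _junction((ct, p - 1, "L"), (c, s, "R"), kind, eid, offsets)
                )
                junctions.append(
                    _junction((c, t - 1, "L"), (ct, p, "R"), kind, eid, offsets)
                )
            eid += 1
    return events, TruthSet(junctions)


def apply_rearrangements(genome, events: list[_Event]):
    """Assemble the cancer genome from the planned events (one pass)."""
    n_chrom = len(genome)
    # per chromosome: interval edits and point insertions
    removals: list[list[tuple[int, int, str, int]]] = [[] for _ in range(n_chrom)]
    insertions: list[list[tuple[int, int, int, int, str]]] = [[] for _ in range(n_chrom)]
    # insertion tuple: (pos, src_chrom, u, v, strand)
    for ev in events:
        if ev.kind == "deletion":
            removals[ev.chrom].append((ev.start, ev.end, "delete", ev.event_id))
        elif ev.kind == "inversion":
            removals[ev.chrom].append((ev.start, ev.end, "invert", ev.event_id))
        elif ev.kind == "tandem_duplication":
            removals[ev.chrom].append((ev.start, ev.end, "tandem", ev.event_id))
        elif ev.kind == "insertion":
            cs, u, v = ev.source
            insertions[ev.target_chrom].append((ev.target_pos, cs, u, v, "+"))
        elif ev.kind in ("intra_translocation", "inter_translocation"):
            removals[ev.chrom].append((ev.start, ev.end, "delete", ev.event_id))
            insertions[ev.target_chrom].append(
                (ev.target_pos, ev.chrom, ev.start, ev.end, "+")
            )
    out = []
    for ci, (name, seq) in enumerate(genome):
        marks = [(s, t, op) for s, t, op, _ in removals[ci]]
        marks += [(p, p, ("insert", cs, u, v, strand)) for p, cs, u, v, strand in insertions[ci]]
        marks.sort(key=lambda m: (m[0], m[1]))
        pieces: list[np.ndarray] = []
        cur = 0
        for s, t, op in marks:
            pieces.append(seq[cur:s])
            if op == "delete":
                pass
            elif op == "invert":
                pieces.append(dna.revcomp(seq[s:t]))
            elif op == "tandem":
                pieces.append(seq[s:t])
                pieces.append(seq[s:t])
            else:  # point insertion
                _, cs, u, v, strand = op
                frag = genome[cs][1][u:v]
                pieces.append(frag if strand == "+" else dna.revcomp(frag))
            cur = t
        pieces.append(seq[cur:])
        out.append((name, np.concatenate(pieces)))
    return out


def make_cancer_genome(genome, spec: RearrangementSpec, seed: int):
    """Plan + apply; returns (cancer genome, TruthSet)."""
    events, truth = plan_rearrangements(genome, spec, seed)
    return apply_rearrangements(genome, events), truth


# -- reads -------------------------------------------------------------


@dataclass
class ReadSet:
    """Paired reads as two (n_pairs, read_len) uint8 matrices (codes 1..4).

    r1 is the fragment's left end read on the forward strand; r2 the right
    end read on the reverse strand (stored 5'->3' as sequenced)."""

    r1: np.ndarray
    r2: np.ndarray
    sample_label: str = "tumor"

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    @property
    def read_len(self) -> int:
        return self.r1.shape[1]

    def subset(self, idx) -> "ReadSet":
        return ReadSet(self.r1[idx], self.r2[idx], self.sample_label)

    def reads_as_strings(self):
        for mat in (self.r1, self.r2):
            for row in mat:
                yield dna.decode(row)

    def to_fastq(self, path1, path2, prefix="rd"):
        qual = "I" * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                f1.write(f"@{prefix}{i}/1\n{dna.decode(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@{prefix}{i}/2\n{dna.decode(self.r2[i])}\n+\n{qual}\n")


def simulate_reads(genome, params: ReadSimParams, seed: int, sample_label="tumor") -> ReadSet:
    """Uniform fragment starts, Gaussian insert lengths, inward 90-bp ends."""
    rng = np.random.default_rng(seed)
    lengths = np.array([seq.size for _, seq in genome], dtype=np.int64)
    starts_of = np.concatenate(([0], np.cumsum(lengths)))
    flat = np.concatenate([seq for _, seq in genome])
    total = int(lengths.sum())
    rl = params.read_len
    n_pairs = int(round(params.coverage * total / (2 * rl)))
    frag_start = np.empty(n_pairs, dtype=np.int64)
    frag_len = np.empty(n_pairs, dtype=np.int64)
    need = np.arange(n_pairs)
    while need.size:
        ls = np.maximum(
            np.round(rng.normal(params.insert_mean, params.insert_sd, size=need.size)),
            2 * rl,
        ).astype(np.int64)
        ss = rng.integers(0, total - ls + 1, dtype=np.int64)
        # fragment must not cross a chromosome boundary
        ci = np.searchsorted(starts_of, ss, side="right") - 1
        ok = ss + ls <= starts_of[ci + 1]
        frag_start[need[ok]] = ss[ok]
        frag_len[need[ok]] = ls[ok]
        need = need[~ok]
    off = np.arange(rl, dtype=np.int64)
    r1 = flat[frag_start[:, None] + off[None, :]]
    r2_fwd = flat[(frag_start + frag_len - rl)[:, None] + off[None, :]]
    r2 = dna._COMPLEMENT[r2_fwd[:, ::-1]]
    for mat in (r1, r2):
        if params.error_rate > 0:
            mask = rng.random(mat.shape) < params.error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] - 1 + shift) % 4 + 1
    return ReadSet(r1=r1, r2=r2, sample_label=sample_label)


def mix_purity(tumor: ReadSet, normal_pool: ReadSet, purity: float, seed: int) -> ReadSet:
    """Tumor sample of given purity: an exact purity split of pair counts,
    pairs chosen without replacement from each pool."""
    if not 0 <= purity <= 1:
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = tumor.n_pairs
    k = int(round(purity * n))
    if k > tumor.n_pairs or n - k > normal_pool.n_pairs:
        raise ValueError("insufficient source reads for requested mix")
    ti = rng.choice(tumor.n_pairs, size=k, replace=False)
    ni = rng.choice(normal_pool.n_pairs, size=n - k, replace=False)
    return ReadSet(
        r1=np.concatenate([tumor.r1[ti], normal_pool.r1[ni]]),
        r2=np.concatenate([tumor.r2[ti], normal_pool.r2[ni]]),
        sample_label=tumor.sample_label,
    )


def write_fasta(genome, path, width=70):
    with open(path, "w") as fh:
        for name, seq in genome:
            fh.write(f">{name}\n")
            s = dna.decode(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
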