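"""Precise breakpoint detection by scanning predicted regions against the
read dictionary.

For each predicted region the reference around one projection (region A) is
scanned right to left with MLU-sized anchor queries.  Read fragments exactly
matching a query are pulled from the BWT dictionary and all their leftward
extensions (up to 20 bp) are enumerated.  Each extension is aligned against
the local reference context and against the partner projection (region B,
both strands), giving multivalued normalised edit-distance functions of the
scan position.  Away from a junction the extensions track the reference
(distance-to-A ~ 0, distance-to-B large); once the anchor crosses onto a
junction's downstream flank, a supported branch appears whose non-reference
prefix aligns to region B — the scan position where that branch departs from
the reference band is the breakpoint on the scanned side, and the prefix's
best alignment position in B is its partner.  The same analysis is repeated
with regions A and B swapped for confirmation, and on the matched normal
sample: a breakpoint is somatic when only the tumor shows the branch change.

A note on scan orientation: a junction flank that continues rightward on the
reference ('-' strand class ends) is scanned in forward orientation; a flank
retained to the left of its breakpoint ('+' ends) is scanned on the reverse
complement, which turns its leftward continuation into the rightward
direction the anchor-and-extend machinery requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna
from .edit import min_edit_distance_end
from .genome_index import GenomeIndex
from .read_index import ReadIndex
from .region_prediction import BreakpointRegion

CTX_SLACK = 4  # extra reference context given to the band alignment


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the region scan.

    alpha: anchor slack over the MLU (bp); ext_len: leftward extension depth;
    min_support: reads required on a branch before it can call a breakpoint;
    low_thresh / high_thresh: normalised edit distances read as "matches" /
    "does not match"; margin: scan range beyond the projection (defaults to
    one insert length); min_anchor: minimum partner-aligned prefix (bp);
    partner_margin: partner window slack beyond the projection (bp);
    max_query: anchors longer than this are skipped as repeat-ambiguous.
    """

    alpha: int = 3
    ext_len: int = 20
    min_support: int = 2
    low_thresh: float = 0.1
    high_thresh: float = 0.3
    margin: int = 760
    min_anchor: int = 10
    partner_margin: int = 100
    max_query: int = 60

    def __post_init__(self):
        if not 0 <= self.low_thresh < self.high_thresh <= 1:
            raise ValueError("need 0 <= low_thresh < high_thresh <= 1")
        if self.ext_len < 10:
            raise ValueError("ext_len must be >= 10")


@dataclass(slots=True)
class ProfileEntry:
    """One extension branch at one scan position (multivalued per x)."""

    x: int  # anchor, forward-strand global coordinate
    ext: str  # extension, in scan orientation
    support: int
    dist_a: float  # normalised distance to the scan-side reference
    dist_b: float  # normalised distance to the partner region (best strand)


@dataclass(slots=True)
class BranchCandidate:
    """A supported non-reference branch whose prefix aligns to the partner.

    scan_label / partner_strand record the flank orientations the evidence
    implies: the scanned flank is '+' (left flank) when scanning the reverse
    complement, '-' otherwise; the partner flank is '+' when the prefix
    aligned to the partner's forward strand.  Together they fix the
    junction's orientation class independently of the region's."""

    scan_coord: int  # junction base on the scanned side (forward coords)
    partner_coord: int  # junction base on the partner side (forward coords)
    partner_strand: str
    scan_label: str
    support: int
    anchor_len: int
    scan_x: int
    dist_prefix: float


@dataclass
class EditProfile:
    sample_label: str
    side: str  # 'A' or 'B'
    scan_strand: str  # '+' forward scan, '-' reverse-complement scan
    entries: list[ProfileEntry] = field(default_factory=list)
    candidates: list[BranchCandidate] = field(default_factory=list)
    n_positions: int = 0
    n_empty: int = 0


@dataclass
class Detection:
    scan_coord: int
    partner_coord: int
    partner_strand: str
    scan_label: str
    support: int
    side: str

    def labeled_pair(self):
        """((x0, label_x), (y0, label_y)) sorted by coordinate."""
        return tuple(
            sorted(
                [
                    (self.scan_coord, self.scan_label),
                    (self.partner_coord, self.partner_strand),
                ]
            )
        )


@dataclass
class BreakpointCall:
    x0: int
    y0: int
    orientation_class: object
    somatic: bool | None
    support: int
    confirmed_by_swap: bool
    region_id: int = -1
    cluster_somatic: bool | None = None

    def as_tuple(self):
        return (self.x0, self.y0)


def write_profile_tsv(profile: EditProfile, fh) -> None:
    """Dump a multivalued profile as TSV (x, dist_a, dist_b, support, ext)
    for plotting edit-distance functions across a region."""
    fh.write("x\tdist_a\tdist_b\tsupport\text\n")
    for e in profile.entries:
        fh.write(f"{e.x}\t{e.dist_a:.3f}\t{e.dist_b:.3f}\t{e.support}\t{e.ext}\n")


def min_edit_distance(pattern, text) -> int:
    """Semi-global minimum edit distance (re-exported from :mod:`edit`)."""
    from .edit import min_edit_distance as _m

    return _m(pattern, text)


def _suffix_match_len(ext: np.ndarray, ctx: np.ndarray) -> int:
    """Length of the maximal common suffix of extension and reference context."""
    k = 0
    while k < ext.size and k < ctx.size and ext[ext.size - 1 - k] == ctx[ctx.size - 1 - k]:
        k += 1
    return k


def scan_junction_side(
    gidx: GenomeIndex,
    ridx: ReadIndex,
    region: BreakpointRegion,
    side: str,
    params: ScanParams,
) -> EditProfile:
    """Scan one projection of a region; fills profile entries and candidates."""
    genome = gidx.genome
    oc = region.orientation_class
    if side == "A":
        lo, hi = region.projection_a
        plo, phi = region.projection_b
        strand_label = oc.strand_x
    else:
        lo, hi = region.projection_b
        plo, phi = region.projection_a
        strand_label = oc.strand_y
    rc_scan = strand_label == "+"
    profile = EditProfile(
        sample_label=ridx.sample_label, side=side, scan_strand="-" if rc_scan else "+"
    )

    # clamp the scan range to the projection's chromosome
    mid = (lo + hi) // 2
    ci = genome.chrom_index(min(max(mid, 0), genome.total_length - 1))
    if ci < 0:
        return profile
    c_lo, c_hi = int(genome.starts[ci]), int(genome.ends[ci])
    if hi - lo > 4000:  # cap pathologically wide projections around the peak
        peak = region.peak_xy[0] if side == "A" else region.peak_xy[1]
        lo, hi = peak - 2000, peak + 2000
    x_lo = max(lo - params.margin, c_lo)
    x_hi = min(hi + params.margin, c_hi)
    if x_lo >= x_hi:
        return profile

    # partner window (forward strand + reverse complement)
    pmid = (plo + phi) // 2
    pci = genome.chrom_index(min(max(pmid, 0), genome.total_length - 1))
    if pci < 0:
        return profile
    ppad = params.ext_len + params.alpha + params.partner_margin
    w0 = max(plo - ppad, int(genome.starts[pci]))
    w1 = min(phi + ppad, int(genome.ends[pci]))
    partner_f = genome.sequence[w0:w1]
    partner_r = dna.revcomp(partner_f)
    if partner_f.size == 0:
        return profile

    e = params.ext_len
    xs = range(x_hi - 1, x_lo - 1, -1) if not rc_scan else range(x_lo, x_hi)
    for x in xs:
        query = gidx.make_window_query(x, params.alpha, "-" if rc_scan else "+")
        if query is None or query.size > params.max_query:
            continue
        profile.n_positions += 1
        exts = ridx.enumerate_left_extensions(query, e)
        if not exts:
            profile.n_empty += 1
            continue
        if rc_scan:
            ctx = dna.revcomp(genome.sequence[x + 1 : min(x + 1 + e + CTX_SLACK, c_hi)])
        else:
            ctx = genome.sequence[max(x - e - CTX_SLACK, c_lo) : x]
        for ext_str, support in exts:
            ext = dna.encode(ext_str)
            if ctx.size:
                da, _ = min_edit_distance_end(ext, ctx)
            else:
                da = ext.size
            dist_a = da / ext.size
            db_f, end_f = min_edit_distance_end(ext, partner_f)
            db_r, end_r = min_edit_distance_end(ext, partner_r)
            dist_b = min(db_f, db_r) / ext.size
            profile.entries.append(
                ProfileEntry(x=x, ext=ext_str, support=support, dist_a=dist_a, dist_b=dist_b)
            )
            if dist_a <= params.high_thresh:
                continue  # still in (or near) the reference band
            k = _suffix_match_len(ext, ctx)
            m = ext.size - k
            if m < params.min_anchor:
                continue
            prefix = ext[:m]
            dp_f, pe_f = min_edit_distance_end(prefix, partner_f)
            dp_r, pe_r = min_edit_distance_end(prefix, partner_r)
            if dp_f <= dp_r:
                dp, strand_used, partner_coord = dp_f, "+", w0 + pe_f - 1
            else:
                dp, strand_used, partner_coord = dp_r, "-", w1 - pe_r
            if dp / m > params.low_thresh:
                continue
            # trade extension length for support: keep the flank suffix plus
            # the minimal partner anchor, and recount reads containing it
            j = max(0, m - params.min_anchor)
            trimmed = np.concatenate([ext[j:], query])
            sup_eff = ridx.count_occurrences(trimmed)
            scan_coord = x + k if rc_scan else x - k
            profile.candidates.append(
                BranchCandidate(
                    scan_coord=int(scan_coord),
                    partner_coord=int(partner_coord),
                    partner_strand=strand_used,
                    scan_label="+" if rc_scan else "-",
                    support=int(max(support, sup_eff)),
                    anchor_len=int(m),
                    scan_x=int(x),
                    dist_prefix=dp / m,
                )
            )
    return profile


def detect_branch_change(profile: EditProfile, params: ScanParams) -> list[Detection]:
    """Aggregate branch candidates into per-junction detections.

    Candidates from successive scan positions that point at the same
    (scan-side, partner-side) coordinates are one junction; the deepest,
    best-supported representative is kept and the support threshold applied.
    """
    groups: dict[tuple[int, int, str], list[BranchCandidate]] = {}
    for c in profile.candidates:
        key = None
        for (sc, pc, st), members in groups.items():
            if abs(c.scan_coord - sc) <= 2 and abs(c.partner_coord - pc) <= 2 and st == c.partner_strand:
                key = (sc, pc, st)
                break
        if key is None:
            key = (c.scan_coord, c.partner_coord, c.partner_strand)
            groups[key] = []
        groups[key].append(c)
    out = []
    for members in groups.values():
        best = max(members, key=lambda c: (c.support, c.anchor_len))
        max_anchor = max(c.anchor_len for c in members)
        # guard against chance partner alignments of shallow prefixes: the
        # branch must reach a deep anchor, and be seen from several scan
        # positions unless its anchor is essentially the full extension
        deep_ok = max_anchor >= min(params.min_anchor + 3, params.ext_len - 2)
        multi_ok = (
            len({c.scan_x for c in members}) >= 2
            or max_anchor >= params.ext_len - 2
        )
        if best.support >= params.min_support and deep_ok and multi_ok:
            out.append(
                Detection(
                    scan_coord=best.scan_coord,
                    partner_coord=best.partner_coord,
                    partner_strand=best.partner_strand,
                    scan_label=best.scan_label,
                    support=best.support,
                    side=profile.side,
                )
            )
    return out


def _same_locus(a: tuple[int, int], b: tuple[int, int], tol: int) -> bool:
    return abs(a[0] - b[0]) <= tol and abs(a[1] - b[1]) <= tol


def confirm_and_type(
    tumor_detections: dict[str, list[Detection]],
    normal_detections: dict[str, list[Detection]],
    region: BreakpointRegion,
    params: ScanParams,
    region_id: int = -1,
    somatic_tol: int = 5,
) -> list[BreakpointCall]:
    """Merge the two scan directions and type calls against the normal sample.

    The call's orientation class is derived from the scan evidence (scanned
    flank orientation plus the partner strand of the aligned prefix); a
    mismatch with the region's class is logged but the evidence wins.  A
    detection from either side yields a call, confirmed when the swapped scan
    found the same junction (both coordinates within 2*alpha).  Somatic
    status: no branch change at the same locus in the normal sample."""
    import logging

    from .discordant import OrientationClass

    logger = logging.getLogger(__name__)
    tol = 2 * params.alpha
    merged: list[dict] = []
    for side in ("A", "B"):
        for d in tumor_detections.get(side, []):
            (x0, lx), (y0, ly) = d.labeled_pair()
            oc = OrientationClass.from_strands(lx, ly)
            if oc != region.orientation_class:
                logger.debug(
                    "region %d: call class %s differs from region class %s",
                    region_id, oc.name, region.orientation_class.name,
                )
            hit = None
            for m in merged:
                if m["class"] == oc and _same_locus(m["pair"], (x0, y0), tol):
                    hit = m
                    break
            if hit is None:
                merged.append(
                    {"pair": (x0, y0), "class": oc, "sides": {side}, "support": d.support}
                )
            else:
                hit["sides"].add(side)
                hit["support"] = max(hit["support"], d.support)
    normal_pairs = [
        d.labeled_pair() for side in ("A", "B") for d in normal_detections.get(side, [])
    ]
    normal_pairs = [(a[0], b[0]) for a, b in normal_pairs]
    calls = []
    for m in merged:
        x0, y0 = m["pair"]
        somatic = not any(_same_locus((x0, y0), np_, somatic_tol) for np_ in normal_pairs)
        calls.append(
            BreakpointCall(
                x0=x0,
                y0=y0,
                orientation_class=m["class"],
                somatic=somatic,
                support=m["support"],
                confirmed_by_swap=len(m["sides"]) == 2,
                region_id=region_id,
                cluster_somatic=region.somatic_flag,
            )
        )
    return calls


def scan_region(
    region: BreakpointRegion,
    ridx_tumor: ReadIndex,
    ridx_normal: ReadIndex | None,
    gidx: GenomeIndex,
    params: ScanParams,
    region_id: int = -1,
    collect_profiles: bool = False,
):
    """Both-direction scan of a region on tumor (and normal) read indexes.

    Returns (calls, profiles) where profiles maps (sample, side) ->
    EditProfile (kept only when collect_profiles is true)."""
    profiles = {}
    tumor_det: dict[str, list[Detection]] = {}
    normal_det: dict[str, list[Detection]] = {}
    for side in ("A", "B"):
        tp = scan_junction_side(gidx, ridx_tumor, region, side, params)
        tumor_det[side] = detect_branch_change(tp, params)
        if collect_profiles:
            profiles[("tumor", side)] = tp
        if ridx_normal is not None:
            npf = scan_junction_side(gidx, ridx_normal, region, side, params)
            normal_det[side] = detect_branch_change(npf, params)
            if collect_profiles:
                profiles[("normal", side)] = npf
    calls = confirm_and_type(
        tumor_det, normal_det, region, params, region_id=region_id
    )
    return calls, profiles
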