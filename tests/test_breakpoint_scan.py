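"""Region scanning: multivalued edit-distance profiles, branch-change
detection, swap confirmation and somatic typing, on error-free toy genomes."""

import numpy as np
import pytest

from bwtsv.breakpoint_scan import ScanParams, scan_junction_side, scan_region
from bwtsv.discordant import OrientationClass
from bwtsv.genome_index import GenomeIndex, GlobalGenome
from bwtsv.read_index import ReadIndex
from bwtsv.region_prediction import BreakpointRegion
from bwtsv.simulate import ReadSimParams, make_genome, simulate_reads


def deletion_region(s, t, width=60):
    return BreakpointRegion(
        projection_a=(s - 1 - width, s - 1 + width),
        projection_b=(t - width, t + width),
        orientation_class=OrientationClass.DELETION_LIKE,
        peak_z=1.0,
        peak_xy=(s - 1, t),
    )


PARAMS = ScanParams(margin=200)


class TestDeletionToy:
    def test_exact_call(self, toy_deletion):
        d = toy_deletion
        calls, _ = scan_region(
            deletion_region(d["s"], d["t"]),
            d["ridx_tumor"], d["ridx_normal"], d["gidx"], PARAMS,
        )
        assert len(calls) == 1
        c = calls[0]
        assert abs(c.x0 - (d["s"] - 1)) <= 1 and abs(c.y0 - d["t"]) <= 1
        assert c.somatic and c.confirmed_by_swap
        assert c.orientation_class is OrientationClass.DELETION_LIKE
        assert c.support >= PARAMS.min_support

    def test_deterministic(self, toy_deletion):
        d = toy_deletion
        r = deletion_region(d["s"], d["t"])
        a, _ = scan_region(r, d["ridx_tumor"], d["ridx_normal"], d["gidx"], PARAMS)
        b, _ = scan_region(r, d["ridx_tumor"], d["ridx_normal"], d["gidx"], PARAMS)
        assert [(c.x0, c.y0, c.support) for c in a] == [(c.x0, c.y0, c.support) for c in b]

    def test_reference_band_on_normal(self, toy_deletion):
        d = toy_deletion
        profile = scan_junction_side(
            d["gidx"], d["ridx_normal"], deletion_region(d["s"], d["t"]), "B", PARAMS
        )
        assert profile.entries
        band = [e for e in profile.entries if e.dist_a <= PARAMS.low_thresh]
        assert len(band) / len(profile.entries) > 0.99
        # region B never looks like a match for reference extensions: the
        # best spurious alignment of a random 20-mer sits near 0.3, far
        # above the low (match) threshold
        assert all(e.dist_b > PARAMS.low_thresh for e in band)
        assert float(np.median([e.dist_b for e in band])) >= PARAMS.high_thresh
        assert profile.candidates == []

    def test_junction_branch_distance_shape(self, toy_deletion):
        """Right of the junction the crossing branch's distance to the
        partner grows with the offset k: the k non-partner bases cost
        between ~k/2 (partially gap-absorbed) and k edits, while the branch
        stays far from the local reference."""
        d = toy_deletion
        profile = scan_junction_side(
            d["gidx"], d["ridx_tumor"], deletion_region(d["s"], d["t"]), "B", PARAMS
        )
        by_x = {}
        for e in profile.entries:
            by_x.setdefault(e.x, []).append(e)
        e_len = PARAMS.ext_len
        last = -1.0
        for k in (0, 2, 5, 8):
            entries = by_x.get(d["t"] + k, [])
            assert entries, f"no coverage at offset {k}"
            best = min(entries, key=lambda e: e.dist_b)
            assert (k // 2 - 1) / e_len <= best.dist_b <= (k + 1) / e_len
            assert best.dist_b >= last  # monotone growth with the offset
            last = best.dist_b
            assert best.dist_a > PARAMS.high_thresh

    def test_min_support_monotone(self, toy_deletion):
        d = toy_deletion
        r = deletion_region(d["s"], d["t"])
        n_calls = []
        for ms in (1, 2, 10, 10_000):
            p = ScanParams(margin=200, min_support=ms)
            calls, _ = scan_region(r, d["ridx_tumor"], d["ridx_normal"], d["gidx"], p)
            n_calls.append(len(calls))
        assert n_calls == sorted(n_calls, reverse=True)
        assert n_calls[-1] == 0  # unattainable support: no call

    def test_germline_when_in_both_samples(self, toy_deletion):
        d = toy_deletion
        calls, _ = scan_region(
            deletion_region(d["s"], d["t"]),
            d["ridx_tumor"], d["ridx_tumor"], d["gidx"], PARAMS,
        )
        assert len(calls) == 1 and not calls[0].somatic


class TestInversionToy:
    def test_both_junctions_called_with_inversion_classes(self, toy_inversion):
        d = toy_inversion
        s, t = d["s"], d["t"]
        regions = [
            BreakpointRegion(
                projection_a=(s - 1 - 60, s - 1 + 60),
                projection_b=(t - 1 - 60, t - 1 + 60),
                orientation_class=OrientationClass.INVERSION_HEAD,
                peak_z=1.0,
                peak_xy=(s - 1, t - 1),
            ),
            BreakpointRegion(
                projection_a=(s - 60, s + 60),
                projection_b=(t - 60, t + 60),
                orientation_class=OrientationClass.INVERSION_TAIL,
                peak_z=1.0,
                peak_xy=(s, t),
            ),
        ]
        got = []
        for r in regions:
            calls, _ = scan_region(r, d["ridx_tumor"], d["ridx_normal"], d["gidx"], PARAMS)
            got.extend(calls)
        heads = [c for c in got if c.orientation_class is OrientationClass.INVERSION_HEAD]
        tails = [c for c in got if c.orientation_class is OrientationClass.INVERSION_TAIL]
        assert heads and tails
        assert any(abs(c.x0 - (s - 1)) <= 1 and abs(c.y0 - (t - 1)) <= 1 for c in heads)
        assert any(abs(c.x0 - s) <= 1 and abs(c.y0 - t) <= 1 for c in tails)


class TestPureReference:
    def test_no_calls_anywhere(self):
        ref = make_genome(1, [30_000], seed=50)
        name, seq = ref[0]
        reads = simulate_reads(ref, ReadSimParams(coverage=40.0, error_rate=0.001), seed=51)
        gidx = GenomeIndex(GlobalGenome([name], [seq]))
        ridx = ReadIndex.build_from_matrices([reads.r1, reads.r2], "tumor")
        region = BreakpointRegion(
            projection_a=(10_000, 10_100),
            projection_b=(20_000, 20_100),
            orientation_class=OrientationClass.DELETION_LIKE,
            peak_z=1.0,
            peak_xy=(10_050, 20_050),
        )
        calls, profiles = scan_region(
            region, ridx, None, gidx, PARAMS, collect_profiles=True
        )
        assert calls == []

    def test_short_extensions_still_profiled(self):
        """A branch whose every supporting read starts a few bases left of
        the anchor is emitted at its own (shorter) length, with distances
        normalised by that length."""
        ref = make_genome(1, [30_000], seed=52)
        name, seq = ref[0]
        gidx = GenomeIndex(GlobalGenome([name], [seq]))
        x = 15_000
        q = gidx.make_window_query(x, 3, "+")
        assert q is not None
        # reads start exactly 5 bases left of the anchor: max extension 5
        reads = np.stack([seq[x - 5 : x - 5 + 90]] * 3)
        ridx = ReadIndex.build_from_matrices([reads], "tumor")
        # side B of a deletion-like region scans forward; anchor our window there
        region = BreakpointRegion(
            projection_a=(10_000, 10_050),
            projection_b=(x - 20, x + 20),
            orientation_class=OrientationClass.DELETION_LIKE,
            peak_z=1.0,
            peak_xy=(10_025, x),
        )
        profile = scan_junction_side(
            gidx, ridx, region, "B", ScanParams(margin=0, min_anchor=10)
        )
        at_x = [e for e in profile.entries if e.x == x]
        assert at_x and all(len(e.ext) == 5 for e in at_x)
        assert all(e.dist_a == 0.0 and 0.0 <= e.dist_b <= 1.0 for e in at_x)
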