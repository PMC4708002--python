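"""Discordant-pair extraction, orientation classes, 2D clustering and the
somatic rule."""

import numpy as np
import pysam
import pytest

from bwtsv.discordant import (
    AlignedPairRecord,
    Cluster,
    DiscordantPoint,
    OrientationClass,
    cluster_points,
    extract_discordant,
    label_somatic,
    pair_to_point,
)
from bwtsv.genome_index import concatenate_genome

from conftest import random_dna

L = 100  # insert length used throughout the clustering tests


def make_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10000}, {"SN": "chr2", "LN": 10000}]}
    )


def seg(header, name, flag, ref_id, pos, mapq, mref_id, mpos):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = ref_id
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = "90M"
    a.query_sequence = "A" * 90
    a.next_reference_id = mref_id
    a.next_reference_start = mpos
    return a


PAIRED, PROPER, REV, MREV, R1, R2 = 0x1, 0x2, 0x10, 0x20, 0x40, 0x80


class TestExtract:
    def test_proper_pair_excluded(self):
        h = make_header()
        recs = [
            seg(h, "p", PAIRED | PROPER | R1 | MREV, 0, 100, 60, 0, 700),
            seg(h, "p", PAIRED | PROPER | R2 | REV, 0, 700, 60, 0, 100),
        ]
        pairs, skipped = extract_discordant(recs)
        assert pairs == [] and skipped == 2

    def test_interchromosomal_pair_included(self):
        h = make_header()
        recs = [
            seg(h, "q", PAIRED | R1 | MREV, 0, 100, 60, 1, 5000),
            seg(h, "q", PAIRED | R2 | REV, 1, 5000, 60, 0, 100),
        ]
        pairs, _ = extract_discordant(recs)
        assert len(pairs) == 1
        assert {pairs[0].chrom1, pairs[0].chrom2} == {"chr1", "chr2"}

    def test_low_mapq_end_excluded(self):
        h = make_header()
        recs = [
            seg(h, "r", PAIRED | R1, 0, 100, 60, 0, 5000),
            seg(h, "r", PAIRED | R2, 0, 5000, 29, 0, 100),
        ]
        pairs, _ = extract_discordant(recs, mapq_min=30)
        assert pairs == []
        # at exactly 30 the pair is kept ("not less than 30")
        recs[1].mapping_quality = 30
        pairs, _ = extract_discordant(recs, mapq_min=30)
        assert len(pairs) == 1

    def test_filter_monotone_in_mapq(self):
        h = make_header()
        rng = np.random.default_rng(0)
        recs = []
        for i in range(50):
            q1, q2 = int(rng.integers(0, 61)), int(rng.integers(0, 61))
            recs.append(seg(h, f"m{i}", PAIRED | R1, 0, 100 + i, q1, 0, 5000))
            recs.append(seg(h, f"m{i}", PAIRED | R2, 0, 5000, q2, 0, 100 + i))
        kept = [len(extract_discordant(recs, mapq_min=q)[0]) for q in (0, 10, 30, 50, 61)]
        assert kept == sorted(kept, reverse=True)


class TestPairToPoint:
    @pytest.fixture()
    def genome(self, rng):
        return concatenate_genome([("chr1", random_dna(rng, 10000))])

    def rec(self, pos1, strand1, pos2, strand2):
        return AlignedPairRecord(
            chrom1="chr1", pos1=pos1, strand1=strand1, mapq1=60, len1=90,
            chrom2="chr1", pos2=pos2, strand2=strand2, mapq2=60, len2=90,
            flag_proper=False, sample_label="tumor",
        )

    def test_swap_rule(self, genome):
        p = pair_to_point(self.rec(500, "+", 100, "+"), genome)
        assert (p.x, p.y) == (100, 500)

    def test_five_prime_coordinate_for_reverse_strand(self, genome):
        p = pair_to_point(self.rec(100, "+", 700, "-"), genome)
        assert p.y == 700 + 89  # 5' base of a reverse read is its right end

    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("+", "-", OrientationClass.DELETION_LIKE),
            ("-", "+", OrientationClass.DUPLICATION_LIKE),
            ("+", "+", OrientationClass.INVERSION_HEAD),
            ("-", "-", OrientationClass.INVERSION_TAIL),
        ],
    )
    def test_class_from_strands(self, genome, s1, s2, expected):
        p = pair_to_point(self.rec(100, s1, 700, s2), genome)
        assert p.orientation_class is expected

    def test_deletion_geometry_consistent_with_forward_simulation(self, genome, rng):
        # pairs from a junction (x0, y0) of the deletion-like class must land
        # in the quadrant x < x0, y > y0
        x0, y0 = 4000, 6000
        for _ in range(200):
            ell = max(int(rng.normal(760, 45)), 200)
            u = int(rng.uniform(1, ell - 1))
            x, y = x0 - u, y0 + (ell - u)
            p = DiscordantPoint(x, y, OrientationClass.DELETION_LIKE, "tumor")
            assert p.x < x0 and p.y > y0


def pt(x, y, oc=OrientationClass.DELETION_LIKE, sample="tumor"):
    return DiscordantPoint(x, y, oc, sample)


class TestClustering:
    def test_close_points_one_cluster(self):
        cs = cluster_points([pt(0, 1000), pt(L - 1, 1000 + L - 1)], L)
        assert len(cs) == 1

    def test_distant_points_two_clusters(self):
        cs = cluster_points([pt(0, 1000), pt(L + 1, 1000)], L)
        assert len(cs) == 2

    def test_classes_never_mix(self):
        cs = cluster_points(
            [pt(0, 1000), pt(1, 1001, OrientationClass.INVERSION_HEAD)], L
        )
        assert len(cs) == 2

    def test_permutation_invariance(self, rng):
        pts = [
            pt(int(x), int(x) + 500 + int(y))
            for x, y in zip(rng.integers(0, 3000, 60), rng.integers(0, 200, 60))
        ]
        ref = cluster_points(pts, L)
        perm = list(pts)
        rng.shuffle(perm)
        got = cluster_points(perm, L)
        as_sets = lambda cs: sorted(sorted((p.x, p.y) for p in c.points) for c in cs)
        assert as_sets(ref) == as_sets(got)

    def test_every_point_in_exactly_one_cluster(self, rng):
        pts = [pt(int(x), 5000 + int(y)) for x, y in zip(rng.integers(0, 2000, 80), rng.integers(0, 2000, 80))]
        cs = cluster_points(pts, L)
        flat = sorted((p.x, p.y) for c in cs for p in c.points)
        assert flat == sorted((p.x, p.y) for p in pts)

    def test_matches_connected_components_oracle(self, rng):
        """On junction-like instances (tight clumps, centers >= 3L apart) the
        alternating fixed point equals single-linkage connected components
        under "both axis gaps < L" adjacency.  On dense uniform scatter the
        alternating procedure is coarser (it never tests joint adjacency and
        can chain through x alone); that divergence is inherent to the
        procedure and absorbed downstream by composite-cluster regions."""
        import networkx as nx

        for trial in range(10):
            n_centers = int(rng.integers(2, 6))
            cx = np.cumsum(rng.integers(3 * L, 10 * L, n_centers)) + 500
            cy = 20_000 + np.cumsum(rng.integers(3 * L, 10 * L, n_centers))
            pts = []
            for x0, y0 in zip(cx, cy):
                for _ in range(int(rng.integers(2, 10))):
                    pts.append(
                        pt(int(x0 + rng.integers(-L // 2, L // 2)),
                           int(y0 + rng.integers(-L // 2, L // 2)))
                    )
            g = nx.Graph()
            g.add_nodes_from(range(len(pts)))
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    if abs(pts[i].x - pts[j].x) < L and abs(pts[i].y - pts[j].y) < L:
                        g.add_edge(i, j)
            want = sorted(
                sorted((pts[i].x, pts[i].y) for i in comp)
                for comp in nx.connected_components(g)
            )
            got = sorted(
                sorted((p.x, p.y) for p in c.points) for c in cluster_points(pts, L)
            )
            assert got == want, f"trial {trial}"

    def test_min_support_filter(self):
        cs = cluster_points([pt(0, 1000), pt(1, 1001), pt(5000, 9000)], L, min_support=2)
        assert len(cs) == 1 and len(cs[0]) == 2


class TestSomaticRule:
    def make(self, n_tumor, n_normal):
        pts = [pt(i, 1000 + i) for i in range(n_tumor)]
        pts += [pt(100 + i, 1100 + i, sample="normal") for i in range(n_normal)]
        return Cluster(points=pts, orientation_class=OrientationClass.DELETION_LIKE)

    def test_pure_tumor_somatic(self):
        assert label_somatic(self.make(10, 0)) == "somatic"

    def test_ninety_percent_is_somatic(self):
        assert label_somatic(self.make(9, 1)) == "somatic"

    def test_below_threshold_germline(self):
        assert label_somatic(self.make(8, 2)) == "germline"
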