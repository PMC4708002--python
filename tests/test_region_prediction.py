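"""Operator algebra of the region predictor: mass conservation, adjointness,
the normal-equation identity, and junction recovery from simulated pairs."""

import numpy as np
import pytest

from bwtsv.discordant import Cluster, DiscordantPoint, OrientationClass
from bwtsv.region_prediction import (
    BreakpointRegion,
    ClusterGrid,
    InsertModel,
    apply_conjugate,
    apply_forward,
    class_translation,
    gaussian_diffuse,
    grid_from_cluster,
    normal_operator,
    predict_regions,
    translate,
    uniform_diag_diffuse,
)

MODEL = InsertModel(L=40, sigma=4.0)
OC = OrientationClass.DELETION_LIKE


def grid(values, oc=OC):
    return ClusterGrid((0, 0), values, oc)


def point_mass(n, at=None):
    v = np.zeros((n, n))
    i, j = at if at else (n // 2, n // 2)
    v[i, j] = 1.0
    return v


class TestFactors:
    def test_mass_conservation_interior(self, rng):
        v = np.zeros((161, 161))
        v[70:90, 70:90] = rng.random((20, 20))
        for out in (
            gaussian_diffuse(v, 4.0),
            uniform_diag_diffuse(v, 40),
            uniform_diag_diffuse(v, 40, anti=True),
            translate(v, -20, 20),
        ):
            assert abs(out.sum() - v.sum()) < 1e-3 * v.sum()

    def test_factors_commute(self, rng):
        v = np.zeros((161, 161))
        v[75:85, 75:85] = rng.random((10, 10))
        a = gaussian_diffuse(uniform_diag_diffuse(v, 40), 4.0)
        b = uniform_diag_diffuse(gaussian_diffuse(v, 4.0), 40)
        assert np.abs(a - b).max() < 1e-8

    def test_translation_direction_per_class(self):
        h = MODEL.half
        assert class_translation(OrientationClass.DELETION_LIKE, MODEL) == (-h, h)
        assert class_translation(OrientationClass.DUPLICATION_LIKE, MODEL) == (h, -h)
        assert class_translation(OrientationClass.INVERSION_HEAD, MODEL) == (-h, -h)
        assert class_translation(OrientationClass.INVERSION_TAIL, MODEL) == (h, h)


class TestForward:
    def test_zero_grid(self):
        out = apply_forward(grid(np.zeros((101, 101))), MODEL)
        assert not out.values.any()

    def test_point_mass_displaced_and_spread(self):
        out = apply_forward(grid(point_mass(161)), MODEL).values
        n = 161
        cx = (out * np.arange(n)[:, None]).sum()
        cy = (out * np.arange(n)[None, :]).sum()
        assert abs(out.sum() - 1) < 1e-6
        assert abs(cx - (80 - 20)) < 1e-6 and abs(cy - (80 + 20)) < 1e-6
        # support spreads +-L/2 along the diagonal plus the Gaussian tails
        nz = np.nonzero(out > 1e-9)
        assert nz[0].min() >= 80 - 20 - 20 - 17 and nz[0].max() <= 80 - 20 + 20 + 17

    def test_insufficient_padding_raises(self):
        v = point_mass(61)  # margin 30 < required L + 4 sigma = 56
        with pytest.raises(ValueError):
            apply_forward(grid(v), MODEL)

    def test_monte_carlo_generative_law(self, rng):
        """Histogram of pairs drawn from the two-step generative rule
        (insert ~ N(L, sigma); junction-to-read distance uniform over the
        insert) against the operator's point-spread.  The operator smooths
        the insert-length jitter isotropically, so first moments agree to
        Monte-Carlo error while the variance along the anti-diagonal is
        mildly over-dispersed; both are asserted at their expected sizes."""
        n, c = 161, 80
        fw = apply_forward(grid(point_mass(n)), MODEL).values
        N = 100_000
        ell = rng.normal(MODEL.L, MODEL.sigma, N)
        u = rng.uniform(0, ell)
        xs = np.round(c - u).astype(int)
        ys = np.round(c + ell - u).astype(int)
        H = np.zeros((n, n))
        np.add.at(H, (xs, ys), 1.0 / N)

        def stats(M):
            gx = (M * np.arange(n)[:, None]).sum() / M.sum()
            gy = (M * np.arange(n)[None, :]).sum() / M.sum()
            vx = (M * (np.arange(n)[:, None] - gx) ** 2).sum() / M.sum()
            return gx, gy, vx

        ox, oy, ovx = stats(fw)
        mx, my, mvx = stats(H)
        assert abs(ox - mx) < 0.2 and abs(oy - my) < 0.2
        assert abs(ovx - mvx) / mvx < 0.2
        assert 0.5 * np.abs(fw / fw.sum() - H / H.sum()).sum() < 0.3


class TestConjugate:
    def test_zero_grid(self):
        out = apply_conjugate(grid(np.zeros((101, 101))), MODEL)
        assert not out.values.any()

    def test_single_pair_plateau_contains_displacement(self):
        z = apply_conjugate(grid(point_mass(161)), MODEL).values
        peak = z.max()
        # the top of z is a diagonal plateau centered at p + (L/2, -L/2)
        assert z[80 + 20, 80 - 20] > 0.999 * peak
        am = np.unravel_index(np.argmax(z), z.shape)
        d = (am[0] - 80) - (am[1] - 80)  # anti-diagonal offset from p
        assert abs(am[0] - (80 + 20)) <= MODEL.L / 2 + 1
        assert abs(d - MODEL.L) <= 2  # on the displaced diagonal

    def test_matches_dense_matrix_conjugate(self, rng):
        """A* on a small grid equals the explicit transpose of the dense
        forward matrix."""
        m = InsertModel(L=8, sigma=1.0)
        n = 41
        cols = []
        for i in range(n):
            for j in range(n):
                e = np.zeros((n, n))
                e[i, j] = 1.0
                cols.append(
                    apply_forward(grid(e), m, enforce_padding=False).values.ravel()
                )
        A = np.array(cols).T  # A[:, k] = A e_k
        y = rng.random((n, n))
        want = (A.T @ y.ravel()).reshape(n, n)
        got = apply_conjugate(grid(y), m).values
        assert np.abs(got - want).max() < 1e-10

    def test_adjointness_inner_product(self, rng):
        u = rng.random((121, 121))
        v = rng.random((121, 121))
        Au = apply_forward(grid(u), MODEL, enforce_padding=False).values
        Asv = apply_conjugate(grid(v), MODEL).values
        lhs = float((Au * v).sum())
        rhs = float((u * Asv).sum())
        assert abs(lhs - rhs) / abs(lhs) < 1e-8


class TestNormalOperator:
    @pytest.mark.parametrize("oc", list(OrientationClass))
    def test_equals_forward_then_conjugate(self, oc):
        v = point_mass(201, (100, 100))
        via = apply_conjugate(apply_forward(grid(v, oc), MODEL), MODEL).values
        direct = normal_operator(grid(v, oc), MODEL).values
        assert np.abs(via - direct).max() < 1e-6 * direct.max()

    def test_point_mass_not_translated(self):
        out = normal_operator(grid(point_mass(201, (100, 100))), MODEL).values
        am = np.unravel_index(np.argmax(out), out.shape)
        # symmetric blur: the peak plateau is centered on the source
        assert out[100, 100] > 0.999 * out.max()
        assert abs((am[0] - 100) + (am[1] - 100)) <= 2  # anti-diagonal symmetric

    def test_positive_semidefinite(self, rng):
        for _ in range(5):
            u = rng.random((121, 121))
            Au = apply_forward(grid(u), MODEL, enforce_padding=False).values
            quad = float((u * apply_conjugate(grid(Au), MODEL).values).sum())
            assert quad >= 0
            assert abs(quad - float((Au**2).sum())) / quad < 1e-8


def simulate_cluster(rng, x0, y0, p, model, oc=OC):
    pts = []
    for _ in range(p):
        ell = max(rng.normal(model.L, model.sigma), 4)
        u = rng.uniform(0, ell)
        dx = u if oc.strand_x == "+" else -u
        dy = ell - u if oc.strand_y == "-" else -(ell - u)
        pts.append(DiscordantPoint(int(x0 - dx), int(y0 + dy), oc, "tumor"))
    return Cluster(points=pts, orientation_class=oc)


class TestPredictRegions:
    def test_zero_z_empty(self):
        assert predict_regions(grid(np.zeros((51, 51)))) == []

    def test_single_pair_region_contains_plateau(self):
        z = apply_conjugate(grid(point_mass(161)), MODEL)
        regions = predict_regions(z)
        assert len(regions) >= 1
        r = regions[0]
        assert r.projection_a[0] <= 100 <= r.projection_a[1]
        assert r.projection_b[0] <= 60 <= r.projection_b[1]

    def test_junction_recovery(self, rng):
        model = InsertModel(L=760, sigma=45)
        hits = 0
        for _ in range(40):
            c = simulate_cluster(rng, 20_000, 40_000, 8, model)
            g = grid_from_cluster(c, model)
            regions = predict_regions(apply_conjugate(g, model))
            assert len(regions) >= 1
            r = regions[0]
            if (
                r.projection_a[0] - 10 <= 20_000 < r.projection_a[1] + 10
                and r.projection_b[0] - 10 <= 40_000 < r.projection_b[1] + 10
            ):
                hits += 1
        assert hits >= 38

    def test_two_junctions_two_regions(self, rng):
        model = InsertModel(L=760, sigma=45)
        sep = 3 * 760
        c1 = simulate_cluster(rng, 20_000, 40_000, 10, model)
        c2 = simulate_cluster(rng, 20_000 + sep, 40_000 + sep, 10, model)
        comp = Cluster(points=c1.points + c2.points, orientation_class=OC)
        g = grid_from_cluster(comp, model)
        regions = predict_regions(apply_conjugate(g, model))
        assert len(regions) == 2
        found = set()
        for r in regions:
            for x0, y0 in ((20_000, 40_000), (20_000 + sep, 40_000 + sep)):
                if (
                    r.projection_a[0] - 10 <= x0 < r.projection_a[1] + 10
                    and r.projection_b[0] - 10 <= y0 < r.projection_b[1] + 10
                ):
                    found.add((x0, y0))
        assert len(found) == 2
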