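"""Breakpoint-region prediction via the conjugate of the pair-scatter operator.

The forward model: a junction at (x0, y0) in G x G generates discordant
pairs whose displacement from the junction is governed by the insert-length
law N(L, sigma) with the fragment start uniform over the insert.  As a linear
operator on gridded distributions this is the composition

    A = G_sigma . U_L . T_{L/2}

of an isotropic 2D Gaussian diffusion (sd sigma), a uniform diffusion of
per-axis extent +-L/2 along the diagonal (or anti-diagonal for the inversion
classes), and a per-axis translation by L/2 whose direction is fixed by the
orientation class (a forward-strand end displaces its coordinate by -L/2,
a reverse-strand end by +L/2).

Region prediction applies the conjugate A* to the empirical pair counts y:
z = A* y peaks where a junction best explains the observed pairs, and the
connected component of {z >= tau * max z} around the peak is the predicted
breakpoint region.  The normal operator A*A is the symmetric diffusion
G_{sqrt(2) sigma} . U_L^2 — translation cancels against its inverse, the
uniform kernel convolves with itself, and the two Gaussians compose by
adding variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .discordant import Cluster, OrientationClass

DEFAULT_TAU = 0.5
GAUSS_TRUNCATE = 4.0  # kernel support +- 4 sigma, renormalized


@dataclass(frozen=True)
class InsertModel:
    """Insert-length law N(L, sigma) of the sequencing library, in bp."""

    L: float
    sigma: float

    def __post_init__(self):
        if self.L <= 0 or self.sigma < 0:
            raise ValueError("insert model requires L > 0 and sigma >= 0")

    @property
    def half(self) -> int:
        return int(round(self.L / 2))

    def required_padding(self) -> int:
        return int(np.ceil(self.L + GAUSS_TRUNCATE * self.sigma))


@dataclass
class ClusterGrid:
    """Dense per-cluster grid over a window of G x G (axis 0 = x, axis 1 = y)."""

    origin: tuple[int, int]
    values: np.ndarray
    orientation_class: OrientationClass
    bin_size: int = 1
    cluster_id: int = -1

    def copy_with(self, values: np.ndarray) -> "ClusterGrid":
        return ClusterGrid(
            self.origin, values, self.orientation_class, self.bin_size, self.cluster_id
        )


@dataclass
class BreakpointRegion:
    """Connected region of significantly large z with its 1D projections."""

    projection_a: tuple[int, int]  # global x interval, half-open
    projection_b: tuple[int, int]  # global y interval, half-open
    orientation_class: OrientationClass
    peak_z: float
    peak_xy: tuple[int, int]
    cluster_id: int = -1
    somatic_flag: bool | None = None
    n_tumor: int = 0
    n_normal: int = 0


def grid_from_cluster(
    cluster: Cluster,
    model: InsertModel,
    cluster_id: int = -1,
    pad_mode: str = "conjugate",
    dtype=np.float64,
) -> ClusterGrid:
    """Empirical pair-count grid, padded so no operator mass leaves it.

    pad_mode "full" pads every side by L + 4 sigma (safe for the forward
    operator); "conjugate" pads asymmetrically — the conjugate translates
    mass only toward the junction ('+'-strand axis upward, '-' downward),
    so the away side needs just the diffusion margin."""
    pad = model.required_padding()
    x0, x1, y0, y1 = cluster.bbox
    if pad_mode == "full":
        pads = (pad, pad, pad, pad)  # x low, x high, y low, y high
    else:
        gpad = int(np.ceil(GAUSS_TRUNCATE * model.sigma)) + 8
        oc = cluster.orientation_class
        pads = (
            gpad if oc.strand_x == "+" else pad,
            pad if oc.strand_x == "+" else gpad,
            gpad if oc.strand_y == "+" else pad,
            pad if oc.strand_y == "+" else gpad,
        )
    ox, oy = x0 - pads[0], y0 - pads[2]
    nx = (x1 - x0) + pads[0] + pads[1] + 1
    ny = (y1 - y0) + pads[2] + pads[3] + 1
    values = np.zeros((nx, ny), dtype=dtype)
    for p in cluster.points:
        values[p.x - ox, p.y - oy] += 1.0
    return ClusterGrid(
        (ox, oy), values, cluster.orientation_class, cluster_id=cluster_id
    )


# -- operator factors -------------------------------------------------


def gaussian_diffuse(values: np.ndarray, sigma: float) -> np.ndarray:
    """Isotropic 2D Gaussian diffusion, truncated at +-4 sigma."""
    if sigma == 0:
        return values.copy()
    return ndimage.gaussian_filter(
        values, sigma=sigma, mode="constant", truncate=GAUSS_TRUNCATE
    )


def uniform_diag_diffuse(values: np.ndarray, L: int, anti: bool = False) -> np.ndarray:
    """Uniform diffusion of per-axis extent +-L/2 along the (anti)diagonal.

    Implemented by shearing the grid so the (anti)diagonals become columns
    and running a centered length-(L+1) uniform filter down the columns.
    """
    size = int(L) + 1
    nx, ny = values.shape
    rows = np.arange(nx)[:, None]
    cols = np.arange(ny)[None, :]
    if anti:
        idx = rows + cols
    else:
        idx = cols - rows + (nx - 1)
    # transposed layout: the filtered direction (grid rows) is contiguous
    sheared = np.zeros((nx + ny - 1, nx), dtype=values.dtype)
    sheared[idx, rows] = values
    sheared = ndimage.uniform_filter1d(sheared, size=size, axis=1, mode="constant")
    return sheared[idx, rows]


def translate(values: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Integer translation with zero fill (mass leaving the grid is lost)."""
    out = np.zeros_like(values)
    nx, ny = values.shape
    sx0, sx1 = max(0, -dx), min(nx, nx - dx)
    sy0, sy1 = max(0, -dy), min(ny, ny - dy)
    if sx0 < sx1 and sy0 < sy1:
        out[sx0 + dx : sx1 + dx, sy0 + dy : sy1 + dy] = values[sx0:sx1, sy0:sy1]
    return out


def class_translation(oc: OrientationClass, model: InsertModel) -> tuple[int, int]:
    """Forward per-axis translation (dx, dy): '+' strand end -> -L/2."""
    h = model.half
    dx = -h if oc.strand_x == "+" else h
    dy = -h if oc.strand_y == "+" else h
    return dx, dy


def _check_padding(grid: ClusterGrid, model: InsertModel) -> None:
    nz = np.nonzero(grid.values)
    if nz[0].size == 0:
        return
    pad = model.required_padding()
    nx, ny = grid.values.shape
    margin = min(
        nz[0].min(), nz[1].min(), nx - 1 - nz[0].max(), ny - 1 - nz[1].max()
    )
    if margin < pad:
        raise ValueError(
            f"grid padding {margin} insufficient (needs >= {pad}); mass would leave the grid"
        )


def apply_forward(
    grid: ClusterGrid, model: InsertModel, enforce_padding: bool = True
) -> ClusterGrid:
    """A = G_sigma . U_L . T_{L/2}: junction distribution -> pair distribution."""
    if enforce_padding:
        _check_padding(grid, model)
    dx, dy = class_translation(grid.orientation_class, model)
    v = translate(grid.values, dx, dy)
    v = uniform_diag_diffuse(
        v, 2 * model.half, anti=not grid.orientation_class.diagonal_spread
    )
    v = gaussian_diffuse(v, model.sigma)
    return grid.copy_with(v)


def apply_conjugate(
    grid: ClusterGrid, model: InsertModel, enforce_padding: bool = False
) -> ClusterGrid:
    """A* = T_{L/2}^{-1} . U_L . G_sigma: pair counts -> junction likelihood z."""
    if enforce_padding:
        _check_padding(grid, model)
    dx, dy = class_translation(grid.orientation_class, model)
    v = gaussian_diffuse(grid.values, model.sigma)
    v = uniform_diag_diffuse(
        v, 2 * model.half, anti=not grid.orientation_class.diagonal_spread
    )
    v = translate(v, -dx, -dy)
    return grid.copy_with(v)


def normal_operator(grid: ClusterGrid, model: InsertModel) -> ClusterGrid:
    """A*A = G_{sqrt(2) sigma} . U_L^2 — symmetric blur, no net translation.

    The composite Gaussian has variance 2 sigma^2; with truncated kernels the
    exact composition G_sigma . G_sigma is applied so that the identity with
    apply_forward followed by apply_conjugate holds to machine precision."""
    anti = not grid.orientation_class.diagonal_spread
    v = gaussian_diffuse(gaussian_diffuse(grid.values, model.sigma), model.sigma)
    v = uniform_diag_diffuse(v, 2 * model.half, anti=anti)
    v = uniform_diag_diffuse(v, 2 * model.half, anti=anti)
    return grid.copy_with(v)


# -- region extraction -------------------------------------------------


def predict_regions(
    z: ClusterGrid, tau: float = DEFAULT_TAU
) -> list[BreakpointRegion]:
    """Connected components of {z >= tau * max z}, as boxes with projections.

    The component containing the argmax is always returned; secondary
    components capture composite clusters holding several junctions.
    """
    values = z.values
    peak = float(values.max(initial=0.0))
    if peak <= 0.0:
        return []
    mask = values >= tau * peak
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    ox, oy = z.origin
    regions = []
    for lab, (sl_x, sl_y) in enumerate(ndimage.find_objects(labels), start=1):
        sub = values[sl_x, sl_y]
        sub_mask = labels[sl_x, sl_y] == lab
        local_peak = float(sub[sub_mask].max())
        pi, pj = np.unravel_index(np.argmax(np.where(sub_mask, sub, -np.inf)), sub.shape)
        regions.append(
            BreakpointRegion(
                projection_a=(ox + sl_x.start, ox + sl_x.stop),
                projection_b=(oy + sl_y.start, oy + sl_y.stop),
                orientation_class=z.orientation_class,
                peak_z=local_peak,
                peak_xy=(ox + sl_x.start + int(pi), oy + sl_y.start + int(pj)),
                cluster_id=z.cluster_id,
            )
        )
    regions.sort(key=lambda r: -r.peak_z)
    return regions


def predict_cluster_regions(
    cluster: Cluster,
    model: InsertModel,
    tau: float = DEFAULT_TAU,
    cluster_id: int = -1,
    dtype=np.float32,
) -> list[BreakpointRegion]:
    """Full per-cluster prediction: counts -> z = A* y -> thresholded regions.

    Single precision by default: the thresholding at tau * max(z) is far
    above float32 rounding for any realistic pair count."""
    grid = grid_from_cluster(cluster, model, cluster_id=cluster_id, dtype=dtype)
    zg = apply_conjugate(grid, model)
    regions = predict_regions(zg)
    for r in regions:
        r.somatic_flag = cluster.somatic_flag
        r.n_tumor = cluster.n_tumor
        r.n_normal = cluster.n_normal
    return regions
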