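"""Derived measurements: divergence maps and aster detection, synthetic
fluorescence rendering, kymographs and ROI intensity traces,
coarse-grained hexagon segmentation, motor-force statistics, plus-end
connectedness, and work/energy accounting.

Aster identification works on the divergence of filament orientation:
each filament contributes its unit orientation vector to the grid box
containing its plus-end; the finite-difference divergence of the summed
field is near zero for disordered networks, and strongly negative at an
aster core (orientations converge on the packed plus-ends) with a
positive shell around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .config import SimulationConfig
from .dynamics import DragCoefficients
from .geometry import HexagonDomain
from .state import SystemState

__all__ = [
    "DivergenceMap",
    "divergence_map",
    "detect_asters",
    "SyntheticFrame",
    "render_frame",
    "roi_mean_intensity",
    "kymograph",
    "coarse_hexagon_segmentation",
    "mean_motor_force",
    "plus_end_connectedness",
    "elastic_energy",
    "energy_accounting",
    "EnergyLedger",
]


# ---------------------------------------------------------------------------
# Divergence maps and aster detection
# ---------------------------------------------------------------------------


@dataclass
class DivergenceMap:
    """Grid of summed plus-end orientation vectors and their divergence.

    Arrays are indexed ``[row, col]`` = ``[y, x]``; ``div = divx + divy``
    box-wise.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    counts: np.ndarray          # plus-ends per box
    divx: np.ndarray
    divy: np.ndarray
    div: np.ndarray
    box_size: float
    inside: np.ndarray          # boxes whose center lies in the hexagon

    def box_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        return cx, cy


def divergence_map(
    plus_ends: np.ndarray,
    angles: np.ndarray,
    domain: HexagonDomain,
    box_size: float,
) -> DivergenceMap:
    """Divergence of the summed plus-end orientation field.

    The domain bounding box is tiled with square boxes of side
    ``box_size`` (the convention is L/8).  Each filament whose plus-end
    falls in a box adds its orientation unit vector to that box's sum
    ``V = [Vx, Vy]``.  The divergence uses central differences between
    neighboring boxes, ``divX[i,j] = (Vx[i,j+1] - Vx[i,j-1]) / (2 h)``
    (one-sided at the grid edge), and ``DIV = divX + divY``.
    """
    plus_ends = np.atleast_2d(np.asarray(plus_ends, dtype=float))
    if plus_ends.shape[0] == 0:
        raise ValueError("need at least one filament")
    xmin, xmax, ymin, ymax = domain.bounding_box()
    x_edges = np.arange(xmin, xmax + box_size, box_size)
    y_edges = np.arange(ymin, ymax + box_size, box_size)
    u = np.column_stack([np.cos(angles), np.sin(angles)])
    vx, _, _ = np.histogram2d(
        plus_ends[:, 1], plus_ends[:, 0], bins=(y_edges, x_edges), weights=u[:, 0]
    )
    vy, _, _ = np.histogram2d(
        plus_ends[:, 1], plus_ends[:, 0], bins=(y_edges, x_edges), weights=u[:, 1]
    )
    counts, _, _ = np.histogram2d(
        plus_ends[:, 1], plus_ends[:, 0], bins=(y_edges, x_edges)
    )
    divx = np.gradient(vx, box_size, axis=1)
    divy = np.gradient(vy, box_size, axis=0)
    ctr_x = 0.5 * (x_edges[:-1] + x_edges[1:])
    ctr_y = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(ctr_x, ctr_y)
    inside = np.asarray(
        domain.contains(np.column_stack([gx.ravel(), gy.ravel()]))
    ).reshape(gx.shape)
    return DivergenceMap(
        x_edges=x_edges,
        y_edges=y_edges,
        vx=vx,
        vy=vy,
        counts=counts,
        divx=divx,
        divy=divy,
        div=divx + divy,
        box_size=box_size,
        inside=inside,
    )


@dataclass
class AsterDetection:
    centers: np.ndarray      # (n, 2) um
    count: int
    smoothed: np.ndarray     # Gaussian-smoothed divergence grid
    threshold: float         # core threshold actually applied


def detect_asters(
    divmap: DivergenceMap,
    smoothing_sigma: float = 1.0,
    core_factor: float = 2.0,
    min_core_boxes: int = 1,
    merge_boxes: int = 2,
    density_factor: float = 4.0,
    min_core_plus_ends: int = 5,
) -> AsterDetection:
    """Locate asters as sign-reversal loci of the divergence field.

    The divergence grid is Gaussian-smoothed (``smoothing_sigma`` in box
    units); candidate cores are in-domain boxes below
    ``-core_factor * sigma_DIV`` (``sigma_DIV`` = standard deviation of
    the smoothed map over the hexagon).  Cores closer than
    ``merge_boxes`` boxes belong to one aster (a compact core's
    divergence dipole is often fragmented across a few boxes).  A merged
    core must pass two confirmations that separate asters from
    divergence noise in disordered networks:

    * sign reversal — either a strongly positive box (above
      ``+core_factor * sigma_DIV``) lies within two boxes of the core
      (the dark-next-to-light dipole of a point-like core), or the
      shell around the core halo has positive mean divergence (the
      positive ring around a broad core);
    * plus-end packing — some 3x3-box window on the core holds at least
      ``min_core_plus_ends`` plus-ends and ``density_factor`` times the
      count an average-density window would hold (an aster core is, by
      definition, a dense pack of plus-ends).

    Returns centers (depth-weighted core centroids) and the count.
    """
    sm = ndimage.gaussian_filter(divmap.div, smoothing_sigma)
    inside = divmap.inside
    sigma = float(sm[inside].std()) if inside.any() else float(sm.std())
    thresh = -core_factor * sigma
    if sigma == 0:
        return AsterDetection(np.empty((0, 2)), 0, sm, thresh)
    core = (sm < thresh) & inside
    merged = ndimage.binary_dilation(core, iterations=merge_boxes) if merge_boxes else core
    labels, n_lab = ndimage.label(merged)
    cx, cy = divmap.box_centers()
    mean_density = float(divmap.counts[inside].mean())
    # 3x3 plus-end window sums, for the packing confirmation
    window9 = ndimage.uniform_filter(divmap.counts, size=3, mode="constant") * 9.0
    pack_need = max(min_core_plus_ends, density_factor * 9.0 * mean_density)
    centers = []
    for lab in range(1, n_lab + 1):
        comp = (labels == lab) & core
        if comp.sum() < min_core_boxes:
            continue
        near = ndimage.binary_dilation(comp, iterations=2)
        halo = labels == lab
        shell = ndimage.binary_dilation(halo, iterations=2) & ~halo
        dipole = sm[near & ~comp].max() > -thresh if (near & ~comp).any() else False
        ring = shell.any() and sm[shell].mean() > 0
        if not (dipole or ring):
            continue
        if window9[ndimage.binary_dilation(comp, iterations=1)].max() < pack_need:
            continue
        w = -sm[comp]
        rows, cols = np.nonzero(comp)
        centers.append(
            [np.average(cx[cols], weights=w), np.average(cy[rows], weights=w)]
        )
    centers_arr = np.asarray(centers) if centers else np.empty((0, 2))
    return AsterDetection(centers_arr, len(centers), sm, thresh)


# ---------------------------------------------------------------------------
# Synthetic fluorescence rendering
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFrame:
    """Additive count raster mimicking a fluorescence image."""

    intensity: np.ndarray   # (ny, nx) counts, row 0 at ymin
    pixel_size: float       # um per pixel
    origin: tuple[float, float]  # (xmin, ymin) of pixel (0, 0)
    channel: str

    def to_pixel(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.column_stack(
            [
                (p[:, 0] - self.origin[0]) / self.pixel_size,
                (p[:, 1] - self.origin[1]) / self.pixel_size,
            ]
        )


def render_frame(
    state: SystemState,
    cfg: SimulationConfig,
    pixel_size: float = 0.05,
    channel: str = "filament",
) -> SyntheticFrame:
    """Rasterize agents into an additive intensity image.

    Filaments are drawn as 1-px-wide Bresenham segments, motors (and
    crosslinkers) as single points; overlapping agents add.
    """
    from skimage.draw import line as skline

    domain = HexagonDomain(cfg.hexagon_circumradius)
    xmin, xmax, ymin, ymax = domain.bounding_box()
    nx = int(np.ceil((xmax - xmin) / pixel_size)) + 1
    ny = int(np.ceil((ymax - ymin) / pixel_size)) + 1
    img = np.zeros((ny, nx), dtype=np.float64)

    def px(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        col = np.clip(((pts[:, 0] - xmin) / pixel_size).round().astype(int), 0, nx - 1)
        row = np.clip(((pts[:, 1] - ymin) / pixel_size).round().astype(int), 0, ny - 1)
        return np.column_stack([row, col])

    if channel == "filament":
        plus = px(state.plus_ends(cfg.filament_length))
        minus = px(state.minus_ends(cfg.filament_length))
        for (r0, c0), (r1, c1) in zip(minus, plus):
            rr, cc = skline(r0, c0, r1, c1)
            img[rr, cc] += 1.0
    elif channel == "motor":
        pos = state.motor_head_positions().mean(axis=1)
        rc = px(pos)
        np.add.at(img, (rc[:, 0], rc[:, 1]), 1.0)
    elif channel == "crosslinker":
        rc = px(state.xl_head_positions().mean(axis=1))
        np.add.at(img, (rc[:, 0], rc[:, 1]), 1.0)
    else:
        raise ValueError("channel must be 'filament', 'motor' or 'crosslinker'")
    return SyntheticFrame(img, pixel_size, (xmin, ymin), channel)


# ---------------------------------------------------------------------------
# ROI intensity and kymographs
# ---------------------------------------------------------------------------


def roi_mean_intensity(
    frames: list[SyntheticFrame],
    center: tuple[float, float],
    radius: float,
    normalize: bool = True,
) -> np.ndarray:
    """Mean intensity inside a circular ROI per frame.

    ``center``/``radius`` are in um.  With ``normalize`` the per-frame
    ROI mean is divided by the whole-frame mean (contraction index).
    """
    if not frames:
        return np.empty(0)
    f0 = frames[0]
    ny, nx = f0.intensity.shape
    xs = f0.origin[0] + f0.pixel_size * np.arange(nx)
    ys = f0.origin[1] + f0.pixel_size * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)
    mask = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 <= radius**2
    if not mask.any():
        raise ValueError("ROI contains no pixels")
    out = np.empty(len(frames))
    for i, fr in enumerate(frames):
        roi = fr.intensity[mask].mean()
        if normalize:
            whole = fr.intensity.mean()
            out[i] = roi / whole if whole > 0 else 0.0
        else:
            out[i] = roi
    return out


def kymograph(
    frames: list[SyntheticFrame],
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 1,
) -> np.ndarray:
    """Intensity profile along a segment, stacked over time.

    Returns an array of shape (position, time).  Each column is the
    per-frame profile sampled along the segment from ``start`` to
    ``end`` (um), averaged across ``width_px`` pixels of width.
    """
    from skimage.measure import profile_line

    if not frames:
        return np.empty((0, 0))
    f0 = frames[0]
    src = f0.to_pixel(np.asarray(start))[0][::-1]  # (row, col)
    dst = f0.to_pixel(np.asarray(end))[0][::-1]
    cols = [
        profile_line(
            fr.intensity, src, dst, linewidth=width_px, mode="constant", cval=0.0
        )
        for fr in frames
    ]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Coarse-grained hexagon segmentation
# ---------------------------------------------------------------------------


@dataclass
class HexSegmentation:
    """Per-frame statistics of bright hexagonal regions."""

    n_regions: np.ndarray        # (T,)
    mean_intensity: np.ndarray   # (T,) mean over highlighted hexagons (0 if none)
    area: np.ndarray             # (T,) total highlighted area, um^2
    min_boundary_distance: np.ndarray  # (T,) um; NaN when no region
    global_mean: float
    hex_centers: np.ndarray      # (H, 2)
    highlighted: np.ndarray      # (T, H) bool


def coarse_hexagon_segmentation(
    frames: list[SyntheticFrame],
    domain: HexagonDomain,
    hex_size: float = 0.5,
    fold_threshold: float = 1.7,
) -> HexSegmentation:
    """Segment bright regions on a small-hexagon tiling of the domain.

    The domain is tiled with regular hexagons of circumradius
    ``hex_size``; pixel means per hexagon and frame are compared against
    ``fold_threshold`` times the global spatiotemporal mean intensity
    (all in-domain pixels, all frames).  Adjacent highlighted hexagons
    merge into one region.  Reports per-frame region count, mean
    intensity of highlighted hexagons, total highlighted area and the
    minimum distance from a region to the domain boundary.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be > 0")
    if not frames:
        raise ValueError("need at least one frame")
    f0 = frames[0]
    ny, nx = f0.intensity.shape
    xs = f0.origin[0] + f0.pixel_size * np.arange(nx)
    ys = f0.origin[1] + f0.pixel_size * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)
    pix = np.column_stack([gx.ravel(), gy.ravel()])
    in_dom = domain.contains(pix)

    # pointy-top hex lattice of centers covering the domain
    dx = np.sqrt(3.0) * hex_size
    dy = 1.5 * hex_size
    xmin, xmax, ymin, ymax = domain.bounding_box()
    centers = []
    j = 0
    y = ymin
    while y <= ymax + dy:
        x0 = xmin + (0.5 * dx if j % 2 else 0.0)
        x = x0
        while x <= xmax + dx:
            centers.append((x, y))
            x += dx
        y += dy
        j += 1
    centers = np.asarray(centers)
    keep = domain.contains(centers)
    centers = centers[keep]

    # nearest-center assignment = Voronoi cells of the hex lattice
    tree = cKDTree(centers)
    _, assign = tree.query(pix[in_dom])
    n_hex = centers.shape[0]
    counts = np.bincount(assign, minlength=n_hex).astype(float)
    counts[counts == 0] = np.nan

    stack = np.stack([fr.intensity.ravel()[in_dom] for fr in frames])
    global_mean = float(stack.mean())
    thresh = fold_threshold * global_mean

    # adjacency between hexagons: centers one lattice spacing apart
    pairs = tree.query_pairs(dx * 1.05, output_type="ndarray")

    n_frames = len(frames)
    highlighted = np.zeros((n_frames, n_hex), dtype=bool)
    n_regions = np.zeros(n_frames, dtype=int)
    mean_int = np.zeros(n_frames)
    area = np.zeros(n_frames)
    min_bdist = np.full(n_frames, np.nan)
    hex_area = 1.5 * np.sqrt(3.0) * hex_size**2
    # distance of each tile center to the domain edge (half-plane geometry)
    bdist_centers = domain.inradius - np.max(centers @ _hex_normals().T, axis=1)

    for t in range(n_frames):
        sums = np.bincount(assign, weights=stack[t], minlength=n_hex)
        means = sums / counts
        hi = np.nan_to_num(means) >= thresh
        highlighted[t] = hi
        if not hi.any():
            continue
        idx = np.nonzero(hi)[0]
        remap = -np.ones(n_hex, dtype=int)
        remap[idx] = np.arange(idx.size)
        edge_mask = hi[pairs[:, 0]] & hi[pairs[:, 1]] if pairs.size else np.empty(0, bool)
        rows = remap[pairs[edge_mask, 0]] if pairs.size else np.empty(0, int)
        cols = remap[pairs[edge_mask, 1]] if pairs.size else np.empty(0, int)
        graph = csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(idx.size, idx.size)
        )
        n_comp, _ = connected_components(graph, directed=False)
        n_regions[t] = n_comp
        mean_int[t] = float(np.nanmean(means[idx]))
        area[t] = hex_area * idx.size
        min_bdist[t] = float(np.maximum(bdist_centers[idx], 0.0).min())
    return HexSegmentation(
        n_regions=n_regions,
        mean_intensity=mean_int,
        area=area,
        min_boundary_distance=min_bdist,
        global_mean=global_mean,
        hex_centers=centers,
        highlighted=highlighted,
    )


def _hex_normals() -> np.ndarray:
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    return np.column_stack([np.cos(ang), np.sin(ang)])


# ---------------------------------------------------------------------------
# Force and clustering statistics
# ---------------------------------------------------------------------------


def mean_motor_force(state: SystemState, cfg: SimulationConfig) -> tuple[float, float]:
    """(mean over all motors, mean over force-exerting motors) in pN.

    Only motors spanning two attachments exert force (magnitude
    ``k * extension``); one-bound and free motors contribute zero to the
    first average and are excluded from the second.
    """
    if state.n_motors == 0:
        return 0.0, 0.0
    active = state.motor_attached().all(axis=1)
    mags = np.zeros(state.n_motors)
    if active.any():
        pos = state.motor_head_positions()[active]
        mags[active] = cfg.motor_stiffness * np.linalg.norm(
            pos[:, 1, :] - pos[:, 0, :], axis=1
        )
    exerting = mags > 0
    return float(mags.mean()), float(mags[exerting].mean()) if exerting.any() else 0.0


def plus_end_connectedness(
    plus_ends: np.ndarray, radius: float
) -> float:
    """Fraction of plus-ends in the largest radius-linked cluster.

    Single linkage: two plus-ends are connected when closer than
    ``radius``; the statistic is (size of largest connected component) /
    (number of filaments).  This is a reconstruction of the
    'connectedness' trace — the clustering radius defaults to twice the
    motor reach in callers.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    pts = np.atleast_2d(np.asarray(plus_ends, dtype=float))
    n = pts.shape[0]
    if n == 0:
        return 0.0
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    graph = csr_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    largest = np.bincount(labels).max()
    return float(largest / n)


# ---------------------------------------------------------------------------
# Work / energy accounting
# ---------------------------------------------------------------------------


@dataclass
class EnergyLedger:
    elastic_energy: float     # pN um stored in stretched connectors
    dissipation: float        # pN um viscous loss over the step
    n_two_bound: int
    n_one_bound: int
    n_free: int


def elastic_energy(state: SystemState, cfg: SimulationConfig) -> float:
    """Total spring energy, sum over two-attachment connectors of k ext^2 / 2."""
    total = 0.0
    active = state.motor_attached().all(axis=1)
    if active.any():
        pos = state.motor_head_positions()[active]
        ext = np.linalg.norm(pos[:, 1, :] - pos[:, 0, :], axis=1)
        total += 0.5 * cfg.motor_stiffness * float(np.sum(ext**2))
    if state.xl_bound.any():
        pos = state.xl_head_positions()[state.xl_bound]
        ext = np.linalg.norm(pos[:, 1, :] - pos[:, 0, :], axis=1)
        total += 0.5 * cfg.xl_stiffness * float(np.sum(ext**2))
    return total


def energy_accounting(
    state_before: SystemState,
    state_after: SystemState,
    cfg: SimulationConfig,
    drags: DragCoefficients,
    dt: float,
) -> EnergyLedger:
    """Energy bookkeeping across one step.

    Elastic energy is evaluated on ``state_after``; viscous dissipation
    is the drag work of the realized filament displacements between the
    two states, decomposed along/across the pre-step filament axis:
    ``sum(Gpar dpar^2 + Gperp dperp^2 + Grot dtheta^2) / dt``.  In the
    overdamped dynamics this equals the work done by the applied forces.
    """
    mob = state_before.fil_mobile
    d = state_after.fil_center[mob] - state_before.fil_center[mob]
    theta = state_before.fil_angle[mob]
    c, s = np.cos(theta), np.sin(theta)
    d_par = d[:, 0] * c + d[:, 1] * s
    d_perp = -d[:, 0] * s + d[:, 1] * c
    d_theta = state_after.fil_angle[mob] - theta
    diss = (
        drags.par * np.sum(d_par**2)
        + drags.perp * np.sum(d_perp**2)
        + drags.rot * np.sum(d_theta**2)
    ) / dt
    n_two, n_one, n_free = state_after.motor_state_counts()
    return EnergyLedger(
        elastic_energy=elastic_energy(state_after, cfg),
        dissipation=float(diss),
        n_two_bound=n_two,
        n_one_bound=n_one,
        n_free=n_free,
    )
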