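"""SMLM point-cloud analysis.

Coordinate-based colocalization (CBC) of two-channel localization tables,
Voronoi-tessellation segmentation of one-channel compartments with sizes
and densities, and pixel-based correlation controls (Pearson / Manders)
on rendered images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import QhullError, Voronoi, cKDTree
from scipy.stats import spearmanr
from shapely.geometry import Polygon, box
from shapely.ops import unary_union
from skimage.filters import threshold_otsu

__all__ = [
    "LocalizationTable",
    "CBCResult",
    "Compartment",
    "cbc",
    "co_occurrence_fraction",
    "voronoi_segment",
    "equivalent_diameter",
    "size_pdf",
    "render_and_correlate",
    "pearson_pixels",
    "manders",
]

LOC_COLUMNS = ["x_nm", "y_nm", "frame", "channel", "precision_nm"]

# segmentation defaults, calibrated so spatially random fields yield no
# compartments (uniform 10^4-point fields give clusters of up to ~20
# supra-threshold polygons at density_factor 2; see tests)
DEFAULT_DENSITY_FACTOR = 2.5
DEFAULT_MIN_POLYGONS = 20


@dataclass
class LocalizationTable:
    """2D localization table with columns x_nm, y_nm, frame, channel, precision_nm."""

    rows: pd.DataFrame
    bounds: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    def __post_init__(self) -> None:
        missing = [c for c in LOC_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")
        if (self.rows["precision_nm"] <= 0).any():
            raise ValueError("localization precision must be > 0")
        xmin, xmax, ymin, ymax = self.bounds
        x, y = self.rows["x_nm"], self.rows["y_nm"]
        if len(self.rows) and not (
            (x >= xmin).all() and (x <= xmax).all() and (y >= ymin).all() and (y <= ymax).all()
        ):
            raise ValueError("localizations outside field bounds")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def xy(self) -> np.ndarray:
        return self.rows[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @property
    def field_area_nm2(self) -> float:
        xmin, xmax, ymin, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)

    def channel(self, ch: int) -> "LocalizationTable":
        return LocalizationTable(
            self.rows[self.rows["channel"] == ch].reset_index(drop=True), self.bounds
        )

    @classmethod
    def from_csv(cls, path, bounds=None) -> "LocalizationTable":
        rows = pd.read_csv(path, comment="#")
        if bounds is None:
            bounds = (
                float(rows["x_nm"].min()),
                float(rows["x_nm"].max()),
                float(rows["y_nm"].min()),
                float(rows["y_nm"].max()),
            )
        return cls(rows, bounds)

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# bounds_nm={','.join(f'{b:g}' for b in self.bounds)}\n")
            self.rows.to_csv(fh, index=False)


@dataclass
class CBCResult:
    """Per-localization colocalization values CA in [-1, 1]."""

    ca: np.ndarray
    radii: np.ndarray
    rmax: float

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.size and (np.any(self.ca < -1) or np.any(self.ca > 1)):
            raise ValueError("CA values must lie in [-1, 1]")


@dataclass
class Compartment:
    """A merged group of dense Voronoi polygons."""

    member_ids: np.ndarray
    polygon: Polygon
    area_nm2: float
    n_localizations: int
    density: float  # count / merged area
    centroid: tuple[float, float]
    equivalent_diameter_nm: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.area_nm2 <= 0:
            raise ValueError("compartment area must be > 0")
        if self.density <= 0:
            raise ValueError("compartment density must be > 0")


def _xy(locs) -> np.ndarray:
    if isinstance(locs, LocalizationTable):
        return locs.xy
    return np.atleast_2d(np.asarray(locs, dtype=float))


def _neighbor_counts(points: np.ndarray, tree: cKDTree, radii: np.ndarray,
                     exclude_self: bool) -> np.ndarray:
    """Count of tree points within each radius for every query point."""
    rmax = radii[-1]
    counts = np.zeros((len(points), len(radii)), dtype=float)
    neighbors = tree.query_ball_point(points, rmax)
    for i, (p, idx) in enumerate(zip(points, neighbors)):
        if not idx:
            continue
        d = np.linalg.norm(tree.data[idx] - p, axis=1)
        if exclude_self:
            # drop exactly one zero-distance entry (the point itself)
            zero = np.flatnonzero(d == 0)
            if zero.size:
                d = np.delete(d, zero[0])
        d.sort()
        counts[i] = np.searchsorted(d, radii, side="right")
    return counts


def cbc(
    locs_a,
    locs_b,
    radii: np.ndarray | None = None,
    rmax: float = 300.0,
) -> CBCResult:
    """Coordinate-based colocalization of channel A against channel B.

    For every A-localization the area-normalized neighbor-density gradients
    D_AA(r) and D_AB(r) are computed over `radii`; the colocalization value
    is the Spearman rank correlation of the two gradients weighted by
    exp(-E_AB / rmax), where E_AB is the distance to the nearest B
    neighbor.  A point with no A or no B neighbors within `rmax` gets
    CA = 0.
    """
    a, b = _xy(locs_a), _xy(locs_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both localization tables must be non-empty")
    if radii is None:
        radii = np.arange(10.0, rmax + 1e-9, 10.0)
    radii = np.asarray(radii, dtype=float)
    if radii.size < 2:
        raise ValueError("need at least two radii")

    tree_a, tree_b = cKDTree(a), cKDTree(b)
    n_aa = _neighbor_counts(a, tree_a, radii, exclude_self=True)
    # a B-localization at exactly zero distance is treated as self in the
    # gradient (identical-channel control), but still sets E_AB = 0
    n_ab = _neighbor_counts(a, tree_b, radii, exclude_self=True)
    e_ab, _ = tree_b.query(a, k=1)

    ca = np.zeros(len(a))
    r2 = radii**2
    for i in range(len(a)):
        if n_aa[i, -1] == 0 or n_ab[i, -1] == 0:
            continue
        d_aa = n_aa[i] / r2 * radii[-1] ** 2 / n_aa[i, -1]
        d_ab = n_ab[i] / r2 * radii[-1] ** 2 / n_ab[i, -1]
        if np.ptp(d_aa) == 0 or np.ptp(d_ab) == 0:
            continue
        rho = spearmanr(d_aa, d_ab).statistic
        if not np.isfinite(rho):
            continue
        ca[i] = rho * np.exp(-e_ab[i] / rmax)
    return CBCResult(np.clip(ca, -1.0, 1.0), radii, float(rmax))


def co_occurrence_fraction(result: CBCResult, threshold: float = 0.5) -> float:
    """Fraction of localizations with CA above `threshold`."""
    if result.ca.size == 0:
        raise ValueError("empty CBC result")
    return float(np.mean(result.ca > threshold))


def _finite_voronoi_polygons(vor: Voronoi, bounds) -> list[Polygon]:
    """Clip Voronoi cells (including unbounded ones) to the bounding box."""
    xmin, xmax, ymin, ymax = bounds
    bbox = box(xmin, ymin, xmax, ymax)
    span = max(xmax - xmin, ymax - ymin) * 4 + 1.0
    center = vor.points.mean(axis=0)

    # far vertices for each unbounded ridge, keyed by (point, point) pair
    far: dict[tuple[int, int], list[np.ndarray]] = {}
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 >= 0 and v2 >= 0:
            continue
        finite = v2 if v1 < 0 else v1
        t = vor.points[p2] - vor.points[p1]
        t = t / np.linalg.norm(t)
        normal = np.array([-t[1], t[0]])
        midpoint = (vor.points[p1] + vor.points[p2]) / 2
        direction = np.sign(np.dot(midpoint - center, normal)) * normal
        far_pt = vor.vertices[finite] + direction * span
        for p in (p1, p2):
            far.setdefault((p, finite), []).append(far_pt)

    polys: list[Polygon] = []
    for i, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 not in region:
            poly = Polygon(vor.vertices[region])
        else:
            pts = [vor.vertices[v] for v in region if v >= 0]
            for (p, _v), fps in far.items():
                if p == i:
                    pts.extend(fps)
            if len(pts) < 3:
                polys.append(Polygon())
                continue
            pts = np.array(pts)
            hull_center = pts.mean(axis=0)
            order = np.argsort(np.arctan2(pts[:, 1] - hull_center[1], pts[:, 0] - hull_center[0]))
            poly = Polygon(pts[order])
        polys.append(poly.buffer(0).intersection(bbox))
    return polys


def voronoi_segment(
    locs: LocalizationTable,
    density_factor: float = DEFAULT_DENSITY_FACTOR,
    min_polygons: int = DEFAULT_MIN_POLYGONS,
    grid: float = 5.0,
) -> list[Compartment]:
    """Segment compartments from a Voronoi tessellation of localizations.

    Per-polygon density is the inverse polygon area; the segmentation
    threshold is ``density_factor`` times the average localization density
    (N / field area).  Supra-threshold polygons that touch are merged;
    merged groups with fewer than `min_polygons` members are discarded.
    The default ``density_factor`` is calibrated so that spatially random
    fields yield no compartments.
    """
    pts = _xy(locs)
    if len(pts) < 4:
        raise ValueError("need at least 4 localizations")
    bounds = locs.bounds if isinstance(locs, LocalizationTable) else (
        pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
    try:
        vor = Voronoi(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) localization input") from exc

    polys = _finite_voronoi_polygons(vor, bounds)
    areas = np.array([p.area for p in polys])
    with np.errstate(divide="ignore"):
        densities = np.where(areas > 0, 1.0 / areas, 0.0)

    field_area = (bounds[1] - bounds[0]) * (bounds[3] - bounds[2])
    threshold = density_factor * len(pts) / field_area
    dense = densities > threshold
    if not dense.any():
        return []

    # connect supra-threshold polygons that share a Voronoi ridge
    rp = vor.ridge_points
    edge_mask = dense[rp[:, 0]] & dense[rp[:, 1]]
    rows, cols = rp[edge_mask, 0], rp[edge_mask, 1]
    n = len(pts)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)

    compartments: list[Compartment] = []
    for comp_label in range(n_comp):
        members = np.flatnonzero((labels == comp_label) & dense)
        if len(members) < min_polygons:
            continue
        merged = unary_union([polys[m] for m in members])
        if merged.is_empty or merged.area <= 0:
            continue
        # centroid from member localizations: the merged outline is skewed
        # by large boundary cells reaching into sparse background
        cx, cy = pts[members].mean(axis=0)
        comp = Compartment(
            member_ids=members,
            polygon=merged,
            area_nm2=float(merged.area),
            n_localizations=len(members),
            density=len(members) / float(merged.area),
            centroid=(float(cx), float(cy)),
        )
        comp.equivalent_diameter_nm = equivalent_diameter(comp, grid=grid)
        compartments.append(comp)
    return compartments


def equivalent_diameter(compartment, grid: float = 5.0) -> float:
    """Equivalent diameter of a compartment outline rasterized on a grid.

    The outline is sampled on a square grid of `grid` nm, holes are filled,
    and the diameter of the circle with the same filled area is returned.
    """
    poly = compartment.polygon if isinstance(compartment, Compartment) else compartment
    if poly.is_empty:
        raise ValueError("compartment has no valid outline")
    xmin, ymin, xmax, ymax = poly.bounds
    xs = np.arange(xmin + grid / 2, xmax + grid / 2, grid)
    ys = np.arange(ymin + grid / 2, ymax + grid / 2, grid)
    if xs.size == 0 or ys.size == 0:
        return float(2 * np.sqrt(poly.area / np.pi))
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    inside = ndi.binary_fill_holes(inside)
    area = inside.sum() * grid**2
    if area == 0:
        area = poly.area
    return float(2 * np.sqrt(area / np.pi))


def size_pdf(diameters, bin_width: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Probability-density histogram: sum of (bar height x bin width) = 1."""
    diameters = np.asarray(diameters, dtype=float)
    if diameters.size == 0:
        raise ValueError("need at least one diameter")
    lo = np.floor(diameters.min() / bin_width) * bin_width
    hi = np.ceil(diameters.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    heights, edges = np.histogram(diameters, bins=edges, density=True)
    return heights, edges


def pearson_pixels(img_a: np.ndarray, img_b: np.ndarray) -> float:
    """Pearson correlation of two images over all pixels."""
    a, b = np.asarray(img_a, float).ravel(), np.asarray(img_b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def manders(img_a: np.ndarray, img_b: np.ndarray,
            thr_a: float | None = None, thr_b: float | None = None) -> tuple[float, float]:
    """Manders split coefficients on thresholded masks.

    M1 = fraction of supra-threshold A intensity falling where B is also
    supra-threshold; M2 symmetric.  Thresholds default to Otsu.
    """
    a, b = np.asarray(img_a, float), np.asarray(img_b, float)

    def _thr(img, given):
        if given is not None:
            return given
        if np.ptp(img) == 0:
            return img.min() - 1  # everything supra-threshold
        return threshold_otsu(img)

    mask_a = a > _thr(a, thr_a)
    mask_b = b > _thr(b, thr_b)
    sum_a = a[mask_a].sum()
    sum_b = b[mask_b].sum()
    m1 = float(a[mask_a & mask_b].sum() / sum_a) if sum_a > 0 else 0.0
    m2 = float(b[mask_a & mask_b].sum() / sum_b) if sum_b > 0 else 0.0
    return m1, m2


def render_image(locs, pixel: float = 20.0, bounds=None,
                 blur_sigma_nm: float | None = None) -> np.ndarray:
    """Render a localization table as a blurred 2D histogram image."""
    pts = _xy(locs)
    if bounds is None:
        bounds = locs.bounds
    xmin, xmax, ymin, ymax = bounds
    nx = max(int(np.ceil((xmax - xmin) / pixel)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel)), 1)
    img, _, _ = np.histogram2d(
        pts[:, 1], pts[:, 0],
        bins=(ny, nx), range=((ymin, ymin + ny * pixel), (xmin, xmin + nx * pixel)),
    )
    if blur_sigma_nm is None and isinstance(locs, LocalizationTable) and len(locs):
        blur_sigma_nm = float(locs.rows["precision_nm"].median())
    if blur_sigma_nm:
        img = ndi.gaussian_filter(img, blur_sigma_nm / pixel)
    return img


def render_and_correlate(locs_a, locs_b, pixel: float = 20.0) -> tuple[float, float, float]:
    """Render both channels and report (Pearson r, Manders M1, M2)."""
    if len(_xy(locs_a)) == 0 or len(_xy(locs_b)) == 0:
        raise ValueError("both localization tables must be non-empty")
    if isinstance(locs_a, LocalizationTable) and isinstance(locs_b, LocalizationTable):
        xmin = min(locs_a.bounds[0], locs_b.bounds[0])
        xmax = max(locs_a.bounds[1], locs_b.bounds[1])
        ymin = min(locs_a.bounds[2], locs_b.bounds[2])
        ymax = max(locs_a.bounds[3], locs_b.bounds[3])
        bounds = (xmin, xmax, ymin, ymax)
    else:
        pts = np.vstack([_xy(locs_a), _xy(locs_b)])
        bounds = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())
    img_a = render_image(locs_a, pixel, bounds)
    img_b = render_image(locs_b, pixel, bounds)
    r = pearson_pixels(img_a, img_b)
    m1, m2 = manders(img_a, img_b)
    return r, m1, m2
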