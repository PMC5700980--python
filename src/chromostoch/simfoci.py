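"""Nucleus segmentation and foci detection in 3D multi-channel voxel stacks.

Operates on reconstructed super-resolution stacks with anisotropic voxels
(default 39.5 nm lateral, 125 nm axial).  Nuclei are segmented from a
DAPI-like channel with a low-pass filter and per-plane thresholds; foci
are detected per channel by maximum-entropy thresholding of in-mask
intensities followed by connected-component labelling, with sub-voxel
centers of mass reported in nanometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelStack",
    "NucleusMask",
    "Focus",
    "CellFoci",
    "PRDistribution",
    "segment_nucleus",
    "max_entropy_threshold",
    "detect_foci",
    "pair_border_distances",
    "pairing_fraction",
    "pr_distribution",
    "average_pr",
    "radius_of_gyration",
    "dmax_from_pr",
]


@dataclass
class VoxelStack:
    """3D intensity grid in (z, y, x) order with anisotropic voxel sizes (nm)."""

    intensities: np.ndarray
    voxel_size_xy: float = 39.5
    voxel_size_z: float = 125.0
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (z, y, x) array")
        if min(self.intensities.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.voxel_size_xy <= 0 or self.voxel_size_z <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_xy**2 * self.voxel_size_z * 1e-9


@dataclass
class NucleusMask:
    """Boolean mask congruent with its stack."""

    mask: np.ndarray
    voxel_size_xy: float
    voxel_size_z: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_size_xy**2 * self.voxel_size_z * 1e-9


@dataclass
class Focus:
    """A detected focus: sub-voxel center of mass in nm, (x, y, z)."""

    center: tuple[float, float, float]
    n_voxels: int
    total_intensity: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")


@dataclass
class CellFoci:
    """Per-cell detected foci, keyed by channel."""

    cell_id: int
    foci: dict[str, list[Focus]] = field(default_factory=dict)
    nucleus_volume_um3: float = float("nan")

    def n_foci(self, channel: str) -> int:
        return len(self.foci.get(channel, []))


@dataclass
class PRDistribution:
    """Normalized pairwise-distance distribution p(r) with summary metrics."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    r_g: float
    d_max: float
    dmax_fraction: float = 0.97

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if self.probabilities.size and not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")


def segment_nucleus(
    dapi: VoxelStack,
    roi: tuple[int, int, int, int] | None = None,
    lowpass_sigma_nm: float = 100.0,
    plane_threshold: str = "otsu",
    k_sd: float = 1.0,
) -> NucleusMask:
    """Segment the nucleus from a DAPI-like channel.

    A Gaussian low-pass filter retains only large-scale (nuclear shape)
    information; a threshold is computed on every z-plane of the (optionally
    ROI-cropped) stack, and the average of the per-plane thresholds is
    applied to the whole 3D region.  The largest connected supra-threshold
    component is returned.

    Parameters
    ----------
    dapi : VoxelStack
        DAPI-like channel.
    roi : (y0, y1, x0, x1), optional
        Rectangular xy region of interest; all z-planes are kept.
    plane_threshold : {"otsu", "mean_sd"}
        Per-plane threshold rule.  ``"mean_sd"`` uses mean + `k_sd` * SD.

    Raises
    ------
    ValueError
        If the ROI exceeds the stack bounds or no supra-threshold voxels
        remain ("no nucleus found").
    """
    nz, ny, nx = dapi.shape
    if roi is None:
        roi = (0, ny, 0, nx)
    y0, y1, x0, x1 = roi
    if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"ROI {roi} outside stack xy bounds ({ny}, {nx})")

    sub = dapi.intensities[:, y0:y1, x0:x1]
    sigma_vox = (
        lowpass_sigma_nm / dapi.voxel_size_z,
        lowpass_sigma_nm / dapi.voxel_size_xy,
        lowpass_sigma_nm / dapi.voxel_size_xy,
    )
    smooth = ndi.gaussian_filter(sub, sigma=sigma_vox)

    # planes with little nuclear cross-section would contribute near-zero
    # thresholds and inflate the mask; keep only informative planes
    global_ptp = np.ptp(smooth)
    thresholds = []
    for plane in smooth:
        if np.ptp(plane) < 0.7 * global_ptp:
            continue
        if plane_threshold == "otsu":
            thresholds.append(threshold_otsu(plane))
        elif plane_threshold == "mean_sd":
            thresholds.append(plane.mean() + k_sd * plane.std())
        else:
            raise ValueError(f"unknown plane_threshold rule {plane_threshold!r}")
    if not thresholds:
        raise ValueError("no nucleus found: all planes are constant")

    thr = float(np.mean(thresholds))
    binary = smooth > thr
    if not binary.any():
        raise ValueError("no nucleus found: no voxels above averaged threshold")

    labels, n = ndi.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1

    mask = np.zeros(dapi.shape, dtype=bool)
    mask[:, y0:y1, x0:x1] = labels == keep
    return NucleusMask(mask, dapi.voxel_size_xy, dapi.voxel_size_z)


def max_entropy_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Kapur maximum-entropy threshold over a histogram of `values`.

    The returned level maximizes the sum of Shannon entropies of the
    background (below) and foreground (above) parts of the histogram.

    Raises
    ------
    ValueError
        If the input has fewer than two distinct values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or np.ptp(values) == 0:
        raise ValueError("degenerate histogram: need at least two distinct values")

    hist, edges = np.histogram(values, bins=nbins)
    p = hist / hist.sum()

    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    P = np.cumsum(p)                    # P[t] = mass of bins 0..t (background for cut t+1)
    S = np.cumsum(plogp)

    best_h, best_t = -np.inf, None
    for t in range(nbins - 1):          # cut between bin t and t+1
        p_bg, p_fg = P[t], 1.0 - P[t]
        if p_bg <= 0 or p_fg <= 0:
            continue
        h_bg = np.log(p_bg) - S[t] / p_bg
        h_fg = np.log(p_fg) - (S[-1] - S[t]) / p_fg
        if h_bg + h_fg > best_h:
            best_h, best_t = h_bg + h_fg, t
    if best_t is None:
        raise ValueError("degenerate histogram: no valid cut point")
    return float(edges[best_t + 1])


def detect_foci(
    stack: VoxelStack,
    mask: NucleusMask,
    threshold: float | None = None,
    min_voxels: int = 2,
    connectivity: int = 3,
) -> list[Focus]:
    """Detect foci as connected supra-threshold voxel groups inside the mask.

    The channel threshold defaults to the maximum-entropy threshold of
    in-mask intensities.  Components are 26-connected (``connectivity=3``)
    by default; components smaller than `min_voxels` are discarded.  Focus
    centers are intensity-weighted centers of mass converted to nm with
    anisotropic voxel scaling, reported as (x, y, z).
    """
    if stack.shape != mask.mask.shape:
        raise ValueError("stack and mask shapes differ")
    inside = stack.intensities[mask.mask]
    if inside.size == 0:
        return []
    if threshold is None:
        try:
            threshold = max_entropy_threshold(inside)
        except ValueError:
            return []

    binary = (stack.intensities > threshold) & mask.mask
    if not binary.any():
        return []

    structure = ndi.generate_binary_structure(3, connectivity)
    labels, n = ndi.label(binary, structure=structure)
    foci: list[Focus] = []
    idx = np.arange(1, n + 1)
    sizes = ndi.sum_labels(binary, labels, index=idx)
    coms = ndi.center_of_mass(stack.intensities, labels, index=idx)
    totals = ndi.sum_labels(stack.intensities, labels, index=idx)
    for size, com, total in zip(sizes, coms, totals):
        if size < min_voxels:
            continue
        cz, cy, cx = com
        center = (
            cx * stack.voxel_size_xy,
            cy * stack.voxel_size_xy,
            cz * stack.voxel_size_z,
        )
        foci.append(Focus(center, int(size), float(total), stack.channel))
    return foci


def _centers(foci) -> np.ndarray:
    if len(foci) and isinstance(foci[0], Focus):
        return np.array([f.center for f in foci], dtype=float)
    return np.atleast_2d(np.asarray(foci, dtype=float))


def pair_border_distances(foci_a, foci_b) -> np.ndarray:
    """Distance from each channel-A focus to its nearest channel-B focus (nm).

    Raises ``ValueError`` on an empty channel so the caller can skip the
    cell with a logged reason.
    """
    a, b = _centers(foci_a), _centers(foci_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty channel: cannot compute closest-foci distances")
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return np.asarray(d, dtype=float)


def pairing_fraction(cells: list[CellFoci], channel: str) -> tuple[float, float]:
    """Fraction of cells with exactly one focus in `channel`, with binomial SE."""
    if not cells:
        raise ValueError("need at least one cell")
    n = len(cells)
    k = sum(1 for c in cells if c.n_foci(channel) == 1)
    f = k / n
    se = float(np.sqrt(f * (1 - f) / n))
    return f, se


def pr_distribution(
    foci,
    bin_width: float = 100.0,
    bin_edges: np.ndarray | None = None,
    dmax_fraction: float = 0.97,
) -> PRDistribution:
    """Normalized histogram of all pairwise 3D distances between foci.

    Exactly ``n*(n-1)/2`` distances are counted and the histogram is
    normalized to sum to 1.  Also computes the radius of gyration and the
    `dmax_fraction` quantile distance D_max.
    """
    centers = _centers(foci)
    if len(centers) < 2:
        raise ValueError("need at least two foci for p(r)")
    dists = pdist(centers)
    if bin_edges is None:
        upper = max(dists.max(), bin_width)
        bin_edges = np.arange(0.0, upper + 2 * bin_width, bin_width)
    counts, bin_edges = np.histogram(dists, bins=bin_edges)
    probs = counts / counts.sum()
    pr = PRDistribution(bin_edges, probs, radius_of_gyration(centers), 0.0, dmax_fraction)
    pr.d_max = dmax_from_pr(pr, dmax_fraction)
    return pr


def average_pr(cells: list[PRDistribution]) -> PRDistribution:
    """Population-average p(r): mean of per-cell p(r) on shared bins."""
    if not cells:
        raise ValueError("need at least one p(r)")
    edges = cells[0].bin_edges
    for c in cells[1:]:
        if c.bin_edges.shape != edges.shape or not np.allclose(c.bin_edges, edges):
            raise ValueError("all p(r) must share the same bin edges")
    probs = np.mean([c.probabilities for c in cells], axis=0)
    probs = probs / probs.sum()
    frac = cells[0].dmax_fraction
    avg = PRDistribution(edges, probs, float(np.mean([c.r_g for c in cells])), 0.0, frac)
    avg.d_max = dmax_from_pr(avg, frac)
    return avg


def radius_of_gyration(foci) -> float:
    """Root-mean-square distance of foci centers from their centroid (nm)."""
    centers = _centers(foci)
    if len(centers) == 0:
        raise ValueError("need at least one focus")
    centroid = centers.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((centers - centroid) ** 2, axis=1))))


def dmax_from_pr(pr: PRDistribution, fraction: float = 0.97) -> float:
    """Smallest distance at which the cumulative p(r) area reaches `fraction`.

    Linear interpolation is used within the bin where the crossing occurs.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    cum = np.cumsum(pr.probabilities)
    idx = int(np.searchsorted(cum, fraction - 1e-12))
    idx = min(idx, len(pr.probabilities) - 1)
    prev = cum[idx - 1] if idx > 0 else 0.0
    p_bin = pr.probabilities[idx]
    lo, hi = pr.bin_edges[idx], pr.bin_edges[idx + 1]
    if p_bin <= 0:
        return float(lo)
    return float(lo + (fraction - prev) / p_bin * (hi - lo))
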