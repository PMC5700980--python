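"""Synthetic input generation with known ground truth.

Every downstream stage can be exercised without external data: 3D
multi-channel nucleus stacks with Gaussian-blob loci, paired-locus cell
populations with truncated-normal inter-border distances, freely jointed
polymer chains, clustered 2D localization fields, alternating ChIP domain
tracks, and distance-decaying contact matrices with multiplicative bin
biases.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chromdomains import GenomicTrack
from .hicmat import ContactMatrix
from .simfoci import VoxelStack
from .storm import LOC_COLUMNS, LocalizationTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_nucleus_stack",
    "generate_paired_loci_cells",
    "sample_polymer_distances",
    "generate_storm_field",
    "generate_chip_track",
    "generate_hic_matrix",
    "write_stack_tiff",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~= 2.355


@dataclass(frozen=True)
class SimConfig:
    """Imaging-simulation parameters (physical sizes in nm).

    PSF sigmas default to the stated optical resolutions (120 nm lateral,
    300 nm axial FWHM) divided by 2.355.
    """

    seed: int = 0
    voxel_size_xy: float = 39.5
    voxel_size_z: float = 125.0
    psf_sigma_xy: float = 120.0 / _FWHM   # ~= 51 nm
    psf_sigma_z: float = 300.0 / _FWHM    # ~= 127 nm
    nucleus_radii: tuple[float, float, float] = (2000.0, 2000.0, 1500.0)
    noise_level: float = 5.0
    field_size: tuple[float, float] = (10000.0, 10000.0)

    def __post_init__(self) -> None:
        for name in ("voxel_size_xy", "voxel_size_z", "psf_sigma_xy", "psf_sigma_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(r <= 0 for r in self.nucleus_radii):
            raise ValueError("nucleus radii must be > 0")
        if any(s <= 0 for s in self.field_size):
            raise ValueError("field size must be > 0")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + offset)


@dataclass
class GroundTruth:
    """Ground-truth record attached to every generated object."""

    positions_nm: dict = field(default_factory=dict)       # per channel / per cell
    pairing_state: np.ndarray | None = None
    distances_nm: np.ndarray | None = None
    compartments: pd.DataFrame | None = None               # center, diameter, count
    domains: pd.DataFrame | None = None                    # start, end, intensity
    biases: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def _convert(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, pd.DataFrame):
                return v.to_dict(orient="list")
            if isinstance(v, dict):
                return {k: _convert(x) for k, x in v.items()}
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            return v

        payload = {k: _convert(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _inside_ellipsoid(pos: np.ndarray, radii, center) -> bool:
    rel = (np.asarray(pos, float) - np.asarray(center, float)) / np.asarray(radii, float)
    return bool(np.sum(rel**2) <= 1.0)


def generate_nucleus_stack(
    config: SimConfig,
    loci: list[tuple[tuple[float, float, float], str, float]],
    margin_nm: float = 500.0,
) -> tuple[dict[str, VoxelStack], GroundTruth]:
    """Render a DAPI-like nucleus plus per-channel Gaussian-blob loci.

    `loci` is a list of ((x, y, z) position in nm, channel label,
    intensity).  The stack origin is at (0, 0, 0) nm and the nucleus
    ellipsoid is centered in the field.  Loci outside the nucleus are
    rejected.
    """
    rx, ry, rz = config.nucleus_radii
    center = (rx + margin_nm, ry + margin_nm, rz + margin_nm)
    extent = (2 * (rx + margin_nm), 2 * (ry + margin_nm), 2 * (rz + margin_nm))

    for pos, ch, _inten in loci:
        if not _inside_ellipsoid(pos, (rx, ry, rz), center):
            raise ValueError(
                f"locus at {tuple(pos)} nm (channel {ch!r}) lies outside the "
                f"nucleus ellipsoid centered at {center} with radii {(rx, ry, rz)}"
            )

    nx = int(np.ceil(extent[0] / config.voxel_size_xy))
    ny = int(np.ceil(extent[1] / config.voxel_size_xy))
    nz = int(np.ceil(extent[2] / config.voxel_size_z))
    # voxel-center coordinate axes in nm
    xs = (np.arange(nx) + 0.5) * config.voxel_size_xy
    ys = (np.arange(ny) + 0.5) * config.voxel_size_xy
    zs = (np.arange(nz) + 0.5) * config.voxel_size_z

    rng = config.rng()

    # DAPI: ellipsoid indicator smoothed by the PSF + Gaussian noise.  The
    # flat-top profile keeps the mid-intensity level set at the true
    # boundary, so threshold-based segmentation recovers the volume.
    rel2 = (
        ((zs[:, None, None] - center[2]) / rz) ** 2
        + ((ys[None, :, None] - center[1]) / ry) ** 2
        + ((xs[None, None, :] - center[0]) / rx) ** 2
    )
    from scipy import ndimage as ndi

    dapi = 100.0 * ndi.gaussian_filter(
        (rel2 <= 1.0).astype(float),
        sigma=(
            config.psf_sigma_z / config.voxel_size_z,
            config.psf_sigma_xy / config.voxel_size_xy,
            config.psf_sigma_xy / config.voxel_size_xy,
        ),
    )
    if config.noise_level > 0:
        dapi = dapi + rng.normal(0.0, config.noise_level, size=dapi.shape)
    stacks: dict[str, VoxelStack] = {
        "dapi": VoxelStack(np.clip(dapi, 0.0, None),
                           config.voxel_size_xy, config.voxel_size_z, "dapi")
    }

    channels = sorted({ch for _p, ch, _i in loci})
    for ch in channels:
        img = np.zeros((nz, ny, nx))
        for pos, locus_ch, inten in loci:
            if locus_ch != ch:
                continue
            x0, y0, z0 = pos
            gz = np.exp(-((zs - z0) ** 2) / (2 * config.psf_sigma_z**2))
            gy = np.exp(-((ys - y0) ** 2) / (2 * config.psf_sigma_xy**2))
            gx = np.exp(-((xs - x0) ** 2) / (2 * config.psf_sigma_xy**2))
            img += inten * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        if config.noise_level > 0:
            img = img + rng.normal(0.0, config.noise_level, size=img.shape)
        stacks[ch] = VoxelStack(np.clip(img, 0.0, None),
                                config.voxel_size_xy, config.voxel_size_z, ch)

    gt = GroundTruth(
        positions_nm={
            ch: np.array([p for p, c, _i in loci if c == ch], dtype=float)
            for ch in channels
        },
        extra={"center_nm": center, "shape_zyx": (nz, ny, nx)},
    )
    return stacks, gt


def _uniform_in_ellipsoid(rng, radii, center, size):
    """Rejection-sample points uniformly inside an axis-aligned ellipsoid."""
    out = np.empty((size, 3))
    done = 0
    while done < size:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (size - done) + 8, 3))
        keep = cand[np.sum(cand**2, axis=1) <= 1.0]
        take = min(len(keep), size - done)
        out[done : done + take] = keep[:take]
        done += take
    return out * np.asarray(radii, float) + np.asarray(center, float)


def _random_directions(rng, size):
    v = rng.normal(size=(size, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _truncnorm(rng, mu, sigma, size):
    """Normal(mu, sigma) truncated at 0, sampled via scipy's truncnorm."""
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size,
                               random_state=rng)


def generate_paired_loci_cells(
    n_cells: int,
    n_loci: int,
    pairing_prob: float,
    distance_model: tuple[float, float],
    config: SimConfig,
    homolog_offset_nm: tuple[float, float] = (800.0, 200.0),
) -> tuple[list[dict[str, np.ndarray]], GroundTruth]:
    """Generate per-cell two-channel locus positions with homolog pairing.

    Each locus is "paired" (one position) with probability `pairing_prob`,
    otherwise two homolog positions separated by an isotropic offset drawn
    from Normal(`homolog_offset_nm`) truncated at 0.  Channel-B partners sit
    at a truncated-normal `distance_model` = (mu, sigma) distance from each
    channel-A position, in a random direction.
    """
    mu, sigma = distance_model
    if not (0.0 <= pairing_prob <= 1.0):
        raise ValueError("pairing probability must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("distance-model sigma must be > 0")
    if stats.norm.cdf(0.0, loc=mu, scale=sigma) > 0.5:
        warnings.warn(
            "distance model truncates more than 50% of its mass at 0; "
            "the realized distance distribution will be far from Gaussian"
        )

    rng = config.rng()
    radii = config.nucleus_radii
    center = radii  # nucleus centered at (rx, ry, rz)

    cells: list[dict[str, np.ndarray]] = []
    paired = rng.random((n_cells, n_loci)) < pairing_prob
    all_distances: list[float] = []
    for c in range(n_cells):
        base = _uniform_in_ellipsoid(rng, radii, center, n_loci)
        pos_a: list[np.ndarray] = []
        for l in range(n_loci):
            pos_a.append(base[l])
            if not paired[c, l]:
                offset = _truncnorm(rng, *homolog_offset_nm, 1)[0]
                pos_a.append(base[l] + _random_directions(rng, 1)[0] * offset)
        pos_a = np.array(pos_a)
        d = _truncnorm(rng, mu, sigma, len(pos_a))
        pos_b = pos_a + _random_directions(rng, len(pos_a)) * d[:, None]
        all_distances.extend(d)
        cells.append({"A": pos_a, "B": pos_b})

    gt = GroundTruth(
        pairing_state=paired,
        distances_nm=np.array(all_distances),
        extra={"n_cells": n_cells, "n_loci": n_loci, "pairing_prob": pairing_prob},
    )
    return cells, gt


def sample_polymer_distances(
    n_segments: int,
    kb_per_segment: float,
    bond_nm: float,
    subchain_lengths_kb: list[float],
    n_chains: int,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """End-to-end distances of freely jointed random-walk subchains.

    Chains are 3D random walks of `n_segments` fixed-length bonds; for each
    genomic subchain length the Euclidean end-to-end distance from the
    chain start is recorded per chain.  Subchain lengths must be multiples
    of `kb_per_segment` and no longer than the chain.
    """
    if bond_nm <= 0 or kb_per_segment <= 0:
        raise ValueError("bond length and kb_per_segment must be > 0")
    n_sub = []
    for length_kb in subchain_lengths_kb:
        m = length_kb / kb_per_segment
        if abs(m - round(m)) > 1e-9:
            raise ValueError(
                f"subchain length {length_kb} kb is not a multiple of "
                f"{kb_per_segment} kb/segment"
            )
        m = int(round(m))
        if m < 1 or m > n_segments:
            raise ValueError(f"subchain of {m} segments exceeds chain of {n_segments}")
        n_sub.append(m)

    rng = np.random.default_rng(seed)
    samples = {length_kb: np.empty(n_chains) for length_kb in subchain_lengths_kb}
    for c in range(n_chains):
        steps = _random_directions(rng, n_segments) * bond_nm
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        for length_kb, m in zip(subchain_lengths_kb, n_sub):
            samples[length_kb][c] = np.linalg.norm(pos[m] - pos[0])
    return samples


def _draw(dist, rng, size=None):
    """Draw from a scalar, a (mean, sd) lognormal-free normal spec, or a callable."""
    if callable(dist):
        return dist(rng) if size is None else np.array([dist(rng) for _ in range(size)])
    if np.isscalar(dist):
        return float(dist) if size is None else np.full(size, float(dist))
    raise TypeError("distribution must be a scalar or a callable(rng)")


def generate_storm_field(
    n_compartments: int,
    diameter_dist,
    locs_per_compartment: int,
    background_density_um2: float,
    field_size: tuple[float, float],
    two_channel_mode: str | None = None,
    seed: int = 0,
    precision_nm: float = 15.0,
    max_tries: int = 10000,
) -> tuple[LocalizationTable, GroundTruth]:
    """Generate a clustered 2D localization field.

    Compartments are uniform discs (diameters from `diameter_dist`, a
    scalar or ``callable(rng) -> nm``) placed without overlap; the
    background is a homogeneous Poisson field of `background_density_um2`
    points per square micron.  With `two_channel_mode`:

    - ``"co-occurring"``: channel 2 discs coincide with channel 1 discs;
    - ``"segregated"``: channel 2 discs are disjoint from channel 1 discs;
    - ``"independent"``: channel 2 discs placed without regard to channel 1.
    """
    if background_density_um2 < 0:
        raise ValueError("background density must be >= 0")
    rng = np.random.default_rng(seed)
    fx, fy = field_size

    def _place_discs(n, avoid):
        discs = []
        tries = 0
        while len(discs) < n:
            if tries >= max_tries:
                raise RuntimeError(
                    f"could not place {n} non-overlapping compartments in the "
                    f"field after {max_tries} tries"
                )
            tries += 1
            diameter = float(_draw(diameter_dist, rng))
            r = diameter / 2
            if 2 * r >= min(fx, fy):
                raise ValueError("compartment does not fit inside the field")
            cx = rng.uniform(r, fx - r)
            cy = rng.uniform(r, fy - r)
            ok = all(
                np.hypot(cx - ox, cy - oy) > r + orr
                for ox, oy, orr in [(d[0], d[1], d[2] / 2) for d in discs + avoid]
            )
            if ok:
                discs.append((cx, cy, diameter))
        return discs

    def _disc_points(discs):
        pts, ids = [], []
        for k, (cx, cy, diameter) in enumerate(discs):
            r = diameter / 2 * np.sqrt(rng.random(locs_per_compartment))
            theta = rng.uniform(0, 2 * np.pi, locs_per_compartment)
            pts.append(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))
            ids.extend([k] * locs_per_compartment)
        return (np.vstack(pts) if pts else np.empty((0, 2))), ids

    def _background():
        lam = background_density_um2 * (fx * fy) * 1e-6
        n = rng.poisson(lam)
        return np.column_stack([rng.uniform(0, fx, n), rng.uniform(0, fy, n)])

    discs1 = _place_discs(n_compartments, avoid=[])
    pts1, _ = _disc_points(discs1)
    bg1 = _background()
    xy1 = np.vstack([pts1, bg1])
    channels = [np.ones(len(xy1), dtype=int)]
    xy_all = [xy1]

    discs2 = []
    if two_channel_mode is not None:
        if two_channel_mode == "co-occurring":
            discs2 = list(discs1)
        elif two_channel_mode == "segregated":
            discs2 = _place_discs(n_compartments, avoid=discs1)
        elif two_channel_mode == "independent":
            discs2 = _place_discs(n_compartments, avoid=[])
        else:
            raise ValueError(f"unknown two_channel_mode {two_channel_mode!r}")
        pts2, _ = _disc_points(discs2)
        bg2 = _background()
        xy2 = np.vstack([pts2, bg2])
        xy_all.append(xy2)
        channels.append(np.full(len(xy2), 2, dtype=int))

    xy = np.vstack(xy_all)
    channel = np.concatenate(channels)
    rows = pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "frame": np.arange(len(xy)),
            "channel": channel,
            "precision_nm": precision_nm,
        }
    )[LOC_COLUMNS]
    table = LocalizationTable(rows, (0.0, fx, 0.0, fy))

    def _disc_frame(discs):
        return pd.DataFrame(discs, columns=["x_nm", "y_nm", "diameter_nm"]).assign(
            n_localizations=locs_per_compartment
        )

    gt = GroundTruth(
        compartments=_disc_frame(discs1),
        extra={
            "n_background_ch1": len(bg1),
            "mode": two_channel_mode,
            "compartments_ch2": _disc_frame(discs2).to_dict(orient="list")
            if discs2
            else None,
        },
    )
    return table, gt


def generate_chip_track(
    genome_length_bp: int,
    domain_size_dist,
    gap_dist,
    intensity_dist,
    seed: int = 0,
    chrom: str = "chr",
) -> tuple[GenomicTrack, GroundTruth]:
    """Generate alternating domain/gap intervals tiling a genome.

    Distributions are scalars or ``callable(rng) -> value``.  Each domain
    is emitted as one scored peak; coordinates are 0-based half-open.  The
    final interval is truncated at the genome end.
    """
    rng = np.random.default_rng(seed)
    first_domain = max(int(round(_draw(domain_size_dist, rng))), 1)
    if genome_length_bp < first_domain:
        raise ValueError(
            f"genome of {genome_length_bp} bp is shorter than the first domain "
            f"({first_domain} bp)"
        )

    peaks, domains = [], []
    pos = 0
    pending_domain = first_domain
    while pos < genome_length_bp:
        end = min(pos + pending_domain, genome_length_bp)
        intensity = float(_draw(intensity_dist, rng))
        peaks.append((chrom, pos, end, intensity))
        domains.append((pos, end, intensity))
        pos = end
        if pos >= genome_length_bp:
            break
        gap = max(int(round(_draw(gap_dist, rng))), 1)
        pos = min(pos + gap, genome_length_bp)
        pending_domain = max(int(round(_draw(domain_size_dist, rng))), 1)

    track = GenomicTrack(
        pd.DataFrame(peaks, columns=["chrom", "start", "end", "intensity"]),
        genome_length_bp,
    )
    gt = GroundTruth(
        domains=pd.DataFrame(domains, columns=["start", "end", "intensity"]),
        extra={"genome_length_bp": genome_length_bp},
    )
    return track, gt


def generate_hic_matrix(
    n_bins: int,
    bin_size_bp: int,
    decay_exponent: float,
    tad_blocks: list[tuple[int, int, float]] | None = None,
    bias_sd: float = 0.0,
    noise: str = "none",
    seed: int = 0,
    scale: float = 100.0,
) -> tuple[ContactMatrix, GroundTruth]:
    """Generate a distance-decaying contact matrix with multiplicative biases.

    Expected counts are ``scale * (|i-j| + 1) ** -decay_exponent`` times any
    TAD-block boost and the bias outer product b_i * b_j, with lognormal
    biases normalized to geometric mean 1.  ``noise="poisson"`` samples a
    symmetric Poisson realization of the expectation.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if decay_exponent <= 0:
        raise ValueError("decay exponent must be > 0")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise mode {noise!r}")

    rng = np.random.default_rng(seed)
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = scale * (dist + 1.0) ** (-decay_exponent)

    boost = np.ones((n_bins, n_bins))
    for start, end, factor in tad_blocks or []:
        boost[start:end, start:end] *= factor
    expected *= boost

    if bias_sd > 0:
        b = rng.lognormal(mean=0.0, sigma=bias_sd, size=n_bins)
        b /= np.exp(np.mean(np.log(b)))  # geometric mean 1
    else:
        b = np.ones(n_bins)
    expected *= np.outer(b, b)

    if noise == "poisson":
        upper = rng.poisson(np.triu(expected))
        counts = np.triu(upper) + np.triu(upper, 1).T
        counts = counts.astype(float)
    else:
        counts = expected

    mat = ContactMatrix(counts, bin_size_bp)
    gt = GroundTruth(
        biases=b,
        extra={
            "decay_exponent": decay_exponent,
            "scale": scale,
            "tad_blocks": tad_blocks or [],
            "expected": expected,
        },
    )
    return mat, gt


def write_stack_tiff(stack: VoxelStack, path) -> None:
    """Write a voxel stack as a multi-page TIFF (one page per z-plane)."""
    import tifffile

    tifffile.imwrite(
        path,
        stack.intensities.astype(np.float32),
        metadata={
            "voxel_size_xy_nm": stack.voxel_size_xy,
            "voxel_size_z_nm": stack.voxel_size_z,
            "channel": stack.channel,
        },
    )


def read_stack_tiff(path, voxel_size_xy: float = 39.5, voxel_size_z: float = 125.0,
                    channel: str = "") -> VoxelStack:
    import tifffile

    data = tifffile.imread(path)
    return VoxelStack(np.asarray(data, dtype=float), voxel_size_xy, voxel_size_z, channel)
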