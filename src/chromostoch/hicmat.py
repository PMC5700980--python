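"""Dense contact-matrix utilities.

Reading/writing whitespace-delimited dense matrices with BED3 bin tables,
low-coverage bin filtering, iterative-correction (ICE) normalization with
a 10%-change / 10-iteration stopping rule and mean-1 rescaling,
distance-decay profiles with random-pair baselines, pairwise count
extraction, and cross-condition log2-ratio matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "ICEResult",
    "read_matrix",
    "write_matrix",
    "filter_low_bins",
    "ice_normalize",
    "distance_decay",
    "extract_pairwise_counts",
    "ratio_matrix",
]


@dataclass
class ContactMatrix:
    """Square symmetric contact counts with a bin table and valid-bin mask."""

    counts: np.ndarray
    bin_size_bp: int
    chrom: str = "chr"
    bins: pd.DataFrame | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape[1] != n:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        asym = np.abs(self.counts - self.counts.T).max()
        if asym > 1e-9 * max(np.abs(self.counts).max(), 1.0):
            raise ValueError("counts matrix is not symmetric")
        if self.bins is None:
            starts = np.arange(n) * self.bin_size_bp
            self.bins = pd.DataFrame(
                {"chrom": self.chrom, "start": starts, "end": starts + self.bin_size_bp}
            )
        if len(self.bins) != n:
            raise ValueError("bin table length does not match matrix size")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (n,):
            raise ValueError("valid mask length does not match matrix size")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class ICEResult:
    """Outcome of ICE normalization."""

    biases: np.ndarray          # NaN on masked bins
    normalized: ContactMatrix
    n_iterations: int
    converged: bool
    final_max_rel_change: float


def read_matrix(path, bins_path=None, bin_size_bp: int | None = None) -> ContactMatrix:
    """Read a dense whitespace-delimited matrix and optional BED3 bin table.

    The matrix is validated (square, finite) and symmetrized by averaging
    when the relative asymmetry is below 1%; larger asymmetry is an error.
    """
    counts = np.loadtxt(path, ndmin=2)
    if counts.shape[0] != counts.shape[1]:
        raise ValueError(f"matrix is not square: shape {counts.shape}")
    bad = np.argwhere(~np.isfinite(counts))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-finite matrix entry at row {i}, column {j}")
    scale = max(np.abs(counts).max(), 1e-300)
    asym = np.abs(counts - counts.T).max() / scale
    if asym >= 0.01:
        raise ValueError(f"matrix asymmetry {asym:.3f} exceeds 1% tolerance")
    counts = (counts + counts.T) / 2

    bins = None
    chrom = "chr"
    if bins_path is not None:
        bins = pd.read_csv(bins_path, sep="\t", header=None,
                           names=["chrom", "start", "end"], comment="#")
        if len(bins) != counts.shape[0]:
            raise ValueError(
                f"bin table has {len(bins)} rows for a {counts.shape[0]}-bin matrix"
            )
        chrom = str(bins["chrom"].iloc[0])
        if bin_size_bp is None:
            bin_size_bp = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    if bin_size_bp is None:
        bin_size_bp = 1
    return ContactMatrix(counts, bin_size_bp, chrom, bins)


def write_matrix(mat: ContactMatrix, path, bins_path=None) -> None:
    np.savetxt(path, mat.counts, fmt="%.10g")
    if bins_path is not None:
        mat.bins.to_csv(bins_path, sep="\t", header=False, index=False)


def filter_low_bins(mat: ContactMatrix, percentile: float = 2.0) -> ContactMatrix:
    """Mask bins with zero or low marginal contact counts.

    Bins whose marginal (row sum over currently valid columns) is zero or
    strictly below the `percentile` cutoff of nonzero marginals are masked.
    """
    marg = mat.counts[:, mat.valid].sum(axis=1)
    valid = mat.valid & (marg > 0)
    nonzero = marg[valid]
    if nonzero.size:
        cutoff = np.percentile(nonzero, percentile)
        valid &= marg >= cutoff
    if not valid.any():
        raise ValueError("all bins masked by low-coverage filter")
    return ContactMatrix(mat.counts, mat.bin_size_bp, mat.chrom, mat.bins, valid)


def ice_normalize(
    mat: ContactMatrix, tol: float = 0.10, max_iter: int = 10
) -> ICEResult:
    """Iterative correction of a filtered contact matrix.

    Each round, per-bin biases are updated by the ratio of the bin's
    marginal to the mean marginal and the matrix is divided by the bias
    outer product.  Iteration stops when the maximum relative per-bin bias
    change drops below `tol`, or after `max_iter` rounds.  The corrected
    matrix is finally rescaled so the mean over valid entries equals 1.
    """
    idx = np.flatnonzero(mat.valid)
    if idx.size < 2:
        raise ValueError("need at least 2 valid bins for ICE")
    w = mat.counts[np.ix_(idx, idx)].copy()
    b = np.ones(idx.size)

    n_it, change, converged = 0, np.inf, False
    for n_it in range(1, max_iter + 1):
        s = w.sum(axis=1)
        mean_s = s.mean()
        if mean_s <= 0:
            raise RuntimeError(f"ICE diverged at iteration {n_it}: zero marginals")
        delta = s / mean_s
        if np.any(delta <= 0) or not np.all(np.isfinite(delta)):
            raise RuntimeError(f"ICE diverged at iteration {n_it}: non-finite biases")
        w /= np.outer(delta, delta)
        b *= delta
        change = float(np.abs(delta - 1.0).max())
        if change < tol:
            converged = True
            break

    mean_entry = w.mean()
    if mean_entry <= 0:
        raise RuntimeError("normalized matrix has non-positive mean")
    w /= mean_entry

    full = np.zeros_like(mat.counts)
    full[np.ix_(idx, idx)] = w
    biases = np.full(mat.n_bins, np.nan)
    biases[idx] = b
    normalized = ContactMatrix(full, mat.bin_size_bp, mat.chrom, mat.bins, mat.valid)
    return ICEResult(biases, normalized, n_it, converged, change)


def distance_decay(
    mat: ContactMatrix,
    loci: np.ndarray | None = None,
    n_random: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean count vs genomic distance for locus pairs, with a random baseline.

    With `loci` given (bin indices), all pairs among them on valid bins are
    grouped by genomic distance; pairs on masked bins are skipped (count
    reported in the ``n_skipped`` attribute of the returned frame).  The
    baseline draws up to `n_random` random valid-bin pairs at each distance.
    Without `loci`, the profile runs over all valid pairs per distance.
    """
    rng = np.random.default_rng(seed)
    valid = mat.valid
    n = mat.n_bins
    records = []
    n_skipped = 0

    if loci is None:
        pair_dist: dict[int, list[float]] = {}
        vidx = np.flatnonzero(valid)
        for a in range(len(vidx)):
            for bdx in range(a + 1, len(vidx)):
                i, j = vidx[a], vidx[bdx]
                pair_dist.setdefault(j - i, []).append(mat.counts[i, j])
        dists = sorted(pair_dist)
    else:
        loci = np.asarray(loci, dtype=int)
        pair_dist = {}
        for a in range(len(loci)):
            for bdx in range(a + 1, len(loci)):
                i, j = sorted((loci[a], loci[bdx]))
                if not (valid[i] and valid[j]):
                    n_skipped += 1
                    continue
                pair_dist.setdefault(j - i, []).append(mat.counts[i, j])
        dists = sorted(pair_dist)

    vmask = valid
    for d in dists:
        vals = pair_dist[d]
        ok = vmask[: n - d] & vmask[d:]
        cand = np.flatnonzero(ok)
        if cand.size:
            pick = rng.choice(cand, size=min(n_random, cand.size * 4), replace=True)
            baseline = float(np.mean(mat.counts[pick, pick + d]))
        else:
            baseline = float("nan")
        records.append(
            {
                "distance_bins": d,
                "distance_bp": d * mat.bin_size_bp,
                "mean_count": float(np.mean(vals)),
                "n_pairs": len(vals),
                "baseline": baseline,
            }
        )
    out = pd.DataFrame(records)
    out.attrs["n_skipped"] = n_skipped
    return out


def extract_pairwise_counts(mat: ContactMatrix, loci) -> pd.DataFrame:
    """All C(n,2) locus-pair counts as a tidy table."""
    loci = np.asarray(loci, dtype=int)
    if loci.size < 2:
        raise ValueError("need at least two loci")
    rows = []
    for a in range(len(loci)):
        for b in range(a + 1, len(loci)):
            i, j = loci[a], loci[b]
            rows.append(
                {
                    "locus_i": int(i),
                    "locus_j": int(j),
                    "distance_bp": abs(j - i) * mat.bin_size_bp,
                    "count": float(mat.counts[i, j]),
                }
            )
    return pd.DataFrame(rows)


def ratio_matrix(
    mat_a: ContactMatrix, mat_b: ContactMatrix, pseudocount: float = 1e-3
) -> ContactMatrix:
    """log2((A + eps) / (B + eps)) on the intersection of valid bins."""
    if mat_a.n_bins != mat_b.n_bins or not mat_a.bins[["start", "end"]].equals(
        mat_b.bins[["start", "end"]]
    ):
        raise ValueError("bin tables differ between matrices")
    joint = mat_a.valid & mat_b.valid
    ratio = np.log2((mat_a.counts + pseudocount) / (mat_b.counts + pseudocount))
    ratio[~joint, :] = 0.0
    ratio[:, ~joint] = 0.0
    out = ContactMatrix.__new__(ContactMatrix)
    out.counts = ratio  # may be negative; bypass non-negativity validation
    out.bin_size_bp = mat_a.bin_size_bp
    out.chrom = mat_a.chrom
    out.bins = mat_a.bins
    out.valid = joint
    return out
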