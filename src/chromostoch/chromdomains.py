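"""Genome-wide domain pipeline.

Peak tracks are resampled into a continuous signal, thresholded in log
space, and turned into domains: segments longer than 2 bp are kept,
domains closer than 1 kb are fused, and genomic lengths are converted
into predicted physical sizes through an empirical power law.  A
clustering percentage compares predicted sizes against imaged compartment
diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicTrack",
    "DomainSet",
    "peaks_to_signal",
    "call_domains",
    "genomic_to_physical",
    "clustering_percentage",
]

#: domains shorter than this are excluded from size-distribution reporting
ROBUST_MIN_LEN_BP = 3000


@dataclass
class GenomicTrack:
    """Scored intervals (0-based, half-open) on a single chromosome."""

    intervals: pd.DataFrame  # columns chrom, start, end, intensity
    genome_length_bp: int

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        required = {"chrom", "start", "end", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        if (df["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if not df["start"].is_monotonic_increasing:
            warnings.warn("unsorted track: sorting intervals by start")
            df = df.sort_values("start", kind="stable").reset_index(drop=True)
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path, genome_length_bp: int | None = None) -> "GenomicTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        track = df[["chrom", "start", "end"]].copy()
        track["intensity"] = df["score"].astype(float)
        if genome_length_bp is None:
            genome_length_bp = int(track["end"].max())
        return cls(track, genome_length_bp)

    def to_bed(self, path) -> None:
        df = self.intervals
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": [f"peak_{i}" for i in range(len(df))],
            "score": df["intensity"],
            "strand": ".",
        })
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class DomainSet:
    """Called genomic domains, optionally with predicted physical sizes."""

    domains: pd.DataFrame  # columns chrom, start, end, length_bp [, size_nm, state]
    mark: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        df = self.domains
        if len(df) and (df["length_bp"] != df["end"] - df["start"]).any():
            raise ValueError("length_bp must equal end - start")

    def __len__(self) -> int:
        return len(self.domains)

    @property
    def lengths_bp(self) -> np.ndarray:
        return self.domains["length_bp"].to_numpy(dtype=float)

    def reportable(self, min_len_bp: int = ROBUST_MIN_LEN_BP) -> "DomainSet":
        """Restrict to domains at or above the robustness bound for reporting."""
        kept = self.domains[self.domains["length_bp"] >= min_len_bp].reset_index(drop=True)
        return DomainSet(kept, self.mark, self.state)


def peaks_to_signal(
    track: GenomicTrack, resolution_bp: int = 10
) -> tuple[np.ndarray, int]:
    """Resample a peak track into a continuous per-bin signal.

    Each bin gets the sum of overlapping peak intensities, weighted by the
    fraction of the bin each peak covers.  Returns (signal, resolution_bp).
    """
    n_bins = int(np.ceil(track.genome_length_bp / resolution_bp))
    signal = np.zeros(n_bins)
    for start, end, intensity in track.intervals[["start", "end", "intensity"]].itertuples(
        index=False
    ):
        end = min(end, track.genome_length_bp)
        b0 = int(start // resolution_bp)
        b1 = min(int(np.ceil(end / resolution_bp)), n_bins)
        if b1 - b0 == 1:
            signal[b0] += intensity * (end - start) / resolution_bp
            continue
        signal[b0] += intensity * ((b0 + 1) * resolution_bp - start) / resolution_bp
        signal[b0 + 1 : b1 - 1] += intensity
        signal[b1 - 1] += intensity * (end - (b1 - 1) * resolution_bp) / resolution_bp
    return signal, resolution_bp


def call_domains(
    signal: np.ndarray,
    resolution_bp: int = 10,
    log_threshold_frac: float = 0.1,
    min_len_bp: int = 2,
    fuse_gap_bp: int = 1000,
    chrom: str = "chr",
) -> DomainSet:
    """Call domains from a continuous signal.

    The signal is log-compressed (``ln(signal + 1)``) and thresholded at
    `log_threshold_frac` of the log maximum, so that even low-intensity
    peaks are retained.  Maximal supra-threshold runs become candidate
    domains; domains of length <= `min_len_bp` are dropped and domains
    separated by less than `fuse_gap_bp` are fused.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be non-negative")
    empty = pd.DataFrame(columns=["chrom", "start", "end", "length_bp"])
    if signal.size == 0 or signal.max() == 0:
        return DomainSet(empty)

    log_sig = np.log1p(signal)
    thr = log_threshold_frac * log_sig.max()
    keep = (log_sig > thr) & (signal > 0)

    # maximal runs of kept bins
    padded = np.concatenate([[False], keep, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts_bin, ends_bin = edges[::2], edges[1::2]
    starts = starts_bin * resolution_bp
    ends = np.minimum(ends_bin * resolution_bp, len(signal) * resolution_bp)

    lengths = ends - starts
    ok = lengths > min_len_bp
    starts, ends = starts[ok], ends[ok]

    fused: list[list[int]] = []
    for s, e in zip(starts, ends):
        if fused and s - fused[-1][1] < fuse_gap_bp:
            fused[-1][1] = max(fused[-1][1], e)
        else:
            fused.append([int(s), int(e)])
    if not fused:
        return DomainSet(empty)

    df = pd.DataFrame(fused, columns=["start", "end"])
    df.insert(0, "chrom", chrom)
    df["length_bp"] = df["end"] - df["start"]
    return DomainSet(df)


def genomic_to_physical(domains: DomainSet, fits) -> DomainSet:
    """Predict physical domain sizes from genomic lengths via a power law.

    ``fits`` is either a single power-law fit (``prefactor`` A in nm,
    ``exponent`` beta over lengths in kb) or a mapping from chromatin-state
    label to fit.  size_nm = A * length_kb ** beta.
    """
    df = domains.domains.copy()
    if hasattr(fits, "items"):
        if domains.state not in fits:
            raise KeyError(
                f"no power-law fit for chromatin state {domains.state!r}; "
                f"available: {sorted(fits)}"
            )
        fit = fits[domains.state]
    else:
        fit = fits
    if fit.prefactor <= 0:
        raise ValueError("power-law prefactor must be > 0")
    length_kb = df["length_bp"].to_numpy(dtype=float) / 1e3
    df["size_nm"] = fit.prefactor * length_kb**fit.exponent
    return DomainSet(df, domains.mark, domains.state)


def clustering_percentage(
    predicted_sizes_nm,
    observed_diameters_nm,
    cutoff_nm: float = 150.0,
    predicted_scale: float = 1.0,
) -> tuple[float, float, list[float]]:
    """Percentage of large imaged compartments unexplained by predicted domains.

    For each cell, with N_pred the (scaled) count of predicted sizes above
    `cutoff_nm` and N_obs the count of observed compartment diameters above
    it, the clustering percentage is ``max(0, 1 - N_pred / N_obs) * 100``.
    `observed_diameters_nm` may be one array (one cell) or a list of
    per-cell arrays; cells with N_obs = 0 are reported missing.

    Returns (mean %, SD %, per-cell %).
    """
    predicted = np.asarray(predicted_sizes_nm, dtype=float)
    if predicted.size == 0:
        raise ValueError("predicted sizes must be non-empty")
    if np.ndim(observed_diameters_nm[0]) == 0:
        cells = [np.asarray(observed_diameters_nm, dtype=float)]
    else:
        cells = [np.asarray(c, dtype=float) for c in observed_diameters_nm]
    if not cells or all(c.size == 0 for c in cells):
        raise ValueError("observed diameters must be non-empty")

    n_pred = float(np.sum(predicted > cutoff_nm)) * predicted_scale
    per_cell: list[float] = []
    for obs in cells:
        n_obs = float(np.sum(obs > cutoff_nm))
        if n_obs == 0:
            per_cell.append(float("nan"))
            continue
        per_cell.append(max(0.0, 1.0 - n_pred / n_obs) * 100.0)
    valid = [v for v in per_cell if np.isfinite(v)]
    if not valid:
        return float("nan"), float("nan"), per_cell
    return float(np.mean(valid)), float(np.std(valid)), per_cell
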