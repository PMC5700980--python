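"""Distance-sample statistics.

Gaussian fits to inter-locus distance distributions, absolute contact
probabilities below a colocalization cutoff, dispersion-distance and
power-law / exponential calibration fits, chromatin scaling exponents
from end-to-end distances, and the resolvable-foci pairing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DistanceSample",
    "GaussianFit",
    "ContactEstimate",
    "PowerLawFit",
    "ExponentialFit",
    "ScalingSample",
    "PairingModel",
    "LinearFit",
    "fit_gaussian",
    "contact_probability",
    "dispersion_vs_distance",
    "fit_power_law",
    "fit_exponential",
    "scaling_exponent",
    "expected_resolvable_foci",
    "hic_vs_probability",
]

#: colocalization cutoff (nm) used for absolute contact probability
DEFAULT_CONTACT_CUTOFF_NM = 120.0
#: two-color colocalization resolution floor (nm)
COLOCALIZATION_FLOOR_NM = 40.0


@dataclass
class DistanceSample:
    """A labelled sample of 3D distances in nm."""

    distances: np.ndarray
    label: str = ""
    cell_type: str = ""
    chromatin_state: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.distances.size


@dataclass
class GaussianFit:
    mu: float
    sigma: float
    amplitude: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class ContactEstimate:
    probability: float
    sem: float
    d_c: float = DEFAULT_CONTACT_CUTOFF_NM
    n: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass
class PowerLawFit:
    prefactor: float
    exponent: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be > 0")

    def __call__(self, x):
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent


@dataclass
class ExponentialFit:
    scale: float
    rate: float
    r_squared: float

    def __call__(self, x):
        return self.scale * np.exp(self.rate * np.asarray(x, dtype=float))


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class ScalingSample:
    """Mean physical distance for one genomic subchain length."""

    d_kb: float
    d_3d: float
    sem: float = 0.0
    chromatin_state: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.d_kb <= 0 or self.d_3d <= 0:
            raise ValueError("d_kb and d_3d must be > 0")


@dataclass
class PairingModel:
    n_loci: int
    pairing_prob: float
    expected_foci: float

    def __post_init__(self) -> None:
        if not (self.n_loci <= self.expected_foci <= 2 * self.n_loci):
            raise ValueError("expected_foci must lie in [n_loci, 2*n_loci]")


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(sample, bin_rule: str = "fd") -> GaussianFit:
    """Least-squares Gaussian fit to the distance histogram.

    Bin edges follow `bin_rule` (default Freedman-Diaconis via numpy).
    R^2 is computed in histogram space.

    Raises
    ------
    ValueError
        For n < 20 or a zero-width histogram (all-equal distances).
    RuntimeError
        On non-convergence, reporting the initial guesses used.
    """
    d = sample.distances if isinstance(sample, DistanceSample) else np.asarray(sample, float)
    if d.size < 20:
        raise ValueError(f"need at least 20 distances, got {d.size}")
    if np.ptp(d) == 0:
        raise ValueError("zero-width histogram: all distances are equal")
    edges = np.histogram_bin_edges(d, bins=bin_rule)
    counts, edges = np.histogram(d, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    p0 = (float(counts.max()), float(d.mean()), float(max(d.std(), 1e-6)))
    try:
        popt, _ = optimize.curve_fit(_gauss, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit did not converge (initial guesses amplitude={p0[0]:.3g}, "
            f"mu={p0[1]:.3g}, sigma={p0[2]:.3g})"
        ) from exc
    amplitude, mu, sigma = popt
    sigma = abs(float(sigma))
    pred = _gauss(centers, amplitude, mu, sigma)
    ss_res = float(np.sum((counts - pred) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GaussianFit(float(mu), sigma, float(amplitude), r2)


def contact_probability(
    fit_or_sample,
    d_c: float = DEFAULT_CONTACT_CUTOFF_NM,
    method: str = "gaussian",
    n_boot: int = 1000,
    seed: int = 0,
    truncate_at_zero: bool = False,
) -> ContactEstimate:
    """Absolute contact probability: Gaussian area below the cutoff d_c.

    With a `GaussianFit` input, probability = Phi((d_c - mu) / sigma), i.e.
    the fraction of the full Gaussian area below the cutoff
    (`truncate_at_zero` renormalizes over [0, inf) instead).  With a
    distance sample, mu and sigma come from the sample moments and the SEM
    is estimated by a seeded nonparametric bootstrap over distances;
    ``method="empirical"`` uses the below-cutoff fraction directly.
    """
    if d_c <= 0:
        raise ValueError("d_c must be > 0")

    def _phi(mu, sigma):
        p = stats.norm.cdf((d_c - mu) / sigma)
        if truncate_at_zero:
            denom = stats.norm.sf((0.0 - mu) / sigma)
            p = max(p - stats.norm.cdf((0.0 - mu) / sigma), 0.0) / denom
        return float(p)

    if isinstance(fit_or_sample, GaussianFit):
        return ContactEstimate(_phi(fit_or_sample.mu, fit_or_sample.sigma), 0.0, d_c, 0)

    d = (
        fit_or_sample.distances
        if isinstance(fit_or_sample, DistanceSample)
        else np.asarray(fit_or_sample, dtype=float)
    )
    if d.size < 20:
        raise ValueError(f"need at least 20 distances, got {d.size}")

    if method == "empirical":
        estimator = lambda x: float(np.mean(x < d_c))  # noqa: E731
    elif method == "gaussian":
        estimator = lambda x: _phi(x.mean(), max(x.std(ddof=1), 1e-12))  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")

    prob = estimator(d)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = estimator(rng.choice(d, size=d.size, replace=True))
    return ContactEstimate(prob, float(boots.std(ddof=1)), d_c, int(d.size))


def dispersion_vs_distance(fits: list[GaussianFit]) -> LinearFit:
    """OLS of fitted sigma against fitted mu across library pairs."""
    if len(fits) < 3:
        raise ValueError("need at least 3 Gaussian fits")
    mu = np.array([f.mu for f in fits])
    sigma = np.array([f.sigma for f in fits])
    res = stats.linregress(mu, sigma)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def fit_power_law(x, y, weights=None) -> PowerLawFit:
    """Power law y = A * x^beta fitted by OLS in log-log space."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    bad = np.flatnonzero((x <= 0) | (y <= 0))
    if bad.size:
        raise ValueError(f"non-positive values at indices {bad.tolist()}: cannot log-transform")
    lx, ly = np.log(x), np.log(y)
    w = np.ones_like(lx) if weights is None else np.asarray(weights, dtype=float)
    coef = np.polyfit(lx, ly, 1, w=np.sqrt(w))
    beta, intercept = float(coef[0]), float(coef[1])
    pred = intercept + beta * lx
    ss_tot = float(np.sum(w * (ly - np.average(ly, weights=w)) ** 2))
    ss_res = float(np.sum(w * (ly - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(np.exp(intercept)), beta, r2)


def fit_exponential(x, y) -> ExponentialFit:
    """Exponential y = a * exp(k x) fitted by OLS of log y against x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    bad = np.flatnonzero(y <= 0)
    if bad.size:
        raise ValueError(f"non-positive y values at indices {bad.tolist()}")
    ly = np.log(y)
    res = stats.linregress(x, ly)
    return ExponentialFit(float(np.exp(res.intercept)), float(res.slope),
                          float(res.rvalue**2))


def scaling_exponent(
    samples: list[ScalingSample],
) -> dict[tuple[str, str], tuple[PowerLawFit, np.ndarray]]:
    """Per (chromatin state, cell type) power-law fit of mean d_3D vs d_kb.

    Returns, per group, the fit and the prefactor-normalized distances
    d_3D / A (so the fitted curve passes through 1 at d_kb = 1).  Groups
    with fewer than 3 genomic lengths are skipped with a warning.
    """
    import warnings

    groups: dict[tuple[str, str], list[ScalingSample]] = {}
    for s in samples:
        groups.setdefault((s.chromatin_state, s.cell_type), []).append(s)

    out: dict[tuple[str, str], tuple[PowerLawFit, np.ndarray]] = {}
    for key, members in groups.items():
        if len(members) < 3:
            warnings.warn(f"group {key} has fewer than 3 genomic lengths; skipped")
            continue
        d_kb = np.array([m.d_kb for m in members])
        d_3d = np.array([m.d_3d for m in members])
        fit = fit_power_law(d_kb, d_3d)
        out[key] = (fit, d_3d / fit.prefactor)
    return out


def expected_resolvable_foci(n_loci: int, p: float) -> PairingModel:
    """Expected resolvable foci: paired loci show one focus, unpaired two.

    expected_foci = n_loci * (2 - p), assuming no long-range clustering.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("pairing probability must lie in [0, 1]")
    return PairingModel(n_loci, p, n_loci * (2.0 - p))


def hic_vs_probability(hic_counts, probabilities) -> tuple[ExponentialFit, PowerLawFit]:
    """Fit both exponential and power-law models of Hi-C counts vs probability.

    Both fits and their R^2 are returned; no model selection is imposed.
    """
    hic = np.asarray(hic_counts, dtype=float)
    prob = np.asarray(probabilities, dtype=float)
    if hic.size != prob.size or hic.size < 4:
        raise ValueError("need at least 4 paired observations")
    return fit_exponential(prob, hic), fit_power_law(prob, hic)
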