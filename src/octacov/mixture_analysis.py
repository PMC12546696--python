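"""Two-component lognormal mixture fit to the CoV histogram.

The CoV distribution over the vasculature is bimodal: main arterioles
and venules fluctuate little (low CoV) while branching capillaries —
and shunting vessels near the FAZ in particular — fluctuate more.  The
histogram of nonzero CoV values is therefore modeled as a weighted sum
of two lognormal densities,

    P_pred(v) = λ₁·P_LN(v; μ₁, σ₁) + λ₂·P_LN(v; μ₂, σ₂),

fitted by bounded nonlinear least squares on the density-normalized
histogram bins (not by maximum likelihood — the histogram is the data).
Starting values: λ₁ = λ₂ = 0.5, σ₁ = σ₂ = 0.5, μ₁ = ln(mean of the bin
centers), μ₂ = 1.5·μ₁.  Note that with CoV < 1 the log-mean is
negative, so the μ₂ start lies *below* μ₁; the fit is started from
these values verbatim and the components are reordered by μ afterwards.

The crossing point v* of the two weighted component densities separates
the low-CoV mode (main vessels) from the high-CoV mode (branching
capillaries) and drives the threshold classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .volume_io import EnFaceMap, MapKind, ValidationError

__all__ = [
    "CoVHistogram",
    "LognormalMixtureFit",
    "VesselClassification",
    "DegenerateFitError",
    "lognormal_pdf",
    "mixture_pdf",
    "build_histogram",
    "fit_mixture",
    "component_intersection",
    "classify_by_threshold",
    "initial_parameters",
]


class DegenerateFitError(RuntimeError):
    """The two fitted components are indistinguishable."""


@dataclass
class CoVHistogram:
    """Density-normalized histogram of nonzero CoV values."""

    centers: np.ndarray  # v_n, strictly increasing
    density: np.ndarray  # P_n
    edges: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if (np.diff(self.centers) <= 0).any():
            raise ValidationError("bin centers must be strictly increasing")
        if (self.centers <= 0).any():
            raise ValidationError("bin centers must be positive (CoV domain)")
        if (self.density < 0).any():
            raise ValidationError("densities must be non-negative")
        mass = float(np.sum(self.density * np.diff(self.edges)))
        if abs(mass - 1.0) > 1e-6:
            raise ValidationError(f"histogram mass {mass} != 1")

    @property
    def n_bins(self) -> int:
        return len(self.centers)


@dataclass
class LognormalMixtureFit:
    """θ = {λ₁, λ₂, μ₁, μ₂, σ₁, σ₂} with components ordered by μ."""

    lam: np.ndarray  # (2,)
    mu: np.ndarray  # (2,), mu[0] <= mu[1]
    sigma: np.ndarray  # (2,)
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=np.float64)
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if (self.sigma <= 0).any():
            raise ValidationError("component sigmas must be > 0")
        if (self.lam < 0).any():
            raise ValidationError("component weights must be >= 0")
        if self.mu[0] > self.mu[1]:
            raise ValidationError("components must be ordered so mu1 <= mu2")

    def predict(self, v: np.ndarray) -> np.ndarray:
        return mixture_pdf(v, self.lam, self.mu, self.sigma)


@dataclass
class VesselClassification:
    """Disjoint main-vessel / branch masks partitioning the CoV support."""

    main_mask: EnFaceMap  # CoV <= v* (low-variability mode)
    branch_mask: EnFaceMap  # CoV > v*
    v_star: float


def lognormal_pdf(v: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Textbook lognormal density; integrates to 1 over (0, inf)."""
    v = np.asarray(v, dtype=np.float64)
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = np.exp(-((np.log(v[pos]) - mu) ** 2) / (2 * sigma**2)) / (
        v[pos] * sigma * np.sqrt(2 * np.pi)
    )
    return out


def mixture_pdf(v: np.ndarray, lam, mu, sigma) -> np.ndarray:
    return lam[0] * lognormal_pdf(v, mu[0], sigma[0]) + lam[1] * lognormal_pdf(
        v, mu[1], sigma[1]
    )


def build_histogram(cov_map: EnFaceMap | np.ndarray, n_bins: int = 100) -> CoVHistogram:
    """Histogram of the *nonzero* CoV values, density-normalized.

    Exact zeros are masked background, not vasculature; including them
    would swamp the first bin."""
    data = cov_map.data if isinstance(cov_map, EnFaceMap) else np.asarray(cov_map)
    vals = data[data > 0]
    if vals.size == 0:
        raise ValidationError("CoV map has no nonzero pixels")
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        # degenerate sample: open a small positive window around it
        vmin, vmax = 0.9 * vmin, 1.1 * vmax
    density, edges = np.histogram(vals, bins=n_bins, range=(vmin, vmax), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CoVHistogram(centers=centers, density=density, edges=edges,
                        source=f"{vals.size} nonzero pixels")


def initial_parameters(hist: CoVHistogram) -> np.ndarray:
    """Stated starting point: λ = (0.5, 0.5), μ₁ = ln(v̄ₙ), μ₂ = 1.5 μ₁,
    σ = (0.5, 0.5); ordered (λ₁, λ₂, μ₁, μ₂, σ₁, σ₂)."""
    mu1 = float(np.log(hist.centers.mean()))
    return np.array([0.5, 0.5, mu1, 1.5 * mu1, 0.5, 0.5])


def fit_mixture(hist: CoVHistogram) -> LognormalMixtureFit:
    """Bounded least-squares fit of the two-component mixture to the
    histogram densities.

    Requires at least 6 occupied bins (six free parameters).  If the
    optimizer does not report convergence the best-so-far parameters
    are returned with a warning rather than raising.
    """
    if int((hist.density > 0).sum()) < 6:
        raise ValidationError("need >= 6 occupied bins to identify 6 parameters")
    x0 = initial_parameters(hist)
    lb = np.array([0.0, 0.0, -10.0, -10.0, 1e-3, 1e-3])
    ub = np.array([10.0, 10.0, 5.0, 5.0, 10.0, 10.0])

    def residuals(theta: np.ndarray) -> np.ndarray:
        lam, mu, sigma = theta[:2], theta[2:4], theta[4:6]
        return mixture_pdf(hist.centers, lam, mu, sigma) - hist.density

    res = optimize.least_squares(residuals, x0, bounds=(lb, ub), max_nfev=20000)
    if not res.success:
        warnings.warn("mixture fit did not converge; returning best-so-far parameters")
    lam, mu, sigma = res.x[:2], res.x[2:4], res.x[4:6]
    order = np.argsort(mu)
    return LognormalMixtureFit(
        lam=lam[order], mu=mu[order], sigma=sigma[order],
        rss=float(2 * res.cost), converged=bool(res.success),
    )


def component_intersection(fit: LognormalMixtureFit) -> float:
    """CoV value v* where the two weighted component densities cross.

    The root is bracketed between the two component modes and located
    numerically (in log-CoV for conditioning).  With equal σ and equal λ
    this reduces to exp((μ₁ + μ₂)/2).  If the weighted densities do not
    change sign in the bracket (extreme weight imbalance) a dense-grid
    minimum of the absolute difference is returned with a warning.
    """
    mu, sigma, lam = fit.mu, fit.sigma, fit.lam
    if abs(mu[0] - mu[1]) < 1e-12 and abs(sigma[0] - sigma[1]) < 1e-12:
        raise DegenerateFitError("components are identical; no intersection")

    def diff(t: float) -> float:
        v = np.exp(t)
        return float(
            lam[0] * lognormal_pdf(np.array([v]), mu[0], sigma[0])[0]
            - lam[1] * lognormal_pdf(np.array([v]), mu[1], sigma[1])[0]
        )

    modes = np.sort(mu - sigma**2)  # lognormal mode: exp(mu - sigma^2)
    t_lo, t_hi = float(modes[0]), float(modes[1])
    if t_hi - t_lo < 1e-12:
        t_lo -= 0.5
        t_hi += 0.5
    f_lo, f_hi = diff(t_lo), diff(t_hi)
    if f_lo == 0.0:
        return float(np.exp(t_lo))
    if f_hi == 0.0:
        return float(np.exp(t_hi))
    if np.sign(f_lo) != np.sign(f_hi):
        t_star = optimize.brentq(diff, t_lo, t_hi, xtol=1e-12)
        return float(np.exp(t_star))
    warnings.warn(
        "weighted densities do not cross between the modes; "
        "falling back to the grid minimum of |difference|"
    )
    ts = np.linspace(t_lo, t_hi, 4096)
    vals = np.abs([diff(t) for t in ts])
    return float(np.exp(ts[int(np.argmin(vals))]))


def classify_by_threshold(cov_map: EnFaceMap, v_star: float) -> VesselClassification:
    """Split the nonzero CoV support at v*: the low-CoV side is the main
    arterioles/venules, the high-CoV side the branching capillaries."""
    if v_star <= 0:
        raise ValidationError("v* must be > 0")
    data = np.asarray(cov_map.data)
    main = ((data > 0) & (data <= v_star)).astype(np.uint8)
    branch = (data > v_star).astype(np.uint8)
    return VesselClassification(
        main_mask=EnFaceMap(main, cov_map.spacing, MapKind.MASK),
        branch_mask=EnFaceMap(branch, cov_map.spacing, MapKind.MASK),
        v_star=float(v_star),
    )
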