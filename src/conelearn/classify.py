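"""Skew-normal mixture fitting, Kolmogorov-Smirnov model selection, and
cone class assignment from the flattened spectral coordinates.

The flattened positions of the longer-wavelength cones form K clusters —
one per spectral class.  Mixtures of K = 1..3 skew-normal components are fit
by maximum likelihood (multi-restart quasi-Newton minimization of the
negative log-likelihood), and the smallest K whose fit cannot be rejected by
a two-sided Kolmogorov-Smirnov goodness-of-fit test at the 0.01 criterion is
selected.  Each cone is labeled by the component whose weighted density is
highest at its flattened position; component identity is anchored by the S
cones — the component whose mean lies farther from the S side represents
the class with the higher peak wavelength.

The skew-normal density is ``2/omega * phi(z) * Phi(alpha * z)`` with
``z = (x - xi)/omega``; ``alpha = 0`` recovers the normal distribution.
The KS p-value uses the asymptotic Kolmogorov distribution without a
correction for estimated parameters (anti-conservative; see docs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "SkewNormalComponent",
    "MixtureFit",
    "SelectionResult",
    "ClassificationResult",
    "SkewNormalMixture",
    "MixtureFitError",
    "skew_normal_pdf",
    "skew_normal_cdf",
    "fit_mixture",
    "ks_pvalue",
    "select_k",
    "assign_classes",
]

logger = logging.getLogger(__name__)

#: scale floor, as a fraction of the data range, below which a component is
#: considered collapsed.
SCALE_FLOOR_FRAC = 1e-4


class MixtureFitError(RuntimeError):
    """Every optimizer restart failed."""


def skew_normal_pdf(x: np.ndarray, xi: float, omega: float, alpha: float) -> np.ndarray:
    """Skew-normal density with location ``xi``, scale ``omega``, shape ``alpha``."""
    if omega <= 0:
        raise ValueError("scale omega must be positive")
    return stats.skewnorm.pdf(x, alpha, loc=xi, scale=omega)


def skew_normal_cdf(x: np.ndarray, xi: float, omega: float, alpha: float) -> np.ndarray:
    """Skew-normal CDF (Owen's-T based)."""
    if omega <= 0:
        raise ValueError("scale omega must be positive")
    return stats.skewnorm.cdf(x, alpha, loc=xi, scale=omega)


@dataclass(frozen=True)
class SkewNormalComponent:
    """One mixture component: location, scale, shape, and mixing weight."""

    xi: float
    omega: float
    alpha: float
    weight: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("scale omega must be positive")
        if not 0 < self.weight <= 1:
            raise ValueError("mixing weight must lie in (0, 1]")

    @property
    def mean(self) -> float:
        delta = self.alpha / np.sqrt(1.0 + self.alpha**2)
        return self.xi + self.omega * delta * np.sqrt(2.0 / np.pi)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return skew_normal_pdf(x, self.xi, self.omega, self.alpha)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return skew_normal_cdf(x, self.xi, self.omega, self.alpha)


@dataclass
class MixtureFit:
    """A fitted K-component skew-normal mixture plus goodness of fit."""

    components: tuple[SkewNormalComponent, ...]
    log_likelihood: float
    ks_statistic: float = np.nan
    p_value: float = np.nan

    def __post_init__(self) -> None:
        if not np.isclose(sum(c.weight for c in self.components), 1.0, atol=1e-8):
            raise ValueError("mixing weights must sum to 1")
        # components are kept sorted by location
        xis = [c.xi for c in self.components]
        if sorted(xis) != xis:
            raise ValueError("components must be sorted by location")

    @property
    def k(self) -> int:
        return len(self.components)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c.weight * c.pdf(x) for c in self.components)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c.weight * c.cdf(x) for c in self.components)

    def weighted_densities(self, x: np.ndarray) -> np.ndarray:
        """(n, K) array of ``weight_k * pdf_k`` at each point."""
        x = np.asarray(x, dtype=float)
        return np.column_stack([c.weight * c.pdf(x) for c in self.components])


@dataclass
class SelectionResult:
    """Outcome of the K = 1..k_max model-selection sweep."""

    best: MixtureFit
    fits: tuple[MixtureFit, ...]
    adequate: bool  # False when no K reached p >= alpha

    @property
    def k(self) -> int:
        return self.best.k


@dataclass
class ClassificationResult:
    """Final per-cone spectral classes for the longer-wavelength cones.

    ``labels[k]`` ranks cone k's class by distance from the S cones: rank 0
    is nearest the S side (lowest inferred peak wavelength), rank K-1 is the
    farthest (highest).  For K = 2, ``threshold`` is the point between the
    component means where the weighted densities are equal.
    """

    k: int
    labels: np.ndarray
    mixture: MixtureFit
    threshold: float | None = None
    all_fits: tuple[MixtureFit, ...] = field(default_factory=tuple)


class SkewNormalMixture(BaseEstimator):
    """Maximum-likelihood skew-normal mixture, scikit-learn style.

    Parameters
    ----------
    n_components : int
        Number of skew-normal components K.
    n_restarts : int
        Optimizer restarts; the first uses a deterministic quantile-split
        initialization, the rest perturb it randomly.
    random_state : int
        Seeds the restart perturbations (fits are deterministic given it).

    Attributes
    ----------
    components_ : tuple of SkewNormalComponent sorted by location.
    log_likelihood_ : maximized log-likelihood.
    """

    def __init__(
        self,
        n_components: int = 1,
        n_restarts: int = 20,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.random_state = random_state

    # parameter vector layout: [xi_1..K, log_omega_1..K, alpha_1..K, logit_1..K-1]

    def _unpack(self, theta: np.ndarray):
        k = self.n_components
        xi = theta[:k]
        omega = np.exp(theta[k : 2 * k])
        alpha = theta[2 * k : 3 * k]
        if k > 1:
            logits = np.append(theta[3 * k :], 0.0)
            w = np.exp(logits - logits.max())
            w = w / w.sum()
        else:
            w = np.ones(1)
        return xi, omega, alpha, w

    def _nll(self, theta: np.ndarray, x: np.ndarray) -> float:
        xi, omega, alpha, w = self._unpack(theta)
        dens = np.zeros_like(x)
        for j in range(self.n_components):
            dens += w[j] * stats.skewnorm.pdf(x, alpha[j], loc=xi[j], scale=omega[j])
        return float(-np.sum(np.log(np.clip(dens, 1e-300, None))))

    def _initializations(self, x: np.ndarray, rng: np.random.Generator):
        k = self.n_components
        rng_range = float(x.max() - x.min())
        edges = np.quantile(x, np.linspace(0, 1, k + 1))
        xi0, lw0 = [], []
        for j in range(k):
            grp = x[(x >= edges[j]) & (x <= edges[j + 1])]
            if grp.size < 2:
                grp = x
            xi0.append(np.median(grp))
            lw0.append(np.log(max(grp.std(), SCALE_FLOOR_FRAC * rng_range * 2)))
        base = np.concatenate(
            [np.array(xi0), np.array(lw0), np.zeros(k), np.zeros(max(k - 1, 0))]
        )
        yield base
        while True:
            pert = base.copy()
            pert[:k] += rng.normal(0.0, rng_range / 10.0, size=k)
            pert[k : 2 * k] += rng.normal(0.0, 0.3, size=k)
            pert[2 * k : 3 * k] = rng.normal(0.0, 1.5, size=k)
            if k > 1:
                pert[3 * k :] += rng.normal(0.0, 0.5, size=k - 1)
            yield pert

    def fit(self, X, y=None) -> "SkewNormalMixture":
        x = np.asarray(X, dtype=float).ravel()
        k = self.n_components
        if x.size < 5 * k:
            raise ValueError(f"need at least {5 * k} values to fit {k} components")
        rng_range = float(x.max() - x.min())
        if rng_range == 0:
            raise MixtureFitError("all values identical; mixture fit is degenerate")
        rng = np.random.default_rng(self.random_state)
        lo, hi = x.min() - rng_range, x.max() + rng_range
        bounds = (
            [(lo, hi)] * k
            + [(np.log(SCALE_FLOOR_FRAC * rng_range), np.log(4.0 * rng_range))] * k
            + [(-80.0, 80.0)] * k
            + [(-12.0, 12.0)] * max(k - 1, 0)
        )
        best_fun, best_theta = np.inf, None
        init_gen = self._initializations(x, rng)
        for _ in range(max(self.n_restarts, 1)):
            theta0 = next(init_gen)
            try:
                res = optimize.minimize(
                    self._nll, theta0, args=(x,), method="L-BFGS-B", bounds=bounds
                )
            except (ValueError, FloatingPointError):  # rejected restart
                continue
            if np.isfinite(res.fun) and res.fun < best_fun:
                best_fun, best_theta = res.fun, res.x
        if best_theta is None:
            raise MixtureFitError("all mixture-fit restarts failed")
        xi, omega, alpha, w = self._unpack(best_theta)
        order = np.argsort(xi)
        self.components_ = tuple(
            SkewNormalComponent(float(xi[j]), float(omega[j]), float(alpha[j]), float(w[j]))
            for j in order
        )
        self.log_likelihood_ = -best_fun
        return self

    def to_mixture_fit(self) -> MixtureFit:
        return MixtureFit(components=self.components_, log_likelihood=self.log_likelihood_)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return self.to_mixture_fit().pdf(x)

    def predict(self, X) -> np.ndarray:
        """Component index (in location order) with the highest weighted density."""
        fit = self.to_mixture_fit()
        dens = fit.weighted_densities(np.asarray(X, float).ravel())
        return _argmax_larger_mean(dens, fit)


def _argmax_larger_mean(dens: np.ndarray, mixture: MixtureFit) -> np.ndarray:
    """Argmax over components, ties broken toward the larger-mean component."""
    means = np.array([c.mean for c in mixture.components])
    order = np.argsort(means)  # ascending mean
    reordered = dens[:, order]
    # scanning the reversed columns makes argmax prefer the largest mean on ties
    pick_rev = np.argmax(reordered[:, ::-1], axis=1)
    picked = order[reordered.shape[1] - 1 - pick_rev]
    ties = np.sum(dens == dens.max(axis=1, keepdims=True), axis=1) > 1
    if np.any(ties):
        logger.info("density ties at %d points broken toward the larger mean", ties.sum())
    return picked


def ks_pvalue(values: np.ndarray, mixture: MixtureFit) -> tuple[float, float]:
    """Two-sided KS statistic and asymptotic p-value of ``values`` vs the
    fitted mixture CDF."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("cannot run a KS test on an empty sample")
    F = mixture.cdf(x)
    grid = np.arange(1, n + 1) / n
    D = float(max(np.max(grid - F), np.max(F - (grid - 1 / n))))
    p = float(stats.kstwobign.sf(np.sqrt(n) * D))
    return D, p


def fit_mixture(
    values: np.ndarray, k: int, restarts: int = 20, seed: int | None = 0
) -> MixtureFit:
    """Maximum-likelihood K-component fit with KS goodness of fit attached."""
    est = SkewNormalMixture(n_components=k, n_restarts=restarts, random_state=seed).fit(
        values
    )
    fit = est.to_mixture_fit()
    fit.ks_statistic, fit.p_value = ks_pvalue(values, fit)
    return fit


def select_k(
    values: np.ndarray,
    k_max: int = 3,
    alpha: float = 0.01,
    restarts: int = 20,
    seed: int | None = 0,
) -> SelectionResult:
    """Choose the smallest K in 1..k_max whose KS p-value reaches ``alpha``.

    If no K passes, the K with the largest p-value is returned with
    ``adequate=False`` rather than raising.
    """
    fits: list[MixtureFit] = []
    for k in range(1, k_max + 1):
        fit = fit_mixture(values, k, restarts=restarts, seed=seed)
        fits.append(fit)
        if fit.p_value >= alpha:
            return SelectionResult(best=fit, fits=tuple(fits), adequate=True)
    best = max(fits, key=lambda f: f.p_value)
    return SelectionResult(best=best, fits=tuple(fits), adequate=False)


def _two_class_threshold(mixture: MixtureFit) -> float | None:
    """Point between the two component means where the weighted densities
    are equal (the explicit two-class decision boundary)."""
    c1, c2 = mixture.components
    lo, hi = sorted([c1.mean, c2.mean])
    if hi - lo < 1e-12:
        return None

    def diff(x: float) -> float:
        return float(c1.weight * c1.pdf(x) - c2.weight * c2.pdf(x))

    grid = np.linspace(lo, hi, 257)
    vals = np.array([diff(g) for g in grid])
    exact = np.flatnonzero(vals == 0.0)
    if exact.size:
        return float(grid[exact[0]])
    signs = np.sign(vals)
    crossings = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    if crossings.size == 0:
        return None
    if crossings.size > 1:
        logger.info("densities cross %d times between the means", crossings.size)
    i = crossings[0]
    return float(optimize.brentq(diff, grid[i], grid[i + 1]))


def assign_classes(
    values: np.ndarray,
    mixture: MixtureFit,
    s_side_sign: float = -1.0,
    all_fits: tuple[MixtureFit, ...] = (),
) -> ClassificationResult:
    """Label each cone by the mixture component with the highest weighted
    density at its flattened position.

    Components are ranked by distance from the S cones: with the
    conventional orientation (``s_side_sign=-1``, S cones on the negative
    side) larger flattened means rank higher and represent higher peak
    wavelengths.
    """
    x = np.asarray(values, dtype=float).ravel()
    dens = mixture.weighted_densities(x)
    comp_idx = _argmax_larger_mean(dens, mixture)
    means = np.array([c.mean for c in mixture.components])
    # distance from S grows with +value when S side is negative, else with -value
    rank_order = np.argsort(means if s_side_sign < 0 else -means)
    rank_of_comp = np.empty(mixture.k, dtype=int)
    rank_of_comp[rank_order] = np.arange(mixture.k)
    labels = rank_of_comp[comp_idx]
    threshold = _two_class_threshold(mixture) if mixture.k == 2 else None
    return ClassificationResult(
        k=mixture.k, labels=labels, mixture=mixture, threshold=threshold, all_fits=all_fits
    )
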