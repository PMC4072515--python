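"""Non-metric multidimensional scaling of the cone dissimilarity matrix,
S-cone identification, and rotation of the embedding onto the spectral axis.

The embedding places every cone in a 3-D space whose inter-point distances
reproduce, up to a free monotone transformation, the -log correlation
dissimilarities.  The optimizer is SMACOF stress majorization alternated
with isotonic (pool-adjacent-violators) regression of the disparities on the
rank order of the dissimilarities, minimizing Kruskal's STRESS1

    stress = sqrt( sum (disparity - dist)^2 / sum dist^2 ),

initialized from classical (Torgerson) scaling.  Because the large S-cone /
longer-wavelength separation dominates the solution, S cones are found by
2-means clustering (smaller cluster wins) and the embedding is rigidly
rotated so the S-to-non-S separation lies along dimension 1 — the inferred
spectral axis — leaving dimensions 2-3 as the spatial plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.isotonic import IsotonicRegression
from sklearn.utils import check_random_state

from .correlation import DissimilarityMatrix

__all__ = [
    "Embedding",
    "NonmetricMDS",
    "AmbiguousClusterError",
    "RotationError",
    "classical_mds",
    "nmds",
    "stress1",
    "identify_s_cones",
    "rotate_embedding",
]


class AmbiguousClusterError(RuntimeError):
    """2-means produced equal-size clusters; no minority S cluster exists."""


class RotationError(RuntimeError):
    """The S / non-S separation vector is degenerate."""


@dataclass
class Embedding:
    """A 3-D cone embedding with optimizer diagnostics.

    After rotation, dimension 1 is the inferred spectral axis (S cones on
    the negative side) and dimensions 2-3 span the spatial plane.
    """

    coords: np.ndarray
    stress: float
    iterations: int
    converged: bool
    stress_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _as_matrix(d: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    d = d.d if isinstance(d, DissimilarityMatrix) else np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.all(np.isfinite(d)):
        raise ValueError("dissimilarities must be finite")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    return 0.5 * (d + d.T)


def classical_mds(d: DissimilarityMatrix | np.ndarray, dim: int = 3) -> np.ndarray:
    """Classical (Torgerson) scaling: double-centered Gram eigendecomposition.

    Deterministic up to sign; signs are fixed by making the first
    non-negligible loading of each axis positive.  If fewer than ``dim``
    positive eigenvalues exist, the remaining axes are zero-padded (with a
    warning).
    """
    d = _as_matrix(d)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    B = 0.5 * (B + B.T)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dim]
    lam = evals[order]
    vec = evecs[:, order]
    n_pos = int(np.sum(lam > 0))
    if n_pos < dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues for a {dim}-D classical "
            "embedding; padding remaining axes with zeros",
            stacklevel=2,
        )
    coords = np.zeros((n, dim))
    coords[:, : vec.shape[1]] = vec * np.sqrt(np.clip(lam, 0.0, None))
    # sign convention: first non-negligible loading of each axis positive
    for k in range(dim):
        col = coords[:, k]
        big = np.flatnonzero(np.abs(col) > 1e-12 * max(1.0, np.abs(col).max()))
        if big.size and col[big[0]] < 0:
            coords[:, k] = -col
    return coords


def stress1(d: DissimilarityMatrix | np.ndarray, coords: np.ndarray) -> float:
    """STRESS1 of a configuration given dissimilarities: the normalized RMS
    mismatch between embedded distances and their best monotone disparities."""
    d = _as_matrix(d)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.lexsort((iu[1], iu[0], d[iu]))
    dist = pdist(coords)
    disp = _isotonic_disparities(dist, order)
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((disp - dist) ** 2) / denom))


def _isotonic_disparities(dist: np.ndarray, order: np.ndarray) -> np.ndarray:
    """PAVA fit of distances against the dissimilarity rank order.

    ``order`` sorts pairs by dissimilarity with ties broken by index (the
    documented secondary ordering), so the result is the non-decreasing
    sequence closest to the distances in least squares.
    """
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    y = dist[order]
    fitted = iso.fit_transform(np.arange(y.size), y)
    disp = np.empty_like(dist)
    disp[order] = fitted
    return disp


class NonmetricMDS(BaseEstimator):
    """Non-metric MDS via SMACOF with isotonic disparity updates.

    Parameters
    ----------
    n_components : int
        Embedding dimensionality (3 throughout this package).
    init : {'classical', 'random'}
        First starting configuration.  Additional restarts beyond the first
        (``n_init > 1``) are always random.
    n_init : int
        Number of starts; the configuration with the lowest final STRESS1
        wins.  The default single start with classical initialization
        mirrors mdscale-style defaults.
    max_iter, tol : optimizer budget and relative stress-change threshold.
    random_state : seeds the random restarts only.

    Attributes
    ----------
    embedding_ : (n, n_components) coordinates.
    stress_ : final STRESS1 (in [0, 1]).
    stress_history_ : recorded stress per iteration (non-increasing).
    n_iter_ : iterations used by the winning start.
    converged_ : False when ``max_iter`` was exhausted first.
    """

    def __init__(
        self,
        n_components: int = 3,
        init: str = "classical",
        n_init: int = 1,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _smacof_single(
        self, d: np.ndarray, x0: np.ndarray
    ) -> tuple[np.ndarray, list[float], bool]:
        n = d.shape[0]
        iu = np.triu_indices(n, k=1)
        order = np.lexsort((iu[1], iu[0], d[iu]))
        x = x0.copy()
        history: list[float] = []
        converged = False
        for _ in range(self.max_iter):
            dist = pdist(x)
            disp = _isotonic_disparities(dist, order)
            denom = float(np.sum(dist**2))
            stress = float(np.sqrt(np.sum((disp - dist) ** 2) / denom)) if denom else 0.0
            if history and stress > history[-1]:
                # majorization step failed to improve STRESS1 (possible since
                # the denominator moves); keep the previous configuration
                x = prev_x
                converged = True
                break
            history.append(stress)
            if len(history) > 1:
                prev = history[-2]
                if prev - stress < self.tol * max(prev, np.finfo(float).tiny):
                    converged = True
                    break
            if stress == 0.0:
                converged = True
                break
            # scale disparities to the current distance norm, then Guttman
            sd = float(np.sum(disp**2))
            if sd > 0:
                disp = disp * np.sqrt(denom / sd)
            dmat = squareform(dist)
            dispmat = squareform(disp)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dmat > 0, dispmat / dmat, 0.0)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            prev_x = x
            x = (B @ x) / n
        return x, history, converged

    def fit(self, X, y=None) -> "NonmetricMDS":
        d = _as_matrix(X)
        n = d.shape[0]
        rng = check_random_state(self.random_state)
        scale = d[np.triu_indices(n, k=1)].mean() if n > 1 else 1.0
        inits: list[np.ndarray] = []
        if self.init == "classical":
            inits.append(classical_mds(d, self.n_components))
        elif self.init == "random":
            inits.append(rng.standard_normal((n, self.n_components)) * max(scale, 1e-12))
        else:
            raise ValueError(f"unknown init {self.init!r}")
        for _ in range(self.n_init - 1):
            inits.append(rng.standard_normal((n, self.n_components)) * max(scale, 1e-12))

        best: tuple[float, np.ndarray, list[float], bool] | None = None
        for x0 in inits:
            x, history, converged = self._smacof_single(d, x0)
            final = history[-1] if history else 0.0
            if best is None or final < best[0]:
                best = (final, x, history, converged)
        assert best is not None
        self.stress_ = best[0]
        self.embedding_ = best[1]
        self.stress_history_ = np.asarray(best[2])
        self.n_iter_ = len(best[2])
        self.converged_ = best[3]
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def nmds(
    d: DissimilarityMatrix | np.ndarray,
    dim: int = 3,
    init: str = "classical",
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 1,
    random_state: int | None = None,
) -> Embedding:
    """Functional wrapper over :class:`NonmetricMDS`."""
    est = NonmetricMDS(
        n_components=dim,
        init=init,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=random_state,
    ).fit(d)
    return Embedding(
        coords=est.embedding_,
        stress=est.stress_,
        iterations=est.n_iter_,
        converged=est.converged_,
        stress_history=est.stress_history_,
    )


def identify_s_cones(
    embedding: Embedding | np.ndarray, seed: int | None = 0, n_restarts: int = 10
) -> np.ndarray:
    """Identify S cones as the minority cluster of a seeded 2-means split.

    Returns a boolean mask over cones.  Equal cluster sizes raise
    :class:`AmbiguousClusterError` rather than being silently resolved.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 cones to identify an S cluster")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed).fit(coords)
    sizes = np.bincount(km.labels_, minlength=2)
    if sizes[0] == sizes[1]:
        raise AmbiguousClusterError(
            "2-means clusters have equal size; cannot pick the S cluster"
        )
    return km.labels_ == int(np.argmin(sizes))


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector ``a`` onto unit vector ``b``."""
    c = float(np.dot(a, b))
    v = np.cross(a, b)
    if c < -1 + 1e-12:
        # antiparallel: rotate by pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def rotate_embedding(embedding: Embedding, s_mask: np.ndarray) -> Embedding:
    """Rigidly rotate so the S / non-S mean separation lies on dimension 1.

    The vector from the mean of the longer-wavelength cones to the mean of
    the S cones is aligned with the negative first axis, putting S cones on
    the negative side of the spectral dimension.  All pairwise distances are
    preserved.
    """
    s_mask = np.asarray(s_mask, dtype=bool)
    coords = embedding.coords
    if s_mask.sum() == 0 or s_mask.sum() == s_mask.size:
        raise ValueError("s_mask must be a nonempty proper subset of cones")
    sep = coords[s_mask].mean(axis=0) - coords[~s_mask].mean(axis=0)
    norm = np.linalg.norm(sep)
    if norm < 1e-12:
        raise RotationError("S / non-S separation vector is degenerate (zero)")
    R = _rotation_between(sep / norm, np.array([-1.0, 0.0, 0.0]))
    return Embedding(
        coords=coords @ R.T,
        stress=embedding.stress,
        iterations=embedding.iterations,
        converged=embedding.converged,
        stress_history=embedding.stress_history,
    )
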