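"""Cone-by-cone Pearson correlation over a patch stream and its conversion
to the embedding dissimilarity (the negative log of the correlation).

The correlation matrix is accumulated in a single pass from running sums of
x, x^2 and x*y, so arbitrarily long patch streams never need to be held in
memory.  Because responses to natural scenes decorrelate with both distance
and spectral separation, -log(rho) behaves like a distance between cones in
the joint space of retinal position and spectral class; nonpositive
correlations (possible once a suppressive surround is applied) are clamped
to a small positive floor before the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .responses import ResponseBatch

__all__ = [
    "CorrelationMatrix",
    "DissimilarityMatrix",
    "CorrelationAccumulator",
    "DegenerateConeError",
    "accumulate_correlation",
    "to_dissimilarity",
]

logger = logging.getLogger(__name__)


class DegenerateConeError(ValueError):
    """A cone's response has zero variance across the patch stream."""

    def __init__(self, cone_indices: np.ndarray):
        self.cone_indices = np.atleast_1d(cone_indices)
        super().__init__(
            "zero response variance for cone(s) "
            + ", ".join(str(int(i)) for i in self.cone_indices)
        )


@dataclass
class CorrelationMatrix:
    """Pearson correlations between all cone pairs, plus the patch count."""

    rho: np.ndarray
    n_patches: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.shape[0]
        if self.rho.shape != (n, n):
            raise ValueError("rho must be square")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative dissimilarities with a zero diagonal."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("dissimilarities must be nonnegative")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("dissimilarity diagonal must be zero")


class CorrelationAccumulator:
    """Streaming accumulator for the cone x cone Pearson correlation."""

    def __init__(self, n_cones: int):
        self.n_cones = n_cones
        self._n = 0
        self._sx = np.zeros(n_cones)
        self._sxy = np.zeros((n_cones, n_cones))

    def update(self, values: np.ndarray | ResponseBatch) -> None:
        """Fold a (n_cones, n_patches) chunk into the running sums."""
        if isinstance(values, ResponseBatch):
            values = values.values
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != self.n_cones:
            raise ValueError(f"expected ({self.n_cones}, n_patches) chunk")
        self._n += values.shape[1]
        self._sx += values.sum(axis=1)
        self._sxy += values @ values.T

    @property
    def n_patches(self) -> int:
        return self._n

    def finalize(self) -> CorrelationMatrix:
        if self._n < 2:
            raise ValueError("need at least 2 patches to form a correlation")
        n = self._n
        mean = self._sx / n
        cov = self._sxy / n - np.outer(mean, mean)
        var = np.diag(cov).copy()
        # a variance at the level of cancellation error in sxy/n - mean^2 is
        # numerically indistinguishable from a constant response
        bad = np.flatnonzero(var <= 1e-12 * mean**2)
        if bad.size:
            raise DegenerateConeError(bad)
        denom = np.sqrt(np.outer(var, var))
        rho = np.clip(cov / denom, -1.0, 1.0)
        rho = 0.5 * (rho + rho.T)
        np.fill_diagonal(rho, 1.0)
        return CorrelationMatrix(rho=rho, n_patches=n)


def accumulate_correlation(
    batches: Iterable[np.ndarray | ResponseBatch],
) -> CorrelationMatrix:
    """Single-pass correlation over an iterable of response chunks.

    Each chunk is a ``(n_cones, n_patches_chunk)`` array or
    :class:`~conelearn.responses.ResponseBatch`; correlations are computed
    over the union of all patches.
    """
    acc: CorrelationAccumulator | None = None
    for chunk in batches:
        values = chunk.values if isinstance(chunk, ResponseBatch) else np.asarray(chunk)
        if acc is None:
            acc = CorrelationAccumulator(values.shape[0])
        acc.update(values)
    if acc is None:
        raise ValueError("empty patch stream")
    return acc.finalize()


def to_dissimilarity(
    corr: CorrelationMatrix | np.ndarray, floor: float = 1e-6
) -> DissimilarityMatrix:
    """Convert correlations to distances via ``d = -log(max(rho, floor))``.

    The floor keeps the log defined for nonpositive correlations (the model
    never addresses them directly; clamping is logged when triggered).  The
    diagonal is forced to zero.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    rho = corr.rho if isinstance(corr, CorrelationMatrix) else np.asarray(corr, float)
    n_floored = int(np.count_nonzero(rho <= floor))
    if n_floored:
        logger.info("correlation floor %g applied to %d entries", floor, n_floored)
    d = -np.log(np.clip(rho, floor, 1.0))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DissimilarityMatrix(d=d)
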