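"""Simulated retinal cone mosaics on a rectangular grid.

A mosaic assigns one cone to each cell of a side x side grid.  S cones make
up a fixed fraction of the mosaic (6% by default, matching typical human
foveal values) and are placed quasi-regularly by rejection sampling: a
candidate position is discarded if it falls closer than a minimum spacing to
an already placed S cone.  The remaining cells are filled independently with
the longer-wavelength classes, with probabilities proportional to a ratio
vector (e.g. an L:M ratio of 4:1 gives per-cell probabilities 4/5 and 1/5).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConeClassSpec",
    "Mosaic",
    "PlacementError",
    "build_mosaic",
    "neighbor_offsets",
    "mosaic_to_csv",
    "mosaic_from_csv",
    "S_CONE",
]

#: canonical S-cone class with the typical human lambda-max.
S_CONE_NAME = "S"


class PlacementError(RuntimeError):
    """Raised when quasi-regular S-cone placement cannot be completed."""


@dataclass(frozen=True)
class ConeClassSpec:
    """A cone class: a name and its wavelength of peak sensitivity (nm)."""

    name: str
    lambda_max: float

    def __post_init__(self) -> None:
        if not 400.0 <= self.lambda_max <= 720.0:
            raise ValueError(
                f"lambda_max {self.lambda_max} nm outside the 400-720 nm grid"
            )


S_CONE = ConeClassSpec(S_CONE_NAME, 420.7)


@dataclass
class Mosaic:
    """Grid of cones with per-cell class labels.

    ``labels`` is a (side, side) array of class names; ``lambda_max`` maps
    each class name to its peak wavelength.  ``ratio_vector`` records the
    relative abundances used for the non-S classes.
    """

    side: int
    labels: np.ndarray
    lambda_max: dict[str, float]
    ratio_vector: tuple[float, ...] = ()
    s_fraction: float = 0.0
    min_s_spacing: float = 0.0
    seed: int = 0
    s_name: str = S_CONE_NAME

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.side, self.side):
            raise ValueError("labels must be a (side, side) array")
        unknown = set(np.unique(self.labels)) - set(self.lambda_max)
        if unknown:
            raise ValueError(f"labels reference unknown classes {sorted(unknown)}")

    @property
    def n_cones(self) -> int:
        return self.side * self.side

    @property
    def label_vector(self) -> np.ndarray:
        """Flat (row-major) class name per cone."""
        return self.labels.reshape(-1)

    @property
    def coords(self) -> np.ndarray:
        """(n_cones, 2) array of (row, col) grid positions, row-major order."""
        r, c = np.divmod(np.arange(self.n_cones), self.side)
        return np.column_stack([r, c]).astype(float)

    @property
    def is_s(self) -> np.ndarray:
        """Flat boolean mask of S cones."""
        return self.label_vector == self.s_name

    @property
    def lw_class_names(self) -> list[str]:
        """Non-S class names sorted by ascending lambda-max."""
        names = [n for n in self.lambda_max if n != self.s_name]
        return sorted(names, key=lambda n: self.lambda_max[n])

    def lambda_max_vector(self) -> np.ndarray:
        return np.array([self.lambda_max[n] for n in self.label_vector])


def build_mosaic(
    side: int,
    class_specs: Sequence[ConeClassSpec],
    ratio_vector: Sequence[float],
    s_fraction: float = 0.06,
    min_s_spacing: float = 2.5,
    seed: int = 0,
    s_spec: ConeClassSpec = S_CONE,
    max_retries: int = 1000,
) -> Mosaic:
    """Construct a mosaic with quasi-regular S placement and ratio-driven
    assignment of the longer-wavelength classes.

    Parameters
    ----------
    side : int
        Grid side length (the mosaic holds ``side**2`` cones).
    class_specs : sequence of ConeClassSpec
        The longer-wavelength (non-S) cone classes.
    ratio_vector : sequence of float
        Relative abundance ``k_i`` of each non-S class; each cell draws class
        ``i`` with probability ``k_i / sum(k)``.
    s_fraction : float
        Fraction of cones that are S; the S count is exactly
        ``round(s_fraction * side**2)``.
    min_s_spacing : float
        Minimum pairwise Euclidean distance (in cone units) between S cones.
    max_retries : int
        Rejection-sampling attempts per S cone before giving up.
    """
    if side <= 0:
        raise ValueError("side must be positive")
    if not class_specs:
        raise ValueError("need at least one longer-wavelength cone class")
    if len(ratio_vector) != len(class_specs):
        raise ValueError("ratio_vector length must match the number of classes")
    ratios = np.asarray(ratio_vector, dtype=float)
    if ratios.size == 0 or np.any(ratios <= 0):
        raise ValueError("ratio_vector entries must be positive")
    if not 0.0 <= s_fraction < 1.0:
        raise ValueError("s_fraction must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n = side * side
    n_s = int(round(s_fraction * n))

    labels = np.empty((side, side), dtype="<U16")
    placed: list[tuple[int, int]] = []
    for _ in range(n_s):
        for _attempt in range(max_retries):
            r, c = rng.integers(side, size=2)
            if all(np.hypot(r - pr, c - pc) >= min_s_spacing for pr, pc in placed):
                placed.append((int(r), int(c)))
                break
        else:
            raise PlacementError(
                f"could not place {n_s} S cones with spacing {min_s_spacing} "
                f"on a {side}x{side} grid after {max_retries} retries each"
            )

    names = [spec.name for spec in class_specs]
    probs = ratios / ratios.sum()
    draw = rng.choice(len(names), size=n, p=probs)
    labels.reshape(-1)[:] = np.array(names)[draw]
    for r, c in placed:
        labels[r, c] = s_spec.name

    lambda_max = {spec.name: spec.lambda_max for spec in class_specs}
    lambda_max[s_spec.name] = s_spec.lambda_max
    return Mosaic(
        side=side,
        labels=labels,
        lambda_max=lambda_max,
        ratio_vector=tuple(float(x) for x in ratios),
        s_fraction=s_fraction,
        min_s_spacing=min_s_spacing,
        seed=seed,
        s_name=s_spec.name,
    )


def neighbor_offsets(
    mosaic: Mosaic, cone: tuple[int, int], radius: int
) -> list[tuple[int, int, int, int]]:
    """Grid neighbors of ``cone`` within Chebyshev ``radius``.

    Returns a list of ``(d_row, d_col, row, col)`` tuples in units of
    inter-cone distance, excluding the center; boundary cones simply return
    truncated lists.
    """
    r0, c0 = cone
    if not (0 <= r0 < mosaic.side and 0 <= c0 < mosaic.side):
        raise ValueError(f"cone {cone} outside the {mosaic.side}x{mosaic.side} grid")
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            r, c = r0 + dr, c0 + dc
            if 0 <= r < mosaic.side and 0 <= c < mosaic.side:
                out.append((dr, dc, r, c))
    return out


def mosaic_to_csv(mosaic: Mosaic, path: str | Path) -> None:
    """Serialize a mosaic as (row, col, class, lambda_max) CSV rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "class", "lambda_max"])
        for r in range(mosaic.side):
            for c in range(mosaic.side):
                name = mosaic.labels[r, c]
                writer.writerow([r, c, name, mosaic.lambda_max[name]])


def mosaic_from_csv(path: str | Path) -> Mosaic:
    """Read a mosaic serialized by :func:`mosaic_to_csv`."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                (int(rec["row"]), int(rec["col"]), rec["class"], float(rec["lambda_max"]))
            )
    side = max(r for r, _, _, _ in rows) + 1
    labels = np.empty((side, side), dtype="<U16")
    lambda_max: dict[str, float] = {}
    for r, c, name, lm in rows:
        labels[r, c] = name
        lambda_max[name] = lm
    return Mosaic(side=side, labels=labels, lambda_max=lambda_max)
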