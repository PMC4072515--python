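"""Cone signals from image patches: spectral integration, center-surround
opponency, and additive response noise.

A cone's raw response to a patch is the inner product of its spectral
sensitivity with the spectrum at its assigned pixel (grid position times the
patch stride).  The signal handed to the learning algorithm subtracts a
suppressive surround: a Gaussian-weighted sum of neighboring cones' raw
responses whose weights are normalized to a fixed total (0.25 by default).
The surround may draw on all neighbors ("uniform") or only on
longer-wavelength neighbors of a different class ("cone_selective"), in
which case cones with no eligible neighbor legitimately have no surround.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mosaic import Mosaic
from .scenes import HyperspectralImage
from .spectra import SpectralSensitivity

__all__ = [
    "SurroundSpec",
    "ResponseBatch",
    "sensitivity_matrix",
    "raw_response",
    "surround_matrix",
    "surround_weights",
    "opponent_response",
    "add_noise",
    "project_scene",
    "gather_responses",
]


@dataclass(frozen=True)
class SurroundSpec:
    """Suppressive-surround configuration.

    ``sigma`` and ``support_radius`` are in units of inter-cone distance;
    ``total_weight`` is the normalized sum of each cone's surround weights
    (cones whose eligible neighbors are truncated by the mosaic boundary are
    renormalized back to this total).
    """

    mode: str = "uniform"  # none | uniform | cone_selective
    sigma: float = 2.0
    total_weight: float = 0.25
    support_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "uniform", "cone_selective"):
            raise ValueError(f"unknown surround mode {self.mode!r}")
        if self.mode != "none" and self.sigma <= 0:
            raise ValueError("surround sigma must be positive")
        if not 0.0 <= self.total_weight < 1.0:
            raise ValueError("total_weight must lie in [0, 1)")


@dataclass
class ResponseBatch:
    """Signals per (cone, patch), with provenance."""

    values: np.ndarray  # (n_cones, n_patches)
    mosaic: Mosaic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.mosaic.n_cones:
            raise ValueError("values must be (n_cones, n_patches)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("responses must be finite")


def sensitivity_matrix(
    mosaic: Mosaic, fundamentals: Mapping[str, SpectralSensitivity]
) -> np.ndarray:
    """(n_cones, n_bands) sensitivity row per cone, by its class."""
    names = mosaic.label_vector
    missing = set(names) - set(fundamentals)
    if missing:
        raise ValueError(f"no fundamentals for classes {sorted(missing)}")
    first = next(iter(fundamentals.values()))
    rows = {name: fundamentals[name].sensitivity for name in set(names)}
    for name, sens in rows.items():
        if sens.shape != first.sensitivity.shape:
            raise ValueError("fundamentals live on different wavelength grids")
    return np.stack([rows[name] for name in names])


def raw_response(
    patch: np.ndarray | HyperspectralImage,
    mosaic: Mosaic,
    fundamentals: Mapping[str, SpectralSensitivity],
    stride: int = 1,
) -> ResponseBatch:
    """Raw (center-only) responses of every mosaic cone to one patch.

    The cone at grid cell (i, j) reads the spectrum at pixel
    (i * stride, j * stride).
    """
    cube = patch.cube if isinstance(patch, HyperspectralImage) else np.asarray(patch)
    if cube.ndim != 3:
        raise ValueError("patch must be (rows, cols, bands)")
    n_bands = next(iter(fundamentals.values())).wavelengths.size
    if cube.shape[2] != n_bands:
        raise ValueError(
            f"patch has {cube.shape[2]} bands, fundamentals expect {n_bands}"
        )
    need = (mosaic.side - 1) * stride + 1
    if cube.shape[0] < need or cube.shape[1] < need:
        raise ValueError(
            f"patch spatial size {cube.shape[:2]} too small for side "
            f"{mosaic.side} at stride {stride}"
        )
    S = sensitivity_matrix(mosaic, fundamentals)
    sub = cube[::stride, ::stride, :][: mosaic.side, : mosaic.side, :]
    spectra = sub.reshape(mosaic.n_cones, -1)
    values = np.einsum("cb,cb->c", S, spectra)[:, None]
    return ResponseBatch(values, mosaic, meta={"stride": stride, "surround": "none"})


def _eligible(mode: str, center: str, neighbor: str, s_name: str) -> bool:
    if mode == "uniform":
        return True
    # cone_selective: surrounds are built from longer-wavelength cones of a
    # different class; S cones never contribute to any surround.
    if neighbor == s_name:
        return False
    if center == s_name:
        return True
    return neighbor != center


def surround_matrix(mosaic: Mosaic, spec: SurroundSpec) -> np.ndarray:
    """(n_cones, n_cones) weight matrix W with W[i, j] the suppressive weight
    of cone j on cone i; each row with >=1 eligible neighbor sums to
    ``spec.total_weight``, rows with none are all zero."""
    n = mosaic.n_cones
    W = np.zeros((n, n))
    if spec.mode == "none" or spec.total_weight == 0.0:
        return W
    side = mosaic.side
    labels = mosaic.label_vector
    box = int(np.floor(spec.support_radius))
    offs = [
        (dr, dc)
        for dr in range(-box, box + 1)
        for dc in range(-box, box + 1)
        if (dr, dc) != (0, 0) and np.hypot(dr, dc) <= spec.support_radius
    ]
    gauss = {
        (dr, dc): np.exp(-(dr * dr + dc * dc) / (2.0 * spec.sigma**2)) for dr, dc in offs
    }
    for i in range(n):
        r0, c0 = divmod(i, side)
        idx, wts = [], []
        for dr, dc in offs:
            r, c = r0 + dr, c0 + dc
            if not (0 <= r < side and 0 <= c < side):
                continue
            j = r * side + c
            if _eligible(spec.mode, labels[i], labels[j], mosaic.s_name):
                idx.append(j)
                wts.append(gauss[(dr, dc)])
        if idx:
            w = np.asarray(wts)
            W[i, idx] = w * (spec.total_weight / w.sum())
    return W


def surround_weights(
    mosaic: Mosaic, cone: tuple[int, int] | int, spec: SurroundSpec
) -> dict[tuple[int, int], float]:
    """Surround weight map for a single cone, keyed by (d_row, d_col).

    Thin wrapper over :func:`surround_matrix`.  Cones with no eligible
    neighbor (possible in cone_selective mode) return an empty map.
    """
    if spec.mode == "none":
        raise ValueError("surround_weights undefined for mode 'none'")
    if isinstance(cone, tuple):
        i = cone[0] * mosaic.side + cone[1]
    else:
        i = int(cone)
    row = surround_matrix(mosaic, spec)[i]
    r0, c0 = divmod(i, mosaic.side)
    out = {}
    for j in np.flatnonzero(row):
        r, c = divmod(int(j), mosaic.side)
        out[(r - r0, c - c0)] = float(row[j])
    return out


def opponent_response(
    batch: ResponseBatch,
    spec: SurroundSpec,
    W: np.ndarray | None = None,
) -> ResponseBatch:
    """Subtract each cone's surround from its raw response.

    ``value' = value - sum_j W[i, j] * value_j``; mode ``none`` (or a zero
    total weight) is the identity.  Pass a precomputed ``W`` from
    :func:`surround_matrix` to avoid rebuilding it per batch.
    """
    if spec.mode == "none" or spec.total_weight == 0.0:
        return ResponseBatch(
            batch.values.copy(), batch.mosaic, dict(batch.meta, surround="none")
        )
    if W is None:
        W = surround_matrix(batch.mosaic, spec)
    values = batch.values - W @ batch.values
    return ResponseBatch(values, batch.mosaic, dict(batch.meta, surround=spec.mode))


def add_noise(
    batch: ResponseBatch,
    fraction: float,
    seed: int | np.random.Generator = 0,
    reference: str = "patch",
) -> ResponseBatch:
    """Add i.i.d. Gaussian noise scaled to the mean cone response.

    With ``reference='patch'`` (default) the noise standard deviation for a
    patch is ``fraction`` times the mean over cones of that patch's
    responses; ``reference='batch'`` uses one global mean over the whole
    batch instead.
    """
    if fraction < 0:
        raise ValueError("noise fraction must be nonnegative")
    if fraction == 0:
        return ResponseBatch(batch.values.copy(), batch.mosaic, dict(batch.meta))
    if reference not in ("patch", "batch"):
        raise ValueError("reference must be 'patch' or 'batch'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if reference == "patch":
        scale = fraction * batch.values.mean(axis=0, keepdims=True)
    else:
        scale = fraction * batch.values.mean()
    values = batch.values + rng.standard_normal(batch.values.shape) * scale
    return ResponseBatch(
        values, batch.mosaic, dict(batch.meta, noise_fraction=fraction)
    )


# ---------------------------------------------------------------------------
# fast path used by the pipeline: project scenes through each class's
# sensitivity once, then responses are pure gathers.
# ---------------------------------------------------------------------------


def project_scene(
    image: HyperspectralImage,
    fundamentals: Mapping[str, SpectralSensitivity],
    class_order: Sequence[str],
) -> np.ndarray:
    """(n_classes, H, W) per-class spectral projections of a scene.

    ``out[k, r, c]`` equals the raw response a cone of class
    ``class_order[k]`` would give at pixel (r, c).
    """
    S = np.stack([fundamentals[name].sensitivity for name in class_order])
    return np.einsum("hwb,kb->khw", image.cube, S)


def gather_responses(
    projections: Sequence[np.ndarray],
    mosaic: Mosaic,
    class_order: Sequence[str],
    img_idx: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    stride: int = 1,
) -> np.ndarray:
    """Raw responses (n_cones, n_patches) for patch anchors drawn from
    projected scenes.  Equivalent to :func:`raw_response` on each patch."""
    class_pos = {name: k for k, name in enumerate(class_order)}
    labels = np.array([class_pos[name] for name in mosaic.label_vector])
    cr = (mosaic.coords[:, 0] * stride).astype(np.intp)
    cc = (mosaic.coords[:, 1] * stride).astype(np.intp)
    n_patches = img_idx.size
    values = np.empty((mosaic.n_cones, n_patches))
    for s, proj in enumerate(projections):
        sel = np.flatnonzero(img_idx == s)
        if sel.size == 0:
            continue
        rr = cr[:, None] + rows[sel][None, :]
        cc2 = cc[:, None] + cols[sel][None, :]
        values[:, sel] = proj[labels[:, None], rr, cc2]
    return values
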