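"""Flattening of the curved surfaces on which non-S cones embed.

In many simulation conditions the longer-wavelength cone classes lie on
similarly shaped curved 2-D sheets inside the 3-D embedding, offset along
the spectral axis; the curvature alone can make their dimension-1 positions
overlap.  A single quadratic surface

    z1 = c0 + c1*z2 + c2*z3 + c3*z2^2 + c4*z2*z3 + c5*z3^2

is fitted through all non-S cones by minimizing the *standard deviation* of
the point-to-surface distances (not their sum — the std objective seeks the
surface equidistant from every cone, which keeps it centered between the
per-class sheets instead of hugging the more numerous class).  Each cone's
flattened spectral coordinate is then its perpendicular distance to the
surface, signed negative on the side where the S cones sit.

Distance is perpendicular Euclidean distance, computed per point by a
vectorized Newton inner minimization over the surface parameters; points
where the inner solve fails fall back to the vertical (z1-residual)
distance, which upper-bounds the true value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QuadraticSurface",
    "FlattenedPositions",
    "QuadraticSurfaceFlattener",
    "SurfaceFitError",
    "SignAmbiguityError",
    "fit_surface",
    "flatten",
]


class SurfaceFitError(RuntimeError):
    """The surface optimizer failed or the support is degenerate."""


class SignAmbiguityError(RuntimeError):
    """The S-cone mean sits exactly on the surface; the side is undefined."""


@dataclass
class QuadraticSurface:
    """Coefficients of ``z1 = c . [1, z2, z3, z2^2, z2*z3, z3^2]``."""

    coeffs: np.ndarray
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (6,):
            raise ValueError("a quadratic surface has exactly 6 coefficients")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("surface coefficients must be finite")

    def height(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        c = self.coeffs
        return c[0] + c[1] * u + c[2] * v + c[3] * u**2 + c[4] * u * v + c[5] * v**2

    def gradient(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = self.coeffs
        return c[1] + 2 * c[3] * u + c[4] * v, c[2] + c[4] * u + 2 * c[5] * v


@dataclass
class FlattenedPositions:
    """Signed perpendicular distances (the flattened spectral coordinate).

    ``values[k]`` belongs to cone ``cone_indices[k]``; the sign is negative
    on the S-cone side of the surface (``s_side_sign`` records which raw
    residual sign that is).
    """

    values: np.ndarray
    cone_indices: np.ndarray
    s_side_sign: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flattened values must be finite")


def _design(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(u), u, v, u**2, u * v, v**2])


def _surface_distances(
    coeffs: np.ndarray, pts: np.ndarray, max_newton: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned perpendicular distances and residual signs for ``pts``.

    Newton iteration on the foot-point parameters, vectorized over points;
    non-convergent points use the vertical residual (a valid upper bound the
    perpendicular distance can never exceed).
    """
    surf = QuadraticSurface(coeffs)
    p1, p2, p3 = pts[:, 0], pts[:, 1], pts[:, 2]
    resid = p1 - surf.height(p2, p3)
    sign = np.sign(resid)
    c = surf.coeffs
    quu, quv, qvv = 2 * c[3], c[4], 2 * c[5]
    u, v = p2.copy(), p3.copy()
    for _ in range(max_newton):
        q = surf.height(u, v)
        qu, qv = surf.gradient(u, v)
        r = p1 - q
        gu = -r * qu + (u - p2)
        gv = -r * qv + (v - p3)
        huu = qu * qu - r * quu + 1.0
        huv = qu * qv - r * quv
        hvv = qv * qv - r * qvv + 1.0
        det = huu * hvv - huv * huv
        ok = np.abs(det) > 1e-14
        du = np.where(ok, (hvv * gu - huv * gv) / np.where(ok, det, 1.0), 0.0)
        dv = np.where(ok, (huu * gv - huv * gu) / np.where(ok, det, 1.0), 0.0)
        # damp absurd steps so curvature pathologies cannot explode
        step = np.hypot(du, dv)
        big = step > 10.0
        if np.any(big):
            safe = np.where(big, step, 1.0)
            du = np.where(big, du * 10.0 / safe, du)
            dv = np.where(big, dv * 10.0 / safe, dv)
        u -= du
        v -= dv
        if np.max(np.hypot(du, dv)) < 1e-12:
            break
    q = surf.height(u, v)
    perp = np.sqrt((p1 - q) ** 2 + (p2 - u) ** 2 + (p3 - v) ** 2)
    dist = np.minimum(perp, np.abs(resid))
    return dist, sign


def fit_surface(
    coords: np.ndarray,
    non_s_mask: np.ndarray | None = None,
    xatol: float = 1e-8,
    fatol: float = 1e-10,
    maxfev: int = 10_000,
) -> QuadraticSurface:
    """Fit the quadratic surface minimizing the std of point distances.

    A derivative-free simplex search over the 6 coefficients, started from
    the least-squares regression of z1 on (z2, z3); requires at least 7
    non-S cones and a non-collinear (z2, z3) support.
    """
    coords = np.asarray(coords, dtype=float)
    pts = coords if non_s_mask is None else coords[np.asarray(non_s_mask, bool)]
    if pts.shape[0] < 7:
        raise SurfaceFitError("need at least 7 non-S cones to fit 6 coefficients")
    X = _design(pts[:, 1], pts[:, 2])
    if np.linalg.matrix_rank(X) < 6:
        raise SurfaceFitError("collinear (z2, z3) support; surface fit is rank-deficient")
    c0, *_ = np.linalg.lstsq(X, pts[:, 0], rcond=None)

    def objective(c: np.ndarray) -> float:
        dist, _ = _surface_distances(c, pts)
        return float(np.std(dist))

    res = optimize.minimize(
        objective,
        c0,
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
    )
    if not np.all(np.isfinite(res.x)):
        raise SurfaceFitError(f"surface optimizer failed: {res.message}")
    # polish: restart the simplex from its own solution until the objective
    # stops moving (a fresh simplex escapes premature shrinkage)
    fun, best = float(res.fun), res.x
    for _ in range(8):
        res = optimize.minimize(
            objective,
            best,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
        )
        if not np.all(np.isfinite(res.x)) or res.fun >= fun - 1e-12:
            break
        fun, best = float(res.fun), res.x
    f0 = objective(c0)
    if f0 < fun:
        fun, best = f0, c0
    return QuadraticSurface(coeffs=best, objective=float(fun))


def flatten(
    coords: np.ndarray,
    surface: QuadraticSurface,
    s_mask: np.ndarray | None,
    s_side_sign: float | None = None,
) -> FlattenedPositions:
    """Signed distance of each non-S cone to the surface.

    The sign convention follows the S cones: a cone on the same side of the
    surface as the mean S-cone residual gets a negative value.  For mosaics
    without S cones (``s_mask=None``) the caller supplies ``s_side_sign``
    directly (the manual-rotation hook).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if s_mask is None:
        if s_side_sign not in (-1.0, 1.0, -1, 1):
            raise ValueError("without S cones, s_side_sign must be -1 or +1")
        non_s = np.ones(n, dtype=bool)
        side = float(s_side_sign)
    else:
        s_mask = np.asarray(s_mask, dtype=bool)
        non_s = ~s_mask
        s_resid = coords[s_mask, 0] - surface.height(coords[s_mask, 1], coords[s_mask, 2])
        mean_resid = float(s_resid.mean())
        if mean_resid == 0.0:
            raise SignAmbiguityError("mean S-cone position lies exactly on the surface")
        side = float(np.sign(mean_resid))

    dist, sign = _surface_distances(surface.coeffs, coords[non_s])
    values = dist * np.where(sign == side, -1.0, 1.0)
    return FlattenedPositions(
        values=values, cone_indices=np.flatnonzero(non_s), s_side_sign=side
    )


class QuadraticSurfaceFlattener(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`fit_surface` / :func:`flatten`.

    ``fit(X)`` fits the surface through the rows of ``X`` (3-D embedded
    positions, already restricted to non-S cones or masked via the
    ``non_s_mask`` fit parameter); ``transform(X)`` returns signed
    perpendicular distances using the orientation set by ``orient``.
    """

    def __init__(self, xatol: float = 1e-8, maxfev: int = 10_000):
        self.xatol = xatol
        self.maxfev = maxfev

    def fit(self, X, y=None, non_s_mask: np.ndarray | None = None):
        self.surface_ = fit_surface(
            np.asarray(X, float), non_s_mask, xatol=self.xatol, maxfev=self.maxfev
        )
        self.s_side_sign_ = -1.0  # default: negative residuals are the S side
        return self

    def orient(self, s_coords: np.ndarray) -> "QuadraticSurfaceFlattener":
        """Set the sign convention from observed S-cone positions."""
        s_coords = np.asarray(s_coords, float)
        resid = s_coords[:, 0] - self.surface_.height(s_coords[:, 1], s_coords[:, 2])
        if float(resid.mean()) == 0.0:
            raise SignAmbiguityError("mean S-cone position lies exactly on the surface")
        self.s_side_sign_ = float(np.sign(resid.mean()))
        return self

    def transform(self, X) -> np.ndarray:
        dist, sign = _surface_distances(self.surface_.coeffs, np.asarray(X, float))
        return dist * np.where(sign == self.s_side_sign_, -1.0, 1.0)
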