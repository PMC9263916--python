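"""Bivariate polynomial surfaces fitted by least squares.

A degree-``n`` surface is ``z = sum_{k=0..n} sum_{i=0..k} a_ki x^(k-i) y^i``
with ``(n+1)(n+2)/2`` coefficients stored in (k, i) lexicographic order.
Because raw planar coordinates span tens of meters, the monomial basis is
numerically singular at degree 3-4; coordinates are therefore centered and
scaled to roughly [-1, 1] before solving ("conditioning"), and the stored
coefficients live on the conditioned coordinates. Evaluation applies the same
conditioning, so the surface is exact regardless of the working units.

Rank-deficient systems (too few points, or degenerate geometry such as
collinear points at degree >= 1) raise :class:`RankDeficiencyError` instead
of silently returning a minimum-norm solution: an underdetermined ground
model is a hazard, not an answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RankDeficiencyError
from .raster import RasterGrid

__all__ = [
    "PolySurface",
    "n_coefficients",
    "fit_polynomial_dtm",
    "evaluate_surface",
    "surface_to_raster",
]


def n_coefficients(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


def _monomial_powers(degree: int) -> list[tuple[int, int]]:
    """(k - i, i) exponent pairs in (k, i) lexicographic order."""
    return [(k - i, i) for k in range(degree + 1) for i in range(k + 1)]


@dataclass(frozen=True)
class PolySurface:
    degree: int
    coefficients: np.ndarray  # (k, i) lexicographic, conditioned coordinates
    center: tuple[float, float] = (0.0, 0.0)
    scale: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float).ravel()
        )
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.coefficients.size != n_coefficients(self.degree):
            raise ValueError(
                f"degree {self.degree} needs {n_coefficients(self.degree)} "
                f"coefficients, got {self.coefficients.size}"
            )

    def design_matrix(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        u = (np.asarray(x, dtype=float) - self.center[0]) / self.scale[0]
        v = (np.asarray(y, dtype=float) - self.center[1]) / self.scale[1]
        return np.column_stack(
            [u**px * v**py for px, py in _monomial_powers(self.degree)]
        )

    def __call__(self, x, y):
        return evaluate_surface(self, x, y)


def fit_polynomial_dtm(points, degree: int) -> PolySurface:
    """Least-squares polynomial surface through (x, y, z) ground samples.

    ``points`` is an (m, 3) array-like. Coordinates are conditioned to the
    sample bounding box before solving. Raises :class:`RankDeficiencyError`
    when m < number of coefficients or the conditioned design matrix loses
    rank.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (m, 3) array of (x, y, z)")
    m = pts.shape[0]
    p = n_coefficients(degree)
    if m < p:
        raise RankDeficiencyError(f"{m} points cannot determine {p} coefficients")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    center = ((x.min() + x.max()) / 2.0, (y.min() + y.max()) / 2.0)
    scale = (max((x.max() - x.min()) / 2.0, 1e-12), max((y.max() - y.min()) / 2.0, 1e-12))
    proto = PolySurface(degree, np.zeros(p), center, scale)
    A = proto.design_matrix(x, y)
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < p:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {p} coefficients (degenerate geometry)"
        )
    return PolySurface(degree, coef, center, scale)


def evaluate_surface(surface: PolySurface, x, y):
    """Evaluate the surface at coordinates; vectorizes over arrays."""
    xb, yb = np.broadcast_arrays(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    A = surface.design_matrix(xb.ravel(), yb.ravel())
    z = A @ surface.coefficients
    return float(z[0]) if xb.shape == () else z.reshape(xb.shape)


def surface_to_raster(surface: PolySurface, like: RasterGrid) -> RasterGrid:
    """Rasterize the surface on the grid geometry of ``like``."""
    X, Y = like.center_mesh()
    values = evaluate_surface(surface, X.ravel(), Y.ravel()).reshape(like.shape)
    return RasterGrid(values, like.origin, like.pixel_size, like.nodata)
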