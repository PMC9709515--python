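"""Height-function surfaces over the nutrient plane.

A performance landscape is modelled as a Monge patch: the graph of a
height function ``z = f(x, y)`` over a rectangular domain of nutrient
intakes.  :class:`SurfacePatch` carries the height together with its
analytic first and second partial derivatives, which is all the
differential geometry in :mod:`perfscape.geometry` needs.  The workhorse
is the quadratic polynomial surface used to approximate fitted
landscapes, but any twice-differentiable patch (sphere caps, cylinder
sections, ...) can be supplied for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

__all__ = ["SurfacePatch", "QuadraticSurface"]

#: signature of a scalar field over the plane; must accept numpy arrays
Field2D = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SurfacePatch:
    """A surface ``(x, y) -> (x, y, f(x, y))`` with analytic partials.

    Parameters
    ----------
    height : callable
        The height function ``f``.
    dx, dy : callable
        First partial derivatives ``f_x`` and ``f_y``.
    dxx, dyy, dxy : callable
        Second partial derivatives; ``dxy`` serves for both mixed
        partials (Schwarz symmetry is assumed).
    name : str
        Optional label used in reports.

    All callables must be vectorized over numpy arrays.
    """

    height: Field2D
    dx: Field2D
    dy: Field2D
    dxx: Field2D
    dyy: Field2D
    dxy: Field2D
    name: str = "surface"

    def __call__(self, x, y):
        return self.height(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


@dataclass(frozen=True)
class QuadraticSurface:
    """The quadratic landscape ``z = a x² + b y² + c x + d y + e xy + intercept``.

    The five curvature-bearing coefficients ``(a, b, c, d, e)`` come from
    an ordinary least-squares fit of trait values on nutrient intakes;
    the intercept shifts the height only and never enters a gradient or
    curvature expression.
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    intercept: float = 0.0
    name: str = "quadratic"

    def __post_init__(self):
        for fname in ("a", "b", "c", "d", "e", "intercept"):
            v = getattr(self, fname)
            if not np.isfinite(v):
                raise ValueError(f"coefficient {fname!r} is not finite: {v!r}")

    # -- SurfacePatch protocol -------------------------------------------
    def height(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (self.a * x**2 + self.b * y**2 + self.c * x + self.d * y
                + self.e * x * y + self.intercept)

    def dx(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return 2.0 * self.a * x + self.c + self.e * y

    def dy(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return 2.0 * self.b * y + self.d + self.e * x

    def dxx(self, x, y):
        return np.broadcast_to(2.0 * self.a, np.broadcast_shapes(np.shape(x), np.shape(y))).copy()

    def dyy(self, x, y):
        return np.broadcast_to(2.0 * self.b, np.broadcast_shapes(np.shape(x), np.shape(y))).copy()

    def dxy(self, x, y):
        return np.broadcast_to(self.e, np.broadcast_shapes(np.shape(x), np.shape(y))).copy()

    def __call__(self, x, y):
        return self.height(x, y)

    # -- conveniences ----------------------------------------------------
    @property
    def coefficients(self) -> tuple[float, float, float, float, float]:
        """``(a, b, c, d, e)`` — the curvature-bearing coefficients."""
        return (self.a, self.b, self.c, self.d, self.e)

    def with_intercept(self, intercept: float) -> "QuadraticSurface":
        return replace(self, intercept=float(intercept))

    def translated(self, u: float, v: float) -> "QuadraticSurface":
        """Return the surface ``g(x, y) = f(x - u, y - v)`` (domain shift).

        Substituting x-u, y-v into the quadratic keeps it quadratic; the
        curvature fields of the result are those of ``f`` shifted by
        ``(u, v)``.
        """
        a, b, c, d, e = self.coefficients
        return QuadraticSurface(
            a=a, b=b,
            c=c - 2 * a * u - e * v,
            d=d - 2 * b * v - e * u,
            e=e,
            intercept=self.intercept + a * u**2 + b * v**2 - c * u - d * v + e * u * v,
            name=self.name,
        )

    def as_patch(self) -> SurfacePatch:
        """View as a generic :class:`SurfacePatch`."""
        return SurfacePatch(self.height, self.dx, self.dy,
                            self.dxx, self.dyy, self.dxy, name=self.name)
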