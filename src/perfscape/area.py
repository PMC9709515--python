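"""Surface area of a landscape and its ratio to a flat reference.

The surface area of a Monge patch over the rectangle
``Ω = [0, x_max] x [0, y_max]`` is the double integral

    A_S = ∬_Ω sqrt(1 + f_x² + f_y²) dx dy,

evaluated by adaptive quadrature.  Dividing by the rectangle area
``A_0 = x_max · y_max`` (the surface area of any flat landscape over
the same domain) gives the dimensionless surface-area ratio
``A = A_S / A_0 ∈ [1, ∞)``: a proxy for how wiggly a landscape is.
The integrand is bounded below by 1, so the ratio can never fall below
1, and it equals 1 exactly when the gradient vanishes everywhere.
Adding a constant to the landscape changes neither term.

Trait values are kept on their original scale here (unlike the
Hausdorff comparison, which mean-standardizes them): the ratio measures
deviation from flatness in the trait's own units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .exceptions import QuadratureError
from .grids import Domain, LandscapeGrid
from .surfaces import SurfacePatch

__all__ = ["SurfaceAreaResult", "surface_area", "surface_area_grid", "area_ratio"]

DEFAULT_TOL = 1e-8


@dataclass(frozen=True)
class SurfaceAreaResult:
    """Area of a landscape and its ratio against the flat reference."""

    area: float          # units of x·y
    flat_area: float     # rectangle area, same units
    ratio: float         # dimensionless, >= 1
    domain: Domain
    tol: float
    error_bound: float   # quadrature error estimate actually achieved
    trait: str = "surface"

    def __post_init__(self):
        if self.ratio < 1.0 - 1e-9:
            raise ValueError(
                f"surface-area ratio {self.ratio} < 1: the integrand is >= 1 "
                "pointwise, so this indicates a computation error")


def _surface_area_with_err(surface: SurfacePatch, domain: Domain,
                           tol: float) -> tuple[float, float]:
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol!r}")

    def integrand(y, x):
        fx = surface.dx(x, y)
        fy = surface.dy(x, y)
        return np.sqrt(1.0 + fx ** 2 + fy ** 2)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", integrate.IntegrationWarning)
        value, err = integrate.dblquad(
            integrand, 0.0, domain.x_max, 0.0, domain.y_max,
            epsabs=tol, epsrel=1e-10)
    trouble = [w for w in caught
               if issubclass(w.category, integrate.IntegrationWarning)]
    if trouble:
        raise QuadratureError(
            f"adaptive quadrature did not converge to tol={tol}: "
            f"{trouble[0].message} (estimate {value}, error bound {err})",
            estimate=float(value), error_bound=float(err))
    return float(value), float(err)


def surface_area(surface: SurfacePatch, domain: Domain,
                 tol: float = DEFAULT_TOL) -> float:
    """Adaptive quadrature of ``∬ sqrt(1 + f_x² + f_y²) dx dy`` over the domain.

    Raises :class:`~perfscape.exceptions.QuadratureError` (carrying the
    best estimate and its error bound) if the requested absolute
    tolerance cannot be certified.
    """
    value, _ = _surface_area_with_err(surface, domain, tol)
    return value


def surface_area_grid(grid: LandscapeGrid) -> float:
    """Surface area of a gridded landscape without analytic partials.

    Gradients are taken by central finite differences on the grid and
    the integrand is integrated with Simpson's rule on both axes.  Use
    this fallback when the landscape exists only as a table of heights;
    for quadratic fits prefer :func:`surface_area` on the surface.
    """
    xs = grid.x[0, :]
    ys = grid.y[:, 0]
    dzdy, dzdx = np.gradient(grid.z, ys, xs)
    integrand = np.sqrt(1.0 + dzdx ** 2 + dzdy ** 2)
    inner = integrate.simpson(integrand, x=xs, axis=1)
    return float(integrate.simpson(inner, x=ys))


def area_ratio(surface: SurfacePatch, domain: Domain,
               tol: float = DEFAULT_TOL, trait: str | None = None) -> SurfaceAreaResult:
    """Surface-area ratio of a landscape against the flat reference.

    ``flat_area`` is the rectangle area ``x_max · y_max`` — the surface
    area of any constant-height landscape over the same domain.
    """
    value, err = _surface_area_with_err(surface, domain, tol)
    flat = domain.area
    name = trait if trait is not None else getattr(surface, "name", "surface")
    return SurfaceAreaResult(area=value, flat_area=flat, ratio=value / flat,
                             domain=domain, tol=tol, error_bound=err, trait=name)
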