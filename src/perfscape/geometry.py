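"""Differential geometry of performance landscapes.

Everything here operates on a Monge patch ``(x, y) -> (x, y, f(x, y))``.
With ``W = sqrt(1 + f_x² + f_y²)`` the first and second fundamental
forms are

.. math::

    E = 1 + f_x^2,\\quad F = f_x f_y,\\quad G = 1 + f_y^2,\\qquad
    L = f_{xx}/W,\\quad M = f_{xy}/W,\\quad N = f_{yy}/W,

and the Gauss and mean curvatures follow as

.. math::

    K = \\frac{LN - M^2}{EG - F^2},\\qquad
    H = \\frac{GL - 2FM + EN}{2(EG - F^2)}.

``K`` is intrinsic (the product of the principal curvatures, invariant
under bending without stretching); ``H`` is extrinsic (their mean) and
depends on the orientation of the unit normal.  We fix the normal as the
normalized cross product of the tangent vectors ``(1, 0, f_x)`` and
``(0, 1, f_y)`` in that order — the upward normal
``(-f_x, -f_y, 1)/W``.  Under this orientation a region of the
landscape bending upwards (a bowl opening downwards, e.g. the first
quadrant of the saddle ``z = xy``) has ``H < 0`` and one bending
downwards has ``H > 0``; flipping the orientation would negate ``H``
everywhere while leaving ``K`` untouched.

The sign of ``K`` classifies each point of the landscape: zero means
locally flat (or cylinder-like), positive means locally sphere-like
(convex — peaks and valleys), negative means locally saddle-like
(hyperbolic — mountain passes).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np
import pandas as pd

from .grids import LandscapeGrid
from .surfaces import SurfacePatch

__all__ = [
    "FundamentalForms", "CurvatureField", "RegionClass",
    "gradient", "unit_normal", "fundamental_forms",
    "gauss_curvature", "mean_curvature", "principal_curvatures",
    "classify_point", "curvature_field",
]

#: default |K| below which a point is called flat (standardized domains)
DEFAULT_FLAT_TOL = 1e-8


class RegionClass(str, Enum):
    """Local surface type by the sign of the Gauss curvature."""
    FLAT = "flat"
    CONVEX = "convex"
    HYPERBOLIC = "hyperbolic"


@dataclass(frozen=True)
class FundamentalForms:
    """First (E, F, G) and second (L, M, N) fundamental forms at a point
    (or elementwise over an array of points), plus the unit normal.

    ``normal`` stacks the three components on the last axis, so for a
    single point it is a plain 3-vector of unit length.
    """

    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    L: np.ndarray
    M: np.ndarray
    N: np.ndarray
    normal: np.ndarray

    @property
    def discriminant(self) -> np.ndarray:
        """``EG - F²``; equals ``1 + f_x² + f_y² >= 1`` on a Monge patch."""
        return self.E * self.G - self.F ** 2


def _as_finite_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("evaluation point contains non-finite coordinates")
    return x, y


def gradient(surface: SurfacePatch, point) -> Tuple[np.ndarray, np.ndarray]:
    """Partial derivatives ``(f_x, f_y)`` of the height at ``point``.

    For the quadratic landscape these are the closed forms
    ``f_x = 2ax + c + ey`` and ``f_y = 2by + d + ex``.
    """
    x, y = _as_finite_xy(*point)
    return surface.dx(x, y), surface.dy(x, y)


def unit_normal(surface: SurfacePatch, point) -> np.ndarray:
    """Upward unit normal ``(-f_x, -f_y, 1)/W`` at ``point``.

    This is the normalized cross product of the tangent vectors
    ``(1, 0, f_x)`` and ``(0, 1, f_y)``, taken in that order.
    """
    fx, fy = gradient(surface, point)
    if not (np.all(np.isfinite(fx)) and np.all(np.isfinite(fy))):
        raise ValueError("surface partials are non-finite at the requested point")
    W = np.sqrt(1.0 + fx ** 2 + fy ** 2)
    return np.stack([-fx / W, -fy / W, 1.0 / W], axis=-1)


def fundamental_forms(surface: SurfacePatch, point) -> FundamentalForms:
    """Evaluate both fundamental forms of the patch at ``point``.

    The second-form entries are the dot products of the second-partial
    vectors ``(0, 0, f_··)`` with the unit normal, i.e. ``f_·· / W``.
    """
    x, y = _as_finite_xy(*point)
    fx, fy = surface.dx(x, y), surface.dy(x, y)
    if not (np.all(np.isfinite(fx)) and np.all(np.isfinite(fy))):
        raise ValueError("surface partials are non-finite at the requested point")
    W = np.sqrt(1.0 + fx ** 2 + fy ** 2)
    normal = np.stack([-fx / W, -fy / W, 1.0 / W], axis=-1)
    return FundamentalForms(
        E=1.0 + fx ** 2,
        F=fx * fy,
        G=1.0 + fy ** 2,
        L=surface.dxx(x, y) / W,
        M=surface.dxy(x, y) / W,
        N=surface.dyy(x, y) / W,
        normal=normal,
    )


def _check_nondegenerate(forms: FundamentalForms) -> np.ndarray:
    disc = forms.discriminant
    if np.any(disc <= 0):
        # impossible for a Monge patch (disc = 1 + fx² + fy²); if it
        # happens the forms were built inconsistently
        raise ArithmeticError(
            "degenerate fundamental forms: EG - F² <= 0; these forms do not "
            "come from a Monge patch")
    return disc


def gauss_curvature(forms: FundamentalForms) -> np.ndarray:
    """Gauss curvature ``K = (LN - M²)/(EG - F²)``."""
    disc = _check_nondegenerate(forms)
    return (forms.L * forms.N - forms.M ** 2) / disc


def mean_curvature(forms: FundamentalForms) -> np.ndarray:
    """Mean curvature ``H = (GL - 2FM + EN)/(2(EG - F²))``.

    Sign follows the upward-normal orientation: negative where the
    landscape bends upwards, positive where it bends downwards.
    """
    disc = _check_nondegenerate(forms)
    return (forms.G * forms.L - 2.0 * forms.F * forms.M + forms.E * forms.N) / (2.0 * disc)


def principal_curvatures(forms: FundamentalForms) -> Tuple[np.ndarray, np.ndarray]:
    """Principal curvatures ``(κ1, κ2)`` with ``κ1 >= κ2``.

    These are the eigenvalues of the shape operator ``I⁻¹ II``; being
    self-adjoint with respect to I its eigenvalues are real, and they
    satisfy ``κ1 κ2 = K`` and ``(κ1 + κ2)/2 = H``, so they solve
    ``κ² - 2Hκ + K = 0``.
    """
    K = gauss_curvature(forms)
    H = mean_curvature(forms)
    # H² - K >= 0 analytically; clamp roundoff
    disc = np.maximum(H ** 2 - K, 0.0)
    root = np.sqrt(disc)
    return H + root, H - root


def classify_point(K, tol: float = DEFAULT_FLAT_TOL):
    """Classify local surface type from the sign of the Gauss curvature.

    ``|K| <= tol`` is flat, ``K > tol`` convex (sphere-like),
    ``K < -tol`` hyperbolic (saddle-like).  Accepts scalars or arrays;
    returns a :class:`RegionClass` for a scalar, an object array of
    :class:`RegionClass` otherwise.
    """
    if not np.isscalar(tol) or tol <= 0:
        raise ValueError(f"tol must be a positive scalar, got {tol!r}")
    K = np.asarray(K, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("Gauss curvature contains non-finite values")
    if K.ndim == 0:
        k = K.item()
        if abs(k) <= tol:
            return RegionClass.FLAT
        return RegionClass.CONVEX if k > tol else RegionClass.HYPERBOLIC
    out = np.empty(K.shape, dtype=object)
    out[...] = RegionClass.HYPERBOLIC
    out[K > tol] = RegionClass.CONVEX
    out[np.abs(K) <= tol] = RegionClass.FLAT
    return out


@dataclass(frozen=True)
class CurvatureField:
    """Pointwise Gauss/mean curvature and region class over a grid.

    ``K`` has units 1/length², ``H`` 1/length (in the units of the
    standardized nutrient axes); ``kappa1 >= kappa2`` are the principal
    curvatures at each node.
    """

    grid: LandscapeGrid
    K: np.ndarray
    H: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray
    region_class: np.ndarray
    tol: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: columns x, y, z, K, H, region_class."""
        return pd.DataFrame({
            "x": self.grid.x.ravel(),
            "y": self.grid.y.ravel(),
            "z": self.grid.z.ravel(),
            "K": self.K.ravel(),
            "H": self.H.ravel(),
            "region_class": [rc.value for rc in self.region_class.ravel()],
        })


def curvature_field(surface: SurfacePatch, grid: LandscapeGrid,
                    tol: float = DEFAULT_FLAT_TOL) -> CurvatureField:
    """Evaluate K, H, principal curvatures and region class at every node."""
    if grid.x.size == 0:
        raise ValueError("cannot evaluate a curvature field on an empty grid")
    forms = fundamental_forms(surface, (grid.x, grid.y))
    K = gauss_curvature(forms)
    H = mean_curvature(forms)
    k1, k2 = principal_curvatures(forms)
    classes = classify_point(K, tol=tol)
    return CurvatureField(grid=grid, K=K, H=H, kappa1=k1, kappa2=k2,
                          region_class=np.asarray(classes, dtype=object), tol=tol)
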