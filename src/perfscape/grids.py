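"""Rectangular domains and discrete landscape grids.

All landscapes derived from one experiment are evaluated on the *same*
square grid over ``[0, x*] x [0, y*]`` so that surface areas and
Hausdorff distances compare like with like.  Grids are closed (both
endpoints included) and stored row-major.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Domain", "LandscapeGrid"]


@dataclass(frozen=True)
class Domain:
    """The rectangle ``[0, x_max] x [0, y_max]`` of nutrient intakes."""

    x_max: float
    y_max: float

    def __post_init__(self):
        if not (np.isfinite(self.x_max) and self.x_max > 0):
            raise ValueError(f"x_max must be positive and finite, got {self.x_max!r}")
        if not (np.isfinite(self.y_max) and self.y_max > 0):
            raise ValueError(f"y_max must be positive and finite, got {self.y_max!r}")

    @property
    def area(self) -> float:
        """Area of the rectangle; the flat-landscape reference area."""
        return self.x_max * self.y_max

    @classmethod
    def unit(cls) -> "Domain":
        return cls(1.0, 1.0)

    @classmethod
    def from_data(cls, x, y) -> "Domain":
        """Smallest domain ``[0, max(x)] x [0, max(y)]`` covering the data."""
        return cls(float(np.max(x)), float(np.max(y)))


@dataclass(frozen=True)
class LandscapeGrid:
    """An ``n x n`` grid of predicted heights over a :class:`Domain`.

    Attributes
    ----------
    x, y : (n, n) arrays
        Node coordinates from ``numpy.meshgrid(..., indexing="xy")``;
        include 0 and the domain maximum on each axis.
    z : (n, n) array
        Predicted trait value at each node.
    trait : str
        Name of the trait (or canonical surface) the grid represents.
    coefficients : tuple or None
        Provenance: ``(a, b, c, d, e, intercept)`` of the generating
        quadratic, when there is one.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    domain: Domain
    trait: str = "trait"
    coefficients: Optional[tuple] = None

    def __post_init__(self):
        x, y, z = (np.asarray(a, dtype=float) for a in (self.x, self.y, self.z))
        if not (x.shape == y.shape == z.shape) or x.ndim != 2:
            raise ValueError("x, y, z must be 2-D arrays of identical shape")
        if x.shape[0] != x.shape[1]:
            raise ValueError(f"grid must be square, got shape {x.shape}")
        if not np.all(np.isfinite(z)):
            raise ValueError("grid heights contain non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    @property
    def n(self) -> int:
        """Nodes per axis."""
        return self.x.shape[0]

    def same_template(self, other: "LandscapeGrid") -> bool:
        """True when both grids share the exact same (x, y) node set."""
        return (self.x.shape == other.x.shape
                and np.array_equal(self.x, other.x)
                and np.array_equal(self.y, other.y))

    def points(self) -> np.ndarray:
        """Flatten to an ``(n², 3)`` array of (x, y, z) points, row-major."""
        return np.column_stack([self.x.ravel(), self.y.ravel(), self.z.ravel()])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns x, y, z (row-major node order)."""
        return pd.DataFrame({
            "x": self.x.ravel(), "y": self.y.ravel(), "z": self.z.ravel(),
        })

    @classmethod
    def from_function(cls, fn, domain: Domain, n: int, trait: str = "trait",
                      coefficients: Optional[tuple] = None) -> "LandscapeGrid":
        """Evaluate a height function on the closed ``n x n`` grid."""
        if n < 2:
            raise ValueError(f"grid needs at least 2 nodes per axis, got {n}")
        xs = np.linspace(0.0, domain.x_max, n)
        ys = np.linspace(0.0, domain.y_max, n)
        X, Y = np.meshgrid(xs, ys, indexing="xy")
        Z = np.asarray(fn(X, Y), dtype=float)
        if Z.shape != X.shape:  # constant height functions
            Z = np.broadcast_to(Z, X.shape).copy()
        return cls(X, Y, Z, domain, trait=trait, coefficients=coefficients)
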