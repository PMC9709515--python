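"""Canonical validation surfaces and a geometric-framework simulator.

Two kinds of synthetic input make the whole pipeline testable without
any empirical download:

* canonical surfaces with known geometry — the flat landscape
  ``(x, y, 1)``, the saddle ``(x, y, xy)``, and sphere/cylinder patches
  whose Gauss and mean curvatures are textbook values;
* :func:`simulate_gf_experiment`, which emulates the structure of a
  real GF dataset: diets on nutritional rails (fixed protein:carbohydrate
  ratios) at several dilutions, replicate animals per diet, intakes
  scattered around the rail targets, and trait values generated from a
  known quadratic landscape plus Gaussian noise.

The intake scatter is multiplicative log-normal: animals fed the same
diet realize intakes proportional to, not exactly equal to, the diet
composition, and the spread grows with the intake level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .grids import Domain, LandscapeGrid
from .surfaces import QuadraticSurface, SurfacePatch

__all__ = [
    "flat_surface", "saddle_surface", "canonical_flat", "canonical_saddle",
    "sphere_patch", "cylinder_patch", "GFDesign", "simulate_gf_experiment",
]


def flat_surface(height: float = 1.0) -> QuadraticSurface:
    """The flat landscape ``(x, y, height)``; all curvatures zero."""
    return QuadraticSurface(intercept=height, name="flat")


def saddle_surface() -> QuadraticSurface:
    """The saddle landscape ``(x, y, xy)``.

    At the origin its Gauss curvature is -1, its mean curvature 0 and
    its principal curvatures (1, -1).
    """
    return QuadraticSurface(e=1.0, name="saddle")


def canonical_flat(domain: Domain = None, n: int = 101) -> LandscapeGrid:
    """Grid of the canonical flat landscape ``z = 1``."""
    domain = domain or Domain.unit()
    return LandscapeGrid.from_function(flat_surface().height, domain, n,
                                       trait="flat",
                                       coefficients=(0, 0, 0, 0, 0, 1.0))


def canonical_saddle(domain: Domain = None, n: int = 101) -> LandscapeGrid:
    """Grid of the canonical saddle landscape ``z = xy``."""
    domain = domain or Domain.unit()
    return LandscapeGrid.from_function(saddle_surface().height, domain, n,
                                       trait="saddle",
                                       coefficients=(0, 0, 0, 0, 1.0, 0))


def sphere_patch(r: float = 1.0) -> SurfacePatch:
    """Upper cap of the sphere of radius ``r``: ``z = sqrt(r² - x² - y²)``.

    Gauss curvature is ``1/r²`` everywhere on the cap.  Valid for
    ``x² + y² < r²``; partials are supplied in closed form.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    r2 = r * r

    def z(x, y):
        return np.sqrt(r2 - x ** 2 - y ** 2)

    return SurfacePatch(
        height=z,
        dx=lambda x, y: -x / z(x, y),
        dy=lambda x, y: -y / z(x, y),
        dxx=lambda x, y: -(r2 - y ** 2) / z(x, y) ** 3,
        dyy=lambda x, y: -(r2 - x ** 2) / z(x, y) ** 3,
        dxy=lambda x, y: -(x * y) / z(x, y) ** 3,
        name=f"sphere(r={r})",
    )


def cylinder_patch(r: float = 1.0) -> SurfacePatch:
    """Half-cylinder of radius ``r`` along the y-axis: ``z = sqrt(r² - x²)``.

    An isometric bend of the flat plane: Gauss curvature 0 everywhere
    (no stretching), yet mean curvature ``-1/(2r)`` distinguishes it
    from the plane, whose mean curvature is 0.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    r2 = r * r

    def z(x, y):
        return np.broadcast_to(np.sqrt(r2 - np.asarray(x, float) ** 2),
                               np.broadcast_shapes(np.shape(x), np.shape(y))).copy()

    def zero(x, y):
        return np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y)))

    return SurfacePatch(
        height=z,
        dx=lambda x, y: np.broadcast_to(-np.asarray(x, float) / np.sqrt(r2 - np.asarray(x, float) ** 2),
                                        np.broadcast_shapes(np.shape(x), np.shape(y))).copy(),
        dy=zero,
        dxx=lambda x, y: np.broadcast_to(-r2 / (r2 - np.asarray(x, float) ** 2) ** 1.5,
                                         np.broadcast_shapes(np.shape(x), np.shape(y))).copy(),
        dyy=zero,
        dxy=zero,
        name=f"cylinder(r={r})",
    )


@dataclass(frozen=True)
class GFDesign:
    """Design of a simulated geometric-framework experiment.

    Parameters
    ----------
    rails : sequence of float
        Protein:carbohydrate ratios (P/C) of the diet rails.  The
        defaults span 1:8 to 2:1, the kind of range used in fly
        lifespan/fecundity studies.
    dilutions : sequence of float
        Target total intake (x + y) at each dilution step along a rail.
    replicates : int
        Animals per diet (rail x dilution combination).
    true_surfaces : mapping trait -> QuadraticSurface
        Ground-truth landscape per trait.
    noise_sd : float or mapping trait -> float
        SD of additive Gaussian trait noise.
    intake_jitter_sd : float
        SD (log scale) of the multiplicative log-normal scatter of
        realized intakes around the rail target.
    seed : int
    """

    rails: Sequence[float] = (1 / 8, 1 / 4, 1 / 2, 1.0, 2.0)
    dilutions: Sequence[float] = (0.25, 0.5, 0.75, 1.0)
    replicates: int = 10
    true_surfaces: Mapping[str, QuadraticSurface] = field(
        default_factory=lambda: {"trait": QuadraticSurface(-1.0, -0.5, 1.0, 0.8, 0.5)})
    noise_sd: Union[float, Mapping[str, float]] = 0.1
    intake_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.rails) == 0:
            raise ValueError("design needs at least one nutritional rail")
        if len(self.dilutions) == 0:
            raise ValueError("design needs at least one dilution")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per diet")
        if any(r <= 0 for r in self.rails) or any(d <= 0 for d in self.dilutions):
            raise ValueError("rail ratios and dilutions must be positive")
        if len(self.true_surfaces) == 0:
            raise ValueError("design needs at least one trait surface")
        for sd in self._noise_map().values():
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")
        if self.intake_jitter_sd < 0:
            raise ValueError("intake_jitter_sd must be >= 0")

    def _noise_map(self) -> dict:
        if isinstance(self.noise_sd, Mapping):
            return dict(self.noise_sd)
        return {t: float(self.noise_sd) for t in self.true_surfaces}

    @property
    def traits(self) -> tuple:
        return tuple(self.true_surfaces)


def simulate_gf_experiment(design: GFDesign) -> pd.DataFrame:
    """Simulate one GF experiment; deterministic under the design seed.

    Returns a tidy frame with columns ``x`` (protein intake), ``y``
    (carbohydrate intake), ``rail``, ``dilution`` and one column per
    trait.  Intakes are placed at the rail/dilution targets, perturbed
    by multiplicative log-normal jitter; trait values are the true
    landscape heights plus Gaussian noise.
    """
    rng = np.random.default_rng(design.seed)
    noise = design._noise_map()
    rows = []
    for ratio in design.rails:
        for t in design.dilutions:
            # split the total intake t in the rail's P:C proportion
            x0 = t * ratio / (1.0 + ratio)
            y0 = t / (1.0 + ratio)
            for _ in range(design.replicates):
                jx, jy = np.exp(rng.normal(0.0, design.intake_jitter_sd, 2))
                rows.append((x0 * jx, y0 * jy, ratio, t))
    frame = pd.DataFrame(rows, columns=["x", "y", "rail", "dilution"])
    for trait, surf in design.true_surfaces.items():
        mean = surf.height(frame["x"].to_numpy(), frame["y"].to_numpy())
        frame[trait] = mean + rng.normal(0.0, noise[trait], len(frame))
    return frame
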