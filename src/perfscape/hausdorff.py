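"""Hausdorff distance between performance landscapes.

Two landscapes over a shared (x, y) grid are compared as finite point
sets in 3-space.  The Hausdorff distance

    d_H(S_m, S_n) = max( sup_{a∈S_m} inf_{b∈S_n} |a-b|,
                         sup_{b∈S_n} inf_{a∈S_m} |a-b| )

is the smallest amount by which either set must be dilated to contain
the other; it is zero exactly when the two sets coincide, and symmetric
by construction.

Scale handling before distancing: nutrient axes are min-max
standardized to [0, 1]² (so neither axis dominates) and the trait axis
of each landscape is mean-standardized (divided by its mean, giving
mean 1) so that landscapes measured in different units are comparable.

Confidence intervals come from a paired bootstrap over grid nodes: the
same resampled node indices are applied to both landscapes, preserving
the shared-domain pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import directed_hausdorff as _scipy_directed

from .exceptions import DegenerateScaleError, GridMismatchError
from .fitting import minmax_standardize
from .grids import LandscapeGrid

__all__ = [
    "HausdorffResult", "mean_standardize", "directed_hausdorff",
    "hausdorff_distance", "hausdorff_bootstrap",
]


def mean_standardize(z) -> np.ndarray:
    """Divide a vector by its mean so the result has mean exactly 1.

    Removes scale effects from the trait axis before Hausdorff
    comparison; shape is preserved up to the single scale factor.

    Raises
    ------
    DegenerateScaleError
        If the mean is zero (no scale to remove).
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("cannot standardize an empty vector")
    m = z.mean()
    if not np.isfinite(m):
        raise ValueError("values contain non-finite entries")
    if m == 0:
        raise DegenerateScaleError("cannot mean-standardize a zero-mean vector")
    return z / m


def _as_point_set(A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2 or A.shape[0] == 0:
        raise ValueError("point set must be a nonempty 1-D or 2-D array")
    return A


def directed_hausdorff(A, B) -> float:
    """Directed distance ``sup_{a∈A} inf_{b∈B} |a - b|`` (exact).

    1-D inputs are treated as sets of scalars.  Not symmetric: the
    worked example A = {1, 2}, B = {1, 2, 3, 4} gives 0 from A to B
    (A is contained in B) but 2 from B to A.
    """
    A, B = _as_point_set(A), _as_point_set(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"dimension mismatch: A has {A.shape[1]} coordinates, B has {B.shape[1]}")
    d, _, _ = _scipy_directed(A, B)
    return float(d)


def hausdorff_distance(grid_m: LandscapeGrid, grid_n: LandscapeGrid,
                       standardize: bool = True) -> float:
    """Symmetric Hausdorff distance between two gridded landscapes.

    Both grids must share the same (x, y) template; otherwise the
    comparison is meaningless and a
    :class:`~perfscape.exceptions.GridMismatchError` asks for
    re-gridding onto a common domain.
    """
    Am, An = _landscape_points(grid_m, grid_n, standardize)
    return max(directed_hausdorff(Am, An), directed_hausdorff(An, Am))


def _landscape_points(grid_m: LandscapeGrid, grid_n: LandscapeGrid,
                      standardize: bool) -> tuple[np.ndarray, np.ndarray]:
    if not grid_m.same_template(grid_n):
        raise GridMismatchError(
            "landscape grids do not share the same (x, y) template; "
            "re-grid both traits with predict_grid on a common Domain and "
            "grid size before comparing")
    if standardize:
        xs = minmax_standardize(grid_m.x.ravel())
        ys = minmax_standardize(grid_m.y.ravel())
        zm = mean_standardize(grid_m.z.ravel())
        zn = mean_standardize(grid_n.z.ravel())
    else:
        xs, ys = grid_m.x.ravel(), grid_m.y.ravel()
        zm, zn = grid_m.z.ravel(), grid_n.z.ravel()
    return (np.column_stack([xs, ys, zm]),
            np.column_stack([xs, ys, zn]))


@dataclass(frozen=True)
class HausdorffResult:
    """Point estimate and bootstrap summary for one landscape pair."""

    d_H: float
    directed_mn: float
    directed_nm: float
    boot_mean: float
    boot_sd: float
    lwr95: float
    upr95: float
    n_boot: int
    seed: int
    comparison: str = ""
    samples: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.lwr95 > self.upr95:
            raise ValueError("lower CI bound exceeds upper CI bound")


def hausdorff_bootstrap(grid_m: LandscapeGrid, grid_n: LandscapeGrid,
                        n_boot: int = 1000, seed: int = 0,
                        standardize: bool = True,
                        comparison: str = "",
                        keep_samples: bool = False) -> HausdorffResult:
    """Percentile-bootstrap 95% CI for the Hausdorff distance.

    Grid nodes are resampled with replacement, the *same* node indices
    applied to both landscapes, and the distance recomputed per
    resample.  Deterministic under a fixed seed.
    """
    if n_boot < 2:
        raise ValueError(f"need n_boot >= 2, got {n_boot}")
    Am, An = _landscape_points(grid_m, grid_n, standardize)
    d_mn = directed_hausdorff(Am, An)
    d_nm = directed_hausdorff(An, Am)
    point = max(d_mn, d_nm)

    rng = np.random.default_rng(seed)
    n = Am.shape[0]
    samples = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        Ab, Bb = Am[idx], An[idx]
        samples[b] = max(directed_hausdorff(Ab, Bb), directed_hausdorff(Bb, Ab))
    lwr, upr = np.percentile(samples, [2.5, 97.5])
    return HausdorffResult(
        d_H=point, directed_mn=d_mn, directed_nm=d_nm,
        boot_mean=float(samples.mean()), boot_sd=float(samples.std(ddof=1)),
        lwr95=float(lwr), upr95=float(upr), n_boot=n_boot, seed=seed,
        comparison=comparison,
        samples=samples if keep_samples else None)
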