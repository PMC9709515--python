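"""End-to-end analysis pipeline for one GF dataset.

The canonical analysis, per trait: fit the quadratic landscape to the
intake/trait records, evaluate it on a shared square grid over
``[0, max x] x [0, max y]``, then derive (i) the pointwise Gauss/mean
curvature field, (ii) the surface-area ratio against the flat
reference, and (iii) Hausdorff distances of every landscape against the
flat landscape ``z = 1`` and against every other trait's landscape,
with bootstrap CIs.  The flat reference height is arbitrary — it has
zero curvature and ratio 1 regardless, and mean-standardization removes
it from the Hausdorff comparison.

Every run writes a manifest recording seed, resolution, tolerances and
package versions, and is bitwise reproducible under a fixed config.
"""

from __future__ import annotations

import itertools
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy
import sklearn
import statsmodels

from . import __version__
from .area import area_ratio
from .fitting import fit_quadratic, minmax_standardize, predict_grid
from .geometry import DEFAULT_FLAT_TOL, curvature_field
from .grids import Domain
from .hausdorff import hausdorff_bootstrap
from .io import read_dataset, write_area_report, write_hausdorff_report
from .synthetic import flat_surface

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("perfscape")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    ``seed`` is mandatory: the Hausdorff bootstrap is the one stochastic
    stage and must be reproducible.
    """

    input: object                       # path to CSV, or an in-memory DataFrame
    seed: int
    traits: Optional[Sequence[str]] = None
    grid_n: int = 101
    domain: Optional[Domain] = None     # override; default spans the data
    standardize_domain: bool = False    # min-max intakes to [0,1] before fitting
    flat_height: float = 1.0
    area_tol: float = 1e-8
    flat_tol: float = DEFAULT_FLAT_TOL
    n_boot: int = 1000
    outdir: Optional[object] = None

    def __post_init__(self):
        if self.area_tol <= 0 or self.flat_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    surfaces: dict                      # trait -> QuadraticSurface
    grids: dict                         # trait -> LandscapeGrid (incl. "flat")
    curvature: dict                     # trait -> CurvatureField
    area: list                          # SurfaceAreaResult per trait
    hausdorff: list                     # HausdorffResult per comparison
    manifest: dict
    outdir: Optional[Path] = None


@contextmanager
def _stage(name: str):
    """Abort with the failing stage named, per the pipeline contract."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full landscape-geometry analysis described in the module docstring."""
    with _stage("ingest"):
        if isinstance(config.input, pd.DataFrame):
            data = config.input.copy()
            traits = list(config.traits) if config.traits else [
                c for c in data.columns if c not in ("x", "y", "rail", "dilution")]
        else:
            data = read_dataset(config.input, traits=config.traits)
            traits = data.attrs["traits"]
        if config.standardize_domain:
            data["x"] = minmax_standardize(data["x"].to_numpy())
            data["y"] = minmax_standardize(data["y"].to_numpy())
        domain = config.domain or Domain.from_data(data["x"], data["y"])

    with _stage("fit"):
        surfaces = {t: fit_quadratic(data, t) for t in traits}

    with _stage("grid"):
        grids = {t: predict_grid(s, domain, config.grid_n)
                 for t, s in surfaces.items()}
        flat = flat_surface(config.flat_height)
        grids["flat"] = predict_grid(flat, domain, config.grid_n)

    with _stage("curvature"):
        curvature = {t: curvature_field(surfaces[t], grids[t], tol=config.flat_tol)
                     for t in traits}

    with _stage("area"):
        area = [area_ratio(surfaces[t], domain, tol=config.area_tol, trait=t)
                for t in traits]

    with _stage("hausdorff"):
        pairs = [(t, "flat") for t in traits]
        pairs += list(itertools.combinations(traits, 2))
        hausdorff = [
            hausdorff_bootstrap(grids[m], grids[n], n_boot=config.n_boot,
                                seed=config.seed, comparison=f"{m}-{n}")
            for m, n in pairs
        ]

    manifest = {
        "perfscape": __version__,
        "numpy": np.__version__, "scipy": scipy.__version__,
        "pandas": pd.__version__, "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
        "seed": config.seed, "grid_n": config.grid_n,
        "domain": {"x_max": domain.x_max, "y_max": domain.y_max},
        "standardize_domain": config.standardize_domain,
        "flat_height": config.flat_height,
        "area_tol": config.area_tol, "flat_tol": config.flat_tol,
        "n_boot": config.n_boot,
        "traits": traits,
        "dropped_rows": int(data.attrs.get("dropped_rows", 0)),
        "coefficients": {
            t: dict(zip("abcde", s.coefficients)) | {"intercept": s.intercept}
            for t, s in surfaces.items()
        },
    }

    result = PipelineResult(surfaces=surfaces, grids=grids, curvature=curvature,
                            area=area, hausdorff=hausdorff, manifest=manifest)

    if config.outdir is not None:
        with _stage("write"):
            outdir = Path(config.outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            for t in traits:
                curvature[t].to_frame().to_csv(
                    outdir / f"curvature_{t}.csv", index=False)
            write_area_report(area, outdir / "area.csv")
            write_hausdorff_report(hausdorff, outdir / "hausdorff.csv")
            with open(outdir / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            result.outdir = outdir
            logger.info("pipeline outputs written to %s", outdir)
    return result
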