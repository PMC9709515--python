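"""Readers and writers for the tabular interchange formats.

The input format is a plain CSV with a header row: columns ``x``
(protein intake) and ``y`` (carbohydrate intake) followed by one column
per performance trait.  Rows with missing values are dropped on ingest
with the count logged to the package logger (stderr under the CLI).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["read_dataset", "write_area_report", "write_hausdorff_report",
           "write_comparison_report"]

logger = logging.getLogger("perfscape")

_COORD_COLUMNS = ("x", "y")
_META_COLUMNS = {"rail", "dilution"}  # simulator provenance, not traits


def read_dataset(path, traits: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read and validate a GF dataset CSV.

    Parameters
    ----------
    path : path-like
    traits : sequence of str, optional
        Trait columns to keep.  By default every non-coordinate,
        non-metadata column is treated as a trait.

    Returns
    -------
    DataFrame with columns ``x``, ``y`` and the trait columns; NA rows
    dropped (count logged), intakes checked non-negative and finite.

    Raises
    ------
    SchemaError
        If required columns are absent.
    ValueError
        If no rows survive filtering or intakes are negative.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _COORD_COLUMNS if c not in frame.columns]
    if traits is not None:
        missing += [t for t in traits if t not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}",
            missing=tuple(missing))
    if traits is None:
        traits = [c for c in frame.columns
                  if c not in _COORD_COLUMNS and c not in _META_COLUMNS]
    if not traits:
        raise SchemaError(f"{path.name}: no trait columns found beyond x and y")
    keep = list(_COORD_COLUMNS) + list(traits)
    frame = frame[keep].apply(pd.to_numeric, errors="coerce")
    n_before = len(frame)
    frame = frame.replace([np.inf, -np.inf], np.nan).dropna().reset_index(drop=True)
    dropped = n_before - len(frame)
    if dropped:
        logger.info("read_dataset: dropped %d row(s) with missing/non-finite values "
                    "(%d remain)", dropped, len(frame))
    if frame.empty:
        raise ValueError(f"{path.name}: no complete rows left after filtering")
    if (frame["x"] < 0).any() or (frame["y"] < 0).any():
        raise ValueError(f"{path.name}: nutrient intakes must be non-negative")
    frame.attrs["dropped_rows"] = dropped
    frame.attrs["traits"] = list(traits)
    return frame


def write_area_report(results, path) -> None:
    """Area report CSV: trait, domain, area, flat_area, ratio, tol."""
    rows = [{
        "trait": r.trait,
        "domain_x_max": r.domain.x_max,
        "domain_y_max": r.domain.y_max,
        "area": r.area,
        "flat_area": r.flat_area,
        "ratio": r.ratio,
        "tol": r.tol,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_hausdorff_report(results, path) -> None:
    """Pairwise report CSV: comparison, point estimate, bootstrap summary."""
    rows = [{
        "comparison": r.comparison,
        "d_H": r.d_H,
        "mean": r.boot_mean,
        "sd": r.boot_sd,
        "lwr95": r.lwr95,
        "upr95": r.upr95,
        "n_boot": r.n_boot,
        "seed": r.seed,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_comparison_report(result, path) -> None:
    """Tidy model-comparison CSV (model, trait, resample, rmse_train, rmse_test)."""
    result.frame.to_csv(path, index=False)
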