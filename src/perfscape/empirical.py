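"""Registry for the empirical fly-nutrition benchmark dataset.

The empirical application of this toolkit is a landmark
geometric-framework experiment in *Drosophila melanogaster* measuring
lifespan, lifetime egg production and daily egg production across
protein:carbohydrate rails.  The data are deposited on Dryad
(https://doi.org/10.5061/dryad.tp7519s) and are not redistributed here;
analyses against them are accession-gated: download the deposit, export
the intake/trait table to the standard CSV schema (columns ``x``,
``y``, one column per trait) and run the pipeline on it.

``REFERENCE_RESULTS`` records the published benchmark values so a user
who reruns the pipeline on the download knows what to expect.  Exact
replication depends on choices the original analysis does not fully
pin down (grid resolution, bootstrap unit and count), so agreement
should be judged loosely — same ordering of traits, ratios within a few
percent, Hausdorff CIs overlapping — rather than to the printed digit.
"""

from __future__ import annotations

from pathlib import Path

from .io import read_dataset

__all__ = ["DRYAD_DOI", "TRAITS", "REFERENCE_RESULTS", "load_empirical_dataset"]

DRYAD_DOI = "10.5061/dryad.tp7519s"

TRAITS = ("lifespan", "lifetime_eggs", "daily_eggs")

#: Published benchmark values for the Dryad dataset.  ``tolerance`` is
#: the agreement one should expect when rerunning with this package,
#: given the unstated resolution/bootstrap choices (relative for
#: ratios, CI-overlap for distances).
REFERENCE_RESULTS = {
    "surface_area_ratio": {
        "lifespan": {"value": 51.125, "tolerance": "relative ~5%"},
        "lifetime_eggs": {"value": 49.587, "tolerance": "relative ~5%"},
        "daily_eggs": {"value": 4.194, "tolerance": "relative ~5%"},
    },
    "hausdorff": {
        # comparison: (mean, sd, lwr95, upr95)
        "lifespan-flat": (2.411, 0.270, 1.426, 2.534),
        "lifetime_eggs-flat": (1.940, 0.110, 1.765, 2.186),
        "daily_eggs-flat": (1.783, 0.134, 1.375, 1.967),
        "lifespan-lifetime_eggs": (2.118, 0.177, 1.616, 2.315),
        "lifespan-daily_eggs": (2.615, 0.197, 2.589, 3.311),
        "lifetime_eggs-daily_eggs": (1.661, 0.212, 1.418, 2.214),
        "tolerance": "expect overlapping 95% CIs, not digit-level equality",
    },
}


def load_empirical_dataset(path) -> "pd.DataFrame":  # noqa: F821
    """Load a locally downloaded copy of the Dryad dataset.

    ``path`` must point to a CSV already converted to the standard
    schema (``x``, ``y``, trait columns).  Raises a descriptive
    ``FileNotFoundError`` when the file is absent, since the deposit is
    never bundled with the package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"empirical dataset not found at {path}. This benchmark is "
            f"accession-gated: download it from Dryad (doi:{DRYAD_DOI}), "
            "convert to the standard CSV schema (columns x, y, "
            f"{', '.join(TRAITS)}) and pass that file's path.")
    return read_dataset(path)
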