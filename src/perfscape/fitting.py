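"""Fitting performance landscapes to geometric-framework data.

A geometric-framework (GF) experiment records, per animal, intakes of
two nutrients (protein ``x``, carbohydrate ``y``) and one or more
performance traits ``z`` (lifespan, egg production, ...).  The landscape
of a trait is approximated by the quadratic response surface

    z = a x² + b y² + c x + d y + e xy + intercept,

fitted by ordinary least squares.  That approximation is the load-bearing
assumption of the whole geometry pipeline, so this module also provides
the two smoothers commonly used on GF data — an additive spline GAM and
a thin-plate spline — and :func:`compare_models`, which benchmarks all
three by train/test RMSE over bootstrap resamples of a single 60/40
split.

Estimators follow the scikit-learn protocol (``fit(X, y)`` /
``predict(X)`` with ``X`` of shape ``(n, 2)``) and compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy
import sklearn
import statsmodels
from scipy.interpolate import RBFInterpolator
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.gam.api import BSplines, GLMGam

from .exceptions import DegenerateScaleError, SingularDesignError
from .grids import Domain, LandscapeGrid
from .surfaces import QuadraticSurface

__all__ = [
    "QuadraticLandscape", "AdditiveSplineGAM", "ThinPlateSpline",
    "ModelComparisonResult", "minmax_standardize", "fit_quadratic",
    "predict_grid", "rmse", "compare_models",
]

_DESIGN_COLUMNS = ("x^2", "y^2", "x", "y", "x*y", "intercept")


def minmax_standardize(values) -> np.ndarray:
    """Rescale a vector to [0, 1] as ``(v - min) / (max - min)``.

    Used to put nutrient axes from different experiments on a common
    domain.  Order-preserving; the minimum maps to exactly 0 and the
    maximum to exactly 1.

    Raises
    ------
    DegenerateScaleError
        If the vector is constant (zero range).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateScaleError("need at least two values to standardize")
    lo, hi = np.min(v), np.max(v)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("values contain non-finite entries")
    if hi == lo:
        raise DegenerateScaleError(
            f"cannot min-max standardize a constant vector (all values {lo!r})")
    return (v - lo) / (hi - lo)


def rmse(predicted, observed) -> float:
    """Root-mean-square error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: predicted {p.shape} vs observed {o.shape}")
    if p.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x ** 2, y ** 2, x, y, x * y, np.ones_like(x)])


class QuadraticLandscape(RegressorMixin, BaseEstimator):
    """OLS fit of the quadratic performance landscape.

    Parameters
    ----------
    fit_intercept : bool, default True
        Include a constant term.  The intercept shifts the landscape
        height only; curvature and surface-area are unaffected by it.

    Attributes
    ----------
    coef_ : ndarray of shape (5,)
        ``(a, b, c, d, e)`` for ``a x² + b y² + c x + d y + e xy``.
    intercept_ : float
    surface_ : QuadraticSurface
        The fitted landscape, ready for the geometry pipeline.
    residuals_ : ndarray
        Training residuals ``z - ẑ``.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=1, y_numeric=True)
        if X.shape[1] != 2:
            raise ValueError(f"X must have two columns (protein, carbohydrate); got {X.shape[1]}")
        xs, ys = X[:, 0], X[:, 1]
        D = _design_matrix(xs, ys)
        names = _DESIGN_COLUMNS
        if not self.fit_intercept:
            D = D[:, :5]
            names = names[:5]
        p = D.shape[1]
        if X.shape[0] < p:
            raise SingularDesignError(
                f"need at least {p} records to fit the quadratic landscape, got {X.shape[0]}")
        rank = np.linalg.matrix_rank(D)
        if rank < p:
            collinear = self._collinear_columns(D, names)
            raise SingularDesignError(
                "quadratic design matrix is rank deficient "
                f"(rank {rank} < {p}); collinear columns: {', '.join(collinear)}",
                collinear=collinear)
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        self.coef_ = beta[:5].copy()
        self.intercept_ = float(beta[5]) if self.fit_intercept else 0.0
        self.surface_ = QuadraticSurface(*self.coef_, intercept=self.intercept_)
        self.residuals_ = y - D @ beta
        self.n_features_in_ = 2
        return self

    @staticmethod
    def _collinear_columns(D, names) -> tuple:
        # QR with column pivoting: columns with ~zero R diagonal are the
        # ones that add no new direction
        from scipy.linalg import qr
        _, R, piv = qr(D, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        thresh = diag.max() * max(D.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= thresh]
        return tuple(bad)

    def predict(self, X):
        check_is_fitted(self, "surface_")
        X = check_array(X)
        return np.asarray(self.surface_.height(X[:, 0], X[:, 1]), dtype=float)


class AdditiveSplineGAM(RegressorMixin, BaseEstimator):
    """Generalized additive model ``z ~ s(x) + s(y)`` with B-spline bases.

    Knot placement can be pinned to explicit axis bounds so that a model
    fitted on a bootstrap resample still predicts over the full
    experimental domain.
    """

    def __init__(self, df: int = 6, degree: int = 3, alpha: float = 1.0,
                 bounds: Optional[tuple] = None):
        self.df = df
        self.degree = degree
        self.alpha = alpha
        self.bounds = bounds  # ((x_lo, x_hi), (y_lo, y_hi)) or None

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns")
        if self.bounds is not None:
            (xl, xh), (yl, yh) = self.bounds
            kw = [{"lower_bound": xl, "upper_bound": xh},
                  {"lower_bound": yl, "upper_bound": yh}]
        else:
            kw = None
        self._smoother = BSplines(X, df=[self.df] * 2, degree=[self.degree] * 2,
                                  knot_kwds=kw)
        exog = np.ones((X.shape[0], 1))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            self._result = GLMGam(y, exog, smoother=self._smoother,
                                  alpha=[self.alpha] * 2).fit()
        self._bounds_used = self.bounds
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "_result")
        X = check_array(X)
        if self._bounds_used is not None:
            (xl, xh), (yl, yh) = self._bounds_used
            X = np.column_stack([np.clip(X[:, 0], xl, xh),
                                 np.clip(X[:, 1], yl, yh)])
        exog = np.ones((X.shape[0], 1))
        return np.asarray(self._result.predict(exog, exog_smooth=X), dtype=float)


class ThinPlateSpline(RegressorMixin, BaseEstimator):
    """Thin-plate spline surface ``z = g(x, y)``.

    A small smoothing ridge keeps the radial-basis system well posed
    when the training set contains duplicated rows, as bootstrap
    resamples routinely do.
    """

    def __init__(self, smoothing: float = 1e-3):
        self.smoothing = smoothing

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns")
        self._rbf = RBFInterpolator(X, y, kernel="thin_plate_spline",
                                    smoothing=self.smoothing)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "_rbf")
        X = check_array(X)
        return np.asarray(self._rbf(X), dtype=float)


def fit_quadratic(data: pd.DataFrame, trait: str,
                  fit_intercept: bool = True) -> QuadraticSurface:
    """Fit the quadratic landscape for one trait of a GF dataset.

    ``data`` must carry columns ``x`` (protein intake), ``y``
    (carbohydrate intake) and the named trait.  Returns the fitted
    :class:`~perfscape.surfaces.QuadraticSurface` (named after the
    trait); the full estimator is available via
    :class:`QuadraticLandscape` when residuals are needed.
    """
    for col in ("x", "y", trait):
        if col not in data.columns:
            raise KeyError(f"dataset has no column {col!r}")
    est = QuadraticLandscape(fit_intercept=fit_intercept)
    est.fit(data[["x", "y"]].to_numpy(dtype=float), data[trait].to_numpy(dtype=float))
    return QuadraticSurface(*est.coef_, intercept=est.intercept_, name=trait)


def predict_grid(surface: QuadraticSurface, domain: Domain, n: int = 101) -> LandscapeGrid:
    """Evaluate a fitted landscape on the closed ``n x n`` grid over ``domain``.

    The same ``(domain, n)`` template must be reused across traits of
    one experiment so their grids share identical nodes.
    """
    if n < 2:
        raise ValueError(f"grid size must be >= 2, got {n}")
    coefs = (surface.a, surface.b, surface.c, surface.d, surface.e, surface.intercept)
    return LandscapeGrid.from_function(surface.height, domain, n,
                                       trait=surface.name, coefficients=coefs)


@dataclass
class ModelComparisonResult:
    """Train/test RMSE of the three candidate landscape models.

    ``frame`` is tidy: one row per (model, resample) with columns
    ``model, trait, resample, rmse_train, rmse_test``.
    """

    frame: pd.DataFrame
    trait: str
    split: float
    n_resamples: int
    seed: int
    warnings: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Median train/test RMSE per model."""
        return (self.frame.groupby("model")[["rmse_train", "rmse_test"]]
                .median().reset_index())


def compare_models(data: pd.DataFrame, trait: str, split: float = 0.6,
                   n_resamples: int = 200, seed: int = 0,
                   gam_params: Optional[dict] = None,
                   tps_params: Optional[dict] = None) -> ModelComparisonResult:
    """Benchmark quadratic-LM vs additive GAM vs thin-plate spline.

    The data are split once into training and testing portions
    (``split`` fraction for training, uniformly at random without
    stratification).  For each of ``n_resamples`` bootstrap resamples of
    the training portion, each model is fitted to the resample and its
    RMSE recorded on the resample (train) and on the held-out test set
    (test).  Deterministic under a fixed seed.

    A model whose back-end fails on a given resample is skipped for that
    resample with a warning recorded in the result — never silently.
    """
    for col in ("x", "y", trait):
        if col not in data.columns:
            raise KeyError(f"dataset has no column {col!r}")
    X = data[["x", "y"]].to_numpy(dtype=float)
    z = data[trait].to_numpy(dtype=float)
    n = len(z)
    rng = np.random.default_rng(seed)
    n_train = int(round(split * n))
    if n_train < 6 or n - n_train < 1:
        raise ValueError(
            f"{n} records cannot support a {split:.0%} train split with a full-rank quadratic fit")
    perm = rng.permutation(n)
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    Xtr, ztr = X[train_idx], z[train_idx]
    Xte, zte = X[test_idx], z[test_idx]

    bounds = ((float(X[:, 0].min()), float(X[:, 0].max())),
              (float(X[:, 1].min()), float(X[:, 1].max())))
    gam_params = {"bounds": bounds, **(gam_params or {})}
    tps_params = dict(tps_params or {})

    def make_models():
        return {
            "quadratic-LM": QuadraticLandscape(),
            "additive-smoother": AdditiveSplineGAM(**gam_params),
            "thin-plate-spline": ThinPlateSpline(**tps_params),
        }

    rows, warns = [], []
    for r in range(n_resamples):
        boot = rng.integers(0, n_train, n_train)
        Xb, zb = Xtr[boot], ztr[boot]
        for name, model in make_models().items():
            try:
                model.fit(Xb, zb)
                rows.append({
                    "model": name, "trait": trait, "resample": r,
                    "rmse_train": rmse(model.predict(Xb), zb),
                    "rmse_test": rmse(model.predict(Xte), zte),
                })
            except Exception as exc:  # noqa: BLE001 - recorded, not hidden
                warns.append(f"resample {r}: {name} failed: {exc}")
    frame = pd.DataFrame(rows, columns=["model", "trait", "resample",
                                        "rmse_train", "rmse_test"])
    meta = {
        "n_records": n, "n_train": n_train, "n_test": n - n_train,
        "statsmodels": statsmodels.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }
    return ModelComparisonResult(frame=frame, trait=trait, split=split,
                                 n_resamples=n_resamples, seed=seed,
                                 warnings=warns, metadata=meta)
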