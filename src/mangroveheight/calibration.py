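"""Weighted calibration of DEM elevation to lidar canopy height.

The calibration relates the footprint-maximum DEM elevation (predictor,
``x``) to the GEDI RH98 canopy height (response, ``y``).  Because short
mangroves dominate the global shot corpus by four orders of magnitude,
observations are weighted so that each of six height categories
([0,10), [10,20), …, [40,50), ≥50 m of RH98) contributes equal total mass
to the fit: every shot in a category of :math:`n_c` shots carries weight

.. math:: w_c = \\frac{1}{6\\,n_c}

so that :math:`\\sum_c n_c w_c = 1`.

Four candidate functional forms are fitted by weighted least squares and
compared on Pearson correlation, MAE, RMSE and bias in the original height
units; the square-root-linear form

.. math:: \\widehat{RH98} = (a\\,\\sqrt{x} + b)^2

is fitted as an ordinary WLS line on the √-transformed variables.  The
published global model carries a = 1.02, b = 0.33.

All models are scikit-learn estimators (``fit`` / ``predict`` /
``get_params``) so they compose with sklearn model selection; the
module-level functions are thin wrappers implementing the pipeline steps
(category weights, stratified 70/30 split, candidate fitting, model
selection, raster application).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .raster import RasterTile

#: RH98 category edges in metres: [0,10), [10,20), ..., [40,50), [50, inf)
CATEGORY_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf)
N_CATEGORIES = 6

#: filtered-shot counts per RH98 category of the global GEDI corpus behind
#: the published a=1.02, b=0.33 calibration (printed reference table)
GLOBAL_CATEGORY_COUNTS = (1_532_815, 716_754, 144_514, 19_830, 684, 55)

#: coefficients of the published global calibration
PUBLISHED_MODEL = ("sqrt_linear", 1.02, 0.33)


@dataclass(frozen=True)
class FitMetrics:
    """Agreement metrics in metres (bias = mean of predicted − observed)."""

    corr: float
    mae: float
    rmse: float
    bias: float


def evaluate_metrics(predicted, observed) -> FitMetrics:
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < 2:
        raise ValueError("need at least two pairs to compute metrics")
    resid = predicted - observed
    if np.std(predicted) == 0 or np.std(observed) == 0:
        corr = np.nan
    else:
        corr = float(np.corrcoef(predicted, observed)[0, 1])
    return FitMetrics(corr=corr,
                      mae=float(np.mean(np.abs(resid))),
                      rmse=float(np.sqrt(np.mean(resid**2))),
                      bias=float(np.mean(resid)))


def assign_categories(rh98, edges=CATEGORY_EDGES) -> np.ndarray:
    """0-based category index per height; lower-closed, upper-open bins."""
    rh98 = np.asarray(rh98, dtype=float)
    idx = np.digitize(rh98, edges[1:-1], right=False)
    if np.any(rh98 < edges[0]):
        raise ValueError("height below the first category edge")
    return idx


def compute_category_weights(rh98, edges=CATEGORY_EDGES) -> "pd.DataFrame":
    """Per-category point counts and weights 1/(n × 6).

    Empty categories are excluded (their weight is undefined).  Returns a
    DataFrame indexed by category with columns ``n_points`` and ``weight``.
    """
    import pandas as pd

    idx = assign_categories(rh98, edges)
    counts = np.bincount(idx, minlength=N_CATEGORIES)
    rows = [{"category": c, "lower_m": edges[c], "upper_m": edges[c + 1],
             "n_points": int(n), "weight": 1.0 / (n * N_CATEGORIES)}
            for c, n in enumerate(counts) if n > 0]
    return pd.DataFrame(rows).set_index("category")


def weights_for(rh98, weight_table) -> np.ndarray:
    """Per-observation weight: its category's weight from the table."""
    idx = assign_categories(rh98)
    lut = weight_table["weight"].reindex(range(N_CATEGORIES))
    w = lut.to_numpy()[idx]
    if np.any(~np.isfinite(w)):
        raise ValueError("observation falls in a category absent from the weight table")
    return w


def stratified_split(rh98, frac: float = 0.7, seed: int = 0,
                     edges=CATEGORY_EDGES) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-category 70/30 split; returns (train_idx, valid_idx).

    Within each category, floor(frac × n) indices go to training by uniform
    sampling without replacement; the remainder validate.
    """
    if not (0 < frac < 1):
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = assign_categories(rh98, edges)
    train, valid = [], []
    for c in range(N_CATEGORIES):
        members = np.flatnonzero(idx == c)
        if members.size == 0:
            continue
        n_train = int(np.floor(frac * members.size))
        perm = rng.permutation(members)
        train.append(perm[:n_train])
        valid.append(perm[n_train:])
    return (np.sort(np.concatenate(train)) if train else np.array([], int),
            np.sort(np.concatenate(valid)) if valid else np.array([], int))


# ---------------------------------------------------------------- estimators


class _WlsLineBase(RegressorMixin, BaseEstimator):
    """Shared WLS-line machinery on (optionally transformed) variables."""

    form: str = ""

    def _transform(self, x, y=None):  # pragma: no cover - overridden
        raise NotImplementedError

    def _inverse(self, z):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y, sample_weight=None):
        x = _as_1d(X, "X")
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if np.unique(x).size < 2:
            raise ValueError("need at least two distinct x values")
        w = (np.ones_like(x) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).ravel())
        tx, ty = self._transform(x, y)
        design = sm.add_constant(tx, prepend=False)
        res = sm.WLS(ty, design, weights=w).fit()
        self.a_ = float(res.params[0])
        self.b_ = float(res.params[1])
        self.n_features_in_ = 1
        self.metrics_ = evaluate_metrics(self.predict(X), y)
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        x = _as_1d(X, "X")
        tx, _ = self._transform(x)
        return self._inverse(self.a_ * tx + self.b_)

    def to_dict(self) -> dict:
        check_is_fitted(self, "a_")
        d = {"form": self.form, "a": self.a_, "b": self.b_}
        if hasattr(self, "metrics_"):
            d["metrics"] = asdict(self.metrics_)
        return d


def _as_1d(X, name):
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D or a single-column 2-D array")
    return x


class LinearHeightModel(_WlsLineBase):
    """y = a·x + b by weighted least squares."""

    form = "linear"

    def _transform(self, x, y=None):
        return x, y

    def _inverse(self, z):
        return z


class SqrtLinearHeightModel(_WlsLineBase):
    """√y = a·√x + b fitted by WLS; predictions are (a√x + b)², so they are
    nonnegative for any x ≥ 0.  Requires x ≥ 0 and y ≥ 0."""

    form = "sqrt_linear"

    def _transform(self, x, y=None):
        if np.any(x < 0) or (y is not None and np.any(y < 0)):
            raise ValueError("sqrt_linear requires nonnegative heights")
        return np.sqrt(x), None if y is None else np.sqrt(y)

    def _inverse(self, z):
        return z**2


class PowerLawHeightModel(_WlsLineBase):
    """y = a·x^b fitted as a WLS line on log-log variables (a stored as the
    multiplier, b as the exponent).  Requires strictly positive x and y."""

    form = "power"

    def _transform(self, x, y=None):
        if np.any(x <= 0) or (y is not None and np.any(y <= 0)):
            raise ValueError("power form requires positive heights")
        return np.log(x), None if y is None else np.log(y)

    def _inverse(self, z):
        return np.exp(z)

    def fit(self, X, y, sample_weight=None):
        super().fit(X, y, sample_weight)
        # params are (exponent, log multiplier) on the log-log line
        self.a_, self.b_ = float(np.exp(self.b_)), float(self.a_)
        self.metrics_ = evaluate_metrics(self.predict(X), np.asarray(y, float).ravel())
        return self

    def predict(self, X):
        check_is_fitted(self, "a_")
        x = _as_1d(X, "X")
        if np.any(x <= 0):
            raise ValueError("power form requires positive heights")
        return self.a_ * x**self.b_


class QuadraticHeightModel(_WlsLineBase):
    """y = a·x² + b by WLS on the squared predictor."""

    form = "quadratic"

    def _transform(self, x, y=None):
        return x**2, y

    def _inverse(self, z):
        return z


MODEL_REGISTRY = {cls.form: cls for cls in
                  (LinearHeightModel, SqrtLinearHeightModel,
                   PowerLawHeightModel, QuadraticHeightModel)}


def make_model(form: str, a: float, b: float):
    """Instantiate a calibration model from stored coefficients."""
    model = MODEL_REGISTRY[form]()
    model.a_, model.b_ = float(a), float(b)
    model.n_features_in_ = 1
    return model


def fit_candidates(x, y, sample_weight=None, forms=None) -> list:
    """Fit the candidate forms by WLS; metrics computed in original units.

    Forms whose domain excludes the data (e.g. the power law with zero
    heights) are silently dropped.
    """
    models = []
    for form in forms or MODEL_REGISTRY:
        try:
            models.append(MODEL_REGISTRY[form]().fit(x, y, sample_weight))
        except ValueError as err:
            if "requires" not in str(err):
                raise
    if not models:
        raise ValueError("no candidate form admits the data")
    return models


def select_model(models: list):
    """Lowest RMSE; ties broken by MAE, then |bias|, then higher corr."""
    if not models:
        raise ValueError("empty model list")
    return min(models, key=lambda m: (m.metrics_.rmse, m.metrics_.mae,
                                      abs(m.metrics_.bias), -m.metrics_.corr))


def apply_calibration(model, dem: RasterTile) -> RasterTile:
    """Predict canopy height for every valid DEM pixel; nodata preserved."""
    valid = dem.valid_mask()
    vals = dem.values[valid]
    if np.any(vals < 0):
        raise ValueError("negative heights in DEM; clip before calibrating")
    out = np.full(dem.shape, dem.nodata, dtype=float)
    if vals.size:
        out[valid] = model.predict(vals)
    return dem.with_values(out)


def save_model(model, path: str | Path, extra: dict | None = None) -> None:
    d = model.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    return make_model(d["form"], d["a"], d["b"])
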