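"""Scikit-learn-style estimators for one-sided reference limits.

Two estimators share a fit/predict surface:

* :class:`ENormsLimit` — the indirect route.  ``fit`` takes the *mixed*
  historical sample for one measure, builds the rank-order S-curve, detects
  its plateau, and derives the limit from the plateau extract.
* :class:`ControlLimit` — the traditional route.  ``fit`` takes a healthy
  control sample and derives the limit directly.

Both expose ``limit_`` (a :class:`~enorms.limits.ReferenceLimit`),
``predict(X)`` with the outlier convention (-1 abnormal, +1 normal), and
``flag_abnormal(X)`` returning booleans.  They compose with sklearn
pipelines and ``clone``/``get_params`` as usual.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import compare, limits as limits_mod
from .curve import build_curve
from .exceptions import ContractError
from .limits import IDENTITY, LOG_SHIFT, TransformSpec
from .plateau import detect_plateau_auto, fit_tangent, plateau_values

__all__ = ["ENormsLimit", "ControlLimit"]


def _as_values(X, min_samples: int = 1) -> np.ndarray:
    """Accept a 1-D array or an (n, 1) column and return a 1-D float array."""
    X = check_array(X, ensure_2d=False, dtype=float, ensure_min_samples=min_samples)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ContractError(
                f"expected a single measurement column, got {X.shape[1]} columns"
            )
        X = X[:, 0]
    return X


class _LimitEstimator(OutlierMixin, BaseEstimator):
    """Shared limit-derivation and classification machinery."""

    def __init__(
        self,
        direction="low",
        method="sd",
        k=2.0,
        percentile=1.0,
        transform="auto",
        skew_threshold=0.5,
        measure=None,
    ):
        self.direction = direction
        self.method = method
        self.k = k
        self.percentile = percentile
        self.transform = transform
        self.skew_threshold = skew_threshold
        self.measure = measure

    def _resolve_transform(self, values) -> TransformSpec:
        if isinstance(self.transform, TransformSpec):
            return self.transform
        if self.transform == "auto":
            return limits_mod.choose_transform(
                values, skew_threshold=self.skew_threshold
            )
        if self.transform == "identity":
            return IDENTITY
        if self.transform == "log_shift":
            return LOG_SHIFT
        raise ContractError(f"unknown transform {self.transform!r}")

    def _derive_limit(self, values) -> None:
        if self.method == "sd":
            self.transform_ = self._resolve_transform(values)
            self.limit_ = limits_mod.sd_limit(
                values,
                k=self.k,
                direction=self.direction,
                transform=self.transform_,
                measure=self.measure,
            )
        elif self.method == "percentile":
            self.transform_ = IDENTITY
            self.limit_ = limits_mod.percentile_limit(
                values,
                p=self.percentile,
                direction=self.direction,
                measure=self.measure,
            )
        else:
            raise ContractError(f"method must be sd|percentile, got {self.method!r}")
        self.threshold_ = self.limit_.limit
        self.n_features_in_ = 1

    def flag_abnormal(self, X) -> np.ndarray:
        """Boolean abnormal flags (strictly beyond the fitted limit)."""
        check_is_fitted(self, "limit_")
        return compare.abnormal_mask(_as_values(X), self.limit_)

    def predict(self, X) -> np.ndarray:
        """Outlier-style labels: -1 for abnormal readings, +1 for normal."""
        return np.where(self.flag_abnormal(X), -1, 1)

    def score_samples(self, X) -> np.ndarray:
        """Signed distance to the limit, positive on the normal side."""
        check_is_fitted(self, "limit_")
        v = _as_values(X)
        d = v - self.threshold_
        return d if self.limit_.direction == "low" else -d

    def fit_predict(self, X, y=None):
        return self.fit(X, y).predict(X)


class ControlLimit(_LimitEstimator):
    """Traditional reference limit from a directly sampled healthy cohort.

    Fit on control values only: transform to normality as necessary
    (skewness-triggered shifted log), take mean +/- k*SD on the transformed
    scale, back-transform.

    Parameters
    ----------
    direction : {'low', 'high'}
        The measure's pathological side.
    method : {'sd', 'percentile'}
        Mean +/- k*SD (default) or empirical tail percentile.
    k : float
        SD multiplier (2.0 conventional, 2.5 lenient).
    percentile : float
        Tail percentage for ``method='percentile'`` (default 1.0).
    transform : {'auto', 'identity', 'log_shift'} or TransformSpec
        'auto' picks by sample skewness.

    Attributes
    ----------
    limit_ : ReferenceLimit
    transform_ : TransformSpec
    threshold_ : float
    """

    def fit(self, X, y=None):
        self._derive_limit(_as_values(X))
        return self


class ENormsLimit(_LimitEstimator):
    """Indirect reference limit from a mixed historical sample.

    Fit sorts the sample into the rank-order S-curve, finds the plateau
    (the longest tolerably-linear low-derivative rank window), extracts the
    plateau values, and derives the limit from the extract exactly as the
    traditional route would from controls.

    Parameters
    ----------
    direction, method, k, percentile, transform, skew_threshold, measure
        As in :class:`ControlLimit`.
    window_fraction : float
        Rolling-mean width for the smoothed first differences, as a
        fraction of n (default 0.001).
    rmse_tolerance : float
        Plateau linearity tolerance as a fraction of the value range
        (default 0.005).
    min_size : int or None
        Minimum plateau size; None means ``max(30, 0.1 * n)``.

    Attributes
    ----------
    curve_ : ENormsCurve
    plateau_ : Plateau
    tangent_ : TangentFit
    plateau_values_ : ndarray
    limit_ : ReferenceLimit
    transform_ : TransformSpec
    threshold_ : float
    """

    def __init__(
        self,
        direction="low",
        method="sd",
        k=2.0,
        percentile=1.0,
        transform="auto",
        skew_threshold=0.5,
        measure=None,
        window_fraction=0.001,
        rmse_tolerance=0.005,
        min_size=None,
    ):
        super().__init__(
            direction=direction,
            method=method,
            k=k,
            percentile=percentile,
            transform=transform,
            skew_threshold=skew_threshold,
            measure=measure,
        )
        self.window_fraction = window_fraction
        self.rmse_tolerance = rmse_tolerance
        self.min_size = min_size

    def fit(self, X, y=None):
        values = _as_values(X)
        self.curve_ = build_curve(values, window_fraction=self.window_fraction)
        self.plateau_ = detect_plateau_auto(
            self.curve_,
            rmse_tolerance=self.rmse_tolerance,
            min_size=self.min_size,
        )
        self.tangent_ = fit_tangent(
            self.curve_, self.plateau_.start_rank, self.plateau_.end_rank
        )
        self.plateau_values_ = plateau_values(self.curve_, self.plateau_)
        self._derive_limit(self.plateau_values_)
        return self
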