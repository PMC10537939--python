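"""Two-step prewhitening: temporal LPC(6) and regularized spatial whitening.

The temporal step fits per-sensor linear-predictive-coding coefficients on a
pre-stimulus baseline (Levinson–Durbin on the biased autocorrelation),
averages them across sensors, and applies the prediction-error (MA) filter
to the post-stimulus data.  The spatial step whitens with the inverse
symmetric square root of the baseline noise covariance ridge-regularized by
10% of its largest eigenvalue.  Both are scikit-learn style transformers
operating on (channels × time) arrays.
"""

from __future__ import annotations

from typing import Optional

import h5py
import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.tsa.stattools import levinson_durbin

from .geometry import LeadFieldSet


class TemporalWhitener(BaseEstimator, TransformerMixin):
    """LPC prediction-error filter fitted on baseline noise.

    Parameters
    ----------
    order : int, default 6
        LPC order.  The prediction-error filter is
        ``e(t) = y(t) - sum_{k=1..order} a_k y(t-k)``.
    drop_warmup : bool, default False
        When True, :meth:`transform` zeros out the first ``order`` output
        samples (computed with zero-padded history) instead of returning the
        transient values.

    Attributes
    ----------
    coefficients_ : (order,) array — across-sensor mean a_1..a_order (the
        applied filter).
    per_sensor_coefficients_ : (M, order) array.
    fitted_on_ : int — number of baseline samples per sensor.
    """

    def __init__(self, order: int = 6, drop_warmup: bool = False):
        self.order = order
        self.drop_warmup = drop_warmup

    def fit(self, baseline: np.ndarray, y=None) -> "TemporalWhitener":
        baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
        M, Nb = baseline.shape
        if Nb <= 10 * self.order:
            raise ValueError(f"baseline too short: need > {10 * self.order} samples")
        coefs = np.empty((M, self.order))
        for m in range(M):
            x = baseline[m]
            if np.ptp(x) == 0:
                raise ValueError(f"baseline channel {m} has zero variance")
            # Levinson–Durbin on the biased sample autocorrelation
            _, arcoefs, *_ = levinson_durbin(x - x.mean(), nlags=self.order, isacov=False)
            coefs[m] = arcoefs
        self.per_sensor_coefficients_ = coefs
        self.coefficients_ = coefs.mean(axis=0)
        self.fitted_on_ = Nb
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        if data.shape[1] <= self.order:
            raise ValueError("data shorter than the filter order")
        b = np.concatenate([[1.0], -self.coefficients_])
        out = sps.lfilter(b, [1.0], data, axis=1)
        if self.drop_warmup:
            out = out.copy()
            out[:, : self.order] = 0.0
        return out


class SpatialWhitener(BaseEstimator, TransformerMixin):
    """Symmetric whitening from a ridge-regularized noise covariance.

    The covariance ``C`` is estimated across all concatenated baseline
    samples and regularized as ``C + λI`` with ``λ = shrinkage · λ_max(C)``
    (default 10% of the largest eigenvalue); the whitener is the inverse
    symmetric square root of the regularized covariance.

    Attributes
    ----------
    covariance_ : (M, M) sample noise covariance.
    lambda_ : the ridge actually added.
    whitener_ : (M, M) symmetric ``(C + λI)^{-1/2}``.
    """

    def __init__(self, shrinkage: float = 0.10):
        self.shrinkage = shrinkage

    def fit(self, baseline, y=None) -> "SpatialWhitener":
        X = _concat_trials(baseline)  # (M, total_samples)
        if not np.all(np.isfinite(X)):
            raise ValueError("baseline must be finite")
        M, n = X.shape
        if n <= M:
            import warnings

            warnings.warn(
                "baseline has fewer samples than channels; covariance is "
                "rank-deficient (regularization keeps the whitener defined)",
                stacklevel=2,
            )
        Xc = X - X.mean(axis=1, keepdims=True)
        C = (Xc @ Xc.T) / max(n - 1, 1)
        w, U = np.linalg.eigh(C)
        lam = self.shrinkage * w[-1]
        self.covariance_ = C
        self.lambda_ = float(lam)
        self.whitener_ = (U * (1.0 / np.sqrt(w + lam))) @ U.T
        self._colorer = (U * np.sqrt(w + lam)) @ U.T
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        return self.whitener_ @ np.asarray(data, dtype=float)

    def inverse_transform(self, data: np.ndarray) -> np.ndarray:
        return self._colorer @ np.asarray(data, dtype=float)

    def transform_leadfields(self, lf: LeadFieldSet) -> LeadFieldSet:
        """Whitened forward model: W·L(p) per grid point (and W·l(p))."""
        out = LeadFieldSet(
            grid=lf.grid,
            matrix=np.einsum("ab,pbi->pai", self.whitener_, lf.matrix),
        )
        if lf.fixed_topographies is not None:
            out.fixed_topographies = lf.fixed_topographies @ self.whitener_.T
            out.orientations = lf.orientations
        return out


# ---------------------------------------------------------------------------
# functional wrappers (module operations)
# ---------------------------------------------------------------------------


def fit_lpc(baseline: np.ndarray, order: int = 6) -> TemporalWhitener:
    """Fit a :class:`TemporalWhitener` of the given order on baseline data."""
    return TemporalWhitener(order=order).fit(baseline)


def apply_temporal_whitening(data: np.ndarray, w: TemporalWhitener) -> np.ndarray:
    """Prediction-error filter the data with the fitted mean coefficients."""
    return w.transform(data)


def average_trials(trials) -> np.ndarray:
    """Element-wise mean across a stack/list of equally shaped trials."""
    trials = np.asarray(trials, dtype=float)
    if trials.ndim == 2:
        trials = trials[None]
    if trials.ndim != 3 or trials.shape[0] < 1:
        raise ValueError("need at least one M×N trial")
    return trials.mean(axis=0)


def spatial_whitener_from_baseline(baseline, shrinkage: float = 0.10) -> SpatialWhitener:
    """Fit a :class:`SpatialWhitener` on baseline trial(s)."""
    return SpatialWhitener(shrinkage=shrinkage).fit(baseline)


def _concat_trials(baseline) -> np.ndarray:
    b = np.asarray(baseline, dtype=float)
    if b.ndim == 2:
        return b
    if b.ndim == 3:
        return np.concatenate(list(b), axis=1)
    raise ValueError("baseline must be (M, N) or (n_trials, M, N)")


def estimate_snr_db(data: np.ndarray, baseline: np.ndarray) -> float:
    """Frobenius-norm SNR of a recording, estimated from its baseline.

    The per-sample noise power is taken from the baseline; the per-sample
    signal power is the total data power minus the noise power (floored at
    ``1e-12`` of the data power).  The result is the amplitude-convention dB
    of the implied signal/noise Frobenius ratio,
    ``10·log10(signal_power / noise_power)``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    baseline = np.atleast_2d(np.asarray(baseline, dtype=float))
    if data.size == 0 or baseline.size == 0:
        raise ValueError("data and baseline must be nonempty")
    noise_p = np.sum(baseline**2) / baseline.shape[1]
    data_p = np.sum(data**2) / data.shape[1]
    if noise_p == 0:
        raise ValueError("baseline power is zero")
    signal_p = max(data_p - noise_p, 1e-12 * data_p)
    return float(10.0 * np.log10(signal_p / noise_p))


def save_whiteners(path, temporal: Optional[TemporalWhitener], spatial: Optional[SpatialWhitener]):
    with h5py.File(path, "w") as f:
        if temporal is not None:
            g = f.create_group("lpc")
            g.create_dataset("coeffs", data=temporal.coefficients_)
            g.create_dataset("per_sensor", data=temporal.per_sensor_coefficients_)
            g.attrs["order"] = temporal.order
        if spatial is not None:
            g = f.create_group("spatial")
            g.create_dataset("C", data=spatial.covariance_)
            g.create_dataset("W", data=spatial.whitener_)
            g.attrs["lambda"] = spatial.lambda_
            g.attrs["shrinkage"] = spatial.shrinkage


def load_whiteners(path):
    temporal = spatial = None
    with h5py.File(path, "r") as f:
        if "lpc" in f:
            temporal = TemporalWhitener(order=int(f["lpc"].attrs["order"]))
            temporal.coefficients_ = f["lpc/coeffs"][()]
            temporal.per_sensor_coefficients_ = f["lpc/per_sensor"][()]
            temporal.fitted_on_ = -1
        if "spatial" in f:
            spatial = SpatialWhitener(shrinkage=float(f["spatial"].attrs["shrinkage"]))
            C = f["spatial/C"][()]
            spatial.covariance_ = C
            spatial.whitener_ = f["spatial/W"][()]
            spatial.lambda_ = float(f["spatial"].attrs["lambda"])
            w, U = np.linalg.eigh(C)
            spatial._colorer = (U * np.sqrt(w + spatial.lambda_)) @ U.T
    return temporal, spatial
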