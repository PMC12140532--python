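"""Biomechanical-feature baseline for wrist-based gait-speed estimation.

The comparator extracts five predefined features from each 10-s wrist
window's acceleration magnitude m_t = ||(ax, ay, az)||:

* cadence estimate — 120 x f_peak, with f_peak the dominant non-DC spectral
  peak of the detrended magnitude in the physiologic stride band
  [0.3, 1.5] Hz (cadence 36-180 steps/min);
* acceleration energy — variance of m_t;
* mean absolute jerk — mean |diff(m_t)| x fs;
* hand-swing intensity — RMS of m_t band-passed +/-0.2 Hz around f_peak;
* mean acceleration norm — mean of m_t.

(An altitude-change feature is deliberately absent: no barometric channel.)
A classical regressor (gradient-boosted trees by default, linear fallback)
maps the features to gait speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import LinearRegression

from .errors import ConfigError, DataError
from .preprocess import GaitWindow

#: physiologic stride-frequency search band, Hz
STRIDE_BAND_HZ = (0.3, 1.5)
#: half-width of the hand-swing band-pass around the stride peak, Hz
SWING_HALFWIDTH_HZ = 0.2

FEATURE_NAMES = [
    "cadence_est_spm",
    "accel_energy_g2",
    "mean_abs_jerk_gps",
    "hand_swing_intensity_g",
    "mean_accel_norm_g",
]


@dataclass
class BiomechFeatures:
    cadence_est_spm: float
    accel_energy_g2: float
    mean_abs_jerk_gps: float
    hand_swing_intensity_g: float
    mean_accel_norm_g: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _stride_peak_hz(mag: np.ndarray, fs: float) -> float:
    """Dominant spectral peak of the detrended magnitude in the stride band.

    The spectrum is zero-padded x8 so the peak location is not quantized to
    the coarse 1/T grid of a 10-s window.
    """
    x = mag - np.mean(mag)
    n_fft = 8 * len(x)
    spec = np.abs(np.fft.rfft(x, n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    band = (freqs >= STRIDE_BAND_HZ[0]) & (freqs <= STRIDE_BAND_HZ[1])
    return float(freqs[band][np.argmax(spec[band])])


def biomech_features(window: GaitWindow | np.ndarray, fs: float = 30.0) -> BiomechFeatures:
    """Extract the five-feature set from one wrist window.

    Accepts a GaitWindow or a raw (n, 3) array in g. Raises DataError on a
    degenerate all-zero window.
    """
    if isinstance(window, GaitWindow):
        samples, fs = window.samples, window.fs
    else:
        samples = np.asarray(window, dtype=float)
    mag = np.linalg.norm(samples, axis=1)
    if not mag.any():
        raise DataError("all-zero window is numerically degenerate")
    mean_norm = float(np.mean(mag))
    energy = float(np.mean((mag - mean_norm) ** 2))
    jerk = float(np.mean(np.abs(np.diff(mag))) * fs)
    f_peak = _stride_peak_hz(mag, fs)
    cadence_est = 60.0 * 2.0 * f_peak  # stride freq -> steps/min

    # band-pass around the stride peak via FFT masking
    x = mag - mean_norm
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    mask = np.abs(freqs - f_peak) <= SWING_HALFWIDTH_HZ
    swing = np.fft.irfft(spec * mask, len(x))
    swing_rms = float(np.sqrt(np.mean(swing**2)))

    return BiomechFeatures(
        cadence_est_spm=cadence_est,
        accel_energy_g2=energy,
        mean_abs_jerk_gps=jerk,
        hand_swing_intensity_g=swing_rms,
        mean_accel_norm_g=mean_norm,
    )


def features_table(windows, fs: float = 30.0) -> pd.DataFrame:
    """Feature matrix with one row per window."""
    return pd.DataFrame(
        [biomech_features(w, fs).as_array() for w in windows],
        columns=FEATURE_NAMES,
    )


class BiomechSpeedRegressor(BaseEstimator, RegressorMixin):
    """Classical regressor from the five biomechanical features to speed.

    ``method='gbm'`` (gradient-boosted trees, default) or ``'linear'``.
    Deterministic for a given ``random_state``.
    """

    def __init__(self, method: str = "gbm", random_state: int = 0):
        self.method = method
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise DataError("X must be a 2-D feature matrix")
        if np.isnan(X).any() or np.isnan(y).any():
            raise DataError("NaN in features or targets")
        if X.shape[0] < 10:
            raise DataError("need >= 10 training windows")
        if self.method == "linear":
            if X.shape[0] <= X.shape[1]:
                raise DataError("fewer samples than features for linear fit")
            self.model_ = LinearRegression()
        elif self.method == "gbm":
            self.model_ = HistGradientBoostingRegressor(
                random_state=self.random_state
            )
        else:
            raise ConfigError(f"unknown method {self.method!r}")
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))

    def coefficients(self) -> dict | None:
        """Linear coefficients for persistence; None for tree models."""
        if isinstance(self.model_, LinearRegression):
            return {
                "intercept": float(self.model_.intercept_),
                "coef": self.model_.coef_.tolist(),
                "features": FEATURE_NAMES,
            }
        return None


def fit_speed_regressor(features, speeds, method: str = "gbm",
                        random_state: int = 0) -> BiomechSpeedRegressor:
    """Functional wrapper over :class:`BiomechSpeedRegressor`.

    ``features`` may be a DataFrame, an (n, 5) array, or a list of
    :class:`BiomechFeatures`.
    """
    if len(features) and isinstance(features[0], BiomechFeatures):
        X = np.stack([f.as_array() for f in features])
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy()
    else:
        X = np.asarray(features, dtype=float)
    return BiomechSpeedRegressor(method=method, random_state=random_state).fit(
        X, speeds
    )
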