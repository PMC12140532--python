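"""Window-level reference outcomes: speed, stride length, cadence, regularity.

Speed and stride length for a 10-s window are the median over all complete
strides (start and end both inside the window). Cadence counts complete
strides: N strides x 2 steps/stride x (60 s / 10 s) = 12 N steps/min.

Stride regularity follows the Moe-Nilssen & Helbostad autocorrelation
procedure: the vertical lower-back acceleration is demeaned and normalized
to unit variance, the unbiased autocorrelation

    A(m) = 1/(N - m) * sum_i x_i x_{i+m}

is normalized by A(0), and the coefficient at the lag of the second dominant
peak -- searched within +/-25 % of the mean stride duration -- is the
regularity index. 1 denotes perfectly periodic strides; values are clipped
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import WalkingBout
from .preprocess import GaitWindow

#: half-width of the regularity peak search window, as a fraction of the
#: nominal stride lag
PEAK_SEARCH_FRAC = 0.25


@dataclass
class WindowLabels:
    """The four reference gait outcomes for one window, with validity flags."""

    speed_cms: float
    stride_len_cm: float
    cadence_spm: float
    regularity: float
    speed_valid: bool
    stride_valid: bool
    cadence_valid: bool
    regularity_valid: bool


def _complete_strides(window: GaitWindow, bout: WalkingBout):
    lo, hi = window.start_s, window.end_s
    eps = 1e-9
    return [s for s in bout.strides if s.start_s >= lo - eps and s.end_s <= hi + eps]


def label_speed_stride(
    window: GaitWindow, bout: WalkingBout
) -> tuple[float, float, bool]:
    """Median stride speed (cm/s) and length (cm) over complete strides.

    The even-count median is the mean of the two central values. Returns
    ``valid=False`` (with NaN values) when no complete stride falls inside
    the window.
    """
    strides = _complete_strides(window, bout)
    if not strides:
        return float("nan"), float("nan"), False
    speed = float(np.median([s.speed_cms for s in strides]))
    length = float(np.median([s.length_cm for s in strides]))
    return speed, length, True


def label_cadence(window: GaitWindow, bout: WalkingBout) -> tuple[float, bool]:
    """Cadence in steps/min from the complete-stride count: 12 x N."""
    n = len(_complete_strides(window, bout))
    if n == 0:
        return float("nan"), False
    scale = 2.0 * 60.0 / window.window_s  # strides -> steps -> per minute
    return scale * n, True


def stride_regularity(
    vert: np.ndarray, mean_stride_s: float, fs: float
) -> tuple[float, bool]:
    """Stride-regularity index of a vertical-acceleration segment.

    Parameters
    ----------
    vert : 1-D array
        Vertical acceleration segment (any units; the index is invariant to
        amplitude scaling and DC offset).
    mean_stride_s : float
        Nominal stride duration in seconds; the autocorrelation peak is
        searched within +/-25 % of the corresponding lag.
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    (regularity, valid)
        regularity in [0, 1]; ``valid=False`` for zero-variance segments or
        segments shorter than two stride durations.
    """
    x = np.asarray(vert, dtype=float)
    n = x.size
    lag0 = int(round(mean_stride_s * fs))
    if lag0 < 1 or n < 2 * lag0:
        return float("nan"), False
    sd = np.std(x)
    if sd == 0 or not np.isfinite(sd):
        return float("nan"), False
    x = (x - np.mean(x)) / sd
    a0 = np.dot(x, x) / n  # unbiased A(0) == 1 after normalization
    lo = max(1, int(round(lag0 * (1 - PEAK_SEARCH_FRAC))))
    hi = min(n - 1, int(round(lag0 * (1 + PEAK_SEARCH_FRAC))))
    best = -np.inf
    for m in range(lo, hi + 1):
        a = np.dot(x[:-m], x[m:]) / (n - m)
        if a > best:
            best = a
    reg = best / a0
    return float(np.clip(reg, 0.0, 1.0)), True


def label_window(
    window: GaitWindow,
    bout: WalkingBout,
    lumbar_vert: np.ndarray | None = None,
    lumbar_fs: float | None = None,
) -> WindowLabels:
    """Construct all four reference outcomes for one window.

    ``lumbar_vert`` is the vertical lower-back segment time-aligned with the
    window; regularity is invalid when it is absent. The regularity lag is
    the mean duration of the window's complete strides.
    """
    speed, length, sv = label_speed_stride(window, bout)
    cadence, cv = label_cadence(window, bout)
    reg, rv = float("nan"), False
    if lumbar_vert is not None and lumbar_fs is not None:
        strides = _complete_strides(window, bout)
        if strides:
            mean_stride = float(np.mean([s.duration_s for s in strides]))
            reg, rv = stride_regularity(lumbar_vert, mean_stride, lumbar_fs)
    return WindowLabels(
        speed_cms=speed,
        stride_len_cm=length,
        cadence_spm=cadence,
        regularity=reg,
        speed_valid=sv,
        stride_valid=sv,
        cadence_valid=cv,
        regularity_valid=rv,
    )
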