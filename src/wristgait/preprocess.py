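"""Resampling and bout-aware fixed-window segmentation.

Recordings are resampled to 30 Hz (typical gait content sits below 10 Hz,
so the rate is Nyquist-safe) and each walking bout strictly longer than the
window length is partitioned into 10-s windows advancing by 1 s (90 %
overlap). Windows are anchored at the bout start and never span two bouts;
trailing partial windows are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .errors import ConfigError
from .io import AccelRecording, WalkingBout


@dataclass
class GaitWindow:
    """A fixed-length signal slice tied to one bout.

    ``samples`` is (window_s * fs, 3) in g; ``start_s`` is the window start
    within the recording's time base.
    """

    subject_id: str
    bout_id: str
    start_s: float
    fs: float
    samples: np.ndarray

    @property
    def window_s(self) -> float:
        return self.samples.shape[0] / self.fs

    @property
    def end_s(self) -> float:
        return self.start_s + self.window_s


def resample(rec: AccelRecording, target_fs: float) -> AccelRecording:
    """Resample a recording to ``target_fs`` with polyphase FIR filtering.

    Anti-aliasing is inherent to the polyphase low-pass design when
    downsampling. Duration is preserved to within one output sample.
    """
    if target_fs <= 0:
        raise ConfigError("target_fs must be > 0")
    if np.isclose(rec.fs, target_fs, rtol=1e-9):
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(rec.samples, up, down, axis=0, padtype="line")
    return AccelRecording(
        subject_id=rec.subject_id,
        device_site=rec.device_site,
        fs=target_fs,
        samples=out,
        t0=rec.t0,
        single_axis=rec.single_axis,
    )


def window_count(duration_s: float, window_s: float = 10.0, hop_s: float = 1.0) -> int:
    """Number of windows a bout of the given duration contributes.

    Bouts must be strictly longer than ``window_s``; then
    count = floor((d - window_s)/hop_s) + 1.
    """
    if duration_s <= window_s:
        return 0
    return int(np.floor((duration_s - window_s) / hop_s + 1e-9)) + 1


def extract_windows(
    rec: AccelRecording,
    bouts: list[WalkingBout],
    window_s: float = 10.0,
    hop_s: float = 1.0,
) -> list[GaitWindow]:
    """Cut fixed windows from a (resampled) recording, one bout at a time.

    Only bouts strictly longer than ``window_s`` contribute. Windows start
    at the bout start and advance by ``hop_s`` while the full window fits
    inside the bout. Bout times are interpreted on the recording's relative
    time base.
    """
    n_samp = int(round(window_s * rec.fs))
    out: list[GaitWindow] = []
    for bout in bouts:
        if bout.subject_id != rec.subject_id:
            continue
        n_win = window_count(bout.duration_s, window_s, hop_s)
        for j in range(n_win):
            start = bout.start_s + j * hop_s
            i0 = int(round((start - rec.t0) * rec.fs))
            if i0 < 0 or i0 + n_samp > rec.n_samples:
                continue  # window extends past the recorded signal
            out.append(
                GaitWindow(
                    subject_id=rec.subject_id,
                    bout_id=bout.bout_id,
                    start_s=start,
                    fs=rec.fs,
                    samples=rec.samples[i0 : i0 + n_samp],
                )
            )
    return out
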