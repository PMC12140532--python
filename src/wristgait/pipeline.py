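"""Glue from simulated (or loaded) recordings to windowed ML datasets.

``windowed_dataset`` runs resample -> extract_windows -> label_window over a
cohort and returns the stacked window tensor alongside a tidy label table,
which is what both the biomechanical baseline and the neural regressor
consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import label_window
from .preprocess import extract_windows, resample
from .simulate import SimulatedCohort


def windowed_dataset(
    cohort: SimulatedCohort,
    window_s: float = 10.0,
    hop_s: float = 1.0,
    target_fs: float = 30.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Window every day's wrist recording and attach reference labels.

    Returns
    -------
    X : (n_windows, window_s*target_fs, 3) array
        Wrist window tensor in g.
    meta : DataFrame
        One row per window: subject_id, day, bout_id, start_s, the four
        labels with validity flags, and the subject's disability label.
    """
    disability = {s.subject_id: s.disability for s in cohort.subjects}
    tensors, rows = [], []
    for day in cohort.days:
        wrist = resample(day.wrist, target_fs)
        lumbar = resample(day.lumbar, target_fs)
        windows = extract_windows(wrist, day.bouts, window_s=window_s, hop_s=hop_s)
        bout_by_id = {b.bout_id: b for b in day.bouts}
        n_win = int(round(window_s * target_fs))
        for w in windows:
            i0 = int(round((w.start_s - lumbar.t0) * target_fs))
            vert = lumbar.vertical[i0 : i0 + n_win]
            lab = label_window(w, bout_by_id[w.bout_id], vert, target_fs)
            tensors.append(w.samples)
            rows.append(
                {
                    "subject_id": w.subject_id,
                    "day": day.day,
                    "bout_id": w.bout_id,
                    "start_s": w.start_s,
                    "speed_cms": lab.speed_cms,
                    "stride_len_cm": lab.stride_len_cm,
                    "cadence_spm": lab.cadence_spm,
                    "regularity": lab.regularity,
                    "speed_valid": lab.speed_valid,
                    "stride_valid": lab.stride_valid,
                    "cadence_valid": lab.cadence_valid,
                    "regularity_valid": lab.regularity_valid,
                    "disability": disability[w.subject_id],
                }
            )
    if not tensors:
        n_win = int(round(window_s * target_fs))
        return np.empty((0, n_win, 3)), pd.DataFrame(rows)
    return np.stack(tensors), pd.DataFrame(rows)
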