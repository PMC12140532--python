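"""Synthetic gait-signal generator.

Produces wrist and lower-back acceleration streams with stride-level
annotations and subject-level disability labels, emulating the statistical
structure of a multi-sensor-referenced free-living gait dataset:

* Walking bouts carry internally consistent speed / cadence / stride length
  (speed = stride_length x cadence / 120, exact by construction).
* The wrist signal is a gravity projection under slow orientation drift plus
  an arm-swing sinusoid at stride frequency (cadence/120 Hz), a step-impact
  harmonic at step frequency, and white noise. Arm-swing amplitude is an
  affine, invertible function of gait speed, which guarantees the regression
  problem is solvable.
* The lower-back vertical channel repeats a fixed stride template (stride
  frequency plus its first two harmonics) with per-stride duration jitter
  N(0, jitter_sd^2); higher jitter lowers autocorrelation stride regularity.
* A cohort draws a latent mobility factor per subject: lower latent means
  slower gait, noisier stride timing and fewer / shorter bouts, and drives a
  binary mobility-disability label with a small label-flip probability.

Non-walking segments (idle wrist movement) are generated between bouts and
carry no stride annotations. No claim of biomechanical realism is made for
the idle model; it exists so that windowing is exercised on signals where
walking does not start at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import ConfigError
from .io import (
    AccelRecording,
    StrideAnnotation,
    WalkingBout,
    write_recording,
    write_strides,
)

import pandas as pd


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GaitParams:
    """Gait parameters for one walking bout.

    speed (cm/s), cadence (steps/min) and stride length (cm) obey
    speed = stride_len x cadence / 120 exactly.
    """

    speed_cms: float
    cadence_spm: float
    stride_len_cm: float
    swing_amp_g: float
    impact_amp_g: float = 0.1
    jitter_sd_s: float = 0.0
    noise_sd_g: float = 0.0

    def __post_init__(self) -> None:
        if not (40.0 <= self.cadence_spm <= 160.0):
            raise ConfigError(f"cadence {self.cadence_spm} outside [40, 160] spm")
        if min(self.swing_amp_g, self.impact_amp_g, self.noise_sd_g) < 0:
            raise ConfigError("amplitudes must be >= 0")
        ident = self.stride_len_cm * self.cadence_spm / 120.0
        if abs(ident - self.speed_cms) > 1e-6 * max(1.0, self.speed_cms):
            raise ConfigError("speed != stride_len x cadence / 120")

    @classmethod
    def from_speed_cadence(cls, speed_cms: float, cadence_spm: float, **kw) -> "GaitParams":
        stride = 120.0 * speed_cms / cadence_spm
        return cls(speed_cms=speed_cms, cadence_spm=cadence_spm,
                   stride_len_cm=stride, **kw)

    @property
    def stride_freq_hz(self) -> float:
        return self.cadence_spm / 120.0

    @property
    def stride_period_s(self) -> float:
        return 120.0 / self.cadence_spm


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Cohort-level defaults emulate an older free-living population: mean gait
    speed 110 cm/s with a 25 cm/s shift per SD of the latent mobility factor
    (so the disabled/non-disabled speed gap is on the order of one
    population SD), cadence around 105 steps/min, arm-swing amplitude affine
    in speed (0.05 g + 0.002 g per cm/s), 0.03 g sensor noise, and stride
    timing jitter that grows as mobility declines.
    """

    fs: float = 30.0
    # subject-level structure
    mean_speed_cms: float = 110.0
    speed_latent_slope: float = 25.0
    bout_speed_sd: float = 6.0
    mean_cadence_spm: float = 105.0
    cadence_latent_slope: float = 8.0
    bout_cadence_sd: float = 4.0
    # wrist signal
    swing_intercept_g: float = 0.05
    swing_slope_g_per_cms: float = 0.002
    impact_amp_g: float = 0.1
    noise_sd_g: float = 0.03
    drift_amp_rad: float = 0.15
    #: lognormal sigma of a per-subject multiplicative gain on the wrist
    #: signal's dynamic components (device wear looseness / arm-use habits).
    #: Mobility-irrelevant by construction: it corrupts amplitude-based PA
    #: summaries of multi-day wear but not reference-anchored gait labels.
    #: The single-session training preset turns it off, mirroring snugly
    #: fitted devices in supervised validation recordings.
    wrist_gain_sd: float = 0.15
    # lower-back signal
    lumbar_amp_g: float = 0.3
    # stride-timing jitter: jitter_base * exp(-scale * latent)
    jitter_base_s: float = 0.015
    jitter_latent_scale: float = 0.5
    jitter_min_s: float = 0.002
    jitter_max_s: float = 0.06
    # bout plan
    bouts_per_day_mean: float = 5.0
    bouts_latent_slope: float = 1.0
    bout_dur_lo_s: float = 14.0
    bout_dur_hi_s: float = 40.0
    bout_dur_latent_slope: float = 4.0
    idle_lo_s: float = 6.0
    idle_hi_s: float = 12.0
    # cohort labels
    disability_prevalence: float = 0.3
    label_flip_prob: float = 0.05
    wear_days_range: tuple[int, int] = (2, 7)

    def swing_amp_for_speed(self, speed_cms: float) -> float:
        return self.swing_intercept_g + self.swing_slope_g_per_cms * speed_cms

    def speed_for_swing_amp(self, swing_amp_g: float) -> float:
        """Inverse of the affine swing-speed coupling (recoverability)."""
        return (swing_amp_g - self.swing_intercept_g) / self.swing_slope_g_per_cms

    @classmethod
    def training(cls, **kw) -> "CohortConfig":
        """Single-day variant used to build regression training sets."""
        kw.setdefault("wear_days_range", (1, 1))
        kw.setdefault("bouts_per_day_mean", 4.0)
        kw.setdefault("wrist_gain_sd", 0.0)
        return cls(**kw)


@dataclass
class SubjectSpec:
    subject_id: str
    mobility_latent: float
    disability: int
    wear_days: int
    n_valid_days: int
    speed_mu_cms: float
    cadence_mu_spm: float
    jitter_sd_s: float
    wrist_gain: float = 1.0


@dataclass
class DayRecording:
    """One simulated day: aligned wrist + lower-back streams and true bouts."""

    subject_id: str
    day: int
    wrist: AccelRecording
    lumbar: AccelRecording
    bouts: list[WalkingBout]
    valid: bool = True


@dataclass
class SimulatedCohort:
    subjects: list[SubjectSpec]
    days: list[DayRecording]
    config: CohortConfig

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "disability": s.disability,
                    "wear_days": s.wear_days,
                    "n_valid_days": s.n_valid_days,
                    "mobility_latent": s.mobility_latent,
                }
                for s in self.subjects
            ]
        )

    def days_for(self, subject_id: str) -> list[DayRecording]:
        return [d for d in self.days if d.subject_id == subject_id]


# ---------------------------------------------------------------------------
# single bout
# ---------------------------------------------------------------------------

def _stride_clock(
    params: GaitParams, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Realized stride start times and durations filling ``duration_s``."""
    T = params.stride_period_s
    starts, durs = [], []
    t = 0.0
    while True:
        d = T
        if params.jitter_sd_s > 0:
            d = float(np.clip(T + params.jitter_sd_s * rng.standard_normal(),
                              0.5 * T, 1.5 * T))
        if t + d > duration_s + 1e-9:
            break
        starts.append(t)
        durs.append(d)
        t += d
    return np.asarray(starts), np.asarray(durs)


def _stride_phase(
    t: np.ndarray, starts: np.ndarray, durs: np.ndarray, period_s: float
) -> np.ndarray:
    """Phase in stride cycles: i + (t - start_i)/dur_i inside stride i."""
    if starts.size == 0:
        return t / period_s
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
    phase = idx + (t - starts[idx]) / durs[idx]
    t_end = starts[-1] + durs[-1]
    tail = t >= t_end
    phase[tail] = starts.size + (t[tail] - t_end) / period_s
    return phase


def simulate_bout(
    params: GaitParams,
    duration_s: float,
    fs: float,
    seed: int | None = None,
    subject_id: str = "s000",
    bout_id: str = "b0",
    t0: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[AccelRecording, AccelRecording, WalkingBout]:
    """Simulate one walking bout on wrist and lower-back devices.

    Returns the wrist recording, the (single-axis) lower-back recording and
    the reference bout with one annotation per realized stride. Per-stride
    speed equals ``params.speed_cms`` and per-stride length equals
    speed x realized duration, so the speed/length/cadence identity holds
    within timing jitter.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be > 0")
    if fs < 30:
        raise ConfigError("fs must be >= 30 Hz")
    if fs < 2 * 3 * params.stride_freq_hz:
        raise ConfigError("fs below Nyquist for the third stride harmonic")
    if rng is None:
        rng = np.random.default_rng(seed)

    starts, durs = _stride_clock(params, duration_s, rng)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = _stride_phase(t, starts, durs, params.stride_period_s)
    phi = 2.0 * np.pi * phase

    # wrist: gravity under slow orientation drift + swing + impact + noise
    f_drift = rng.uniform(0.01, 0.04)
    psi = rng.uniform(0, 2 * np.pi)
    theta = 0.15 + DRIFT_AMP_RAD * np.sin(2 * np.pi * f_drift * t + psi)
    swing, impact = params.swing_amp_g, params.impact_amp_g
    # pendular swing decomposed along the instantaneous gravity direction
    # (radial) and orthogonal to it (tangential): the magnitude envelope is
    # then swing_amp to first order regardless of orientation, keeping the
    # affine swing-speed coupling invertible from the wrist signal
    radial = 1.0 + swing * np.sin(phi)
    tangential = 0.4 * swing * np.cos(phi)
    ax = np.sin(theta) * radial + np.cos(theta) * tangential
    ay = 0.2 * swing * np.sin(phi + 0.7)
    az = np.cos(theta) * radial - np.sin(theta) * tangential \
        + impact * np.sin(2 * phi + 0.9)
    wrist_samples = np.column_stack([ax, ay, az])
    if params.noise_sd_g > 0:
        wrist_samples = wrist_samples + params.noise_sd_g * rng.standard_normal(
            wrist_samples.shape
        )

    # lower back: stride template (fundamental + first two harmonics)
    vert = _LUMBAR_AMP_DEFAULT * (
        np.sin(phi) + 0.4 * np.sin(2 * phi) + 0.2 * np.sin(3 * phi)
    )
    if params.noise_sd_g > 0:
        vert = vert + params.noise_sd_g * rng.standard_normal(vert.shape)
    lumbar_samples = np.column_stack([np.zeros(n), np.zeros(n), vert])

    wrist = AccelRecording(subject_id, "wrist", fs, wrist_samples, t0=t0)
    lumbar = AccelRecording(
        subject_id, "lower_back", fs, lumbar_samples, t0=t0, single_axis=True
    )
    strides = [
        StrideAnnotation(
            start_s=t0 + s,
            end_s=t0 + s + d,
            length_cm=params.speed_cms * d,
            speed_cms=params.speed_cms,
        )
        for s, d in zip(starts, durs)
    ]
    bout = WalkingBout(subject_id=subject_id, bout_id=bout_id, strides=strides)
    return wrist, lumbar, bout


_LUMBAR_AMP_DEFAULT = 0.3

#: orientation drift kept well below swing so the stride peak dominates
DRIFT_AMP_RAD = 0.15


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _idle_wrist(duration_s: float, fs: float, rng: np.random.Generator,
                noise_sd_g: float) -> np.ndarray:
    """Non-walking wrist signal: gravity + noise + occasional movement burst."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sig = np.column_stack([np.zeros(n), np.zeros(n), np.ones(n)])
    if rng.uniform() < 0.5 and duration_s > 3:
        f = rng.uniform(1.0, 3.0)
        amp = rng.uniform(0.05, 0.3)
        b0 = rng.uniform(0, duration_s - 2.0)
        mask = (t >= b0) & (t < b0 + rng.uniform(1.0, 2.0))
        axis = rng.integers(0, 3)
        sig[mask, axis] += amp * np.sin(2 * np.pi * f * t[mask])
    sig += max(noise_sd_g, 1e-3) * rng.standard_normal(sig.shape)
    return sig


def _subject_day(
    spec: SubjectSpec, day: int, cfg: CohortConfig, rng: np.random.Generator
) -> DayRecording:
    wrist_parts, lumbar_parts, bouts = [], [], []
    t_cursor = 0.0
    n_bouts = max(
        1,
        rng.poisson(
            max(0.5, cfg.bouts_per_day_mean + cfg.bouts_latent_slope * spec.mobility_latent)
        ),
    )
    for k in range(n_bouts):
        idle = rng.uniform(cfg.idle_lo_s, cfg.idle_hi_s)
        wi = _idle_wrist(idle, cfg.fs, rng, cfg.noise_sd_g)
        wrist_parts.append(wi)
        li = cfg.noise_sd_g * rng.standard_normal((wi.shape[0], 1))
        lumbar_parts.append(np.column_stack([np.zeros_like(li), np.zeros_like(li), li]))
        t_cursor += wi.shape[0] / cfg.fs

        dur = float(
            np.clip(
                rng.uniform(cfg.bout_dur_lo_s, cfg.bout_dur_hi_s)
                + cfg.bout_dur_latent_slope * spec.mobility_latent,
                12.0,
                60.0,
            )
        )
        speed = float(np.clip(rng.normal(spec.speed_mu_cms, cfg.bout_speed_sd), 40, 170))
        cadence = float(np.clip(rng.normal(spec.cadence_mu_spm, cfg.bout_cadence_sd), 60, 160))
        params = GaitParams.from_speed_cadence(
            speed,
            cadence,
            swing_amp_g=cfg.swing_amp_for_speed(speed) * spec.wrist_gain,
            impact_amp_g=cfg.impact_amp_g * spec.wrist_gain,
            jitter_sd_s=spec.jitter_sd_s,
            noise_sd_g=cfg.noise_sd_g,
        )
        w, l, bout = simulate_bout(
            params,
            dur,
            cfg.fs,
            subject_id=spec.subject_id,
            bout_id=f"{spec.subject_id}_d{day}_b{k}",
            t0=t_cursor,
            rng=rng,
        )
        wrist_parts.append(w.samples)
        lumbar_parts.append(l.samples)
        bouts.append(bout)
        t_cursor += w.n_samples / cfg.fs

    wrist = AccelRecording(
        spec.subject_id, "wrist", cfg.fs, np.concatenate(wrist_parts, axis=0)
    )
    lumbar = AccelRecording(
        spec.subject_id,
        "lower_back",
        cfg.fs,
        np.concatenate(lumbar_parts, axis=0),
        single_axis=True,
    )
    return DayRecording(spec.subject_id, day, wrist, lumbar, bouts)


def simulate_cohort(
    n_subjects: int,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a cohort with a latent mobility factor and disability labels.

    The latent factor (standard normal) shifts mean gait speed and cadence,
    scales stride-timing jitter, and modulates bout count and duration.
    Disability is 1 when the latent falls below the prevalence quantile,
    flipped with ``label_flip_prob`` so classification is non-degenerate.
    """
    if n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2 for a stratifiable cohort")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    thr = norm.ppf(cfg.disability_prevalence)
    subjects: list[SubjectSpec] = []
    days: list[DayRecording] = []
    for i in range(n_subjects):
        latent = float(rng.standard_normal())
        disability = int(latent < thr)
        if rng.uniform() < cfg.label_flip_prob:
            disability = 1 - disability
        lo, hi = cfg.wear_days_range
        wear_days = int(rng.integers(lo, hi + 1))
        spec = SubjectSpec(
            subject_id=f"s{i:03d}",
            mobility_latent=latent,
            disability=disability,
            wear_days=wear_days,
            n_valid_days=wear_days,
            speed_mu_cms=float(
                np.clip(cfg.mean_speed_cms + cfg.speed_latent_slope * latent, 50, 160)
            ),
            cadence_mu_spm=float(
                np.clip(cfg.mean_cadence_spm + cfg.cadence_latent_slope * latent, 70, 150)
            ),
            jitter_sd_s=float(
                np.clip(
                    cfg.jitter_base_s * np.exp(-cfg.jitter_latent_scale * latent),
                    cfg.jitter_min_s,
                    cfg.jitter_max_s,
                )
            ),
            wrist_gain=float(
                np.exp(cfg.wrist_gain_sd * rng.standard_normal())
                if cfg.wrist_gain_sd > 0
                else 1.0
            ),
        )
        subjects.append(spec)
        for day in range(wear_days):
            days.append(_subject_day(spec, day, cfg, rng))
    return SimulatedCohort(subjects=subjects, days=days, config=cfg)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def cohort_to_csv(cohort: SimulatedCohort, out_dir: str | Path) -> None:
    """Write the cohort as the canonical recording / stride / subject CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_bouts = []
    for d in cohort.days:
        stem = f"{d.subject_id}_day{d.day}"
        write_recording(d.wrist, out / f"{stem}_wrist.csv")
        write_recording(d.lumbar, out / f"{stem}_lumbar.csv")
        # per-day stride files pair with the matching recording; bout times
        # are on that day's recording time base
        write_strides(d.bouts, out / f"{stem}_strides.csv")
        all_bouts.extend(d.bouts)
    write_strides(all_bouts, out / "strides.csv")
    cohort.subject_table().to_csv(out / "subjects.csv", index=False)
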