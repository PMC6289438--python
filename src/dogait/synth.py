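"""Synthetic-data generators for the gait-analysis pipeline.

Every input the pipeline consumes can be generated here: raw six-channel
gait trials (periodic run waveforms plus gravity offset and noise),
longitudinal dog-month outcome panels drawn from the same local-level
model the trend module fits, covariate series (clinical grading totals,
spontaneous locomotor activity counts), and MRI ROI tables with a
group shift between dystrophic and wild-type dogs.

All generators are pure functions of their arguments including the seed:
the same call produces bit-identical output.

The packaged cohort and missing-data pattern mirror the study design:
five dystrophic and six wild-type beagles followed monthly from 2 to 12
months of age, with named dog-months absent from the thoracic recordings,
the clinical scores and the activity counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mri import MUSCLES, ROIMeasurement
from .signals import ACCEL_RANGE_G, GYRO_RANGE_DPS, TrialRecording
from .trend import Panel, forward_transform, inverse_transform

GAIT_PATTERNS = ("gallop", "trot", "walk")
COVARIATE_KINDS = ("clinical_score", "locomotor_activity")

#: study window: ages 2-12 months
STUDY_MONTHS = tuple(range(2, 13))

#: the eleven-dog cohort in littermate order (id, phenotype, sex)
COHORT = (
    ("13103FN", "WT", "F"),
    ("13102MA", "DYS", "M"),
    ("13301MN", "WT", "M"),
    ("13303MA", "DYS", "M"),
    ("13401MA", "DYS", "M"),
    ("13402FN", "WT", "F"),
    ("13802MA", "DYS", "M"),
    ("13804MN", "WT", "M"),
    ("13805MN", "WT", "M"),
    ("14102MA", "DYS", "M"),
    ("14103MN", "WT", "M"),
)

#: dog-months with incomplete thoracic-region recordings
THORACIC_MISSING = frozenset(
    {("13103FN", m) for m in (2, 3, 4, 5, 11)}
    | {("13102MA", m) for m in (2, 3, 4, 5)}
    | {("13303MA", m) for m in (2, 3)}
    | {("13301MN", m) for m in (2, 3)}
)
#: dog-months with absent clinical grading scores
CLINICAL_MISSING = frozenset({("13303MA", 4), ("13401MA", 2)})
#: dog-months with absent locomotor-activity counts
ACTIVITY_MISSING = frozenset({("13401MA", 2), ("13401MA", 3)})
#: trials where the gravity offset was sampled for only 2-5 s
SHORT_OFFSET_TRIALS = frozenset(
    {("13103FN", m) for m in (2, 3, 4, 5)}
    | {("13102MA", m) for m in (2, 3, 4, 5)}
    | {("13301MN", 5)}
)

#: seven clinical sign categories, each graded 1 (none) to 5 (severe)
N_CLINICAL_SIGNS = 7
CLINICAL_GRADE_MIN, CLINICAL_GRADE_MAX = 1, 5
CLINICAL_TOTAL_MIN = N_CLINICAL_SIGNS * CLINICAL_GRADE_MIN   # 7
CLINICAL_TOTAL_MAX = N_CLINICAL_SIGNS * CLINICAL_GRADE_MAX   # 35


@dataclass(frozen=True)
class GaitProfile:
    """Qualitative description of one phenotype-month's gait waveform.

    Amplitudes are per-axis peak accelerations (G) / angular velocities
    (dps) of the periodic run component; dystrophic profiles at a given
    month carry elementwise lower acceleration amplitudes than the matched
    wild-type profile (dystrophic waves are lower and broader).
    """

    phenotype: str
    gait_pattern: str
    stride_frequency: float          # strides per second
    axis_amplitudes: tuple[float, float, float]   # G, axes X/Y/Z
    gyro_amplitudes: tuple[float, float, float]   # dps
    noise_sd: float                  # G
    gravity_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.phenotype not in ("WT", "DYS"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.gait_pattern not in GAIT_PATTERNS:
            raise ValueError(f"unknown gait_pattern {self.gait_pattern!r}")
        if not 0.5 < self.stride_frequency < 6:
            raise ValueError("stride_frequency must lie in (0.5, 6) strides/s")
        if any(a < 0 for a in self.axis_amplitudes + self.gyro_amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class TruePanelParams:
    """Ground-truth parameters of a generated outcome panel.

    ``m`` is the latent trend on the transformed scale, one entry per study
    month; ``sigma0_sq``/``sigma1_sq`` the observation and evolution
    variances; ``beta`` the covariate coefficient (0 when no covariate).
    """

    m: tuple[float, ...]
    sigma0_sq: float
    sigma1_sq: float
    beta: float
    transform: str

    def __post_init__(self) -> None:
        if self.sigma0_sq <= 0 or self.sigma1_sq <= 0:
            raise ValueError("variances must be strictly positive")
        if self.transform not in ("log", "logit100"):
            raise ValueError(f"unknown transform {self.transform!r}")


#: relative weights of the first three stride harmonics
_HARMONIC_WEIGHTS = np.array([1.0, 0.4, 0.15])
_HARMONIC_NORM = _HARMONIC_WEIGHTS.sum()


def generate_gait_trial(
    profile: GaitProfile,
    duration_s: float = 14.0,
    sampling_interval_ms: float = 20.0,
    seed: int = 0,
    dog_id: str = "SYN",
    region: str = "thoracic",
    month: int = 0,
    standing_s: float = 10.0,
) -> TrialRecording:
    """Simulate one run: a quasi-static standing window then a periodic run.

    The standing window (first ``standing_s`` seconds) contains only the
    gravity offset plus sensor noise; the remainder is the run segment,
    a sum of up to three harmonics at the stride frequency per axis with
    per-axis amplitudes from the profile, on top of gravity and noise.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    if sampling_interval_ms <= 0:
        raise ValueError(
            f"sampling_interval_ms must be positive, got {sampling_interval_ms}"
        )
    if duration_s < 4:
        raise ValueError(
            f"duration_s must be at least 4 s (standing window plus run), "
            f"got {duration_s}"
        )
    standing_s = min(standing_s, duration_s - 2.0)
    if standing_s < 2.0:
        raise ValueError("standing_s must leave at least a 2 s standing window")

    dt = sampling_interval_ms / 1000.0
    n = int(round(duration_s / dt))
    n_stand = int(round(standing_s / dt))
    t = np.arange(n) * dt

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phases = rng.uniform(0, 2 * np.pi, size=(6, 3))  # channel x harmonic
    run = np.zeros((n, 6))
    run_t = t[n_stand:] - t[n_stand]
    amps = np.array(profile.axis_amplitudes + profile.gyro_amplitudes)
    for ch in range(6):
        wave = np.zeros_like(run_t)
        for h in range(3):
            wave += _HARMONIC_WEIGHTS[h] * np.sin(
                2 * np.pi * (h + 1) * profile.stride_frequency * run_t
                + phases[ch, h]
            )
        run[n_stand:, ch] = amps[ch] / _HARMONIC_NORM * wave

    accel = run[:, :3] + np.asarray(profile.gravity_vector)
    gyro = run[:, 3:]
    if profile.noise_sd > 0:
        accel = accel + rng.normal(0.0, profile.noise_sd, size=accel.shape)
        # gyro noise scaled to the sensor's dps range
        gyro = gyro + rng.normal(
            0.0, profile.noise_sd * GYRO_RANGE_DPS / ACCEL_RANGE_G, size=gyro.shape
        )
    accel = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)
    gyro = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)

    return TrialRecording(
        dog_id=dog_id,
        phenotype=profile.phenotype,
        region=region,
        month=month,
        sampling_interval=dt,
        accel=accel,
        gyro=gyro,
        standing_window=(0, n_stand),
        run_segment=(n_stand, n),
    )


def generate_panel(
    params: TruePanelParams,
    dog_ids: Sequence[str],
    months: Sequence[int],
    covariate_table: Optional[Mapping[tuple[str, int], float]] = None,
    missing: frozenset[tuple[str, int]] = frozenset(),
    seed: int = 0,
    extra_columns: Optional[Mapping[str, str]] = None,
) -> Panel:
    """Draw an outcome panel from the local-level generative model.

    For each non-missing (dog, month) a transformed value is drawn from
    N(m_t + beta * x_it, sigma0^2) and back-transformed to the natural
    scale (exp for log; 100/(1+exp(-z)) for logit100, which keeps ratios
    strictly inside (0, 100)).  ``extra_columns`` adds constant metadata
    columns (e.g. phenotype, region).  The returned panel records the true
    parameters for recovery tests.
    """
    months_arr = np.asarray(list(months), dtype=int)
    if months_arr.size == 0 or np.any(np.diff(months_arr) != 1):
        raise ValueError("months must be contiguous")
    if len(params.m) != months_arr.size:
        raise ValueError(
            f"params.m has {len(params.m)} entries for {months_arr.size} months"
        )
    if covariate_table is None and params.beta != 0:
        raise ValueError("beta != 0 requires a covariate_table")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma0 = np.sqrt(params.sigma0_sq)
    rows = []
    for dog in dog_ids:
        for ti, month in enumerate(months_arr):
            if (dog, int(month)) in missing:
                continue
            x = None
            loc = params.m[ti]
            if covariate_table is not None:
                x = float(covariate_table[(dog, int(month))])
                loc = loc + params.beta * x
            z = rng.normal(loc, sigma0)
            value = float(inverse_transform(np.array(z), params.transform))
            if params.transform == "logit100":
                assert 0.0 < value < 100.0, "logit100 back-transform left (0,100)"
            row = {"dog_id": dog, "month": int(month), "value": value}
            if x is not None:
                row["covariate"] = x
            rows.append(row)
    df = pd.DataFrame(rows)
    if extra_columns:
        for col, val in extra_columns.items():
            df[col] = val
    return Panel(
        data=df, transform=params.transform, months=months_arr,
        true_params=params,
    )


def generate_covariate_series(
    kind: str,
    dog_ids: Sequence[str],
    months: Sequence[int],
    severity: float = 0.5,
    seed: int = 0,
) -> dict[tuple[str, int], float]:
    """Per-(dog, month) covariate values.

    ``clinical_score``: integer totals of seven sign grades (each 1-5, so
    totals in [7, 35]), non-decreasing with month then plateauing; severity
    scales how high and how fast scores rise (severity 0 leaves every sign
    at grade 1, total 7).

    ``locomotor_activity``: non-negative movement counts summed over the
    07:00-09:00 window, trending downward with month when severity > 0.
    """
    if kind not in COVARIATE_KINDS:
        raise ValueError(f"unknown covariate kind {kind!r}")
    if not 0 <= severity <= 1:
        raise ValueError("severity must lie in [0, 1]")
    months_arr = np.asarray(list(months), dtype=int)
    t0, t_end = months_arr.min(), months_arr.max()
    span = max(t_end - t0, 1)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    out: dict[tuple[str, int], float] = {}
    for dog in dog_ids:
        if kind == "clinical_score":
            # per-dog peak total and ramp midpoint; logistic rise, then plateau
            peak = CLINICAL_TOTAL_MIN + severity * (
                CLINICAL_TOTAL_MAX - CLINICAL_TOTAL_MIN
            ) * rng.uniform(0.6, 1.0)
            mid = t0 + span * rng.uniform(0.3, 0.7)
            rate = rng.uniform(0.6, 1.2)
            for m in months_arr:
                ramp = 1.0 / (1.0 + np.exp(-rate * (m - mid)))
                ramp0 = 1.0 / (1.0 + np.exp(-rate * (t0 - mid)))
                frac = (ramp - ramp0) / (1.0 - ramp0)
                score = CLINICAL_TOTAL_MIN + round((peak - CLINICAL_TOTAL_MIN) * frac)
                out[(dog, int(m))] = float(
                    min(max(score, CLINICAL_TOTAL_MIN), CLINICAL_TOTAL_MAX)
                )
        else:
            base = rng.uniform(3000, 5000)  # healthy morning activity counts
            for m in months_arr:
                decline = 1.0 - 0.8 * severity * (m - t0) / span
                noise = rng.lognormal(0.0, 0.05)
                out[(dog, int(m))] = float(
                    np.round(max(base * decline * noise, 0.0))
                )
    return out


#: default wild-type mean T2 intensities per crus muscle (arbitrary units)
DEFAULT_BASE_INTENSITIES = {
    "TC": 60.0, "EDL": 62.0, "FDL": 58.0, "FHL": 57.0,
    "GM": 55.0, "GL": 56.0, "FDS": 54.0,
}


def generate_mri_rois(
    muscles: Sequence[str] = MUSCLES,
    group: str = "WT",
    n_rois_per_side: int = 3,
    group_shift: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    base_intensities: Optional[Mapping[str, float]] = None,
    noise_sd: float = 2.0,
    sd_air: float = 4.0,
    pixel_range: tuple[int, int] = (60, 180),
) -> list[ROIMeasurement]:
    """ROI table for one subject: intensities, pixel counts, shared SD_air.

    Dystrophic intensities are the wild-type base plus ``group_shift``
    (scalar or per-muscle mapping) plus ROI noise; with zero shift and
    zero noise the two groups are identical under the same seed.
    """
    if group not in ("WT", "DYS"):
        raise ValueError(f"unknown group {group!r}")
    if n_rois_per_side not in (2, 3):
        raise ValueError(
            f"n_rois_per_side must be 2 or 3, got {n_rois_per_side}"
        )
    base = dict(DEFAULT_BASE_INTENSITIES)
    if base_intensities:
        base.update(base_intensities)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rois = []
    for muscle in muscles:
        shift = (
            group_shift.get(muscle, 0.0)
            if isinstance(group_shift, Mapping) else group_shift
        )
        shift = shift if group == "DYS" else 0.0
        for side in ("Right", "Left"):
            for i in range(1, n_rois_per_side + 1):
                intensity = base[muscle] + shift + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                )
                pixels = int(rng.integers(pixel_range[0], pixel_range[1] + 1))
                rois.append(ROIMeasurement(
                    muscle=muscle, side=side, roi_index=i,
                    mean_intensity=max(float(intensity), 0.0),
                    pixel_count=pixels, sd_air=sd_air,
                ))
    return rois
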