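"""Signal processing for triaxial accelerometer/gyroscope gait trials.

A trial is one 15-m run recorded by a trunk-mounted hybrid sensor: three
acceleration channels (X caudal-cranial, Y medial-lateral, Z ventral-dorsal,
in G) and three angular-velocity channels (in degrees per second, dps),
sampled every 20 ms.  The chain is:

1. estimate the gravity (DC) offset on a quasi-static standing window and
   subtract it from the acceleration channels;
2. restrict all channels to the start→goal run segment;
3. summarise the trial as mean absolute values per axis (Ax, Ay, Az,
   Gx, Gy, Gz), the trial-averaged acceleration magnitude
   AM_k = sqrt(ax_k^2 + ay_k^2 + az_k^2), and the three acceleration
   ratios (per-sample percentage contribution of each axis to AM,
   averaged over the trial).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: hardware dynamic range of the hybrid sensor
ACCEL_RANGE_G = 8.0
GYRO_RANGE_DPS = 1000.0

#: standing windows shorter than this are rejected as unusable calibration
MIN_STANDING_S = 1.0
#: standing windows shorter than this raise a warning (shortened-offset trials)
SHORT_STANDING_S = 6.0

PHENOTYPES = ("WT", "DYS")
REGIONS = ("thoracic", "lumbar")


@dataclass
class TrialRecording:
    """Raw (or offset-corrected) six-channel recording of one run.

    ``accel`` and ``gyro`` are ``(L, 3)`` arrays sharing one length L.
    ``standing_window`` and ``run_segment`` are half-open index intervals
    ``[a, b)`` into the sample axis; they must not overlap.
    """

    dog_id: str
    phenotype: str
    region: str
    month: int
    sampling_interval: float  # seconds between samples
    accel: np.ndarray
    gyro: np.ndarray
    standing_window: Optional[tuple[int, int]]
    run_segment: tuple[int, int]
    offset_corrected: bool = False

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel must be an (L, 3) array")
        if self.gyro.shape != self.accel.shape:
            raise ValueError("gyro must match accel shape (six channels, one length)")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        L = self.n_samples
        s, g = self.run_segment
        if not (0 <= s < g <= L):
            raise ValueError(f"run_segment [{s}, {g}) out of bounds for length {L}")
        if self.standing_window is not None:
            a, b = self.standing_window
            if not (0 <= a < b <= L):
                raise ValueError(
                    f"standing_window [{a}, {b}) out of bounds for length {L}"
                )
            if max(a, s) < min(b, g):
                raise ValueError("standing_window and run_segment overlap")
        if not self.offset_corrected:
            # raw samples must respect the sensor's dynamic range
            if np.any(np.abs(self.accel) > ACCEL_RANGE_G * (1 + 1e-9)):
                raise ValueError(f"raw acceleration exceeds +/-{ACCEL_RANGE_G} G")
        if np.any(np.abs(self.gyro) > GYRO_RANGE_DPS * (1 + 1e-9)):
            raise ValueError(f"angular velocity exceeds +/-{GYRO_RANGE_DPS} dps")
        n_sat = int(
            np.sum(np.abs(self.accel) >= ACCEL_RANGE_G)
            + np.sum(np.abs(self.gyro) >= GYRO_RANGE_DPS)
        )
        if n_sat:
            logger.info(
                "trial %s m%d %s: %d samples at the sensor range limit "
                "(possible clipping)",
                self.dog_id, self.month, self.region, n_sat,
            )

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sampling_interval


def remove_gravity_offset(trial: TrialRecording) -> TrialRecording:
    """Subtract the standing-window mean from every acceleration sample.

    Gravity enters the acceleration channels as a DC component; while the
    dog stands still the channels measure gravity plus noise, so their
    standing-window mean estimates the offset.  Angular-velocity channels
    are left untouched.  Idempotent: the corrected standing-window mean
    is zero, so applying twice equals applying once.
    """
    if trial.standing_window is None:
        raise ValueError("standing_window is unset: no calibration segment")
    a, b = trial.standing_window
    dur = (b - a) * trial.sampling_interval
    if dur < MIN_STANDING_S:
        raise ValueError(
            f"standing window of {dur:.2f} s is below the {MIN_STANDING_S} s "
            "minimum: unusable gravity calibration"
        )
    if dur < SHORT_STANDING_S:
        warnings.warn(
            f"shortened standing window ({dur:.1f} s); offset estimate is noisier",
            stacklevel=2,
        )
    offset = trial.accel[a:b].mean(axis=0)
    return replace(
        trial, accel=trial.accel - offset, offset_corrected=True,
    )


def segment_run(
    trial: TrialRecording, window: Optional[tuple[int, int]] = None
) -> TrialRecording:
    """Restrict all six channels to the start→goal run segment.

    ``window`` overrides ``trial.run_segment`` (used when composing nested
    segmentations).  The returned trial's run segment spans its whole
    length and the standing window is dropped (its indices no longer
    refer to retained samples).
    """
    s, g = window if window is not None else trial.run_segment
    if not (0 <= s < g <= trial.n_samples):
        raise ValueError(f"segment [{s}, {g}) out of bounds")
    if g - s < 2:
        raise ValueError(f"degenerate run segment [{s}, {g}): fewer than 2 samples")
    return replace(
        trial,
        accel=trial.accel[s:g],
        gyro=trial.gyro[s:g],
        standing_window=None,
        run_segment=(0, g - s),
    )


def mean_abs(channel: Sequence[float]) -> float:
    """Arithmetic mean of absolute values of one channel."""
    x = np.asarray(channel, dtype=float)
    if x.size == 0:
        raise ValueError("mean_abs of an empty channel")
    return float(np.mean(np.abs(x)))


def am_series(
    ax: Sequence[float], ay: Sequence[float], az: Sequence[float]
) -> np.ndarray:
    """Per-sample acceleration magnitude sqrt(ax^2 + ay^2 + az^2)."""
    ax, ay, az = (np.asarray(c, dtype=float) for c in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape) or ax.ndim != 1 or ax.size < 1:
        raise ValueError("am_series requires three equal-length 1-D sequences")
    return np.sqrt(ax * ax + ay * ay + az * az)


def trial_am(
    ax: Sequence[float], ay: Sequence[float], az: Sequence[float]
) -> float:
    """Trial-averaged acceleration magnitude (mean of the AM series)."""
    return float(am_series(ax, ay, az).mean())


def acceleration_ratios(
    ax: Sequence[float], ay: Sequence[float], az: Sequence[float]
) -> tuple[tuple[float, float, float], int]:
    """Per-axis percentage contribution to AM, averaged over samples.

    For each retained sample k the ratio of axis j is
    ``100 * |a_jk| / AM_k``; the returned value per axis is the mean over
    samples.  Samples with AM_k = 0 carry no directional information and
    are dropped from the average; their count is returned alongside the
    three ratios.  Per sample the three ratios sum to between 100 and
    100*sqrt(3), hence so do their means.
    """
    ax, ay, az = (np.asarray(c, dtype=float) for c in (ax, ay, az))
    am = am_series(ax, ay, az)
    keep = am > 0
    n_dropped = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("all samples have AM = 0: no motion to apportion")
    if n_dropped:
        logger.info("acceleration_ratios: dropped %d zero-AM samples", n_dropped)
    ratios = tuple(
        float(np.mean(100.0 * np.abs(c[keep]) / am[keep])) for c in (ax, ay, az)
    )
    return ratios, n_dropped  # type: ignore[return-value]


@dataclass
class TrialSummary:
    """The eleven per-trial outcomes plus provenance."""

    dog_id: str
    phenotype: str
    region: str
    month: int
    Ax: float
    Ay: float
    Az: float
    AM: float
    Ax_ratio: float
    Ay_ratio: float
    Az_ratio: float
    Gx: float
    Gy: float
    Gz: float
    n_samples: int = 0
    n_ratio_dropped: int = 0
    provenance: Optional[TrialRecording] = field(default=None, repr=False)

    def as_row(self) -> dict:
        return {
            "dog_id": self.dog_id,
            "phenotype": self.phenotype,
            "region": self.region,
            "month": self.month,
            "Ax": self.Ax, "Ay": self.Ay, "Az": self.Az, "AM": self.AM,
            "Ax_ratio": self.Ax_ratio,
            "Ay_ratio": self.Ay_ratio,
            "Az_ratio": self.Az_ratio,
            "Gx": self.Gx, "Gy": self.Gy, "Gz": self.Gz,
        }


def summarize_trial(trial: TrialRecording) -> TrialSummary:
    """Compute the per-trial outcome vector from a corrected, segmented trial.

    Expects the pipeline order: gravity-offset removal (on the standing
    window of the full recording) then run segmentation; summaries are
    taken over all retained samples.
    """
    if not trial.offset_corrected:
        raise ValueError("trial must be offset-corrected before summarising")
    s, g = trial.run_segment
    acc = trial.accel[s:g]
    gyr = trial.gyro[s:g]
    ax, ay, az = acc[:, 0], acc[:, 1], acc[:, 2]
    ratios, n_dropped = acceleration_ratios(ax, ay, az)
    return TrialSummary(
        dog_id=trial.dog_id,
        phenotype=trial.phenotype,
        region=trial.region,
        month=trial.month,
        Ax=mean_abs(ax), Ay=mean_abs(ay), Az=mean_abs(az),
        AM=trial_am(ax, ay, az),
        Ax_ratio=ratios[0], Ay_ratio=ratios[1], Az_ratio=ratios[2],
        Gx=mean_abs(gyr[:, 0]), Gy=mean_abs(gyr[:, 1]), Gz=mean_abs(gyr[:, 2]),
        n_samples=g - s,
        n_ratio_dropped=n_dropped,
        provenance=trial,
    )


def process_trial(trial: TrialRecording) -> TrialSummary:
    """Full chain: offset removal → segmentation → summary."""
    return summarize_trial(segment_run(remove_gravity_offset(trial)))


def summaries_to_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Tidy table of trial summaries, one row per trial."""
    return pd.DataFrame([s.as_row() for s in summaries])


def session_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of pass summaries per (dog, region, month) session."""
    keys = ["dog_id", "phenotype", "region", "month"]
    return summaries.groupby(keys, as_index=False).mean(numeric_only=True)


# ---------------------------------------------------------------------------
# on-disk trial format: CSV of samples + JSON sidecar of segments/metadata

TRIAL_CSV_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]


def write_trial(trial: TrialRecording, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        np.column_stack([trial.time, trial.accel, trial.gyro]),
        columns=TRIAL_CSV_COLUMNS,
    )
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "dog_id": trial.dog_id,
        "phenotype": trial.phenotype,
        "region": trial.region,
        "month": trial.month,
        "sampling_interval": trial.sampling_interval,
        "standing_window": list(trial.standing_window)
        if trial.standing_window is not None else None,
        "run_segment": list(trial.run_segment),
        "offset_corrected": trial.offset_corrected,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trial(csv_path: str | Path) -> TrialRecording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return TrialRecording(
        dog_id=meta["dog_id"],
        phenotype=meta["phenotype"],
        region=meta["region"],
        month=int(meta["month"]),
        sampling_interval=float(meta["sampling_interval"]),
        accel=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
        gyro=df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(),
        standing_window=tuple(meta["standing_window"])
        if meta["standing_window"] is not None else None,
        run_segment=tuple(meta["run_segment"]),
        offset_corrected=bool(meta["offset_corrected"]),
    )
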