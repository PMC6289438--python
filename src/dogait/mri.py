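"""MRI signal-to-noise analysis of crus muscles and correlation with gait.

Each region of interest (ROI) drawn on a T2-weighted image yields a mean
signal intensity and a pixel count; the background noise standard
deviation (SD_air) converts intensity to a signal-to-noise ratio,
SNR = intensity / SD_air.  A muscle's bilateral average SNR (Ave SNR) is
the pixel-count-weighted mean of its ROI SNRs over both sides:

    Ave SNR = (sum_i SNR_i,R * Pixel_i,R + sum_i SNR_i,L * Pixel_i,L) / Pixel_Total

Group comparisons (dystrophic vs wild-type) use the Mann-Whitney U test;
associations between acceleration magnitude (AM) and Ave SNR use
Pearson's correlation, both at the 5% significance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MUSCLES = ("TC", "EDL", "FDL", "FHL", "GM", "GL", "FDS")
SIDES = ("Right", "Left")

#: predominant myosin-heavy-chain grouping of the crus muscles (metadata
#: only; GM is the sign exception among slow muscles in group contrasts)
FAST_MUSCLES = ("TC", "EDL")
SLOW_MUSCLES = ("GM", "GL", "FDS")

ALPHA = 0.05

#: largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (the study compares 5 vs 6 dogs)
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class ROIMeasurement:
    """One manually drawn ROI on one side of one muscle."""

    muscle: str
    side: str
    roi_index: int
    mean_intensity: float
    pixel_count: int
    sd_air: float

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be Right or Left, got {self.side!r}")
        if not 1 <= self.roi_index <= 3:
            raise ValueError("roi_index must be 1..3")
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be non-negative")
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        if self.sd_air <= 0:
            raise ValueError("sd_air must be positive")


@dataclass(frozen=True)
class MuscleSNR:
    muscle: str
    ave_snr: float
    total_pixels: int
    n_rois: int


def roi_snr(m: ROIMeasurement) -> float:
    """Signal-to-noise ratio of one ROI: mean intensity / SD_air."""
    return m.mean_intensity / m.sd_air


def average_snr(rois: Sequence[ROIMeasurement]) -> MuscleSNR:
    """Pixel-weighted bilateral average SNR of one muscle's ROIs."""
    if len(rois) == 0:
        raise ValueError("average_snr of an empty ROI list")
    muscles = {r.muscle for r in rois}
    if len(muscles) != 1:
        raise ValueError(f"mixed muscles in one average: {sorted(muscles)}")
    snrs = np.array([roi_snr(r) for r in rois])
    pixels = np.array([r.pixel_count for r in rois], dtype=float)
    total = int(pixels.sum())
    ave = float((snrs * pixels).sum() / total)
    return MuscleSNR(
        muscle=rois[0].muscle, ave_snr=ave, total_pixels=total, n_rois=len(rois)
    )


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    """U of group A from its pooled midranks."""
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    ``method``: "exact" enumerates all C(n_a+n_b, n_a) group assignments of
    the pooled midranks (valid with ties); "normal" uses the Gaussian
    approximation with tie correction; "auto" picks exact when the combined
    sample size is at most 12 (covers the study's 5 vs 6 design).

    Returns (U of group_a, two-sided p).  The two-sided p is the null
    probability that |U - n_a n_b / 2| is at least as large as observed.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mu = n_a * n_b / 2.0

    if method == "auto":
        method = "exact" if n_a + n_b <= EXACT_MW_LIMIT else "normal"

    if method == "exact":
        dev = abs(u_obs - mu) - 1e-9
        hits = 0
        idx = range(n_a + n_b)
        for subset in combinations(idx, n_a):
            u = _u_statistic(ranks[list(subset)], n_a)
            if abs(u - mu) >= dev:
                hits += 1
        p = hits / comb(n_a + n_b, n_a)
    elif method == "normal":
        n = n_a + n_b
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            zstat = (abs(u_obs - mu) - 0.5) / np.sqrt(var)  # continuity corrected
            p = float(2 * stats.norm.sf(max(zstat, 0.0)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return u_obs, min(float(p), 1.0)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson's r and its two-sided p (t distribution, n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def rois_from_frame(df: pd.DataFrame) -> dict[str, list[ROIMeasurement]]:
    """Group a ROI table (one row per ROI) into per-muscle measurement lists."""
    out: dict[str, list[ROIMeasurement]] = {}
    for _, row in df.iterrows():
        m = ROIMeasurement(
            muscle=row["muscle"],
            side=row["side"],
            roi_index=int(row["roi_index"]),
            mean_intensity=float(row["mean_intensity"]),
            pixel_count=int(row["pixel_count"]),
            sd_air=float(row["sd_air"]),
        )
        out.setdefault(m.muscle, []).append(m)
    return out


def subject_ave_snrs(roi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(dog, muscle) Ave SNR table from a long ROI table.

    Expects columns dog_id, phenotype, muscle, side, roi_index,
    mean_intensity, pixel_count, sd_air.
    """
    rows = []
    for (dog, phen), sub in roi_table.groupby(["dog_id", "phenotype"], sort=True):
        for muscle, rois in sorted(rois_from_frame(sub).items()):
            ms = average_snr(rois)
            rows.append({
                "dog_id": dog, "phenotype": phen, "muscle": muscle,
                "ave_snr": ms.ave_snr, "total_pixels": ms.total_pixels,
                "n_rois": ms.n_rois,
            })
    return pd.DataFrame(rows)


def group_snr_comparison(snr_table: pd.DataFrame) -> pd.DataFrame:
    """Per-muscle Mann-Whitney comparison of Ave SNRs between phenotypes."""
    rows = []
    for muscle in MUSCLES:
        sub = snr_table[snr_table["muscle"] == muscle]
        dys = sub[sub["phenotype"] == "DYS"]["ave_snr"].to_numpy()
        wt = sub[sub["phenotype"] == "WT"]["ave_snr"].to_numpy()
        if dys.size == 0 or wt.size == 0:
            continue
        u, p = mann_whitney_u(dys, wt)
        rows.append({
            "muscle": muscle,
            "median_dys": float(np.median(dys)),
            "median_wt": float(np.median(wt)),
            "U": u, "p": p, "significant": p < ALPHA,
        })
    return pd.DataFrame(rows)


def am_snr_correlation_table(
    am_table: pd.DataFrame,
    snr_table: pd.DataFrame,
    regions: Sequence[str] = ("thoracic", "lumbar"),
    muscles: Sequence[str] = MUSCLES,
) -> pd.DataFrame:
    """Pearson correlations between per-dog AM and per-muscle Ave SNR.

    ``am_table`` has one row per (dog_id, region) with an ``AM`` column;
    ``snr_table`` one row per (dog_id, muscle) with ``ave_snr``.  Returns
    one record per (region, muscle) with r, p and the 5%-level flag.
    Negative r means dogs with worse muscle involvement (higher SNR)
    accelerate less.
    """
    rows = []
    for region in regions:
        am_r = am_table[am_table["region"] == region].set_index("dog_id")["AM"]
        for muscle in muscles:
            snr_m = snr_table[snr_table["muscle"] == muscle].set_index("dog_id")[
                "ave_snr"
            ]
            dogs = sorted(set(am_r.index) & set(snr_m.index))
            if len(dogs) < 3:
                raise ValueError(
                    f"fewer than 3 dogs with complete data for ({region}, {muscle})"
                )
            r, p = pearson_correlation(snr_m.loc[dogs], am_r.loc[dogs])
            rows.append({
                "region": region, "muscle": muscle, "n": len(dogs),
                "r": r, "p": p, "significant": p < ALPHA,
            })
    return pd.DataFrame(rows)
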