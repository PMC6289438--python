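"""End-to-end synthetic study: simulate → process → fit trends → MRI.

Stages are pure functions of their inputs plus hierarchically derived
seeds (one base seed; per-dog/stage children), so adding a dog or a stage
does not perturb other draws and a rerun with the same configuration and
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .mri import am_snr_correlation_table, group_snr_comparison, subject_ave_snrs
from .signals import (
    TrialRecording,
    process_trial,
    session_means,
    summaries_to_frame,
    write_trial,
)
from .synth import (
    ACTIVITY_MISSING,
    CLINICAL_MISSING,
    SHORT_OFFSET_TRIALS,
    THORACIC_MISSING,
    GaitProfile,
    TruePanelParams,
    generate_covariate_series,
    generate_gait_trial,
    generate_mri_rois,
    generate_panel,
)
from .trend import (
    LocalLevelFit,
    Panel,
    compare_trends,
    fit_local_level,
    forward_transform,
)

logger = logging.getLogger(__name__)

_MOD = 2**31


def derive_seed(base: int, *parts) -> int:
    """Stable child seed from a base seed and a path of labels."""
    key = zlib.crc32("/".join(str(p) for p in parts).encode())
    return int(np.random.SeedSequence([int(base) % _MOD, key]).generate_state(1)[0] % _MOD)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


# ---------------------------------------------------------------------------
# stage 1: trial simulation

def _dog_factor(cfg: StudyConfig, dog_id: str, phenotype: str) -> float:
    lo, hi = (
        cfg.gait.dog_factor_range_dys
        if phenotype == "DYS" else cfg.gait.dog_factor_range_wt
    )
    rng = np.random.default_rng(derive_seed(cfg.seed, "dogfactor", dog_id))
    return float(rng.uniform(lo, hi))


def profile_for(
    cfg: StudyConfig, phenotype: str, region: str, month: int,
    dog_factor: float = 1.0,
) -> GaitProfile:
    """Gait profile for one phenotype-region-month (optionally one dog).

    Dystrophic amplitudes are the matched wild-type amplitudes scaled by a
    factor that declines linearly over the study window (their waves are
    lower and broader: also a slower stride), so at every month the
    canonical dystrophic profile is elementwise below the wild-type one.
    """
    g = cfg.gait
    base_ax = np.asarray(g.wt_axis_amplitudes[region], dtype=float)
    base_gy = np.asarray(g.wt_gyro_amplitudes[region], dtype=float)
    months = cfg.months
    if phenotype == "DYS":
        frac = (month - months[0]) / max(months[-1] - months[0], 1)
        factor = g.dys_factor_start + (g.dys_factor_end - g.dys_factor_start) * frac
        pattern = "trot" if frac > 0.5 else "gallop"
    else:
        factor = 1.0
        pattern = "gallop"
    return GaitProfile(
        phenotype=phenotype,
        gait_pattern=pattern,
        stride_frequency=g.stride_frequency[phenotype],
        axis_amplitudes=tuple(base_ax * factor * dog_factor),
        gyro_amplitudes=tuple(base_gy * factor * dog_factor),
        noise_sd=g.noise_sd,
    )


@_stage("simulate")
def simulate_trials(cfg: StudyConfig) -> list[TrialRecording]:
    """All per-pass trial recordings, honouring the missing-data pattern."""
    trials = []
    for dog in cfg.dogs:
        factor = _dog_factor(cfg, dog.id, dog.phenotype)
        for region in cfg.regions:
            for month in cfg.months:
                if (
                    cfg.apply_missing_pattern
                    and region == "thoracic"
                    and (dog.id, month) in THORACIC_MISSING
                ):
                    continue
                standing = cfg.trial.standing_s
                if cfg.apply_missing_pattern and (dog.id, month) in SHORT_OFFSET_TRIALS:
                    standing = 4.0  # shortened-offset sessions
                profile = profile_for(cfg, dog.phenotype, region, month, factor)
                for p in range(cfg.trial.passes_per_session):
                    trials.append(generate_gait_trial(
                        profile,
                        duration_s=cfg.trial.duration_s,
                        sampling_interval_ms=cfg.trial.sampling_interval_ms,
                        seed=derive_seed(cfg.seed, "trial", dog.id, region, month, p),
                        dog_id=dog.id,
                        region=region,
                        month=month,
                        standing_s=standing,
                    ))
    return trials


@_stage("process")
def process_trials(
    trials: list[TrialRecording],
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Per-trial summaries, per-session means and total dropped-sample count."""
    import warnings as _warnings

    summaries = []
    for trial in trials:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # shortened standing windows
            summaries.append(process_trial(trial))
    df = summaries_to_frame(summaries)
    dropped = int(sum(s.n_ratio_dropped for s in summaries))
    return df, session_means(df), dropped


# ---------------------------------------------------------------------------
# stage 2: panels and trend fits

def anchors_to_trend(
    anchors: dict, months: list[int], transform: str
) -> tuple[float, ...]:
    """True trend m_t: linear interpolation of natural-scale anchors on the
    transformed scale."""
    ms = sorted(int(k) for k in anchors)
    vals = np.array([float(anchors[k]) for k in ms])
    z = forward_transform(vals, transform)
    return tuple(np.interp(np.asarray(months, float), np.asarray(ms, float), z))


def _region_missing(cfg: StudyConfig, region: str) -> frozenset:
    if cfg.apply_missing_pattern and region == "thoracic":
        return THORACIC_MISSING
    return frozenset()


@_stage("fit-trends")
def trend_stage(
    cfg: StudyConfig,
) -> tuple[dict[tuple[str, str, str], tuple[Panel, LocalLevelFit]], dict]:
    """Per (outcome, region, phenotype): simulate a panel from the
    generative model and fit the local-level trend.  Returns the fits and
    per-(outcome, region) group comparisons."""
    fits: dict[tuple[str, str, str], tuple[Panel, LocalLevelFit]] = {}
    comparisons: dict[tuple[str, str], pd.DataFrame] = {}
    for spec in cfg.outcomes:
        for region in cfg.regions:
            for phen in ("WT", "DYS"):
                dogs = cfg.dogs_of(phen)
                if not dogs or region not in spec.anchors.get(phen, {}):
                    continue
                m_true = anchors_to_trend(
                    spec.anchors[phen][region], cfg.months, spec.transform
                )
                params = TruePanelParams(
                    m=m_true, sigma0_sq=spec.sigma0_sq,
                    sigma1_sq=spec.sigma1_sq, beta=0.0,
                    transform=spec.transform,
                )
                panel = generate_panel(
                    params, dogs, cfg.months,
                    missing=_region_missing(cfg, region),
                    seed=derive_seed(cfg.seed, "panel", spec.name, region, phen),
                    extra_columns={
                        "phenotype": phen, "region": region, "outcome": spec.name,
                    },
                )
                mcmc = replace(
                    cfg.mcmc,
                    seed=derive_seed(cfg.seed, "mcmc", spec.name, region, phen),
                )
                fits[(spec.name, region, phen)] = (
                    panel, fit_local_level(panel, mcmc=mcmc)
                )
            if (spec.name, region, "WT") in fits and (spec.name, region, "DYS") in fits:
                comparisons[(spec.name, region)] = compare_trends(
                    fits[(spec.name, region, "WT")][1],
                    fits[(spec.name, region, "DYS")][1],
                )
    return fits, comparisons


# ---------------------------------------------------------------------------
# stage 3: covariate-coefficient fits (dystrophic dogs only)

_COVARIATE_MISSING = {
    "clinical_score": CLINICAL_MISSING,
    "locomotor_activity": ACTIVITY_MISSING,
}


@_stage("covariates")
def covariate_stage(
    cfg: StudyConfig,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], LocalLevelFit]]:
    """Covariate-coefficient fits on dystrophic panels.

    For each covariate kind, outcome and region: generate the covariate
    series, standardize it, simulate a dystrophic panel with the planted
    beta, fit, and collect the coefficient forest table.
    """
    dys = cfg.dogs_of("DYS")
    if len(dys) == 0:
        logger.info("covariate stage skipped: no dystrophic dogs in cohort")
        return pd.DataFrame(), {}
    rows = []
    fits: dict[tuple[str, str, str], LocalLevelFit] = {}
    for kind in cfg.covariates.kinds:
        series = generate_covariate_series(
            kind, dys, cfg.months, severity=cfg.covariates.severity,
            seed=derive_seed(cfg.seed, "covariate", kind),
        )
        vals = np.array(list(series.values()))
        sd = vals.std()
        if cfg.standardize_covariate and sd > 0:
            series = {k: (v - vals.mean()) / sd for k, v in series.items()}
        for spec in cfg.outcomes:
            beta = float(spec.betas.get(kind, 0.0))
            for region in cfg.regions:
                if region not in spec.anchors.get("DYS", {}):
                    continue
                m_true = anchors_to_trend(
                    spec.anchors["DYS"][region], cfg.months, spec.transform
                )
                params = TruePanelParams(
                    m=m_true, sigma0_sq=spec.sigma0_sq,
                    sigma1_sq=spec.sigma1_sq, beta=beta,
                    transform=spec.transform,
                )
                missing = _region_missing(cfg, region) | (
                    _COVARIATE_MISSING[kind] if cfg.apply_missing_pattern
                    else frozenset()
                )
                panel = generate_panel(
                    params, dys, cfg.months,
                    covariate_table=series,
                    missing=frozenset(missing),
                    seed=derive_seed(
                        cfg.seed, "covpanel", kind, spec.name, region
                    ),
                    extra_columns={
                        "phenotype": "DYS", "region": region,
                        "outcome": spec.name,
                    },
                )
                mcmc = replace(
                    cfg.mcmc,
                    seed=derive_seed(
                        cfg.seed, "covmcmc", kind, spec.name, region
                    ),
                )
                fit = fit_local_level(panel, mcmc=mcmc)
                fits[(kind, spec.name, region)] = fit
                assert fit.beta is not None
                rows.append({
                    "covariate": kind,
                    "outcome": spec.name,
                    "region": region,
                    "beta_true": beta,
                    "beta_mean": fit.beta["mean"],
                    "beta_lower": fit.beta["lower"],
                    "beta_upper": fit.beta["upper"],
                    "excludes_zero": fit.beta["excludes_zero"],
                    "converged": fit.diagnostics.get("converged", True),
                })
    return pd.DataFrame(rows), fits


# ---------------------------------------------------------------------------
# stage 4: MRI simulation, SNR comparison and AM correlation

@_stage("mri")
def mri_stage(
    cfg: StudyConfig, sessions: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Simulate per-dog ROI tables coupled to end-of-study gait AM.

    Dystrophic intensities carry the group shift plus a per-muscle
    coupling to the dog's standardized AM, so fast-muscle Ave SNRs
    correlate negatively with AM (worse involvement, less propulsion) and
    slow muscles positively, with the gastrocnemius medial head planted
    as the negative exception.
    """
    last_month = cfg.months[-1]
    final = sessions[sessions["month"] == last_month]
    am_table = final[["dog_id", "phenotype", "region", "AM"]].reset_index(drop=True)

    dys_ids = cfg.dogs_of("DYS")
    am_std: dict[str, float] = {}
    if dys_ids:
        ref_region = "lumbar" if "lumbar" in cfg.regions else cfg.regions[0]
        ref = (
            am_table[
                (am_table["phenotype"] == "DYS")
                & (am_table["region"] == ref_region)
            ]
            .set_index("dog_id")["AM"]
        )
        mu, sd = ref.mean(), ref.std()
        for dog in dys_ids:
            am_std[dog] = float((ref[dog] - mu) / sd) if sd > 0 else 0.0

    roi_rows = []
    for dog in cfg.dogs:
        if dog.phenotype == "DYS":
            shift = {
                m: cfg.mri.group_shift
                + cfg.mri.coupling.get(m, 0.0)
                * cfg.mri.coupling_scale
                * am_std.get(dog.id, 0.0)
                for m in cfg.mri.coupling
            }
        else:
            shift = 0.0
        rois = generate_mri_rois(
            group=dog.phenotype,
            n_rois_per_side=cfg.mri.n_rois_per_side,
            group_shift=shift,
            seed=derive_seed(cfg.seed, "mri", dog.id),
            noise_sd=cfg.mri.noise_sd,
            sd_air=cfg.mri.sd_air,
        )
        for r in rois:
            roi_rows.append({
                "dog_id": dog.id, "phenotype": dog.phenotype,
                "muscle": r.muscle, "side": r.side, "roi_index": r.roi_index,
                "mean_intensity": r.mean_intensity,
                "pixel_count": r.pixel_count, "sd_air": r.sd_air,
            })
    roi_df = pd.DataFrame(roi_rows)
    snr_df = subject_ave_snrs(roi_df)
    out = {"rois": roi_df, "snr": snr_df, "am": am_table}
    if dys_ids and cfg.dogs_of("WT"):
        out["snr_comparison"] = group_snr_comparison(snr_df)
    if len(dys_ids) >= 3:
        out["am_snr_correlation"] = am_snr_correlation_table(
            am_table[am_table["phenotype"] == "DYS"],
            snr_df[snr_df["phenotype"] == "DYS"],
            regions=cfg.regions,
        )
    else:
        logger.info("AM-SNR correlation skipped: fewer than 3 dystrophic dogs")
    return out


# ---------------------------------------------------------------------------
# full study

def run_study(cfg: StudyConfig, out_dir: str | Path) -> dict:
    """Run the whole synthetic study and write its report bundle.

    Writes per-trial/session summary CSVs (and raw trial CSVs when
    ``cfg.write_trials``), per-fit trend JSON/CSV, the coefficient forest
    table, the MRI SNR and correlation tables, and a run manifest
    recording versions, seeds, dropped-sample counts and convergence
    flags.  Deterministic given the configuration and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.name,
        "seed": cfg.seed,
        "versions": {
            "dogait": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "skipped": [],
    }

    trials = simulate_trials(cfg)
    manifest["stages"]["simulate"] = {"n_trials": len(trials)}
    if cfg.write_trials:
        tdir = out / "trials"
        tdir.mkdir(exist_ok=True)
        for i, tr in enumerate(trials):
            write_trial(
                tr, tdir / f"{tr.dog_id}_{tr.region}_m{tr.month:02d}_p{i % max(cfg.trial.passes_per_session, 1)}.csv"
            )

    summaries, sessions, dropped = process_trials(trials)
    summaries.to_csv(out / "trial_summaries.csv", index=False)
    sessions.to_csv(out / "session_means.csv", index=False)
    manifest["stages"]["process"] = {
        "n_summaries": len(summaries), "n_zero_am_samples_dropped": dropped,
    }

    fits, comparisons = trend_stage(cfg)
    fdir = out / "fits"
    fdir.mkdir(exist_ok=True)
    conv = {}
    for (name, region, phen), (panel, fit) in fits.items():
        stem = f"{name}_{region}_{phen}"
        panel.to_csv(fdir / f"panel_{stem}.csv")
        fit.to_json(fdir / f"fit_{stem}.json")
        fit.trend_frame().to_csv(fdir / f"trend_{stem}.csv", index=False)
        conv[stem] = fit.diagnostics.get("converged", True)
    for (name, region), comp in comparisons.items():
        comp.to_csv(fdir / f"compare_{name}_{region}.csv", index=False)
    manifest["stages"]["fit-trends"] = {"n_fits": len(fits), "converged": conv}

    coef_table, cov_fits = covariate_stage(cfg)
    if len(coef_table):
        coef_table.to_csv(out / "coefficients.csv", index=False)
        manifest["stages"]["covariates"] = {
            "n_fits": len(cov_fits),
            "converged": {
                "_".join(k): f.diagnostics.get("converged", True)
                for k, f in cov_fits.items()
            },
        }
    else:
        manifest["skipped"].append(
            {"stage": "covariates", "reason": "no dystrophic dogs in cohort"}
        )

    mri_out = mri_stage(cfg, sessions)
    mri_out["rois"].to_csv(out / "mri_rois.csv", index=False)
    mri_out["snr"].to_csv(out / "mri_snr.csv", index=False)
    if "snr_comparison" in mri_out:
        mri_out["snr_comparison"].to_csv(out / "mri_snr_comparison.csv", index=False)
    if "am_snr_correlation" in mri_out:
        mri_out["am_snr_correlation"].to_csv(
            out / "am_snr_correlation.csv", index=False
        )
    else:
        manifest["skipped"].append(
            {"stage": "am-snr-correlation",
             "reason": "fewer than 3 dystrophic dogs"}
        )
    manifest["stages"]["mri"] = {"n_rois": len(mri_out["rois"])}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
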