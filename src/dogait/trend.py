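"""Bayesian local-level trend models for unbalanced dog-month panels.

The model: each group (wild-type or dystrophic) shares one latent trend
m_t that evolves as a Gaussian random walk,

    m_t ~ N(m_{t-1}, sigma1^2),

observed through every dog i measured at month t,

    z_it ~ N(m_t + beta * x_it, sigma0^2),

where z is the transformed outcome — log(y) for positive outcomes
(accelerations, angular velocities, activity counts) or the logit of a
percentage, log(r / (100 - r)), for acceleration ratios — and x_it is an
optional covariate (clinical score or locomotor activity) with scalar
coefficient beta.  There is no per-dog random effect: all dogs in a group
inform the same trend.

Inference is Gibbs sampling: the state sequence is drawn jointly by
forward-filtering backward-sampling (FFBS), the two variances by conjugate
inverse-gamma updates, and beta by a conjugate normal update.  An exact
Kalman filter/smoother over the same state space serves as the
fixed-variance oracle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSFORMS = ("log", "logit100")

#: split-chain convergence statistic above this flags non-convergence
RHAT_THRESHOLD = 1.05


# ---------------------------------------------------------------------------
# transforms

def forward_transform(values: np.ndarray, transform: str) -> np.ndarray:
    """Map natural-scale outcomes to the model's Gaussian scale."""
    v = np.asarray(values, dtype=float)
    if transform == "log":
        if np.any(v <= 0):
            bad = int(np.argmax(v <= 0))
            raise ValueError(f"log transform requires value > 0 (row {bad}: {v.flat[bad]})")
        return np.log(v)
    if transform == "logit100":
        if np.any((v <= 0) | (v >= 100)):
            bad = int(np.argmax((v <= 0) | (v >= 100)))
            raise ValueError(
                f"logit100 transform requires 0 < value < 100 (row {bad}: {v.flat[bad]})"
            )
        return np.log(v / (100.0 - v))
    raise ValueError(f"unknown transform {transform!r}")


def inverse_transform(z: np.ndarray, transform: str) -> np.ndarray:
    """Back-transform to the natural scale.

    For logit100 the complementary form 100 / (1 + exp(-z)) is used (no
    overflow for large |z|), and the result is clamped to the nearest
    representable values inside the open interval (0, 100) so extreme z
    cannot round onto the boundary.
    """
    z = np.asarray(z, dtype=float)
    if transform == "log":
        return np.exp(z)
    if transform == "logit100":
        out = 100.0 / (1.0 + np.exp(-z))
        return np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(100.0, 0.0))
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# panel container

@dataclass
class Panel:
    """Unbalanced longitudinal table of per-dog monthly outcomes.

    ``data`` holds one row per observed (dog, month) with columns
    ``dog_id``, ``month``, ``value`` and optionally ``covariate``.
    ``months`` is the contiguous study window; months without observations
    are allowed (the trend still evolves across them).
    """

    data: pd.DataFrame
    transform: str
    months: Sequence[int]
    true_params: Optional["object"] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        months = np.asarray(list(self.months), dtype=int)
        if months.size == 0 or np.any(np.diff(months) != 1):
            raise ValueError("months must be a non-empty contiguous integer range")
        self.months = months
        if len(self.data) == 0:
            raise ValueError("panel has no observations")
        missing_cols = {"dog_id", "month", "value"} - set(self.data.columns)
        if missing_cols:
            raise ValueError(f"panel missing columns {sorted(missing_cols)}")
        if not self.data["month"].isin(months).all():
            raise ValueError("panel contains months outside the study window")
        # raises with the offending row if out of the transform's domain
        forward_transform(self.data["value"].to_numpy(), self.transform)

    @property
    def has_covariate(self) -> bool:
        return "covariate" in self.data.columns and self.data["covariate"].notna().all()

    def transformed(self) -> pd.DataFrame:
        """Copy of the panel rows with a ``z`` column on the model scale."""
        df = self.data.copy()
        df["z"] = forward_transform(df["value"].to_numpy(), self.transform)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def transform_values(panel: Panel) -> pd.DataFrame:
    """Panel rows with the transformed outcome ``z`` appended."""
    return panel.transformed()


# ---------------------------------------------------------------------------
# exact Kalman filter / smoother for the local level model

def _collapse_observations(
    months: np.ndarray,
    obs_month: np.ndarray,
    z: np.ndarray,
    beta: float,
    x: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-month count and mean of z - beta*x (sufficient statistics).

    Conditionally on m_t the dogs' observations are iid N(m_t, sigma0^2),
    so a month with n_t observations is equivalent to one observation of
    their mean with variance sigma0^2 / n_t.
    """
    resid = z - (beta * x if x is not None else 0.0)
    T = months.size
    n = np.zeros(T)
    s = np.zeros(T)
    idx = np.searchsorted(months, obs_month)
    np.add.at(n, idx, 1.0)
    np.add.at(s, idx, resid)
    mean = np.divide(s, n, out=np.zeros(T), where=n > 0)
    return n, mean


def _forward_filter(
    n: np.ndarray,
    zbar: np.ndarray,
    sigma0_sq: float,
    sigma1_sq: float,
    m1_prior: tuple[float, float],
) -> tuple[list, list, list, list]:
    """Kalman forward pass; returns predicted and filtered means/variances."""
    T = len(n)
    a_pred = [0.0] * T
    P_pred = [0.0] * T
    a_filt = [0.0] * T
    P_filt = [0.0] * T
    a, P = float(m1_prior[0]), float(m1_prior[1])
    nl = [float(v) for v in n]
    zl = [float(v) for v in zbar]
    for t in range(T):
        if t > 0:
            a, P = a_filt[t - 1], P_filt[t - 1] + sigma1_sq
        a_pred[t], P_pred[t] = a, P
        if nl[t] > 0:
            R = sigma0_sq / nl[t]
            K = P / (P + R)
            a = a + K * (zl[t] - a)
            P = R * K  # = P*R/(P+R), stable for diffuse priors
        a_filt[t], P_filt[t] = a, P
    return a_pred, P_pred, a_filt, P_filt


def kalman_smoother(
    months: Sequence[int],
    obs_month: Sequence[int],
    z: Sequence[float],
    sigma0_sq: float,
    sigma1_sq: float,
    beta: float = 0.0,
    x: Optional[Sequence[float]] = None,
    m1_prior: tuple[float, float] = (0.0, 100.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian smoothed marginals of the trend m_t.

    Parameters
    ----------
    months : contiguous study months (length T).
    obs_month : month of each observation (length N, values in ``months``).
    z : transformed observations (length N).
    sigma0_sq, sigma1_sq : observation and evolution variances (> 0).
    beta, x : optional covariate coefficient and per-observation covariate;
        the offset beta * x is subtracted before filtering.
    m1_prior : mean and variance of the initial level m_1.

    Returns
    -------
    (mean, variance) arrays of length T — the marginals p(m_t | all data).
    Months with no observations receive pure prediction/smoothing updates.
    """
    if sigma0_sq <= 0 or sigma1_sq < 0:
        raise ValueError("variances must be positive (sigma1_sq may be ~0)")
    months = np.asarray(list(months), dtype=int)
    obs_month = np.asarray(list(obs_month), dtype=int)
    z = np.asarray(list(z), dtype=float)
    xa = np.asarray(list(x), dtype=float) if x is not None else None
    n, zbar = _collapse_observations(months, obs_month, z, beta, xa)
    a_pred, P_pred, a_filt, P_filt = _forward_filter(
        n, zbar, sigma0_sq, sigma1_sq, (m1_prior[0], m1_prior[1])
    )
    T = months.size
    mean = np.empty(T)
    var = np.empty(T)
    mean[-1], var[-1] = a_filt[-1], P_filt[-1]
    for t in range(T - 2, -1, -1):  # Rauch-Tung-Striebel backward recursion
        C = P_filt[t] / P_pred[t + 1] if P_pred[t + 1] > 0 else 0.0
        mean[t] = a_filt[t] + C * (mean[t + 1] - a_pred[t + 1])
        var[t] = P_filt[t] + C * C * (var[t + 1] - P_pred[t + 1])
    return mean, var


def _ffbs_draw(
    n: np.ndarray,
    zbar: np.ndarray,
    sigma0_sq: float,
    sigma1_sq: float,
    m1_prior: tuple[float, float],
    rng: np.random.Generator,
    eps: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Joint draw of m_1..m_T from its full conditional (FFBS).

    ``eps`` supplies T pre-drawn standard normals (an optimisation for the
    Gibbs loop); when absent they are drawn from ``rng``.
    """
    a_pred, P_pred, a_filt, P_filt = _forward_filter(
        n, zbar, sigma0_sq, sigma1_sq, m1_prior
    )
    T = len(n)
    if eps is None:
        eps = rng.standard_normal(T)
    m = [0.0] * T
    m[-1] = a_filt[-1] + np.sqrt(max(P_filt[-1], 0.0)) * eps[T - 1]
    for t in range(T - 2, -1, -1):
        C = P_filt[t] / P_pred[t + 1] if P_pred[t + 1] > 0 else 0.0
        mu = a_filt[t] + C * (m[t + 1] - a_pred[t + 1])
        v = P_filt[t] - C * C * P_pred[t + 1]
        m[t] = mu + np.sqrt(max(v, 0.0)) * eps[t]
    return np.asarray(m)


# ---------------------------------------------------------------------------
# Gibbs sampler

@dataclass
class PriorSpec:
    """Priors for the local-level model (all configurable).

    Defaults: diffuse normal on the initial level and on beta, and weakly
    informative inverse-gamma(0.001, 0.001) on both variances.  Setting
    ``fix_sigma0_sq``/``fix_sigma1_sq`` pins a variance at a point value
    (degenerate prior), which turns the sampler into pure FFBS over states.
    """

    m1_mean: float = 0.0
    m1_var: float = 100.0
    sigma0_a: float = 0.001
    sigma0_b: float = 0.001
    sigma1_a: float = 0.001
    sigma1_b: float = 0.001
    beta_mean: float = 0.0
    beta_var: float = 100.0
    fix_sigma0_sq: Optional[float] = None
    fix_sigma1_sq: Optional[float] = None


@dataclass
class MCMCSettings:
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")


@dataclass
class LocalLevelFit:
    """Posterior summaries and retained draws of a local-level fit."""

    months: np.ndarray
    transform: str
    trend_mean: np.ndarray      # posterior mean of m_t (transformed scale)
    trend_lower: np.ndarray     # 2.5% quantile
    trend_upper: np.ndarray     # 97.5% quantile
    natural_mean: np.ndarray    # back-transformed curves
    natural_lower: np.ndarray
    natural_upper: np.ndarray
    sigma0_sq: dict
    sigma1_sq: dict
    beta: Optional[dict]        # mean/lower/upper/excludes_zero, or None
    draws: dict                 # arrays keyed by parameter, (chains, n, ...)
    diagnostics: dict

    def to_json(self, path: str | Path) -> None:
        out = {
            "months": self.months.tolist(),
            "transform": self.transform,
            "trend_mean": self.trend_mean.tolist(),
            "trend_lower": self.trend_lower.tolist(),
            "trend_upper": self.trend_upper.tolist(),
            "natural_mean": self.natural_mean.tolist(),
            "natural_lower": self.natural_lower.tolist(),
            "natural_upper": self.natural_upper.tolist(),
            "sigma0_sq": self.sigma0_sq,
            "sigma1_sq": self.sigma1_sq,
            "beta": self.beta,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(out, indent=1))

    def trend_frame(self) -> pd.DataFrame:
        """Tidy per-month trend table (natural scale) for plotting."""
        return pd.DataFrame({
            "month": self.months,
            "mean": self.natural_mean,
            "lower": self.natural_lower,
            "upper": self.natural_upper,
        })


def _summary(draws: np.ndarray) -> dict:
    flat = draws.reshape(-1)
    lo, hi = np.quantile(flat, [0.025, 0.975])
    return {"mean": float(flat.mean()), "lower": float(lo), "upper": float(hi)}


def beta_report_from_draws(draws: np.ndarray) -> dict:
    """Posterior mean, equal-tailed 95% interval and excludes-zero flag of a
    set of coefficient draws."""
    s = _summary(np.asarray(draws, dtype=float))
    s["excludes_zero"] = bool(s["lower"] > 0 or s["upper"] < 0)
    return s


def _run_chain(
    n_per_month: np.ndarray,
    obs_idx: np.ndarray,
    z: np.ndarray,
    x: Optional[np.ndarray],
    priors: PriorSpec,
    iterations: int,
    burn_in: int,
    thin: int,
    seed_seq: np.random.SeedSequence,
) -> dict:
    rng = np.random.default_rng(seed_seq)
    T = n_per_month.size
    N = z.size
    m1_prior = (priors.m1_mean, priors.m1_var)

    # initial values: moment-based, overdispersed across chains via rng
    z_var = float(np.var(z)) if N > 1 else 1.0
    sigma0_sq = priors.fix_sigma0_sq or max(z_var, 1e-3) * rng.uniform(0.5, 2.0)
    sigma1_sq = priors.fix_sigma1_sq or sigma0_sq / 4.0 * rng.uniform(0.5, 2.0)
    beta = 0.0 if x is None else rng.normal(0.0, 0.1)

    n_keep = (iterations - burn_in) // thin
    out_m = np.empty((n_keep, T))
    out_s0 = np.empty(n_keep)
    out_s1 = np.empty(n_keep)
    out_b = np.empty(n_keep) if x is not None else None

    x_ss = float(np.sum(x * x)) if x is not None else 0.0
    nz = n_per_month > 0
    safe_n = np.where(nz, n_per_month, 1.0)
    # sufficient statistics; fixed when there is no covariate
    zbar_z = np.bincount(obs_idx, weights=z, minlength=T) / safe_n * nz
    xbar_sum = (
        np.bincount(obs_idx, weights=x, minlength=T) / safe_n * nz
        if x is not None else None
    )
    # pre-drawn standard normals for the FFBS pass, one row per iteration
    eps_all = rng.standard_normal((iterations, T))
    kept = 0
    for it in range(iterations):
        # (a) states by FFBS
        if x is not None:
            resid = z - beta * x
            zbar = zbar_z - beta * xbar_sum
        else:
            resid = z
            zbar = zbar_z
        m = _ffbs_draw(
            n_per_month, zbar, sigma0_sq, sigma1_sq, m1_prior, rng,
            eps=eps_all[it],
        )

        # (b) variances, conjugate inverse-gamma
        eps = resid - m[obs_idx]
        if priors.fix_sigma0_sq is None:
            a_post = priors.sigma0_a + 0.5 * N
            b_post = priors.sigma0_b + 0.5 * float(eps @ eps)
            sigma0_sq = b_post / rng.gamma(a_post)
        if priors.fix_sigma1_sq is None and T > 1:
            dm = np.diff(m)
            a_post = priors.sigma1_a + 0.5 * (T - 1)
            b_post = priors.sigma1_b + 0.5 * float(dm @ dm)
            sigma1_sq = b_post / rng.gamma(a_post)

        # (c) beta, conjugate normal
        if x is not None:
            prec = 1.0 / priors.beta_var + x_ss / sigma0_sq
            mu = (
                priors.beta_mean / priors.beta_var
                + float(x @ (z - m[obs_idx])) / sigma0_sq
            ) / prec
            beta = rng.normal(mu, np.sqrt(1.0 / prec))

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_m[kept] = m
            out_s0[kept] = sigma0_sq
            out_s1[kept] = sigma1_sq
            if out_b is not None:
                out_b[kept] = beta
            kept += 1

    res = {"m": out_m[:kept], "sigma0_sq": out_s0[:kept], "sigma1_sq": out_s1[:kept]}
    if out_b is not None:
        res["beta"] = out_b[:kept]
    return res


def _diagnostics(draws: dict) -> dict:
    """Split-chain Rhat and effective sample size per parameter (via arviz)."""
    import arviz as az

    ds = az.convert_to_dataset(dict(draws))
    rhat_ds = az.rhat(ds)
    ess_ds = az.ess(ds)
    diag = {}
    max_rhat = 0.0
    min_ess = np.inf
    for name in draws:
        r = rhat_ds[name].values
        e = ess_ds[name].values
        diag[name] = {
            "rhat": float(np.nanmax(r)),
            "ess": float(np.nanmin(e)),
        }
        max_rhat = max(max_rhat, float(np.nanmax(r)))
        min_ess = min(min_ess, float(np.nanmin(e)))
    diag["max_rhat"] = max_rhat
    diag["min_ess"] = float(min_ess)
    diag["converged"] = bool(max_rhat < RHAT_THRESHOLD)
    return diag


def fit_local_level(
    panel: Panel,
    mcmc: Optional[MCMCSettings] = None,
    priors: Optional[PriorSpec] = None,
    standardize_covariate: bool = False,
    compute_diagnostics: bool = True,
) -> LocalLevelFit:
    """Fit the local-level model to a panel by FFBS Gibbs sampling.

    When the panel carries a covariate column the coefficient beta is
    sampled; otherwise beta is fixed at 0 and omitted from the fit.
    ``standardize_covariate`` z-scores x across the panel before fitting,
    so beta is per standard deviation of the covariate.  Reruns with the
    same settings and seed produce identical draws.
    """
    mcmc = mcmc or MCMCSettings()
    priors = priors or PriorSpec()

    df = panel.transformed().sort_values(["month", "dog_id"], kind="stable")
    months = np.asarray(panel.months, dtype=int)
    obs_month = df["month"].to_numpy(dtype=int)
    months_with_data = np.unique(obs_month)
    if months_with_data.size < 2 and priors.m1_var > 1e6:
        raise ValueError(
            "fewer than 2 months with data and no informative prior: "
            "trend is unidentifiable"
        )
    z = df["z"].to_numpy(dtype=float)
    obs_idx = np.searchsorted(months, obs_month)
    n_per_month = np.zeros(months.size)
    np.add.at(n_per_month, obs_idx, 1.0)

    x = None
    if panel.has_covariate:
        x = df["covariate"].to_numpy(dtype=float)
        if standardize_covariate:
            sd = x.std()
            if sd == 0:
                raise ValueError("covariate has zero variance; cannot standardize")
            x = (x - x.mean()) / sd

    ss = np.random.SeedSequence(mcmc.seed)
    chain_seeds = ss.spawn(mcmc.chains)
    chain_draws = [
        _run_chain(
            n_per_month, obs_idx, z, x, priors,
            mcmc.iterations, mcmc.burn_in, mcmc.thin, cs,
        )
        for cs in chain_seeds
    ]
    draws = {
        k: np.stack([c[k] for c in chain_draws]) for k in chain_draws[0]
    }

    m_flat = draws["m"].reshape(-1, months.size)
    trend_mean = m_flat.mean(axis=0)
    trend_lower, trend_upper = np.quantile(m_flat, [0.025, 0.975], axis=0)

    beta_summary = beta_report_from_draws(draws["beta"]) if "beta" in draws else None

    diagnostics = _diagnostics(draws) if compute_diagnostics else {}
    if compute_diagnostics and not diagnostics.get("converged", True):
        logger.warning(
            "convergence flag raised: max split-Rhat %.3f >= %.2f",
            diagnostics["max_rhat"], RHAT_THRESHOLD,
        )

    return LocalLevelFit(
        months=months,
        transform=panel.transform,
        trend_mean=trend_mean,
        trend_lower=trend_lower,
        trend_upper=trend_upper,
        natural_mean=inverse_transform(trend_mean, panel.transform),
        natural_lower=inverse_transform(trend_lower, panel.transform),
        natural_upper=inverse_transform(trend_upper, panel.transform),
        sigma0_sq=_summary(draws["sigma0_sq"]),
        sigma1_sq=_summary(draws["sigma1_sq"]),
        beta=beta_summary,
        draws=draws,
        diagnostics=diagnostics,
    )


def coefficient_report(fit: LocalLevelFit) -> tuple[float, tuple[float, float], bool]:
    """Point estimate, equal-tailed 95% credible interval, excludes-zero flag."""
    if fit.beta is None:
        raise ValueError("fit has no covariate coefficient")
    b = fit.beta
    return b["mean"], (b["lower"], b["upper"]), b["excludes_zero"]


def compare_trends(fit_a: LocalLevelFit, fit_b: LocalLevelFit) -> pd.DataFrame:
    """Per-month natural-scale comparison of two group fits.

    Reports both trend means and 95% bands and whether the bands are
    disjoint at each month.  Requires identical month ranges and transforms.
    """
    if not np.array_equal(fit_a.months, fit_b.months):
        raise ValueError("month ranges differ between fits")
    if fit_a.transform != fit_b.transform:
        raise ValueError("transforms differ between fits")
    disjoint = (fit_a.natural_lower > fit_b.natural_upper) | (
        fit_b.natural_lower > fit_a.natural_upper
    )
    return pd.DataFrame({
        "month": fit_a.months,
        "mean_a": fit_a.natural_mean,
        "lower_a": fit_a.natural_lower,
        "upper_a": fit_a.natural_upper,
        "mean_b": fit_b.natural_mean,
        "lower_b": fit_b.natural_lower,
        "upper_b": fit_b.natural_upper,
        "disjoint": disjoint,
    })
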