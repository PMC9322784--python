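"""Synthetic prediabetes-cohort generator with known variability structure.

Real account-export data from the kind of six-month activity-tracker study
this package analyses are rarely shareable, so every stage is exercised on
simulated cohorts whose ground truth is known in closed form.

Each subject's daily activity in a metric follows a stationary Gaussian
AR(1) process plus an optional linear trend:

    x₀ ~ N(baseline, σ²),  xₜ = baseline + ρ·(xₜ₋₁ − baseline) + εₜ,
    εₜ ~ N(0, σ²(1−ρ²)),   observed value = xₜ + t·trend_per_day.

σ is the *marginal* (stationary) SD — not the innovation SD — so the
Poincaré descriptors of the latent process have closed forms:

    SD1 = σ√(1−ρ),  SD2 = σ√(1+ρ),  SD12 = √((1−ρ)/(1+ρ)),
    AFE = π·σ²·√(1−ρ²),  AVG = baseline,  SD = σ.

Between-subject heterogeneity (lognormal σ spread, truncated-normal ρ
jitter, baseline spread) makes the true descriptors vary across subjects,
which is what lets clinical-outcome changes be coupled to them: each
coupling draws delta = coefficient × true descriptor + N(0, noise_sd).
Ground truth refers to the latent continuous stationary component;
clamping to non-negative integers, the trend, and missing days are applied
afterwards, so estimation error from those steps is part of what recovery
tests measure.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import CANONICAL_COLUMNS, MINUTE_METRICS
from .exceptions import ConfigurationError, UnsupportedConfigurationError, ValidationError
from .poincare import PoincareDescriptors

#: Metrics simulated directly; distance_km is derived from steps.
SIMULATED_METRICS = (
    "steps",
    "minutes_sedentary",
    "minutes_lightly_active",
    "minutes_fairly_active",
    "minutes_very_active",
)

DESCRIPTOR_SET = ("AVG", "SD", "SD1", "SD2", "SD12", "AFE")

DEFAULT_START_DATE = dt.date(2020, 8, 1)


@dataclass(frozen=True)
class Ar1Params:
    """Stationary AR(1) parameters for one activity metric.

    ``sigma`` is the marginal SD of the stationary process (metric units,
    e.g. steps/day), ``rho`` the lag-1 autocorrelation, ``baseline`` the
    stationary mean, and ``trend_per_day`` a deterministic linear drift
    added on top of the stationary component.
    """

    sigma: float
    rho: float
    baseline: float
    trend_per_day: float = 0.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if not abs(self.rho) < 1:
            raise ValidationError("|rho| must be < 1")


@dataclass(frozen=True)
class OutcomeCoupling:
    """Linear link from a true variability descriptor to an outcome change.

    delta(outcome) += coefficient × true descriptor(metric) + N(0, noise_sd²)
    """

    metric: str
    descriptor_name: str
    outcome_name: str
    coefficient: float
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.descriptor_name not in DESCRIPTOR_SET:
            raise ValidationError(
                f"descriptor_name must be one of {DESCRIPTOR_SET}, got {self.descriptor_name!r}"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """Marginal distribution of one clinical outcome.

    ``delta_mean`` and ``delta_noise_sd`` describe the change component not
    explained by couplings (pure noise for uncoupled outcomes; an offset
    keeping the mean change realistic for coupled ones).
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    delta_mean: float = 0.0
    delta_noise_sd: float = 0.0


@dataclass(frozen=True)
class BetweenSubjectVariation:
    """How subject-level AR(1) parameters scatter around the metric defaults.

    sigma is drawn lognormally with coefficient of variation ``sigma_cv``
    (mean preserved); rho is N(rho, rho_sd) truncated to (−0.9, 0.9);
    baseline is N(baseline, baseline_cv·|baseline|) clamped to ≥ 0.
    """

    sigma_cv: float = 0.4
    rho_sd: float = 0.1
    baseline_cv: float = 0.2


def _default_activity_params() -> dict:
    # Scaled to a prediabetes cohort wearing consumer trackers for six
    # months: ~9900 steps/day at entry declining to ~8000 (trend), sedentary
    # time drifting up, light activity down.
    return {
        "steps": Ar1Params(sigma=2800, rho=0.3, baseline=9900, trend_per_day=-12.4),
        "minutes_sedentary": Ar1Params(sigma=250, rho=0.3, baseline=830, trend_per_day=0.45),
        "minutes_lightly_active": Ar1Params(sigma=110, rho=0.3, baseline=280, trend_per_day=-0.31),
        "minutes_fairly_active": Ar1Params(sigma=12, rho=0.2, baseline=14, trend_per_day=0.0),
        "minutes_very_active": Ar1Params(sigma=10, rho=0.2, baseline=9, trend_per_day=0.0),
    }


def _default_outcomes() -> tuple:
    # Baselines sized like a middle-aged cohort at increased T2D risk; the
    # delta offsets keep the mean changes near typical six-month lifestyle-
    # intervention effects once the coupling contributions are added.
    return (
        OutcomeSpec("weight_kg", 87.6, 16.9, delta_mean=10.8, delta_noise_sd=2.8),
        OutcomeSpec("hba1c_pct", 5.61, 0.352, delta_mean=0.047, delta_noise_sd=0.28),
        OutcomeSpec("tc_mmol_l", 5.70, 1.14, delta_mean=-1.1, delta_noise_sd=0.9),
    )


def _default_couplings() -> tuple:
    # Positive lipid link to long-term steps variability; weight change
    # linked (negatively) to the fairly-active SD1/SD2 ratio.
    return (
        OutcomeCoupling("steps", "SD2", "tc_mmol_l", coefficient=4e-4, noise_sd=0.0),
        OutcomeCoupling("minutes_fairly_active", "SD12", "weight_kg", coefficient=-15.0, noise_sd=0.0),
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full specification of a synthetic cohort; the bundle is a pure
    function of this object (including ``seed``)."""

    n_subjects: int = 30
    n_days: int = 180
    seed: int = 0
    missing_day_rate: float = 0.05
    activity_params: dict = field(default_factory=_default_activity_params)
    between_subject: BetweenSubjectVariation = field(default_factory=BetweenSubjectVariation)
    outcomes: tuple = field(default_factory=_default_outcomes)
    couplings: tuple = field(default_factory=_default_couplings)
    stride_km_per_step: float = 0.0007
    start_date: dt.date = DEFAULT_START_DATE

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_days < 3:
            raise ValidationError("n_days must be >= 3")
        if not 0 <= self.missing_day_rate < 1:
            raise ValidationError("missing_day_rate must be in [0, 1)")
        unknown = set(self.activity_params) - set(SIMULATED_METRICS)
        if unknown:
            raise ConfigurationError(f"unknown activity metrics: {sorted(unknown)}")
        outcome_names = {o.name for o in self.outcomes}
        for c in self.couplings:
            if c.metric not in self.activity_params:
                raise ConfigurationError(
                    f"coupling references unsimulated metric {c.metric!r}"
                )
            if c.outcome_name not in outcome_names:
                raise ConfigurationError(
                    f"coupling references unknown outcome {c.outcome_name!r}"
                )


# ---------------------------------------------------------------------------
# AR(1) machinery
# ---------------------------------------------------------------------------

def simulate_ar1(params: Ar1Params, n_days: int, seed) -> np.ndarray:
    """Simulate one AR(1) path of length ``n_days``.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The process is
    initialised from its stationary distribution, so the marginal SD is
    ``sigma`` and the lag-1 autocorrelation ``rho`` from day 1 (no burn-in).
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    z = rng.standard_normal(n_days)
    centered = np.empty(n_days)
    centered[0] = params.sigma * z[0]
    innov_sd = params.sigma * math.sqrt(1.0 - params.rho**2)
    for t in range(1, n_days):
        centered[t] = params.rho * centered[t - 1] + innov_sd * z[t]
    trend = params.trend_per_day * np.arange(n_days)
    return params.baseline + centered + trend


def _simulate_ar1_matrix(
    sigmas: np.ndarray,
    rhos: np.ndarray,
    baselines: np.ndarray,
    trend_per_day: float,
    n_days: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised AR(1): one row per subject, stationary initialisation."""
    n = len(sigmas)
    z = rng.standard_normal((n, n_days))
    out = np.empty((n, n_days))
    out[:, 0] = sigmas * z[:, 0]
    innov_sd = sigmas * np.sqrt(1.0 - rhos**2)
    for t in range(1, n_days):
        out[:, t] = rhos * out[:, t - 1] + innov_sd * z[:, t]
    out += baselines[:, None]
    out += trend_per_day * np.arange(n_days)[None, :]
    return out


def theoretical_descriptors(params: Ar1Params) -> PoincareDescriptors:
    """Closed-form Poincaré descriptors of the stationary AR(1) process.

    Requires ``trend_per_day == 0`` (the closed form assumes stationarity).
    For lag-1 pairs of a stationary AR(1), Var(xₙ − xₙ₊₁) = 2σ²(1−ρ), so
    SD1 = σ√(1−ρ) and SD2 = √(2σ² − σ²(1−ρ)) = σ√(1+ρ).
    """
    if params.trend_per_day != 0:
        raise UnsupportedConfigurationError(
            "closed-form descriptors assume stationarity (trend_per_day = 0)"
        )
    sigma, rho = params.sigma, params.rho
    sd1 = sigma * math.sqrt(1.0 - rho)
    sd2 = sigma * math.sqrt(1.0 + rho)
    sd12 = math.sqrt((1.0 - rho) / (1.0 + rho))
    afe = math.pi * sigma**2 * math.sqrt(1.0 - rho**2)
    return PoincareDescriptors(
        avg=params.baseline, sd=sigma, sd1=sd1, sd2=sd2, sd12=sd12, afe=afe, n_pairs=0
    )


def coefficient_for_correlation(
    target_r: float, descriptor_sd: float, noise_sd: float
) -> float:
    """Coupling coefficient giving population correlation ``target_r``.

    For delta = c·D + ε with ε ~ N(0, noise_sd²) independent of D,
    r = c·SD(D)/√(c²·Var(D) + noise_sd²); inverting gives
    c = r·noise_sd / (SD(D)·√(1−r²)).
    """
    if not 0 < abs(target_r) < 1:
        raise ValidationError("target_r must be in (-1, 0) or (0, 1)")
    if descriptor_sd <= 0 or noise_sd <= 0:
        raise ValidationError("descriptor_sd and noise_sd must be > 0")
    return target_r * noise_sd / (descriptor_sd * math.sqrt(1.0 - target_r**2))


# ---------------------------------------------------------------------------
# subject- and cohort-level simulation
# ---------------------------------------------------------------------------

def _clamp_round(values: np.ndarray) -> np.ndarray:
    return np.maximum(np.rint(values), 0).astype(int)


def _trim_minutes(minutes: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Cap the four minute channels at 1440/day, trimming sedentary first."""
    order = list(MINUTE_METRICS)  # sedentary first
    total = sum(minutes[m] for m in order)
    excess = np.maximum(total - 1440, 0)
    out = {m: minutes[m].copy() for m in order}
    for m in order:
        cut = np.minimum(out[m], excess)
        out[m] -= cut
        excess -= cut
    return out


def _daily_frame(
    subject_id: str,
    latent: dict[str, np.ndarray],
    n_days: int,
    missing_day_rate: float,
    stride_km_per_step: float,
    start_date: dt.date,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Observed canonical rows for one subject from latent metric paths."""
    steps = _clamp_round(latent.get("steps", np.zeros(n_days)))
    minutes = {m: _clamp_round(latent.get(m, np.zeros(n_days))) for m in MINUTE_METRICS}
    # an all-zero day is recorded as fully sedentary (the tracker always
    # accounts for the full day)
    total = sum(minutes.values())
    minutes["minutes_sedentary"] = np.where(
        total == 0, 1440, minutes["minutes_sedentary"]
    )
    minutes = _trim_minutes(minutes)
    distance = steps * stride_km_per_step
    keep = rng.random(n_days) >= missing_day_rate
    dates = np.array(start_date, dtype="datetime64[D]") + np.arange(n_days)
    frame = pd.DataFrame(
        {
            "subject_id": subject_id,
            "date": dates,
            "steps": steps,
            "distance_km": distance,
            "minutes_sedentary": minutes["minutes_sedentary"],
            "minutes_lightly_active": minutes["minutes_lightly_active"],
            "minutes_fairly_active": minutes["minutes_fairly_active"],
            "minutes_very_active": minutes["minutes_very_active"],
        }
    )
    return frame.loc[keep].reset_index(drop=True)


def simulate_subject(
    activity_params: dict,
    n_days: int,
    missing_day_rate: float = 0.0,
    seed=0,
    stride_km_per_step: float = 0.0007,
    subject_id: str = "S01",
    start_date: dt.date = DEFAULT_START_DATE,
):
    """Simulate one subject's daily records.

    ``activity_params`` maps metric name → :class:`Ar1Params` for any subset
    of the simulated metrics; unlisted metrics are zero.  Returns a list of
    :class:`~stepvar.data.DailyActivityRecord` (missing days removed
    independently at ``missing_day_rate``).
    """
    from .data import frame_to_records

    unknown = set(activity_params) - set(SIMULATED_METRICS)
    if unknown:
        raise ConfigurationError(f"unknown activity metrics: {sorted(unknown)}")
    if not 0 <= missing_day_rate < 1:
        raise ValidationError("missing_day_rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    latent = {
        metric: simulate_ar1(params, n_days, rng)
        for metric, params in activity_params.items()
    }
    frame = _daily_frame(
        subject_id, latent, n_days, missing_day_rate, stride_km_per_step, start_date, rng
    )
    return frame_to_records(frame)


@dataclass(frozen=True)
class CohortBundle:
    """Everything a simulated cohort produces.

    ``activity`` is the canonical long DataFrame of observed records;
    ``outcomes`` the flat clinical table (subject_id, outcome, baseline,
    followup); ``ground_truth`` one row per subject × metric with the
    latent AR(1) parameters and their closed-form descriptors.
    """

    config: SyntheticCohortConfig
    activity: pd.DataFrame
    outcomes: pd.DataFrame
    ground_truth: pd.DataFrame

    def write(self, outdir) -> dict:
        """Write activity and outcomes CSVs (canonical formats); returns paths."""
        from pathlib import Path
        from .io import write_canonical
        from .data import frame_to_records

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "activity": outdir / "activity.csv",
            "outcomes": outdir / "outcomes.csv",
            "ground_truth": outdir / "ground_truth.csv",
        }
        paths["activity"].write_text(write_canonical(frame_to_records(self.activity)))
        self.outcomes.to_csv(paths["outcomes"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


def _draw_subject_params(
    base: Ar1Params, bs: BetweenSubjectVariation, n: int, rng: np.random.Generator
) -> list[Ar1Params]:
    if bs.sigma_cv > 0 and base.sigma > 0:
        s = math.sqrt(math.log(1.0 + bs.sigma_cv**2))
        sigmas = base.sigma * rng.lognormal(-0.5 * s * s, s, size=n)
    else:
        sigmas = np.full(n, base.sigma)
    rhos = np.clip(rng.normal(base.rho, bs.rho_sd, size=n), -0.9, 0.9)
    baselines = np.maximum(
        rng.normal(base.baseline, bs.baseline_cv * abs(base.baseline), size=n), 0.0
    )
    return [
        replace(base, sigma=float(sigmas[i]), rho=float(rhos[i]), baseline=float(baselines[i]))
        for i in range(n)
    ]


def _truth_row(subject_id: str, metric: str, p: Ar1Params) -> dict:
    d = theoretical_descriptors(replace(p, trend_per_day=0.0))
    return {
        "subject_id": subject_id,
        "metric": metric,
        "sigma": p.sigma,
        "rho": p.rho,
        "baseline": p.baseline,
        "trend_per_day": p.trend_per_day,
        "AVG": d.avg,
        "SD": d.sd,
        "SD1": d.sd1,
        "SD2": d.sd2,
        "SD12": d.sd12,
        "AFE": d.afe,
    }


def simulate_cohort(config: SyntheticCohortConfig) -> CohortBundle:
    """Generate a full cohort bundle, reproducible from ``config.seed``.

    Ground-truth descriptors refer to each subject's latent stationary
    component (trend stripped); outcome deltas are built from those truths
    before any clamping/rounding of the observed records.  ``distance_km``
    truths are steps truths scaled by the stride length (AVG, SD, SD1, SD2
    by the stride; AFE by its square; SD12 unchanged).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_params = np.random.default_rng(seeds[0])
    rng_series = np.random.default_rng(seeds[1])
    rng_outcomes = np.random.default_rng(seeds[2])
    subject_ids = [f"S{i + 1:03d}" for i in range(config.n_subjects)]

    # per-subject latent parameters and ground truth
    per_metric_params: dict[str, list[Ar1Params]] = {
        metric: _draw_subject_params(
            base, config.between_subject, config.n_subjects, rng_params
        )
        for metric, base in sorted(config.activity_params.items())
    }
    truth_rows = []
    for metric, plist in per_metric_params.items():
        for sid, p in zip(subject_ids, plist):
            truth_rows.append(_truth_row(sid, metric, p))
            if metric == "steps":
                row = _truth_row(sid, "distance_km", p)
                k = config.stride_km_per_step
                for col in ("sigma", "baseline", "AVG", "SD", "SD1", "SD2"):
                    row[col] *= k
                row["trend_per_day"] *= k
                row["AFE"] *= k * k
                truth_rows.append(row)
    ground_truth = pd.DataFrame(truth_rows).sort_values(
        ["subject_id", "metric"], kind="stable"
    ).reset_index(drop=True)

    # observed activity
    frames = []
    for i, sid in enumerate(subject_ids):
        latent = {
            metric: simulate_ar1(plist[i], config.n_days, rng_series)
            for metric, plist in per_metric_params.items()
        }
        frames.append(
            _daily_frame(
                sid,
                latent,
                config.n_days,
                config.missing_day_rate,
                config.stride_km_per_step,
                config.start_date,
                rng_series,
            )
        )
    activity = pd.concat(frames, ignore_index=True)[list(CANONICAL_COLUMNS)]

    # clinical outcomes: baseline ~ spec, delta = offset + Σ couplings + noise
    truth_idx = ground_truth.set_index(["subject_id", "metric"])
    outcome_rows = []
    for spec in config.outcomes:
        baseline = rng_outcomes.normal(
            spec.baseline_mean, spec.baseline_sd, size=config.n_subjects
        )
        delta = np.full(config.n_subjects, spec.delta_mean)
        if spec.delta_noise_sd > 0:
            delta = delta + rng_outcomes.normal(
                0.0, spec.delta_noise_sd, size=config.n_subjects
            )
        for c in config.couplings:
            if c.outcome_name != spec.name:
                continue
            truths = np.array(
                [truth_idx.loc[(sid, c.metric), c.descriptor_name] for sid in subject_ids]
            )
            delta = delta + c.coefficient * truths
            if c.noise_sd > 0:
                delta = delta + rng_outcomes.normal(0.0, c.noise_sd, size=config.n_subjects)
        for i, sid in enumerate(subject_ids):
            outcome_rows.append(
                {
                    "subject_id": sid,
                    "outcome": spec.name,
                    "baseline": float(baseline[i]),
                    "followup": float(baseline[i] + delta[i]),
                }
            )
    outcomes = pd.DataFrame(
        outcome_rows, columns=["subject_id", "outcome", "baseline", "followup"]
    )
    return CohortBundle(config, activity, outcomes, ground_truth)
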