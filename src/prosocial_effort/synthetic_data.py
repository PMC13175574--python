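"""Generative model for the full study: participants, behavior, and EEG.

Every downstream stage (ERP quantification, discounting fits, mixed
models, power analysis) is testable against data from this module, whose
defaults encode the study conditions: 40 participants, 200 effort-task
trials and 150 decision trials each, choices from ``SV = R - K*E**2``
with a softmax, and single-trial RewP amplitudes generated from a linear
model whose fixed-effect loadings default to the reported estimates
(recipient -0.68, valence -1.08, magnitude +0.42, recipient x effort
-0.55, recipient x effort x magnitude -0.49, recipient x magnitude x
valence +0.86 µV per unit of the coded predictors). Those loadings come
from the original authors' data and are simulator defaults, not ground
truth; all are overridable.

The EEG layer renders each trial's generative RewP amplitude as a
Gaussian temporal kernel (peak 350 ms, SD 35 ms) on FC3/FCz/FC4 and a
P3 kernel (peak 370 ms, SD 50 ms) on P3/Pz/P4, both normalized so the
measurement-window mean recovers the amplitude parameter exactly, plus
white sensor noise and optional injected artifacts (steps, flatlines,
drifts) for testing the rejection rules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import task_design
from .discounting_model import choice_prob, effort_units, subjective_value
from .epochs import EpochSet, default_time_axis
from .task_design import TrialSpec, build_decision_task_design, build_effort_task_design

__all__ = [
    "GenerativeConfig",
    "ParticipantProfile",
    "ParticipantData",
    "Dataset",
    "DEFAULT_REWP_LOADINGS",
    "REWP_TERMS",
    "sample_participants",
    "calibrated_maximum",
    "simulate_calibration",
    "simulate_effort_execution",
    "simulate_effort_task",
    "simulate_choices",
    "simulate_ratings",
    "simulate_rewp_amplitudes",
    "simulate_p3_amplitudes",
    "simulate_epochs",
    "simulate_participant",
    "simulate_dataset",
    "write_dataset",
    "coded_predictors",
    "rewp_window_noise_sd",
]

#: All fixed-effect terms of the recipient x effort x magnitude x valence
#: factorial, in the coded-predictor basis used for analysis.
REWP_TERMS: tuple[str, ...] = (
    "Intercept",
    "recipient_c",
    "effort_z",
    "magnitude_z",
    "valence_c",
    "recipient_c:effort_z",
    "recipient_c:magnitude_z",
    "recipient_c:valence_c",
    "effort_z:magnitude_z",
    "effort_z:valence_c",
    "magnitude_z:valence_c",
    "recipient_c:effort_z:magnitude_z",
    "recipient_c:effort_z:valence_c",
    "recipient_c:magnitude_z:valence_c",
    "effort_z:magnitude_z:valence_c",
    "recipient_c:effort_z:magnitude_z:valence_c",
)

#: Default generative loadings (µV per coded-predictor unit).
DEFAULT_REWP_LOADINGS: dict[str, float] = {
    "Intercept": 5.0,
    "recipient_c": -0.68,
    "valence_c": -1.08,
    "magnitude_z": 0.42,
    "recipient_c:effort_z": -0.55,
    "recipient_c:effort_z:magnitude_z": -0.49,
    "recipient_c:magnitude_z:valence_c": 0.86,
}

DEFAULT_CHANNELS = ("FC3", "FCz", "FC4", "Cz", "P3", "Pz", "P4", "Oz")


@dataclass
class GenerativeConfig:
    """Population parameters of the simulator. SDs must be >= 0."""

    n_participants: int = 40
    seed: int = 0

    # calibration / physical capacity (button presses per 6000 ms)
    max_effort_mean: float = 36.06
    max_effort_sd: float = 4.95
    calibration_noise_sd: float = 3.0

    # discounting population (level coding of effort)
    logk_self_mean: float = -4.48
    logk_other_mean: float = -3.78
    logk_sd: float = 0.8
    logk_cross_corr: float = 0.52
    beta_log_mean: float = 1.6
    beta_log_sd: float = 0.3
    negative_k_rate: float = 0.05
    effort_coding: str = "level"

    # single-trial RewP generative model
    rewp_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REWP_LOADINGS)
    )
    rewp_random_sd: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 2.0,
            "recipient": 0.5,
            "effort": 0.3,
            "magnitude": 0.3,
        }
    )
    rewp_residual_sd: float = 3.0

    # P3 to effort-completion feedback
    p3_intercept: float = 6.0
    p3_effort_slope: float = 0.72
    p3_recipient: float = 0.0
    p3_intercept_sd: float = 1.5
    p3_residual_sd: float = 3.0

    # effort execution (success, presses per second)
    success_logit_intercept: float = 8.5
    success_logit_effort: float = -4.77
    success_intercept_sd: float = 1.0
    speed_intercept: float = 6.0
    speed_effort: float = 0.56
    speed_recipient: float = -0.07
    speed_magnitude: float = 0.01
    speed_intercept_sd: float = 0.4
    speed_noise_sd: float = 0.5

    # decision times (ms, multiplicative lognormal noise)
    dt_base_ms: float = 1200.0
    dt_effort_linear: float = 38.91
    dt_effort_quadratic: float = -64.89
    dt_magnitude: float = -54.88
    dt_recipient_x_effort: float = -41.49
    dt_recipient_x_magnitude: float = 44.86
    dt_effort_x_magnitude: float = 33.23
    dt_effortq_x_magnitude: float = 15.14
    dt_intercept_sd: float = 80.0
    dt_lognorm_sd: float = 0.25
    no_response_rate: float = 0.0091
    catch_accuracy: float = 0.92

    # post-experimental ratings (9-point scales)
    rating_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "difficulty": {"intercept": 5.0, "effort": 2.38, "recipient": 0.19, "recipient_x_effort": 0.0},
            "effort": {"intercept": 5.0, "effort": 1.90, "recipient": -0.32, "recipient_x_effort": 0.0},
            "liking": {"intercept": 5.0, "effort": -1.79, "recipient": -0.62, "recipient_x_effort": -0.28},
        }
    )
    rating_intercept_sd: float = 0.5
    rating_noise_sd: float = 0.8

    # EEG layer; sensor noise is band-limited (Gaussian-smoothed white
    # noise emulating the recording's ~35 Hz lowpass), so that clean
    # epochs respect the sample-to-sample artifact rule
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sfreq: float = 512.0
    noise_sd: float = 10.0
    noise_lowpass_hz: float = 35.0
    pink_noise_sd: float = 0.0
    artifact_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        sds = [
            self.max_effort_sd, self.calibration_noise_sd, self.logk_sd,
            self.beta_log_sd, self.rewp_residual_sd, self.p3_intercept_sd,
            self.p3_residual_sd, self.success_intercept_sd, self.speed_intercept_sd,
            self.speed_noise_sd, self.dt_intercept_sd, self.dt_lognorm_sd,
            self.rating_intercept_sd, self.rating_noise_sd, self.noise_sd,
            self.pink_noise_sd,
            *self.rewp_random_sd.values(),
        ]
        if any(s < 0 for s in sds):
            raise ValueError("all SDs must be >= 0")
        if not -1.0 <= self.logk_cross_corr <= 1.0:
            raise ValueError("logk_cross_corr must be in [-1, 1]")
        unknown = set(self.rewp_loadings) - set(REWP_TERMS)
        if unknown:
            raise ValueError(f"unknown RewP loading terms: {sorted(unknown)}")

    def replace(self, **kwargs) -> "GenerativeConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ParticipantProfile:
    """Generative parameters of one simulated participant."""

    id: int
    max_effort_count: float
    K_self: float
    K_other: float
    beta: float
    rewp_loadings: dict[str, float]
    rewp_random_effects: dict[str, float]
    p3_intercept_dev: float = 0.0
    success_intercept_dev: float = 0.0
    speed_intercept_dev: float = 0.0
    dt_intercept_dev: float = 0.0
    rating_intercept_dev: float = 0.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.max_effort_count <= 0:
            raise ValueError("max_effort_count must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def sample_participants(config: GenerativeConfig) -> list[ParticipantProfile]:
    """Draw ``config.n_participants`` profiles from the population model.

    logK_self and logK_other are bivariate normal with the configured
    cross-participant correlation; a ``negative_k_rate`` fraction of
    participants has one K flipped to a small negative value (effort
    slightly *adding* value), emulating the rare anti-discounting
    individuals.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    cov = (config.logk_sd ** 2) * np.array(
        [[1.0, config.logk_cross_corr], [config.logk_cross_corr, 1.0]]
    )
    logk = rng.multivariate_normal(
        [config.logk_self_mean, config.logk_other_mean], cov, size=n
    )
    profiles = []
    for i in range(n):
        k_self, k_other = np.exp(logk[i])
        if rng.random() < config.negative_k_rate:
            small_neg = -np.exp(rng.normal(-6.0, 0.5))
            if rng.random() < 0.5:
                k_self = small_neg
            else:
                k_other = small_neg
        profiles.append(
            ParticipantProfile(
                id=i,
                max_effort_count=max(float(rng.normal(config.max_effort_mean, config.max_effort_sd)), 5.0),
                K_self=float(k_self),
                K_other=float(k_other),
                beta=float(np.exp(rng.normal(config.beta_log_mean, config.beta_log_sd))),
                rewp_loadings=dict(config.rewp_loadings),
                rewp_random_effects={
                    name: float(rng.normal(0.0, sd))
                    for name, sd in config.rewp_random_sd.items()
                },
                p3_intercept_dev=float(rng.normal(0.0, config.p3_intercept_sd)),
                success_intercept_dev=float(rng.normal(0.0, config.success_intercept_sd)),
                speed_intercept_dev=float(rng.normal(0.0, config.speed_intercept_sd)),
                dt_intercept_dev=float(rng.normal(0.0, config.dt_intercept_sd)),
                rating_intercept_dev=float(rng.normal(0.0, config.rating_intercept_sd)),
                noise_sd=config.noise_sd,
            )
        )
    return profiles


# --------------------------------------------------------------------------
# calibration and effort execution

def calibrated_maximum(press_counts) -> float:
    """The calibrated maximum effort level: mean press count over the
    three 6000 ms calibration trials."""
    counts = np.asarray(press_counts, dtype=float)
    if counts.size != 3:
        raise ValueError("calibration uses exactly three trials")
    return float(counts.mean())


def simulate_calibration(
    profile: ParticipantProfile, config: GenerativeConfig, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Three noisy press counts around the profile's true capacity;
    returns (calibrated maximum, the three counts)."""
    counts = profile.max_effort_count + rng.normal(0.0, config.calibration_noise_sd, 3)
    counts = np.maximum(counts, 1.0)
    return calibrated_maximum(counts), counts


def _z_levels(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    return (values - values.mean()) / sd


def coded_predictors(frame: pd.DataFrame) -> pd.DataFrame:
    """Add the analysis-scale coded predictors to a single participant's
    trial frame: recipient_c (+-0.5), valence_c (+-0.5 where present),
    and effort_z / magnitude_z z-scored over the frame's trials."""
    out = frame.copy()
    out["recipient_c"] = np.where(out["recipient"] == "other", 0.5, -0.5)
    if "valence" in out.columns and out["valence"].isin(["gain", "nongain"]).any():
        out["valence_c"] = np.where(out["valence"] == "nongain", 0.5, -0.5)
    out["effort_z"] = _z_levels(out["effort_index"].to_numpy(dtype=float))
    out["magnitude_z"] = _z_levels(out["magnitude_yuan"].to_numpy(dtype=float))
    return out


def simulate_effort_execution(
    profile: ParticipantProfile,
    trial: TrialSpec,
    config: GenerativeConfig,
    rng: np.random.Generator,
    effort_z: float | None = None,
) -> tuple[bool, float]:
    """One effort-task trial: success (logistic, declining in effort) and
    press speed (linear, increasing in effort, higher for self)."""
    if effort_z is None:
        effort_z = (trial.effort_index - 3.0) / np.std([1, 2, 3, 4, 5], ddof=1)
    recipient_c = 0.5 if trial.recipient == "other" else -0.5
    magnitude_z = (trial.magnitude_yuan - 0.6) / np.std([0.2, 0.4, 0.6, 0.8, 1.0], ddof=1)
    p_success = special.expit(
        config.success_logit_intercept
        + profile.success_intercept_dev
        + config.success_logit_effort * effort_z
    )
    success = bool(rng.random() < p_success)
    speed = (
        config.speed_intercept
        + profile.speed_intercept_dev
        + config.speed_effort * effort_z
        + config.speed_recipient * recipient_c
        + config.speed_magnitude * magnitude_z
        + rng.normal(0.0, config.speed_noise_sd)
    )
    return success, float(max(speed, 0.1))


def simulate_effort_task(
    profile: ParticipantProfile,
    design: list[TrialSpec],
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Execute the whole effort-task design; returns the trial table with
    coded predictors, success, speed, and generative RewP/P3 amplitudes."""
    frame = coded_predictors(task_design.design_to_frame(design))
    successes, speeds = [], []
    for row, trial in zip(frame.itertuples(), design):
        s, v = simulate_effort_execution(profile, trial, config, rng, effort_z=row.effort_z)
        successes.append(s)
        speeds.append(v)
    frame["success"] = successes
    frame["presses_per_sec"] = speeds
    frame["rewp_amplitude_true"] = simulate_rewp_amplitudes(profile, frame, config, rng)
    frame["p3_amplitude_true"] = simulate_p3_amplitudes(profile, frame, config, rng)
    return frame


# --------------------------------------------------------------------------
# choices, decision times, ratings

def simulate_choices(
    profile: ParticipantProfile,
    design: list[TrialSpec],
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Decision task: softmax choices under the participant's (K, beta)
    and lognormal decision times with linear + quadratic effort effects
    and magnitude facilitation."""
    frame = coded_predictors(task_design.design_to_frame(design))
    is_choice = ~frame["is_catch"].to_numpy(dtype=bool)
    E = effort_units(frame["effort_index"].to_numpy(), config.effort_coding)
    K = np.where(frame["recipient"] == "other", profile.K_other, profile.K_self)
    sv_high = subjective_value(frame["magnitude_yuan"].to_numpy(dtype=float), E, K)
    sv_base = subjective_value(task_design.BASELINE_REWARD_YUAN, task_design.BASELINE_EFFORT, K)
    p_high = choice_prob(sv_high, sv_base, profile.beta)

    eff_z = frame["effort_z"].to_numpy()
    eff_q = eff_z ** 2 - np.mean(eff_z[is_choice] ** 2)
    rec = frame["recipient_c"].to_numpy()
    mag = frame["magnitude_z"].to_numpy()
    dt_mean = (
        config.dt_base_ms
        + profile.dt_intercept_dev
        + config.dt_effort_linear * eff_z
        + config.dt_effort_quadratic * eff_q
        + config.dt_magnitude * mag
        + config.dt_recipient_x_effort * rec * eff_z
        + config.dt_recipient_x_magnitude * rec * mag
        + config.dt_effort_x_magnitude * eff_z * mag
        + config.dt_effortq_x_magnitude * eff_q * mag
    )
    dt = np.clip(dt_mean * np.exp(rng.normal(0.0, config.dt_lognorm_sd, len(frame))), 200.0, 3500.0)

    chose_high = rng.random(len(frame)) < p_high
    no_resp = rng.random(len(frame)) < config.no_response_rate
    choice = np.where(chose_high, "high", "baseline").astype(object)
    choice[no_resp] = "none"
    choice[~is_choice] = "n/a"
    dt = dt.astype(object)
    dt[no_resp] = np.nan

    frame["p_high_true"] = p_high
    frame["choice"] = choice
    frame["decision_time_ms"] = pd.to_numeric(dt)
    frame["catch_correct"] = np.where(
        frame["is_catch"], rng.random(len(frame)) < config.catch_accuracy, np.nan
    )
    return frame


def simulate_ratings(
    profile: ParticipantProfile,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Post-experimental 9-point ratings (difficulty, invested effort,
    liking) per recipient x effort level, from a clipped linear latent
    model with the configured effect signs."""
    levels = np.array(task_design.EFFORT_LEVELS, dtype=float)
    eff_z = _z_levels(levels)
    rows = []
    for scale, eff in config.rating_effects.items():
        for recipient, rec_c in (("self", -0.5), ("other", 0.5)):
            latent = (
                eff["intercept"]
                + profile.rating_intercept_dev
                + eff["effort"] * eff_z
                + eff["recipient"] * rec_c
                + eff.get("recipient_x_effort", 0.0) * rec_c * eff_z
                + rng.normal(0.0, config.rating_noise_sd, len(levels))
            )
            for lvl, val in zip(task_design.EFFORT_LEVELS, np.clip(latent, 1.0, 9.0)):
                rows.append(
                    {"scale": scale, "recipient": recipient, "effort_index": lvl, "rating": float(val)}
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# single-trial amplitudes and epochs

def _term_columns(frame: pd.DataFrame, term: str) -> np.ndarray:
    if term == "Intercept":
        return np.ones(len(frame))
    cols = term.split(":")
    out = np.ones(len(frame))
    for c in cols:
        out = out * frame[c].to_numpy(dtype=float)
    return out


def simulate_rewp_amplitudes(
    profile: ParticipantProfile,
    coded_frame: pd.DataFrame,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-trial RewP amplitude: fixed loadings x coded predictors,
    plus the participant's random intercept/slopes and Gaussian residual."""
    amp = np.zeros(len(coded_frame))
    for term in REWP_TERMS:
        loading = profile.rewp_loadings.get(term, 0.0)
        if loading != 0.0:
            amp += loading * _term_columns(coded_frame, term)
    u = profile.rewp_random_effects
    amp += u.get("intercept", 0.0)
    amp += u.get("recipient", 0.0) * coded_frame["recipient_c"].to_numpy()
    amp += u.get("effort", 0.0) * coded_frame["effort_z"].to_numpy()
    amp += u.get("magnitude", 0.0) * coded_frame["magnitude_z"].to_numpy()
    amp += rng.normal(0.0, config.rewp_residual_sd, len(coded_frame))
    return amp


def simulate_p3_amplitudes(
    profile: ParticipantProfile,
    coded_frame: pd.DataFrame,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-trial parietal P3 to effort-completion feedback, increasing
    with prior effort demand."""
    return (
        config.p3_intercept
        + profile.p3_intercept_dev
        + config.p3_effort_slope * coded_frame["effort_z"].to_numpy()
        + config.p3_recipient * coded_frame["recipient_c"].to_numpy()
        + rng.normal(0.0, config.p3_residual_sd, len(coded_frame))
    )


def _normalized_kernel(times_ms: np.ndarray, center: float, sd: float, window: tuple[float, float]) -> np.ndarray:
    kernel = np.exp(-0.5 * ((times_ms - center) / sd) ** 2)
    kernel[times_ms < 0] = 0.0
    in_win = (times_ms >= window[0]) & (times_ms < window[1])
    return kernel / kernel[in_win].mean()


def _noise_smoothing_kernel(config: GenerativeConfig) -> np.ndarray:
    """Unit-sum Gaussian kernel whose width emulates the recording
    bandwidth: sigma = sfreq / (2*pi*f_lowpass) samples."""
    sigma = config.sfreq / (2.0 * np.pi * config.noise_lowpass_hz)
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    return k / k.sum()


def _smooth_noise(white: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Band-limit white noise along the time axis (axis 1), rescaled so
    the output keeps the input's standard deviation."""
    from scipy.signal import fftconvolve

    gain = np.sqrt(np.sum(kernel**2))
    out = fftconvolve(white, kernel[None, :, None], mode="same", axes=1)
    return out / gain


def _window_mean_noise_sd(
    config: GenerativeConfig,
    window: tuple[float, float],
    n_cluster: int = 3,
    include_baseline: bool = True,
) -> float:
    """SD of a cluster/window mean of the band-limited sensor noise.

    Accounts for the temporal autocorrelation induced by the smoothing
    kernel and, optionally, for the variance added by subtracting the
    prestimulus baseline mean."""
    kernel = _noise_smoothing_kernel(config)
    acf = np.correlate(kernel, kernel, "full")
    acf = acf / acf[len(kernel) - 1]
    times = default_time_axis(config.sfreq)

    def win_var(n: int) -> float:
        lags = np.arange(-(n - 1), n)
        rho = np.where(np.abs(lags) < len(kernel), acf[len(kernel) - 1 + np.minimum(np.abs(lags), len(kernel) - 1)], 0.0)
        return float(np.sum((n - np.abs(lags)) * rho)) / n**2

    n_win = int(((times >= window[0]) & (times < window[1])).sum())
    var = win_var(n_win)
    if include_baseline:
        var += win_var(int((times < 0).sum()))
    return config.noise_sd * np.sqrt(var / n_cluster)


def rewp_window_noise_sd(config: GenerativeConfig, n_cluster: int = 3, window=(300.0, 400.0)) -> float:
    """SD of the RewP window mean of the sensor noise alone: the
    measurement-noise floor the epoch route adds to the amplitude."""
    return _window_mean_noise_sd(config, window, n_cluster=n_cluster)


def simulate_epochs(
    profile: ParticipantProfile,
    effort_table: pd.DataFrame,
    config: GenerativeConfig,
    rng: np.random.Generator,
) -> EpochSet:
    """Render feedback-locked epochs for a completed effort-task table.

    Each trial's epoch is white sensor noise plus the trial's RewP
    amplitude times a frontocentral kernel and its P3 amplitude times a
    parietal kernel; kernels are zero before feedback onset and
    normalized so the component window-mean equals the amplitude
    parameter. Artifacts (single-sample steps, channel flatlines, slow
    drifts) are injected at ``config.artifact_rate`` per trial.
    """
    required = {"rewp_amplitude_true", "p3_amplitude_true"}
    if not required <= set(effort_table.columns):
        raise ValueError(f"effort table lacks columns {sorted(required)}")
    channels = list(config.channels)
    times = default_time_axis(config.sfreq)
    n_ch, n_t, n_trials = len(channels), len(times), len(effort_table)

    data = rng.normal(0.0, profile.noise_sd, size=(n_ch, n_t, n_trials))
    if profile.noise_sd > 0:
        data = _smooth_noise(data, _noise_smoothing_kernel(config))
    if config.pink_noise_sd > 0:
        # crude 1/f: random-walk noise rescaled to the requested SD
        walk = np.cumsum(rng.normal(0.0, 1.0, size=(n_ch, n_t, n_trials)), axis=1)
        walk -= walk.mean(axis=1, keepdims=True)
        walk /= max(walk.std(), 1e-12)
        data += config.pink_noise_sd * walk

    rewp_kernel = _normalized_kernel(times, 350.0, 35.0, (300.0, 400.0))
    p3_kernel = _normalized_kernel(times, 370.0, 50.0, (300.0, 440.0))
    fc = [channels.index(c) for c in ("FC3", "FCz", "FC4")]
    par = [channels.index(c) for c in ("P3", "Pz", "P4")]

    rewp_amp = effort_table["rewp_amplitude_true"].to_numpy()
    p3_amp = effort_table["p3_amplitude_true"].to_numpy()
    data[np.ix_(fc, range(n_t))] += rewp_kernel[None, :, None] * rewp_amp[None, None, :]
    data[np.ix_(par, range(n_t))] += p3_kernel[None, :, None] * p3_amp[None, None, :]

    for i in range(n_trials):
        if rng.random() >= config.artifact_rate:
            continue
        kind = rng.choice(["step", "flatline", "drift"])
        ch = int(rng.integers(n_ch))
        if kind == "step":
            t0 = int(rng.integers(1, n_t - 1))
            data[ch, t0, i] += 120.0 * (1 if rng.random() < 0.5 else -1)
        elif kind == "flatline":
            data[ch, :, i] = data[ch, 0, i]
        else:
            data[ch, :, i] += np.linspace(-75.0, 75.0, n_t) * (1 if rng.random() < 0.5 else -1)

    return EpochSet(
        data=data,
        channel_labels=channels,
        trial_table=effort_table.reset_index(drop=True),
        sfreq=config.sfreq,
        times_ms=times,
    )


# --------------------------------------------------------------------------
# whole-participant / whole-dataset assembly

@dataclass
class ParticipantData:
    profile: ParticipantProfile
    calibrated_max: float
    effort_table: pd.DataFrame
    decision_table: pd.DataFrame
    ratings: pd.DataFrame
    payout_positions: list[int]
    epochs: EpochSet | None = None


@dataclass
class Dataset:
    config: GenerativeConfig
    participants: list[ParticipantData]

    def _concat(self, attr: str) -> pd.DataFrame:
        frames = []
        for p in self.participants:
            f = getattr(p, attr).copy()
            f.insert(0, "participant", p.profile.id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def effort_frame(self) -> pd.DataFrame:
        return self._concat("effort_table")

    def decision_frame(self) -> pd.DataFrame:
        return self._concat("decision_table")

    def ratings_frame(self) -> pd.DataFrame:
        return self._concat("ratings")


def simulate_participant(
    profile: ParticipantProfile,
    config: GenerativeConfig,
    seed_seq: np.random.SeedSequence,
    include_epochs: bool = True,
) -> ParticipantData:
    rng = np.random.default_rng(seed_seq)
    design_seed = int(rng.integers(2**31))
    effort_design = build_effort_task_design(design_seed)
    decision_design = build_decision_task_design(design_seed + 1)

    calibrated, _counts = simulate_calibration(profile, config, rng)
    effort_table = simulate_effort_task(profile, effort_design, config, rng)
    # measured amplitude if no epochs are rendered: generative amplitude plus
    # the window-mean noise floor the epoch route would contribute
    noise_floor = rewp_window_noise_sd(config)
    effort_table["rewp_amplitude"] = effort_table["rewp_amplitude_true"] + rng.normal(
        0.0, noise_floor, len(effort_table)
    )
    p3_floor = _window_mean_noise_sd(config, (300.0, 440.0))
    effort_table["p3_amplitude"] = effort_table["p3_amplitude_true"] + rng.normal(
        0.0, p3_floor, len(effort_table)
    )

    decision_table = simulate_choices(profile, decision_design, config, rng)
    payout = task_design.select_payout_trials(decision_design, design_seed + 2)
    ratings = simulate_ratings(profile, config, rng)
    epochs = (
        simulate_epochs(profile, effort_table, config, rng) if include_epochs else None
    )
    return ParticipantData(
        profile=profile,
        calibrated_max=calibrated,
        effort_table=effort_table,
        decision_table=decision_table,
        ratings=ratings,
        payout_positions=[t.position for t in payout],
        epochs=epochs,
    )


def simulate_dataset(config: GenerativeConfig, include_epochs: bool = False) -> Dataset:
    """Simulate the whole study under one master seed (``config.seed``).

    With ``include_epochs=False`` the effort table still carries measured
    single-trial amplitudes (generative value + the epoch route's
    window-noise floor), so model-level analyses run without the memory
    cost of dense epoch arrays.
    """
    profiles = sample_participants(config)
    children = np.random.SeedSequence(config.seed).spawn(len(profiles) + 1)[1:]
    data = [
        simulate_participant(p, config, child, include_epochs=include_epochs)
        for p, child in zip(profiles, children)
    ]
    return Dataset(config=config, participants=data)


def write_dataset(dataset: Dataset, outdir, header_comment: str | None = None) -> None:
    """One directory per participant: trials_effort.csv, trials_decision.csv,
    ratings.csv, and (if present) epochs.bin + epochs.json."""
    outdir = Path(outdir)
    for p in dataset.participants:
        pdir = outdir / f"sub-{p.profile.id:02d}"
        pdir.mkdir(parents=True, exist_ok=True)
        for name, frame in (
            ("trials_effort", p.effort_table),
            ("trials_decision", p.decision_table),
            ("ratings", p.ratings),
        ):
            with open(pdir / f"{name}.csv", "w", encoding="utf-8") as fh:
                if header_comment:
                    fh.write(f"# {header_comment}\n")
                frame.to_csv(fh, index=False)
        if p.epochs is not None:
            p.epochs.save(pdir / "epochs")
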