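"""Epoch-level ERP processing: baseline correction, artifact screening,
retention accounting, and single-trial component quantification.

The pipeline starts from extracted epochs (continuous-EEG steps such as
filtering, re-referencing and ICA are out of scope). Four automatic
artifact rules are applied per trial and channel:

* sample-to-sample voltage step exceeding ``p2p_step_uV`` (default 50 µV);
* within-trial peak-to-peak range exceeding ``range_uV`` (default 200 µV);
* flatline — a maximum voltage difference below ``flat_uV`` (default
  0.5 µV) inside any 100 ms window;
* slow drift — a net least-squares linear trend over the epoch larger in
  magnitude than ``drift_uV`` (default 100 µV).

A trial is rejected when any rule fires on any channel.

Components are quantified as single-trial mean voltage over an electrode
cluster and a fixed time window: RewP as 300-400 ms over FC3/FCz/FC4,
locked to reward feedback; P3 as 300-440 ms over P3/Pz/P4, locked to
effort-completion feedback. Windows are half-open ([start, stop) in
sample time), so adjacent windows never double-count a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "ArtifactRuleSet",
    "ComponentSpec",
    "REWP",
    "P3",
    "baseline_correct",
    "detect_artifacts",
    "retention_rate",
    "measure_component",
    "single_trial_amplitudes",
]

RULE_NAMES = ("p2p_step", "range", "flatline", "drift")


@dataclass(frozen=True)
class ArtifactRuleSet:
    """Thresholds of the four automatic rejection rules (µV)."""

    p2p_step_uV: float = 50.0
    range_uV: float = 200.0
    flat_uV: float = 0.5
    drift_uV: float = 100.0
    flat_window_ms: float = 100.0

    def __post_init__(self) -> None:
        for name in ("p2p_step_uV", "range_uV", "flat_uV", "drift_uV", "flat_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ComponentSpec:
    """Mean-amplitude component: cluster of channels x time window."""

    name: str
    window_ms: tuple[float, float]
    cluster: tuple[str, ...]
    locking: str  # descriptive: which feedback event the epochs are locked to

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede stop")


REWP = ComponentSpec("RewP", (300.0, 400.0), ("FC3", "FCz", "FC4"), "reward feedback")
P3 = ComponentSpec("P3", (300.0, 440.0), ("P3", "Pz", "P4"), "effort-completion feedback")


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the prestimulus mean (samples with t < 0) per trial/channel.

    Idempotent: re-applying changes nothing.
    """
    pre = epochs.times_ms < 0.0
    if not pre.any():
        raise ValueError("epoch has no prestimulus samples")
    out = epochs.copy()
    baseline = out.data[:, pre, :].mean(axis=1, keepdims=True)
    out.data = out.data - baseline
    return out


def _flat_windows(data: np.ndarray, n_win: int, step: int) -> np.ndarray:
    """Min over sliding windows of per-window peak-to-peak range.

    data: (n_ch, n_t, n_trials) -> (n_ch, n_trials)."""
    n_t = data.shape[1]
    starts = list(range(0, n_t - n_win + 1, step))
    if not starts or starts[-1] != n_t - n_win:
        starts.append(max(n_t - n_win, 0))
    mins = np.full((data.shape[0], data.shape[2]), np.inf)
    for s in starts:
        seg = data[:, s : s + n_win, :]
        ptp = seg.max(axis=1) - seg.min(axis=1)
        mins = np.minimum(mins, ptp)
    return mins


def rule_masks(
    epochs: EpochSet, rules: ArtifactRuleSet | None = None
) -> dict[str, np.ndarray]:
    """Per-rule boolean trial masks (True = the rule fires on some channel)."""
    rules = rules or ArtifactRuleSet()
    data = epochs.data
    n_t = data.shape[1]

    step_ptp = np.abs(np.diff(data, axis=1)).max(axis=1)  # (ch, trials)
    hit_step = step_ptp > rules.p2p_step_uV

    rng_tr = data.max(axis=1) - data.min(axis=1)
    hit_range = rng_tr > rules.range_uV

    n_win = max(int(round(rules.flat_window_ms / 1000.0 * epochs.sfreq)), 2)
    if n_win > n_t:
        raise ValueError("flatline window longer than epoch")
    hit_flat = _flat_windows(data, n_win, max(n_win // 2, 1)) < rules.flat_uV

    # net linear drift over the epoch: least-squares slope x epoch duration
    t = epochs.times_ms - epochs.times_ms.mean()
    denom = float(np.sum(t * t))
    slope = np.einsum("t,ctr->cr", t, data) / denom  # µV per ms
    duration = epochs.times_ms[-1] - epochs.times_ms[0]
    hit_drift = np.abs(slope * duration) > rules.drift_uV

    return {
        "p2p_step": hit_step.any(axis=0),
        "range": hit_range.any(axis=0),
        "flatline": hit_flat.any(axis=0),
        "drift": hit_drift.any(axis=0),
    }


def detect_artifacts(
    epochs: EpochSet, rules: ArtifactRuleSet | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Apply the four rules to every trial over all channels present.

    Returns ``(reject_mask, counts)`` where ``reject_mask[i]`` is True if
    any rule fired on any channel of trial ``i`` and ``counts`` gives the
    number of trials flagged by each rule (a trial can count under
    several rules).
    """
    per_rule = rule_masks(epochs, rules)
    reject = np.zeros(epochs.n_trials, dtype=bool)
    for mask in per_rule.values():
        reject |= mask
    counts = {name: int(mask.sum()) for name, mask in per_rule.items()}
    return reject, counts


def retention_rate(reject_mask: np.ndarray) -> float:
    """Fraction of trials retained after artifact screening."""
    reject_mask = np.asarray(reject_mask, dtype=bool)
    if reject_mask.size == 0:
        raise ValueError("empty mask")
    return 1.0 - reject_mask.mean()


def measure_component(
    epochs: EpochSet,
    spec: ComponentSpec,
    reject_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Single-trial mean amplitude over ``spec``'s cluster and window.

    Channels of the cluster are averaged first, then samples with
    ``start <= t < stop`` (the two means commute). Rejected trials get
    NaN so the result stays aligned to ``epochs.trial_table``.
    """
    ch = epochs.channel_index(spec.cluster)
    lo, hi = spec.window_ms
    in_win = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not in_win.any():
        raise ValueError(f"window {spec.window_ms} outside epoch")
    amps = epochs.data[np.ix_(ch, np.flatnonzero(in_win))].mean(axis=(0, 1))
    amps = np.asarray(amps, dtype=float)
    if reject_mask is not None:
        amps = amps.copy()
        amps[np.asarray(reject_mask, dtype=bool)] = np.nan
    return amps


def single_trial_amplitudes(
    epochs: EpochSet,
    components: Sequence[ComponentSpec] = (REWP, P3),
    rules: ArtifactRuleSet | None = None,
    apply_baseline: bool = True,
) -> pd.DataFrame:
    """Full epoch-level pipeline for one participant.

    Baseline-corrects, screens artifacts, and measures each component,
    returning the trial table augmented with one amplitude column per
    component (NaN for rejected trials), a ``rejected`` flag and the
    semicolon-joined names of the rules that fired.
    """
    ep = baseline_correct(epochs) if apply_baseline else epochs
    per_rule = rule_masks(ep, rules)
    reject = np.zeros(ep.n_trials, dtype=bool)
    for mask in per_rule.values():
        reject |= mask
    out = ep.trial_table.copy().reset_index(drop=True)
    for spec in components:
        out[f"{spec.name.lower()}_amplitude"] = measure_component(ep, spec, reject)
    out["rejected"] = reject
    out["rejecting_rule"] = [
        ";".join(n for n in RULE_NAMES if per_rule[n][i]) for i in range(len(out))
    ]
    return out
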