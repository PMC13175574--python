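"""Simulation-based sensitivity analysis for the single-trial RewP model.

For a chosen fixed-effect term, datasets are simulated from the
generative model with that term's loading set to a candidate effect size
(all other loadings and variance components at their configured values),
the mixed model is refitted, and power is the fraction of simulations
with p < alpha. The minimum detectable effect (MDE) is found by
bisection on the effect magnitude until estimated power crosses the
target (default 80% at alpha = 0.05).

Every power estimate carries a Clopper-Pearson binomial confidence
interval. Refits use the random-effects structure that converged on a
template fit of the configured generator, established once up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .mixed_models import CodedDataset, ModelSpec, fit_mixed_model
from .synthetic_data import (
    REWP_TERMS,
    GenerativeConfig,
    coded_predictors,
    rewp_window_noise_sd,
    sample_participants,
    simulate_rewp_amplitudes,
)
from . import task_design

__all__ = [
    "PowerQuery",
    "PowerEstimate",
    "MDEResult",
    "REWP_FORMULA",
    "simulate_rewp_study",
    "template_spec",
    "power_at_effect",
    "minimum_detectable_effect",
]

REWP_FORMULA = "rewp_amplitude ~ recipient_c * effort_z * magnitude_z * valence_c"
_FULL_RE = ("recipient_c", "effort_z", "magnitude_z")


@dataclass
class PowerQuery:
    """Settings of one sensitivity question."""

    term: str
    alpha: float = 0.05
    power_goal: float = 0.80
    n_sims: int = 200
    bracket: tuple[float, float] = (0.02, 1.5)
    seed: int = 0
    resolution_frac: float = 0.05  # bisection tolerance, fraction of bracket width
    max_nonconverged_frac: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_goal < 1:
            raise ValueError("power_goal must be in (0, 1)")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.bracket[0] < 0 or self.bracket[0] >= self.bracket[1]:
            raise ValueError("bracket must be 0 <= lo < hi")


@dataclass
class PowerEstimate:
    term: str
    effect: float
    power: float
    ci_low: float
    ci_high: float
    n_sims: int
    n_converged: int
    flagged_nonconvergence: bool


@dataclass
class MDEResult:
    term: str
    mde: float
    power_goal: float
    curve: pd.DataFrame = field(repr=False)


def simulate_rewp_study(config: GenerativeConfig, seed: int) -> pd.DataFrame:
    """One simulated study at the amplitude level: per participant, a
    seeded effort-task design with coded predictors and single-trial
    measured RewP amplitudes (generative value + window-noise floor)."""
    cfg = config.replace(seed=seed)
    profiles = sample_participants(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    noise_floor = rewp_window_noise_sd(cfg)
    frames = []
    for p in profiles:
        design = task_design.build_effort_task_design(int(rng.integers(2**31)))
        frame = coded_predictors(task_design.design_to_frame(design))
        amp = simulate_rewp_amplitudes(p, frame, cfg, rng)
        frame["rewp_amplitude"] = amp + rng.normal(0.0, noise_floor, len(frame))
        frame.insert(0, "participant", p.id)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def template_spec(config: GenerativeConfig, seed: int = 0) -> ModelSpec:
    """Random-effects structure for power refits: fit the maximal
    structure once on a template simulation and keep whatever converged
    (possibly simplified)."""
    df = simulate_rewp_study(config, seed)
    spec = ModelSpec(formula=REWP_FORMULA, re_terms=_FULL_RE)
    result = fit_mixed_model(CodedDataset(df, "rewp_amplitude"), spec)
    return result.spec


def power_at_effect(
    config: GenerativeConfig,
    term: str,
    effect: float,
    query: PowerQuery,
    spec: ModelSpec | None = None,
) -> PowerEstimate:
    """Estimated power for ``term`` at loading ``effect``.

    Simulates ``query.n_sims`` studies with the term's generative loading
    set to ``effect``, refits each, and counts p < alpha among converged
    fits. Flags the estimate when more than ``max_nonconverged_frac`` of
    fits fail to converge.
    """
    if term not in REWP_TERMS:
        raise ValueError(f"unknown model term {term!r}")
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    cfg = config.replace(rewp_loadings={**config.rewp_loadings, term: float(effect)})
    if spec is None:
        spec = template_spec(cfg, seed=query.seed)
    seeds = np.random.SeedSequence([query.seed, abs(hash(term)) % (2**31), int(round(abs(effect) * 1e6))])
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seeds.spawn(query.n_sims)]

    n_sig = 0
    n_conv = 0
    for s in sim_seeds:
        df = simulate_rewp_study(cfg, s)
        result = fit_mixed_model(CodedDataset(df, "rewp_amplitude"), spec, max_simplify=0)
        usable = result.converged or result.singular  # singular fits still test
        n_conv += int(usable)
        if usable and result.pvalue(term) < query.alpha:
            n_sig += 1
    denom = max(n_conv, 1)
    power = n_sig / denom
    lo, hi = proportion_confint(n_sig, denom, alpha=0.05, method="beta")
    return PowerEstimate(
        term=term,
        effect=float(effect),
        power=power,
        ci_low=float(lo),
        ci_high=float(hi),
        n_sims=query.n_sims,
        n_converged=n_conv,
        flagged_nonconvergence=(query.n_sims - n_conv) > query.max_nonconverged_frac * query.n_sims,
    )


def minimum_detectable_effect(
    config: GenerativeConfig, term: str, query: PowerQuery,
    spec: ModelSpec | None = None,
) -> MDEResult:
    """Smallest effect magnitude reaching the power goal, by bisection.

    The bracket must span the goal: power at the lower edge below it,
    power at the upper edge at or above it. The sign of the reported MDE
    is positive (magnitude); the power curve evaluated along the way is
    returned for inspection. ``spec`` overrides the refit structure
    (default: whatever converged on a template fit).
    """
    if spec is None:
        spec = template_spec(config, seed=query.seed)
    records = []

    def measure(effect: float) -> float:
        est = power_at_effect(config, term, effect, query, spec=spec)
        records.append(est)
        return est.power

    lo, hi = query.bracket
    p_lo, p_hi = measure(lo), measure(hi)
    if not (p_lo < query.power_goal <= p_hi):
        raise ValueError(
            f"bracket {query.bracket} does not span power goal "
            f"{query.power_goal}: power({lo})={p_lo:.3f}, power({hi})={p_hi:.3f}"
        )
    tol = query.resolution_frac * (hi - lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if measure(mid) >= query.power_goal:
            hi = mid
        else:
            lo = mid
    curve = pd.DataFrame(
        {
            "effect": [r.effect for r in records],
            "power": [r.power for r in records],
            "ci_low": [r.ci_low for r in records],
            "ci_high": [r.ci_high for r in records],
            "n_converged": [r.n_converged for r in records],
        }
    ).sort_values("effect", ignore_index=True)
    return MDEResult(term=term, mde=float(hi), power_goal=query.power_goal, curve=curve)
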