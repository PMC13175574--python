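"""End-to-end orchestration: simulate, quantify ERPs, fit discounting,
run every named regression analysis, and assemble a reproduction report.

The named analyses mirror the study's statistical models:

* ``rewp`` — single-trial RewP ~ recipient x effort x magnitude x valence,
  with the Fig-4-style simple-slope decompositions;
* ``p3`` — completion-locked P3 ~ recipient x effort x magnitude;
* ``success`` / ``speed`` — effort-execution models;
* ``ratings`` — difficulty / invested effort / liking per scale;
* ``decision_time`` — linear + quadratic effort, magnitude, recipient;
* ``choice`` — logistic willingness to exert effort;
* ``cross_task`` — RewP model augmented with z-scored logK (and the
  choice-proportion robustness variant);
* ``covariate_control`` — RewP model with response-speed and
  effort-rating covariates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discounting_model import (
    correlate_K,
    fit_participant,
    fits_to_frame,
    group_compare,
)
from .erp_pipeline import retention_rate, single_trial_amplitudes
from .mixed_models import (
    CodedDataset,
    ModelSpec,
    code_predictors,
    covariate_control,
    cross_task_moderation,
    fit_mixed_model,
    simple_slopes,
)
from .sensitivity import PowerQuery, power_at_effect, template_spec
from .synthetic_data import Dataset, GenerativeConfig, simulate_dataset, write_dataset

ANALYSES = (
    "rewp",
    "p3",
    "success",
    "speed",
    "ratings",
    "decision_time",
    "choice",
    "cross_task",
    "covariate_control",
)

REWP_FORMULA = "rewp_amplitude ~ recipient_c * effort_z * magnitude_z * valence_c"
_GAUSS_RE = ("recipient_c", "effort_z", "magnitude_z")
# pragmatic default for the binomial family: a by-participant intercept and
# effort slope (the term binomial inferences here hinge on)
_BINOM_RE = ("effort_z",)


@dataclass
class PipelineConfig:
    """Master configuration of one full run."""

    master_seed: int = 0
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)
    effort_coding: str = "level"
    n_starts: int = 20
    analyses: tuple[str, ...] = ANALYSES
    include_epochs: bool = True
    power_terms: tuple[str, ...] = ("recipient_c:effort_z",)
    power_n_sims: int = 50
    outdir: str = "results"

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        self.generative = dataclasses.replace(self.generative, seed=self.master_seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GenerativeConfig(**raw.pop("generative", {}))
        raw.pop("seed", None)
        cfg = cls(generative=gen, **{k: v for k, v in raw.items()})
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generative"]["channels"] = list(d["generative"]["channels"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _log(msg: str) -> None:
    print(f"[prosocial-effort] {msg}", file=sys.stderr)


# ---------------------------------------------------------------------------
# stage: ERP quantification

def quantify_erps(dataset: Dataset) -> dict:
    """Replace direct amplitude columns with epoch-derived measurements
    where epochs exist; returns retention accounting."""
    rejected_total, n_total = 0, 0
    for p in dataset.participants:
        if p.epochs is None:
            continue
        measured = single_trial_amplitudes(p.epochs)
        for col in ("rewp_amplitude", "p3_amplitude", "rejected", "rejecting_rule"):
            p.effort_table[col] = measured[col].to_numpy()
        rejected_total += int(measured["rejected"].sum())
        n_total += len(measured)
    if n_total == 0:
        return {"epochs_present": False}
    return {
        "epochs_present": True,
        "n_trials": n_total,
        "n_rejected": rejected_total,
        "retention": retention_rate(
            np.concatenate(
                [
                    p.effort_table["rejected"].to_numpy(dtype=bool)
                    for p in dataset.participants
                    if p.epochs is not None
                ]
            )
        ),
    }


# ---------------------------------------------------------------------------
# named analyses

def _coded_effort(dataset: Dataset, outcome: str, drop_failed: bool = True) -> CodedDataset:
    df = dataset.effort_frame()
    df = df[np.isfinite(df[outcome])]
    return code_predictors(df, outcome=outcome, drop_failed=drop_failed)


def analysis_rewp(dataset: Dataset) -> dict:
    coded = _coded_effort(dataset, "rewp_amplitude")
    result = fit_mixed_model(coded, ModelSpec(REWP_FORMULA, re_terms=_GAUSS_RE))
    effort_slopes = simple_slopes(
        result, "effort_z", {"recipient_c": [-0.5, 0.5], "magnitude_z": [-1.0, 1.0]}
    )
    magnitude_slopes = simple_slopes(
        result, "magnitude_z", {"recipient_c": [-0.5, 0.5], "valence_c": [-0.5, 0.5]}
    )
    return {
        "result": result,
        "simple_slopes": pd.concat([effort_slopes, magnitude_slopes], ignore_index=True),
    }


def analysis_p3(dataset: Dataset) -> dict:
    coded = _coded_effort(dataset, "p3_amplitude")
    spec = ModelSpec(
        "p3_amplitude ~ recipient_c * effort_z * magnitude_z", re_terms=_GAUSS_RE
    )
    return {"result": fit_mixed_model(coded, spec)}


def analysis_success(dataset: Dataset) -> dict:
    df = dataset.effort_frame()
    df["success"] = df["success"].astype(int)
    coded = code_predictors(df, outcome="success", drop_failed=False)
    spec = ModelSpec(
        "success ~ recipient_c * effort_z * magnitude_z * valence_c",
        re_terms=_BINOM_RE,
        family="binomial",
    )
    return {"result": fit_mixed_model(coded, spec)}


def analysis_speed(dataset: Dataset) -> dict:
    coded = _coded_effort(dataset, "presses_per_sec")
    spec = ModelSpec(
        "presses_per_sec ~ recipient_c * effort_z * magnitude_z * valence_c",
        re_terms=_GAUSS_RE,
    )
    return {"result": fit_mixed_model(coded, spec)}


def analysis_ratings(dataset: Dataset) -> dict:
    df = dataset.ratings_frame()
    out = {}
    for scale, sub in df.groupby("scale"):
        coded = code_predictors(
            sub, outcome="rating", z_cols={"effort_index": "effort_z"}
        )
        spec = ModelSpec(
            "rating ~ recipient_c * effort_z", re_terms=("recipient_c", "effort_z")
        )
        result = fit_mixed_model(coded, spec)
        out[scale] = {
            "result": result,
            "simple_slopes": simple_slopes(
                result, "effort_z", {"recipient_c": [-0.5, 0.5]}
            ),
        }
    return out


def analysis_decision_time(dataset: Dataset) -> dict:
    df = dataset.decision_frame()
    df = df[np.isfinite(df["decision_time_ms"])]
    coded = code_predictors(
        df,
        outcome="decision_time_ms",
        drop_no_response=True,
        add_effort_quadratic=True,
    )
    spec = ModelSpec(
        "decision_time_ms ~ recipient_c * magnitude_z * (effort_z + effort_z2_c)",
        re_terms=_GAUSS_RE,
    )
    result = fit_mixed_model(coded, spec)
    slopes = pd.concat(
        [
            simple_slopes(result, "effort_z", {"recipient_c": [-0.5, 0.5]}),
            simple_slopes(result, "magnitude_z", {"recipient_c": [-0.5, 0.5]}),
            simple_slopes(result, "effort_z", {"magnitude_z": [-1.0, 1.0]}),
            simple_slopes(result, "effort_z2_c", {"magnitude_z": [-1.0, 1.0]}),
        ],
        ignore_index=True,
    )
    return {"result": result, "simple_slopes": slopes}


def analysis_choice(dataset: Dataset) -> dict:
    df = dataset.decision_frame()
    coded = code_predictors(df, outcome="choice", drop_no_response=True)
    coded.frame["chose_high"] = (coded.frame["choice"] == "high").astype(int)
    coded = CodedDataset(coded.frame, "chose_high", coded.participant_col, coded.coded_cols)
    spec = ModelSpec(
        "chose_high ~ recipient_c * effort_z * magnitude_z",
        re_terms=_BINOM_RE,
        family="binomial",
    )
    result = fit_mixed_model(coded, spec)
    slopes = pd.concat(
        [
            simple_slopes(result, "magnitude_z", {"recipient_c": [-0.5, 0.5]}),
            simple_slopes(result, "effort_z", {"magnitude_z": [-1.0, 1.0]}),
        ],
        ignore_index=True,
    )
    return {"result": result, "simple_slopes": slopes}


def discounting_stage(dataset: Dataset, coding: str, n_starts: int, seed: int) -> dict:
    fits = []
    for p in dataset.participants:
        fits.append(
            fit_participant(
                p.decision_table, coding=coding, n_starts=n_starts,
                seed=seed + p.profile.id,
            )
        )
    frame = fits_to_frame(fits, [p.profile.id for p in dataset.participants])
    try:
        comparison = dataclasses.asdict(group_compare(fits))
    except ValueError as exc:
        comparison = {"error": str(exc)}
    try:
        r, r_p = correlate_K(fits)
    except ValueError:
        r, r_p = np.nan, np.nan
    return {
        "fits": fits,
        "frame": frame,
        "group": comparison,
        "pearson_r": r,
        "pearson_p": r_p,
    }


def analysis_cross_task(dataset: Dataset, fits_frame: pd.DataFrame) -> dict:
    coded = _coded_effort(dataset, "rewp_amplitude")
    # domain-general discounting: mean of the two condition logKs
    logk = (
        fits_frame.set_index("participant")[["logK_self", "logK_other"]]
        .mean(axis=1)
        .to_dict()
    )
    result, grid = cross_task_moderation(coded, logk, moderator_name="logK_z")

    # robustness variant: overall high-effort choice proportion
    dec = dataset.decision_frame()
    dec = dec[dec["choice"].isin(["high", "baseline"])]
    prop = dec.groupby("participant")["choice"].apply(lambda s: (s == "high").mean()).to_dict()
    result_prop, grid_prop = cross_task_moderation(
        coded, prop, moderator_name="choice_prop_z"
    )
    return {
        "result": result,
        "simple_slopes": grid,
        "result_choice_proportion": result_prop,
        "simple_slopes_choice_proportion": grid_prop,
    }


def analysis_covariate_control(dataset: Dataset) -> dict:
    df = dataset.effort_frame()
    # per-trial effort rating: the participant's rating of this trial's
    # recipient x effort level on the "effort" scale
    ratings = dataset.ratings_frame()
    eff_ratings = ratings[ratings["scale"] == "effort"].rename(
        columns={"rating": "effort_rating"}
    )[["participant", "recipient", "effort_index", "effort_rating"]]
    df = df.merge(eff_ratings, on=["participant", "recipient", "effort_index"], how="left")
    df = df[np.isfinite(df["rewp_amplitude"])]
    out = {}
    for cov_src, cov in (("presses_per_sec", "speed_z"), ("effort_rating", "effort_rating_z")):
        coded = code_predictors(
            df,
            outcome="rewp_amplitude",
            drop_failed=True,
            z_cols={
                "effort_index": "effort_z",
                "magnitude_yuan": "magnitude_z",
                cov_src: cov,
            },
        )
        result, comparison = covariate_control(
            coded, ModelSpec(REWP_FORMULA, re_terms=_GAUSS_RE), cov
        )
        out[cov_src] = {"result": result, "comparison": comparison}
    return out


# ---------------------------------------------------------------------------
# report assembly

def _result_payload(result) -> dict:
    return {
        "coefficients": result.table.reset_index(names="term").to_dict("records"),
        "re_structure": {
            "terms": list(result.spec.re_terms),
            "correlated": result.spec.correlated,
        },
        "converged": result.converged,
        "singular": result.singular,
        "simplification_log": result.simplification_log,
        "backend": result.backend,
        "n_obs": result.n_obs,
        "n_groups": result.n_groups,
    }


def _payload(entry: dict) -> dict:
    out = {}
    for key, val in entry.items():
        if key == "result" or key.startswith("result"):
            out[key] = _result_payload(val)
        elif isinstance(val, pd.DataFrame):
            out[key] = val.to_dict("records")
        elif isinstance(val, dict) and "result" in val:
            out[key] = _payload(val)
        elif hasattr(val, "__dataclass_fields__"):
            out[key] = dataclasses.asdict(val)
        elif key == "fits":
            continue
        else:
            out[key] = val
    return out


def run_all(config: PipelineConfig, write_files: bool = True) -> dict:
    """Run every stage under one master seed and return the report dict."""
    if config.generative.n_participants < 10:
        warnings.warn(
            f"degraded power: only {config.generative.n_participants} participants; "
            "interaction estimates will be unstable",
            stacklevel=2,
        )
        _log("WARNING: degraded power (n_participants < 10)")

    stamp = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
    }
    header = f"prosocial-effort v{__version__} config={stamp['config_hash']} seed={config.master_seed}"

    _log("simulating dataset")
    dataset = simulate_dataset(config.generative, include_epochs=config.include_epochs)
    _log("quantifying single-trial ERPs")
    erp_info = quantify_erps(dataset)

    _log("fitting discounting model")
    disc = discounting_stage(
        dataset, config.effort_coding, config.n_starts, config.master_seed
    )

    report: dict = {**stamp, "erp": erp_info, "analyses": {}}
    report["discounting"] = {
        "fits": disc["frame"].to_dict("records"),
        "group": disc["group"],
        "pearson_r": disc["pearson_r"],
        "pearson_p": disc["pearson_p"],
    }

    runners = {
        "rewp": lambda: analysis_rewp(dataset),
        "p3": lambda: analysis_p3(dataset),
        "success": lambda: analysis_success(dataset),
        "speed": lambda: analysis_speed(dataset),
        "ratings": lambda: analysis_ratings(dataset),
        "decision_time": lambda: analysis_decision_time(dataset),
        "choice": lambda: analysis_choice(dataset),
        "cross_task": lambda: analysis_cross_task(dataset, disc["frame"]),
        "covariate_control": lambda: analysis_covariate_control(dataset),
    }
    for name in config.analyses:
        _log(f"analysis: {name}")
        try:
            entry = runners[name]()
        except Exception as exc:  # stage-tagged diagnostics
            raise RuntimeError(f"analysis stage {name!r} failed: {exc}") from exc
        report["analyses"][name] = _payload(entry)

    if config.power_terms and config.power_n_sims > 0:
        _log("sensitivity analysis")
        spec = template_spec(config.generative, seed=config.master_seed)
        power = {}
        for term in config.power_terms:
            query = PowerQuery(
                term=term, n_sims=config.power_n_sims, seed=config.master_seed
            )
            est = power_at_effect(
                config.generative, term, config.generative.rewp_loadings.get(term, 0.0),
                query, spec=spec,
            )
            power[term] = dataclasses.asdict(est)
        report["power"] = power

    if write_files:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dataset(dataset, outdir / "data", header_comment=header)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=_json_default))
        _write_summary(outdir / "summary.txt", report, header)
        with open(outdir / "discounting_fits.csv", "w") as fh:
            fh.write(f"# {header}\n")
            disc["frame"].to_csv(fh, index=False)
        for name, entry in report["analyses"].items():
            _write_analysis_csvs(outdir, name, entry, header)
        _log(f"report written to {outdir}")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_analysis_csvs(outdir: Path, name: str, entry: dict, header: str) -> None:
    def dump(prefix: str, sub: dict) -> None:
        if "coefficients" in sub:
            with open(outdir / f"{prefix}_coefficients.csv", "w") as fh:
                fh.write(f"# {header}\n")
                pd.DataFrame(sub["coefficients"]).to_csv(fh, index=False)
        for key, val in sub.items():
            if key == "coefficients":
                continue
            child = prefix if key == "result" else f"{prefix}_{key}"
            if isinstance(val, list) and val and isinstance(val[0], dict):
                with open(outdir / f"{child}.csv", "w") as fh:
                    fh.write(f"# {header}\n")
                    pd.DataFrame(val).to_csv(fh, index=False)
            elif isinstance(val, dict):
                dump(child, val)

    dump(name, entry)


def _write_summary(path: Path, report: dict, header: str) -> None:
    lines = [header, "=" * len(header), ""]
    if report["erp"].get("epochs_present"):
        lines.append(
            f"ERP retention: {report['erp']['retention']:.4f} "
            f"({report['erp']['n_rejected']} of {report['erp']['n_trials']} trials rejected)"
        )
    g = report["discounting"]["group"]
    if "error" in g:
        lines.append(f"Discounting group test unavailable: {g['error']}")
    else:
        lines.append(
            f"Discounting: mean logK self {g['mean_logK_self']:.2f}, other "
            f"{g['mean_logK_other']:.2f}, paired t({g['df']})={g['t']:.2f}, p={g['p']:.2g}, "
            f"n={g['n_used']} (excluded negative K: {g['n_excluded_negative_K']})"
        )
    lines.append(
        f"logK self-other correlation: r={report['discounting']['pearson_r']:.2f}"
    )
    lines.append("")
    for name, entry in report["analyses"].items():
        lines.append(f"[{name}]")
        sub = entry.get("result") or next(
            (v["result"] for v in entry.values() if isinstance(v, dict) and "result" in v),
            None,
        )
        if sub:
            for row in sub["coefficients"]:
                star = "*" if row["p"] < 0.05 else " "
                lines.append(
                    f"  {row['term']:<55s} b={row['estimate']:+8.3f} p={row['p']:.4f}{star}"
                )
        lines.append("")
    if "power" in report:
        lines.append("[power]")
        for term, est in report["power"].items():
            lines.append(
                f"  {term}: power={est['power']:.3f} "
                f"[{est['ci_low']:.3f}, {est['ci_high']:.3f}] at b={est['effect']:+.3f}"
            )
    path.write_text("\n".join(lines) + "\n")
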