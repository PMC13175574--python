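"""Mixed-effects regression layer: predictor coding, model fitting,
random-effects simplification, simple slopes, and the cross-task /
covariate workflows.

Coding follows the study's conventions: binary factors are contrast
coded (recipient: -0.5 self / +0.5 other; valence: -0.5 gain / +0.5
nongain) and continuous predictors (effort, magnitude) are z-scored
within participant, so a factor's coefficient is the condition
difference at the mean of the other predictors.

Fitting is delegated to established engines behind a uniform surface:
Gaussian models use statsmodels ``MixedLM`` (REML) with Wald-z p-values;
Satterthwaite degrees of freedom and binomial models use lme4/lmerTest
through an ``Rscript`` subprocess when R is available. When the maximal
random-effects structure is singular or fails to converge, the structure
is simplified step by step — correlations dropped first, then the slope
with the smallest estimated variance, terminating at intercept-only —
and every step is logged on the result.

Simple slopes of a focal predictor at fixed moderator settings (usually
mean +-1 SD, or the two levels of a coded factor) are linear
combinations of fixed-effect coefficients; their standard errors come
from the quadratic form with the fixed-effect covariance and use a
normal (Wald) reference.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "CodedDataset",
    "ModelSpec",
    "ModelResult",
    "code_predictors",
    "fit_mixed_model",
    "simplify_random_effects",
    "simple_slopes",
    "cross_task_moderation",
    "covariate_control",
    "lme4_available",
]

_SINGULAR_TOL = 1e-6


@dataclass
class CodedDataset:
    """A trial table with analysis-ready coded predictors."""

    frame: pd.DataFrame
    outcome: str
    participant_col: str = "participant"
    coded_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = {self.outcome, self.participant_col} - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")


@dataclass
class ModelSpec:
    """Fixed formula + random-effects structure + family + df method."""

    formula: str  # e.g. "rewp_amplitude ~ recipient_c * effort_z * magnitude_z * valence_c"
    re_terms: tuple[str, ...] = ()  # random slopes; intercept always included
    correlated: bool = True
    family: str = "gaussian"  # or "binomial"
    df_method: str = "wald"  # or "satterthwaite" (lme4 backend)
    backend: str = "auto"  # "statsmodels" | "lme4" | "auto"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.df_method not in ("wald", "satterthwaite"):
            raise ValueError(f"unknown df method {self.df_method!r}")
        fixed_rhs = self.formula.split("~", 1)[1]
        for t in self.re_terms:
            if t not in fixed_rhs:
                raise ValueError(f"random term {t!r} absent from fixed effects")

    def resolve_backend(self) -> str:
        if self.backend != "auto":
            return self.backend
        if self.family == "binomial" or self.df_method == "satterthwaite":
            return "lme4"
        return "statsmodels"


@dataclass
class ModelResult:
    """Coefficient table, fixed-effect covariance, and fit diagnostics."""

    table: pd.DataFrame  # index: term; columns: estimate, se, stat, df, p
    cov: pd.DataFrame  # fixed-effect covariance
    spec: ModelSpec
    re_variances: dict[str, float]
    converged: bool
    singular: bool
    simplification_log: list[str] = field(default_factory=list)
    backend: str = "statsmodels"
    n_obs: int = 0
    n_groups: int = 0

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


# ---------------------------------------------------------------------------
# predictor coding

def _z_within(series: pd.Series, by: pd.Series) -> pd.Series:
    def _z(x):
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"constant predictor within a participant (column {series.name!r})"
            )
        return (x - x.mean()) / sd

    return series.groupby(by, group_keys=False).transform(_z)


def code_predictors(
    raw: pd.DataFrame,
    outcome: str,
    *,
    participant_col: str = "participant",
    z_cols: Mapping[str, str] | None = None,
    drop_failed: bool = False,
    drop_no_response: bool = False,
    drop_catch: bool = True,
    add_effort_quadratic: bool = False,
) -> CodedDataset:
    """Contrast-code factors and z-score continuous predictors within
    participant.

    ``z_cols`` maps source column -> coded name; default is effort_index
    -> effort_z and magnitude_yuan -> magnitude_z. ``drop_failed``
    removes unsuccessful effort-task trials (as in the reported 3.34%
    exclusion); ``drop_no_response`` removes decision trials without a
    response (0.91%); catch trials are dropped by default where present.
    """
    df = raw.copy()
    if drop_catch and "is_catch" in df.columns:
        df = df[~df["is_catch"].astype(bool)]
    if drop_failed:
        if "success" not in df.columns:
            raise ValueError("drop_failed requires a 'success' column")
        df = df[df["success"].astype(bool)]
    if drop_no_response:
        df = df[df["choice"].isin(["high", "baseline"])]
    df = df.copy()

    coded: list[str] = []
    if "recipient" in df.columns:
        df["recipient_c"] = np.where(df["recipient"] == "other", 0.5, -0.5)
        coded.append("recipient_c")
    if "valence" in df.columns and df["valence"].isin(["gain", "nongain"]).all():
        df["valence_c"] = np.where(df["valence"] == "nongain", 0.5, -0.5)
        coded.append("valence_c")

    if z_cols is None:
        z_cols = {}
        if "effort_index" in df.columns:
            z_cols["effort_index"] = "effort_z"
        if "magnitude_yuan" in df.columns:
            z_cols["magnitude_yuan"] = "magnitude_z"
    for src, dst in z_cols.items():
        df[dst] = _z_within(df[src].astype(float), df[participant_col])
        coded.append(dst)

    if add_effort_quadratic:
        if "effort_z" not in df.columns:
            raise ValueError("quadratic term requires effort_z")
        sq = df["effort_z"] ** 2
        df["effort_z2_c"] = sq - sq.groupby(df[participant_col]).transform("mean")
        coded.append("effort_z2_c")

    return CodedDataset(
        frame=df.reset_index(drop=True),
        outcome=outcome,
        participant_col=participant_col,
        coded_cols=coded,
    )


# ---------------------------------------------------------------------------
# fitting

def lme4_available() -> bool:
    """True when an R installation with lme4 is reachable via Rscript."""
    if shutil.which("Rscript") is None:
        return False
    try:
        proc = subprocess.run(
            ["Rscript", "--vanilla", "-e", "invisible(loadNamespace('lme4'))"],
            capture_output=True,
            timeout=120,
        )
    except (OSError, subprocess.TimeoutExpired):
        return False
    return proc.returncode == 0


def _fit_statsmodels(data: CodedDataset, spec: ModelSpec):
    df = data.frame
    kwargs = {}
    if spec.re_terms and spec.correlated:
        kwargs["re_formula"] = "1 + " + " + ".join(spec.re_terms)
    elif spec.re_terms:
        kwargs["re_formula"] = "1"
        kwargs["vc_formula"] = {t: f"0 + {t}" for t in spec.re_terms}
    model = smf.mixedlm(spec.formula, df, groups=df[data.participant_col], **kwargs)
    result, warn_text = None, ""
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                candidate = model.fit(reml=True, method=method, maxiter=500)
        except (np.linalg.LinAlgError, ValueError):
            continue
        text = " ".join(str(w.message) for w in caught)
        sane = np.isfinite(candidate.bse_fe).all() and candidate.bse_fe.max() < 1e5
        if result is None or (candidate.converged and sane):
            result, warn_text = candidate, text
        if candidate.converged and sane:
            break
    if result is None:
        raise np.linalg.LinAlgError("all optimizers failed")

    k_fe = model.k_fe
    fe_names = model.exog_names[:k_fe]
    params = np.asarray(result.fe_params)
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[:k_fe, :k_fe], index=fe_names, columns=fe_names
    )
    se = np.sqrt(np.diag(cov.to_numpy()))
    z = params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"estimate": params, "se": se, "stat": z, "df": np.nan, "p": p}, index=fe_names
    )

    # random-effect variance estimates, keyed by term
    re_var: dict[str, float] = {}
    if spec.re_terms and spec.correlated:
        names = ["intercept"] + list(spec.re_terms)
        diag = np.diag(np.asarray(result.cov_re))
        re_var = {n: float(v) for n, v in zip(names, diag)}
    elif spec.re_terms:
        re_var = {"intercept": float(np.asarray(result.cov_re)[0, 0])}
        for t, v in zip(spec.re_terms, np.asarray(result.vcomp)):
            re_var[t] = float(v)
    else:
        re_var = {"intercept": float(np.asarray(result.cov_re)[0, 0])}

    scale = float(result.scale)
    rel = max(scale, max(re_var.values()), 1e-12)
    singular = min(re_var.values()) < _SINGULAR_TOL * rel
    if spec.re_terms and spec.correlated:
        eig = np.linalg.eigvalsh(np.asarray(result.cov_re))
        singular = singular or eig.min() < _SINGULAR_TOL * rel
    converged = bool(result.converged) and "MLE may be on the boundary" not in warn_text
    return table, cov, re_var, converged, singular


_R_TEMPLATE = """
suppressMessages({{
  library(jsonlite)
  library(lme4)
  {extra_lib}
}})
d <- read.csv("{csv}")
d$participant <- factor(d$participant)
{fit_call}
co <- as.data.frame(summary(m)$coefficients)
vc <- as.data.frame(VarCorr(m))
out <- list(
  terms = rownames(co),
  columns = colnames(co),
  coef = unname(as.matrix(co)),
  vcov = unname(as.matrix(vcov(m))),
  singular = isSingular(m),
  messages = unlist(m@optinfo$conv$lme4$messages),
  varcorr_grp = vc$grp, varcorr_var1 = vc$var1, varcorr_var2 = vc$var2,
  varcorr_vcov = vc$vcov
)
write(toJSON(out, digits = 14, na = "null"), "{out}")
"""


def _fit_lme4(data: CodedDataset, spec: ModelSpec):
    if spec.re_terms:
        sep = " | " if spec.correlated else " || "
        re_part = f"(1 + {' + '.join(spec.re_terms)}{sep}participant)"
    else:
        re_part = "(1 | participant)"
    lhs, rhs = (s.strip() for s in spec.formula.split("~", 1))
    r_formula = f"{lhs} ~ {rhs} + {re_part}"
    if spec.family == "gaussian":
        extra_lib = "library(lmerTest)"
        fit_call = f'm <- lmer({r_formula}, data = d, REML = TRUE)'
    else:
        extra_lib = ""
        fit_call = (
            f'm <- glmer({r_formula}, data = d, family = binomial, '
            f'control = glmerControl(optimizer = "bobyqa"))'
        )

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        csv = tmp / "data.csv"
        cols = {data.outcome, data.participant_col}
        for tok in rhs.replace("*", "+").replace(":", "+").split("+"):
            tok = tok.strip()
            if tok and tok not in ("1", "0") and tok in data.frame.columns:
                cols.add(tok)
        sub = data.frame[sorted(cols)].copy()
        if spec.family == "binomial":
            sub[data.outcome] = sub[data.outcome].astype(int)
        sub.to_csv(csv, index=False)
        out_json = tmp / "fit.json"
        script = tmp / "fit.R"
        script.write_text(
            _R_TEMPLATE.format(
                extra_lib=extra_lib, csv=csv.as_posix(), fit_call=fit_call,
                out=out_json.as_posix(),
            )
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True,
            timeout=1800,
        )
        if proc.returncode != 0 or not out_json.exists():
            raise RuntimeError(f"lme4 backend failed:\n{proc.stderr[-2000:]}")
        res = json.loads(out_json.read_text())

    terms = [t.replace("(Intercept)", "Intercept") for t in res["terms"]]
    coef = np.asarray(res["coef"], dtype=float)
    columns = list(res["columns"])
    est = coef[:, columns.index("Estimate")]
    se = coef[:, columns.index("Std. Error")]
    if spec.family == "gaussian":
        dfs = coef[:, columns.index("df")]
        stat = coef[:, columns.index("t value")]
        p = coef[:, columns.index("Pr(>|t|)")]
    else:
        dfs = np.full(len(terms), np.nan)
        stat = coef[:, columns.index("z value")]
        p = coef[:, columns.index("Pr(>|z|)")]
    table = pd.DataFrame(
        {"estimate": est, "se": se, "stat": stat, "df": dfs, "p": p}, index=terms
    )
    cov = pd.DataFrame(np.asarray(res["vcov"], dtype=float), index=terms, columns=terms)

    grp = list(np.atleast_1d(res.get("varcorr_grp", [])))
    var1 = list(np.atleast_1d(res.get("varcorr_var1", [])))
    var2 = list(np.atleast_1d(res.get("varcorr_var2", [])))
    vcv = list(np.atleast_1d(res.get("varcorr_vcov", [])))
    var2 += [None] * (len(grp) - len(var2))
    re_var: dict[str, float] = {}
    for g, v1, v2, v in zip(grp, var1, var2, vcv):
        if g == "Residual" or v1 is None:
            continue
        if v2 is not None and not (isinstance(v2, float) and np.isnan(v2)):
            continue  # covariance row
        name = "intercept" if v1 == "(Intercept)" else str(v1)
        re_var[name] = float(v)
    # keep only variances of terms we asked for
    wanted = {"intercept", *spec.re_terms}
    re_var = {k: v for k, v in re_var.items() if k in wanted} or {"intercept": float("nan")}
    messages = res.get("messages") or []
    converged = len(messages) == 0
    singular = bool(res.get("singular", False))
    return table, cov, re_var, converged, singular


def simplify_random_effects(spec: ModelSpec, re_variances: Mapping[str, float]) -> ModelSpec:
    """One step of the simplification policy.

    Order: drop slope correlations first; then drop the slope with the
    smallest estimated variance; intercept-only is the terminal state
    (returned unchanged if already there).
    """
    if spec.re_terms and spec.correlated:
        return replace(spec, correlated=False)
    if spec.re_terms:
        slope_vars = {t: re_variances.get(t, 0.0) for t in spec.re_terms}
        victim = min(slope_vars, key=lambda t: slope_vars[t])
        remaining = tuple(t for t in spec.re_terms if t != victim)
        return replace(spec, re_terms=remaining)
    return spec


def fit_mixed_model(
    data: CodedDataset, spec: ModelSpec, max_simplify: int | None = None
) -> ModelResult:
    """Fit ``spec`` on ``data``, simplifying the random structure until
    the model converges non-singularly (or reaches intercept-only).

    Gaussian models are estimated by REML via statsmodels MixedLM with
    Wald-z p-values; ``df_method='satterthwaite'`` and binomial families
    are delegated to lme4/lmerTest through Rscript.
    """
    df = data.frame
    if df[data.outcome].nunique() <= 1:
        raise ValueError("outcome has no variance")
    n_groups = df[data.participant_col].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 participants")
    backend = spec.resolve_backend()
    if backend == "lme4" and not lme4_available():
        raise RuntimeError(
            "lme4 backend requested (binomial family or Satterthwaite df) but "
            "Rscript/lme4 is not available"
        )

    log: list[str] = []
    current = spec
    n_steps = 0
    limit = max_simplify if max_simplify is not None else len(spec.re_terms) + 1
    while True:
        fitter = _fit_lme4 if backend == "lme4" else _fit_statsmodels
        structure = _describe_structure(current)
        try:
            table, cov, re_var, converged, singular = fitter(data, current)
            failed = False
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            if not current.re_terms:
                raise  # intercept-only is the terminal fallback
            failed = True
            re_var = {}
        if failed:
            log.append(f"fitted {structure}: failed outright")
            log.append("simplified: " + _structure_diff(current, simplify_random_effects(current, re_var)))
            current = simplify_random_effects(current, re_var)
            n_steps += 1
            continue
        if converged and not singular:
            log.append(f"fitted {structure}: ok")
            break
        log.append(
            f"fitted {structure}: "
            + ("singular" if singular else "non-convergent")
        )
        simpler = simplify_random_effects(current, re_var)
        if simpler == current or n_steps >= limit:
            log.append(f"terminal structure {structure}; keeping fit")
            break
        dropped = _structure_diff(current, simpler)
        log.append(f"simplified: {dropped}")
        current = simpler
        n_steps += 1

    return ModelResult(
        table=table,
        cov=cov,
        spec=current,
        re_variances=re_var,
        converged=converged,
        singular=singular,
        simplification_log=log,
        backend=backend,
        n_obs=len(df),
        n_groups=n_groups,
    )


def _describe_structure(spec: ModelSpec) -> str:
    if not spec.re_terms:
        return "(1 | participant)"
    sep = " | " if spec.correlated else " || "
    return f"(1 + {' + '.join(spec.re_terms)}{sep}participant)"


def _structure_diff(old: ModelSpec, new: ModelSpec) -> str:
    if old.correlated and not new.correlated:
        return "dropped slope correlations"
    gone = set(old.re_terms) - set(new.re_terms)
    return f"dropped random slope {', '.join(sorted(gone))}"


# ---------------------------------------------------------------------------
# simple slopes

@dataclass
class SimpleSlope:
    focal: str
    settings: dict[str, float]
    slope: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


def simple_slopes(
    result: ModelResult,
    focal: str,
    moderators: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Conditional effect of ``focal`` at each combination of moderator
    settings.

    The slope is the sum, over every fixed term containing the focal
    predictor, of the coefficient times the product of the moderator
    settings of the term's other components (components not listed among
    the moderators sit at their center, zeroing the term). SEs use the
    fixed-effect covariance; the reference distribution is normal.
    """
    terms = list(result.table.index)
    if not any(focal in t.split(":") for t in terms):
        raise ValueError(f"focal predictor {focal!r} not in model terms")
    zcrit = stats.norm.ppf(1 - alpha / 2)
    cov = result.cov.loc[terms, terms].to_numpy()
    b = result.table["estimate"].to_numpy()

    rows = []
    names = list(moderators)
    for combo in product(*(moderators[m] for m in names)):
        setting = dict(zip(names, combo))
        w = np.zeros(len(terms))
        for i, term in enumerate(terms):
            parts = term.split(":")
            if focal not in parts:
                continue
            weight = 1.0
            for comp in parts:
                if comp == focal:
                    continue
                weight *= setting.get(comp, 0.0)
            w[i] = weight
        slope = float(w @ b)
        se = float(np.sqrt(w @ cov @ w))
        z = slope / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "focal": focal,
                **{f"at_{m}": v for m, v in setting.items()},
                "slope": slope,
                "se": se,
                "ci_low": slope - zcrit * se,
                "ci_high": slope + zcrit * se,
                "z": z,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-task moderation and covariate control

def cross_task_moderation(
    coded: CodedDataset,
    moderator_by_participant: Mapping,
    moderator_name: str = "logK_z",
    re_terms: tuple[str, ...] = ("recipient_c", "effort_z", "magnitude_z"),
    backend: str = "auto",
) -> tuple[ModelResult, pd.DataFrame]:
    """Augment the RewP model with a per-participant moderator (z-scored
    across participants) interacting with recipient, effort and
    magnitude, then decompose the four-way interaction at +-1 SD of
    magnitude and moderator, separately per recipient.

    ``moderator_by_participant`` maps participant id -> raw moderator
    value (e.g. logK, or the high-effort choice proportion); participants
    with a missing value (e.g. negative K) are dropped, erroring if more
    than 20% are missing.
    """
    df = coded.frame.copy()
    ids = df[coded.participant_col].unique()
    values = {i: moderator_by_participant.get(i) for i in ids}
    missing = [i for i, v in values.items() if v is None or (isinstance(v, float) and np.isnan(v))]
    if len(missing) > 0.2 * len(ids):
        raise ValueError(
            f"moderator missing for {len(missing)}/{len(ids)} participants (> 20%)"
        )
    usable = {i: float(v) for i, v in values.items() if i not in missing}
    vals = np.array(list(usable.values()))
    if vals.std(ddof=1) == 0:
        raise ValueError("moderator is constant across participants; its interactions are inestimable")
    zmap = {i: (v - vals.mean()) / vals.std(ddof=1) for i, v in usable.items()}
    df = df[df[coded.participant_col].isin(usable)].copy()
    df[moderator_name] = df[coded.participant_col].map(zmap)

    formula = (
        f"{coded.outcome} ~ recipient_c * effort_z * magnitude_z * {moderator_name}"
        + (" + valence_c" if "valence_c" in df.columns else "")
    )
    spec = ModelSpec(formula=formula, re_terms=re_terms, backend=backend)
    result = fit_mixed_model(
        CodedDataset(df, coded.outcome, coded.participant_col, coded.coded_cols), spec
    )
    grid = simple_slopes(
        result,
        focal="effort_z",
        moderators={
            "recipient_c": [-0.5, 0.5],
            "magnitude_z": [-1.0, 1.0],
            moderator_name: [-1.0, 1.0],
        },
    )
    return result, grid


def covariate_control(
    coded: CodedDataset,
    base_spec: ModelSpec,
    covariate: str,
    key_terms: Sequence[str] = (
        "recipient_c:effort_z",
        "recipient_c:effort_z:magnitude_z",
    ),
) -> tuple[ModelResult, pd.DataFrame]:
    """Refit the model with a trial-level covariate added as a fixed
    effect and report whether the key interactions retain sign and
    significance."""
    df = coded.frame
    if covariate not in df.columns:
        raise ValueError(f"covariate {covariate!r} absent")
    if df[covariate].std(ddof=1) == 0 or not np.isfinite(df[covariate].std(ddof=1)):
        raise ValueError(f"covariate {covariate!r} has zero variance")
    if np.corrcoef(df[covariate], df[coded.outcome])[0, 1] > 0.999:
        raise ValueError(f"covariate {covariate!r} duplicates the outcome")

    base = fit_mixed_model(coded, base_spec)
    lhs, rhs = base_spec.formula.split("~", 1)
    aug_spec = replace(base_spec, formula=f"{lhs}~{rhs} + {covariate}")
    aug = fit_mixed_model(coded, aug_spec)

    rows = []
    for term in key_terms:
        b0, p0 = base.coef(term), base.pvalue(term)
        b1, p1 = aug.coef(term), aug.pvalue(term)
        rows.append(
            {
                "term": term,
                "estimate_base": b0,
                "p_base": p0,
                "estimate_controlled": b1,
                "p_controlled": p1,
                "sign_retained": np.sign(b0) == np.sign(b1),
                "significance_retained": (p0 < 0.05) == (p1 < 0.05),
            }
        )
    return aug, pd.DataFrame(rows)
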