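"""Filtered analysis table, logistic mixed-effects models, and error analysis.

The binary categorization outcome (hit/miss) is modelled with logistic
mixed-effects regression: fixed effects for time and the distributional
predictors, a by-corpus random intercept, and by-word random intercepts
and slopes over time (the slopes absorb the autocorrelation between
outcomes for the same word at successive slices). Model selection is by
AIC: single-predictor fits over the time-only baseline, and a forward
search adding the best candidate until no AIC improvement remains or a
fit stops converging.

Estimation is delegated to R's lme4 (``glmer``) through an Rscript
subprocess; when no R toolchain is available a fixed-effects logistic
fallback (statsmodels GLM with corpus and word indicator terms) is used
and flagged as such in the result. Variance explained is summarized with
marginal and conditional r-squared (fixed effects alone vs fixed plus
random), using the logit-link distribution-specific variance pi^2 / 3.

The error analysis cross-tabulates correct against predicted coarse tags,
compares observed counts with expectations under independence, and flags
cells whose standardized Pearson residual exceeds |1.96|.
"""

from __future__ import annotations

import json
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import CoarseTag

#: logit-link distribution-specific variance used in the r-squared denominators
LOGIT_VARIANCE = np.pi**2 / 3

DEFAULT_RANDOM_SPEC = "(1 | corpus_id) + (1 + time | word)"

_COARSE_ORDER = [t.value for t in CoarseTag]


# ---------------------------------------------------------------------------
# analysis-table assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableFilters:
    """Row filters applied before modelling.

    * ``require_all_corpora`` — keep only words observed in every
      sub-corpus of the run (cross-corpus identity is wordform + fine tag).
    * ``require_first_half`` — the word must already occur within the
      first 50% prefix of *each* corpus (time index <= 1).
    * ``drop_freq1`` — drop individual observations whose token frequency
      at that slice is 1 (a hapax has a perfectly determined diversity).
    * ``exclude_function_words`` — drop FUNCT-tagged words (the
      content-word replication).
    """

    require_all_corpora: bool = True
    require_first_half: bool = True
    drop_freq1: bool = True
    exclude_function_words: bool = False


def assemble_table(
    outcomes: pd.DataFrame,
    predictors: pd.DataFrame,
    filters: TableFilters = TableFilters(),
) -> pd.DataFrame:
    """Join outcomes with predictors and apply the analysis filters.

    ``outcomes`` needs columns corpus_id, time_index, word_id, wordform,
    fine_tag, coarse_tag, hit; ``predictors`` needs corpus_id, time_index,
    word (the corpus-local key), frequency, log_frequency, log_diversity,
    avg_cond_prob, median_ig. Returns one row per surviving
    (word, corpus, slice) with a global ``word`` identity column and a
    numeric ``time`` column.
    """
    preds = predictors.rename(columns={"word": "word_id"})
    preds = preds.drop(
        columns=[c for c in ("wordform", "fine_tag", "coarse_tag") if c in preds],
        errors="ignore",
    )
    merged = outcomes.merge(
        preds, on=["corpus_id", "time_index", "word_id"], how="left", validate="1:1"
    )
    if merged["log_frequency"].isna().any():
        missing = merged[merged["log_frequency"].isna()]
        raise KeyError(
            "outcomes and predictors are not keyed identically; first orphan: "
            f"{missing.iloc[0][['corpus_id', 'time_index', 'word_id']].to_dict()}"
        )
    merged["word"] = merged["wordform"] + "/" + merged["fine_tag"]
    merged["time"] = merged["time_index"].astype(int)

    n_corpora = merged["corpus_id"].nunique()
    if filters.require_all_corpora:
        per_word = merged.groupby("word")["corpus_id"].nunique()
        keep = set(per_word[per_word == n_corpora].index)
        merged = merged[merged["word"].isin(keep)]
    if filters.require_first_half:
        early = merged[merged["time_index"] <= 1]
        per_word = early.groupby("word")["corpus_id"].nunique()
        keep = set(per_word[per_word == n_corpora].index)
        merged = merged[merged["word"].isin(keep)]
    if filters.drop_freq1:
        merged = merged[merged["frequency"] > 1]
    if filters.exclude_function_words:
        merged = merged[merged["coarse_tag"] != CoarseTag.FUNCT.value]

    cols = [
        "hit",
        "corpus_id",
        "word",
        "word_id",
        "time",
        "time_index",
        "coarse_tag",
        "frequency",
        "log_frequency",
        "log_diversity",
        "avg_cond_prob",
        "median_ig",
    ]
    out = merged[cols].reset_index(drop=True)
    out["hit"] = out["hit"].astype(int)
    return out


# ---------------------------------------------------------------------------
# mixed-effects fitting
# ---------------------------------------------------------------------------


@dataclass
class RandomTerm:
    group: str
    variables: list[str]  # covariance-matrix order, "(Intercept)" first
    cov: np.ndarray  # covariance matrix of the random effects


@dataclass
class RegressionResult:
    formula: str
    terms: list[str]  # fixed-term names in model order (incl. intercept)
    beta: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    aic: float = float("nan")
    marginal_r2: float = float("nan")
    conditional_r2: float = float("nan")
    converged: bool = False
    singular: bool = False
    engine: str = "lme4"
    n_obs: int = 0
    random_terms: list[RandomTerm] = field(default_factory=list)
    message: str = ""

    def coef_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "beta": self.beta.get(t, float("nan")),
                "se": self.se.get(t, float("nan")),
                "z": self.z.get(t, float("nan")),
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


class UndefinedResultError(RuntimeError):
    """Raised when a quantity is requested from a non-converged fit."""


_R_FIT_TEMPLATE = r"""
suppressMessages({library(lme4); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$corpus_id <- factor(d$corpus_id)
if ("word" %in% names(d)) d$word <- factor(d$word)
fml <- as.formula(args[2])
nagq <- as.integer(args[3])
out <- list(ok = FALSE, message = "")
res <- tryCatch({
  m <- glmer(fml, data = d, family = binomial, nAGQ = nagq,
             control = glmerControl(calc.derivs = FALSE))
  msgs <- m@optinfo$conv$lme4$messages
  vc <- VarCorr(m)
  vclist <- lapply(names(vc), function(g) {
    mat <- as.matrix(vc[[g]])
    list(group = g, vars = rownames(mat),
         cov = matrix(as.numeric(mat), nrow = nrow(mat)))
  })
  list(ok = TRUE,
       fixef_names = names(fixef(m)),
       fixef = as.numeric(fixef(m)),
       se = as.numeric(sqrt(diag(as.matrix(vcov(m))))),
       aic = AIC(m),
       n_obs = nobs(m),
       singular = isSingular(m),
       converged = is.null(msgs),
       messages = if (is.null(msgs)) "" else paste(msgs, collapse = "; "),
       varcorr = vclist)
}, error = function(e) list(ok = FALSE, message = conditionMessage(e)))
writeLines(toJSON(res, digits = 12, auto_unbox = TRUE), args[4])
"""


def _r_available() -> bool:
    global _R_OK
    try:
        return _R_OK
    except NameError:
        pass
    _R_OK = False
    if shutil.which("Rscript"):
        try:
            proc = subprocess.run(
                ["Rscript", "-e", "invisible(loadNamespace('lme4'))"],
                capture_output=True,
                timeout=120,
            )
            _R_OK = proc.returncode == 0
        except Exception:
            _R_OK = False
    return _R_OK


def _parse_random_spec(random_spec: str) -> list[tuple[list[str], str]]:
    """``"(1 | g) + (1 + x | h)"`` -> [(["1"], "g"), (["1", "x"], "h")]."""
    parsed = []
    for terms, group in re.findall(r"\(([^|]+)\|([^)]+)\)", random_spec):
        names = [t.strip() for t in terms.split("+")]
        parsed.append((names, group.strip()))
    if not parsed:
        raise ValueError(f"cannot parse random spec {random_spec!r}")
    return parsed


def _fit_lme4(
    table: pd.DataFrame, formula: str, nagq: int
) -> dict:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        csv_path = tmp / "table.csv"
        out_path = tmp / "fit.json"
        script = tmp / "fit.R"
        table.to_csv(csv_path, index=False)
        script.write_text(_R_FIT_TEMPLATE, encoding="utf-8")
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv_path), formula,
             str(nagq), str(out_path)],
            capture_output=True,
            text=True,
            timeout=900,
        )
        if proc.returncode != 0 or not out_path.exists():
            return {"ok": False, "message": proc.stderr.strip()[-500:]}
        return json.loads(out_path.read_text())


def _linear_predictor_variances(
    table: pd.DataFrame,
    beta: dict[str, float],
    random_terms: list[RandomTerm],
) -> tuple[float, float]:
    """Population variances of the fixed and random parts of eta."""
    eta = np.zeros(len(table))
    for name, b in beta.items():
        if name == "(Intercept)":
            continue
        eta = eta + b * table[name].to_numpy(dtype=float)
    var_fixed = float(np.var(eta))

    var_random = 0.0
    for rt in random_terms:
        z_cols = []
        for v in rt.variables:
            if v == "(Intercept)":
                z_cols.append(np.ones(len(table)))
            else:
                z_cols.append(table[v].to_numpy(dtype=float))
        Z = np.column_stack(z_cols)
        var_random += float(np.mean(np.einsum("ij,jk,ik->i", Z, rt.cov, Z)))
    return var_fixed, var_random


def nakagawa_r2(
    result: RegressionResult, table: pd.DataFrame
) -> tuple[float, float]:
    """Marginal and conditional r-squared of a logistic mixed model.

    marginal = var_f / (var_f + var_r + pi^2/3);
    conditional = (var_f + var_r) / (same denominator).
    """
    if not result.converged:
        raise UndefinedResultError("r-squared undefined for a non-converged fit")
    var_f, var_r = _linear_predictor_variances(table, result.beta, result.random_terms)
    denom = var_f + var_r + LOGIT_VARIANCE
    return var_f / denom, (var_f + var_r) / denom


def _fit_fixed_fallback(
    table: pd.DataFrame, fixed_terms: list[str], random_spec: str, formula: str
) -> RegressionResult:
    """Fixed-effects logistic approximation: corpus and word indicators.

    Used only when no GLMM estimator is available; flagged in the result's
    ``engine`` field.
    """
    import statsmodels.api as sm

    groups = [g for _, g in _parse_random_spec(random_spec) if g in table.columns]
    X_parts = [pd.Series(1.0, index=table.index, name="(Intercept)")]
    X_parts += [table[t].astype(float) for t in fixed_terms]
    dummy_cols: list[str] = []
    for g in groups:
        d = pd.get_dummies(table[g], prefix=g, drop_first=True, dtype=float)
        dummy_cols.extend(d.columns)
        X_parts.append(d)
    X = pd.concat(X_parts, axis=1)
    y = table["hit"].astype(float)
    res = RegressionResult(
        formula=formula, terms=["(Intercept)", *fixed_terms], engine="fixed_fallback",
        n_obs=len(table),
    )
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - depends on data pathology
        res.message = str(exc)
        return res
    res.converged = bool(getattr(fit, "converged", True))
    for t in res.terms:
        res.beta[t] = float(fit.params[t])
        res.se[t] = float(fit.bse[t])
        res.z[t] = float(fit.tvalues[t])
    res.aic = float(fit.aic)
    if res.converged:
        eta_fix = sum(
            res.beta[t] * table[t].to_numpy(dtype=float) for t in fixed_terms
        ) if fixed_terms else np.zeros(len(table))
        lin = np.asarray(X @ fit.params, dtype=float)
        var_f = float(np.var(np.asarray(eta_fix)))
        var_g = float(np.var(lin - np.asarray(eta_fix) - res.beta["(Intercept)"]))
        denom = var_f + var_g + LOGIT_VARIANCE
        res.marginal_r2 = var_f / denom
        res.conditional_r2 = (var_f + var_g) / denom
    return res


def fit_logistic_mixed(
    table: pd.DataFrame,
    fixed_terms: list[str],
    random_spec: str = DEFAULT_RANDOM_SPEC,
    engine: str = "auto",
    nagq: int = 0,
) -> RegressionResult:
    """Fit hit ~ fixed_terms + random_spec with a binomial logit link.

    ``engine`` is ``"auto"`` (lme4 when available, else the fixed-effects
    fallback), ``"lme4"`` or ``"fixed"``. ``nagq=0`` uses lme4's fast
    deviance approximation; ``nagq=1`` the Laplace approximation.
    Convergence failures are reported in the result, never raised.
    """
    fixed_part = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"hit ~ {fixed_part} + {random_spec}"

    if table["hit"].nunique() < 2:
        return RegressionResult(
            formula=formula,
            terms=["(Intercept)", *fixed_terms],
            converged=False,
            n_obs=len(table),
            message="degenerate response: all outcomes identical (complete separation)",
        )

    if engine == "auto":
        engine = "lme4" if _r_available() else "fixed"
    if engine == "fixed":
        return _fit_fixed_fallback(table, fixed_terms, random_spec, formula)
    if engine != "lme4":
        raise ValueError(f"unknown engine {engine!r}")

    groups = {g for _, g in _parse_random_spec(random_spec)}
    needed = ["hit", *fixed_terms, *sorted(groups)]
    extra = [
        v
        for terms, _ in _parse_random_spec(random_spec)
        for v in terms
        if v != "1" and v not in needed
    ]
    data = table[needed + extra].copy()

    raw = _fit_lme4(data, formula, nagq)
    res = RegressionResult(
        formula=formula, terms=["(Intercept)", *fixed_terms], engine="lme4",
    )
    if not raw.get("ok"):
        res.message = str(raw.get("message", "lme4 fit failed"))
        return res
    names = list(raw["fixef_names"])
    res.beta = {n: float(b) for n, b in zip(names, raw["fixef"])}
    res.se = {n: float(s) for n, s in zip(names, raw["se"])}
    res.z = {n: res.beta[n] / res.se[n] if res.se[n] else float("nan") for n in names}
    res.aic = float(raw["aic"])
    res.n_obs = int(raw["n_obs"])
    res.singular = bool(raw["singular"])
    res.converged = bool(raw["converged"])
    res.message = str(raw.get("messages", ""))
    for vc in raw.get("varcorr", []):
        cov = np.atleast_2d(np.asarray(vc["cov"], dtype=float))
        vars_raw = vc.get("vars") or ["(Intercept)"]
        variables = [vars_raw] if isinstance(vars_raw, str) else list(vars_raw)
        res.random_terms.append(RandomTerm(str(vc["group"]), variables, cov))
    if res.converged:
        res.marginal_r2, res.conditional_r2 = nakagawa_r2(res, table)
    return res


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    baseline: RegressionResult
    single: list[RegressionResult]  # one candidate each, ranked by AIC
    path: list[RegressionResult]  # accepted steps of the forward search
    final: RegressionResult


def forward_select(
    table: pd.DataFrame,
    candidate_terms: list[str],
    baseline_terms: tuple[str, ...] = ("time",),
    random_spec: str = DEFAULT_RANDOM_SPEC,
    engine: str = "auto",
    nagq: int = 0,
) -> SelectionReport:
    """AIC forward selection over the baseline model.

    Emits the single-predictor fits (each candidate alone over the
    baseline, ranked by AIC) and then adds candidates one by one, each
    step taking the largest AIC reduction, stopping when no candidate
    improves the AIC or the augmented model fails to converge. A failed
    candidate fit is recorded and skipped, never fatal.
    """
    overlap = set(candidate_terms) & set(baseline_terms)
    if overlap:
        raise ValueError(f"candidates overlap baseline terms: {sorted(overlap)}")

    def fit(terms: list[str]) -> RegressionResult:
        return fit_logistic_mixed(table, terms, random_spec, engine, nagq)

    baseline = fit(list(baseline_terms))
    single = sorted(
        (fit([*baseline_terms, c]) for c in candidate_terms),
        key=lambda r: r.aic if np.isfinite(r.aic) else np.inf,
    )

    current = baseline
    current_terms = list(baseline_terms)
    remaining = list(candidate_terms)
    path: list[RegressionResult] = []
    while remaining:
        trials = [(c, fit([*current_terms, c])) for c in remaining]
        usable = [
            (c, r)
            for c, r in trials
            if r.converged and np.isfinite(r.aic) and r.aic < current.aic
        ]
        if not usable:
            break
        best_c, best_r = min(usable, key=lambda cr: cr[1].aic)
        current = best_r
        current_terms.append(best_c)
        remaining.remove(best_c)
        path.append(best_r)
    return SelectionReport(baseline=baseline, single=single, path=path, final=current)


# ---------------------------------------------------------------------------
# error analysis
# ---------------------------------------------------------------------------


@dataclass
class ErrorAnalysis:
    observed: pd.DataFrame  # correct tag (rows) x predicted tag (cols)
    expected: pd.DataFrame
    residuals: pd.DataFrame  # standardized Pearson residuals
    flags: pd.DataFrame  # "+", "-", or "" per cell at |r| > 1.96


def error_analysis(
    outcomes: pd.DataFrame, categories: list[str] | None = None
) -> ErrorAnalysis:
    """Correct-vs-predicted contingency analysis of categorization outcomes.

    ``outcomes`` needs columns coarse_tag (correct) and predicted_coarse.
    Expected counts assume independence (row total x column total / N);
    standardized Pearson residuals are (O - E) / sqrt(E (1 - r/N) (1 - c/N)).
    """
    if len(outcomes) == 0:
        raise ValueError("empty outcome set")
    cats = categories if categories is not None else _COARSE_ORDER
    obs = pd.crosstab(outcomes["coarse_tag"], outcomes["predicted_coarse"])
    obs = obs.reindex(index=cats, columns=cats, fill_value=0).astype(float)
    O = obs.to_numpy()
    n = O.sum()
    r = O.sum(axis=1, keepdims=True)
    c = O.sum(axis=0, keepdims=True)
    E = r @ c / n
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(E * (1 - r / n) * (1 - c / n))
        R = np.where(denom > 0, (O - E) / denom, 0.0)
    flags = np.where(R > 1.96, "+", np.where(R < -1.96, "-", ""))
    idx = pd.Index(cats, name="correct")
    cols = pd.Index(cats, name="predicted")
    return ErrorAnalysis(
        observed=pd.DataFrame(O, index=idx, columns=cols),
        expected=pd.DataFrame(E, index=idx, columns=cols),
        residuals=pd.DataFrame(R, index=idx, columns=cols),
        flags=pd.DataFrame(flags, index=idx, columns=cols),
    )


def plot_mosaic(err: ErrorAnalysis, path: str | Path) -> None:
    """Minimal mosaic rendering of the error analysis (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    O = err.observed.to_numpy()
    n = O.sum()
    widths = O.sum(axis=1) / n
    fig, ax = plt.subplots(figsize=(6, 6))
    x = 0.0
    for i, cat in enumerate(err.observed.index):
        col_total = O[i].sum()
        y = 0.0
        for j, pred in enumerate(err.observed.columns):
            h = O[i, j] / col_total if col_total else 0.0
            res = err.residuals.iloc[i, j]
            color = (
                "#2166ac" if res > 1.96 else "#b2182b" if res < -1.96 else "#ffffff"
            )
            ax.add_patch(
                plt.Rectangle((x, y), widths[i], h, facecolor=color,
                              edgecolor="black", linewidth=0.5)
            )
            y += h
        ax.text(x + widths[i] / 2, 1.02, cat, ha="center", fontsize=8)
        x += widths[i]
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.08)
    ax.set_xlabel("correct category (width = frequency)")
    ax.set_ylabel("predicted category share")
    ax.set_xticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
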