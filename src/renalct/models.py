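"""Per-phase logistic prediction models for ccRCC vs fat-poor AML.

Two routes are provided:

* :func:`published_model` loads the published fixed-coefficient model for a
  scan phase (intercept + named coefficients over demographics, morphology
  flags and quantitative ROI parameters) from a versioned JSON resource, for
  scoring new lesions exactly as printed;
* :func:`fit_logistic` / :func:`screen_variables` refit models by maximum
  likelihood on a lesion table, with backward stepwise elimination by
  likelihood-ratio test.

Coding convention throughout: male = 1, morphology feature present = 1, and
ccRCC is the positive class (coded 1). Classification uses a probability
threshold of 0.5 unless configured otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import expit

from .stats import ROCResult, roc_auc

__all__ = [
    "LogisticModel",
    "ModelPerformance",
    "FitResult",
    "SeparationError",
    "published_model",
    "predict_probability",
    "predict_table",
    "evaluate_model",
    "fit_logistic",
    "screen_variables",
]

PHASES = ("PCP", "CMP", "NP", "EP")


class SeparationError(RuntimeError):
    """Raised when the likelihood is unbounded (perfect separation)."""


@dataclass
class LogisticModel:
    """A logistic classifier: intercept + named coefficients + coding map."""

    phase: str
    intercept: float
    coefficients: dict[str, float]
    coding: dict[str, dict] = field(default_factory=dict)
    threshold: float = 0.5
    positive_class: str = "ccRCC"
    printed_odds_ratios: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")

    @property
    def variables(self) -> list[str]:
        return list(self.coefficients)

    def odds_ratios(self) -> dict[str, float]:
        """exp(coefficient) per variable."""
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}


@dataclass
class ModelPerformance:
    """Confusion counts and the rates derived from them.

    Every rate is exactly the ratio of its integer counts (positive class:
    ccRCC), so printed ratios like 69/74 reproduce without rounding drift.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    roc: ROCResult | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def summary(self) -> dict[str, float]:
        out = {"sensitivity": self.sensitivity, "specificity": self.specificity,
               "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
               "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}
        if self.roc is not None:
            out.update({"auc": self.roc.auc, "auc_ci_lower": self.roc.ci_lower,
                        "auc_ci_upper": self.roc.ci_upper})
        return out


def _load_published() -> dict:
    path = resources.files("renalct").joinpath("data/published_models.json")
    return json.loads(path.read_text())


def published_model(phase: str) -> LogisticModel:
    """The published fixed-coefficient model for one scan phase.

    Raises
    ------
    ValueError
        For a phase outside {PCP, CMP, NP, EP}.
    """
    spec = _load_published()
    if phase not in spec["models"]:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    m = spec["models"][phase]
    return LogisticModel(
        phase=phase,
        intercept=float(m["intercept"]),
        coefficients={k: float(v) for k, v in m["coefficients"].items()},
        coding=spec["coding"],
        threshold=float(spec["threshold"]),
        positive_class=spec["positive_class"],
        printed_odds_ratios={k: float(v)
                             for k, v in m["printed_odds_ratios"].items()},
    )


def _encode(model: LogisticModel, name: str, value):
    """Map a raw table value through the model's coding to a number."""
    if isinstance(value, str):
        coding = model.coding.get(name)
        if coding is None or value not in coding:
            raise KeyError(f"no coding for level {value!r} of {name!r}")
        return float(coding[value])
    return float(value)


def predict_probability(model: LogisticModel, row) -> float:
    """Probability of the positive class (ccRCC) for one lesion row.

    ``row`` is a mapping (or pandas Series) from variable names to values;
    string-valued categoricals are passed through the coding map.

    Raises
    ------
    KeyError
        If a model variable is missing from the row.
    """
    lp = model.intercept
    for name, coef in model.coefficients.items():
        if name not in row or pd.isna(row[name]):
            raise KeyError(f"model variable {name!r} missing from lesion row")
        lp += coef * _encode(model, name, row[name])
    return float(expit(lp))


def predict_table(model: LogisticModel, table: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`predict_probability` over a lesion table."""
    return np.array([predict_probability(model, row)
                     for _, row in table.iterrows()])


def evaluate_model(model: LogisticModel, table: pd.DataFrame,
                   label_col: str = "label") -> ModelPerformance:
    """Classify a lesion table at the model threshold and tabulate performance.

    Raises
    ------
    ValueError
        On an empty table.
    """
    if len(table) == 0:
        raise ValueError("empty lesion table")
    probs = predict_table(model, table)
    truth = (table[label_col] == model.positive_class).to_numpy()
    pred = probs >= model.threshold
    perf = ModelPerformance(
        tp=int(np.sum(pred & truth)), fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)), fp=int(np.sum(pred & ~truth)),
        roc=roc_auc(probs, table[label_col].to_numpy(),
                    positive_class=model.positive_class))
    return perf


@dataclass
class FitResult:
    """A maximum-likelihood logistic fit with Wald inference per coefficient."""

    model: LogisticModel
    coef_table: pd.DataFrame  # coef, odds_ratio, or_ci_lower, or_ci_upper, p
    llf: float
    n: int
    converged: bool


def _design(table: pd.DataFrame, variables: list[str],
            coding: dict) -> np.ndarray:
    cols = []
    for v in variables:
        col = table[v]
        if col.dtype == object:
            cmap = coding.get(v)
            if cmap is None:
                raise ValueError(f"no coding for categorical variable {v!r}")
            col = col.map(cmap)
            if col.isna().any():
                raise ValueError(f"unmapped level in variable {v!r}")
        cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


DEFAULT_CODING = {
    "gender": {"male": 1, "female": 0},
    "location": {"left": 1, "right": 0},
    "growth_pattern": {"endophytic": 1, "exophytic": 0},
    "pseudocapsule": {"present": 1, "absent": 0},
    "cystic": {"present": 1, "absent": 0},
    "angular": {"present": 1, "absent": 0},
}


def fit_logistic(table: pd.DataFrame, variables: list[str],
                 label_col: str = "label", positive_class: str = "ccRCC",
                 phase: str = "", coding: dict | None = None) -> FitResult:
    """Maximum-likelihood logistic regression of class on ``variables``.

    Reports coefficients, odds ratios with Wald 95% CIs and p-values.

    Raises
    ------
    SeparationError
        On (quasi-)complete separation, where the MLE does not exist.
    """
    coding = DEFAULT_CODING if coding is None else coding
    y = (table[label_col] == positive_class).to_numpy(dtype=float)
    X = sm.add_constant(_design(table, variables, coding), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error",
                              sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore",
                              sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError) as err:
            raise SeparationError(
                "complete separation: logistic MLE does not exist "
                f"for variables {variables}") from err
    params = res.params
    bse = res.bse
    if np.any(np.abs(params[1:]) > 50) or np.any(bse > 500):
        raise SeparationError("separation suspected: unbounded coefficients")
    z = 1.959963984540054
    rows = []
    for i, v in enumerate(variables, start=1):
        rows.append({
            "variable": v, "coef": params[i],
            "odds_ratio": np.exp(params[i]),
            "or_ci_lower": np.exp(params[i] - z * bse[i]),
            "or_ci_upper": np.exp(params[i] + z * bse[i]),
            "p": res.pvalues[i]})
    model = LogisticModel(
        phase=phase, intercept=float(params[0]),
        coefficients={v: float(params[i])
                      for i, v in enumerate(variables, start=1)},
        coding=coding, positive_class=positive_class)
    return FitResult(model=model, coef_table=pd.DataFrame(rows),
                     llf=float(res.llf), n=len(table),
                     converged=bool(res.mle_retvals["converged"]))


def _lr_pvalue(full: FitResult, reduced: FitResult) -> float:
    lr = 2.0 * (full.llf - reduced.llf)
    return float(sps.chi2.sf(max(lr, 0.0), df=1))


def screen_variables(table: pd.DataFrame, candidate_vars: list[str],
                     phase: str = "", alpha: float = 0.05,
                     label_col: str = "label", positive_class: str = "ccRCC",
                     univariate_filter: bool = True,
                     coding: dict | None = None
                     ) -> tuple[list[str], FitResult | None]:
    """Backward stepwise variable screening by likelihood-ratio test.

    Candidates are first reduced to those univariately significant at
    ``alpha`` (likelihood-ratio test of the single-variable model against
    the intercept-only model), mirroring an entry pool of variables that
    differ significantly between the groups. Backward elimination then
    repeatedly drops the variable whose removal is least harmful (largest
    LR p-value) until every remaining variable is significant at ``alpha``.

    Returns the retained variables and the final fit (``None`` if nothing
    survives).
    """
    pool = list(candidate_vars)
    y = (table[label_col] == positive_class).to_numpy(dtype=float)
    null_llf = float(sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf)
    uni_p: dict[str, float] = {}
    for v in pool:
        try:
            f = fit_logistic(table, [v], label_col=label_col,
                             positive_class=positive_class, coding=coding)
            uni_p[v] = float(sps.chi2.sf(2.0 * (f.llf - null_llf), df=1))
        except SeparationError:
            uni_p[v] = 0.0  # a separating variable is maximally predictive
    if univariate_filter:
        pool = [v for v in pool if uni_p[v] < alpha]
    if not pool:
        return [], None
    # strongest-first; if the full pool (quasi-)separates at this sample
    # size, shed the weakest candidates until the MLE exists
    current = sorted(pool, key=lambda v: uni_p[v])
    fit_full = None
    while current:
        try:
            fit_full = fit_logistic(table, current, label_col=label_col,
                                    positive_class=positive_class,
                                    phase=phase, coding=coding)
            break
        except SeparationError:
            current = current[:-1]
    if fit_full is None:
        return [], None
    while len(current) > 1:
        drops = []
        for v in current:
            reduced_vars = [w for w in current if w != v]
            fit_red = fit_logistic(table, reduced_vars, label_col=label_col,
                                   positive_class=positive_class, phase=phase,
                                   coding=coding)
            drops.append((v, _lr_pvalue(fit_full, fit_red), fit_red))
        v, p, fit_red = max(drops, key=lambda t: t[1])
        if p >= alpha:
            current = [w for w in current if w != v]
            fit_full = fit_red
        else:
            break
    if len(current) == 1:
        y = (table[label_col] == positive_class).to_numpy(dtype=float)
        null_llf = float(sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf)
        if sps.chi2.sf(2.0 * (fit_full.llf - null_llf), df=1) >= alpha:
            return [], None
    return current, fit_full
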