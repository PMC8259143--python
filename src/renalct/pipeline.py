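"""End-to-end analysis steps over a lesion table or phantom cohort.

Each function here is one reproducible analysis step: phantom cohorts are
measured with the ROI protocol, lesion tables are compared group-wise with
the dispatched test suite, quantitative discriminators are ranked by ROC
AUC, and the per-phase logistic models are scored (published coefficients)
or refit. The CLI subcommands and the numbered analysis drivers are thin
wrappers around these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics, models, phantom, roi, stats

__all__ = [
    "measure_phantom_cohort",
    "demographic_comparison",
    "quantitative_comparison",
    "roc_table",
    "published_model_performance",
    "refit_published_structure",
    "screened_models",
]

DEMOGRAPHIC_VARS = ("age", "size_cm", "gender", "location", "growth_pattern",
                    "pseudocapsule", "cystic", "angular")
QUANT_VARS = tuple(k for k in phantom.PUBLISHED_QUANT if k not in
                   ("age", "size_cm"))

#: Variable structure of the published per-phase models.
PUBLISHED_STRUCTURE = {
    "PCP": ["gender", "pseudocapsule", "angular", "AVT_PCP_1"],
    "CMP": ["gender", "cystic", "RER_CMP_2", "SHR_CMP"],
    "NP": ["gender", "pseudocapsule", "RER_NP_2", "HDT_NP"],
    "EP": ["gender", "angular", "RER_EP_2", "SHR_EP"],
}


def measure_phantom_cohort(n_ccrcc: int, n_aml: int, seed: int = 0,
                           protocol: roi.ProtocolConfig | None = None,
                           heterogeneity: bool = True,
                           logger=None) -> pd.DataFrame:
    """Simulate a phantom cohort, run the ROI protocol, derive all metrics.

    Returns the assembled quantitative lesion table (one row per lesion)
    with class labels, produced entirely by the voxel pipeline.
    """
    ss = np.random.SeedSequence([seed, 7])
    records = []
    n_regions = []
    for lesion_id, label, spec, volume in phantom.generate_lesions(
            n_ccrcc, n_aml, seed=seed, heterogeneity=heterogeneity):
        cfg = protocol or roi.ProtocolConfig()
        cfg = roi.ProtocolConfig(**{**cfg.__dict__,
                                    "seed": int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))})
        result = roi.measure_lesion_protocol(volume, cfg, lesion_id=lesion_id,
                                             label=label)
        records.append(result.record)
        n_regions.append(result.n_regions)
        if logger is not None:
            logger.info("lesion %s (%s): %d enhancing regions, ROI3 r=%.1f mm",
                        lesion_id, label, result.n_regions,
                        result.geometries["roi3"].radius_mm)
    table = metrics.assemble_quant_table(records, ndigits=None)
    table["n_enhancing_regions"] = n_regions
    return table


def _result_row(res: stats.ComparisonResult) -> dict:
    row = {"variable": res.variable, "test": res.test,
           "statistic": res.statistic, "df": res.df, "p": res.p_value}
    for grp, summ in res.group_summaries.items():
        if isinstance(summ, dict) and "mean" in summ:
            row[f"{grp}_mean"] = summ["mean"]
            row[f"{grp}_sd"] = summ["sd"]
    return row


def demographic_comparison(table: pd.DataFrame, alpha: float = 0.05,
                           logger=None) -> pd.DataFrame:
    """Compare demographics and morphology flags between the two classes."""
    rows = []
    for var in DEMOGRAPHIC_VARS:
        if var not in table.columns:
            continue
        res = stats.compare_groups(table, var, alpha=alpha)
        if logger is not None:
            logger.info("dispatch %s -> %s", var, res.test)
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def quantitative_comparison(table: pd.DataFrame, alpha: float = 0.05,
                            logger=None) -> pd.DataFrame:
    """Compare every quantitative ROI parameter between the two classes.

    Normality in each class picks pooled-t vs Mann–Whitney per variable;
    the dispatch decision is recorded in the ``test`` column.
    """
    rows = []
    for var in QUANT_VARS:
        if var not in table.columns:
            continue
        res = stats.compare_groups(table, var, alpha=alpha)
        if logger is not None:
            logger.info("dispatch %s -> %s", var, res.test)
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def roc_table(table: pd.DataFrame, comparison: pd.DataFrame | None = None,
              alpha: float = 0.05) -> pd.DataFrame:
    """ROC AUC with 95% CI for the significant quantitative parameters."""
    comparison = (quantitative_comparison(table, alpha=alpha)
                  if comparison is None else comparison)
    keep = comparison.loc[comparison["p"] < alpha, "variable"]
    rows = []
    for var in keep:
        r = stats.roc_auc(table[var].to_numpy(dtype=float),
                          table["label"].to_numpy())
        rows.append({"variable": var, "auc": r.auc, "ci_lower": r.ci_lower,
                     "ci_upper": r.ci_upper, "direction": r.direction})
    cols = ["variable", "auc", "ci_lower", "ci_upper", "direction"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols).sort_values(
        "auc", ascending=False, ignore_index=True)


def published_model_performance(table: pd.DataFrame) -> pd.DataFrame:
    """Score every published per-phase model on a lesion table."""
    rows = []
    for phase in models.PHASES:
        model = models.published_model(phase)
        perf = models.evaluate_model(model, table)
        rows.append({"model": f"Model_{phase}", **perf.summary()})
    return pd.DataFrame(rows)


def refit_published_structure(table: pd.DataFrame, phase: str
                              ) -> tuple[models.FitResult, float]:
    """Refit the published variable structure for one phase; return fit + AUC."""
    fit = models.fit_logistic(table, PUBLISHED_STRUCTURE[phase], phase=phase)
    probs = models.predict_table(fit.model, table)
    auc = stats.roc_auc(probs, table["label"].to_numpy()).auc
    return fit, auc


def screened_models(table: pd.DataFrame, alpha: float = 0.05,
                    logger=None) -> dict[str, dict]:
    """Per-phase variable screening + refit, mirroring the modeling protocol.

    Candidates per phase are demographics, morphology flags and that phase's
    quantitative parameters, restricted to those univariately significant at
    ``alpha``; backward stepwise elimination (likelihood-ratio) returns the
    retained variables and fit.
    """
    base = [v for v in DEMOGRAPHIC_VARS if v in table.columns]
    out = {}
    for phase in models.PHASES:
        quant = [v for v in QUANT_VARS
                 if v in table.columns and f"_{phase}" in v]
        selected, fit = models.screen_variables(
            table, base + quant, phase=phase, alpha=alpha)
        entry = {"selected": selected, "fit": fit}
        if fit is not None:
            probs = models.predict_table(fit.model, table)
            entry["auc"] = stats.roc_auc(probs, table["label"].to_numpy()).auc
        if logger is not None:
            logger.info("phase %s screened -> %s", phase, selected)
        out[phase] = entry
    return out
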