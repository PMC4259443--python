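"""Survival association: Kaplan-Meier / log-rank by cluster, per-gene Cox screen.

Clinical tables carry one row per sample with overall-survival time (days)
and an event indicator. Cluster comparisons use the k-group log-rank test;
the per-gene screen fits a univariate Cox proportional-hazards model with
the (variance-stabilized) expression as a continuous covariate, Wald p per
gene, and BH adjustment across the screened list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .normalization_de import bh_adjust

logger = logging.getLogger(__name__)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the os_time / os_event schema (one row per sample index)."""
    for col in ("os_time", "os_event"):
        if col not in clinical.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    if (clinical["os_time"] <= 0).any():
        raise ValueError("os_time must be positive")
    if clinical.index.duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    return clinical


@dataclass
class KMResult:
    """Per-group survival curves plus the k-group log-rank test."""

    curves: dict  # group label -> DataFrame(time, survival)
    statistic: float
    p_value: float


def km_logrank(groups: pd.Series, clinical: pd.DataFrame) -> KMResult:
    """Product-limit curves per group and the k-group log-rank test."""
    clinical = validate_clinical(clinical)
    groups = groups.reindex(clinical.index).dropna()
    clinical = clinical.loc[groups.index]
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    if clinical["os_event"].sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    curves = {}
    for lab, idx in groups.groupby(groups).groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.loc[idx, "os_time"], clinical.loc[idx, "os_event"])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(
        clinical["os_time"], groups, clinical["os_event"]
    )
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


def cox_screen(
    expr: pd.DataFrame, clinical: pd.DataFrame, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Univariate Cox PH fit per gene (continuous covariate, Breslow ties).

    Returns gene_id-indexed coef (log hazard per expression unit), p (Wald),
    fdr (BH over the screened list) and a significant flag (fdr < fdr_max).
    Constant covariates get coef 0 / p 1; non-convergent fits p 1 (flagged).
    """
    clinical = validate_clinical(clinical)
    samples = expr.columns.intersection(clinical.index)
    if len(samples) < 10:
        raise ValueError("too few samples shared between expression and clinical")
    surv = clinical.loc[samples, ["os_time", "os_event"]]
    rows = []
    for gene in expr.index:
        x = expr.loc[gene, samples].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append((gene, 0.0, 1.0, True))
            continue
        df = surv.copy()
        df["x"] = x
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="os_time", event_col="os_event")
            rows.append(
                (gene, float(cph.params_["x"]), float(cph.summary.loc["x", "p"]), False)
            )
        except (ConvergenceError, ValueError):
            logger.warning("Cox fit failed for gene %s; p set to 1", gene)
            rows.append((gene, np.nan, 1.0, True))
    out = pd.DataFrame(rows, columns=["gene_id", "coef", "p_value", "flagged"]).set_index("gene_id")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < fdr_max
    return out


def dichotomize(expr_row: pd.Series, rule: str = "median") -> pd.Series:
    """Split samples into high/low at the median (ties go to 'low')."""
    if rule != "median":
        raise ValueError(f"unknown rule {rule!r}")
    med = expr_row.median()
    out = pd.Series(np.where(expr_row > med, "high", "low"), index=expr_row.index)
    if (out == "low").all():
        logger.warning("degenerate dichotomization: all samples below or at the median")
    return out
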