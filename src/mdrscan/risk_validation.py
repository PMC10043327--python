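"""Patient-level validation of a selected MDR model.

A selected model's cell labels induce a HIGH/LOW risk group for every
patient; the association of that grouping with 5-year recurrence is then
verified by multivariable logistic regression (adjusting for stage,
location, chemo- and radiotherapy) and summarized with Kaplan-Meier
curves and a two-group log-rank test on the long-term follow-up data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .genotype_io import GenotypeMatrix
from .gmdr_core import EMPTY, HIGH, DEFAULT_COVARIATES, MdrModel, build_design, _cell_index_single

log = logging.getLogger(__name__)


@dataclass
class RiskAssignment:
    """Per-sample HIGH/LOW risk group induced by a model's cell labels."""

    combo: tuple[str, ...]
    groups: pd.Series  # index sample_id, values "HIGH"/"LOW"
    empty_cell: pd.Series  # True where the sample's cell was EMPTY in training


@dataclass
class RegressionResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    params: pd.Series

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI does not bracket the OR point estimate")


@dataclass
class SurvivalSummary:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival, n_risk
    chi2: float
    p_value: float


def assign_risk(model: MdrModel, matrix: GenotypeMatrix) -> RiskAssignment:
    """Map each sample through its genotype cell to HIGH or LOW.

    Samples falling in EMPTY cells are assigned LOW and flagged.
    """
    cell_idx = _cell_index_single(matrix, model.combo)
    labels = model.cell_labels[cell_idx]
    is_empty = labels == EMPTY
    if is_empty.any():
        log.warning("%d samples fall in EMPTY cells; assigned LOW", int(is_empty.sum()))
    groups = pd.Series(
        np.where(labels == HIGH, "HIGH", "LOW"), index=pd.Index(matrix.samples, name="sample_id")
    )
    return RiskAssignment(
        combo=model.combo,
        groups=groups,
        empty_cell=pd.Series(is_empty, index=groups.index),
    )


def fit_adjusted_logistic(
    assignment: RiskAssignment,
    samples: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> RegressionResult:
    """status5y ~ risk(HIGH=1) + covariates, ML logistic fit, Wald inference.

    OR = exp(risk coefficient) with a symmetric-on-log-scale 95% Wald CI.
    """
    df = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    df = df.loc[df["status5y"].notna()]
    risk = (assignment.groups.reindex(df.index) == "HIGH").astype(float)
    if risk.isna().any():
        raise ValueError("risk assignment missing for some samples")
    n_high, n_low = int(risk.sum()), int((1 - risk).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("one risk group is empty: regression undefined")
    X = build_design(df.reset_index(), covariates)
    X.insert(1, "risk_high", risk.to_numpy())
    y = df["status5y"].to_numpy(float)
    model = sm.Logit(y, X.set_index(df.index))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 30:
        margins = pd.crosstab(risk, y)
        raise ValueError(f"separation in adjusted logistic fit; margins:\n{margins}")
    beta = res.params["risk_high"]
    se = res.bse["risk_high"]
    return RegressionResult(
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(res.pvalues["risk_high"]),
        params=res.params,
    )


def km_logrank(assignment: RiskAssignment, samples: pd.DataFrame) -> SurvivalSummary:
    """Kaplan-Meier curves per risk group and the two-group log-rank test.

    Samples censored before or at 5 years (status5y missing) are included
    here even though they are excluded from the MDR search.
    """
    df = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    if "time" not in df.columns or "event" not in df.columns:
        raise ValueError("sample table lacks time/event columns")
    groups = assignment.groups.reindex(df.index)
    curves: dict[str, pd.DataFrame] = {}
    for g in ("HIGH", "LOW"):
        sub = df[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=g)
        if sub["event"].sum() == 0:
            log.warning("risk group %s has no events", g)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        at_risk = [int((sub["time"] >= t).sum()) for t in sf["time"]]
        sf["n_risk"] = at_risk
        curves[g] = sf
    mask_h = (groups == "HIGH").to_numpy()
    lr = logrank_test(
        df["time"][mask_h], df["time"][~mask_h],
        event_observed_A=df["event"][mask_h], event_observed_B=df["event"][~mask_h],
    )
    return SurvivalSummary(curves=curves, chi2=float(lr.test_statistic), p_value=float(lr.p_value))
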