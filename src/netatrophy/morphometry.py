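"""Group-difference thinning maps and normative W-score deviation maps.

Sign convention, stated in every output: positive t / z / W means cortical
THINNING in patients relative to the control-derived expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import CohortData, ParcellationScheme

__all__ = ["GroupDifferenceMap", "WScoreMatrix", "group_difference", "t_to_z", "fit_wscores"]


@dataclass
class GroupDifferenceMap:
    """Per-region case-control contrast (positive = thinning in patients)."""

    frame: ParcellationScheme
    t: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    df: int
    bonferroni_alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "z": self.z, "p": self.p, "significant": self.significant},
            index=self.frame.names,
        )


@dataclass
class WScoreMatrix:
    """Patient x region standardized deviations from the control normative model.

    ``w[p, j] = (predicted - observed) / scale_j`` with the model fit on
    controls only; scale is the df-corrected residual SD of the control fit.
    """

    frame: ParcellationScheme
    w: np.ndarray
    coefficients: np.ndarray      # regions x (1 + covariates)
    residual_scale: np.ndarray    # mm, per region
    covariate_names: tuple[str, ...]


def _design(subjects: pd.DataFrame, columns) -> np.ndarray:
    x = np.column_stack([np.ones(len(subjects))]
                        + [subjects[c].to_numpy(dtype=float) for c in columns])
    return x


def _drop_constant(x: np.ndarray) -> np.ndarray:
    keep = [0] + [j for j in range(1, x.shape[1]) if np.ptp(x[:, j]) > 0]
    return x[:, keep]


def group_difference(cohort: CohortData) -> GroupDifferenceMap:
    """Per-region OLS of thickness on group + sex + age + education + ICV.

    The group indicator is coded so the returned t is positive where
    patients are thinner; p is two-tailed at residual df, significance is
    Bonferroni 0.05 / n_regions, and z is the signed normal quantile of the
    two-tailed p (see :func:`t_to_z`). Constant covariates are dropped from
    the design, so with no informative covariates the statistic reduces to
    the pooled two-sample t.
    """
    is_pat = cohort.is_patient.astype(float)
    if is_pat.sum() < 2 or (1 - is_pat).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    # group coded -1 for patients: positive coefficient = patient thinning
    x = np.column_stack([np.ones(cohort.n_subjects), -is_pat])
    covs = _design(cohort.subjects, CohortData.COVARIATES)[:, 1:]
    x = _drop_constant(np.column_stack([x, covs]))
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("rank-deficient design matrix")
    df = n - p
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ cohort.thickness
    resid = cohort.thickness - x @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    z = t_to_z(t, df)
    alpha = 0.05 / cohort.frame.n_regions
    return GroupDifferenceMap(
        frame=cohort.frame, t=t, z=z, p=pval,
        significant=pval < alpha, df=df, bonferroni_alpha=alpha,
    )


def t_to_z(t, df: int):
    """Map t statistics to z statistics through the two-tailed p-value.

    z = sign(t) * Phi^{-1}(1 - p_two / 2), evaluated in log space
    (``ndtri_exp``) so extreme t never overflows to +-inf; odd in t and
    monotone, with z -> t as df -> infinity.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    log_p_one = stats.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(log_p_one)
    out = np.sign(t) * z
    return out if out.ndim else float(out)


def fit_wscores(cohort: CohortData) -> WScoreMatrix:
    """Normative W-scores: control-fit regression, patient deviations.

    Per region, thickness ~ 1 + sex + age + education + icv is fit on
    CONTROLS ONLY; the residual scale is the df-corrected SD of control
    residuals. Each patient's W is (predicted - observed) / scale, so
    thinner-than-expected gives W > 0.
    """
    is_pat = cohort.is_patient
    controls = cohort.subjects.loc[~is_pat]
    covs = CohortData.COVARIATES
    xc = _design(controls, covs)
    n, p = xc.shape
    if n <= p:
        raise ValueError(f"need more than {p} controls for the normative fit")
    if np.linalg.matrix_rank(xc) < p:
        raise ValueError("rank-deficient normative design")
    yc = cohort.thickness[~is_pat]
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    resid = yc - xc @ beta
    scale = np.sqrt((resid**2).sum(axis=0) / (n - p))
    if np.any(scale <= 0):
        bad = list(cohort.frame.names[scale <= 0])
        raise ValueError(f"zero residual variance in region(s) {bad[:5]}")
    xp = _design(cohort.subjects.loc[is_pat], covs)
    predicted = xp @ beta
    w = (predicted - cohort.thickness[is_pat]) / scale
    return WScoreMatrix(
        frame=cohort.frame, w=w, coefficients=beta.T,
        residual_scale=scale, covariate_names=("intercept",) + covs,
    )


def wscores_for(cohort: CohortData, model: WScoreMatrix, rows: np.ndarray) -> np.ndarray:
    """W-scores for an arbitrary subject subset under a fitted normative model."""
    xs = _design(cohort.subjects.iloc[rows], model.covariate_names[1:])
    predicted = xs @ model.coefficients.T
    return (predicted - cohort.thickness[rows]) / model.residual_scale
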