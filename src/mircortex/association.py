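"""Covariate-adjusted linear-model association of expression with pathology.

For each feature, expression (the response) is regressed on one pathology
outcome — neuritic plaques (NP), neurofibrillary tangles (NFT) or pathologic
AD — plus the demographic/technical covariates age, sex, study, neuronal
proportion (NNLS), PMI and RIN. Effects are summarized as beta, SE(beta),
the standardized statistic z = beta/SE(beta), a two-sided t-test p-value and
the squared partial correlation of the outcome with expression given the
covariates (the "variance explained").

Family-wise control uses a Bonferroni threshold over the features of one
class tested against one outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COVARIATES, ExpressionMatrix


@dataclass
class AssociationResult:
    feature_id: str
    outcome: str
    beta: float
    se: float
    z: float            # standardized statistic beta / SE(beta)
    p: float            # two-sided, t distribution with residual df
    r2: float           # squared partial correlation (variance explained)
    n: int


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha outside (0, 1)")
    return alpha / n_tests


def _design(outcome: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(outcome)), outcome]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    return np.column_stack(cols)


def _ols_multi(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, ...]:
    """Multi-response OLS of each row of Y on X; stats for X's 2nd column.

    Returns (beta, se, t, p, partial_r2, df) as per-feature arrays.
    """
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("not enough complete cases for the model")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular design matrix") from e
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular design matrix")
    B = XtX_inv @ (X.T @ Y.T)                     # k x p
    resid = Y.T - X @ B                           # n x p
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)       # p in (0, 1]
    r2 = t ** 2 / (t ** 2 + df)
    return beta, se, t, p, r2, df


def fit_association(expr, outcome, covariates=None, *,
                    feature_id: str = "feature", outcome_name: str = "outcome",
                    ) -> AssociationResult:
    """OLS of one feature's expression on an outcome plus covariates.

    Missing expression entries are dropped (complete-case). ``covariates``
    may be a DataFrame/2-D array aligned with ``outcome`` or None.
    """
    y = np.asarray(expr, dtype=float)
    x = np.asarray(outcome, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = ~np.isnan(y) & ~np.isnan(x)
    if C is not None:
        keep &= ~np.isnan(C).any(axis=1)
    y, x = y[keep], x[keep]
    if C is not None:
        C = C[keep]
    k = 2 + (0 if C is None else C.shape[1])
    if len(y) < k + 2:
        raise ValueError("too few complete cases")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance expression")
    X = _design(x, C)
    beta, se, t, p, r2, df = _ols_multi(y[None, :], X)
    return AssociationResult(feature_id=feature_id, outcome=outcome_name,
                             beta=float(beta[0]), se=float(se[0]),
                             z=float(t[0]), p=float(p[0]), r2=float(r2[0]),
                             n=int(len(y)))


def _prepare_outcome(cohort: pd.DataFrame, outcome: str,
                     standardize: bool) -> np.ndarray:
    if outcome not in ("np", "nft", "ad"):
        raise ValueError(f"unknown outcome {outcome!r}")
    x = cohort[outcome].to_numpy(float)
    if outcome in ("np", "nft") and standardize:
        x = (x - x.mean()) / x.std()
    return x


def associate_all(matrix: ExpressionMatrix, cohort: pd.DataFrame,
                  outcomes=("np", "nft", "ad"),
                  covariates=COVARIATES, *, standardize: bool = True,
                  alpha: float = 0.05, fixed_threshold: float | None = None,
                  ) -> pd.DataFrame:
    """Associate every feature with every outcome; flag Bonferroni hits.

    Returns a long-format DataFrame (feature, outcome, beta, se, z, p, r2,
    n, significant). The Bonferroni family is the retained features of this
    matrix's class against one outcome; ``fixed_threshold`` substitutes a
    user-chosen per-test threshold (e.g. a published one) for all outcomes.

    NP and NFT are z-scaled by default so coefficients are comparable
    across outcomes; AD stays 0/1.
    """
    if matrix.n_features == 0:
        raise ValueError("empty expression matrix")
    samples = matrix.sample_ids.intersection(cohort.index)
    if len(samples) == 0:
        raise ValueError("no overlapping samples between matrix and cohort")
    vals = matrix.values[samples]
    cohort = cohort.loc[samples]
    C = cohort[list(covariates)].to_numpy(float) if covariates else None

    threshold = (fixed_threshold if fixed_threshold is not None
                 else bonferroni_threshold(matrix.n_features, alpha))
    rows = []
    Y = vals.to_numpy(float)
    has_nan = np.isnan(Y).any()
    for outcome in outcomes:
        x = _prepare_outcome(cohort, outcome, standardize)
        if not has_nan:
            X = _design(x, C)
            beta, se, t, p, r2, df = _ols_multi(Y, X)
            n_used = np.full(len(vals), len(samples))
            for i, fid in enumerate(vals.index):
                rows.append((fid, outcome, beta[i], se[i], t[i], p[i], r2[i],
                             n_used[i]))
        else:
            for fid in vals.index:
                r = fit_association(vals.loc[fid].to_numpy(), x, C,
                                    feature_id=fid, outcome_name=outcome)
                rows.append((fid, outcome, r.beta, r.se, r.z, r.p, r.r2, r.n))
    out = pd.DataFrame(rows, columns=["feature_id", "outcome", "beta", "se",
                                      "z", "p", "r2", "n"])
    out["significant"] = out["p"] < threshold
    out.attrs["bonferroni_threshold"] = threshold
    return out


def covariate_sensitivity(matrix: ExpressionMatrix, cohort: pd.DataFrame,
                          covariates=COVARIATES, outcome: str = "ad",
                          ) -> pd.DataFrame:
    """Leave-one-covariate-out sensitivity of the AD association p-value.

    For each feature: the p-value from the full covariate model, from each
    model dropping one covariate, and from the unadjusted model. Columns:
    ``p_full``, ``p_minus_<cov>`` for each covariate, ``p_none``.
    """
    samples = matrix.sample_ids.intersection(cohort.index)
    vals = matrix.values[samples]
    cohort = cohort.loc[samples]
    x = _prepare_outcome(cohort, outcome, standardize=True)
    Y = vals.to_numpy(float)
    covariates = list(covariates)

    def family_p(cov_subset):
        C = cohort[cov_subset].to_numpy(float) if cov_subset else None
        X = _design(x, C)
        *_, p, _, _ = _ols_multi(Y, X)
        return p

    table = pd.DataFrame(index=vals.index)
    table["p_full"] = family_p(covariates)
    for cov in covariates:
        table[f"p_minus_{cov}"] = family_p([c for c in covariates if c != cov])
    table["p_none"] = family_p([])
    return table


def variance_explained_comparison(matrix: ExpressionMatrix, cohort: pd.DataFrame,
                                  features: list, outcome: str = "ad",
                                  reference_columns: list | None = None,
                                  covariates=COVARIATES) -> pd.DataFrame:
    """Partial variance explained for features vs reference covariates.

    Computes the squared partial correlation with the outcome, given the
    standard covariates, for each listed feature and for each reference
    cohort column (e.g. a planted risk-allele indicator), so effect sizes
    are directly comparable.
    """
    samples = matrix.sample_ids.intersection(cohort.index)
    cohort_s = cohort.loc[samples]
    x = _prepare_outcome(cohort_s, outcome, standardize=True)
    C = cohort_s[list(covariates)].to_numpy(float)
    rows = []
    for fid in features:
        if fid not in matrix.feature_ids:
            raise KeyError(f"unknown feature {fid}")
        r = fit_association(matrix.values.loc[fid, samples].to_numpy(), x, C,
                            feature_id=fid, outcome_name=outcome)
        rows.append((fid, "feature", r.r2))
    for col in (reference_columns or []):
        if col not in cohort.columns:
            raise KeyError(f"unknown cohort column {col}")
        r = fit_association(cohort_s[col].to_numpy(float), x, C,
                            feature_id=col, outcome_name=outcome)
        rows.append((col, "reference", r.r2))
    return pd.DataFrame(rows, columns=["id", "kind", "partial_r2"])
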