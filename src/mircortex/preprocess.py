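"""QC and normalization chain for Nanostring-like miRNA counts and lincRNA.

Pipeline order for miRNA:

1. :func:`adjust_background` — subtract per-probe background; values at or
   below background become missing.
2. :func:`filter_by_call_rate` — drop features, then samples, with
   non-missing fraction below the call-rate threshold (default 95%).
3. :func:`filter_low_expression` — drop features below a count floor
   (default 15) in at least half the samples; missing counts as below.
4. :func:`quantile_normalize` — impute residual missing values to the
   per-feature minimum, log2(x+1) transform, then map every sample to the
   across-sample mean order statistics.
5. :func:`combat_adjust` — parametric empirical-Bayes location/scale batch
   adjustment (cartridges as batches).

For lincRNA, :func:`filter_lincrna` replaces steps 1-3 (drop features with
mean expected count below 5), followed by the same normalization steps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FilterReport, FilterStep


# ---------------------------------------------------------------------------
# background adjustment
# ---------------------------------------------------------------------------

def adjust_background(raw: ExpressionMatrix, background: pd.Series) -> ExpressionMatrix:
    """Subtract per-feature probe background; non-positive results go missing.

    ``value' = value - background`` where ``value > background``; entries at
    or below background are treated as unexpressed (missing).
    """
    raw.require_state("raw")
    background = pd.Series(background)
    missing = raw.feature_ids.difference(background.index)
    if len(missing):
        raise ValueError(f"background missing for features: {list(missing)[:5]}")
    bg = background.reindex(raw.feature_ids).astype(float)
    if (bg < 0).any():
        raise ValueError("negative background level")
    adj = raw.values.sub(bg, axis=0)
    adj = adj.where(raw.values.gt(bg, axis=0))
    return raw.evolve(values=adj, state="background_adjusted")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_by_call_rate(m: ExpressionMatrix, feature_rate: float = 0.95,
                        sample_rate: float = 0.95,
                        report: FilterReport | None = None,
                        ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features, then samples, whose call rate falls below threshold.

    The call rate is the non-missing fraction. Features are filtered first,
    then samples against the retained feature set.
    """
    m.require_state("background_adjusted", "filtered")
    for name, rate in (("feature_rate", feature_rate), ("sample_rate", sample_rate)):
        if not 0.0 < rate <= 1.0:
            raise ValueError(f"{name}={rate} outside (0, 1]")
    report = report or FilterReport()

    mask = m.mask
    feat_rate = mask.mean(axis=1)
    keep_f = feat_rate >= feature_rate
    report.add(FilterStep(
        name="call_rate_features", axis="feature", threshold=feature_rate,
        n_before=m.n_features, n_after=int(keep_f.sum()),
        removed=list(m.feature_ids[~keep_f])))
    vals = m.values.loc[keep_f]

    samp_rate = vals.notna().mean(axis=0) if len(vals) else pd.Series(
        0.0, index=m.sample_ids)
    keep_s = samp_rate >= sample_rate
    report.add(FilterStep(
        name="call_rate_samples", axis="sample", threshold=sample_rate,
        n_before=m.n_samples, n_after=int(keep_s.sum()),
        removed=list(m.sample_ids[~keep_s])))
    vals = vals.loc[:, keep_s]
    return m.evolve(values=vals, state="filtered"), report


def filter_low_expression(m: ExpressionMatrix, min_value: float = 15.0,
                          frac: float = 0.5,
                          report: FilterReport | None = None,
                          ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop features whose value is below ``min_value`` in >= ``frac`` samples.

    Missing entries count as below the floor: a below-background measurement
    is an unexpressed one. The boundary is inclusive ("at least" the
    fraction).
    """
    m.require_state("filtered")
    if min_value < 0:
        raise ValueError("min_value must be non-negative")
    report = report or FilterReport()
    below = m.values.lt(min_value) | m.values.isna()
    low_frac = below.mean(axis=1)
    keep = low_frac < frac
    report.add(FilterStep(
        name="low_expression", axis="feature", threshold=min_value,
        n_before=m.n_features, n_after=int(keep.sum()),
        removed=list(m.feature_ids[~keep])))
    return m.evolve(values=m.values.loc[keep], state="filtered"), report


def filter_lincrna(counts: ExpressionMatrix, min_expected: float = 5.0,
                   report: FilterReport | None = None,
                   ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop lincRNA whose mean expected count is below ``min_expected``.

    The comparison is strict ("less than"): a feature with mean exactly at
    the floor is retained.
    """
    if counts.feature_class != "lincrna":
        raise ValueError("filter_lincrna expects a lincRNA matrix")
    if min_expected < 0:
        raise ValueError("min_expected must be non-negative")
    counts.require_state("raw", "filtered")
    report = report or FilterReport()
    mean_count = counts.values.mean(axis=1)
    keep = mean_count >= min_expected
    report.add(FilterStep(
        name="lincrna_low_count", axis="feature", threshold=min_expected,
        n_before=counts.n_features, n_after=int(keep.sum()),
        removed=list(counts.feature_ids[~keep])))
    return counts.evolve(values=counts.values.loc[keep], state="filtered"), report


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def impute_missing_to_feature_min(values: pd.DataFrame) -> pd.DataFrame:
    """Impute residual missing entries to the per-feature minimum observed
    value (features left after filtering have few missing entries)."""
    mins = values.min(axis=1)
    return values.apply(lambda row: row.fillna(mins[row.name]), axis=1)


def quantile_normalize(m: ExpressionMatrix, log2: bool = True) -> ExpressionMatrix:
    """Quantile-normalize samples to the across-sample mean order statistics.

    Residual missing entries are first imputed to the per-feature minimum,
    values are log2(x+1)-transformed (configurable), and each sample column
    is then mapped so that all columns share the identical sorted vector.
    Ties within a column receive the mean of their tied order statistics.
    """
    m.require_state("filtered", "normalized")
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values
    if vals.isna().any().any():
        vals = impute_missing_to_feature_min(vals)
    if log2:
        vals = np.log2(vals + 1.0)
    x = vals.to_numpy(float)
    order = np.sort(x, axis=0)
    target = order.mean(axis=1)           # mean of order statistics across samples
    out = np.empty_like(x)
    n_feat = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        sorter = np.argsort(col, kind="mergesort")
        srt = col[sorter]
        # dense-rank-mean convention: runs of tied values share the mean of
        # their tied order statistics
        starts = np.flatnonzero(np.r_[True, srt[1:] != srt[:-1]])
        counts = np.diff(np.r_[starts, n_feat])
        means = np.add.reduceat(target, starts) / counts
        tgt = np.repeat(means, counts)
        assigned = np.empty(n_feat, dtype=float)
        assigned[sorter] = tgt
        out[:, j] = assigned
    values = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return m.evolve(values=values, state="normalized")


# ---------------------------------------------------------------------------
# ComBat (parametric empirical Bayes)
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_solve(s_data: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
              g_bar: float, t2: float, a: float, b: float,
              conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the coupled EB posterior equations for one batch."""
    n = (~np.isnan(s_data)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = np.nansum((s_data - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-12)))
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_adjust(m: ExpressionMatrix, batch: pd.Series | None = None,
                  covariates: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Remove batch location/scale effects by parametric empirical Bayes.

    Per feature, data are standardized given the batch design (and optional
    biological covariates), batch-specific means and variances are estimated,
    shrunk toward across-feature moment-matched priors, and removed; the
    covariate effects and pooled mean/scale are then restored.
    """
    m.require_state("normalized")
    batch = m.batch if batch is None else pd.Series(batch).reindex(m.sample_ids)
    if batch is None:
        raise ValueError("no batch labels supplied")
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    batch = batch.astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        raise ValueError("ComBat needs at least 2 batches")
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batches with <2 samples: {list(small.index)}")

    X = m.values.to_numpy(float)          # features x samples
    n_feat, n_samp = X.shape
    onehot = pd.get_dummies(batch)[levels].to_numpy(float)   # samples x B
    n_batches = onehot.shape[1]
    design = onehot
    if covariates is not None:
        C = pd.DataFrame(covariates).reindex(m.sample_ids).to_numpy(float)
        design = np.hstack([onehot, C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design is singular (batch confounded with a covariate)")

    # feature-wise GLS fit of the full design; grand mean weighted by batch size
    B_hat = np.linalg.solve(design.T @ design, design.T @ X.T)   # p x features
    batch_frac = onehot.sum(axis=0) / n_samp
    grand_mean = batch_frac @ B_hat[:n_batches]                  # per feature
    resid = X - (design @ B_hat).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)

    stand_mean = grand_mean[:, None] * np.ones((1, n_samp))
    if covariates is not None:
        stand_mean = stand_mean + (design[:, n_batches:] @ B_hat[n_batches:]).T
    s_data = (X - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((n_batches, n_feat))
    delta_star = np.empty((n_batches, n_feat))
    for bi, lv in enumerate(levels):
        sel = (batch == lv).to_numpy()
        sb = s_data[:, sel]
        g_hat = sb.mean(axis=1)
        d_hat = sb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d_hat), _bprior(d_hat)
        gamma_star[bi], delta_star[bi] = _it_solve(sb, g_hat, d_hat, g_bar, t2, a, b)

    adj = s_data.copy()
    for bi, lv in enumerate(levels):
        sel = (batch == lv).to_numpy()
        adj[:, sel] = ((s_data[:, sel] - gamma_star[bi][:, None])
                       / np.sqrt(delta_star[bi])[:, None])
    out = adj * np.sqrt(var_pooled)[:, None] + stand_mean
    values = pd.DataFrame(out, index=m.feature_ids, columns=m.sample_ids)
    return m.evolve(values=values, state="batch_adjusted")


# ---------------------------------------------------------------------------
# convenience pipelines
# ---------------------------------------------------------------------------

def preprocess_mirna(raw: ExpressionMatrix, background: pd.Series,
                     call_rate: float = 0.95, min_value: float = 15.0,
                     low_frac: float = 0.5, log2: bool = True,
                     run_combat: bool = True,
                     ) -> tuple[ExpressionMatrix, FilterReport]:
    """Full miRNA chain: background -> call-rate -> low-expression -> QN -> ComBat."""
    report = FilterReport()
    m = adjust_background(raw, background)
    m, report = filter_by_call_rate(m, call_rate, call_rate, report)
    m, report = filter_low_expression(m, min_value, low_frac, report)
    m = quantile_normalize(m, log2=log2)
    if run_combat:
        m = combat_adjust(m)
    return m, report


def preprocess_lincrna(raw: ExpressionMatrix, min_expected: float = 5.0,
                       log2: bool = True, run_combat: bool = True,
                       ) -> tuple[ExpressionMatrix, FilterReport]:
    """lincRNA chain: low-count filter -> quantile normalization -> ComBat."""
    m, report = filter_lincrna(raw, min_expected)
    m = quantile_normalize(m, log2=log2)
    if run_combat:
        m = combat_adjust(m)
    return m, report
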