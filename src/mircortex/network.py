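"""Confounder-aware association networks between ncRNA and phenotype nodes.

Features enter the network if a joint model (expression on age, NNLS, sex,
study, PMI, RIN, NP, NFT and AD) shows evidence that any pathology effect is
non-zero — a partial F-test of {NP, NFT, AD} at nominal p < 0.05. Edges are
then chosen per feature by forward stepwise selection under BIC over the
demographic and pathology variables, with the intercept and RIN forced into
every model: RIN is ubiquitously associated with expression, so it is kept
as an adjustment but its edges are suppressed from the exported network.

BIC uses the Gaussian form n*ln(RSS/n) + k*ln(n) with k the number of
estimated coefficients. Selection is forward-only and deterministic; ties in
BIC decrease resolve by (alphabetical) candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

#: candidate explanatory variables for edge selection (RIN is forced, not a candidate)
CANDIDATES = ("ad", "age", "nft", "nnls", "np", "pmi", "sex", "study")
FORCED = ("rin",)
PATHOLOGY = ("np", "nft", "ad")


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def screen_pathology(expr, cohort: pd.DataFrame,
                     covariates=("age", "nnls", "sex", "study", "pmi", "rin"),
                     pathology=PATHOLOGY) -> tuple[float, float]:
    """Partial F-test of the pathology block {NP, NFT, AD}.

    Compares expression ~ covariates + pathology against expression ~
    covariates; returns (F, p). A feature passes the screen at p < 0.05.
    """
    y = np.asarray(expr, dtype=float)
    C = cohort[list(covariates)].to_numpy(float)
    P = cohort[list(pathology)].to_numpy(float)
    n = len(y)
    X_red = np.column_stack([np.ones(n), C])
    X_full = np.column_stack([X_red, P])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular design in pathology screen")
    rss_red = _rss(y, X_red)
    rss_full = _rss(y, X_full)
    q = len(pathology)
    df_full = n - X_full.shape[1]
    F = ((rss_red - rss_full) / q) / (rss_full / df_full)
    p = float(stats.f.sf(F, q, df_full))
    return float(F), p


def bic(y: np.ndarray, X: np.ndarray) -> float:
    """Gaussian BIC: n*ln(RSS/n) + k*ln(n), k = number of coefficients."""
    n, k = X.shape
    rss = _rss(y, X)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + k * np.log(n)


@dataclass
class StepwiseResult:
    selected: list                      # candidate names in selection order
    coefficients: dict                  # name -> beta in the final model
    bic_path: list = field(default_factory=list)   # BIC after each accepted step


def forward_stepwise_bic(y, cohort: pd.DataFrame,
                         candidates=CANDIDATES, forced=FORCED,
                         ) -> StepwiseResult:
    """Forward stepwise variable selection under BIC.

    Starting from the forced model (intercept + forced terms), repeatedly
    add the candidate producing the largest BIC decrease; stop when no
    addition decreases BIC. Ties break by candidate order, which is fixed
    (alphabetical by default) so the procedure is deterministic.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    forced = list(forced)
    candidates = list(candidates)
    if n < len(forced) + 3:
        raise ValueError("too few samples for the forced model")

    def design(names):
        cols = [np.ones(n)]
        cols += [cohort[v].to_numpy(float) for v in names]
        return np.column_stack(cols)

    current = list(forced)
    current_bic = bic(y, design(current))
    bic_path = [current_bic]
    remaining = [c for c in candidates if c not in current]
    selected: list = []
    while remaining:
        trials = [(bic(y, design(current + [c])), i, c)
                  for i, c in enumerate(remaining)]
        best_bic, _, best_c = min(trials)       # ties -> lowest candidate index
        if best_bic < current_bic:
            current.append(best_c)
            selected.append(best_c)
            current_bic = best_bic
            bic_path.append(best_bic)
            remaining.remove(best_c)
        else:
            break
    X = design(current)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefs = {name: float(b) for name, b in zip(current, beta[1:])}
    return StepwiseResult(selected=selected, coefficients=coefs,
                          bic_path=bic_path)


def exhaustive_best_subset_bic(y, cohort: pd.DataFrame,
                               candidates=CANDIDATES, forced=FORCED,
                               ) -> tuple[frozenset, float]:
    """Best subset by exhaustive BIC search over all 2^len(candidates) sets.

    Independent of the forward path; usable as an oracle on small candidate
    sets.
    """
    from itertools import combinations

    y = np.asarray(y, dtype=float)
    n = len(y)
    forced = list(forced)
    candidates = list(candidates)

    def design(names):
        cols = [np.ones(n)] + [cohort[v].to_numpy(float) for v in names]
        return np.column_stack(cols)

    best = (np.inf, frozenset())
    for r in range(len(candidates) + 1):
        for combo in combinations(candidates, r):
            b = bic(y, design(forced + list(combo)))
            if b < best[0]:
                best = (b, frozenset(combo))
    return best[1], best[0]


def build_network(matrix: ExpressionMatrix, cohort: pd.DataFrame,
                  screen_alpha: float = 0.05,
                  significant_threshold: float | None = None,
                  candidates=CANDIDATES, forced=FORCED) -> nx.Graph:
    """Screen features, select edges per feature, and assemble the network.

    Nodes are features (kind="feature") and explanatory variables
    (kind="variable"); edges carry the coefficient sign, value and the BIC
    at which the edge was accepted. RIN edges are suppressed from the
    export although RIN stays in every model. Features are annotated
    ``significance="significant"`` when their screen p-value is below
    ``significant_threshold`` (default: Bonferroni over screened features),
    else "suggestive".
    """
    samples = matrix.sample_ids.intersection(cohort.index)
    vals = matrix.values[samples]
    coh = cohort.loc[samples].copy()
    for col in ("np", "nft"):       # standardized scale, as in association
        x = coh[col].to_numpy(float)
        coh[col] = (x - x.mean()) / x.std()

    screen = {}
    for fid in vals.index:
        F, p = screen_pathology(vals.loc[fid].to_numpy(), coh)
        screen[fid] = (F, p)
    passed = [fid for fid, (_, p) in screen.items() if p < screen_alpha]
    if significant_threshold is None:
        significant_threshold = 0.05 / max(1, matrix.n_features)

    g = nx.Graph()
    for var in candidates:
        g.add_node(var, kind="variable")
    for fid in passed:
        F, p = screen[fid]
        label = "significant" if p < significant_threshold else "suggestive"
        g.add_node(fid, kind="feature", screen_F=float(F), screen_p=float(p),
                   significance=label)
        res = forward_stepwise_bic(vals.loc[fid].to_numpy(), coh,
                                   candidates=candidates, forced=forced)
        for i, var in enumerate(res.selected):
            if var in forced:
                continue
            beta = res.coefficients[var]
            g.add_edge(fid, var, sign="+" if beta >= 0 else "-",
                       beta=float(beta), bic=float(res.bic_path[i + 1]))
    # variable nodes with no edges are kept: they are the fixed anatomy of the plot
    return g


def network_to_edge_table(g: nx.Graph) -> pd.DataFrame:
    """Edge-list export: feature, variable, sign, beta, bic."""
    rows = []
    for u, v, d in g.edges(data=True):
        feature, var = (u, v) if g.nodes[u].get("kind") == "feature" else (v, u)
        rows.append((feature, var, d["sign"], d["beta"], d["bic"]))
    return pd.DataFrame(rows, columns=["feature_id", "variable", "sign",
                                      "beta", "bic"]).sort_values(
        ["feature_id", "variable"]).reset_index(drop=True)


def edge_table_to_network(table: pd.DataFrame,
                          candidates=CANDIDATES) -> nx.Graph:
    """Rebuild a network from its edge-list export (round-trip inverse)."""
    g = nx.Graph()
    for var in candidates:
        g.add_node(var, kind="variable")
    for _, row in table.iterrows():
        fid = row["feature_id"]
        if fid not in g:
            g.add_node(fid, kind="feature")
        g.add_edge(fid, row["variable"], sign=row["sign"],
                   beta=float(row["beta"]), bic=float(row["bic"]))
    return g


def correlation_map(matrix: ExpressionMatrix, cohort: pd.DataFrame,
                    features: list, outcomes=("np", "nft", "ad"),
                    ) -> pd.DataFrame:
    """Pearson correlation matrix of selected features and outcome variables.

    Complete pairwise cases; symmetric with unit diagonal.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    samples = matrix.sample_ids.intersection(cohort.index)
    block = matrix.values.loc[features, samples].T
    if (block.std(ddof=0) == 0).any():
        raise ValueError("zero-variance feature in correlation map")
    block = pd.concat([block, cohort.loc[samples, list(outcomes)]], axis=1)
    return block.corr(method="pearson")
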