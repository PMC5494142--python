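"""Integrated miRNA:mRNA pathway scoring and effect-size decomposition.

A miR-pathway is the intersection of one miRNA's predicted target genes with
one annotated pathway's gene set. Within a miR-pathway, gene-level
association z-statistics with the outcome are combined by Stouffer's method
(sum z / sqrt(k)); the resulting pathway evidence and the miRNA's own
association are each converted to one-sided p-values and combined by a
Fisher/Pearson-family product statistic, -2(ln p1 + ln p2) referred to a
chi-square with 4 df. Because member genes within an annotated pathway are
correlated, the combined score is inflated relative to a p-value and is
used strictly for ranking.

By default the pathway's one-sided direction is the opposite of the
miRNA's (repression logic: when the miRNA falls with disease its targets
should rise), configurable to same-sign.

The module also decomposes a gene's outcome effect into the part explained
by one or more miRNAs (comparing beta with and without the miRNA in the
model) and reports the miRNAs' incremental adjusted R-squared for the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COVARIATES, ExpressionMatrix
from .association import _design, _ols_multi


# ---------------------------------------------------------------------------
# miR-pathway construction
# ---------------------------------------------------------------------------

def build_mir_pathways(targets: pd.DataFrame, pathways: dict,
                       min_size: int = 3) -> pd.DataFrame:
    """All (miRNA, pathway) pairs whose target/pathway intersection is large
    enough.

    ``targets`` has columns mirna_id, gene_id; ``pathways`` maps pathway name
    to a gene list. Pathway aliases with identical member gene sets (after
    intersecting with the miRNA's targets) are merged into one row with
    names concatenated by ';'. Returns columns mirna_id, pathways, genes
    (sorted tuple).
    """
    if targets.empty:
        raise ValueError("empty target table")
    if not {"mirna_id", "gene_id"} <= set(targets.columns):
        raise ValueError("target table needs columns mirna_id, gene_id")
    tmap = {m: set(g) for m, g in targets.groupby("mirna_id")["gene_id"]}
    rows = []
    for mirna, tset in tmap.items():
        by_members: dict = {}
        for pname, genes in pathways.items():
            member = tuple(sorted(tset & set(genes)))
            if len(member) >= min_size:
                by_members.setdefault(member, []).append(pname)
        for member, names in by_members.items():
            rows.append((mirna, ";".join(sorted(names)), member))
    return pd.DataFrame(rows, columns=["mirna_id", "pathways", "genes"])


# ---------------------------------------------------------------------------
# significance combination
# ---------------------------------------------------------------------------

def stouffer_combine(z) -> float:
    """Unweighted Stouffer combination: sum(z) / sqrt(k)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty z list")
    if not np.isfinite(z).all():
        raise ValueError("non-finite z statistic")
    return float(z.sum() / np.sqrt(z.size))


def one_sided_p(z: float, direction: str) -> float:
    """Upper-tail normal probability of z in the expected direction.

    ``direction`` is '+' (evidence = positive z) or '-' (negative z).
    """
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    s = 1.0 if direction == "+" else -1.0
    return float(stats.norm.sf(s * z))


def combine_joint(p_mirna: float, p_pathway: float) -> float:
    """Fisher/Pearson-family product of two one-sided p-values.

    X = -2(ln p_mirna + ln p_pathway), scored as the upper-tail chi-square(4)
    probability. The result is a ranking score, not a calibrated p-value:
    within-pathway gene correlation inflates it.
    """
    tiny = np.finfo(float).tiny
    ps = []
    for p in (p_mirna, p_pathway):
        if p <= 0.0:
            warnings.warn("one-sided p of 0 floored at machine minimum")
            p = tiny
        if p > 1.0:
            raise ValueError("p-value above 1")
        ps.append(p)
    X = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(stats.chi2.sf(X, df=4))


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass
class MirPathwayScore:
    mirna_id: str
    pathways: str
    genes: tuple
    stouffer_z: float
    p_mirna_one_sided: float
    p_pathway_one_sided: float
    joint_score: float          # ranking only, never a p-value
    direction: str              # Up/Down: sign of the miRNA-outcome association
    rank: int = 0


def rank_mir_pathways(mirna_assoc: pd.DataFrame, gene_assoc: pd.DataFrame,
                      mir_pathways: pd.DataFrame, outcome: str = "ad",
                      opposite_direction: bool = True) -> pd.DataFrame:
    """Score and rank miR-pathways by the joint miRNA+pathway evidence.

    ``mirna_assoc`` / ``gene_assoc`` are association tables (long format,
    from :func:`mircortex.association.associate_all`) computed on the same
    (paired) samples. For each miR-pathway: member-gene z-scores are
    Stouffer-combined; one-sided p-values are taken in the miRNA's own
    association direction and — under the default repression convention —
    the opposite direction for the pathway; the two are combined into the
    joint ranking score. Rows are sorted ascending by score, ties broken by
    larger |Stouffer z|.
    """
    ma = mirna_assoc[mirna_assoc["outcome"] == outcome].set_index("feature_id")
    ga = gene_assoc[gene_assoc["outcome"] == outcome].set_index("feature_id")
    if ma.empty or ga.empty:
        raise ValueError("association tables lack the requested outcome")
    rows = []
    for _, row in mir_pathways.iterrows():
        mirna = row["mirna_id"]
        if mirna not in ma.index:
            continue
        genes = [g for g in row["genes"] if g in ga.index]
        if not genes:
            continue
        z_mirna = float(ma.loc[mirna, "z"])
        mdir = "+" if z_mirna >= 0 else "-"
        pdir = ({"+": "-", "-": "+"}[mdir]) if opposite_direction else mdir
        sz = stouffer_combine(ga.loc[genes, "z"].to_numpy())
        p_m = one_sided_p(z_mirna, mdir)
        p_g = one_sided_p(sz, pdir)
        score = combine_joint(p_m, p_g)
        rows.append(MirPathwayScore(
            mirna_id=mirna, pathways=row["pathways"], genes=tuple(genes),
            stouffer_z=sz, p_mirna_one_sided=p_m, p_pathway_one_sided=p_g,
            joint_score=score, direction="Up" if mdir == "+" else "Down"))
    if not rows:
        raise ValueError("no scorable miR-pathways (no overlapping ids)")
    table = pd.DataFrame([vars(r) for r in rows])
    table = table.sort_values(
        ["joint_score", "stouffer_z"],
        key=lambda s: -s.abs() if s.name == "stouffer_z" else s,
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# effect decomposition
# ---------------------------------------------------------------------------

@dataclass
class EffectDecomposition:
    gene_id: str
    mirna_ids: tuple
    beta_total: float
    se_total: float
    beta_adjusted: float
    se_adjusted: float
    explained_fraction: float       # 1 - beta_adjusted / beta_total
    fraction_out_of_range: bool     # True when outside [0, 1] (reported unclipped)
    fraction_undefined: bool        # True when beta_total ~ 0
    incremental_adj_r2: float       # adj R^2 gain from adding the miRNA(s)
    n: int


def _adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k)


def decompose_effect(gene_expr, outcome, mirna_exprs, covariates=None, *,
                     gene_id: str = "gene", mirna_ids: tuple = ("mirna",),
                     ) -> EffectDecomposition:
    """Split a gene's outcome effect into miRNA-explained and residual parts.

    Fits gene ~ outcome + covariates (total effect) and gene ~ outcome +
    miRNA(s) + covariates (adjusted effect). The explained fraction is
    1 - beta_adjusted/beta_total, reported unclipped with a flag when it
    falls outside [0, 1]; it is flagged undefined when the total effect is
    indistinguishable from zero. Also reports the incremental adjusted
    R-squared contributed by the miRNA block (EP300-style multi-miRNA fits
    are supported by passing several expression vectors).
    """
    y = np.asarray(gene_expr, dtype=float)
    x = np.asarray(outcome, dtype=float)
    M = np.column_stack([np.asarray(m, dtype=float) for m in
                         (mirna_exprs if isinstance(mirna_exprs, (list, tuple))
                          else [mirna_exprs])])
    C = None
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
    n = len(y)

    X_total = _design(x, C)
    X_adj = np.column_stack([X_total, M])
    b_t, se_t, *_ = _ols_multi(y[None, :], X_total)
    b_a, se_a, *_ = _ols_multi(y[None, :], X_adj)
    beta_total, se_total = float(b_t[0]), float(se_t[0])
    beta_adj, se_adj = float(b_a[0]), float(se_a[0])

    undefined = abs(beta_total) < 2.0 * se_total * np.finfo(float).eps ** 0.25 \
        and abs(beta_total) < 1e-10
    if undefined:
        frac, out_of_range = float("nan"), False
    else:
        frac = 1.0 - beta_adj / beta_total
        out_of_range = not (0.0 <= frac <= 1.0)

    inc = _adj_r2(y, X_adj) - _adj_r2(y, X_total)
    return EffectDecomposition(
        gene_id=gene_id, mirna_ids=tuple(mirna_ids),
        beta_total=beta_total, se_total=se_total,
        beta_adjusted=beta_adj, se_adjusted=se_adj,
        explained_fraction=float(frac), fraction_out_of_range=bool(out_of_range),
        fraction_undefined=bool(undefined),
        incremental_adj_r2=float(inc), n=n)


def decompose_pathway_effects(mrna: ExpressionMatrix, mirna: ExpressionMatrix,
                              cohort: pd.DataFrame, genes: list, mirna_id: str,
                              outcome: str = "ad", covariates=COVARIATES,
                              ) -> pd.DataFrame:
    """Per-gene decomposition against one miRNA over the paired samples."""
    samples = (mrna.sample_ids.intersection(mirna.sample_ids)
               .intersection(cohort.index))
    if len(samples) == 0:
        raise ValueError("no overlapping samples")
    coh = cohort.loc[samples]
    x = coh[outcome].to_numpy(float)
    C = coh[list(covariates)].to_numpy(float) if covariates else None
    m = mirna.values.loc[mirna_id, samples].to_numpy(float)
    rows = []
    for g in genes:
        d = decompose_effect(mrna.values.loc[g, samples].to_numpy(), x, [m],
                             C, gene_id=g, mirna_ids=(mirna_id,))
        rows.append((g, mirna_id, d.beta_total, d.beta_adjusted,
                     d.explained_fraction, d.incremental_adj_r2,
                     d.fraction_undefined))
    return pd.DataFrame(rows, columns=["gene_id", "mirna_id", "beta_total",
                                       "beta_adjusted", "explained_fraction",
                                       "incremental_adj_r2", "undefined"])
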