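"""Synthetic cohort generator emulating a prospective aging-brain autopsy study.

Generates, from a single integer seed:

* a cohort table (age, sex, study, neuronal proportion, PMI, RIN, cartridge)
  together with correlated neuritic-plaque (NP) and neurofibrillary-tangle
  (NFT) burdens and a binary pathologic-AD diagnosis derived from them,
* Nanostring-like raw miRNA count matrices with probe backgrounds, cartridge
  batch shifts, RIN-coupled expression and planted pathology effects of known
  variance-explained,
* miRNA-coupled mRNA abundances plus target tables and pathway gene sets with
  a planted coherent miR-pathway,

all with the ground truth recorded so downstream stages can be tested for
parameter recovery without any external data.

Demographic defaults mirror a large prospective autopsy cohort: ~700 donors,
mean age 88, 64% female, 61% pathologic AD, RIN in [2, 9] with mean 6.5,
samples processed in cartridges of 96.

Randomness is split through ``numpy.random.SeedSequence(seed, spawn_key=k)``
with a fixed spawn key per sub-generator, so each component is independently
reproducible from the one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

# spawn keys for the documented seed-splitting scheme
_STREAM_COHORT = 1
_STREAM_MIRNA = 2
_STREAM_MRNA = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Distribution settings for the synthetic cohort.

    NP and NFT are negative-binomial counts sharing a Gaussian latent factor
    (a Gaussian copula), which sets their correlation; pathologic AD is a
    deterministic threshold rule on the two burdens, collapsing an
    intermediate/high-likelihood autopsy criterion to a binary diagnosis.
    """

    age_mean: float = 88.0
    age_sd: float = 6.5
    frac_female: float = 0.64
    frac_map: float = 0.5          # study indicator: ROS=0, MAP=1
    nnls_a: float = 8.0            # Beta shape params for neuronal proportion
    nnls_b: float = 12.0
    pmi_shape: float = 3.0         # Gamma, hours; mean = shape*scale ~ 7 h
    pmi_scale: float = 2.3
    rin_mean: float = 6.5
    rin_sd: float = 1.2
    rin_bounds: tuple = (2.0, 9.0)
    np_mean: float = 10.0
    np_dispersion: float = 2.0     # NB size parameter
    nft_mean: float = 12.0
    nft_dispersion: float = 2.0
    latent_corr: float = 0.6       # Gaussian-copula correlation of NP and NFT
    ad_np_threshold: float = 4.0   # AD=1 iff NP>=this AND NFT>=nft threshold
    ad_nft_threshold: float = 7.0
    rin_pathology_corr: float = 0.0  # couples RIN to the shared pathology factor
    cartridge_size: int = 96
    sqrt_transform: bool = False   # report sqrt(NP), sqrt(NFT) instead of counts

    def validate(self) -> None:
        for name in ("frac_female", "frac_map"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.rin_bounds
        if lo >= hi:
            raise ValueError("RIN bounds inverted")
        if not -1.0 < self.latent_corr < 1.0:
            raise ValueError("latent correlation outside (-1, 1)")
        if not -1.0 <= self.rin_pathology_corr <= 1.0:
            raise ValueError("rin_pathology_corr outside [-1, 1]")


@dataclass
class MirnaParams:
    """Settings for the Nanostring-like raw count generator.

    Counts are Poisson draws around ``exp(linear predictor) + background``
    where the log-scale predictor has a per-feature intercept, a cartridge
    shift, a RIN slope, any planted pathology effect and Gaussian noise.
    """

    intercept_log_low: float = float(np.log(100.0))
    intercept_log_high: float = float(np.log(5000.0))
    planted_intercept_log: float = float(np.log(1500.0))
    rin_slope_mean: float = 0.2    # natural-log counts per RIN unit
    rin_slope_sd: float = 0.05
    batch_sd: float = 0.3          # SD of per-cartridge log-scale shifts
    noise_sd: float = 0.5          # per-sample biological noise, log scale
    background_log_mean: float = 3.0   # per-feature background ~ logN(3, 0.5) ≈ 20
    background_log_sd: float = 0.5


@dataclass
class MrnaParams:
    """Settings for the miRNA-coupled mRNA generator (log-abundance scale)."""

    n_genes: int = 300
    n_pathways: int = 40
    pathway_size: int = 20
    target_set_size: int = 60
    noise_sd: float = 1.0
    intercept_mean: float = 5.0
    intercept_sd: float = 1.0


@dataclass
class PlantedPathway:
    """A coherent miR-pathway planted in the mRNA layer.

    ``coupling`` is the coefficient of the (standardized) miRNA log
    expression in each member gene; ``direct_beta`` is the gene's direct
    effect of the standardized outcome, bypassing the miRNA.
    """

    mirna_id: str
    pathway_id: str = "PLANTED_PATHWAY"
    n_genes: int = 5
    coupling: float = -0.5
    direct_beta: float = 0.0
    outcome: str = "ad"
    genes: list = field(default_factory=list)
    expected_mediated_fraction: Optional[float] = None


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping: what was injected where, at what size.

    ``effects`` maps feature id -> (outcome name, signed fraction of outcome
    variance the feature should explain after preprocessing; the sign sets
    the direction of the effect, e.g. -0.067 for a feature diminished with
    pathology that explains 6.7% of its variance). Null features carry no
    entry: all their planted effects are exactly zero.
    """

    seed: int = 0
    effects: dict = field(default_factory=dict)   # fid -> (outcome, frac_var)
    beta_log: dict = field(default_factory=dict)  # fid -> realized log-scale slope
    planted_pathway: Optional[PlantedPathway] = None

    def is_null(self, feature_id: str) -> bool:
        return feature_id not in self.effects

    def to_dict(self) -> dict:
        d = {"seed": self.seed, "effects": {k: list(v) for k, v in self.effects.items()},
             "beta_log": dict(self.beta_log)}
        if self.planted_pathway is not None:
            d["planted_pathway"] = asdict(self.planted_pathway)
        return d


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(n: int, seed: int,
                    params: CohortParams | None = None) -> pd.DataFrame:
    """Generate an ``n``-row cohort with covariates and pathology outcomes.

    Returns a DataFrame indexed by sample id with columns
    ``age, sex, study, nnls, pmi, rin, cartridge, np, nft, ad``.
    Identical ``(n, seed, params)`` produce bit-identical output.
    """
    if n < 2:
        raise ValueError("cohort size must be at least 2")
    params = params or CohortParams()
    params.validate()
    rng = _rng(seed, _STREAM_COHORT)

    age = rng.normal(params.age_mean, params.age_sd, size=n)
    sex = (rng.random(n) < params.frac_female).astype(int)
    study = (rng.random(n) < params.frac_map).astype(int)
    nnls = rng.beta(params.nnls_a, params.nnls_b, size=n)
    pmi = rng.gamma(params.pmi_shape, params.pmi_scale, size=n)

    # shared latent pathology factor f; NP/NFT via Gaussian copula
    rho = params.latent_corr
    sgn = np.sign(rho) if rho != 0 else 1.0
    f = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    a = np.sqrt(abs(rho))
    z1 = a * f + np.sqrt(1 - abs(rho)) * e1
    z2 = sgn * a * f + np.sqrt(1 - abs(rho)) * e2

    def nb_from_z(z, mu, k):
        p = k / (k + mu)
        u = stats.norm.cdf(z)
        return stats.nbinom.ppf(u, k, p)

    np_counts = nb_from_z(z1, params.np_mean, params.np_dispersion)
    nft_counts = nb_from_z(z2, params.nft_mean, params.nft_dispersion)
    ad = ((np_counts >= params.ad_np_threshold)
          & (nft_counts >= params.ad_nft_threshold)).astype(int)

    # RIN, optionally confounded with the pathology factor (lower RIN with
    # more pathology when rin_pathology_corr > 0)
    c = params.rin_pathology_corr
    lo, hi = params.rin_bounds
    if c == 0.0:
        rin = _truncnorm(rng, params.rin_mean, params.rin_sd, lo, hi, n)
    else:
        e_r = rng.standard_normal(n)
        rin_z = -c * f + np.sqrt(1 - c * c) * e_r
        rin = np.clip(params.rin_mean + params.rin_sd * rin_z, lo, hi)

    # cartridge assignment: random permutation into blocks of cartridge_size,
    # at least two cartridges, mirroring batched sample processing
    n_cart = max(2, int(np.ceil(n / params.cartridge_size)))
    order = rng.permutation(n)
    cart = np.empty(n, dtype=object)
    for i, idx in enumerate(order):
        cart[idx] = f"cart{(i % n_cart) + 1:02d}"

    if params.sqrt_transform:
        np_out, nft_out = np.sqrt(np_counts), np.sqrt(nft_counts)
    else:
        np_out, nft_out = np_counts, nft_counts

    idx = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(
        {"age": age, "sex": sex, "study": study, "nnls": nnls, "pmi": pmi,
         "rin": rin, "cartridge": cart, "np": np_out, "nft": nft_out, "ad": ad},
        index=idx,
    )


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------

def _standardized_outcome_residual(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    """Outcome standardized to unit variance, plus its residual SD given the
    demographic/technical covariates (used to size planted effects)."""
    x = cohort[outcome].to_numpy(float)
    x_s = (x - x.mean()) / x.std()
    covs = cohort[["age", "sex", "study", "nnls", "pmi", "rin"]].to_numpy(float)
    design = np.column_stack([np.ones(len(x_s)), covs])
    beta, *_ = np.linalg.lstsq(design, x_s, rcond=None)
    resid = x_s - design @ beta
    return x_s, float(resid.std())


def generate_mirna_counts(cohort: pd.DataFrame, truth: GroundTruth,
                          n_features: int, seed: int,
                          params: MirnaParams | None = None,
                          feature_prefix: str = "miR-synth",
                          ) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate Nanostring-like raw miRNA counts plus per-feature backgrounds.

    Planted features listed in ``truth.effects`` receive a log-scale slope on
    the named outcome sized so that, after preprocessing, the feature's
    squared partial correlation with the outcome equals the requested
    variance fraction in expectation.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    for fid, (outcome, frac) in truth.effects.items():
        if abs(frac) >= 1.0:
            raise ValueError(f"|variance fraction| {frac} for {fid} must be < 1")
    params = params or MirnaParams()
    rng = _rng(seed, _STREAM_MIRNA)
    n = len(cohort)

    fids = [f"{feature_prefix}-{i + 1:04d}" for i in range(n_features)]
    known = set(fids)
    for fid in truth.effects:
        if fid not in known:
            raise ValueError(f"unknown feature id in truth: {fid}")

    intercepts = rng.uniform(params.intercept_log_low, params.intercept_log_high,
                             size=n_features)
    rin_slopes = rng.normal(params.rin_slope_mean, params.rin_slope_sd,
                            size=n_features)
    cart_labels = cohort["cartridge"].astype(str)
    cart_levels = sorted(cart_labels.unique())
    cart_shift = {lv: s for lv, s in
                  zip(cart_levels, rng.normal(0.0, params.batch_sd,
                                              size=len(cart_levels)))}
    shift_vec = cart_labels.map(cart_shift).to_numpy(float)
    background = pd.Series(
        rng.lognormal(params.background_log_mean, params.background_log_sd,
                      size=n_features),
        index=pd.Index(fids, name="feature_id"), name="background",
    )

    rin_c = cohort["rin"].to_numpy(float) - cohort["rin"].mean()
    outcome_cache: dict = {}
    log_mu = np.empty((n_features, n), dtype=float)
    for i, fid in enumerate(fids):
        pred = intercepts[i] + shift_vec + rin_slopes[i] * rin_c
        if fid in truth.effects:
            outcome, frac = truth.effects[fid]
            if outcome not in outcome_cache:
                outcome_cache[outcome] = _standardized_outcome_residual(cohort, outcome)
            x_s, sd_resid = outcome_cache[outcome]
            # slope giving partial R^2 = |frac| against noise_sd after
            # adjustment; sign of frac sets the effect direction
            v = abs(frac)
            b = np.sign(frac) * np.sqrt(v / (1.0 - v)) * params.noise_sd / sd_resid
            pred = params.planted_intercept_log + shift_vec + rin_slopes[i] * rin_c
            pred = pred + b * x_s
            truth.beta_log[fid] = float(b)
        log_mu[i] = pred
    noise = rng.normal(0.0, params.noise_sd, size=(n_features, n))
    mu = np.exp(log_mu + noise)
    counts = rng.poisson(mu + background.to_numpy()[:, None]).astype(float)

    values = pd.DataFrame(counts, index=pd.Index(fids, name="feature_id"),
                          columns=cohort.index)
    matrix = ExpressionMatrix(values=values, feature_class="mirna",
                              batch=cart_labels, state="raw")
    return matrix, background


# ---------------------------------------------------------------------------
# mRNA, targets and pathways
# ---------------------------------------------------------------------------

def generate_mrna_and_annotations(
    cohort: pd.DataFrame,
    mirna: ExpressionMatrix,
    truth: GroundTruth,
    seed: int,
    params: MrnaParams | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Generate mRNA log-abundances, a miRNA->gene target table and pathways.

    If ``truth.planted_pathway`` is set, its member genes are coupled to the
    planted miRNA's (standardized log) expression with the stated
    coefficient, plus an optional direct outcome effect; the expected
    mediated fraction implied by the realized coefficients is recorded on the
    planted-pathway record. Non-member genes are pure noise. Returns
    ``(mrna_matrix, target_table, pathway_sets)`` where ``pathway_sets`` maps
    pathway name -> list of gene ids (GMT semantics).
    """
    params = params or MrnaParams()
    if params.pathway_size > params.n_genes:
        raise ValueError("pathway size exceeds number of genes")
    rng = _rng(seed, _STREAM_MRNA)
    n = len(cohort)
    genes = [f"G{i + 1:04d}" for i in range(params.n_genes)]

    expr = (rng.normal(params.intercept_mean, params.intercept_sd,
                       size=(params.n_genes, 1))
            + rng.normal(0.0, params.noise_sd, size=(params.n_genes, n)))
    values = pd.DataFrame(expr, index=pd.Index(genes, name="feature_id"),
                          columns=cohort.index)

    pathway_sets: dict = {}
    targets: dict = {}
    planted = truth.planted_pathway
    if planted is not None:
        if planted.mirna_id not in mirna.feature_ids:
            raise ValueError(f"planted miRNA {planted.mirna_id} not in matrix")
        member = list(genes[: planted.n_genes])
        planted.genes = member
        # standardized log expression of the planted miRNA (counts observed raw)
        m = np.log2(mirna.values.loc[planted.mirna_id].to_numpy(float) + 1.0)
        m_std = (m - m.mean()) / m.std()
        x = cohort[planted.outcome].to_numpy(float)
        x_s = (x - x.mean()) / x.std()
        for g in member:
            values.loc[g] = (values.loc[g].to_numpy()
                             + planted.coupling * m_std
                             + planted.direct_beta * x_s)
        # mediated fraction from the realized coefficients: with
        # m = b*x + u, gene = c*m + d*x + e, the x-coefficient drops from
        # c*b + d to d once m is adjusted for, so the mediated share is
        # c*b / (c*b + d); b estimated from the realized draw.
        b_hat = float(np.cov(m_std, x_s)[0, 1] / np.var(x_s))
        cb = planted.coupling * b_hat
        denom = cb + planted.direct_beta
        planted.expected_mediated_fraction = (
            float(cb / denom) if abs(denom) > 1e-12 else float("nan"))
        targets[planted.mirna_id] = set(member)

    # random target sets and null pathways draw from the non-planted genes,
    # so the planted pathway is the one annotated set carrying the signal
    planted_genes = set() if planted is None else set(planted.genes)
    null_pool = [g for g in genes if g not in planted_genes]
    for fid in mirna.feature_ids:
        extra = rng.choice(null_pool, size=min(params.target_set_size,
                                               len(null_pool)), replace=False)
        targets.setdefault(fid, set()).update(extra)

    # pathways: the planted one (members + random fillers) plus null sets
    if planted is not None:
        fill = rng.choice(null_pool, size=max(0, params.pathway_size
                                              - len(planted.genes)),
                          replace=False)
        pathway_sets[planted.pathway_id] = sorted(planted.genes) + sorted(fill)
    for j in range(params.n_pathways):
        name = f"PATHWAY_{j + 1:03d}"
        if name in pathway_sets:
            raise ValueError(f"duplicate pathway name {name}")
        members = rng.choice(null_pool, size=min(params.pathway_size,
                                                 len(null_pool)), replace=False)
        pathway_sets[name] = sorted(members)

    rows = [(fid, g) for fid in mirna.feature_ids for g in sorted(targets[fid])]
    target_table = pd.DataFrame(rows, columns=["mirna_id", "gene_id"])

    matrix = ExpressionMatrix(values=values, feature_class="mrna",
                              batch=None, state="batch_adjusted")
    return matrix, target_table, pathway_sets
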