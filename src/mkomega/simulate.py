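"""Synthetic gene tables with known ground truth.

The generator emulates the statistical structure of a hominid-scale coding
data set: ~15,000 genes with correlated lognormal covariates (recombination
rate, gene age, expression, protein length), a gamma DFE whose mean effect
is log-linearly linked to the covariates, a small adaptive divergence
component, a demography-distorted frequency spectrum, multi-membership GO
annotation with a virus-interacting-protein (VIP) subset, and weak/strong
mutation-class labels for the biased-gene-conversion control.

Every stochastic quantity is drawn from a caller-supplied seed, and the
per-gene ground truth (mean effect, omega_na, omega_a) is returned
alongside the gene records so downstream estimates can be validated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dfe import GammaDFE, omega_na_from_dfe, selection_kernel
from .sfs import (
    ClassCounts,
    GeneRecord,
    SiteFrequencySpectrum,
    MUTATION_CLASSES,
    NONSYNONYMOUS,
    SYNONYMOUS,
)

#: Published gene-level correlations between (log) recombination rate, gene
#: age, expression and protein length.  This matrix is NOT positive definite
#: (its entries were evidently estimated pairwise on different gene subsets),
#: so it cannot be realized by any joint distribution and is kept only as the
#: documented target.
RAW_COVARIATE_CORR = np.array(
    [
        [1.0, -0.62, -0.035, 0.10],
        [-0.62, 1.0, 0.87, 0.86],
        [-0.035, 0.87, 1.0, 0.44],
        [0.10, 0.86, 0.44, 1.0],
    ]
)

#: Default generator matrix: the minimum-distance positive-definite
#: completion that keeps the three strong age-row correlations exact
#: (age-expression 0.87, age-length 0.86, age-RR -0.62) and lets the weak
#: RR/length entries move (see docs/methods.md).  Order: rec_rate, age,
#: expression, length, on the latent (log) scale.
DEFAULT_COVARIATE_CORR = np.array(
    [
        [1.0, -0.62, -0.3189, -0.2489],
        [-0.62, 1.0, 0.87, 0.86],
        [-0.3189, 0.87, 1.0, 0.7850],
        [-0.2489, 0.86, 0.7850, 1.0],
    ]
)

_COV_ORDER = ("rec_rate", "age", "expression", "length")


def nearest_correlation(A: np.ndarray, min_eig: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Nearest correlation matrix by Higham's alternating projections."""
    A = np.asarray(A, dtype=float)
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        R = Y - dS
        w, V = np.linalg.eigh(R)
        X = (V * np.maximum(w, min_eig)) @ V.T
        dS = X - R
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.linalg.norm(Y - X) < 1e-12 and np.linalg.eigvalsh(Y).min() > 0:
            break
    return Y


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic world.

    Covariate margins are lognormal except gene age, which is an ordinal
    phylostratum 1..n_age_strata (1 = oldest) with a geometric-ish skew
    toward old genes.  The DFE link acts multiplicatively on the mean
    effect: log Ebar = intercept + sum_j slope_j * z_j over standardized
    log covariates, with the intercept calibrated so the gene-average
    omega_na hits ``target_mean_omega_na``.
    """

    n_genes: int = 15500
    n_chrom: int = 40
    seed: int = 0

    covariate_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_COVARIATE_CORR.copy()
    )
    rec_rate_median: float = 1.2      # cM/Mb
    rec_rate_sigma: float = 0.89      # ln-scale; raw CV ~ 1.1
    expression_median: float = 8.0    # TPM-like
    expression_sigma: float = 1.08    # raw CV ~ 1.5
    length_median: float = 430.0     # codons
    length_sigma: float = 1.0        # raw CV ~ 1.3
    n_age_strata: int = 19
    age_skew: float = 0.12           # P(stratum k) propto exp(-age_skew*(k-1))

    # DFE and rates
    dfe_shape: float = 0.4
    target_mean_omega_na: float = 0.19
    dfe_link_slopes: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.45,
            "expression": 0.5,
            "rec_rate": 0.7,
            "length": 0.2,
        }
    )
    omega_a: float = 0.04
    omega_a_link_slopes: Mapping[str, float] = field(default_factory=dict)
    theta: float = 1e-3               # per-site neutral mutation parameter
    div_rate: float = 0.012           # synonymous substitutions per site
    #: divergence-phase omega_na multiplier; values != 1 decouple the
    #: divergence-phase DFE from the polymorphism-phase DFE, emulating the
    #: population-contraction artifact.
    contraction_factor: float = 1.0

    # demography distortion of the SFS (absorbed by the nuisance r_i)
    singleton_excess: float = 1.3
    distortion_decay: float = 4.0
    r_profile: np.ndarray | None = None

    # GO / VIP structure
    n_go_categories: int = 50
    go_membership_mean: float = 2.0   # Poisson mean memberships per gene
    go_membership_exact: int | None = None  # overrides the Poisson draw
    vip_fraction: float = 0.13
    vip_omega_a_multiplier: float = 1.6
    #: additive omega_a effect: +delta for VIPs, -delta for non-VIPs
    #: (a fixed two-level effect with variance delta^2)
    vip_omega_a_delta: float = 0.0
    vip_mean_effect_multiplier: float | None = None  # default 2**(1/shape)
    go_omega_a_effects: np.ndarray | None = None     # additive, per category
    go_mean_effect_multipliers: np.ndarray | None = None

    # mutation classes (W = A/T, S = G/C); WW+SS defaults to 20% of counts
    with_class_split: bool = True
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"WW": 0.08, "SS": 0.12, "WS": 0.35, "SW": 0.45}
    )
    #: >1 inflates weak-to-strong *fixations* only (gBGC fixation bias)
    ws_fixation_bias: float = 1.0

    def __post_init__(self):
        M = np.asarray(self.covariate_corr, dtype=float)
        if M.shape != (4, 4) or not np.allclose(M, M.T):
            raise ValueError("covariate_corr must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(M).min() <= 0:
            suggestion = nearest_correlation(M)
            raise ValueError(
                "covariate correlation matrix is not positive definite; "
                f"nearest correlation matrix:\n{np.array_str(suggestion, precision=3)}"
            )
        fr = dict(self.class_fractions)
        if set(fr) != set(MUTATION_CLASSES):
            raise ValueError(f"class_fractions must have keys {MUTATION_CLASSES}")
        vals = np.array([fr[c] for c in MUTATION_CLASSES])
        if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
            raise ValueError("class_fractions must be non-negative and sum to 1")
        if self.vip_mean_effect_multiplier is None:
            self.vip_mean_effect_multiplier = 2.0 ** (1.0 / self.dfe_shape)

    @property
    def r_distortion(self) -> np.ndarray:
        """Demographic distortion profile r_i, i = 1..n-1."""
        if self.r_profile is not None:
            r = np.asarray(self.r_profile, dtype=float)
            if len(r) != self.n_chrom - 1:
                raise ValueError("r_profile must have length n_chrom - 1")
            return r
        i = np.arange(1, self.n_chrom)
        return 1.0 + (self.singleton_excess - 1.0) * np.exp(
            -(i - 1) / self.distortion_decay
        )


def gen_covariates(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw correlated covariates through a Gaussian copula.

    Returns a frame with columns gene_id, rec_rate, age_stratum, age_score,
    expression, length plus the standardized latent scores z_* used by the
    DFE link.  ``age_score = K + 1 - stratum`` increases with age so that
    correlation signs match the usual orientation (older genes: higher
    expression, longer, lower recombination).
    """
    M = np.asarray(cfg.covariate_corr, dtype=float)
    Lc = np.linalg.cholesky(M)
    Z = rng.standard_normal((cfg.n_genes, 4)) @ Lc.T
    z = {name: Z[:, k] for k, name in enumerate(_COV_ORDER)}

    rec_rate = cfg.rec_rate_median * np.exp(cfg.rec_rate_sigma * z["rec_rate"])
    expression = cfg.expression_median * np.exp(cfg.expression_sigma * z["expression"])
    length = np.maximum(
        30, np.round(cfg.length_median * np.exp(cfg.length_sigma * z["length"]))
    )

    K = cfg.n_age_strata
    w = np.exp(-cfg.age_skew * np.arange(K))
    w /= w.sum()
    # larger latent age = older = smaller stratum index (1 = oldest)
    u_old = stats.norm.sf(z["age"])
    stratum = 1 + np.searchsorted(np.cumsum(w)[:-1], u_old)
    age_score = K + 1 - stratum

    return pd.DataFrame(
        {
            "gene_id": [f"g{k:05d}" for k in range(cfg.n_genes)],
            "rec_rate": rec_rate,
            "age_stratum": stratum,
            "age_score": age_score,
            "expression": expression,
            "length": length,
            "z_rec_rate": z["rec_rate"],
            "z_age": z["age"],
            "z_expression": z["expression"],
            "z_length": z["length"],
        }
    )


def gen_go_annotations(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[frozenset[str]], np.ndarray]:
    """Assign GO memberships and VIP flags.

    Each gene joins k categories, k ~ Poisson(go_membership_mean) truncated
    at the number of categories (k = 0 allowed); VIP flags are Bernoulli
    with the configured fraction.
    """
    cats = [f"GO:{k:04d}" for k in range(cfg.n_go_categories)]
    go_ids = []
    for _ in range(cfg.n_genes):
        if cfg.go_membership_exact is not None:
            k = min(cfg.go_membership_exact, cfg.n_go_categories)
        else:
            k = min(int(rng.poisson(cfg.go_membership_mean)), cfg.n_go_categories)
        if k == 0:
            go_ids.append(frozenset())
        else:
            chosen = rng.choice(cfg.n_go_categories, size=k, replace=False)
            go_ids.append(frozenset(cats[j] for j in chosen))
    vip = rng.random(cfg.n_genes) < cfg.vip_fraction
    return go_ids, vip


def calibrate_mean_effect(shape: float, target_omega_na: float) -> float:
    """Mean effect Ebar at which a gamma DFE yields the given omega_na."""
    if not 0 < target_omega_na < 1:
        raise ValueError("target omega_na must lie in (0, 1)")
    f = lambda logE: omega_na_from_dfe(GammaDFE(shape, np.exp(logE))) - target_omega_na
    lo, hi = np.log(1e-4), np.log(1e8)
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-10)))


def _calibrate_intercept(
    kernel, shape: float, raw_mean_effects: np.ndarray, target: float,
    weights: np.ndarray | None = None,
) -> float:
    """Multiplier c so that the (site-weighted) mean of omega_na(c * Ebar_g)
    equals the target.

    Weighting by nonsynonymous sites makes the target an approximation of
    what a pooled fit over all genes reports, matching how the headline
    genome-wide rate is measured.
    """

    def gap(logc):
        E = np.clip(np.exp(logc) * raw_mean_effects, 1e-4, 1e7)
        w = kernel.omega_na_many(shape, E)
        return np.average(w, weights=weights) - target

    return float(np.exp(optimize.brentq(gap, np.log(1e-6), np.log(1e10), xtol=1e-9)))


def _split_counts(rng, value: int, probs: np.ndarray) -> np.ndarray:
    return rng.multinomial(value, probs)


def gen_gene_data(
    covariates: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    go_ids: Sequence[frozenset[str]] | None = None,
    vip: np.ndarray | None = None,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Draw gene records given covariates; returns (genes, ground truth).

    Per gene: the mean deleterious effect comes from the log-linear link
    (VIP and optional per-category adjustments applied), SFS counts are
    Poisson around the demography-distorted expectation, divergence counts
    are Poisson with rate L * d * (omega_na + omega_a); every count is then
    split multinomially into the four weak/strong mutation classes.
    """
    n = cfg.n_chrom
    kernel = selection_kernel(n)
    m = len(covariates)
    if go_ids is None:
        go_ids = [frozenset()] * m
    if vip is None:
        vip = np.zeros(m, dtype=bool)
    vip = np.asarray(vip, dtype=bool)

    z = {name: covariates[f"z_{name}"].to_numpy() for name in _COV_ORDER}
    log_E = np.zeros(m)
    for name, slope in cfg.dfe_link_slopes.items():
        log_E += slope * z[name]
    raw_E = np.exp(log_E)
    raw_E = np.where(vip, raw_E * cfg.vip_mean_effect_multiplier, raw_E)
    if cfg.go_mean_effect_multipliers is not None:
        mult = _category_values(go_ids, cfg.go_mean_effect_multipliers, neutral=1.0)
        raw_E = raw_E * mult
    codons_w = covariates["length"].to_numpy()
    scale_c = _calibrate_intercept(
        kernel, cfg.dfe_shape, raw_E, cfg.target_mean_omega_na,
        weights=codons_w,
    )
    mean_effect = np.clip(scale_c * raw_E, 1e-4, 1e7)
    omega_na = kernel.omega_na_many(cfg.dfe_shape, mean_effect)

    omega_a = np.full(m, cfg.omega_a, dtype=float)
    for name, slope in cfg.omega_a_link_slopes.items():
        omega_a = omega_a * np.exp(slope * z[name])
    omega_a = np.where(vip, omega_a * cfg.vip_omega_a_multiplier, omega_a)
    if cfg.vip_omega_a_delta:
        omega_a = omega_a + np.where(vip, cfg.vip_omega_a_delta, -cfg.vip_omega_a_delta)
    if cfg.go_omega_a_effects is not None:
        omega_a = omega_a + _category_values(go_ids, cfg.go_omega_a_effects, neutral=0.0)
    omega_a = np.maximum(omega_a, 0.0)

    codons = covariates["length"].to_numpy()
    L_syn = np.round(0.75 * codons)
    L_nonsyn = 3.0 * codons - L_syn

    i = np.arange(1, n)
    r = cfg.r_distortion
    phi = kernel.weights_many(cfg.dfe_shape, mean_effect)  # (m, n-1)
    mu_syn = cfg.theta * L_syn[:, None] * (r / i)[None, :]
    mu_non = cfg.theta * L_nonsyn[:, None] * r[None, :] * phi

    sfs_syn = rng.poisson(mu_syn)
    sfs_non = rng.poisson(mu_non)
    D_syn = rng.poisson(cfg.div_rate * L_syn)
    omega_div = cfg.contraction_factor * omega_na + omega_a
    # gBGC fixation bias inflates the weak-to-strong share of fixations
    frac = np.array([cfg.class_fractions[c] for c in MUTATION_CLASSES])
    bias_w = frac.copy()
    bias_w[MUTATION_CLASSES.index("WS")] *= cfg.ws_fixation_bias
    D_non = rng.poisson(cfg.div_rate * L_nonsyn * omega_div * bias_w.sum())
    frac_div = bias_w / bias_w.sum()

    if cfg.with_class_split:
        splits = _draw_class_splits(
            rng, L_syn, L_nonsyn, sfs_syn, sfs_non, D_syn, D_non, frac, frac_div
        )
    genes = []
    for g in range(m):
        split = splits[g] if cfg.with_class_split else None
        genes.append(
            GeneRecord(
                gene_id=covariates["gene_id"].iloc[g],
                L_syn=float(L_syn[g]),
                L_nonsyn=float(L_nonsyn[g]),
                sfs_syn=SiteFrequencySpectrum(n, sfs_syn[g].astype(float), site_class=SYNONYMOUS),
                sfs_nonsyn=SiteFrequencySpectrum(n, sfs_non[g].astype(float), site_class=NONSYNONYMOUS),
                D_syn=float(D_syn[g]),
                D_nonsyn=float(D_non[g]),
                rec_rate=float(covariates["rec_rate"].iloc[g]),
                age_stratum=int(covariates["age_stratum"].iloc[g]),
                expression=float(covariates["expression"].iloc[g]),
                length=float(codons[g]),
                vip=bool(vip[g]),
                go_ids=go_ids[g],
                class_split=split,
            )
        )
    truth = pd.DataFrame(
        {
            "gene_id": covariates["gene_id"],
            "mean_effect": mean_effect,
            "omega_na": omega_na,
            "omega_a": omega_a,
            "omega_div": omega_div,
            "vip": vip,
        }
    )
    return genes, truth


def _category_values(go_ids, per_category: np.ndarray, neutral: float) -> np.ndarray:
    """Mean per-category effect over each gene's memberships (neutral if none)."""
    per_category = np.asarray(per_category, dtype=float)
    out = np.full(len(go_ids), neutral)
    for k, ids in enumerate(go_ids):
        if ids:
            idx = [int(c.split(":")[1]) for c in ids]
            out[k] = per_category[idx].mean()
    return out


def _multinomial_chain(rng, counts, probs):
    """Vectorized multinomial split of an integer array along a new leading
    axis of len(probs), via a chain of conditional binomials."""
    rem = np.asarray(counts, dtype=np.int64)
    p_left = 1.0
    parts = []
    for p in probs[:-1]:
        cond = 0.0 if p_left <= 0 else min(1.0, p / p_left)
        draw = rng.binomial(rem, cond)
        parts.append(draw)
        rem = rem - draw
        p_left -= p
    parts.append(rem)
    return np.array(parts)


def _site_split(L, frac):
    """Deterministic largest-remainder partition of site totals (m,) -> (4, m)."""
    raw = frac[:, None] * np.asarray(L, dtype=float)[None, :]
    base = np.floor(raw)
    rem = np.round(L - base.sum(axis=0)).astype(int)
    order = np.argsort(-(raw - base), axis=0)
    for k in range(len(frac)):
        bump = rem > k
        base[order[k, bump], np.nonzero(bump)[0]] += 1
    return base


def _draw_class_splits(rng, Ls, Ln, sfs_s, sfs_n, Ds, Dn, frac, frac_div):
    """Partition every count of every gene into the WW/SS/WS/SW classes.

    Polymorphism and substitution counts split multinomially; site totals
    are partitioned deterministically in proportion to the
    mutational-opportunity fractions (largest-remainder rounding) so that
    class-restricted rates stay per-site comparable.
    """
    m = len(Ls)
    Ls_c = _site_split(Ls, frac)
    Ln_c = _site_split(Ln, frac)
    sfs_s_c = _multinomial_chain(rng, sfs_s, frac)      # (4, m, n-1)
    sfs_n_c = _multinomial_chain(rng, sfs_n, frac)
    Ds_c = _multinomial_chain(rng, Ds, frac)            # (4, m)
    Dn_c = _multinomial_chain(rng, Dn, frac_div)
    splits = []
    for g in range(m):
        split = {}
        for k, cls in enumerate(MUTATION_CLASSES):
            split[cls] = ClassCounts(
                L_syn=float(Ls_c[k, g]),
                L_nonsyn=float(Ln_c[k, g]),
                sfs_syn=sfs_s_c[k, g].astype(float),
                sfs_nonsyn=sfs_n_c[k, g].astype(float),
                D_syn=float(Ds_c[k, g]),
                D_nonsyn=float(Dn_c[k, g]),
            )
        splits.append(split)
    return splits


@dataclass
class SyntheticDataset:
    genes: list[GeneRecord]
    covariates: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig
    seed: int


def simulate_dataset(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete synthetic world from a single seed."""
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_cov, r_go, r_genes = [np.random.default_rng(s) for s in ss.spawn(3)]
    covariates = gen_covariates(cfg, r_cov)
    go_ids, vip = gen_go_annotations(cfg, r_go)
    genes, truth = gen_gene_data(covariates, cfg, r_genes, go_ids=go_ids, vip=vip)
    return SyntheticDataset(genes=genes, covariates=covariates, truth=truth,
                            config=cfg, seed=seed)


def write_truth_json(ds: SyntheticDataset, path: str | Path) -> None:
    """Ground-truth sidecar: per-gene truth plus the seeds and key settings."""
    payload = {
        "seed": ds.seed,
        "n_genes": len(ds.genes),
        "dfe_shape": ds.config.dfe_shape,
        "omega_a": ds.config.omega_a,
        "target_mean_omega_na": ds.config.target_mean_omega_na,
        "class_fractions": dict(ds.config.class_fractions),
        "per_gene": ds.truth.to_dict("list"),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
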