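"""Gene-function analyses: GO categories, VIP status, and their variance.

Three questions: do per-category rates differ beyond sampling noise (a
gene-label shuffle test that preserves the overlapping-membership
covariance structure); do virus-interacting proteins (VIPs) evolve
differently; and how much of the rate variance does the VIP axis explain
relative to the GO axis (a balanced two-way random-effects ANOVA on
site-downsampled, split-half cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dfe import FitError, FitOptions, GammaZeroFit, fit_gamma_zero
from .sfs import GeneRecord, PooledData, downsample_counts, pool_genes

logger = logging.getLogger(__name__)


def go_map_from_genes(genes: Sequence[GeneRecord]) -> dict[str, list[int]]:
    """category id -> indices of member genes (genes may repeat across
    categories; that is the point)."""
    out: dict[str, list[int]] = {}
    for j, g in enumerate(genes):
        for c in g.go_ids:
            out.setdefault(c, []).append(j)
    return out


@dataclass(frozen=True)
class CategoryEstimates:
    """Rates for one GO category, optionally split by VIP status."""

    category: str
    n_genes: int
    fit: GammaZeroFit | None = None
    n_vip: int = 0
    n_nonvip: int = 0
    fit_vip: GammaZeroFit | None = None
    fit_nonvip: GammaZeroFit | None = None


def estimate_by_category(
    genes: Sequence[GeneRecord],
    min_genes: int = 100,
    split_vip: bool = False,
    opts: FitOptions | None = None,
) -> list[CategoryEstimates]:
    """Pool and fit each GO category (each VIP group when splitting).

    A gene in three categories contributes its counts to all three.  Only
    categories with more than ``min_genes`` genes in every required group
    enter comparative analyses; smaller ones are skipped with a log entry.
    """
    genes = list(genes)
    gm = go_map_from_genes(genes)
    out = []
    for cat in sorted(gm):
        idx = gm[cat]
        members = [genes[j] for j in idx]
        if split_vip:
            vips = [g for g in members if g.vip]
            nons = [g for g in members if not g.vip]
            if len(vips) <= min_genes or len(nons) <= min_genes:
                logger.info("category %s below threshold (%d VIP / %d non-VIP); skipped",
                            cat, len(vips), len(nons))
                continue
            out.append(
                CategoryEstimates(
                    category=cat, n_genes=len(members),
                    n_vip=len(vips), n_nonvip=len(nons),
                    fit_vip=fit_gamma_zero(pool_genes(vips), opts),
                    fit_nonvip=fit_gamma_zero(pool_genes(nons), opts),
                )
            )
        else:
            if len(members) <= min_genes:
                logger.info("category %s below threshold (%d genes); skipped", cat, len(members))
                continue
            out.append(
                CategoryEstimates(
                    category=cat, n_genes=len(members),
                    fit=fit_gamma_zero(pool_genes(members), opts),
                )
            )
    return out


_DATA_FIELDS = ("L_syn", "L_nonsyn", "sfs_syn", "sfs_nonsyn", "D_syn", "D_nonsyn",
                "class_split")


def _permute_data_blocks(genes: list[GeneRecord], perm: np.ndarray) -> list[GeneRecord]:
    """Reassign each gene's data block (sites, spectra, substitutions) to a
    new gene label, keeping annotations and covariates with the label."""
    return [
        replace(g, **{f: getattr(genes[perm[j]], f) for f in _DATA_FIELDS})
        for j, g in enumerate(genes)
    ]


@dataclass(frozen=True)
class ShuffleTestResult:
    observed: float
    null: np.ndarray
    p: float
    response: str
    n_categories: int


def shuffle_test(
    genes: Sequence[GeneRecord],
    response: str = "omega_a",
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    min_genes: int = 100,
    opts: FitOptions | None = None,
) -> ShuffleTestResult:
    """Is there more among-category rate variation than labels explain?

    The statistic is the unweighted variance of per-category point
    estimates over eligible categories.  The null is built by permuting
    each gene's data block across gene labels — annotations stay put, so
    the overlapping-membership covariance structure is preserved exactly —
    and refitting.  p = (1 + #{null >= observed})/(n_shuffles + 1).
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)

    def statistic(gs):
        ests = estimate_by_category(gs, min_genes=min_genes, opts=opts)
        vals = [getattr(e.fit, response) for e in ests]
        if len(vals) < 2:
            raise ValueError("need at least 2 eligible categories")
        return float(np.var(vals)), len(vals)

    observed, n_cat = statistic(genes)
    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        perm = rng.permutation(len(genes))
        null[b], _ = statistic(_permute_data_blocks(genes, perm))
    p = (1 + int(np.sum(null >= observed))) / (n_shuffles + 1)
    return ShuffleTestResult(observed=observed, null=null, p=p,
                             response=response, n_categories=n_cat)


def vip_go_cells(
    genes: Sequence[GeneRecord], min_genes: int = 100
) -> dict[tuple[bool, str], PooledData]:
    """Pooled (VIP, category) cells for categories with enough genes in
    both VIP groups."""
    genes = list(genes)
    gm = go_map_from_genes(genes)
    cells = {}
    for cat in sorted(gm):
        members = [genes[j] for j in gm[cat]]
        vips = [g for g in members if g.vip]
        nons = [g for g in members if not g.vip]
        if len(vips) <= min_genes or len(nons) <= min_genes:
            continue
        cells[(True, cat)] = pool_genes(vips)
        cells[(False, cat)] = pool_genes(nons)
    return cells


def balance_cells(
    cells: Mapping[tuple[bool, str], PooledData],
    target_sites: int = 200_000,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[bool, str], PooledData]:
    """Downsample every cell to the same number of combined sites.

    Equalizing the site totals equalizes the error variance across cells,
    which the two-way ANOVA requires.  Cells below the target cannot be
    enlarged by without-replacement sampling and are dropped (with a
    warning); if either VIP group of a category is dropped the whole
    category goes.
    """
    rng = np.random.default_rng(seed)
    kept: dict[tuple[bool, str], PooledData] = {}
    dropped_cats = set()
    for key, cell in sorted(cells.items(), key=lambda kv: (kv[0][1], not kv[0][0])):
        if cell.total_sites < target_sites:
            logger.warning("cell %s has %.0f < %d sites; dropped", key,
                           cell.total_sites, target_sites)
            dropped_cats.add(key[1])
            continue
        kept[key] = downsample_counts(cell, target_sites, rng)
    return {k: v for k, v in kept.items() if k[1] not in dropped_cats}


def split_half(
    cell: PooledData, seed: int | np.random.Generator = 0
) -> tuple[PooledData, PooledData]:
    """Hypergeometric split of a cell into two halves of equal site count.

    One half receives a multivariate-hypergeometric draw over half the
    sites of each site class; the complement forms the other half, so the
    halves sum exactly to the cell and give two independent rate
    estimates with (approximately) equal error variance.
    """
    rng = np.random.default_rng(seed)
    Ls = int(round(cell.L_syn))
    Ln = int(round(cell.L_nonsyn))
    target = Ls // 2 + Ln // 2
    half1 = downsample_counts(cell, target, rng)
    half2 = PooledData(
        L_syn=cell.L_syn - half1.L_syn,
        L_nonsyn=cell.L_nonsyn - half1.L_nonsyn,
        sfs_syn=replace(cell.sfs_syn,
                        counts=np.round(cell.sfs_syn.counts) - half1.sfs_syn.counts),
        sfs_nonsyn=replace(cell.sfs_nonsyn,
                           counts=np.round(cell.sfs_nonsyn.counts) - half1.sfs_nonsyn.counts),
        D_syn=round(cell.D_syn) - half1.D_syn,
        D_nonsyn=round(cell.D_nonsyn) - half1.D_nonsyn,
        n_genes=cell.n_genes,
        gene_ids=cell.gene_ids,
    )
    return half1, half2


@dataclass(frozen=True)
class VarianceDecomposition:
    """Random-effects variance components from the balanced 2 x G x 2 design.

    Components are method-of-moments estimates truncated at zero; the
    primary extraction subtracts the interaction mean square from the main
    effects (``sigma2_*``); the ``*_err_denom`` variants subtract the error
    mean square instead.  ``ratio`` is sigma2_vip / sigma2_go, flagged
    undefined when sigma2_go truncates to zero.
    """

    sigma2_vip: float
    sigma2_go: float
    sigma2_interaction: float
    sigma2_error: float
    ratio: float
    ratio_defined: bool
    sigma2_vip_err_denom: float
    sigma2_go_err_denom: float
    n_categories: int
    mean_squares: dict

    @property
    def components(self) -> dict:
        return {
            "vip": self.sigma2_vip,
            "go": self.sigma2_go,
            "interaction": self.sigma2_interaction,
            "error": self.sigma2_error,
        }


def variance_components(estimates: np.ndarray) -> VarianceDecomposition:
    """Partition rate variance between the VIP axis and the GO axis.

    ``estimates`` has shape (2, G, 2): VIP level x category x split-half
    replicate, with no missing cells.  Both axes are treated as random
    effects; with a = 2 VIP levels, b = G categories and n = 2 replicates
    the expected mean squares give

        sigma2_error = MS_error
        sigma2_int   = max(0, (MS_int - MS_error)/2)
        sigma2_go    = max(0, (MS_GO  - MS_int)/(2*2))
        sigma2_vip   = max(0, (MS_VIP - MS_int)/(2*G))
    """
    y = np.asarray(estimates, dtype=float)
    if y.ndim != 3 or y.shape[0] != 2 or y.shape[2] != 2:
        raise ValueError(f"estimates must have shape (2, G, 2), got {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = np.argwhere(~np.isfinite(y))
        raise ValueError(f"incomplete table: missing cells at indices {bad.tolist()}")
    a, G, n_rep = y.shape
    grand = y.mean()
    m_vip = y.mean(axis=(1, 2))
    m_go = y.mean(axis=(0, 2))
    m_cell = y.mean(axis=2)

    ss_vip = G * n_rep * np.sum((m_vip - grand) ** 2)
    ss_go = a * n_rep * np.sum((m_go - grand) ** 2)
    ss_int = n_rep * np.sum((m_cell - m_vip[:, None] - m_go[None, :] + grand) ** 2)
    ss_err = np.sum((y - m_cell[:, :, None]) ** 2)

    ms_vip = ss_vip / (a - 1)
    ms_go = ss_go / (G - 1)
    ms_int = ss_int / ((a - 1) * (G - 1))
    ms_err = ss_err / (a * G * (n_rep - 1))

    s2_err = ms_err
    s2_int = max(0.0, (ms_int - ms_err) / n_rep)
    s2_go = max(0.0, (ms_go - ms_int) / (n_rep * a))
    s2_vip = max(0.0, (ms_vip - ms_int) / (n_rep * G))
    s2_go_alt = max(0.0, (ms_go - ms_err) / (n_rep * a))
    s2_vip_alt = max(0.0, (ms_vip - ms_err) / (n_rep * G))
    defined = s2_go > 0
    return VarianceDecomposition(
        sigma2_vip=s2_vip,
        sigma2_go=s2_go,
        sigma2_interaction=s2_int,
        sigma2_error=s2_err,
        ratio=s2_vip / s2_go if defined else np.nan,
        ratio_defined=defined,
        sigma2_vip_err_denom=s2_vip_alt,
        sigma2_go_err_denom=s2_go_alt,
        n_categories=G,
        mean_squares={"vip": ms_vip, "go": ms_go, "interaction": ms_int, "error": ms_err},
    )


def variance_partition(
    genes: Sequence[GeneRecord],
    response: str = "omega_a",
    target_sites: int = 200_000,
    min_genes: int = 100,
    seed: int | np.random.Generator = 0,
    opts: FitOptions | None = None,
) -> tuple[VarianceDecomposition, pd.DataFrame]:
    """End-to-end variance partition: cells -> balance -> split -> fit -> ANOVA."""
    rng = np.random.default_rng(seed)
    cells = vip_go_cells(genes, min_genes=min_genes)
    balanced = balance_cells(cells, target_sites=target_sites, seed=rng)
    cats = sorted({cat for _, cat in balanced})
    if len(cats) < 2:
        raise ValueError("need at least 2 eligible categories for the variance partition")
    table = np.empty((2, len(cats), 2))
    rows = []
    for gi, cat in enumerate(cats):
        for vi, vip_level in enumerate((True, False)):
            halves = split_half(balanced[(vip_level, cat)], rng)
            for hi, half in enumerate(halves):
                fit = fit_gamma_zero(half, opts)
                table[vi, gi, hi] = getattr(fit, response)
                rows.append({"category": cat, "vip": vip_level, "half": hi,
                             response: table[vi, gi, hi]})
    return variance_components(table), pd.DataFrame(rows)
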