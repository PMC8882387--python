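"""Binned correlation of evolutionary rates with gene-level factors.

Genes are binned by a factor (20 near-equal quantile bins, or one bin per
age stratum), each bin is pooled and fitted, and the per-bin rate estimate
is correlated (Pearson, on log10-transformed bin means by default) with the
bin-mean factor.  Three confound controls are provided:

* modal-value restriction: keep genes within +/-0.5 SD of the cofactor's
  modal (log) value, shrinking the cofactor's spread;
* predicted-correlation comparison: the correlation expected between Y and
  X if both are driven solely by a third factor Z is r_YZ * r_XZ, compared
  with the observed correlation over bootstrap replicates;
* dN window: restrict to genes in a band of nonsynonymous rates to control
  for the difficulty of detecting fast-evolving genes in distant taxa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dfe import FitError, FitOptions, GammaZeroFit, fit_gamma_zero
from .sfs import GeneRecord, pool_genes

logger = logging.getLogger(__name__)

FACTORS = ("rec_rate", "age", "expression", "length")


def factor_value(gene: GeneRecord, factor: str, max_stratum: int = 19) -> float:
    """Numeric value of a binning/correlation factor for one gene.

    ``age`` maps the phylostratum (1 = oldest) to an age score
    ``max_stratum + 1 - stratum`` that increases with gene age, so
    correlation signs read naturally (e.g. older genes evolve slower).
    """
    if factor == "rec_rate":
        v = gene.rec_rate
    elif factor == "age":
        v = None if gene.age_stratum is None else max_stratum + 1 - gene.age_stratum
    elif factor == "expression":
        v = gene.expression
    elif factor == "length":
        v = gene.length
    elif factor == "dn":
        return gene.dn
    else:
        raise ValueError(f"unknown factor {factor!r}")
    if v is None:
        raise ValueError(f"gene {gene.gene_id} lacks factor {factor!r}")
    return float(v)


def _factor_values(genes: Sequence[GeneRecord], factor: str) -> np.ndarray:
    max_stratum = max((g.age_stratum or 0) for g in genes) if factor == "age" else 19
    return np.array([factor_value(g, factor, max_stratum) for g in genes])


@dataclass
class BinnedAnalysis:
    """Bin assignments and (after estimation) per-bin fits for one factor."""

    factor: str
    mode: str
    assignments: dict[str, int]            # gene_id -> bin index
    bins: pd.DataFrame                     # bin, n_genes, mean_factor, log10_mean_factor
    fits: list[GammaZeroFit | None] = field(default_factory=list)
    failed_bins: list[int] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation over bins with a parametric two-sided p-value."""

    r: float
    p: float
    n_bins: int
    transform: str
    response: str
    factor: str
    role: str = "observed"


def bin_by_factor(
    genes: Sequence[GeneRecord],
    factor: str,
    k: int = 20,
    mode: str = "quantile",
) -> BinnedAnalysis:
    """Partition genes into factor bins.

    Quantile mode sorts by (factor value, gene_id) — the gene_id tiebreak
    makes the assignment deterministic — and splits into k contiguous
    groups whose sizes differ by at most one.  Stratum mode makes one bin
    per age stratum (oldest first).
    """
    genes = list(genes)
    if mode == "quantile":
        if k > len(genes):
            raise ValueError(f"k = {k} exceeds the number of genes ({len(genes)})")
        vals = _factor_values(genes, factor)
        order = sorted(range(len(genes)), key=lambda j: (vals[j], genes[j].gene_id))
        chunks = np.array_split(np.array(order), k)
        assignments = {}
        rows = []
        for b, chunk in enumerate(chunks):
            for j in chunk:
                assignments[genes[j].gene_id] = b
            mv = float(np.mean(vals[chunk]))
            rows.append({"bin": b, "n_genes": len(chunk), "mean_factor": mv,
                         "log10_mean_factor": math.log10(mv) if mv > 0 else np.nan})
    elif mode == "stratum":
        strata = sorted({g.age_stratum for g in genes})
        if any(s is None for s in strata):
            raise ValueError("stratum mode requires age_stratum on every gene")
        vals = _factor_values(genes, "age")
        assignments = {}
        rows = []
        for b, s in enumerate(strata):
            members = [j for j, g in enumerate(genes) if g.age_stratum == s]
            for j in members:
                assignments[genes[j].gene_id] = b
            mv = float(np.mean(vals[members]))
            rows.append({"bin": b, "n_genes": len(members), "mean_factor": mv,
                         "log10_mean_factor": math.log10(mv) if mv > 0 else np.nan})
        factor = "age"
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return BinnedAnalysis(
        factor=factor, mode=mode, assignments=assignments, bins=pd.DataFrame(rows)
    )


def estimate_bins(
    binned: BinnedAnalysis,
    genes: Sequence[GeneRecord],
    opts: FitOptions | None = None,
) -> BinnedAnalysis:
    """Pool and fit each bin; failed bins are flagged and later excluded."""
    by_bin: dict[int, list[GeneRecord]] = {}
    for g in genes:
        if g.gene_id in binned.assignments:
            by_bin.setdefault(binned.assignments[g.gene_id], []).append(g)
    fits: list[GammaZeroFit | None] = []
    failed = []
    for b in range(binned.n_bins):
        try:
            fits.append(fit_gamma_zero(pool_genes(by_bin[b]), opts))
        except (FitError, ValueError) as exc:
            logger.warning("bin %d fit failed (%s); excluded from correlation", b, exc)
            fits.append(None)
            failed.append(b)
    binned.fits = fits
    binned.failed_bins = failed
    return binned


_RESPONSES = {
    "omega_a": lambda f: f.omega_a,
    "omega_na": lambda f: f.omega_na,
    "alpha": lambda f: f.alpha,
    "log_mean_S": lambda f: math.log10(f.dfe.mean_effect),
}


def correlate_bins(
    binned: BinnedAnalysis,
    response: str = "omega_a",
    transform: str = "log10",
) -> CorrelationResult:
    """Pearson correlation between the per-bin response and bin-mean factor.

    ``transform="log10"`` correlates against the log10 of the bin means
    (logs are taken of all factors); ``"linear"`` uses raw means.  The
    p-value comes from the t distribution with n_bins - 2 df.
    """
    if response not in _RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    ok = [b for b in range(binned.n_bins) if binned.fits and binned.fits[b] is not None]
    if len(ok) < 3:
        raise ValueError("need at least 3 estimated bins to correlate")
    y = np.array([_RESPONSES[response](binned.fits[b]) for b in ok])
    col = "log10_mean_factor" if transform == "log10" else "mean_factor"
    x = binned.bins[col].to_numpy()[ok]
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), n_bins=len(ok), transform=transform,
        response=response, factor=binned.factor,
    )


@dataclass(frozen=True)
class ModalControlResult:
    genes: list[GeneRecord]
    cofactor: str
    mode_log10: float
    sd_log10: float
    cv_before: float
    cv_after: float


def modal_control(genes: Sequence[GeneRecord], cofactor: str) -> ModalControlResult:
    """Restrict to genes near the cofactor's modal value.

    The mode is located on the log10 scale as the midpoint of the tallest
    Freedman-Diaconis histogram bin; genes within +/-0.5 SD (of the log10
    values) around it are kept.  The coefficient of variation of the raw
    cofactor before and after restriction is reported as the control
    diagnostic — restriction can only shrink the spread.
    """
    genes = list(genes)
    vals = _factor_values(genes, cofactor)
    if np.any(vals <= 0):
        raise ValueError("modal control requires strictly positive cofactor values")
    logv = np.log10(vals)
    if np.ptp(logv) == 0:
        kept = genes
        mode = float(logv[0])
    else:
        hist, edges = np.histogram(logv, bins="fd")
        tallest = int(np.argmax(hist))
        mode = 0.5 * (edges[tallest] + edges[tallest + 1])
        half_width = 0.5 * logv.std()
        keep = np.abs(logv - mode) <= half_width
        kept = [g for g, k in zip(genes, keep) if k]
    if not kept:
        raise ValueError("modal restriction removed every gene")
    before = vals.std() / vals.mean()
    after_vals = _factor_values(kept, cofactor)
    after = after_vals.std() / after_vals.mean()
    return ModalControlResult(
        genes=kept, cofactor=cofactor, mode_log10=float(mode),
        sd_log10=float(logv.std()), cv_before=float(before), cv_after=float(after),
    )


def predicted_correlation(r_yz: float, r_xz: float) -> float:
    """Correlation expected between Y and X if both are driven only by Z.

    sqrt(r_YZ^2 * r_XZ^2) signed positive iff r_YZ and r_XZ share sign —
    algebraically the product r_YZ * r_XZ.
    """
    if not (-1 <= r_yz <= 1 and -1 <= r_xz <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    return float(r_yz * r_xz)


def dn_modal_filter(
    genes: Sequence[GeneRecord], lo: float = 0.002, hi: float = 0.007
) -> list[GeneRecord]:
    """Keep genes whose dN lies in [lo, hi] (inclusive).

    The default window brackets the second mode of the bimodal dN
    distribution (many genes have dN = 0), controlling for the rate at
    which a protein evolves in the gene-age analysis.
    """
    return [g for g in genes if lo <= g.dn <= hi]


@dataclass(frozen=True)
class PredictedObservedComparison:
    """Bootstrap comparison of observed vs predicted bin-level correlation."""

    proportion: float          # fraction of replicates with predicted/observed > 1
    observed_r: float
    predicted_r: float
    records: pd.DataFrame
    n_excluded: int
    response: str
    x: str
    z: str


def compare_predicted_observed(
    genes: Sequence[GeneRecord],
    response: str,
    x: str,
    z: str,
    k: int = 20,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    opts: FitOptions | None = None,
    transform: str = "log10",
) -> PredictedObservedComparison:
    """Is the Y-X correlation stronger than its Z-induced prediction?

    Genes are grouped into X bins (held fixed); each bootstrap replicate
    resamples genes with replacement within every bin, refits the per-bin
    rates and computes the observed r_YX together with the predicted
    r_YZ * r_XZ from the replicate's bin-level correlations.  The reported
    proportion of replicates with predicted/observed > 1 is read as a
    significance level: <= 0.05 means the observed correlation is
    significantly greater in magnitude than predicted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    binned = bin_by_factor(genes, x, k=k)
    by_bin: dict[int, list[GeneRecord]] = {}
    for g in genes:
        by_bin.setdefault(binned.assignments[g.gene_id], []).append(g)

    xv = {g.gene_id: factor_value(g, x, _max_stratum(genes)) for g in genes}
    zv = {g.gene_id: factor_value(g, z, _max_stratum(genes)) for g in genes}

    def bin_stats(members_by_bin):
        ys, xs, zs = [], [], []
        for b in range(binned.n_bins):
            members = members_by_bin[b]
            fit = fit_gamma_zero(pool_genes(members), opts)
            ys.append(_RESPONSES[response](fit))
            mx = np.mean([xv[g.gene_id] for g in members])
            mz = np.mean([zv[g.gene_id] for g in members])
            if transform == "log10":
                mx, mz = math.log10(mx), math.log10(mz)
            xs.append(mx)
            zs.append(mz)
        return np.array(ys), np.array(xs), np.array(zs)

    y0, x0, z0 = bin_stats(by_bin)
    obs_point = float(stats.pearsonr(x0, y0).statistic)
    pred_point = predicted_correlation(
        float(stats.pearsonr(z0, y0).statistic),
        float(stats.pearsonr(z0, x0).statistic),
    )

    rows = []
    n_excluded = 0
    exceed = 0
    for b_rep in range(B):
        resampled = {
            b: [members[j] for j in rng.integers(0, len(members), size=len(members))]
            for b, members in by_bin.items()
        }
        y, xb, zb = bin_stats(resampled)
        r_yx = float(stats.pearsonr(xb, y).statistic)
        r_yz = float(stats.pearsonr(zb, y).statistic)
        r_xz = float(stats.pearsonr(zb, xb).statistic)
        pred = predicted_correlation(r_yz, r_xz)
        if r_yx == 0:
            n_excluded += 1
            ratio = np.nan
        else:
            ratio = pred / r_yx
            if ratio > 1:
                exceed += 1
        rows.append({"replicate": b_rep, "observed": r_yx, "r_yz": r_yz,
                     "r_xz": r_xz, "predicted": pred, "ratio": ratio})
    n_valid = B - n_excluded
    if n_excluded:
        logger.warning("%d replicates had observed r = 0 and were excluded", n_excluded)
    return PredictedObservedComparison(
        proportion=exceed / n_valid if n_valid else np.nan,
        observed_r=obs_point,
        predicted_r=pred_point,
        records=pd.DataFrame(rows),
        n_excluded=n_excluded,
        response=response,
        x=x,
        z=z,
    )


def _max_stratum(genes) -> int:
    strata = [g.age_stratum for g in genes if g.age_stratum is not None]
    return max(strata) if strata else 19
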