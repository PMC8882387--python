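"""Core domain types and site-frequency-spectrum algebra.

The unit of data is the gene: codon-degeneracy-weighted counts of
synonymous and nonsynonymous sites, an unfolded (or folded) site-frequency
spectrum (SFS) per site class, lineage substitution counts, and the
gene-level covariates used by the downstream analyses.  Genes are pooled
(summed element-wise) before model fitting because single genes carry too
little polymorphism to estimate anything.

Site counts are real-valued (degeneracy weighting makes them fractional);
polymorphism and substitution counts are integers except where an
expected-value projection has been applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

#: Mutation class labels: W = weak (A/T), S = strong (G/C); first letter ancestral.
MUTATION_CLASSES = ("WW", "SS", "WS", "SW")


class GeneTableError(ValueError):
    """Malformed gene table (bad SFS length, negative counts, ...)."""


def _n_classes(sample_size: int, folded: bool) -> int:
    return sample_size // 2 if folded else sample_size - 1


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Counts of derived variants by sample-frequency class for one site class.

    Parameters
    ----------
    sample_size
        Number of sampled chromosomes n (>= 4).
    counts
        Vector indexed by derived-allele count i = 1..n-1 (unfolded) or by
        minor-allele count 1..floor(n/2) (folded).  May be fractional after
        an expected-value projection.
    folded
        Whether the spectrum is folded (unpolarized).
    site_class
        ``"synonymous"`` or ``"nonsynonymous"``.
    """

    sample_size: int
    counts: np.ndarray
    folded: bool = False
    site_class: str = SYNONYMOUS

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.sample_size < 4:
            raise ValueError(f"sample_size must be >= 4, got {self.sample_size}")
        expected = _n_classes(self.sample_size, self.folded)
        if counts.ndim != 1 or len(counts) != expected:
            raise ValueError(
                f"SFS length {counts.shape} does not match sample_size "
                f"{self.sample_size} (folded={self.folded}): expected {expected}"
            )
        if np.any(counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if self.site_class not in (SYNONYMOUS, NONSYNONYMOUS):
            raise ValueError(f"unknown site_class {self.site_class!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "SiteFrequencySpectrum") -> "SiteFrequencySpectrum":
        if (self.sample_size, self.folded, self.site_class) != (
            other.sample_size,
            other.folded,
            other.site_class,
        ):
            raise ValueError(
                "cannot add spectra with different sample sizes, foldedness or "
                "site classes; project to a common sample size first"
            )
        return replace(self, counts=self.counts + other.counts)


def fold_sfs(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Fold an unfolded SFS onto minor-allele-count classes.

    Entry j of the folded SFS is ``counts[j] + counts[n-j]`` for j < n/2 and
    ``counts[n/2]`` at j = n/2 when n is even.  The total count is preserved.
    """
    if sfs.folded:
        raise ValueError("SFS is already folded")
    n = sfs.sample_size
    half = n // 2
    c = sfs.counts
    out = np.zeros(half)
    for j in range(1, half + 1):
        if j == n - j:
            out[j - 1] = c[j - 1]
        else:
            out[j - 1] = c[j - 1] + c[n - j - 1]
    return SiteFrequencySpectrum(n, out, folded=True, site_class=sfs.site_class)


def project_sfs(sfs: SiteFrequencySpectrum, m: int) -> SiteFrequencySpectrum:
    """Expected-value (hypergeometric) projection to a smaller sample size m.

    Entry j at size m is ``sum_i counts[i] P(j | hypergeometric draw of m
    from n with i derived)`` restricted to 1 <= j <= m-1, so mass projected
    onto the monomorphic classes 0 and m is dropped.  Output counts are
    fractional in general; they are expected values, suitable for pooling
    and model expectations but not for count-based resampling.
    """
    if sfs.folded:
        raise ValueError("projection requires an unfolded SFS")
    n = sfs.sample_size
    if not 4 <= m < n:
        raise ValueError(f"projection size must satisfy 4 <= m < n, got m={m}, n={n}")
    i = np.arange(1, n)
    j = np.arange(1, m)
    # P(j | i) for a draw of m chromosomes out of n carrying i derived copies
    pmat = hypergeom.pmf(j[:, None], n, i[None, :], m)
    return SiteFrequencySpectrum(
        m, pmat @ sfs.counts, folded=False, site_class=sfs.site_class
    )


@dataclass(frozen=True)
class ClassCounts:
    """One mutation class's share of a gene's sites, SFS and substitutions."""

    L_syn: float
    L_nonsyn: float
    sfs_syn: np.ndarray
    sfs_nonsyn: np.ndarray
    D_syn: float
    D_nonsyn: float

    def __post_init__(self):
        object.__setattr__(self, "sfs_syn", np.asarray(self.sfs_syn, dtype=float))
        object.__setattr__(self, "sfs_nonsyn", np.asarray(self.sfs_nonsyn, dtype=float))


@dataclass(frozen=True)
class GeneRecord:
    """One gene: sites, spectra, divergence, covariates and annotation.

    ``class_split``, when present, partitions every count (and the site
    totals) into the four weak/strong mutation classes used by the biased
    gene conversion control; components must sum to the totals.
    """

    gene_id: str
    L_syn: float
    L_nonsyn: float
    sfs_syn: SiteFrequencySpectrum
    sfs_nonsyn: SiteFrequencySpectrum
    D_syn: float
    D_nonsyn: float
    rec_rate: float | None = None
    age_stratum: int | None = None
    expression: float | None = None
    length: float | None = None
    vip: bool = False
    go_ids: frozenset[str] = field(default_factory=frozenset)
    class_split: Mapping[str, ClassCounts] | None = None

    def __post_init__(self):
        if self.L_syn < 0 or self.L_nonsyn < 0:
            raise ValueError(f"{self.gene_id}: negative site counts")
        if self.D_syn < 0 or self.D_nonsyn < 0:
            raise ValueError(f"{self.gene_id}: negative substitution counts")
        if self.D_syn > self.L_syn or self.D_nonsyn > self.L_nonsyn:
            raise ValueError(
                f"{self.gene_id}: substitution count exceeds site count"
            )
        if self.sfs_syn.site_class != SYNONYMOUS:
            object.__setattr__(self, "sfs_syn", replace(self.sfs_syn, site_class=SYNONYMOUS))
        if self.sfs_nonsyn.site_class != NONSYNONYMOUS:
            object.__setattr__(
                self, "sfs_nonsyn", replace(self.sfs_nonsyn, site_class=NONSYNONYMOUS)
            )
        object.__setattr__(self, "go_ids", frozenset(self.go_ids))
        if self.class_split is not None:
            self._check_class_split()

    def _check_class_split(self):
        cs = self.class_split
        for name, total, getter in [
            ("L_syn", self.L_syn, lambda c: c.L_syn),
            ("L_nonsyn", self.L_nonsyn, lambda c: c.L_nonsyn),
            ("D_syn", self.D_syn, lambda c: c.D_syn),
            ("D_nonsyn", self.D_nonsyn, lambda c: c.D_nonsyn),
        ]:
            s = sum(getter(c) for c in cs.values())
            if not np.isclose(s, total, rtol=1e-6, atol=1e-6):
                raise ValueError(
                    f"{self.gene_id}: class_split {name} components sum to {s}, "
                    f"expected {total}"
                )
        for attr, ref in [("sfs_syn", self.sfs_syn), ("sfs_nonsyn", self.sfs_nonsyn)]:
            s = sum(getattr(c, attr) for c in cs.values())
            if not np.allclose(s, ref.counts, rtol=1e-6, atol=1e-6):
                raise ValueError(f"{self.gene_id}: class_split {attr} does not sum to total")

    @property
    def dn(self) -> float:
        """Nonsynonymous substitutions per nonsynonymous site."""
        return self.D_nonsyn / self.L_nonsyn

    @property
    def ds(self) -> float:
        return self.D_syn / self.L_syn

    @property
    def sample_size(self) -> int:
        return self.sfs_syn.sample_size


@dataclass(frozen=True)
class PooledData:
    """Element-wise sum of a set of genes; the substrate of every model fit."""

    L_syn: float
    L_nonsyn: float
    sfs_syn: SiteFrequencySpectrum
    sfs_nonsyn: SiteFrequencySpectrum
    D_syn: float
    D_nonsyn: float
    n_genes: int
    gene_ids: tuple[str, ...] = ()

    @property
    def sample_size(self) -> int:
        return self.sfs_syn.sample_size

    @property
    def folded(self) -> bool:
        return self.sfs_syn.folded

    @property
    def dn_ds(self) -> float:
        """(D_nonsyn/L_nonsyn) / (D_syn/L_syn)."""
        return (self.D_nonsyn / self.L_nonsyn) / (self.D_syn / self.L_syn)

    @property
    def total_sites(self) -> float:
        return self.L_syn + self.L_nonsyn


def pool_genes(genes: Sequence[GeneRecord]) -> PooledData:
    """Sum counts element-wise over genes.

    All spectra must share the same sample size and foldedness; mixed sample
    sizes must be harmonized with :func:`project_sfs` first.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("cannot pool an empty gene list")
    sizes = {(g.sample_size, g.sfs_syn.folded) for g in genes}
    if len(sizes) > 1:
        raise ValueError(
            f"genes mix sample sizes / foldedness {sorted(sizes)}; "
            "project spectra to a common sample size before pooling"
        )
    g0 = genes[0]
    syn_sum = np.zeros_like(g0.sfs_syn.counts)
    non_sum = np.zeros_like(g0.sfs_nonsyn.counts)
    for g in genes:
        syn_sum += g.sfs_syn.counts
        non_sum += g.sfs_nonsyn.counts
    return PooledData(
        L_syn=float(sum(g.L_syn for g in genes)),
        L_nonsyn=float(sum(g.L_nonsyn for g in genes)),
        sfs_syn=replace(g0.sfs_syn, counts=syn_sum),
        sfs_nonsyn=replace(g0.sfs_nonsyn, counts=non_sum),
        D_syn=float(sum(g.D_syn for g in genes)),
        D_nonsyn=float(sum(g.D_nonsyn for g in genes)),
        n_genes=len(genes),
        gene_ids=tuple(g.gene_id for g in genes),
    )


def downsample_counts(
    pooled: PooledData, target_sites: int, seed: int | np.random.Generator
) -> PooledData:
    """Downsample a pooled block to ``target_sites`` combined sites.

    Sites are drawn without replacement from the combined synonymous +
    nonsynonymous site pool, and every polymorphism and substitution count
    follows the corresponding (multivariate) hypergeometric law, so
    expectations scale by ``target_sites / total_sites``.  Counts are
    rounded to integers first (site counts are degeneracy-weighted reals).
    """
    rng = np.random.default_rng(seed)
    Ls = int(round(pooled.L_syn))
    Ln = int(round(pooled.L_nonsyn))
    total = Ls + Ln
    if target_sites > total:
        raise ValueError(
            f"target_sites {target_sites} exceeds available sites {total}"
        )
    if target_sites == total:
        return pooled
    new_Ls = int(rng.hypergeometric(Ls, Ln, target_sites))
    new_Ln = target_sites - new_Ls

    def _sample_class(L, new_L, sfs, D):
        counts = np.round(sfs.counts).astype(np.int64)
        D = int(round(D))
        empty = L - counts.sum() - D
        if empty < 0:
            raise ValueError("polymorphism + substitution counts exceed site count")
        colors = np.concatenate([counts, [D, empty]])
        draw = rng.multivariate_hypergeometric(colors, new_L)
        return (
            replace(sfs, counts=draw[:-2].astype(float)),
            float(draw[-2]),
        )

    sfs_syn, D_syn = _sample_class(Ls, new_Ls, pooled.sfs_syn, pooled.D_syn)
    sfs_nonsyn, D_nonsyn = _sample_class(Ln, new_Ln, pooled.sfs_nonsyn, pooled.D_nonsyn)
    return PooledData(
        L_syn=float(new_Ls),
        L_nonsyn=float(new_Ln),
        sfs_syn=sfs_syn,
        sfs_nonsyn=sfs_nonsyn,
        D_syn=D_syn,
        D_nonsyn=D_nonsyn,
        n_genes=pooled.n_genes,
        gene_ids=pooled.gene_ids,
    )


# ---------------------------------------------------------------------------
# Gene table I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "gene_id",
    "n_chrom",
    "L_syn",
    "L_nonsyn",
    "sfs_syn",
    "sfs_nonsyn",
    "D_syn",
    "D_nonsyn",
]
_COVARIATE_COLUMNS = ["rec_rate", "age_stratum", "expression", "length", "vip", "go_ids"]


def _format_sfs(counts: np.ndarray) -> str:
    vals = []
    for c in counts:
        if float(c).is_integer():
            vals.append(str(int(c)))
        else:
            vals.append(repr(float(c)))
    return ",".join(vals)


def _parse_sfs(text, gene_id: str, row: int, n: int, label: str) -> np.ndarray:
    try:
        counts = np.array([float(x) for x in str(text).split(",")])
    except ValueError as exc:
        raise GeneTableError(
            f"row {row} (gene {gene_id}): cannot parse {label}: {exc}"
        ) from None
    if len(counts) != n - 1:
        raise GeneTableError(
            f"row {row} (gene {gene_id}): {label} has {len(counts)} entries, "
            f"expected n-1 = {n - 1} for n_chrom = {n}"
        )
    if np.any(counts < 0):
        raise GeneTableError(f"row {row} (gene {gene_id}): negative counts in {label}")
    return counts


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write genes to the tab-separated gene-table format (UTF-8)."""
    rows = []
    has_split = False
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "n_chrom": g.sample_size,
            "L_syn": g.L_syn,
            "L_nonsyn": g.L_nonsyn,
            "sfs_syn": _format_sfs(g.sfs_syn.counts),
            "sfs_nonsyn": _format_sfs(g.sfs_nonsyn.counts),
            "D_syn": g.D_syn,
            "D_nonsyn": g.D_nonsyn,
            "rec_rate": g.rec_rate,
            "age_stratum": g.age_stratum,
            "expression": g.expression,
            "length": g.length,
            "vip": int(g.vip),
            "go_ids": ";".join(sorted(g.go_ids)),
        }
        if g.class_split is not None:
            has_split = True
            for cls, cc in g.class_split.items():
                row[f"L_syn_{cls}"] = cc.L_syn
                row[f"L_nonsyn_{cls}"] = cc.L_nonsyn
                row[f"sfs_syn_{cls}"] = _format_sfs(cc.sfs_syn)
                row[f"sfs_nonsyn_{cls}"] = _format_sfs(cc.sfs_nonsyn)
                row[f"D_syn_{cls}"] = cc.D_syn
                row[f"D_nonsyn_{cls}"] = cc.D_nonsyn
        rows.append(row)
    columns = _BASE_COLUMNS + _COVARIATE_COLUMNS
    if has_split:
        for cls in MUTATION_CLASSES:
            columns += [
                f"L_syn_{cls}", f"L_nonsyn_{cls}", f"sfs_syn_{cls}",
                f"sfs_nonsyn_{cls}", f"D_syn_{cls}", f"D_nonsyn_{cls}",
            ]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a tab-separated gene table; one :class:`GeneRecord` per data row.

    Missing optional columns yield absent fields (``None``), not zeros.
    Raises :class:`GeneTableError` on malformed spectra or negative counts,
    naming the offending gene and row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableError(f"gene table missing required columns: {missing}")
    if df.empty:
        logger.warning("gene table %s has an empty data section", path)
        return []
    has_split = all(f"sfs_syn_{cls}" in df.columns for cls in MUTATION_CLASSES)
    genes = []
    for idx, rec in enumerate(df.to_dict("records")):
        gid = rec["gene_id"]
        n = int(rec["n_chrom"])
        syn = _parse_sfs(rec["sfs_syn"], gid, idx, n, "sfs_syn")
        non = _parse_sfs(rec["sfs_nonsyn"], gid, idx, n, "sfs_nonsyn")
        for col in ("L_syn", "L_nonsyn", "D_syn", "D_nonsyn"):
            if rec[col] < 0:
                raise GeneTableError(f"row {idx} (gene {gid}): negative {col}")

        def _opt(col, cast=float):
            if col not in rec or pd.isna(rec[col]):
                return None
            return cast(rec[col])

        class_split = None
        if has_split:
            class_split = {}
            for cls in MUTATION_CLASSES:
                class_split[cls] = ClassCounts(
                    L_syn=float(rec[f"L_syn_{cls}"]),
                    L_nonsyn=float(rec[f"L_nonsyn_{cls}"]),
                    sfs_syn=_parse_sfs(rec[f"sfs_syn_{cls}"], gid, idx, n, f"sfs_syn_{cls}"),
                    sfs_nonsyn=_parse_sfs(
                        rec[f"sfs_nonsyn_{cls}"], gid, idx, n, f"sfs_nonsyn_{cls}"
                    ),
                    D_syn=float(rec[f"D_syn_{cls}"]),
                    D_nonsyn=float(rec[f"D_nonsyn_{cls}"]),
                )
        go_raw = rec.get("go_ids")
        go_ids = frozenset()
        if go_raw is not None and not pd.isna(go_raw) and str(go_raw):
            go_ids = frozenset(str(go_raw).split(";"))
        vip_raw = rec.get("vip")
        genes.append(
            GeneRecord(
                gene_id=gid,
                L_syn=float(rec["L_syn"]),
                L_nonsyn=float(rec["L_nonsyn"]),
                sfs_syn=SiteFrequencySpectrum(n, syn, site_class=SYNONYMOUS),
                sfs_nonsyn=SiteFrequencySpectrum(n, non, site_class=NONSYNONYMOUS),
                D_syn=float(rec["D_syn"]),
                D_nonsyn=float(rec["D_nonsyn"]),
                rec_rate=_opt("rec_rate"),
                age_stratum=_opt("age_stratum", int),
                expression=_opt("expression"),
                length=_opt("length"),
                vip=bool(int(vip_raw)) if vip_raw is not None and not pd.isna(vip_raw) else False,
                go_ids=go_ids,
                class_split=class_split,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# DOFE export (the text dialect used by MK-extension estimators)
# ---------------------------------------------------------------------------

def write_dofe(pooled: PooledData, path: str | Path, label: str = "pooled") -> None:
    """Write pooled counts as a DOFE file.

    Layout: a comment line, then one whitespace-separated data line with
    ``label n L_nonsyn <n-1 nonsynonymous SFS entries> L_syn <n-1
    synonymous entries> L_nonsyn D_nonsyn L_syn D_syn``.  All numeric
    fields are written as integers (counts are rounded), matching the
    dialect of external MK-extension software so a pooled block can be
    cross-validated against an independent estimator.
    """
    if pooled.folded:
        raise ValueError("DOFE export requires unfolded spectra")
    n = pooled.sample_size

    def ints(x):
        arr = np.round(np.atleast_1d(np.asarray(x, dtype=float))).astype(np.int64)
        return [str(v) for v in arr]

    fields = (
        [label, str(n)]
        + ints(pooled.L_nonsyn)
        + ints(pooled.sfs_nonsyn.counts)
        + ints(pooled.L_syn)
        + ints(pooled.sfs_syn.counts)
        + ints(pooled.L_nonsyn)
        + ints(pooled.D_nonsyn)
        + ints(pooled.L_syn)
        + ints(pooled.D_syn)
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mkomega pooled counts\n")
        fh.write("\t".join(fields) + "\n")


def read_dofe(path: str | Path) -> PooledData:
    """Parse a DOFE file written by :func:`write_dofe` (round-trip check)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise GeneTableError("DOFE file has no data line")
    fields = lines[0].split()
    label, n = fields[0], int(fields[1])
    vals = [float(x) for x in fields[2:]]
    k = n - 1
    Ln = vals[0]
    sfs_n = np.array(vals[1 : 1 + k])
    Ls = vals[1 + k]
    sfs_s = np.array(vals[2 + k : 2 + 2 * k])
    Ln2, Dn, Ls2, Ds = vals[2 + 2 * k : 6 + 2 * k]
    if Ln2 != Ln or Ls2 != Ls:
        raise GeneTableError("DOFE divergence site counts disagree with SFS site counts")
    return PooledData(
        L_syn=Ls,
        L_nonsyn=Ln,
        sfs_syn=SiteFrequencySpectrum(n, sfs_s, site_class=SYNONYMOUS),
        sfs_nonsyn=SiteFrequencySpectrum(n, sfs_n, site_class=NONSYNONYMOUS),
        D_syn=Ds,
        D_nonsyn=Dn,
        n_genes=1,
        gene_ids=(label,),
    )
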