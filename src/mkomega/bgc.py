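"""Biased gene conversion (gBGC) control.

GC-biased gene conversion favors the fixation of strong (G/C) over weak
(A/T) alleles in recombining regions and can mimic or mask adaptive
evolution.  Mutations are classified by their weak/strong base change;
restricting all counts to the gBGC-insensitive classes (A<>T and G<>C
changes, i.e. WW + SS) removes the bias at the cost of discarding roughly
80% of the data under a human-like mutation spectrum.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .sfs import GeneRecord, SiteFrequencySpectrum, MUTATION_CLASSES

WEAK = frozenset("AT")
STRONG = frozenset("GC")

#: Classes unaffected by gBGC (no change in weak/strong status).
BGC_INSENSITIVE = ("WW", "SS")


def classify_change(ancestral: str, derived: str) -> str:
    """Mutation class of an ancestral -> derived base change.

    W = weak (A or T), S = strong (G or C); the first letter of the label
    is the ancestral state.  A<>T changes are WW, G<>C changes are SS;
    only WS and SW changes are subject to gBGC.
    """
    anc = ancestral.upper()
    der = derived.upper()
    for b in (anc, der):
        if b not in "ACGT":
            raise ValueError(f"invalid base {b!r}")
    if anc == der:
        raise ValueError("ancestral and derived bases must differ")
    a = "W" if anc in WEAK else "S"
    d = "W" if der in WEAK else "S"
    return a + d


def filter_bgc_insensitive(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Restrict every count to the gBGC-insensitive (WW + SS) component.

    Site counts, spectra and substitution counts are all replaced by their
    WW + SS shares so that per-site rates remain comparable; the class
    split is retained (restricted to the kept classes), which makes the
    filter idempotent.  Raises if any gene lacks a class split.
    """
    missing = [g.gene_id for g in genes if g.class_split is None]
    if missing:
        raise ValueError(
            f"{len(missing)} genes lack mutation-class splits "
            f"(e.g. {missing[:5]}); cannot apply the gBGC restriction"
        )
    out = []
    for g in genes:
        kept = {c: g.class_split[c] for c in BGC_INSENSITIVE if c in g.class_split}
        L_syn = sum(c.L_syn for c in kept.values())
        L_nonsyn = sum(c.L_nonsyn for c in kept.values())
        sfs_syn = np.sum([c.sfs_syn for c in kept.values()], axis=0)
        sfs_nonsyn = np.sum([c.sfs_nonsyn for c in kept.values()], axis=0)
        out.append(
            replace(
                g,
                L_syn=float(L_syn),
                L_nonsyn=float(L_nonsyn),
                sfs_syn=replace(g.sfs_syn, counts=np.asarray(sfs_syn, dtype=float)),
                sfs_nonsyn=replace(g.sfs_nonsyn, counts=np.asarray(sfs_nonsyn, dtype=float)),
                D_syn=float(sum(c.D_syn for c in kept.values())),
                D_nonsyn=float(sum(c.D_nonsyn for c in kept.values())),
                class_split=kept,
            )
        )
    return out
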