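"""Breed-of-origin assignment of crossbred alleles.

Purebred haplotypes are catalogued in overlapping windows; each crossbred
gamete is then matched window by window against the purebred libraries
and per-allele window votes are reconciled.  The paternal gamete of a
three-way crossbred can only descend from the sire line (S); the
maternal gamete is a mosaic of the two maternal lines (LR, LW).

Input haplotypes must be phased; phasing itself is out of scope and is
taken as a contract on the input (simulated data are truth-phased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import (HaplotypePanel, ORIGIN_CODES, PURE_BREEDS, TrueOrigins,
                      UNASSIGNED)

_BIT = {"S": 1, "LR": 2, "LW": 4}


@dataclass
class HaplotypeLibrary:
    """Distinct purebred window haplotypes with breed-membership flags."""

    window_size: int
    step: int
    windows: list          # (chrom, start, end) locus-index ranges
    tables: list           # dict: haplotype bytes -> breed bitmask

    def breeds_carrying(self, w: int, hap: np.ndarray) -> int:
        return self.tables[w].get(hap.tobytes(), 0)


@dataclass
class OriginMatrix:
    ids: list
    codes: np.ndarray      # (n_cb, n_loci, 2) int8; UNASSIGNED = -1

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}

    def row(self, ind_id) -> int:
        return self._index[ind_id]


def _window_grid(n: int, window_size: int, step: int):
    if window_size > n:
        raise ValueError(f"window_size {window_size} exceeds chromosome "
                         f"locus count {n}")
    starts = list(range(0, n - window_size + 1, step))
    if starts[-1] + window_size < n:
        starts.append(n - window_size)
    return starts


def build_haplotype_library(pb_panel: HaplotypePanel, window_size: int = 50,
                            step: int = 10) -> HaplotypeLibrary:
    """Catalogue every purebred window haplotype and which breeds carry it."""
    if not np.isin(pb_panel.haplo, (0, 1)).all():
        raise ValueError("purebred panel must be fully phased 0/1")
    windows, tables = [], []
    for c, lo, hi in pb_panel.chromosome_slices():
        for start in _window_grid(hi - lo, window_size, step):
            s, e = lo + start, lo + start + window_size
            table: dict = {}
            for k, breed in enumerate(pb_panel.breeds):
                if breed not in PURE_BREEDS:
                    continue
                bit = _BIT[breed]
                for g in (0, 1):
                    key = pb_panel.haplo[k, s:e, g].tobytes()
                    table[key] = table.get(key, 0) | bit
            windows.append((c, s, e))
            tables.append(table)
    return HaplotypeLibrary(window_size, step, windows, tables)


def breed_exclusive_counts(library: HaplotypeLibrary) -> dict:
    """Number of window haplotypes carried by exactly one breed, per breed."""
    counts = {b: 0 for b in PURE_BREEDS}
    for table in library.tables:
        for mask in table.values():
            for b, bit in _BIT.items():
                if mask == bit:
                    counts[b] += 1
    return counts


def assign_origin(cb_panel: HaplotypePanel, library: HaplotypeLibrary,
                  vote: str = "strict") -> OriginMatrix:
    """Label each crossbred allele with its inferred breed-of-origin.

    Per window: the paternal gamete votes S where its haplotype occurs in
    the S library; the maternal gamete votes LR (or LW) where its
    haplotype occurs in only that maternal library — occurrence in both,
    or in neither, casts no vote.  Per allele, overlapping-window votes
    are reconciled: with ``vote="strict"`` (default) a label is assigned
    only when all voting windows agree; ``vote="majority"`` takes the
    plurality, with ties left unassigned.
    """
    if not np.isin(cb_panel.haplo, (0, 1)).all():
        raise ValueError("crossbred input must be phased 0/1; phase upstream")
    if vote not in ("strict", "majority"):
        raise ValueError("vote must be 'strict' or 'majority'")
    n_cb, n_loci = cb_panel.n_ind, cb_panel.n_loci
    codes = np.full((n_cb, n_loci, 2), UNASSIGNED, dtype=np.int8)
    lr_bit, lw_bit, s_bit = _BIT["LR"], _BIT["LW"], _BIT["S"]
    for k in range(n_cb):
        # votes[locus, label] for the maternal gamete; paternal only needs S
        votes_m = np.zeros((n_loci, 2), dtype=np.int32)   # columns: LR, LW
        votes_p = np.zeros(n_loci, dtype=np.int32)
        for w, (c, s, e) in enumerate(library.windows):
            table = library.tables[w]
            mask_p = table.get(cb_panel.haplo[k, s:e, 0].tobytes(), 0)
            if mask_p & s_bit:
                votes_p[s:e] += 1
            mask_m = table.get(cb_panel.haplo[k, s:e, 1].tobytes(), 0)
            m = mask_m & (lr_bit | lw_bit)
            if m == lr_bit:
                votes_m[s:e, 0] += 1
            elif m == lw_bit:
                votes_m[s:e, 1] += 1
        codes[k, votes_p > 0, 0] = ORIGIN_CODES["S"]
        lr_v, lw_v = votes_m[:, 0], votes_m[:, 1]
        if vote == "strict":
            lr_sel = (lr_v > 0) & (lw_v == 0)
            lw_sel = (lw_v > 0) & (lr_v == 0)
        else:
            lr_sel = lr_v > lw_v
            lw_sel = lw_v > lr_v
        codes[k, lr_sel, 1] = ORIGIN_CODES["LR"]
        codes[k, lw_sel, 1] = ORIGIN_CODES["LW"]
    return OriginMatrix(list(cb_panel.ids), codes)


def assignment_rate(origins: OriginMatrix) -> float:
    """Fraction of crossbred alleles with an assigned breed-of-origin."""
    if origins.codes.size == 0:
        raise ValueError("empty origin matrix")
    return float((origins.codes != UNASSIGNED).mean())


def agreement_with_truth(origins: OriginMatrix, truth: TrueOrigins) -> float:
    """Fraction of assigned alleles whose label matches the true origin."""
    rows = [truth.row(i) for i in origins.ids]
    true_codes = truth.codes[rows]
    assigned = origins.codes != UNASSIGNED
    if assigned.sum() == 0:
        return float("nan")
    return float((origins.codes[assigned] == true_codes[assigned]).mean())
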