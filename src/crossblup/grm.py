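"""Relationship matrices: pedigree A, VanRaden G_A, breed-frequency G_B,
and the breed-of-origin partial matrices G^(S), G^(LR), G^(LW).

All genomic matrices use the VanRaden method-2 locus scaling
1/(2 p_j (1 - p_j)) and divide by the total number of loci N, so that a
Hardy-Weinberg population has a mean diagonal of 1 and the crossbred
diagonal of a partial matrix equals the genome fraction contributed by
that breed (0.5 for the sire line, 0.25 for each dam line).  Crossbred
alleles without an assigned origin (or of the other maternal origin)
are missing and contribute exactly zero, with N unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boa import OriginMatrix
from .simdata import HaplotypePanel, ORIGIN_CODES, PURE_BREEDS

FREQ_CLIP = (0.01, 0.99)


@dataclass
class AlleleContent:
    """Counted-allele dosages for one target breed-of-origin.

    Purebred rows are diploid dosages in {0, 1, 2}; crossbred rows are
    single-gamete dosages in {0, 1} with NaN where the allele is
    unassigned or of a different origin.
    """

    ids: list
    values: np.ndarray        # (n_ind, n_loci) float, NaN = missing
    is_pb: np.ndarray         # bool per row
    breed: str


@dataclass
class FrequencyVector:
    values: np.ndarray
    flavor: str
    raw: np.ndarray = None    # pre-clip frequencies


@dataclass
class GenomicMatrix:
    ids: list
    values: np.ndarray
    flavor: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, rows, cols=None):
        ri = [self._index[i] for i in rows]
        ci = ri if cols is None else [self._index[i] for i in cols]
        return self.values[np.ix_(ri, ci)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _gamete_for_breed(breed: str) -> int:
    # paternal gamete can only carry S; maternal only LR/LW
    return 0 if breed == "S" else 1


def breed_allele_content(panel: HaplotypePanel, origins: OriginMatrix,
                         breed: str) -> AlleleContent:
    """Dosage of alleles originating from `breed`, over PB-of-breed + CB."""
    if breed not in PURE_BREEDS:
        raise ValueError(f"unknown breed {breed!r}")
    code, g = ORIGIN_CODES[breed], _gamete_for_breed(breed)
    ids, rows_pb = [], []
    for k, br in enumerate(panel.breeds):
        if br == breed:
            ids.append(panel.ids[k])
            rows_pb.append(k)
    pb_vals = panel.haplo[rows_pb].sum(axis=2).astype(float)

    cb_rows = [panel.row(i) for i in origins.ids]
    alle = panel.haplo[cb_rows][:, :, g].astype(float)
    ocode = origins.codes[:, :, g]
    cb_vals = np.where(ocode == code, alle, np.nan)

    values = np.vstack([pb_vals, cb_vals])
    is_pb = np.array([True] * len(rows_pb) + [False] * len(cb_rows))
    return AlleleContent(ids + list(origins.ids), values, is_pb, breed)


def breed_specific_frequencies(content: AlleleContent) -> FrequencyVector:
    """Counted-allele frequency across PB alleles and assigned CB alleles."""
    pb = content.values[content.is_pb]
    cb = content.values[~content.is_pb]
    count1 = pb.sum(axis=0) + np.nansum(cb, axis=0)
    total = 2.0 * pb.shape[0] + np.sum(~np.isnan(cb), axis=0)
    raw = np.full(content.values.shape[1], 0.5)
    zero = total == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} loci with no informative alleles; "
                      "frequency defaulted to 0.5")
    raw[~zero] = count1[~zero] / total[~zero]
    clipped = np.clip(raw, *FREQ_CLIP)
    return FrequencyVector(clipped, f"breed-{content.breed}", raw=raw)


def allele_frequencies(panel: HaplotypePanel, ids=None,
                       flavor: str = "across") -> FrequencyVector:
    """Observed counted-allele frequency across the given individuals."""
    sub = panel if ids is None else panel.subset(ids)
    raw = sub.dosage().mean(axis=0) / 2.0
    return FrequencyVector(np.clip(raw, *FREQ_CLIP), flavor, raw=raw)


def _informative(raw: np.ndarray) -> np.ndarray:
    """Loci polymorphic among the informative alleles (pre-clip)."""
    return (raw > 0) & (raw < 1)


def build_GA(panel: HaplotypePanel, ids=None,
             freq: FrequencyVector = None) -> GenomicMatrix:
    """VanRaden method-2 matrix with across-population frequencies."""
    sub = panel if ids is None else panel.subset(ids)
    if freq is None:
        freq = allele_frequencies(sub)
    keep = _informative(freq.raw if freq.raw is not None else freq.values)
    n_dropped = int((~keep).sum())
    p = freq.values[keep]
    M = sub.dosage()[:, keep]
    Z = (M - 2 * p) / np.sqrt(2 * p * (1 - p))
    N = keep.sum()
    G = Z @ Z.T / N
    return GenomicMatrix(list(sub.ids), G, "G_A",
                         {"n_loci": int(N), "dropped_monomorphic": n_dropped,
                          "freq": "across"})


def build_GB(panel: HaplotypePanel, ids=None, pb_freqs: dict = None,
             weights: dict = None) -> GenomicMatrix:
    """Genomic matrix with breed-specific centering.

    Purebred rows are centered by twice their own breed's frequency;
    crossbred rows by twice the weighted frequency (weights 0.5 for the
    sire breed, 0.25 for each dam breed, matching the crossbred genome
    composition).  A single scaling diagonal is formed from the weighted
    frequency.
    """
    sub = panel if ids is None else panel.subset(ids)
    if weights is None:
        weights = {"S": 0.5, "LR": 0.25, "LW": 0.25}
    if pb_freqs is None:
        pb_freqs = {}
        for b in PURE_BREEDS:
            bids = [i for i, br in zip(sub.ids, sub.breeds) if br == b]
            pb_freqs[b] = allele_frequencies(sub, bids, flavor=f"pb-{b}")
    p_w_raw = sum(weights[b] * (pb_freqs[b].raw if pb_freqs[b].raw is not None
                                else pb_freqs[b].values)
                  for b in PURE_BREEDS)
    keep = _informative(p_w_raw)
    p_w = np.clip(p_w_raw, *FREQ_CLIP)[keep]
    M = sub.dosage()[:, keep]
    center = np.empty_like(M)
    for k, br in enumerate(sub.breeds):
        if br in PURE_BREEDS:
            center[k] = 2 * pb_freqs[br].values[keep]
        else:
            center[k] = 2 * p_w
    Z = (M - center) / np.sqrt(2 * p_w * (1 - p_w))
    N = keep.sum()
    G = Z @ Z.T / N
    return GenomicMatrix(list(sub.ids), G, "G_B",
                         {"n_loci": int(N), "freq": "weighted-breed",
                          "weights": weights})


def build_partial(content: AlleleContent,
                  freq: FrequencyVector = None) -> GenomicMatrix:
    """Breed-of-origin partial relationship matrix over PB-of-breed + CB.

    Purebred rows are centered by 2p (diploid); crossbred rows by p
    (single gamete).  Missing crossbred entries contribute zero while N
    stays at the full locus count, so the crossbred diagonal estimates
    the genome fraction of that breed-of-origin.
    """
    if freq is None:
        freq = breed_specific_frequencies(content)
    if freq.flavor != f"breed-{content.breed}":
        raise ValueError(f"frequency flavor {freq.flavor!r} does not match "
                         f"content breed {content.breed!r}")
    raw = freq.raw if freq.raw is not None else freq.values
    keep = _informative(raw)
    p = freq.values[keep]
    V = content.values[:, keep]
    center = np.where(content.is_pb[:, None], 2 * p, p)
    Z = (V - center) / np.sqrt(2 * p * (1 - p))
    Z = np.nan_to_num(Z, nan=0.0)  # missing alleles contribute exactly 0
    N = keep.sum()
    G = Z @ Z.T / N
    return GenomicMatrix(list(content.ids), G, f"partial-{content.breed}",
                         {"n_loci": int(N), "freq": freq.flavor,
                          "dropped_monomorphic": int((~keep).sum())})


def build_all_partials(panel: HaplotypePanel, origins: OriginMatrix) -> dict:
    out = {}
    for b in PURE_BREEDS:
        content = breed_allele_content(panel, origins, b)
        out[b] = build_partial(content)
    return out


def build_pedigree_A(pedigree: pd.DataFrame) -> GenomicMatrix:
    """Numerator relationship matrix by the tabular (recursive) method."""
    ids = list(pedigree["id"])
    index = {i: k for k, i in enumerate(ids)}
    sires = [index.get(s, -1) for s in pedigree["sire"]]
    dams = [index.get(d, -1) for d in pedigree["dam"]]
    for k, (s, d) in enumerate(zip(sires, dams)):
        if s >= k or d >= k:
            raise ValueError("pedigree not sorted parents-first, or cyclic")
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
            A[i, :i] = A[:i, i] = 0.5 * (A[s, :i] + A[d, :i])
        elif s >= 0 or d >= 0:
            p = max(s, d)
            A[i, i] = 1.0
            A[i, :i] = A[:i, i] = 0.5 * A[p, :i]
        else:
            A[i, i] = 1.0
    return GenomicMatrix(ids, A, "A")


def pca_coordinates(G: GenomicMatrix, k: int = 2) -> pd.DataFrame:
    """Top-k principal coordinates of a relationship matrix.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalues; a column of explained-variance fractions is attached.
    """
    vals, vecs = np.linalg.eigh(G.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if k > (vals > 1e-10).sum():
        raise ValueError(f"k={k} exceeds the rank of the matrix")
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    df = pd.DataFrame(coords, index=G.ids,
                      columns=[f"PC{j + 1}" for j in range(k)])
    total = vals[vals > 0].sum()
    df.attrs["explained"] = [float(v / total) for v in vals[:k]]
    return df


def check_symmetric(G: GenomicMatrix, tol: float = 1e-10) -> bool:
    m = np.abs(G.values).max()
    if m == 0:
        return True
    return np.abs(G.values - G.values.T).max() < tol * m
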