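"""Henderson mixed-model equations for the three GBLUP models.

The genetic part of the equations is organised in *structures*: the
breed-of-origin (BOA) model has three independent structures, one per
breed, each a 2x2 genetic covariance (PB performance, CB performance)
Kronecker that breed's partial relationship matrix; the GA/GB models
have a single structure with a 4x4 covariance over the populations
(S, LR, LW, CB) Kronecker the full genomic matrix.  Every genotyped
animal appears in every structure it belongs to, phenotyped or not, so
purebreds acquire EBVs for crossbred performance through the crossbred
records.

Relationship matrices are blended with identity (0.99 G + 0.01 I)
before inversion; solving is by dense Cholesky with a relative-residual
check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GenomicMatrix
from .simdata import PURE_BREEDS
from .varcomp import ModelSpec, VarCompSet, bend_to_psd, build_fixed_design

BLEND = 0.01


@dataclass
class GeneticStructure:
    name: str
    ids: list                     # animals, defining the G order
    K: np.ndarray                 # t x t trait covariance
    Ginv: np.ndarray              # inverse of blended relationship matrix
    trait_names: tuple
    Gdiag: np.ndarray = None      # diagonal of the blended matrix

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}
        self.q = len(self.ids)
        self.t = self.K.shape[0]

    def animal_index(self, ind_id):
        return self._index[ind_id]


@dataclass
class MMESystem:
    C: np.ndarray
    rhs: np.ndarray
    n_fixed: int
    litters: list
    structures: list              # GeneticStructure
    offsets: list                 # equation offset per structure
    record_ids: list
    spec: ModelSpec
    varcomps: VarCompSet

    def eq_index(self, struct_idx: int, trait_idx: int, ind_id) -> int:
        s = self.structures[struct_idx]
        return self.offsets[struct_idx] + trait_idx * s.q + s.animal_index(ind_id)


@dataclass
class MMESolution:
    system: MMESystem
    solutions: np.ndarray
    rel_residual: float
    Cinv_diag: np.ndarray = None

    def ebv(self, struct_name: str, trait_name: str, ids) -> pd.Series:
        si = [s.name for s in self.system.structures].index(struct_name)
        s = self.system.structures[si]
        ti = s.trait_names.index(trait_name)
        idx = [self.system.eq_index(si, ti, i) for i in ids]
        return pd.Series(self.solutions[idx], index=ids)


def _blend(G: np.ndarray) -> np.ndarray:
    return (1 - BLEND) * G + BLEND * np.eye(G.shape[0])


def _genetic_structures(spec: ModelSpec, varcomps: VarCompSet,
                        matrices: dict) -> list:
    structures = []
    if spec.model == "BOA":
        for b in PURE_BREEDS:
            Gm: GenomicMatrix = matrices[b]
            K = varcomps.genetic[b].K
            K, _ = bend_to_psd(K)
            Gb = _blend(Gm.values)
            structures.append(GeneticStructure(
                f"partial-{b}", list(Gm.ids), K, np.linalg.inv(Gb),
                ("PB", "CB"), np.diag(Gb).copy()))
    else:
        Gm: GenomicMatrix = matrices["G"]
        K4 = varcomps.genetic4
        if K4 is None:
            raise ValueError("GA/GB model requires the combined 4x4 covariance")
        K4, _ = bend_to_psd(K4)
        Gb = _blend(Gm.values)
        structures.append(GeneticStructure(
            "G", list(Gm.ids), K4, np.linalg.inv(Gb),
            ("S", "LR", "LW", "CB"), np.diag(Gb).copy()))
    return structures


def _record_links(spec: ModelSpec, population: str, structures: list):
    """(structure index, trait index) pairs a record loads on."""
    links = []
    if spec.model == "BOA":
        if population == "CB":
            for si, s in enumerate(structures):
                links.append((si, s.trait_names.index("CB")))
        else:
            si = [s.name for s in structures].index(f"partial-{population}")
            links.append((si, 0))
    else:
        links.append((0, structures[0].trait_names.index(population)))
    return links


def assemble_mme(spec: ModelSpec, varcomps: VarCompSet, matrices: dict,
                 traitdata: pd.DataFrame, trait: str = None) -> MMESystem:
    """Build Henderson's equations for the given model on phenotyped records.

    ``matrices``: for BOA a dict breed -> partial GenomicMatrix; for
    GA/GB a dict with key "G".  All phenotyped animals must be present in
    the matrices they load on; unphenotyped animals in the matrices
    receive equations (and EBVs) through their relationships.
    """
    ycol = "y" if "y" in traitdata.columns else f"y_{trait}"
    structures = _genetic_structures(spec, varcomps, matrices)
    struct_animals = [set(s.ids) for s in structures]

    df = traitdata[traitdata[ycol].notna()].copy()
    keep = []
    for _, row in df.iterrows():
        links = _record_links(spec, row["population"], structures)
        keep.append(all(row["id"] in struct_animals[si] for si, _ in links))
    df = df[np.array(keep, dtype=bool)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no usable phenotyped records")
    if df["id"].duplicated().any():
        raise ValueError("one record per animal: duplicate ids in phenotypes")
    y = df[ycol].to_numpy(dtype=float)
    X = build_fixed_design(df, spec)
    p = X.shape[1]

    litters = sorted(df["litter"].unique())
    lit_index = {l: k for k, l in enumerate(litters)}
    lit_pop = {}
    for l, popn in zip(df["litter"], df["population"]):
        lit_pop[l] = popn
    n_lit = len(litters)

    offsets, off = [], p + n_lit
    for s in structures:
        offsets.append(off)
        off += s.q * s.t
    n_eq = off

    rinv = np.array([1.0 / varcomps.resid[popn] for popn in df["population"]])

    # incidence T = [X | W | Z]; dense at desk scale
    n = len(df)
    T = np.zeros((n, n_eq))
    T[:, :p] = X
    for r in range(n):
        T[r, p + lit_index[df.loc[r, "litter"]]] = 1.0
        for si, ti in _record_links(spec, df.loc[r, "population"], structures):
            s = structures[si]
            T[r, offsets[si] + ti * s.q + s.animal_index(df.loc[r, "id"])] = 1.0

    C = (T * rinv[:, None]).T @ T
    rhs = T.T @ (rinv * y)

    for l, k in lit_index.items():
        C[p + k, p + k] += 1.0 / varcomps.litter[lit_pop[l]]
    for si, s in enumerate(structures):
        Kinv = np.linalg.inv(s.K + 1e-12 * np.trace(s.K) * np.eye(s.t))
        o = offsets[si]
        prior = np.kron(Kinv, s.Ginv)
        C[o:o + s.t * s.q, o:o + s.t * s.q] += prior
    return MMESystem(C, rhs, p, litters, structures, offsets,
                     list(df["id"]), spec, varcomps)


def assemble_univariate_mme(Gm: GenomicMatrix, traitdata: pd.DataFrame,
                            var_a: float, var_u: float, var_e: float,
                            spec: ModelSpec, trait: str = None) -> MMESystem:
    """Single-population animal model (one genetic effect, any G or A).

    Used for the pedigree-based validation EBVs and as the reduced model
    in equivalence checks.  All animals of ``Gm`` get equations; records
    whose ids are absent from ``Gm`` are dropped.
    """
    ycol = "y" if "y" in traitdata.columns else f"y_{trait}"
    df = traitdata[traitdata[ycol].notna()
                   & traitdata["id"].isin(Gm.ids)].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no usable phenotyped records")
    y = df[ycol].to_numpy(dtype=float)
    X = build_fixed_design(df, spec)
    p = X.shape[1]
    with_litter = var_u is not None and "litter" in df.columns
    litters = sorted(df["litter"].unique()) if with_litter else []
    lit_index = {l: k for k, l in enumerate(litters)}
    n_lit = len(litters)
    Gb = _blend(Gm.values)
    structure = GeneticStructure("G", list(Gm.ids), np.array([[var_a]]),
                                 np.linalg.inv(Gb), ("EBV",),
                                 np.diag(Gb).copy())
    n_eq = p + n_lit + structure.q
    n = len(df)
    T = np.zeros((n, n_eq))
    T[:, :p] = X
    for r in range(n):
        if with_litter:
            T[r, p + lit_index[df.loc[r, "litter"]]] = 1.0
        T[r, p + n_lit + structure.animal_index(df.loc[r, "id"])] = 1.0
    rinv = np.full(n, 1.0 / var_e)
    C = (T * rinv[:, None]).T @ T
    rhs = T.T @ (rinv * y)
    if with_litter:
        C[p:p + n_lit, p:p + n_lit] += np.eye(n_lit) / var_u
    C[p + n_lit:, p + n_lit:] += structure.Ginv / var_a
    pops = set(df["population"])
    vcs = VarCompSet("GA", {}, litter={popn: var_u for popn in pops},
                     resid={popn: var_e for popn in pops})
    return MMESystem(C, rhs, p, litters, [structure], [p + n_lit],
                     list(df["id"]), spec, vcs)


def solve_mme(system: MMESystem, compute_inverse: bool = False,
              tol: float = 1e-8) -> MMESolution:
    """Solve by dense Cholesky; relative residual is checked against tol."""
    C, rhs = system.C, system.rhs
    jitter = 0.0
    for attempt in range(4):
        try:
            cf = cho_factor(C + jitter * np.eye(C.shape[0]), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-8 * np.abs(np.diag(C)).max())
    else:
        raise RuntimeError(
            "Cholesky factorization failed; condition estimate "
            f"{np.linalg.cond(C):.3e}")
    sol = cho_solve(cf, rhs)
    denom = np.linalg.norm(rhs)
    rel = np.linalg.norm(C @ sol - rhs) / (denom if denom > 0 else 1.0)
    if rel > tol:
        raise RuntimeError(f"solver residual {rel:.2e} exceeds {tol:.0e}")
    cinv_diag = None
    if compute_inverse:
        cinv_diag = np.diag(cho_solve(cf, np.eye(C.shape[0])))
    return MMESolution(system, sol, float(rel), cinv_diag)


def ebv_table(solution: MMESolution, trait: str = None) -> pd.DataFrame:
    """EBVs of every animal for every effect role of the fitted model."""
    rows = []
    sys_ = solution.system
    model = sys_.spec.model
    for si, s in enumerate(sys_.structures):
        for ti, tname in enumerate(s.trait_names):
            if model == "BOA":
                role = (f"PB-performance-{s.name.split('-')[1]}" if tname == "PB"
                        else f"CB-performance-{s.name.split('-')[1]}")
            else:
                role = (f"{tname}-performance" if tname != "CB"
                        else "CB-performance")
            vals = solution.solutions[
                sys_.offsets[si] + ti * s.q: sys_.offsets[si] + (ti + 1) * s.q]
            for ind, v in zip(s.ids, vals):
                rows.append((ind, model, role, v))
    return pd.DataFrame(rows, columns=["id", "model", "role", "ebv"])


def reliability(solution: MMESolution, struct_name: str, trait_name: str,
                ids) -> pd.Series:
    """r^2 = 1 - PEV / (K_tt * G*_ii) from the direct inverse diagonal."""
    if solution.Cinv_diag is None:
        raise ValueError("reliabilities require solve_mme(..., "
                         "compute_inverse=True)")
    sys_ = solution.system
    si = [s.name for s in sys_.structures].index(struct_name)
    s = sys_.structures[si]
    ti = s.trait_names.index(trait_name)
    ktt = s.K[ti, ti]
    out = {}
    for i in ids:
        k = s.animal_index(i)
        pev = solution.Cinv_diag[sys_.offsets[si] + ti * s.q + k]
        denom = ktt * s.Gdiag[k]
        out[i] = float(np.clip(1.0 - pev / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return pd.Series(out)
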