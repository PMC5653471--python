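"""Bivariate REML for purebred/crossbred variance components.

Each fit treats purebred records of one breed as trait 1 and all
crossbred records as trait 2, with a shared relationship matrix (a
breed-of-origin partial matrix, or a full genomic matrix) giving the
genetic covariance structure K (2x2) Kronecker G.  Common-litter and
residual variances are population-specific and independent.

The optimizer is average-information (AI) REML with step-halving line
search against the exact restricted log-likelihood and an
expectation-maximization fallback step; accepted iterations therefore
never decrease the likelihood.  Standard errors come from the inverse
AI matrix at convergence.

Three bivariate fits (one per breed) are combined into the full
four-population covariance, bending it to positive definite when
needed, and heritabilities and the purebred-crossbred genetic
correlation are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GenomicMatrix
from .simdata import PURE_BREEDS

POPS4 = ("S", "LR", "LW", "CB")


@dataclass
class ModelSpec:
    model: str                      # "BOA", "GA", or "GB"
    breed: str = None               # breed under analysis for bivariate runs
    # "a*b" denotes an interaction factor; populations get separate blocks,
    # so "farm*sex" within a purebred block is the farm_breed_sex effect
    fixed_pb: tuple = ("farm*sex",)
    fixed_cb: tuple = ("trial", "farm*sex")
    covariate: str = None           # covariate column, centered
    include_pb_pb_covariance: bool = False

    def __post_init__(self):
        if self.model not in ("BOA", "GA", "GB"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class GeneticCovBlock:
    K: np.ndarray                   # 2x2 [[var PB, cov], [cov, var CB]]
    se: np.ndarray = None           # elementwise SEs
    cov_params: np.ndarray = None   # 3x3 covariance of (k11, k12, k22)


@dataclass
class RemlResult:
    block: GeneticCovBlock
    litter: dict                    # {"PB": s2u, "CB": s2u}
    resid: dict
    litter_se: dict
    resid_se: dict
    loglik: float
    ll_trail: list
    n_iter: int
    converged: bool


@dataclass
class VarCompSet:
    model: str
    genetic: dict                   # BOA: breed -> GeneticCovBlock
    genetic4: np.ndarray = None     # GA/GB (and BOA assembled): 4x4 over POPS4
    litter: dict = field(default_factory=dict)   # population -> s2u
    resid: dict = field(default_factory=dict)
    bending_delta: float = 0.0


def build_fixed_design(df: pd.DataFrame, spec: ModelSpec):
    """Population-blocked fixed-effect design with drop-first dummies.

    Purebred and crossbred records get separate intercepts, factor
    effects, and covariate slopes (covariates centered within block).
    """
    n = len(df)
    cols = []
    for popn in pd.unique(df["population"]):
        mask = (df["population"] == popn).to_numpy()
        factors = spec.fixed_cb if popn == "CB" else spec.fixed_pb
        block = np.zeros((n, 1))
        block[mask, 0] = 1.0
        cols.append(block)
        for f in factors:
            parts = f.split("*")
            if any(p not in df.columns for p in parts):
                continue
            vals = df[parts[0]].astype(str)
            for p in parts[1:]:
                vals = vals + "_" + df[p].astype(str)
            levels = sorted(vals[mask].unique())
            for lev in levels[1:]:
                col = np.zeros((n, 1))
                col[mask & (vals == lev).to_numpy(), 0] = 1.0
                cols.append(col)
        if spec.covariate and spec.covariate in df.columns:
            col = np.zeros((n, 1))
            v = df.loc[mask, spec.covariate].to_numpy(dtype=float)
            col[mask, 0] = v - v.mean()
            cols.append(col)
    X = np.hstack(cols)
    # guard against rank deficiency after blocking
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(np.diag(r)).max()
    return X[:, keep]


class _BivariateREML:
    """Internal: dense V-scale REML machinery for one bivariate run."""

    PARAMS = ("k11", "k12", "k22", "u_pb", "u_cb", "e_pb", "e_cb")

    def __init__(self, y, X, trait, litter_codes, Grec, n_animals_G):
        self.y = y
        self.X = X
        self.n = len(y)
        self.trait = trait                      # 0 = PB, 1 = CB per record
        self.Grec = Grec                        # G at record level (n x n)
        self.qG = n_animals_G
        t = trait
        self.m11 = np.outer(t == 0, t == 0)
        self.m22 = np.outer(t == 1, t == 1)
        self.m12 = np.outer(t == 0, t == 1)
        self.m12 = self.m12 | self.m12.T
        lit = np.asarray(litter_codes)
        same = lit[:, None] == lit[None, :]
        self.Lpb = same & self.m11
        self.Lcb = same & self.m22
        self.n_lit_pb = len(np.unique(lit[t == 0]))
        self.n_lit_cb = len(np.unique(lit[t == 1]))
        self.d_pb = np.where(t == 0, 1.0, 0.0)
        self.d_cb = np.where(t == 1, 1.0, 0.0)

    def build_V(self, th):
        k11, k12, k22, upb, ucb, epb, ecb = th
        Kexp = k11 * self.m11 + k12 * self.m12 + k22 * self.m22
        V = self.Grec * Kexp
        V += upb * self.Lpb + ucb * self.Lcb
        V[np.diag_indices(self.n)] += epb * self.d_pb + ecb * self.d_cb
        return V

    def dV(self, j):
        if j == 0:
            return self.Grec * self.m11
        if j == 1:
            return self.Grec * self.m12
        if j == 2:
            return self.Grec * self.m22
        if j == 3:
            return self.Lpb.astype(float)
        if j == 4:
            return self.Lcb.astype(float)
        if j == 5:
            return np.diag(self.d_pb)
        return np.diag(self.d_cb)

    def loglik_parts(self, th):
        V = self.build_V(th)
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.log(np.diag(c[0])).sum()
        Vinv = cho_solve(c, np.eye(self.n))
        XtVX = self.X.T @ Vinv @ self.X
        sign, logdetX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        B = np.linalg.solve(XtVX, self.X.T @ Vinv)
        P = Vinv - Vinv @ self.X @ B
        Py = P @ self.y
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetX + yPy)
        return ll, P, Py

    def loglik(self, th):
        parts = self.loglik_parts(th)
        return -np.inf if parts is None else parts[0]

    def grad_ai(self, th, P, Py):
        npar = 7
        grad = np.empty(npar)
        w = []
        for j in range(npar):
            dVj = self.dV(j)
            wj = dVj @ Py
            w.append(wj)
            grad[j] = -0.5 * (np.sum(P * dVj) - float(Py @ wj))
        W = np.stack(w, axis=1)
        AI = 0.5 * (W.T @ P @ W)
        return grad, AI

    def em_step(self, th, P, Py):
        """Exact EM update on the V/P scale (monotone in the likelihood)."""
        t = self.trait
        u = np.zeros((2, self.n))
        u[0, t == 0] = Py[t == 0]
        u[1, t == 1] = Py[t == 1]
        # S_ml = (Z_m' Py)' G (Z_l' Py); T_ml = tr(Z_m' P Z_l G)
        Gu = self.Grec @ u.T                        # record-level
        S = u @ Gu
        T = np.empty((2, 2))
        PG = P * self.Grec
        T[0, 0] = PG[np.ix_(t == 0, t == 0)].sum()
        T[1, 1] = PG[np.ix_(t == 1, t == 1)].sum()
        T[0, 1] = T[1, 0] = PG[np.ix_(t == 0, t == 1)].sum()
        K = np.array([[th[0], th[1]], [th[1], th[2]]])
        Knew = K + (K @ (S - T) @ K) / self.qG
        new = th.copy()
        new[0], new[1], new[2] = Knew[0, 0], Knew[0, 1], Knew[1, 1]
        for j, (Vmask, q) in enumerate(
                ((self.Lpb, self.n_lit_pb), (self.Lcb, self.n_lit_cb)),
                start=3):
            quad = float(Py @ (Vmask @ Py))
            tr = np.sum(P * Vmask)
            new[j] = th[j] + (th[j] ** 2 / max(q, 1)) * (quad - tr)
        for j, d in ((5, self.d_pb), (6, self.d_cb)):
            quad = float((Py * d) @ Py)
            tr = float(np.sum(np.diag(P) * d))
            q = d.sum()
            new[j] = th[j] + (th[j] ** 2 / q) * (quad - tr)
        return new

    def feasible(self, th, floor):
        th = th.copy()
        th[[0, 2, 3, 4, 5, 6]] = np.maximum(th[[0, 2, 3, 4, 5, 6]], floor)
        lim = 0.999 * np.sqrt(th[0] * th[2])
        th[1] = np.clip(th[1], -lim, lim)
        return th


def reml_bivariate(spec: ModelSpec, traitdata: pd.DataFrame,
                   G: GenomicMatrix, trait: str = None,
                   max_iter: int = 200, tol_param: float = 1e-8,
                   tol_ll: float = 1e-6, verbose: bool = False):
    """Fit the bivariate (PB-of-one-breed, CB) model by AI-REML.

    ``traitdata`` must contain columns id, population, litter, the fixed
    factors of the spec, and a phenotype column ``y`` (or ``y_<trait>``).

    Returns a RemlResult; raises RuntimeError with the likelihood
    trajectory on non-convergence.
    """
    ycol = "y" if "y" in traitdata.columns else f"y_{trait}"
    df = traitdata[traitdata["population"].isin([spec.breed, "CB"])].copy()
    df = df[df[ycol].notna() & df["id"].isin(G.ids)].reset_index(drop=True)
    y = df[ycol].to_numpy(dtype=float)
    tr = (df["population"] == "CB").to_numpy().astype(int)
    X = build_fixed_design(df, spec)
    Grec = G.loc(list(df["id"]))
    eng = _BivariateREML(y, X, tr, df["litter"].to_numpy(), Grec, len(G.ids))

    vy_pb = float(np.var(y[tr == 0], ddof=1))
    vy_cb = float(np.var(y[tr == 1], ddof=1))
    gdiag_cb = float(np.mean(np.diag(Grec)[tr == 1])) or 1.0
    th = np.array([0.4 * vy_pb, 0.05 * np.sqrt(vy_pb * vy_cb),
                   0.4 * vy_cb / gdiag_cb, 0.1 * vy_pb, 0.1 * vy_cb,
                   0.45 * vy_pb, 0.45 * vy_cb])
    floor = 1e-8 * max(vy_pb, vy_cb)

    parts = eng.loglik_parts(th)
    if parts is None:
        raise RuntimeError("non-PD starting variance structure")
    ll, P, Py = parts
    trail = [ll]
    converged = False
    AI = np.eye(7)
    for it in range(max_iter):
        grad, AI = eng.grad_ai(th, P, Py)
        accepted = False
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(7) * np.abs(AI).max(),
                                    grad)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(12):
                cand = eng.feasible(th + step * delta, floor)
                parts_c = eng.loglik_parts(cand)
                if parts_c is not None and parts_c[0] >= ll - 1e-12:
                    th_new, (ll_new, P_new, Py_new) = cand, parts_c
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            cand = eng.feasible(eng.em_step(th, P, Py), floor)
            parts_c = eng.loglik_parts(cand)
            if parts_c is None or parts_c[0] < ll - 1e-8:
                # numerically stuck at a boundary; treat as converged
                converged = True
                break
            th_new, (ll_new, P_new, Py_new) = cand, parts_c
        rel = np.max(np.abs(th_new - th) / np.maximum(np.abs(th), floor))
        dll = ll_new - ll
        th, ll, P, Py = th_new, ll_new, P_new, Py_new
        trail.append(ll)
        if verbose:
            print(f"iter {it}: ll={ll:.6f} rel={rel:.2e}")
        # likelihood tolerance is relative to its magnitude: boundary
        # estimates (variance -> 0) otherwise crawl forever at O(1e-5)/iter
        if rel < tol_param or abs(dll) < tol_ll * (1.0 + abs(ll)):
            converged = True
            break
    if not converged:
        raise RuntimeError(f"REML did not converge in {max_iter} iterations; "
                           f"log-likelihood trail: {trail}")

    grad, AI = eng.grad_ai(th, P, Py)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((7, 7), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    K = np.array([[th[0], th[1]], [th[1], th[2]]])
    seK = np.array([[se[0], se[1]], [se[1], se[2]]])
    block = GeneticCovBlock(K, seK, cov[np.ix_([0, 1, 2], [0, 1, 2])])
    return RemlResult(block,
                      {"PB": th[3], "CB": th[4]}, {"PB": th[5], "CB": th[6]},
                      {"PB": se[3], "CB": se[4]}, {"PB": se[5], "CB": se[6]},
                      ll, trail, len(trail) - 1, converged)


def combine_bivariate(fits: dict, model: str,
                      pb_pb_cov: dict = None) -> VarCompSet:
    """Combine three bivariate fits into the full 4-population set.

    For GA/GB the single crossbred genetic variance (and the crossbred
    litter and residual variances) is the average over the three fits;
    for BOA the breed-specific crossbred components are retained.
    Purebred-purebred covariances are zero unless supplied.
    """
    for b in PURE_BREEDS:
        if b not in fits:
            raise ValueError(f"missing bivariate fit for breed {b}")
    litter = {b: fits[b].litter["PB"] for b in PURE_BREEDS}
    resid = {b: fits[b].resid["PB"] for b in PURE_BREEDS}
    litter["CB"] = float(np.mean([fits[b].litter["CB"] for b in PURE_BREEDS]))
    resid["CB"] = float(np.mean([fits[b].resid["CB"] for b in PURE_BREEDS]))
    genetic = {b: fits[b].block for b in PURE_BREEDS}
    vcs = VarCompSet(model, genetic, litter=litter, resid=resid)
    if model in ("GA", "GB"):
        K4 = np.zeros((4, 4))
        for j, b in enumerate(PURE_BREEDS):
            K4[j, j] = fits[b].block.K[0, 0]
            K4[j, 3] = K4[3, j] = fits[b].block.K[0, 1]
        K4[3, 3] = float(np.mean([fits[b].block.K[1, 1] for b in PURE_BREEDS]))
        if pb_pb_cov:
            for (a, b), v in pb_pb_cov.items():
                ia, ib = POPS4.index(a), POPS4.index(b)
                K4[ia, ib] = K4[ib, ia] = v
        K4, delta = bend_to_psd(K4)
        vcs.genetic4 = K4
        vcs.bending_delta = delta
    else:
        deltas = []
        for b in PURE_BREEDS:
            Kb, d = bend_to_psd(genetic[b].K)
            genetic[b] = GeneticCovBlock(Kb, genetic[b].se,
                                         genetic[b].cov_params)
            deltas.append(d)
        vcs.bending_delta = float(np.mean(deltas))
    return vcs


def bend_to_psd(cov: np.ndarray, eps: float = 1e-4):
    """Raise small/negative eigenvalues to eps * (largest eigenvalue).

    Returns the bent matrix and the mean absolute percent change of the
    elements.  Idempotent: bending a bent matrix changes nothing.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("input must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    vmax = vals.max()
    scale = np.abs(vals).max() or 1.0
    floor = eps * (vmax if vmax > 0 else scale)
    if vals.min() >= floor - 1e-10 * scale:
        return cov.copy(), 0.0
    bent = (vecs * np.maximum(vals, floor)) @ vecs.T
    bent = 0.5 * (bent + bent.T)
    mask = np.abs(cov) > 1e-12
    delta = float(np.mean(np.abs((bent[mask] - cov[mask]) / cov[mask])) * 100
                  ) if mask.any() else 0.0
    return bent, delta


def heritability(vcs: VarCompSet, population: str,
                 cb_weights=(0.5, 0.25, 0.25)) -> float:
    """h2 for one population under the model of this VarCompSet.

    Purebreds: s2_a / (s2_a + s2_u + s2_e).  Crossbreds: under GA/GB the
    single crossbred genetic variance; under BOA the weighted sum of the
    three breed-of-origin variances (weights = genome fractions).
    """
    if population == "CB":
        if vcs.model == "BOA":
            va = sum(w * vcs.genetic[b].K[1, 1]
                     for w, b in zip(cb_weights, PURE_BREEDS))
        else:
            va = vcs.genetic4[3, 3]
    else:
        if vcs.model == "BOA":
            va = vcs.genetic[population].K[0, 0]
        else:
            va = vcs.genetic4[POPS4.index(population),
                              POPS4.index(population)]
    denom = va + vcs.litter[population] + vcs.resid[population]
    if denom == 0:
        raise ZeroDivisionError("zero phenotypic variance")
    return float(va / denom)


def genetic_correlation_pc(block: GeneticCovBlock) -> float:
    """Purebred-crossbred genetic correlation from a 2x2 block."""
    v1, v2 = block.K[0, 0], block.K[1, 1]
    if v1 <= 0 or v2 <= 0:
        warnings.warn("non-positive genetic variance; r_pc undefined")
        return float("nan")
    return float(block.K[0, 1] / np.sqrt(v1 * v2))


def rpc_standard_error(block: GeneticCovBlock) -> float:
    """Delta-method SE of r_pc from the AI-matrix parameter covariance."""
    if block.cov_params is None or not np.isfinite(block.cov_params).all():
        return float("nan")
    v1, c, v2 = block.K[0, 0], block.K[0, 1], block.K[1, 1]
    r = c / np.sqrt(v1 * v2)
    grad = np.array([-0.5 * r / v1, 1.0 / np.sqrt(v1 * v2), -0.5 * r / v2])
    var = float(grad @ block.cov_params @ grad)
    return float(np.sqrt(max(var, 0.0)))


def varcomps_to_frame(vcs: VarCompSet) -> pd.DataFrame:
    """Long-format table of components (model, breed, component, estimate)."""
    rows = []
    for b in PURE_BREEDS:
        blk = vcs.genetic[b]
        rows.append((vcs.model, b, "var_a_pb", blk.K[0, 0]))
        rows.append((vcs.model, b, "cov_pb_cb", blk.K[0, 1]))
        rows.append((vcs.model, b, "var_a_cb", blk.K[1, 1]))
        rows.append((vcs.model, b, "r_pc", genetic_correlation_pc(blk)))
    for popn in POPS4:
        rows.append((vcs.model, popn, "var_litter", vcs.litter[popn]))
        rows.append((vcs.model, popn, "var_resid", vcs.resid[popn]))
        rows.append((vcs.model, popn, "h2", heritability(vcs, popn)))
    return pd.DataFrame(rows, columns=["model", "breed", "component",
                                       "estimate"])
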