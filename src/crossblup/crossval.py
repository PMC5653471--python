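"""Cross-validation of purebred EBVs for crossbred performance.

Purebreds of each breed are split into four folds by K-means on a
genomic dissimilarity (so validation animals are not closely related to
the training crossbreds); each crossbred joins the fold of the purebred
cluster it is most related to, with a rebalancing rule for skewed
assignments.  Validation purebreds receive pedigree-based EBVs from the
held-out crossbred records, which are deregressed into pseudo-phenotypes
(DRP) with effective-record-contribution weights; accuracy is the
weighted correlation between DRP and each model's EBVs, with
SE = (1 - r^2) / sqrt(N).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .boa import OriginMatrix, assign_origin, build_haplotype_library
from .grm import (GenomicMatrix, breed_allele_content, build_GA, build_GB,
                  build_all_partials, build_partial, build_pedigree_A)
from .predict import (assemble_mme, assemble_univariate_mme, reliability,
                      solve_mme)
from .simdata import PURE_BREEDS, SimulatedDataset
from .varcomp import (GeneticCovBlock, ModelSpec, VarCompSet,
                      combine_bivariate, reml_bivariate)


def kmeans_pb_folds(G_A: GenomicMatrix, breed_ids, k: int = 4,
                    seed: int = 0, n_mds: int = 10) -> pd.Series:
    """K-means folds from a genomic dissimilarity d = max(G) - G.

    The dissimilarity is embedded by classical multidimensional scaling
    (top ``n_mds`` coordinates) before clustering; multiple seeded
    restarts keep the best inertia.  Returns fold labels 1..k by id.
    """
    if k > len(breed_ids):
        raise ValueError(f"k={k} exceeds the number of animals")
    Gbb = G_A.loc(list(breed_ids))
    d = Gbb.max() - Gbb
    np.fill_diagonal(d, 0.0)
    if np.allclose(d, 0):
        warnings.warn("all animals equally related; clusters are arbitrary")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    m = min(n_mds, n - 1)
    coords = vecs[:, order[:m]] * np.sqrt(np.maximum(vals[order[:m]], 0.0))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
    return pd.Series(km.labels_ + 1, index=list(breed_ids), name="fold")


def assign_cb_folds(G_A: GenomicMatrix, pb_folds: pd.Series, cb_ids,
                    rebalance: bool = True, seed: int = 0) -> pd.Series:
    """Assign each crossbred to the purebred fold it is most related to.

    Fold = argmax over folds of the mean relationship to that fold's
    purebreds (ties to the lowest fold index).  If one fold collects more
    than half of the crossbreds and ``rebalance`` is set, its crossbreds
    are split uniformly at random across all folds.
    """
    folds = sorted(pb_folds.unique())
    rel = G_A.loc(list(cb_ids), list(pb_folds.index))
    means = np.stack([rel[:, (pb_folds == f).to_numpy()].mean(axis=1)
                      for f in folds], axis=1)
    if np.allclose(rel, 0):
        warnings.warn("crossbreds unrelated to all purebred folds; "
                      "assignment falls back to the overall mean (ties)")
    assigned = np.array([folds[j] for j in means.argmax(axis=1)])
    if rebalance and len(folds) > 1:
        counts = pd.Series(assigned).value_counts()
        big = counts.idxmax()
        if counts.max() > 0.5 * len(cb_ids):
            rng = np.random.default_rng(seed)
            idx = np.flatnonzero(assigned == big)
            rng.shuffle(idx)
            for grp, fold in zip(np.array_split(idx, len(folds)), folds):
                assigned[grp] = fold
    return pd.Series(assigned, index=list(cb_ids), name="fold")


def fold_assignment(G_A: GenomicMatrix, breed: str, breed_ids, cb_ids,
                    genotyped_cb, k: int = 4, seed: int = 0,
                    rebalance: bool = True) -> pd.DataFrame:
    pb = kmeans_pb_folds(G_A, breed_ids, k=k, seed=seed)
    cb = assign_cb_folds(G_A, pb, [c for c in cb_ids if c in genotyped_cb],
                         rebalance=rebalance, seed=seed)
    rows = [(i, breed, int(f), "PB-validation") for i, f in pb.items()]
    rows += [(i, "CB", int(f), "CB-training-attached") for i, f in cb.items()]
    rows += [(i, "CB", 0, "CB-extra") for i in cb_ids
             if i not in genotyped_cb]
    return pd.DataFrame(rows, columns=["id", "breed", "fold", "role"])


# ---------------------------------------------------------------------------
# Deregression
# ---------------------------------------------------------------------------

def deregress_ebv(ebv: pd.Series, reliabilities: pd.Series,
                  pedigree: pd.DataFrame, ids, h2: float) -> pd.DataFrame:
    """Deregressed proofs with effective-record-contribution weights.

    Uses the two-information-source decomposition: the parent average
    (PA) carries r2_PA = (r2_sire + r2_dam) / 4; the animal's own
    information is what remains.  DRP = PA + (EBV - PA) / r2*, with
    r2* = (r2 - r2_PA) / (1 - r2_PA) the reliability of the own-source
    deviation, and w = lambda [r2/(1-r2) - r2_PA/(1-r2_PA)] the
    own-equivalent record count (lambda = (1-h2)/h2).  Animals whose EBV
    reliability does not exceed their PA reliability get w = 0 and an
    unusable (NaN) DRP.
    """
    lam = (1.0 - h2) / h2
    ped = pedigree.set_index("id")
    rows = []
    for i in ids:
        r2 = float(reliabilities.get(i, 0.0))
        sire, dam = ped.loc[i, "sire"], ped.loc[i, "dam"]
        pa, r2pa = 0.0, 0.0
        for parent in (sire, dam):
            if parent != "0" and parent in ebv.index:
                pa += 0.5 * float(ebv[parent])
                r2pa += float(reliabilities.get(parent, 0.0)) / 4.0
        r2 = min(r2, 1.0 - 1e-12)
        r2pa = min(r2pa, 1.0 - 1e-12)
        w = lam * (r2 / (1 - r2) - r2pa / (1 - r2pa))
        if w <= 1e-12 or r2 <= r2pa:
            rows.append((i, np.nan, 0.0, 0.0, r2))
            continue
        r2_dev = (r2 - r2pa) / (1 - r2pa)
        drp = pa + (float(ebv[i]) - pa) / r2_dev
        r2_drp = w / (w + lam)
        rows.append((i, drp, w, r2_drp, r2))
    return pd.DataFrame(rows, columns=["id", "drp", "w", "rel_drp", "rel_ebv"])


def weighted_accuracy(drp: pd.DataFrame, ebv: pd.Series) -> float:
    """Weighted Pearson correlation between DRP and EBV."""
    df = drp[(drp["w"] > 0) & drp["drp"].notna()].copy()
    df["ebv"] = df["id"].map(ebv)
    df = df[df["ebv"].notna()]
    if len(df) < 3:
        raise ValueError("need >= 3 animals with positive weight")
    w = df["w"].to_numpy()
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    x, y = df["drp"].to_numpy(), df["ebv"].to_numpy()
    xm, ym = np.average(x, weights=w), np.average(y, weights=w)
    cov = np.average((x - xm) * (y - ym), weights=w)
    vx = np.average((x - xm) ** 2, weights=w)
    vy = np.average((y - ym) ** 2, weights=w)
    return float(cov / np.sqrt(vx * vy))


def accuracy_se(r: float, n: int) -> float:
    """SE of a validation accuracy, approximated as (1 - r^2)/sqrt(N)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((1.0 - r ** 2) / np.sqrt(n))


# ---------------------------------------------------------------------------
# Variance components for the full pipeline
# ---------------------------------------------------------------------------

def true_varcomps(dataset: SimulatedDataset, trait: str, model: str) -> VarCompSet:
    """Generating components of the simulator, packaged per model."""
    tr = dataset.truths[trait]
    genetic = {b: GeneticCovBlock(tr.K2[b].copy()) for b in PURE_BREEDS}
    litter = {**tr.litter_var}
    resid = {**tr.resid_var}
    vcs = VarCompSet(model, genetic, litter=litter, resid=resid)
    if model in ("GA", "GB"):
        K4 = np.zeros((4, 4))
        for j, b in enumerate(PURE_BREEDS):
            K4[j, j] = tr.K2[b][0, 0]
            K4[j, 3] = K4[3, j] = tr.K2[b][0, 1]
        K4[3, 3] = tr.var_cb_total
        from .varcomp import bend_to_psd
        vcs.genetic4, vcs.bending_delta = bend_to_psd(K4)
    return vcs


def reml_varcomps(traitdata: pd.DataFrame, trait: str, model: str,
                  matrices: dict, spec_kw: dict = None) -> VarCompSet:
    """Three bivariate REML fits combined into the model's full set."""
    fits = {}
    for b in PURE_BREEDS:
        spec = ModelSpec(model, breed=b, covariate=f"cov_{trait}",
                         **(spec_kw or {}))
        G = matrices[b] if model == "BOA" else matrices["G"]
        fits[b] = reml_bivariate(spec, traitdata, G, trait=trait)
    return combine_bivariate(fits, model)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_crossvalidation(dataset: SimulatedDataset, models=("BOA", "GA", "GB"),
                        trait: str = None, breeds=PURE_BREEDS, k: int = 4,
                        seed: int = 0, varcomps: str | dict = "reml",
                        origins: str | OriginMatrix = "boa",
                        window_size: int = 50, step: int = 10,
                        rebalance: bool = True,
                        min_mean_reliability: float = 0.05):
    """K-fold cross-validation of all models on a simulated dataset.

    ``varcomps``: "reml" (estimate on the full data, once per model),
    "true" (the simulator's generating components), or a prebuilt dict
    model -> VarCompSet.  ``origins``: "boa" (windowed assignment),
    "true", or a prebuilt OriginMatrix.

    Returns (AccuracyReport DataFrame, fold assignment DataFrame, log list).
    """
    if trait is None:
        trait = dataset.config.traits[0].name
    log = [f"seed={seed} trait={trait} k={k}"]
    gids = dataset.genotyped_ids()
    panel_g = dataset.panel.subset(gids)
    genotyped_cb = [i for i in dataset.cb_ids if i in dataset.genotyped]

    if "BOA" not in models:
        om = None                       # origin assignment stage not needed
    elif isinstance(origins, OriginMatrix):
        om = origins
    elif origins == "true":
        rows = [dataset.origins.row(i) for i in genotyped_cb]
        om = OriginMatrix(genotyped_cb, dataset.origins.codes[rows].copy())
    else:
        pb_ids = [i for i, b in zip(panel_g.ids, panel_g.breeds)
                  if b in PURE_BREEDS]
        lib = build_haplotype_library(panel_g.subset(pb_ids), window_size, step)
        om = assign_origin(panel_g.subset(genotyped_cb), lib)
        log.append("origin assignment: windowed library vote")

    GA_m = build_GA(panel_g)
    matrices = {"GA": {"G": GA_m}}
    if "BOA" in models:
        matrices["BOA"] = {}
        for b in PURE_BREEDS:
            matrices["BOA"][b] = build_partial(
                breed_allele_content(panel_g, om, b))
    if "GB" in models:
        matrices["GB"] = {"G": build_GB(panel_g)}

    pheno = dataset.phenotypes
    vcs = {}
    for m in models:
        if isinstance(varcomps, dict):
            vcs[m] = varcomps[m]
        elif varcomps == "true":
            vcs[m] = true_varcomps(dataset, trait, m)
        else:
            vcs[m] = reml_varcomps(pheno, trait, m, matrices[m],
                                   spec_kw={})
            log.append(f"REML varcomps estimated for {m}")

    # pedigree A for the validation EBV step (CB-extra enters here only)
    ped = dataset.pedigree
    A_m = build_pedigree_A(ped)
    ref = vcs["GA"] if "GA" in vcs else vcs[list(vcs)[0]]
    if ref.genetic4 is not None:
        va_cb = float(ref.genetic4[3, 3])
    else:
        va_cb = float(np.mean([ref.genetic[b].K[1, 1] for b in PURE_BREEDS]))
    vu_cb, ve_cb = ref.litter["CB"], ref.resid["CB"]
    h2_cb = va_cb / (va_cb + vu_cb + ve_cb)

    rows, fold_frames = [], []
    for breed in breeds:
        breed_ids = [i for i, b in zip(panel_g.ids, panel_g.breeds)
                     if b == breed]
        fa = fold_assignment(GA_m, breed, breed_ids, dataset.cb_ids,
                             set(genotyped_cb), k=k, seed=seed,
                             rebalance=rebalance)
        fold_frames.append(fa)
        pb_fold = fa[fa["role"] == "PB-validation"].set_index("id")["fold"]
        cb_fold = fa[fa["role"] == "CB-training-attached"].set_index("id")["fold"]
        extra_ids = set(fa.loc[fa["role"] == "CB-extra", "id"])
        per_model_r = {m: [] for m in models}
        for f in sorted(pb_fold.unique()):
            val_pb = list(pb_fold[pb_fold == f].index)
            val_cb = set(cb_fold[cb_fold == f].index)
            if len(val_cb) == 0:
                log.append(f"{breed} fold {f}: no CB phenotypes; skipped")
                continue
            ycol = f"y_{trait}"
            is_val_pb = pheno["id"].isin(val_pb)
            is_val_cb = pheno["id"].isin(val_cb)
            is_extra = pheno["id"].isin(extra_ids)
            train = pheno[~is_val_pb & ~is_val_cb & ~is_extra]

            # validation DRP from the fold's CB (+ ungenotyped extras)
            val_rec = pheno[(is_val_cb | is_extra) & pheno[ycol].notna()]
            spec_val = ModelSpec("GA", covariate=f"cov_{trait}")
            sys_val = assemble_univariate_mme(A_m, val_rec, va_cb, vu_cb,
                                              ve_cb, spec_val, trait=trait)
            sol_val = solve_mme(sys_val, compute_inverse=True)
            ids_needed = set(val_pb)
            for i in val_pb:
                prow = ped.set_index("id").loc[i]
                ids_needed.update(p for p in (prow["sire"], prow["dam"])
                                  if p != "0")
            ids_needed = [i for i in ids_needed if i in set(A_m.ids)]
            ebv_val = sol_val.ebv("G", "EBV", ids_needed)
            rel_val = reliability(sol_val, "G", "EBV", ids_needed)
            drp = deregress_ebv(ebv_val, rel_val, ped, val_pb, h2_cb)
            usable = drp[drp["w"] > 0]
            mean_rel = usable["rel_drp"].mean() if len(usable) else 0.0
            if mean_rel < min_mean_reliability:
                log.append(f"{breed} fold {f}: mean DRP reliability "
                           f"{mean_rel:.3f} < {min_mean_reliability}; excluded")
                continue

            for m in models:
                spec = ModelSpec(m, covariate=f"cov_{trait}")
                system = assemble_mme(spec, vcs[m], matrices[m], train,
                                      trait=trait)
                sol = solve_mme(system)
                if m == "BOA":
                    ebv_m = sol.ebv(f"partial-{breed}", "CB", val_pb)
                else:
                    ebv_m = sol.ebv("G", "CB", val_pb)
                r = weighted_accuracy(drp, ebv_m)
                n_used = int((drp["w"] > 0).sum())
                rows.append((m, breed, trait, int(f), r,
                             accuracy_se(r, n_used), n_used,
                             float(usable["w"].mean())))
                per_model_r[m].append(r)
        for m in models:
            if per_model_r[m]:
                rbar = float(np.mean(per_model_r[m]))
                rows.append((m, breed, trait, 0, rbar, np.nan,
                             sum(1 for _ in per_model_r[m]), np.nan))
    report = pd.DataFrame(rows, columns=["model", "breed", "trait", "fold",
                                         "r", "se", "n", "mean_w"])
    report["fold"] = report["fold"].replace(0, pd.NA)
    folds = pd.concat(fold_frames, ignore_index=True) if fold_frames else \
        pd.DataFrame(columns=["id", "breed", "fold", "role"])
    return report, folds, log
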