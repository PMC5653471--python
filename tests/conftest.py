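import numpy as np
import pytest

from crossblup import OriginMatrix, SimConfig, TraitConfig, simulate_dataset
from crossblup.simdata import PURE_BREEDS


def small_config(**overrides):
    kw = dict(n_pb=100, n_cb=200, n_cb_extra=60, n_loci=600, n_chromosomes=2,
              n_dams_f1=30, n_sires_s=20, n_f1_grandsires=6, n_f1_granddams=10,
              litter_size=5, qtl_count=150, seed=42)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest three-way cross shared by most tests."""
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def genotyped_panel(small_dataset):
    return small_dataset.panel.subset(small_dataset.genotyped_ids())


def true_origin_matrix(dataset, ids=None):
    """The simulator's recorded origins as an OriginMatrix (genotyped CB)."""
    if ids is None:
        ids = [i for i in dataset.cb_ids if i in dataset.genotyped]
    rows = [dataset.origins.row(i) for i in ids]
    return OriginMatrix(list(ids), dataset.origins.codes[rows].copy())


def simulate_from_bivariate_model(G, n_pb, n_cb, K, var_u, var_e,
                                  litter_size=5, seed=0, breed="S"):
    """Draw records exactly from the bivariate PB/CB animal model.

    G: GenomicMatrix over n_pb + n_cb animals (PB first).  Genetic values
    a (q x 2) have Var(vec a) = K kron G; PB records express trait 1, CB
    records trait 2; litters are blocks of `litter_size` within each
    population with its own variance; residuals are population-specific.
    Returns a phenotype DataFrame shaped like the simulator's output.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    q = n_pb + n_cb
    vals, vecs = np.linalg.eigh(G.values)
    Lg = vecs * np.sqrt(np.clip(vals, 0, None))
    Lk = np.linalg.cholesky(K + 1e-12 * np.trace(K) * np.eye(2))
    a = Lg @ rng.standard_normal((q, 2)) @ Lk.T
    rows = []
    for i in range(q):
        popn = breed if i < n_pb else "CB"
        t = 0 if i < n_pb else 1
        j = i if i < n_pb else i - n_pb
        rows.append({"id": G.ids[i], "population": popn,
                     "litter": f"{popn}L{j // litter_size}",
                     "farm": int(rng.integers(3)), "sex": "MF"[j % 2],
                     "trial": int(rng.integers(2)),
                     "genetic": a[i, t]})
    df = pd.DataFrame(rows)
    farm_eff = {}
    y = np.empty(q)
    lit_eff = {}
    for r in range(q):
        popn = df.loc[r, "population"]
        t = 0 if popn != "CB" else 1
        fe = farm_eff.setdefault((popn, df.loc[r, "farm"], df.loc[r, "sex"]),
                                 rng.normal(0, np.sqrt(var_e[t]) * 0.3))
        le = lit_eff.setdefault(df.loc[r, "litter"],
                                rng.normal(0, np.sqrt(var_u[t])))
        y[r] = fe + le + df.loc[r, "genetic"] + rng.normal(
            0, np.sqrt(var_e[t]))
    df["y"] = y
    return df


def pb_ids_of(panel, breed=None):
    if breed is None:
        return [i for i, b in zip(panel.ids, panel.breeds) if b in PURE_BREEDS]
    return [i for i, b in zip(panel.ids, panel.breeds) if b == breed]


def gls_oracle(spec, vcs, matrices, df, trait):
    """Dense generalized-least-squares BLUP, independent of the MME path.

    Builds Var(y) record by record from the trait covariances and blended
    relationship matrices, estimates fixed effects by GLS, and recovers
    every genetic effect as Cov(a, y) V^-1 (y - Xb).
    """
    import pandas as pd

    from crossblup.predict import _genetic_structures, _record_links
    from crossblup.varcomp import build_fixed_design

    ycol = f"y_{trait}" if f"y_{trait}" in df.columns else "y"
    df = df[df[ycol].notna()].reset_index(drop=True)
    structures = _genetic_structures(spec, vcs, matrices)
    keep = []
    for _, row in df.iterrows():
        links = _record_links(spec, row["population"], structures)
        keep.append(all(row["id"] in set(structures[si].ids)
                        for si, _ in links))
    df = df[np.array(keep)].reset_index(drop=True)
    y = df[ycol].to_numpy(float)
    X = build_fixed_design(df, spec)
    n = len(df)
    Gb = {si: np.linalg.inv(s.Ginv) for si, s in enumerate(structures)}
    links = [_record_links(spec, df.loc[r, "population"], structures)
             for r in range(n)]
    aidx = [{si: structures[si].animal_index(df.loc[r, "id"])
             for si, _ in links[r]} for r in range(n)]
    V = np.zeros((n, n))
    for r in range(n):
        for s_ in range(n):
            tot = 0.0
            for si, ti in links[r]:
                for sj, tj in links[s_]:
                    if si == sj:
                        st = structures[si]
                        tot += st.K[ti, tj] * Gb[si][aidx[r][si],
                                                     aidx[s_][si]]
            V[r, s_] = tot
    lit = df["litter"].to_numpy()
    same = lit[:, None] == lit[None, :]
    for popn in df["population"].unique():
        m = (df["population"] == popn).to_numpy()
        V += vcs.litter[popn] * (same & np.outer(m, m))
    V[np.diag_indices(n)] += [vcs.resid[p] for p in df["population"]]
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = Vi @ (y - X @ b)
    out = {}
    for si, s in enumerate(structures):
        for ti, tname in enumerate(s.trait_names):
            vals = np.zeros(s.q)
            for r in range(n):
                for sj, tj in links[r]:
                    if sj == si:
                        vals += s.K[ti, tj] * Gb[si][:, aidx[r][si]] * resid[r]
            out[(s.name, tname)] = pd.Series(vals, index=s.ids)
    return out
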