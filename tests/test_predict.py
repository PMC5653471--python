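import numpy as np
import pandas as pd
import pytest

from crossblup import (GeneticCovBlock, ModelSpec, assemble_mme,
                       assemble_univariate_mme, build_GA, ebv_table,
                       reliability, simulate_hwe_population, solve_mme,
                       true_varcomps)
from crossblup.predict import BLEND
from crossblup.simdata import PURE_BREEDS
from crossblup.varcomp import VarCompSet, build_fixed_design

from conftest import gls_oracle, pb_ids_of, true_origin_matrix


def _mini_varcomps(model, dataset, trait="ADG"):
    return true_varcomps(dataset, trait, model)


@pytest.fixture(scope="module")
def boa_inputs(small_dataset):
    from crossblup import breed_allele_content, build_partial
    panel = small_dataset.panel.subset(small_dataset.genotyped_ids())
    om = true_origin_matrix(small_dataset)
    mats = {b: build_partial(breed_allele_content(panel, om, b))
            for b in PURE_BREEDS}
    return panel, mats


class TestAssembly:
    def test_equation_count_audit_boa(self, small_dataset, boa_inputs):
        panel, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        system = assemble_mme(spec, vcs, mats, small_dataset.phenotypes,
                              trait="ADG")
        n_genetic = sum(2 * len(m.ids) for m in mats.values())
        ph = small_dataset.phenotypes
        used = ph[ph["id"].isin(set().union(*[set(m.ids)
                                              for m in mats.values()]))]
        assert system.C.shape[0] == (system.n_fixed + len(system.litters)
                                     + n_genetic)
        assert len(system.litters) == used["litter"].nunique()

    def test_duplicate_record_rejected(self, small_dataset, boa_inputs):
        _, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        ph = small_dataset.phenotypes
        dup = pd.concat([ph, ph.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_mme(ModelSpec("BOA", covariate="cov_ADG"), vcs, mats,
                         dup, trait="ADG")


class TestSolutions:
    def test_mme_matches_gls_oracle_on_small_fixture(self, small_dataset,
                                                     boa_inputs):
        panel, mats = boa_inputs
        # 30-record fixture: a subset of phenotyped animals
        ph = small_dataset.phenotypes
        ids = (list(ph[ph["population"] == "S"]["id"][:10])
               + list(ph[ph["population"] == "CB"]["id"][:20]))
        sub = ph[ph["id"].isin(ids)]
        vcs = _mini_varcomps("BOA", small_dataset)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        system = assemble_mme(spec, vcs, mats, sub, trait="ADG")
        sol = solve_mme(system)
        oracle = gls_oracle(spec, vcs, mats, sub, "ADG")
        for (sname, tname), expect in oracle.items():
            got = sol.ebv(sname, tname, list(expect.index))
            assert np.max(np.abs(got.to_numpy() - expect.to_numpy())) < 1e-6

    def test_record_permutation_leaves_ebv_unchanged(self, small_dataset,
                                                     boa_inputs):
        panel, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        ph = small_dataset.phenotypes
        sol1 = solve_mme(assemble_mme(spec, vcs, mats, ph, trait="ADG"))
        shuffled = ph.sample(frac=1.0, random_state=1).reset_index(drop=True)
        sol2 = solve_mme(assemble_mme(spec, vcs, mats, shuffled, trait="ADG"))
        ids = pb_ids_of(panel, "S")
        np.testing.assert_allclose(sol1.ebv("partial-S", "CB", ids),
                                   sol2.ebv("partial-S", "CB", ids),
                                   atol=1e-8)

    def test_zero_genetic_variance_shrinks_ebv_to_zero(self, small_dataset,
                                                       boa_inputs):
        panel, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        scale = 1e-8
        for b in PURE_BREEDS:
            vcs.genetic[b] = GeneticCovBlock(vcs.genetic[b].K * scale)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        sol = solve_mme(assemble_mme(spec, vcs, mats,
                                     small_dataset.phenotypes, trait="ADG"))
        tab = ebv_table(sol)
        assert np.abs(tab["ebv"]).max() < 1e-3

    def test_ridge_equivalence_univariate(self):
        # G = I, no litter: the animal model collapses to ridge regression
        rng = np.random.default_rng(3)
        n = 40
        panel = simulate_hwe_population(n, 60, seed=8)
        from crossblup.grm import GenomicMatrix
        I = GenomicMatrix(list(panel.ids), np.eye(n), "G_A")
        df = pd.DataFrame({"id": panel.ids,
                           "population": ["CB"] * n,
                           "trial": 0, "farm": 0,
                           "sex": ["M", "F"] * (n // 2),
                           "y": rng.normal(size=n)})
        va, ve = 2.0, 3.0
        spec = ModelSpec("GA")
        system = assemble_univariate_mme(I, df, va, None, ve, spec)
        sol = solve_mme(system)
        X = build_fixed_design(df, spec)
        y = df["y"].to_numpy()
        lam = ve / (va * (1 - BLEND) + va * BLEND)  # blended I stays I
        Vi = np.linalg.inv(np.eye(n) * (va + ve))
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a = va / (va + ve) * (y - X @ b)
        got = sol.ebv("G", "EBV", list(panel.ids)).to_numpy()
        np.testing.assert_allclose(got, a, atol=1e-8)

    def test_boa_structures_decouple_when_covariance_zero(self, small_dataset,
                                                          boa_inputs):
        # with zero PB-CB genetic covariance in the maternal blocks, the
        # purebred records of those breeds carry no information about the
        # sire-line crossbred effects: shuffling them changes nothing
        panel, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        for b in ("LR", "LW"):
            K = vcs.genetic[b].K.copy()
            K[0, 1] = K[1, 0] = 0.0
            vcs.genetic[b] = GeneticCovBlock(K)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        ph = small_dataset.phenotypes.copy()
        sol1 = solve_mme(assemble_mme(spec, vcs, mats, ph, trait="ADG"))
        rng = np.random.default_rng(0)
        for b in ("LR", "LW"):
            m = (ph["population"] == b) & ph["y_ADG"].notna()
            ph.loc[m, "y_ADG"] = rng.permutation(ph.loc[m, "y_ADG"].to_numpy())
        sol2 = solve_mme(assemble_mme(spec, vcs, mats, ph, trait="ADG"))
        ids = pb_ids_of(panel, "S")
        np.testing.assert_allclose(sol1.ebv("partial-S", "CB", ids),
                                   sol2.ebv("partial-S", "CB", ids),
                                   atol=1e-8)

    def test_ga_gb_rankings_agree_within_breed(self, small_dataset,
                                               genotyped_panel):
        from crossblup import build_GB
        sols = {}
        for m, G in (("GA", build_GA(genotyped_panel)),
                     ("GB", build_GB(genotyped_panel))):
            vcs = _mini_varcomps(m, small_dataset)
            spec = ModelSpec(m, covariate="cov_ADG")
            sols[m] = solve_mme(assemble_mme(spec, vcs, {"G": G},
                                             small_dataset.phenotypes,
                                             trait="ADG"))
        for b in PURE_BREEDS:
            ids = pb_ids_of(genotyped_panel, b)
            r = np.corrcoef(sols["GA"].ebv("G", "CB", ids),
                            sols["GB"].ebv("G", "CB", ids))[0, 1]
            assert r > 0.98

    def test_training_size_improves_accuracy(self, small_dataset,
                                             genotyped_panel):
        vcs = _mini_varcomps("GA", small_dataset)
        G = build_GA(genotyped_panel)
        spec = ModelSpec("GA", covariate="cov_ADG")
        ph = small_dataset.phenotypes
        cb = ph[ph["population"] == "CB"]
        cb = cb[cb["id"].isin(set(G.ids))]
        pb = ph[ph["population"].isin(PURE_BREEDS)]
        truth = ph.set_index("id")["tbv_cb_ADG"]
        accs = []
        for frac in (0.25, 0.6, 1.0):
            train = pd.concat([pb, cb.iloc[: int(len(cb) * frac)]])
            sol = solve_mme(assemble_mme(spec, vcs, {"G": G}, train,
                                         trait="ADG"))
            ids = pb_ids_of(genotyped_panel)
            accs.append(np.corrcoef(sol.ebv("G", "CB", ids),
                                    truth.loc[ids])[0, 1])
        assert accs[0] < accs[1] < accs[2]


class TestReliability:
    def test_single_record_reliability_close_to_h2(self):
        n = 150
        panel = simulate_hwe_population(n, 60, seed=5)
        from crossblup.grm import GenomicMatrix
        I = GenomicMatrix(list(panel.ids), np.eye(n), "G_A")
        rng = np.random.default_rng(1)
        h2, vp = 0.5, 4.0
        df = pd.DataFrame({"id": panel.ids, "population": "CB",
                           "trial": 0, "farm": 0, "sex": "M",
                           "y": rng.normal(size=n)})
        system = assemble_univariate_mme(I, df, h2 * vp, None,
                                         (1 - h2) * vp, ModelSpec("GA"))
        sol = solve_mme(system, compute_inverse=True)
        rel = reliability(sol, "G", "EBV", list(panel.ids))
        assert rel.mean() == pytest.approx(h2, abs=0.02)

    def test_unphenotyped_unrelated_animal_zero(self):
        from crossblup.grm import GenomicMatrix
        n = 20
        I = GenomicMatrix([f"I{k}" for k in range(n)], np.eye(n), "G_A")
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"id": [f"I{k}" for k in range(n - 1)],
                           "population": "CB", "trial": 0, "farm": 0,
                           "sex": "M", "y": rng.normal(size=n - 1)})
        system = assemble_univariate_mme(I, df, 2.0, None, 3.0,
                                         ModelSpec("GA"))
        sol = solve_mme(system, compute_inverse=True)
        rel = reliability(sol, "G", "EBV", [f"I{n - 1}"])
        assert rel.iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_direct_inverse_oracle(self, small_dataset, boa_inputs):
        panel, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        ph = small_dataset.phenotypes
        ids = (list(ph[ph["population"] == "S"]["id"][:15])
               + list(ph[ph["population"] == "CB"]["id"][:25]))
        system = assemble_mme(spec, vcs, mats, ph[ph["id"].isin(ids)],
                              trait="ADG")
        sol = solve_mme(system, compute_inverse=True)
        Cinv = np.linalg.inv(system.C)
        some = pb_ids_of(panel, "S")[:5]
        rel = reliability(sol, "partial-S", "CB", some)
        s = system.structures[0]
        assert s.name == "partial-S"
        for i, r in rel.items():
            k = system.eq_index(0, 1, i)
            expect = 1.0 - Cinv[k, k] / (s.K[1, 1] * s.Gdiag[
                s.animal_index(i)])
            assert r == pytest.approx(max(0.0, expect), abs=1e-8)

    def test_requires_inverse(self, small_dataset, boa_inputs):
        panel, mats = boa_inputs
        vcs = _mini_varcomps("BOA", small_dataset)
        spec = ModelSpec("BOA", covariate="cov_ADG")
        sol = solve_mme(assemble_mme(spec, vcs, mats,
                                     small_dataset.phenotypes, trait="ADG"))
        with pytest.raises(ValueError, match="inverse"):
            reliability(sol, "partial-S", "CB", ["S_0"])
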