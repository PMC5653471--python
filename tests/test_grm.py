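import itertools

import numpy as np
import pandas as pd
import pytest

from crossblup import (OriginMatrix, allele_frequencies, breed_allele_content,
                       breed_specific_frequencies, build_GA, build_GB,
                       build_partial, build_pedigree_A, pca_coordinates)
from crossblup.grm import FrequencyVector, check_symmetric
from crossblup.simdata import (HaplotypePanel, ORIGIN_CODES, PURE_BREEDS,
                               UNASSIGNED)

from conftest import pb_ids_of, true_origin_matrix


def _panel(haplo, breeds, ids=None):
    haplo = np.asarray(haplo, dtype=np.int8)
    n, L = haplo.shape[0], haplo.shape[1]
    return HaplotypePanel(ids or [f"I{k}" for k in range(n)],
                          np.array(breeds, dtype=object),
                          np.ones(L, dtype=int),
                          np.linspace(0, 1, L, endpoint=False), haplo)


class TestAlleleContent:
    def _toy(self):
        # 1 S purebred, 2 CB, 4 loci; hand-set origins on the CB gametes
        hap = [
            [[1, 0], [1, 1], [0, 0], [1, 1]],   # S1
            [[1, 0], [0, 1], [1, 1], [0, 0]],   # CB1
            [[0, 1], [1, 0], [0, 0], [1, 1]],   # CB2
        ]
        panel = _panel(hap, ["S", "CB", "CB"], ["S1", "CB1", "CB2"])
        S, LR, LW, U = (ORIGIN_CODES["S"], ORIGIN_CODES["LR"],
                        ORIGIN_CODES["LW"], UNASSIGNED)
        codes = np.array([
            [[S, LR], [S, LW], [U, LR], [S, LR]],
            [[S, LW], [U, LR], [S, U], [S, LW]],
        ], dtype=np.int8)
        return panel, OriginMatrix(["CB1", "CB2"], codes)

    def test_other_maternal_origin_is_missing(self):
        panel, om = self._toy()
        c = breed_allele_content(panel, om, "LR")
        # CB1 maternal alleles (0,1,1,0) with origins (LR,LW,LR,LR):
        # the LW-origin allele at locus 2 is missing for target LR
        row = c.values[c.ids.index("CB1")]
        np.testing.assert_array_equal(row, [0.0, np.nan, 1.0, 0.0])

    def test_paternal_s_allele_counted(self):
        panel, om = self._toy()
        c = breed_allele_content(panel, om, "S")
        # CB1 paternal alleles (1,0,1,0) with origins (S,S,U,S)
        row1 = c.values[c.ids.index("CB1")]
        np.testing.assert_array_equal(row1, [1.0, 0.0, np.nan, 0.0])

    def test_full_toy_matches_hand_coding(self):
        panel, om = self._toy()
        c = breed_allele_content(panel, om, "S")
        np.testing.assert_array_equal(c.values[0], [1, 2, 0, 2])  # S1 dosage
        # CB2 paternal alleles (0,1,0,1) with origins (S,U,S,S)
        np.testing.assert_array_equal(c.values[2], [0.0, np.nan, 0.0, 1.0])

    def test_unknown_breed_rejected(self):
        panel, om = self._toy()
        with pytest.raises(ValueError):
            breed_allele_content(panel, om, "XX")


class TestFrequencies:
    def test_purebred_only_direct_count(self):
        hap = [[[0, 0]], [[1, 0]], [[0, 1]], [[1, 1]]]  # dosages 0,1,1,2
        panel = _panel(hap, ["S"] * 4)
        om = OriginMatrix([], np.zeros((0, 1, 2), dtype=np.int8))
        c = breed_allele_content(panel, om, "S")
        f = breed_specific_frequencies(c)
        assert f.raw[0] == pytest.approx(0.5)

    def test_fixed_allele_clipped(self):
        hap = [[[1, 1]], [[1, 1]]]
        panel = _panel(hap, ["S", "CB"], ["S1", "CB1"])
        codes = np.array([[[ORIGIN_CODES["S"], ORIGIN_CODES["LR"]]]],
                         dtype=np.int8)
        c = breed_allele_content(panel, OriginMatrix(["CB1"], codes), "S")
        f = breed_specific_frequencies(c)
        assert f.raw[0] == pytest.approx(1.0)
        assert f.values[0] == pytest.approx(0.99)

    def test_cb_alleles_enter_count(self):
        # 1 S animal dosage 1, two CB each contributing one assigned S allele
        hap = [[[1, 0]], [[1, 0]], [[0, 1]]]
        panel = _panel(hap, ["S", "CB", "CB"], ["S1", "CB1", "CB2"])
        S, LR = ORIGIN_CODES["S"], ORIGIN_CODES["LR"]
        codes = np.array([[[S, LR]], [[S, LR]]], dtype=np.int8)
        c = breed_allele_content(panel, OriginMatrix(["CB1", "CB2"], codes),
                                 "S")
        f = breed_specific_frequencies(c)
        # alleles: S1 (1,0), CB1 paternal 1, CB2 paternal 0 -> 2/4
        assert f.raw[0] == pytest.approx(0.5)

    def test_zero_informative_warns_default_half(self):
        hap = [[[1, 1]], [[0, 0]]]
        panel = _panel(hap, ["CB", "CB"], ["CB1", "CB2"])
        codes = np.full((2, 1, 2), UNASSIGNED, dtype=np.int8)
        c = breed_allele_content(panel, OriginMatrix(["CB1", "CB2"], codes),
                                 "LR")
        # no LR purebreds and no assigned alleles at all
        assert c.values.shape == (2, 1)
        with pytest.warns(UserWarning, match="no informative"):
            f = breed_specific_frequencies(c)
        assert f.raw[0] == 0.5


class TestGA:
    def test_all_heterozygous_centered_to_zero(self):
        hap = [[[1, 0]] * 6]
        panel = _panel(hap, ["POP"])
        G = build_GA(panel)
        assert G.values[0, 0] == pytest.approx(0.0)

    def test_homozygote_closed_form(self):
        hap = [[[1, 1]] * 6]
        panel = _panel(hap, ["POP"])
        p = FrequencyVector(np.full(6, 0.5), "across", raw=np.full(6, 0.5))
        G = build_GA(panel, freq=p)
        # (2-1)^2 / (2*0.25) = 2 per locus, averaged over loci
        assert G.values[0, 0] == pytest.approx(2.0)

    def test_hwe_population_mean_diagonal_near_one(self):
        from crossblup import simulate_hwe_population
        panel = simulate_hwe_population(200, 800, seed=3)
        G = build_GA(panel)
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_between_breed_mean_nonpositive_on_drifted_panels(
            self, genotyped_panel):
        G = build_GA(genotyped_panel)
        for a, b in itertools.combinations(PURE_BREEDS, 2):
            blk = G.values[np.ix_(
                [k for k, x in enumerate(genotyped_panel.breeds) if x == a],
                [k for k, x in enumerate(genotyped_panel.breeds) if x == b])]
            assert blk.mean() < 0


class TestGB:
    def _freqs(self, p_by_breed, L):
        return {b: FrequencyVector(np.full(L, p), f"pb-{b}",
                                   raw=np.full(L, p))
                for b, p in p_by_breed.items()}

    def test_perfectly_centered_purebred_row_is_zero(self):
        hap = [[[1, 0], [0, 1]],   # S dosage (1,1) = 2 * 0.5
               [[1, 1], [0, 0]],
               [[0, 0], [1, 1]]]
        panel = _panel(hap, ["S", "LR", "LW"])
        freqs = self._freqs({"S": 0.5, "LR": 0.3, "LW": 0.7}, 2)
        G = build_GB(panel, pb_freqs=freqs)
        np.testing.assert_allclose(G.values[0], 0.0, atol=1e-12)

    def test_three_animal_toy_matches_hand_computation(self):
        hap = [[[1, 1], [0, 1]],
               [[1, 0], [0, 0]],
               [[0, 0], [1, 1]]]
        panel = _panel(hap, ["S", "LR", "LW"])
        pf = {"S": 0.6, "LR": 0.3, "LW": 0.5}
        freqs = self._freqs(pf, 2)
        G = build_GB(panel, pb_freqs=freqs)
        # independent arithmetic
        M = np.array([[2.0, 1.0], [1.0, 0.0], [0.0, 2.0]])
        pw = 0.5 * 0.6 + 0.25 * 0.3 + 0.25 * 0.5
        center = np.array([[2 * 0.6] * 2, [2 * 0.3] * 2, [2 * 0.5] * 2])
        Z = (M - center) / np.sqrt(2 * pw * (1 - pw))
        np.testing.assert_allclose(G.values, Z @ Z.T / 2, atol=1e-12)

    def test_between_breed_blocks_average_zero(self, genotyped_panel):
        G = build_GB(genotyped_panel)
        for a, b in itertools.combinations(PURE_BREEDS, 2):
            blk = G.values[np.ix_(
                [k for k, x in enumerate(genotyped_panel.breeds) if x == a],
                [k for k, x in enumerate(genotyped_panel.breeds) if x == b])]
            assert abs(blk.mean()) < 0.01


class TestPartial:
    def test_all_missing_cb_gives_zero_rows(self):
        hap = [[[1, 0], [1, 1]], [[1, 0], [0, 1]]]
        panel = _panel(hap, ["S", "CB"], ["S1", "CB1"])
        codes = np.full((1, 2, 2), UNASSIGNED, dtype=np.int8)
        c = breed_allele_content(panel, OriginMatrix(["CB1"], codes), "S")
        G = build_partial(c)
        k = G.ids.index("CB1")
        np.testing.assert_allclose(G.values[k], 0.0, atol=1e-12)
        np.testing.assert_allclose(G.values[:, k], 0.0, atol=1e-12)

    def test_two_locus_toy_blocks_match_hand_arithmetic(self):
        # S1 dosages (1, 2); CB1 paternal alleles (1, 0), both S origin
        hap = [[[1, 0], [1, 1]], [[1, 0], [0, 1]]]
        panel = _panel(hap, ["S", "CB"], ["S1", "CB1"])
        S, LR = ORIGIN_CODES["S"], ORIGIN_CODES["LR"]
        codes = np.array([[[S, LR], [S, LR]]], dtype=np.int8)
        c = breed_allele_content(panel, OriginMatrix(["CB1"], codes), "S")
        G = build_partial(c)
        # frequencies: locus1 (1+1)/3, locus2 (2+0)/3; both 2/3
        # D = 1/(2*(2/3)*(1/3)) = 2.25
        # S centered: (1-4/3, 2-4/3); CB centered: (1-2/3, 0-2/3)
        assert G.values[0, 0] == pytest.approx(0.625)
        assert G.values[0, 1] == pytest.approx(-0.625)
        assert G.values[1, 1] == pytest.approx(0.625)

    def test_pb_block_equals_vanraden_on_same_inputs(self, small_dataset,
                                                     genotyped_panel):
        om = true_origin_matrix(small_dataset)
        c = breed_allele_content(genotyped_panel, om, "LR")
        f = breed_specific_frequencies(c)
        Gp = build_partial(c, f)
        lr_ids = pb_ids_of(genotyped_panel, "LR")
        Gv = build_GA(genotyped_panel, ids=lr_ids, freq=f)
        np.testing.assert_allclose(Gp.loc(lr_ids), Gv.values, atol=1e-10)

    def test_cb_diagonals_near_genome_fractions(self, small_dataset,
                                                genotyped_panel):
        om = true_origin_matrix(small_dataset)
        cb_ids = om.ids
        for b, expect in (("S", 0.5), ("LR", 0.25), ("LW", 0.25)):
            G = build_partial(breed_allele_content(genotyped_panel, om, b))
            d = np.diag(G.loc(cb_ids))
            assert d.mean() == pytest.approx(expect, abs=0.04)
            assert ((d >= 0) & (d <= 2)).all()

    def test_frequency_flavor_mismatch_rejected(self, small_dataset,
                                                genotyped_panel):
        om = true_origin_matrix(small_dataset)
        c = breed_allele_content(genotyped_panel, om, "LR")
        f = breed_specific_frequencies(
            breed_allele_content(genotyped_panel, om, "LW"))
        with pytest.raises(ValueError, match="flavor"):
            build_partial(c, f)

    def test_symmetry_of_all_matrices(self, small_dataset, genotyped_panel):
        om = true_origin_matrix(small_dataset)
        mats = [build_GA(genotyped_panel), build_GB(genotyped_panel),
                build_pedigree_A(small_dataset.pedigree)]
        mats += [build_partial(breed_allele_content(genotyped_panel, om, b))
                 for b in PURE_BREEDS]
        for G in mats:
            assert check_symmetric(G)
            if G.flavor in ("G_A", "G_B"):
                assert (np.diag(G.values) >= 0).all()


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = pd.DataFrame({"id": ["A", "B", "C"],
                            "sire": ["0"] * 3, "dam": ["0"] * 3})
        A = build_pedigree_A(ped)
        np.testing.assert_allclose(A.values, np.eye(3))

    def test_full_sibs_half(self):
        ped = pd.DataFrame({"id": ["A", "B", "X", "Y"],
                            "sire": ["0", "0", "A", "A"],
                            "dam": ["0", "0", "B", "B"]})
        A = build_pedigree_A(ped)
        assert A.loc(["X"], ["Y"])[0, 0] == pytest.approx(0.5)
        assert A.loc(["X"], ["X"])[0, 0] == pytest.approx(1.0)

    def test_inbred_mating_matches_path_counting(self):
        # E = full-sib mating; F = parent-offspring mating
        ped = pd.DataFrame({"id": ["A", "B", "C", "D", "E", "F"],
                            "sire": ["0", "0", "A", "A", "C", "A"],
                            "dam": ["0", "0", "B", "B", "D", "C"]})
        A = build_pedigree_A(ped)
        get = lambda i, j: A.loc([i], [j])[0, 0]
        assert get("E", "E") == pytest.approx(1.25)   # 1 + 0.5 * a(C,D)
        assert get("F", "F") == pytest.approx(1.25)   # 1 + 0.5 * a(A,C)
        assert get("A", "E") == pytest.approx(0.5)
        assert get("C", "E") == pytest.approx(0.75)
        assert get("E", "F") == pytest.approx(0.625)

    def test_unsorted_pedigree_rejected(self):
        ped = pd.DataFrame({"id": ["X", "A", "B"],
                            "sire": ["A", "0", "0"],
                            "dam": ["B", "0", "0"]})
        with pytest.raises(ValueError, match="parents-first"):
            build_pedigree_A(ped)


class TestPCA:
    def test_block_structure_separated_by_pc1(self):
        G = np.block([[np.full((5, 5), 0.8), np.zeros((5, 5))],
                      [np.zeros((5, 5)), np.full((5, 5), 0.8)]])
        G += 0.2 * np.eye(10)
        from crossblup.grm import GenomicMatrix
        gm = GenomicMatrix([f"I{k}" for k in range(10)], G, "G_A")
        df = pca_coordinates(gm, k=2)
        pc1 = df["PC1"].to_numpy()
        assert len(set(np.sign(pc1[:5]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[5])

    def test_identity_explained_fraction(self):
        from crossblup.grm import GenomicMatrix
        gm = GenomicMatrix([f"I{k}" for k in range(8)], np.eye(8), "G_A")
        df = pca_coordinates(gm, k=2)
        assert sum(df.attrs["explained"]) == pytest.approx(2 / 8)

    def test_topk_reconstruction_is_best_rank_k(self, genotyped_panel):
        G = build_GA(genotyped_panel)
        k = 3
        df = pca_coordinates(G, k=k)
        C = df.to_numpy()
        # independent eigen-truncation oracle
        vals, vecs = np.linalg.eigh(G.values)
        idx = np.argsort(vals)[::-1][:k]
        best = (vecs[:, idx] * vals[idx]) @ vecs[:, idx].T
        np.testing.assert_allclose(C @ C.T, best, atol=1e-8)

    def test_k_beyond_rank_rejected(self):
        from crossblup.grm import GenomicMatrix
        gm = GenomicMatrix(["a", "b"], np.ones((2, 2)), "G_A")
        with pytest.raises(ValueError):
            pca_coordinates(gm, k=2)
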