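"""Relationship-matrix construction against closed forms and dense oracles."""

import numpy as np
import pandas as pd
import pytest

from reactnorm.pedkin import (
    KinshipSet,
    Pedigree,
    PedigreeError,
    blend_G,
    build_A,
    build_Ainv,
    build_G,
    build_Hinv,
)

from conftest import random_pedigree


class TestNumeratorRelationship:
    def test_closed_form_relationships(self, toy_pedigree):
        A = build_A(toy_pedigree)
        ids = list(toy_pedigree.ids)
        a = lambda x, y: A[ids.index(x), ids.index(y)]
        assert a("A", "B") == 0.0  # unrelated founders
        assert a("A", "C") == 0.5  # parent-offspring
        assert a("C", "D") == 0.75  # full sib-ish via parent-offspring mating
        # D is offspring of A x C where C is A's offspring: F = 0.25
        assert a("D", "D") == pytest.approx(1.25)

    def test_half_and_full_sibs(self):
        ped = Pedigree.from_frame(
            pd.DataFrame(
                {
                    "animal": ["S", "D1", "D2", "C1", "C2", "C3"],
                    "sire": ["0", "0", "0", "S", "S", "S"],
                    "dam": ["0", "0", "0", "D1", "D2", "D1"],
                }
            )
        )
        A = build_A(ped)
        ids = list(ped.ids)
        a = lambda x, y: A[ids.index(x), ids.index(y)]
        assert a("C1", "C2") == 0.25  # half sibs
        assert a("C1", "C3") == 0.5  # full sibs
        assert a("C1", "C1") == 1.0  # non-inbred

    def test_founders_identity(self):
        ped = Pedigree.from_frame(
            pd.DataFrame({"animal": list("ab"), "sire": "0", "dam": "0"})
        )
        assert np.array_equal(build_A(ped), np.eye(2))
        assert np.allclose(build_Ainv(ped).toarray(), np.eye(2))

    def test_cycle_detection(self):
        df = pd.DataFrame(
            {"animal": ["A", "B"], "sire": ["B", "A"], "dam": ["0", "0"]}
        )
        with pytest.raises(PedigreeError):
            Pedigree.from_frame(df)

    def test_sparse_inverse_matches_dense_inversion(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(rng, n_founders=10, n_off=40)
        A = build_A(ped)
        Ainv = build_Ainv(ped).toarray()
        assert np.abs(A @ Ainv - np.eye(len(ped))).max() < 1e-8

    def test_removing_unrelated_animal_leaves_block(self):
        base = pd.DataFrame(
            {
                "animal": ["A", "B", "C"],
                "sire": ["0", "0", "A"],
                "dam": ["0", "0", "B"],
            }
        )
        plus = pd.concat(
            [base, pd.DataFrame({"animal": ["Z"], "sire": ["0"], "dam": ["0"]})]
        )
        Ainv1 = build_Ainv(Pedigree.from_frame(base)).toarray()
        Ainv2 = build_Ainv(Pedigree.from_frame(plus)).toarray()
        assert np.allclose(Ainv2[:3, :3], Ainv1)

    def test_a_psd_and_colleau_consistency(self, small_sim):
        ped = small_sim.pedigree
        sub = ped.ids[~ped.is_founder][:60]
        A22 = ped.a_submatrix(sub)
        np.linalg.cholesky(A22 + 1e-10 * np.eye(len(A22)))  # psd
        d0, F = ped.factored_submatrix(sub)
        assert np.abs(np.diag(d0) + (F @ F.T).toarray() - A22).max() < 1e-12

    def test_inbreeding_matches_tabular_diagonal(self):
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, n_founders=6, n_off=50)
        A = build_A(ped)
        assert np.allclose(ped.inbreeding(), np.diag(A) - 1.0, atol=1e-12)


class TestGenomicRelationship:
    def make_geno(self, rng, n=5, m=20):
        p = rng.uniform(0.2, 0.5, m)
        M = rng.binomial(2, p, size=(n, m)).astype(float)
        mono = (M.mean(axis=0) == 0) | (M.mean(axis=0) == 2)
        M[0, mono] = 1.0  # keep every column polymorphic
        return M

    def test_brute_force_formula(self):
        rng = np.random.default_rng(3)
        M = self.make_geno(rng)
        p = M.mean(axis=0) / 2
        G = build_G(M)
        denom = 2 * np.sum(p * (1 - p))
        for i in range(5):
            for j in range(5):
                gij = np.sum((M[i] - 2 * p) * (M[j] - 2 * p)) / denom
                assert G[i, j] == pytest.approx(gij, rel=1e-12)

    def test_identical_rows(self):
        M = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 1]], float)
        G = build_G(M)
        assert G[0, 0] == pytest.approx(G[1, 1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_monomorphic_rejected(self):
        M = np.array([[0, 2], [0, 1], [0, 0]], float)
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(M)

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(4)
        M = self.make_geno(rng, 6, 30)
        perm = rng.permutation(30)
        assert np.allclose(build_G(M), build_G(M[:, perm]))

    def test_centering_identity(self):
        # with p estimated from data the column sums of Z vanish, so the
        # off-diagonal mean balances the diagonal mean: sum_ij G_ij = 0
        rng = np.random.default_rng(5)
        M = self.make_geno(rng, 12, 50)
        G = build_G(M)
        assert abs(G.sum()) < 1e-8


class TestSingleStepInverse:
    def _kinship(self, ped, genotyped, G, eps=0.05):
        return KinshipSet(
            ped=ped,
            genotyped_ids=np.asarray(genotyped),
            Ainv=build_Ainv(ped),
            A22=ped.a_submatrix(genotyped),
            G=G,
            eps=eps,
        )

    def test_no_genotyped_returns_Ainv(self, toy_pedigree):
        kin = KinshipSet(
            ped=toy_pedigree,
            genotyped_ids=np.array([]),
            Ainv=build_Ainv(toy_pedigree),
            A22=np.zeros((0, 0)),
            G=np.zeros((0, 0)),
        )
        H = build_Hinv(kin)
        assert np.allclose(H.toarray(), kin.Ainv.toarray())

    def test_G_equal_A22_cancels(self, toy_pedigree):
        ids = list(toy_pedigree.ids)
        A22 = toy_pedigree.a_submatrix(ids)
        kin = self._kinship(toy_pedigree, ids, A22, eps=0.0)
        H = build_Hinv(kin)
        assert np.abs(H.toarray() - build_Ainv(toy_pedigree).toarray()).max() < 1e-8

    def test_H_matches_joint_covariance_oracle(self):
        # direct H construction: conditional multivariate-normal algebra
        rng = np.random.default_rng(9)
        ped = random_pedigree(rng, n_founders=8, n_off=22)
        A = build_A(ped)
        gen_idx = np.arange(len(ped))[-12:]
        ids = ped.ids[gen_idx]
        A22 = A[np.ix_(gen_idx, gen_idx)]
        # a synthetic psd "genomic" matrix near A22
        E = rng.normal(0, 0.05, A22.shape)
        Gb = A22 + E @ E.T
        kin = self._kinship(ped, ids, Gb, eps=0.0)
        Hinv = build_Hinv(kin).toarray()
        H = np.linalg.inv(Hinv)
        n1 = np.setdiff1d(np.arange(len(ped)), gen_idx)
        A11, A12, A22i = A[np.ix_(n1, n1)], A[np.ix_(n1, gen_idx)], np.linalg.inv(A22)
        H_oracle = np.zeros_like(A)
        H_oracle[np.ix_(gen_idx, gen_idx)] = Gb
        H_oracle[np.ix_(n1, gen_idx)] = A12 @ A22i @ Gb
        H_oracle[np.ix_(gen_idx, n1)] = H_oracle[np.ix_(n1, gen_idx)].T
        H_oracle[np.ix_(n1, n1)] = A11 + A12 @ A22i @ (Gb - A22) @ A22i @ A12.T
        assert np.abs(H - H_oracle).max() < 1e-6

    def test_singular_blend_raises(self, toy_pedigree):
        ids = list(toy_pedigree.ids)
        G = np.zeros((5, 5))  # rank-0 "genomic" matrix
        kin = self._kinship(toy_pedigree, ids, G, eps=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="blending"):
            build_Hinv(kin)

    def test_blending_moves_toward_A22(self, toy_pedigree):
        ids = list(toy_pedigree.ids)
        A22 = toy_pedigree.a_submatrix(ids)
        G = np.eye(5)
        assert np.allclose(blend_G(G, A22, 1.0), A22)
        assert np.allclose(blend_G(G, A22, 0.0), G)
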