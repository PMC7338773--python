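"""Pedigree A, genomic G (VanRaden 2), blending and the single-step H inverse."""

import numpy as np
import pandas as pd
import pytest

import heatnorm as hn
from heatnorm.relationship import (
    GenotypeSet,
    a_inverse,
    blend_G,
    build_A,
    build_G_vanraden2,
    build_H_inverse,
    qc_genotypes,
)


def _geno(dosages, chrom=None, pos=None, ids=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeSet(
        ids=np.arange(1, n + 1) if ids is None else np.asarray(ids),
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        chrom=np.ones(m, dtype=int) if chrom is None else np.asarray(chrom),
        pos=np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos),
        dosages=dosages,
    )


class TestQC:
    def test_exact_filter_semantics(self, rng):
        """Each filter removes exactly the SNPs violating its threshold."""
        n = 400
        good = rng.binomial(2, 0.3, size=(n, 5)).astype(np.int8)
        mono = np.zeros((n, 1), dtype=np.int8)  # MAF 0
        rare = np.zeros((n, 1), dtype=np.int8)
        rare[:8, 0] = 1  # MAF 0.01 < 0.05
        missing = rng.binomial(2, 0.3, size=(n, 1)).astype(np.int8)
        missing[:50, 0] = -1  # call rate 350/400 < 0.90
        hwe_bad = np.ones((n, 1), dtype=np.int8)  # all hets, extreme HWE deviation
        geno = _geno(np.hstack([good, mono, rare, missing, hwe_bad]))
        filtered, report = qc_genotypes(geno)
        assert report["n_removed"] == 4
        assert report["fail_maf"] == 2  # monomorphic and rare
        assert report["fail_call_rate"] == 1
        assert report["fail_hwe"] >= 1
        assert filtered.n_snps == 5

    def test_hwe_type_one_error_bound(self, rng):
        d = rng.binomial(2, 0.3, size=(500, 1000)).astype(np.int8)
        _, report = qc_genotypes(_geno(d), maf_min=0.0, call_rate_min=0.0)
        # expected false positives at p<1e-6 over 1000 HWE SNPs: ~0.001
        assert report["fail_hwe"] <= 1

    def test_all_filtered_raises(self):
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_genotypes(_geno(np.zeros((10, 3), dtype=np.int8)))


class TestAMatrix:
    def test_parent_offspring_and_full_sibs(self, toy_pedigree):
        amat = build_A(toy_pedigree)
        idx = {a: i for i, a in enumerate(amat.ids)}
        assert amat.matrix[idx[1], idx[5]] == pytest.approx(0.5)
        assert amat.matrix[idx[5], idx[6]] == pytest.approx(0.5)
        assert amat.inbreeding[idx[5]] == pytest.approx(0.0)

    def test_offspring_of_full_sibs_inbred(self, toy_pedigree):
        amat = build_A(toy_pedigree)
        idx = {a: i for i, a in enumerate(amat.ids)}
        assert amat.inbreeding[idx[7]] == pytest.approx(0.25)
        assert amat.matrix[idx[7], idx[7]] == pytest.approx(1.25)

    def test_wrights_path_counting_three_generations(self):
        # half sibs 4,5 via common sire 1; 6 = offspring of 4 x 5
        ped = pd.DataFrame(
            {
                "animal": [1, 2, 3, 4, 5, 6],
                "sire": [0, 0, 0, 1, 1, 4],
                "dam": [0, 0, 0, 2, 3, 5],
            }
        )
        amat = build_A(ped)
        idx = {a: i for i, a in enumerate(amat.ids)}
        # half sibs: a = 0.25; their offspring: F = 0.125
        assert amat.matrix[idx[4], idx[5]] == pytest.approx(0.25)
        assert amat.inbreeding[idx[6]] == pytest.approx(0.125)

    def test_cycle_detection(self):
        ped = pd.DataFrame(
            {"animal": [1, 2], "sire": [2, 1], "dam": [0, 0]}
        )
        with pytest.raises(ValueError, match="cycle"):
            build_A(ped)

    def test_sparse_inverse_matches_dense(self, small_sim):
        ped = small_sim.pedigree
        amat = build_A(ped)
        ids, ainv = a_inverse(ped)
        assert np.array_equal(ids, amat.ids)
        dense_inv = np.linalg.inv(amat.matrix)
        assert np.abs(ainv.toarray() - dense_inv).max() < 1e-10

    def test_positive_semidefinite(self, small_sim):
        amat = build_A(small_sim.pedigree)
        assert np.linalg.eigvalsh(amat.matrix).min() > -1e-10


class TestGMatrix:
    def test_single_snp_closed_form(self):
        g = build_G_vanraden2(_geno([[0], [1], [2]]))
        # p = 0.5: Z = (-1, 0, 1), D = 1/(2*0.25*... ) = 2
        assert g.d_weights[0] == pytest.approx(2.0)
        assert np.diag(g.matrix) == pytest.approx([2.0, 0.0, 2.0])

    def test_mean_diagonal_near_one_under_hwe(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 3000), size=(800, 3000))
        g = build_G_vanraden2(_geno(d.astype(np.int8)))
        assert np.mean(np.diag(g.matrix)) == pytest.approx(1.0, abs=0.05)

    def test_duplicate_animal_rows_identical(self, rng):
        d = rng.binomial(2, 0.3, size=(5, 50)).astype(np.int8)
        d[4] = d[0]
        poly = (d.sum(axis=0) > 0) & (d.sum(axis=0) < 2 * d.shape[0])
        d = d[:, poly]
        g = build_G_vanraden2(_geno(d))
        assert np.allclose(g.matrix[0], g.matrix[4])

    def test_snp_order_invariance(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 60), size=(20, 60)).astype(np.int8)
        g1 = build_G_vanraden2(_geno(d))
        perm = rng.permutation(60)
        order = np.argsort(perm)  # keep positions increasing after permutation
        g2 = build_G_vanraden2(_geno(d[:, perm][:, order]))
        assert np.allclose(g1.matrix, g2.matrix)


class TestBlending:
    def test_omega_limits(self, rng):
        d = rng.binomial(2, 0.3, size=(8, 40)).astype(np.int8)
        g = build_G_vanraden2(_geno(d))
        a22 = np.eye(8)
        assert np.allclose(blend_G(g, a22, omega=1.0).matrix, g.matrix)
        assert np.allclose(blend_G(g, a22, omega=0.0).matrix, a22)

    def test_blending_guarantees_positive_definite(self, rng):
        # rank-deficient G: fewer SNPs than animals
        d = rng.binomial(2, 0.4, size=(30, 5)).astype(np.int8)
        g = build_G_vanraden2(_geno(d))
        a22 = np.eye(30)
        blended = blend_G(g, a22, omega=0.95)
        min_eig = np.linalg.eigvalsh(blended.matrix).min()
        assert min_eig >= 0.05 * 1.0 - 1e-10


class TestHInverse:
    def test_no_genotypes_equals_a_inverse(self, toy_pedigree):
        h = build_H_inverse(toy_pedigree, None)
        _, ainv = a_inverse(toy_pedigree)
        assert (h.matrix != ainv).nnz == 0  # bit-exact

    def test_genomic_block_equal_a22_reduces_to_a_inverse(self, toy_pedigree):
        from heatnorm.relationship import AMatrix, GMatrix

        amat = build_A(toy_pedigree)
        gen_ids = [5, 6, 7]
        g_star = GMatrix(
            ids=np.array(gen_ids),
            matrix=amat.block(gen_ids),
            d_weights=np.array([]),
            freqs=np.array([]),
        )
        h = build_H_inverse(toy_pedigree, g_star)
        ainv_dense = np.linalg.inv(amat.matrix)
        # reorder dense A^-1 into H ordering
        order = [a for a in amat.ids if a not in gen_ids] + gen_ids
        idx = [list(amat.ids).index(a) for a in order]
        assert np.abs(h.to_dense() - ainv_dense[np.ix_(idx, idx)]).max() < 1e-8

    def test_joint_distribution_oracle(self, rng):
        """H from the conditional-genomic identity, inverted numerically."""
        ped = pd.DataFrame(
            {
                "animal": [1, 2, 3, 4, 5, 6],
                "sire": [0, 0, 1, 1, 3, 3],
                "dam": [0, 0, 2, 2, 4, 4],
            }
        )
        amat = build_A(ped)
        gen_ids = [5, 6]
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 200), size=(2, 200)).astype(np.int8)
        poly = (d.sum(axis=0) > 0) & (d.sum(axis=0) < 2 * d.shape[0])
        d = d[:, poly]
        g = build_G_vanraden2(_geno(d, ids=gen_ids))
        g_star = blend_G(g, amat.block(gen_ids), omega=0.95)

        ids = list(amat.ids)
        nidx = [ids.index(a) for a in [1, 2, 3, 4]]
        gidx = [ids.index(a) for a in gen_ids]
        A11 = amat.matrix[np.ix_(nidx, nidx)]
        A12 = amat.matrix[np.ix_(nidx, gidx)]
        A22 = amat.matrix[np.ix_(gidx, gidx)]
        A22i = np.linalg.inv(A22)
        Gm = g_star.matrix
        H = np.block(
            [
                [A11 + A12 @ A22i @ (Gm - A22) @ A22i @ A12.T, A12 @ A22i @ Gm],
                [Gm @ A22i @ A12.T, Gm],
            ]
        )
        h = build_H_inverse(ped, g_star)
        assert np.abs(h.to_dense() - np.linalg.inv(H)).max() < 1e-8

    def test_symmetry(self, small_sim):
        geno, _ = qc_genotypes(small_sim.genotypes)
        amat = build_A(small_sim.pedigree)
        g = build_G_vanraden2(geno)
        g_star = blend_G(g, amat.block(g.ids))
        h = build_H_inverse(small_sim.pedigree, g_star)
        dense = h.to_dense()
        assert np.abs(dense - dense.T).max() < 1e-8

    def test_singular_g_star_advises_blending(self, toy_pedigree, rng):
        from heatnorm.relationship import GMatrix

        singular = GMatrix(
            ids=np.array([5, 6]),
            matrix=np.ones((2, 2)),
            d_weights=np.array([]),
            freqs=np.array([]),
        )
        with pytest.raises(ValueError, match="blend"):
            build_H_inverse(toy_pedigree, singular)
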