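"""Indirect candidate prediction: backsolving, RPG algebra and the four
predictors, each against an independent dense-algebra oracle."""

import numpy as np
import pandas as pd
import pytest

from ssgblup import (
    CandidateSet,
    EvaluationSolutions,
    MarkerScaling,
    ModelSpec,
    RegularizationSpec,
    a_submatrix,
    allele_frequencies,
    backsolve_snp_effects,
    build_genomic_factor,
    make_pedigree,
    parent_status,
    predict,
    rpg_candidates_ancestor,
    rpg_candidates_exact,
    rpg_genotyped,
    rpg_regression,
    tabular_a,
)
from ssgblup.genomics import dense_gc, dense_z
from ssgblup.workflow import solve_evaluation

from conftest import random_pedigree


def build_instance(seed, n=45, n_g=14, m=10, w=0.2, n_cand=5):
    """Pedigree with a genotyped band and leaf candidates, plus a factor."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n)
    cand = np.arange(n - n_cand + 1, n + 1)
    pool = np.arange(8, n - n_cand)
    gcodes = np.sort(rng.choice(pool, size=n_g, replace=False))
    counts = rng.integers(0, 3, size=(n_g, m)).astype(np.int8)
    counts[0] = 1
    p = allele_frequencies(counts)
    agg = a_submatrix(ped, gcodes)
    reg = RegularizationSpec.w_agg(w, agg)
    fac = build_genomic_factor(counts, MarkerScaling.vanraden(p, w=w), reg)
    u_g = rng.standard_normal(n_g)
    return ped, gcodes, cand, counts, fac, agg, u_g, rng


class TestBacksolve:
    def test_zero_solutions_give_zero_effects(self):
        _, _, _, _, fac, _, _, _ = build_instance(0)
        assert np.allclose(backsolve_snp_effects(fac, np.zeros(fac.n)), 0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equals_dense_bzt_gcinv(self, seed):
        _, _, _, counts, fac, _, u_g, _ = build_instance(seed)
        got = backsolve_snp_effects(fac, u_g)
        z = dense_z(counts, fac.p)
        ref = fac.scaling.b_diag * (z.T @ np.linalg.solve(dense_gc(fac), u_g))
        assert np.allclose(got, ref, atol=1e-8)

    def test_converged_snpblup_matches_backsolve(self, mini_study):
        sol = mini_study.sol_snp
        backsolved = backsolve_snp_effects(sol.factor, sol.u_g)
        scale = max(np.abs(sol.snp_effects).max(), 1e-3)
        assert np.allclose(backsolved, sol.snp_effects,
                           atol=10 * 1e-7 * scale)

    def test_dimension_mismatch(self):
        _, _, _, _, fac, _, _, _ = build_instance(4)
        with pytest.raises(ValueError):
            backsolve_snp_effects(fac, np.zeros(fac.n + 1))


class TestRpgGenotyped:
    @pytest.mark.parametrize("seed", [5, 6])
    def test_woodbury_identity_w_agg_gcinv(self, seed):
        _, _, _, _, fac, agg, u_g, _ = build_instance(seed)
        d_g = rpg_genotyped(u_g, fac)
        ref = fac.reg.w * (agg @ np.linalg.solve(dense_gc(fac), u_g))
        assert np.allclose(d_g, ref, atol=1e-8)

    def test_vanishes_as_w_shrinks(self):
        # d_g = w A_gg G_C^-1 u_g -> 0 as w -> 0 for u_g in the range of
        # the marker term Z B Z' (centred Z annihilates the 1-vector, so a
        # mean component would persist in d_g by design)
        ped, gcodes, _, counts, _, agg, _, rng = build_instance(7)
        p = allele_frequencies(counts)
        u_g = dense_z(counts, p) @ rng.standard_normal(counts.shape[1])
        norms = []
        for w in (0.2, 1e-4):
            reg = RegularizationSpec.w_agg(w, agg)
            fac = build_genomic_factor(counts,
                                       MarkerScaling.vanraden(p, w=w), reg)
            norms.append(np.linalg.norm(rpg_genotyped(u_g, fac))
                         / np.linalg.norm(u_g))
        assert norms[1] < 0.02 and norms[1] < norms[0] / 10


class TestRpgCandidates:
    @pytest.mark.parametrize("seed", [8, 9, 10])
    def test_two_step_and_ancestor_match_dense(self, seed):
        ped, gcodes, cand, _, fac, agg, u_g, _ = build_instance(seed)
        d_g = rpg_genotyped(u_g, fac)
        exact = rpg_candidates_exact(ped, gcodes, cand, d_g, fac.reg.agg_factor)
        anc = rpg_candidates_ancestor(ped, gcodes, cand, d_g)
        a = tabular_a(ped)
        ref = a[np.ix_(cand - 1, gcodes - 1)] @ np.linalg.solve(agg, d_g)
        assert np.allclose(exact, ref, atol=1e-8)
        assert np.allclose(anc, ref, atol=1e-8)

    def test_both_parents_genotyped_is_parent_average(self):
        # leaf candidate of two genotyped parents: A_cg row is the mean of
        # the parents' A_gg rows, so d_c = (d_sire + d_dam) / 2
        ped = make_pedigree([0, 0, 0, 1, 1], [0, 0, 0, 2, 3])
        gcodes = np.array([1, 2, 3])
        import scipy.linalg as la

        agg_factor = la.cholesky(a_submatrix(ped, gcodes), lower=True)
        d_g = np.array([0.4, -0.2, 1.0])
        got = rpg_candidates_exact(ped, gcodes, np.array([4, 5]), d_g,
                                   agg_factor)
        assert got == pytest.approx([(0.4 - 0.2) / 2, (0.4 + 1.0) / 2])
        anc = rpg_candidates_ancestor(ped, gcodes, np.array([4, 5]), d_g)
        assert anc == pytest.approx(list(got))

    def test_unrelated_and_founder_candidates_get_zero(self):
        # animal 4 is an unrelated founder candidate
        ped = make_pedigree([0, 0, 1, 0], [0, 0, 2, 0])
        gcodes = np.array([1, 2, 3])
        import scipy.linalg as la

        agg_factor = la.cholesky(a_submatrix(ped, gcodes), lower=True)
        d_g = np.array([1.0, 2.0, 3.0])
        assert rpg_candidates_exact(ped, gcodes, np.array([4]), d_g,
                                    agg_factor) == pytest.approx([0.0])
        assert rpg_candidates_ancestor(ped, gcodes, np.array([4]),
                                       d_g) == pytest.approx([0.0])

    def test_overlap_rejected(self):
        ped, gcodes, cand, _, fac, _, u_g, _ = build_instance(11)
        with pytest.raises(ValueError, match="disjoint"):
            rpg_candidates_exact(ped, gcodes, gcodes[:2],
                                 rpg_genotyped(u_g, fac), fac.reg.agg_factor)


class TestRpgRegression:
    def test_coefficients_match_lstsq_oracle(self, mini_study):
        sol = mini_study.sol_reduced
        cand = mini_study.study.candidates
        _, a_hat, b_hat = rpg_regression(sol.ped, sol, cand)
        x = np.column_stack([np.ones(sol.u_g.size), sol.u_g])
        ref, *_ = np.linalg.lstsq(x, sol.rpg_genotyped, rcond=None)
        assert a_hat == pytest.approx(ref[0], abs=1e-10)
        assert b_hat == pytest.approx(ref[1], abs=1e-10)

    def test_perfect_proportionality_recovered(self):
        ped, gcodes, cand, _, fac, _, _, rng = build_instance(12)
        u = rng.standard_normal(ped.n)
        c = 0.37
        sol = EvaluationSolutions(
            ped=ped, factor=fac, genotyped_codes=gcodes, u=u,
            fixed=np.empty(0), fixed_labels=[])
        # force d_g proportional to u_g
        sol._rpg_genotyped = c * sol.u_g
        d_c, a_hat, b_hat = rpg_regression(ped, sol, cand)
        assert a_hat == pytest.approx(0.0, abs=1e-12)
        assert b_hat == pytest.approx(c)
        for k, code in enumerate(cand):
            s, d = ped.sire[code - 1], ped.dam[code - 1]
            expect = 0.5 * ((c * u[s - 1] if s else 0.0)
                            + (c * u[d - 1] if d else 0.0))
            assert d_c[k] == pytest.approx(expect)


class TestPredict:
    def make_solutions(self, seed):
        ped, gcodes, cand, counts, fac, _, u_g, rng = build_instance(seed)
        u = rng.standard_normal(ped.n)
        u[gcodes - 1] = u_g
        sol = EvaluationSolutions(ped=ped, factor=fac,
                                  genotyped_codes=gcodes, u=u,
                                  fixed=np.empty(0), fixed_labels=[],
                                  jfactor_mu=0.15,
                                  jfactor_covariate=rng.uniform(-1, 0, ped.n))
        cset = CandidateSet(
            codes=cand,
            counts=rng.integers(0, 3, size=(cand.size, fac.m)).astype(np.int8),
            ids=[str(c) for c in cand])
        return ped, sol, cset

    def test_pa_mean_of_parent_gebv(self):
        ped = make_pedigree([0, 0, 1], [0, 0, 2])
        counts = np.array([[1, 0], [1, 2]], dtype=np.int8)
        fac = build_genomic_factor(
            counts, MarkerScaling.vanraden(allele_frequencies(counts), w=0.2),
            RegularizationSpec.w_agg(0.2, a_submatrix(ped, np.array([1, 2]))))
        sol = EvaluationSolutions(ped=ped, factor=fac,
                                  genotyped_codes=np.array([1, 2]),
                                  u=np.array([2.0, 4.0, 0.0]),
                                  fixed=np.empty(0), fixed_labels=[])
        cset = CandidateSet(codes=np.array([3]),
                            counts=np.array([[1, 1]], dtype=np.int8),
                            ids=["3"])
        out = predict(cset, sol, "PA")
        assert out["gebv"].iloc[0] == pytest.approx(3.0)

    def test_dgv_zero_when_no_snp_effects(self):
        ped, sol, cset = self.make_solutions(13)
        sol._snp_effects = np.zeros(sol.factor.m)
        out = predict(cset, sol, "DGV")
        assert np.allclose(out["gebv"], 0.0)

    def test_grv_additive_decomposition(self):
        ped, sol, cset = self.make_solutions(14)
        out = predict(cset, sol, "GRV")
        recon = out["j_component"] + out["dgv_component"] + \
            out["rpg_component"]
        assert np.allclose(out["gebv"], recon, atol=1e-15)

    def test_reg_equals_grv_for_gg_candidates(self, mini_study):
        preds = mini_study.predictions
        reg = preds[preds.method == "REG"].reset_index(drop=True)
        grv = preds[preds.method == "GRV"].reset_index(drop=True)
        gg = reg.parent_status == "GG"
        assert gg.any()
        assert np.allclose(reg.loc[gg, "gebv"], grv.loc[gg, "gebv"],
                           atol=1e-9)

    def test_unknown_method_rejected(self):
        ped, sol, cset = self.make_solutions(15)
        with pytest.raises(ValueError):
            predict(cset, sol, "XYZ")

    def test_parent_status_partition(self):
        ped = make_pedigree([0, 0, 1, 1, 0], [0, 0, 2, 0, 0])
        status = parent_status(ped, np.array([3, 4, 5]), np.array([1, 2]))
        assert list(status) == ["GG", "NG", "NN"]

    def test_grv_self_consistency_for_held_out_no_data_animal(self):
        """Holding the genotype of a no-data, no-progeny animal with both
        parents genotyped out of the evaluation changes nothing else (it is
        conditionally independent of everyone given its parents), so GRV
        from the reduced solutions reproduces its full-evaluation GEBV."""
        from ssgblup import GenotypeMatrix

        rng = np.random.default_rng(16)
        ped0 = random_pedigree(rng, 40)
        sire41, dam41 = 20, 25
        ped = make_pedigree(np.append(ped0.sire, sire41),
                            np.append(ped0.dam, dam41))
        held_out = 41
        gcodes_red = np.unique(np.concatenate(
            [rng.choice(np.arange(8, 38), size=13, replace=False),
             [sire41, dam41]]))
        gcodes_full = np.sort(np.append(gcodes_red, held_out))
        counts_red = rng.integers(0, 3,
                                  size=(gcodes_red.size, 12)).astype(np.int8)
        counts_red[0] = 1
        held_counts = rng.integers(0, 3, size=(1, 12)).astype(np.int8)
        order = np.argsort(np.append(gcodes_red, held_out))
        counts_full = np.vstack([counts_red, held_counts])[order]
        p_red = allele_frequencies(counts_red)
        phen = pd.DataFrame({
            "animal": [str(a) for a in rng.integers(1, 31, size=60)],
            "y": rng.standard_normal(60) + 4.0,
        })

        def geno(counts, codes):
            # both evaluations centred at the reduced-set frequencies so
            # the genomic covariance of shared animals is identical
            return GenotypeMatrix(
                counts=counts, animal_ids=[str(c) for c in codes],
                marker_ids=[f"m{j}" for j in range(12)], allele_freq=p_red)

        model = ModelSpec(lambda_=2.0, w=0.2, jfactor=False)
        sol_red, r1 = solve_evaluation(ped, geno(counts_red, gcodes_red),
                                       gcodes_red, phen, model,
                                       tol=1e-12, maxit=6000)
        sol_full, r2 = solve_evaluation(ped, geno(counts_full, gcodes_full),
                                        gcodes_full, phen, model,
                                        tol=1e-12, maxit=6000)
        assert r1.converged and r2.converged
        others = np.delete(np.arange(ped.n), held_out - 1)
        assert np.allclose(sol_red.u[others], sol_full.u[others], atol=1e-8)
        row = int(np.where(gcodes_full == held_out)[0][0])
        cset = CandidateSet(codes=np.array([held_out]),
                            counts=counts_full[[row]], ids=["held-out"])
        out = predict(cset, sol_red, "GRV")
        assert out["gebv"].iloc[0] == pytest.approx(
            sol_full.u[held_out - 1], abs=1e-6)
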