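"""Generator contracts: pedigree structure, Mendelian genotypes, phenotype
variance structure, seeded reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reactnorm.pedkin import UNKNOWN
from reactnorm.rnm import RNMSpec, build_covariates
from reactnorm.simdata import (
    SimConfig,
    simulate,
    simulate_genotypes,
    simulate_pedigree,
)


class TestPedigree:
    def test_founders_only(self):
        cfg = SimConfig(n_founders=4, n_generations=0, n_snps=0)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 4
        assert (ped.sire == UNKNOWN).all() and (ped.dam == UNKNOWN).all()

    def test_single_generation_counts(self):
        cfg = SimConfig(
            n_founders=2, n_sires_per_gen=2, progeny_per_sire=50,
            n_generations=1, n_snps=0,
        )
        ped = simulate_pedigree(cfg)
        progeny = np.where((ped.sire != UNKNOWN))[0]
        assert len(progeny) == 100
        sires = set(ped.sire[progeny])
        assert sires <= {0, 1}
        # every progeny also has a known (unique founder) dam
        assert (ped.dam[progeny] != UNKNOWN).all()
        assert len(set(ped.dam[progeny])) == 100

    def test_seeded_reproducibility(self):
        cfg = SimConfig(n_founders=5, n_sires_per_gen=5, progeny_per_sire=10, n_snps=50)
        a, b = simulate(cfg), simulate(cfg)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert np.array_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.true_cg, b.true_cg)

    def test_insufficient_sires_raises(self):
        cfg = SimConfig(n_founders=3, n_sires_per_gen=5, n_snps=0)
        with pytest.raises(ValueError, match="candidate sires"):
            simulate_pedigree(cfg)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_cg", 1),
            ("cg_effect_sd", 0.0),
            ("maf_range", (0.0, 0.5)),
            ("maf_range", (0.1, 0.7)),
        ],
    )
    def test_invalid_configs(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_non_psd_K_rejected(self):
        K = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimConfig(true_K=K)


class TestGenotypes:
    def test_mendelian_consistency(self, small_sim):
        ped, M = small_sim.pedigree, small_sim.genotypes
        for i in np.where(~ped.is_founder)[0]:
            s, d = ped.sire[i], ped.dam[i]
            for p in (s, d):
                # a homozygous parent forces at least one matching allele
                child, par = M[i], M[p]
                bad = ((par == 0) & (child == 2)) | ((par == 2) & (child == 0))
                assert not bad.any()

    def test_homozygous_parents_fix_offspring(self):
        # direct check of the transmission rule on constructed genotypes
        rng = np.random.default_rng(0)
        cfg = SimConfig(n_founders=2, n_sires_per_gen=1, progeny_per_sire=5, n_snps=10)
        ped = simulate_pedigree(cfg)
        M, _ = simulate_genotypes(cfg, ped)
        founders = np.where(ped.is_founder)[0]
        prog = np.where(~ped.is_founder)[0]
        for i in prog:
            s, d = ped.sire[i], ped.dam[i]
            both0 = (M[s] == 0) & (M[d] == 0)
            both2 = (M[s] == 2) & (M[d] == 2)
            assert (M[i][both0] == 0).all()
            assert (M[i][both2] == 2).all()

    def test_founder_frequency_within_maf_range(self):
        cfg = SimConfig(
            n_founders=1000, n_generations=0, n_snps=60, maf_range=(0.2, 0.4)
        )
        ped = simulate_pedigree(cfg)
        M, _ = simulate_genotypes(cfg, ped)
        freq = M.mean(axis=0) / 2.0
        # binomial bound: freq_hat ~ p +- z * sqrt(p(1-p)/2n), z = 4.5
        bound = 4.5 * np.sqrt(0.4 * 0.6 / (2 * 1000))
        assert (freq > 0.2 - bound).all() and (freq < 0.4 + bound).all()


class TestPhenotypes:
    def test_unit_variance_when_no_signal(self):
        cfg = SimConfig(
            n_founders=60, n_sires_per_gen=60, progeny_per_sire=200, n_cg=40,
            n_snps=0, qtl_var_fraction=0.0, age_beta=(0.0, 0.0),
            true_K=np.zeros((3, 3)),
            true_eta=np.array([0.0, 0.0, 0.0]),  # sigma2_e = exp(0) = 1
            seed=3,
        )
        out = simulate(cfg, with_genotypes=False)
        rec = out.phenotypes.assign(pwg300=lambda d: d["gain"] * 300.0 / d["days"])
        v = rec.groupby("cg")["pwg300"].var()
        n = len(rec)
        # pooled within-CG variance ~ chi2_{n-ncg}/(n-ncg)
        pooled = np.average(v, weights=rec.groupby("cg").size() - 1)
        lo, hi = stats.chi2.ppf([1e-5, 1 - 1e-5], n - 40) / (n - 40)
        assert lo < pooled < hi

    def test_flat_reaction_norms_when_slope_variance_zero(self):
        K = np.diag([50.0, 0.0, 0.0])
        cfg = SimConfig(
            n_founders=10, n_sires_per_gen=10, progeny_per_sire=30, n_cg=20,
            n_snps=0, qtl_var_fraction=0.0, true_K=K, seed=5,
        )
        out = simulate(cfg, with_genotypes=False)
        slopes = out.true_bv[["b1", "b1dev"]].to_numpy()
        assert np.abs(slopes).max() < 1e-4  # numerical jitter only
        assert np.var(slopes, axis=0) == pytest.approx([0.0, 0.0], abs=1e-10)

    def test_realized_coefficient_covariance(self):
        cfg = SimConfig(seed=17, n_snps=200, n_qtl_per_coefficient=30,
                        qtl_var_fraction=0.3)
        out = simulate(cfg)
        phen = out.phenotypes["animal"]
        b = out.true_bv.loc[phen].to_numpy()
        C = np.cov(b.T)
        Kt = cfg.true_K
        # family correlation reduces the effective sample size: generous
        # Monte-Carlo band of 25% of the leading variance
        tol = 0.25 * np.diag(Kt) + 1.5
        assert np.all(np.abs(np.diag(C) - np.diag(Kt)) < tol)
        assert abs(C[0, 1] - Kt[0, 1]) < 0.35 * Kt[0, 1] + 1.5

    def test_cg_effect_distribution(self):
        cfg = SimConfig(n_cg=400, n_snps=0, seed=2)
        out = simulate(cfg, with_genotypes=False)
        sd = out.true_cg["effect"].std(ddof=1)
        # chi-square interval for a sample sd at n=400
        lo = cfg.cg_effect_sd * np.sqrt(stats.chi2.ppf(1e-5, 399) / 399)
        hi = cfg.cg_effect_sd * np.sqrt(stats.chi2.ppf(1 - 1e-5, 399) / 399)
        assert lo < sd < hi

    def test_heteroscedastic_residuals_follow_gradient(self):
        cfg = SimConfig(
            n_founders=50, n_sires_per_gen=50, progeny_per_sire=100, n_cg=60,
            n_snps=0, qtl_var_fraction=0.0, true_K=np.zeros((3, 3)),
            age_beta=(0.0, 0.0), seed=8,
        )
        out = simulate(cfg, with_genotypes=False)
        rec = out.phenotypes.assign(pwg300=lambda d: d["gain"] * 300.0 / d["days"])
        per_cg = rec.groupby("cg")["pwg300"].var()
        w = out.true_cg.set_index("cg").loc[per_cg.index, "w"]
        cov = build_covariates(RNMSpec("spline-ll"), w.to_numpy())["residual"]
        coef, *_ = np.linalg.lstsq(cov, np.log(per_cg.to_numpy()), rcond=None)
        assert coef[0] == pytest.approx(cfg.true_eta[0], abs=0.15)
        assert coef[1] == pytest.approx(cfg.true_eta[1], abs=0.2)

    def test_planted_qtl_variance_share(self):
        cfg = SimConfig(
            n_founders=40, n_sires_per_gen=40, progeny_per_sire=50,
            n_cg=50, n_snps=500, qtl_var_fraction=0.0,
            planted_qtl=("b1s2", 0.2), seed=4,
        )
        out = simulate(cfg)
        qtl = out.true_qtl
        assert len(qtl) == 1
        assert (qtl[["b0", "b1"]].to_numpy() == 0).all()  # only the deviation loads
        # realised share of segment-2 slope variance near the target
        snp_idx = out.snp_map.set_index("snp").index.get_loc(qtl.index[0])
        phen_idx = out.pedigree.indices(out.phenotypes["animal"])
        z = out.genotypes[phen_idx, snp_idx].astype(float)
        qtl_var = np.var(z * qtl["b1dev"].iloc[0], ddof=0)
        c = np.array([0.0, 1.0, 1.0])
        target = c @ cfg.true_K @ c
        assert qtl_var / target == pytest.approx(0.2, abs=0.04)
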