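"""SNP QC, single-step solving, back-solving and window variance against
brute-force and equivalent-model oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from reactnorm import ssgwas
from reactnorm.pedkin import build_Ainv, build_G
from reactnorm.rnm import RNMFit, RNMSpec, reml_fit
from reactnorm.ssgwas import (
    backsolve_snp_effects,
    call_regions,
    qc_snps,
    solve_gblup_direct,
    solve_ssgblup_mme,
    update_weights,
    window_variance,
)


def simple_map(m, chrom=None, spacing=40_000):
    return pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chr": chrom if chrom is not None else np.ones(m, int),
            "bp": (np.arange(m) % (m if chrom is None else m)) * spacing + spacing,
        }
    )


class TestSnpQC:
    def test_maf_filter(self):
        rng = np.random.default_rng(0)
        M = rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        M[:, 1] = rng.binomial(2, 0.01, size=200)  # MAF ~ 0.01
        while np.minimum(M[:, 1].mean() / 2, 1 - M[:, 1].mean() / 2) > 0.02:
            M[:, 1] = rng.binomial(2, 0.01, size=200)
        kept, kmap, rep = qc_snps(M, simple_map(3))
        assert "s1" not in set(kmap["snp"])
        assert rep.set_index("filter").loc["maf", "removed"] >= 1

    def test_duplicate_snp_pruned(self):
        rng = np.random.default_rng(1)
        M = rng.binomial(2, 0.4, size=(100, 4)).astype(float)
        M[:, 2] = M[:, 1]  # r^2 = 1 within the window
        kept, kmap, rep = qc_snps(M, simple_map(4))
        assert "s2" not in set(kmap["snp"])
        assert "s1" in set(kmap["snp"])  # the earlier copy survives

    def test_call_rate_filter(self):
        rng = np.random.default_rng(2)
        M = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
        M[:5, 0] = np.nan  # call rate 0.95 < 0.98
        kept, kmap, rep = qc_snps(M, simple_map(2))
        assert list(kmap["snp"]) == ["s1"]

    def test_hwe_filter(self):
        rng = np.random.default_rng(3)
        M = rng.binomial(2, 0.5, size=(300, 2)).astype(float)
        M[:, 0] = np.tile([0, 2], 150)  # no heterozygotes: extreme HWE failure
        kept, kmap, rep = qc_snps(M, simple_map(2))
        assert "s0" not in set(kmap["snp"])

    def test_engineered_fixture_survivor_list(self):
        rng = np.random.default_rng(4)
        m = 100
        M = rng.binomial(2, rng.uniform(0.25, 0.5, m), size=(300, m)).astype(float)
        fails = {"maf": [7, 31], "call": [12], "hwe": [48], "dup": [60, 81]}
        for j in fails["maf"]:
            M[:, j] = 0.0
            M[:3, j] = 1.0  # MAF = 0.005
        for j in fails["call"]:
            M[:30, j] = np.nan
        for j in fails["hwe"]:
            M[:, j] = np.tile([0, 2], 150)
        for j in fails["dup"]:
            M[:, j] = M[:, j - 1]
        kept, kmap, rep = qc_snps(M, simple_map(m))
        expected = {f"s{j}" for j in range(m)} - {
            f"s{j}" for js in fails.values() for j in js
        }
        assert set(kmap["snp"]) == expected

    def test_unsorted_map_rejected(self):
        M = np.ones((10, 2))
        bad = simple_map(2)
        bad.loc[0, "bp"] = 10**9
        with pytest.raises(ValueError, match="sorted"):
            qc_snps(M, bad)


class TestWeights:
    def test_uniform_effects_give_unit_weights(self):
        u = np.full(10, 0.3)
        p = np.full(10, 0.25)
        assert update_weights(u, p) == pytest.approx(np.ones(10))

    def test_single_snp_carries_all_weight(self):
        u = np.zeros(8)
        u[3] = 1.0
        d = update_weights(u, np.full(8, 0.5))
        assert d[3] == pytest.approx(8.0, rel=1e-6)
        assert np.all(d[np.arange(8) != 3] <= 1e-8)

    def test_idempotent_for_fixed_effects(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=20)
        p = rng.uniform(0.1, 0.5, 20)
        assert update_weights(u, p) == pytest.approx(update_weights(u, p))

    def test_all_zero_effects_keep_unit_weights(self):
        assert update_weights(np.zeros(5), np.full(5, 0.3)) == pytest.approx(np.ones(5))


class TestBacksolve:
    def setup_gblup(self, seed=0, n=300, m=200):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.15, 0.5, m)
        M = rng.binomial(2, p, size=(n, m)).astype(float)
        mono = (M.mean(0) == 0) | (M.mean(0) == 2)
        M[0, mono] = 1
        p_hat = M.mean(axis=0) / 2
        Z = M - 2 * p_hat
        denom = 2 * np.sum(p_hat * (1 - p_hat))
        G = Z @ Z.T / denom
        s2a, s2e = 40.0, 60.0
        alpha = rng.normal(0, np.sqrt(s2a / denom), m)
        y = 100.0 + Z @ alpha + rng.normal(0, np.sqrt(s2e), n)
        return M, p_hat, Z, G, denom, y, s2a, s2e

    def test_snp_blup_equivalence(self):
        # u_hat from back-solving GEBVs must equal ridge-regression SNP-BLUP
        # with the matched variance ratio (D = I, no blending)
        M, p, Z, G, denom, y, s2a, s2e = self.setup_gblup()
        n, m = Z.shape
        X = np.ones((n, 1))
        W = np.ones((n, 1))
        Zr = np.ones((n, 1))
        gebv, beta = solve_gblup_direct(
            y, X, W, Zr, G, np.array([[s2a]]), np.array([np.log(s2e)])
        )
        u = backsolve_snp_effects(gebv[:, 0], Z, p, np.ones(m), G)
        # oracle: SNP-BLUP normal equations (Z'Z + lambda I) a = Z'(y - X b)
        lam = s2e / (s2a / denom)
        XtX = X.T @ X
        # GLS beta under the equivalent model equals the GBLUP beta
        a_or = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ (y - X @ beta))
        assert np.abs(u - a_or).max() < 1e-6

    def test_zero_gebv_zero_effects(self):
        M, p, Z, G, denom, y, *_ = self.setup_gblup(seed=1)
        u = backsolve_snp_effects(np.zeros(len(y)), Z, p, np.ones(Z.shape[1]), G)
        assert np.abs(u).max() == 0.0

    def test_predicted_gebv_reproduced(self):
        # Z u reproduces the (centred) GEBVs exactly when eps = 0
        M, p, Z, G, denom, y, s2a, s2e = self.setup_gblup(seed=2)
        n = len(y)
        gebv, _ = solve_gblup_direct(
            y, np.ones((n, 1)), np.ones((n, 1)), np.ones((n, 1)),
            G, np.array([[s2a]]), np.array([np.log(s2e)]),
        )
        u = backsolve_snp_effects(gebv[:, 0], Z, p, np.ones(Z.shape[1]), G)
        pred = Z @ u
        assert np.corrcoef(pred, gebv[:, 0])[0, 1] > 1 - 1e-9
        assert np.abs(pred - gebv[:, 0]).max() < 1e-6 * np.abs(gebv).max() + 1e-9


class TestSsgblupMME:
    def test_matches_marginal_solutions_with_pedigree(self, small_sim, small_records, w_truth):
        # two independent solution paths: sparse MME with A^-1 (x) K^-1
        # versus the marginal GLS + kriging route used by reml_fit
        fit = reml_fit(
            RNMSpec("hete-linear"), small_records, w_truth, small_sim.pedigree
        )
        ped = small_sim.pedigree
        sols, beta = solve_ssgblup_mme(
            fit.spec, small_records, w_truth, build_Ainv(ped), ped.ids,
            fit.K, fit.eta,
        )
        a = sols.loc[fit.solutions.index].to_numpy()
        b = fit.solutions.to_numpy()
        # the MME route squares the condition number of K (K^-1 enters the
        # equations), so agreement is relative, not absolute
        assert np.abs(a - b).max() < 1e-3 * max(np.abs(b).max(), 1.0)

    def test_null_phenotypes_give_null_gebv(self, small_sim, small_records, w_truth):
        rec = small_records.copy()
        rec["pwg300"] = 100.0
        ped = small_sim.pedigree
        sols, beta = solve_ssgblup_mme(
            RNMSpec("hete-linear"), rec, w_truth, build_Ainv(ped), ped.ids,
            np.diag([50.0, 5.0]), np.array([np.log(200.0), 0.0]),
        )
        assert np.abs(sols.to_numpy()).max() < 1e-8


class TestWindows:
    def test_zero_effects_zero_windows(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(50, 12))
        wtab = window_variance(np.zeros(12), Z, simple_map(12), coef_variance=4.0)
        assert (wtab["pct_var"] == 0).all()

    def test_brute_force_window_variance(self):
        rng = np.random.default_rng(1)
        m = 13
        Z = rng.normal(size=(50, m))
        u = rng.normal(size=m)
        wtab = window_variance(u, Z, simple_map(m), coef_variance=4.0, size=5)
        assert len(wtab) == m - 4
        for s in range(m - 4):
            seg = Z[:, s:s + 5] @ u[s:s + 5]
            expected = 100.0 * np.var(seg, ddof=1) / 4.0
            assert wtab["pct_var"].iloc[s] == pytest.approx(expected, rel=1e-10)

    def test_windows_respect_chromosomes(self):
        rng = np.random.default_rng(2)
        chrom = np.array([1] * 7 + [2] * 3)  # chr2 has < 5 SNPs: skipped
        Z = rng.normal(size=(30, 10))
        smap = simple_map(10, chrom=chrom)
        wtab = window_variance(rng.normal(size=10), Z, smap, coef_variance=1.0)
        assert set(wtab["chr"]) == {1}
        assert len(wtab) == 3  # 7 - 5 + 1

    def test_center_assignment(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(30, 6))
        smap = simple_map(6)
        first = window_variance(rng.normal(size=6), Z, smap, 1.0, assign="first")
        center = window_variance(rng.normal(size=6), Z, smap, 1.0, assign="center")
        assert list(first["snp"]) == ["s0", "s1"]
        assert list(center["snp"]) == ["s2", "s3"]


class TestRegions:
    def make_windows(self, rows):
        return pd.DataFrame(
            rows, columns=["snp", "chr", "window_start", "window_end", "pct_var"]
        )

    def test_no_significant_windows(self):
        w = self.make_windows([("s0", 1, 100, 200, 0.2)])
        assert len(call_regions({"b1": w})) == 0

    def test_single_window_flanks(self):
        w = self.make_windows([("s0", 1, 1_000_000, 1_160_000, 0.9)])
        reg = call_regions({"b1": w})
        assert len(reg) == 1
        assert reg["start"].iloc[0] == 800_000
        assert reg["end"].iloc[0] == 1_360_000
        assert reg["pct_b1"].iloc[0] == pytest.approx(0.9)

    def test_nearby_windows_merge(self):
        w = self.make_windows(
            [
                ("s0", 1, 1_000_000, 1_100_000, 0.8),
                ("s9", 1, 1_200_000, 1_300_000, 0.6),  # 100 kb gap < 2x flank
            ]
        )
        reg = call_regions({"b1": w})
        assert len(reg) == 1
        assert reg["start"].iloc[0] == 800_000
        assert reg["end"].iloc[0] == 1_500_000

    def test_merge_across_coefficients_keeps_leading_pct(self):
        wa = self.make_windows([("s0", 1, 1_000_000, 1_100_000, 0.8)])
        wb = self.make_windows([("s1", 1, 1_050_000, 1_150_000, 1.4)])
        reg = call_regions({"b1s1": wa, "b1s2": wb})
        assert len(reg) == 1
        assert reg["pct_b1s1"].iloc[0] == pytest.approx(0.8)
        assert reg["pct_b1s2"].iloc[0] == pytest.approx(1.4)

    def test_interval_merge_oracle(self):
        # brute-force merge on random intervals must match
        rng = np.random.default_rng(7)
        rows = []
        for i in range(25):
            s = int(rng.integers(1, 5_000_000))
            rows.append((f"s{i}", int(rng.integers(1, 3)), s, s + 160_000, 1.0))
        w = self.make_windows(rows)
        reg = call_regions({"b1": w}, flank=200_000)
        # oracle: merge flanked intervals per chromosome
        for c, grp in w.groupby("chr"):
            iv = sorted(
                (max(1, s - 200_000), e + 200_000)
                for s, e in zip(grp["window_start"], grp["window_end"])
            )
            merged = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            got = reg[reg["chr"] == c]
            assert len(got) == len(merged)
            assert list(got["start"]) == [s for s, _ in merged]
            assert list(got["end"]) == [e for _, e in merged]
        # merged regions never overlap
        for c, grp in reg.groupby("chr"):
            assert (grp["start"].iloc[1:].to_numpy() > grp["end"].iloc[:-1].to_numpy()).all()
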