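"""Synthetic pedigrees, genotypes, environments and phenotypes.

The generator emulates the data structure of large tropical beef-cattle
field recording schemes: multi-generation paternal half-sib families from
heavily used AI sires (essentially unique dams), thousands of phenotyped
animals spread over hundreds of contemporary groups (CG) spanning a wide
environmental range, and a post-weaning weight-gain phenotype whose genetic
part follows a reaction norm on the standardised CG effect and whose
residual variance increases log-linearly with the gradient.

The generative model mirrors the fitted reaction-norm model (spline
linear-linear by default) so that REML parameter recovery is well-posed:

    y = CG effect + age effects + z(w)' b_animal + e,
    b = QTL part (sum of causal-SNP effects) + polygenic pedigree part,
    e ~ N(0, exp(eta' z_r(w))).

Truth tables (true CG effects, true coefficient vectors, causal SNPs) are
emitted alongside the data so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedkin import UNKNOWN, Pedigree
from .rnm import RNMSpec, build_covariates, coefficient_contrast

__all__ = ["SimConfig", "SimOutput", "simulate_pedigree", "simulate_genotypes",
           "simulate_phenotypes", "simulate"]


def _default_K() -> np.ndarray:
    # coefficient (co)variances for the spline-ll generator, kg^2,
    # on the (b0, b1, b1dev) basis
    return np.array([[90.0, 16.3, 0.0], [16.3, 4.0, 0.0], [0.0, 0.0, 16.0]])


def _default_eta() -> np.ndarray:
    return np.array([np.log(250.0), 0.3, -0.15])


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults describe a single-generation design of 100 AI sires with 50
    progeny each (5000 phenotyped animals) in 200 contemporary groups, a CG
    effect distribution matching a mean of ~94 kg with ~28 kg spread, and a
    2000-SNP genome on 10 chromosomes.
    """

    n_founders: int = 100
    n_generations: int = 1
    n_sires_per_gen: int = 100
    progeny_per_sire: int = 50
    n_cg: int = 200
    cg_effect_mean: float = 93.7  # kg
    cg_effect_sd: float = 28.16  # kg
    n_snps: int = 2000
    n_chromosomes: int = 10
    snp_spacing_bp: int = 40_000
    n_qtl_per_coefficient: int = 50
    qtl_var_fraction: float = 0.3  # share of each coefficient variance from QTL
    model: RNMSpec = field(default_factory=RNMSpec)
    true_K: np.ndarray = field(default_factory=_default_K)
    true_eta: np.ndarray = field(default_factory=_default_eta)
    knot: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    age_beta: tuple[float, float] = (0.02, -5e-5)  # kg/day, kg/day^2 on (days-300)
    weaning_age: tuple[int, int] = (90, 300)  # days
    yearling_age: tuple[int, int] = (310, 730)  # days
    min_period: int = 150  # shortest post-weaning period simulated, days
    planted_qtl: tuple[str, float] | None = None  # (coefficient name, variance share)
    seed: int = 0

    def __post_init__(self):
        self.true_K = np.asarray(self.true_K, float)
        self.true_eta = np.asarray(self.true_eta, float)
        q = self.model.n_coefficients
        if self.true_K.shape != (q, q):
            raise ValueError(f"true_K must be {q}x{q} for model {self.model.kind}")
        if len(self.true_eta) != len(self.model.residual_terms):
            raise ValueError("true_eta length does not match the residual basis")
        ev = np.linalg.eigvalsh(0.5 * (self.true_K + self.true_K.T))
        if ev.min() < -1e-8 * max(ev.max(), 1.0):
            raise ValueError("true_K must be positive semi-definite")
        if self.n_cg < 2:
            raise ValueError("need at least two contemporary groups")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.cg_effect_sd <= 0:
            raise ValueError("cg_effect_sd must be positive")
        for name in ("n_founders", "n_sires_per_gen", "progeny_per_sire"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")


@dataclass
class SimOutput:
    """Synthetic dataset plus the truth tables that generated it."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: np.ndarray  # phenotyped+founder animals x SNPs, 0/1/2
    genotype_ids: np.ndarray
    snp_map: pd.DataFrame  # snp, chr, bp
    phenotypes: pd.DataFrame  # animal, cg, days, gain (raw), pwg300
    true_cg: pd.DataFrame  # cg, effect, w
    true_bv: pd.DataFrame  # animal x coefficient truth
    true_qtl: pd.DataFrame  # snp x coefficient effect (causal only)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigree.to_frame().to_csv(out / "pedigree.csv", index=False)
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        geno = pd.DataFrame(
            self.genotypes, index=self.genotype_ids, columns=self.snp_map["snp"]
        )
        geno.index.name = "animal"
        geno.to_csv(out / "genotypes.tsv", sep="\t")
        self.snp_map.to_csv(out / "snp_map.tsv", sep="\t", index=False)
        self.true_cg.to_csv(out / "true_cg.tsv", sep="\t", index=False)
        self.true_bv.to_csv(out / "true_bv.tsv", sep="\t")
        self.true_qtl.to_csv(out / "true_qtl.tsv", sep="\t")


# ------------------------------------------------------------------ pedigree
def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Multi-generation paternal half-sib pedigree.

    Founders are the AI-sire pool; every mating uses a fresh founder dam
    (dams in large beef populations rarely have more than one recorded
    calf).  Generation-g sires are sampled from generation g-1 males
    (founders for g = 1), so families span the whole recording period.
    """
    rng = np.random.default_rng(cfg.seed)
    ids: list[str] = [f"F{i:05d}" for i in range(cfg.n_founders)]
    sire: list[int] = [UNKNOWN] * cfg.n_founders
    dam: list[int] = [UNKNOWN] * cfg.n_founders
    males = list(range(cfg.n_founders))
    for g in range(1, cfg.n_generations + 1):
        if len(males) < cfg.n_sires_per_gen:
            raise ValueError(
                f"generation {g}: only {len(males)} candidate sires available, "
                f"{cfg.n_sires_per_gen} requested"
            )
        gen_sires = rng.choice(males, size=cfg.n_sires_per_gen, replace=False)
        new_males: list[int] = []
        for s in gen_sires:
            for _ in range(cfg.progeny_per_sire):
                d_idx = len(ids)
                ids.append(f"D{g}_{d_idx:06d}")
                sire.append(UNKNOWN)
                dam.append(UNKNOWN)
                c_idx = len(ids)
                ids.append(f"G{g}_{c_idx:06d}")
                sire.append(int(s))
                dam.append(d_idx)
                if rng.random() < 0.5:
                    new_males.append(c_idx)
        males = new_males
    return Pedigree(np.array(ids, dtype=object), np.array(sire), np.array(dam))


def progeny_ids(ped: Pedigree) -> np.ndarray:
    """Animals with at least one known parent (the phenotyped cohort)."""
    return ped.ids[~ped.is_founder]


# ----------------------------------------------------------------- genotypes
def simulate_genotypes(cfg: SimConfig, ped: Pedigree, rng=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Mendelian gene-drop through the pedigree.

    Founder genotypes are Binomial(2, p_j) with p_j uniform in
    ``maf_range``; each offspring receives one allele per parent with
    transmission probability g_parent / 2 (exact for unphased 0/1/2 data).
    Returns the full genotype matrix (pedigree order) and the SNP map.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n, m = len(ped), cfg.n_snps
    p = rng.uniform(*cfg.maf_range, size=m)
    M = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        a1 = (
            rng.random(m) < (M[s] / 2.0) if s != UNKNOWN else rng.random(m) < p
        )
        a2 = (
            rng.random(m) < (M[d] / 2.0) if d != UNKNOWN else rng.random(m) < p
        )
        M[i] = a1.astype(np.int8) + a2.astype(np.int8)
    per_chr = int(np.ceil(m / cfg.n_chromosomes))
    chrom = 1 + (np.arange(m) // per_chr)
    bp = (np.arange(m) % per_chr + 1) * cfg.snp_spacing_bp
    snp_map = pd.DataFrame(
        {"snp": [f"snp{j:06d}" for j in range(m)], "chr": chrom, "bp": bp}
    )
    return M, snp_map


# ---------------------------------------------------------------- phenotypes
def _polygenic_values(ped: Pedigree, K_poly: np.ndarray, rng) -> np.ndarray:
    """Exact A (x) K_poly sample by recursive pedigree sampling."""
    n, q = len(ped), K_poly.shape[0]
    D = ped.mendelian_variances()
    L = np.linalg.cholesky(K_poly + 1e-12 * np.eye(q))
    noise = rng.standard_normal((n, q)) @ L.T
    b = np.zeros((n, q))
    for i in range(n):
        mid = np.zeros(q)
        if ped.sire[i] != UNKNOWN:
            mid += 0.5 * b[ped.sire[i]]
        if ped.dam[i] != UNKNOWN:
            mid += 0.5 * b[ped.dam[i]]
        b[i] = mid + np.sqrt(D[i]) * noise[i]
    return b


def simulate_phenotypes(
    cfg: SimConfig, ped: Pedigree, geno: np.ndarray, snp_map: pd.DataFrame, rng=None
) -> SimOutput:
    """Phenotypes, truth tables and causal-SNP effects for the pedigree.

    Each coefficient's genetic variance is split into a causal-SNP part
    (``qtl_var_fraction``, rescaled to the realised variance over phenotyped
    animals) and a polygenic pedigree part carrying the remaining
    (co)variance.  A single large QTL can additionally be planted on one
    coefficient via ``planted_qtl``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    spec = replace(cfg.model, knot=cfg.knot)
    q = spec.n_coefficients
    phen_idx = np.where(~ped.is_founder)[0]
    n_phen = len(phen_idx)
    if n_phen == 0:
        raise ValueError("pedigree has no non-founder animals to phenotype")

    # --- environments ------------------------------------------------------
    cg_effect = rng.normal(cfg.cg_effect_mean, cfg.cg_effect_sd, size=cfg.n_cg)
    w_true = (cg_effect - cg_effect.mean()) / cg_effect.std()
    cg_of = rng.integers(cfg.n_cg, size=n_phen)

    # --- genetic coefficient vectors --------------------------------------
    f = cfg.qtl_var_fraction
    Kt = cfg.true_K
    b = np.zeros((len(ped), q))
    n_avail = geno.shape[1]
    qtl_effects = np.zeros((n_avail, q))
    qtl_idx = np.array([], dtype=int)
    if f > 0 and cfg.n_qtl_per_coefficient > 0 and n_avail > 0:
        n_qtl = min(cfg.n_qtl_per_coefficient, n_avail)
        qtl_idx = rng.choice(n_avail, size=n_qtl, replace=False)
        # correlated effects across coefficients, matching corr(true_K)
        sd = np.sqrt(np.clip(np.diag(Kt), 1e-12, None))
        Corr = Kt / np.outer(sd, sd)
        Lc = np.linalg.cholesky(Corr + 1e-10 * np.eye(q))
        alpha = rng.standard_normal((n_qtl, q)) @ Lc.T
        Zq = geno[:, qtl_idx].astype(float)
        Zq = Zq - Zq[phen_idx].mean(axis=0)
        raw = Zq @ alpha
        sv = raw[phen_idx].var(axis=0)
        scale = np.where(sv > 0, np.sqrt(f * np.diag(Kt) / np.where(sv > 0, sv, 1.0)), 0.0)
        alpha *= scale
        qtl_effects[qtl_idx] = alpha
        b += raw * scale
        K_poly = (1.0 - f) * Kt
    else:
        K_poly = Kt.copy()

    if cfg.planted_qtl is not None:
        if n_avail == 0:
            raise ValueError("planted_qtl requires simulated genotypes")
        coef_name, share = cfg.planted_qtl
        c = coefficient_contrast(spec, coef_name)
        target_var = float(c @ Kt @ c)
        free = np.setdiff1d(np.arange(n_avail), qtl_idx)
        j = int(rng.choice(free))
        z = geno[:, j].astype(float)
        z = z - z[phen_idx].mean()
        zv = z[phen_idx].var()
        if zv <= 0:
            raise ValueError("planted QTL landed on a monomorphic SNP")
        a = np.sqrt(share * target_var / zv)
        # load the effect on a single basis coefficient so that, for spline
        # segment quantities, only the named segment is affected (a QTL on
        # b1s2 acts through the deviation b1dev and leaves b1s1 untouched)
        basis = {"b1s1": "b1", "b1s2": "b1dev", "b2s1": "b2", "b2s2": "b2dev"}
        coef_basis = basis.get(coef_name, coef_name)
        load = np.zeros(q)
        load[list(spec.coefficients).index(coef_basis)] = 1.0
        qtl_effects[j] += a * load
        b += np.outer(z, a * load)
        # keep total variance on target: shrink the matching polygenic block
        K_poly = K_poly - share * np.outer(load, load) * target_var
        ev = np.linalg.eigvalsh(K_poly)
        if ev.min() < -1e-9:
            raise ValueError(
                "planted QTL share too large for the remaining polygenic (co)variance"
            )
        K_poly = _nearest_psd(K_poly)

    b += _polygenic_values(ped, _nearest_psd(K_poly), rng)

    # --- records -----------------------------------------------------------
    wean = rng.integers(cfg.weaning_age[0], cfg.weaning_age[1] + 1, size=n_phen)
    year = rng.integers(cfg.yearling_age[0], cfg.yearling_age[1] + 1, size=n_phen)
    days = np.maximum(year - wean, cfg.min_period)
    w_rec = w_true[cg_of]
    cov = build_covariates(spec, w_rec)
    g_val = np.einsum("ij,ij->i", cov["genetic"], b[phen_idx])
    var_e = np.exp(cov["residual"] @ cfg.true_eta)
    e = rng.standard_normal(n_phen) * np.sqrt(var_e)
    d300 = days - 300.0
    pwg300 = (
        cg_effect[cg_of]
        + cfg.age_beta[0] * d300
        + cfg.age_beta[1] * d300**2
        + g_val
        + e
    )
    gain_raw = pwg300 * days / 300.0

    animals = ped.ids[phen_idx]
    phen = pd.DataFrame(
        {
            "animal": animals,
            "sire": np.where(ped.sire[phen_idx] >= 0, ped.ids[ped.sire[phen_idx]], "0"),
            "dam": np.where(ped.dam[phen_idx] >= 0, ped.ids[ped.dam[phen_idx]], "0"),
            "cg": [f"cg{c:04d}" for c in cg_of],
            "days": days,
            "gain": gain_raw,
        }
    )
    true_cg = pd.DataFrame(
        {"cg": [f"cg{c:04d}" for c in range(cfg.n_cg)], "effect": cg_effect, "w": w_true}
    )
    true_bv = pd.DataFrame(b, index=ped.ids, columns=spec.coefficients)
    true_bv.index.name = "animal"
    true_qtl = pd.DataFrame(qtl_effects, index=snp_map["snp"], columns=spec.coefficients)
    true_qtl = true_qtl.loc[(true_qtl != 0).any(axis=1)]
    return SimOutput(
        config=cfg,
        pedigree=ped,
        genotypes=geno,
        genotype_ids=ped.ids,
        snp_map=snp_map,
        phenotypes=phen,
        true_cg=true_cg,
        true_bv=true_bv,
        true_qtl=true_qtl,
    )


def _nearest_psd(K: np.ndarray) -> np.ndarray:
    K = 0.5 * (K + K.T)
    ev, V = np.linalg.eigh(K)
    return (V * np.clip(ev, 0.0, None)) @ V.T


def simulate(cfg: SimConfig, with_genotypes: bool = True) -> SimOutput:
    """Convenience wrapper: pedigree -> genotypes -> phenotypes."""
    ped = simulate_pedigree(cfg)
    if with_genotypes and cfg.n_snps > 0:
        geno, snp_map = simulate_genotypes(cfg, ped)
    else:
        geno = np.zeros((len(ped), 0), dtype=np.int8)
        snp_map = pd.DataFrame({"snp": [], "chr": [], "bp": []})
    return simulate_phenotypes(cfg, ped, geno, snp_map)
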