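"""Weighted single-step GBLUP association on reaction-norm coefficients.

Coefficient GEBVs are predicted under the reaction-norm model with the
(co)variance components fixed at their REML estimates and the pedigree
relationship replaced by the combined pedigree-genomic matrix; SNP effects
are then obtained by back-solving through the equivalent SNP-BLUP model,

    u_hat = (1 / (2 sum p(1-p))) D Z' G_w^-1 g_hat,

iteratively re-weighting each SNP by the variance it explained
(d_i proportional to u_i^2 2 p_i (1 - p_i), mean 1) for a fixed number of
rounds (three in total, all SNPs weighted 1 in the first).  Association
signal is summarised as the percentage of a coefficient's genetic variance
explained by sliding segments of five adjacent SNPs, and significant
segments are merged into candidate regions extended 200 kb on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
from scipy.linalg import blas as _blas
from scipy.stats import chi2

from .pedkin import allele_frequencies, blend_G
from .rnm import RNMFit, RNMSpec, build_covariates, coefficient_contrast

log = logging.getLogger(__name__)

__all__ = [
    "qc_snps",
    "solve_ssgblup_mme",
    "CoefficientGEBV",
    "backsolve_snp_effects",
    "update_weights",
    "window_variance",
    "call_regions",
    "wssgwas",
]


# ------------------------------------------------------------------- SNP QC
def _hwe_pvalues(M: np.ndarray) -> np.ndarray:
    """Chi-square (1 df) Hardy-Weinberg test per SNP on 0/1/2 counts."""
    M = np.asarray(M, float)
    n = np.sum(~np.isnan(M), axis=0)
    n2 = np.nansum(M == 2, axis=0)
    n1 = np.nansum(M == 1, axis=0)
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2 * np.maximum(n, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2
        stat = (
            (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
        )
    stat = np.where(np.isfinite(stat), stat, np.inf)
    return chi2.sf(stat, df=1)


def _ld_prune(M: np.ndarray, chrom: np.ndarray, r2_max: float, window: int) -> np.ndarray:
    """Greedy pruning: drop the later SNP of any pair with r^2 > r2_max
    within ``window`` neighbouring (kept) markers on the same chromosome."""
    n_snp = M.shape[1]
    keep = np.ones(n_snp, dtype=bool)
    Mc = M - np.nanmean(M, axis=0)
    sd = np.sqrt(np.nanmean(Mc**2, axis=0))
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        kept: list[int] = []
        for j in idx:
            ok = True
            for k in kept[-window:]:
                denom = sd[j] * sd[k]
                if denom == 0:
                    continue
                r = np.nanmean(Mc[:, j] * Mc[:, k]) / denom
                if r * r > r2_max:
                    ok = False
                    break
            if ok:
                kept.append(j)
            else:
                keep[j] = False
    return keep


def qc_snps(
    M: np.ndarray,
    snp_map: pd.DataFrame,
    maf_min: float = 0.02,
    hwe_alpha: float = 1e-5,
    call_rate_min: float = 0.98,
    ld_r2_max: float = 0.998,
    ld_window: int = 50,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Marker quality control: call rate, MAF, HWE and LD pruning.

    ``M`` is animals x SNPs with NaN for missing calls; ``snp_map`` must be
    sorted by chromosome then position.  Returns the filtered matrix, the
    filtered map and a per-filter report of removal counts.
    """
    M = np.asarray(M, float)
    if len(snp_map) != M.shape[1]:
        raise ValueError("snp_map length does not match the genotype matrix")
    key = snp_map[["chr", "bp"]].to_numpy()
    if not all(
        (key[i][0], key[i][1]) <= (key[i + 1][0], key[i + 1][1])
        for i in range(len(key) - 1)
    ):
        raise ValueError("snp_map must be sorted by chromosome then bp")
    report = {}
    keep = np.ones(M.shape[1], dtype=bool)
    call = 1.0 - np.mean(np.isnan(M), axis=0)
    step = call > call_rate_min
    report["call_rate"] = int(np.sum(~step))
    keep &= step
    p = allele_frequencies(M)
    maf = np.minimum(p, 1 - p)
    step = maf > maf_min
    report["maf"] = int(np.sum(~step & keep))
    keep &= step
    step = _hwe_pvalues(M) >= hwe_alpha
    report["hwe"] = int(np.sum(~step & keep))
    keep &= step
    idx = np.where(keep)[0]
    sub = _ld_prune(M[:, idx], snp_map["chr"].to_numpy()[idx], ld_r2_max, ld_window)
    report["ld_prune"] = int(np.sum(~sub))
    keep[idx[~sub]] = False
    rep = pd.DataFrame(
        {"filter": list(report), "removed": list(report.values())}
    )
    log.info("SNP QC: %s; %d/%d kept", report, int(keep.sum()), len(keep))
    return M[:, keep], snp_map.loc[keep].reset_index(drop=True), rep


# --------------------------------------------------- single-step MME solver
def solve_ssgblup_mme(
    spec: RNMSpec,
    records: pd.DataFrame,
    w_map: pd.Series,
    Ginv_struct: sp.spmatrix,
    animal_ids: np.ndarray,
    K: np.ndarray,
    eta: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Direct sparse mixed-model-equation solve with known components.

    ``Ginv_struct`` is the inverse relationship structure over
    ``animal_ids`` (A^-1 or H^-1); the coefficient covariance among animals
    is struct (x) K.  Returns per-animal coefficient solutions and the
    fixed-effect vector.  Intended for moderate problem sizes; the dense
    equivalent-model path in :func:`wssgwas` covers the genomic case where
    every phenotyped animal is genotyped.
    """
    from .rnm import build_design

    w = records["cg"].map(w_map).to_numpy(float)
    y = records["pwg300"].to_numpy(float)
    X, xnames, W, Zr = build_design(spec, records, w)
    n, q = len(y), spec.n_coefficients
    n_a = len(animal_ids)
    a_index = {a: i for i, a in enumerate(animal_ids)}
    rows = np.arange(n)
    cols = np.array([a_index[a] for a in records["animal"]])
    Rinv = 1.0 / np.exp(Zr @ eta)
    # Z maps records to animal-coefficient effects (animal-major blocks)
    Zparts = [
        sp.csr_matrix((W[:, r], (rows, cols)), shape=(n, n_a)) for r in range(q)
    ]
    Z = sp.hstack([Zp for Zp in Zparts], format="csr")
    Xs = sp.csr_matrix(X)
    Ri = sp.diags(Rinv)
    Kinv = np.linalg.inv(K)
    Gterm = sp.kron(sp.csr_matrix(Kinv), Ginv_struct, format="csr")
    top = sp.hstack([Xs.T @ Ri @ Xs, Xs.T @ Ri @ Z])
    bot = sp.hstack([Z.T @ Ri @ Xs, Z.T @ Ri @ Z + Gterm])
    C = sp.vstack([top, bot]).tocsc()
    rhs = np.concatenate([Xs.T @ (Rinv * y), Z.T @ (Rinv * y)])
    sol = sp.linalg.spsolve(C, rhs)
    p = X.shape[1]
    beta = sol[:p]
    b = sol[p:].reshape(q, n_a).T
    return pd.DataFrame(b, index=animal_ids, columns=spec.coefficients), beta


# -------------------------------------------------------- equivalent models
def _syrk(A: np.ndarray) -> np.ndarray:
    """A @ A.T via BLAS syrk (half the flops of a general matmul)."""
    C = _blas.dsyrk(1.0, np.asarray(A, float, order="F"), lower=1)
    return C + np.tril(C, -1).T


@dataclass
class CoefficientGEBV:
    """GEBVs for one (possibly derived) coefficient plus solver context."""

    coefficient: str
    gebv: np.ndarray  # genotyped animals
    Gb: np.ndarray  # blended (weighted) genomic relationship used
    weights: np.ndarray


def solve_gblup_direct(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    Zr: np.ndarray,
    Gb: np.ndarray,
    K: np.ndarray,
    eta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """GEBV coefficients via the marginal (equivalent-model) GLS solve.

    Every phenotyped animal carries genomic relationships ``Gb``.  Returns
    (coefficient GEBVs n x q, beta).  b_hat = Gb diag(Py) W K, the BLUP of
    coefficients given V = (W K W') o Gb + R.
    """
    n = len(y)
    r = np.exp(Zr @ eta)
    V = (W @ K @ W.T) * Gb
    V[np.diag_indices(n)] += r
    cho = la.cho_factor(V, lower=True, overwrite_a=True)
    Viy = la.cho_solve(cho, y)
    ViX = la.cho_solve(cho, X)
    XtViX = X.T @ ViX
    beta = la.solve(XtViX, X.T @ Viy, assume_a="pos")
    Py = Viy - ViX @ beta
    bhat = Gb @ (Py[:, None] * (W @ K))
    return bhat, beta


def backsolve_snp_effects(
    gebv: np.ndarray,
    Z: np.ndarray,
    p: np.ndarray,
    weights: np.ndarray,
    Gb: np.ndarray,
) -> np.ndarray:
    """SNP effects from GEBVs through the equivalent SNP-BLUP model.

    ``Z`` is the centred gene-content matrix (M - 2p), ``Gb`` the blended
    weighted genomic relationship actually used in the evaluation.
    """
    denom = 2.0 * np.sum(p * (1.0 - p))
    try:
        t = la.solve(Gb, gebv, assume_a="pos")
    except np.linalg.LinAlgError:
        # G is rank-deficient when there are fewer SNPs than animals; the
        # GEBVs lie in its range and Z' annihilates its null space, so the
        # minimum-norm solution gives the unique SNP effects
        t, *_ = np.linalg.lstsq(Gb, gebv, rcond=None)
        resid = np.abs(Gb @ t - gebv).max()
        if resid > 1e-6 * max(np.abs(gebv).max(), 1.0):
            raise np.linalg.LinAlgError(
                "weighted genomic relationship is singular and the GEBVs are "
                "not in its range; increase the blending weight"
            )
    return weights * (Z.T @ t) / denom


def update_weights(u: np.ndarray, p: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """d_i proportional to u_i^2 2 p_i (1-p_i), normalised to mean one."""
    d = u**2 * 2.0 * p * (1.0 - p)
    total = d.sum()
    if total <= 0:
        log.warning("all SNP effects zero; keeping unit weights")
        return np.ones_like(d)
    d = d * (len(d) / total)
    return np.maximum(d, floor)


# ------------------------------------------------------------------ windows
def window_variance(
    u: np.ndarray,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    coef_variance: float,
    size: int = 5,
    assign: str = "first",
) -> pd.DataFrame:
    """Percentage of genetic variance per sliding segment of adjacent SNPs.

    The window value is 100 * Var_animals(sum_{j in window} Z_j u_j) /
    ``coef_variance`` and is assigned to the window's first SNP (or its
    central SNP with ``assign='center'``).  Windows never span chromosomes;
    chromosomes with fewer than ``size`` SNPs are skipped.
    """
    if assign not in ("first", "center"):
        raise ValueError("assign must be 'first' or 'center'")
    out = []
    chrom = snp_map["chr"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        if len(idx) < size:
            log.info("chromosome %s has < %d SNPs; no windows", c, size)
            continue
        # cumulative genomic values allow O(1) per-window sums
        gv = np.cumsum(Z[:, idx] * u[idx], axis=1)
        for s in range(len(idx) - size + 1):
            seg = gv[:, s + size - 1] - (gv[:, s - 1] if s > 0 else 0.0)
            pct = 100.0 * np.var(seg, ddof=1) / coef_variance
            anchor = idx[s] if assign == "first" else idx[s + size // 2]
            out.append(
                {
                    "snp": snp_map["snp"].iloc[anchor],
                    "chr": c,
                    "window_start": int(snp_map["bp"].iloc[idx[s]]),
                    "window_end": int(snp_map["bp"].iloc[idx[s + size - 1]]),
                    "pct_var": pct,
                }
            )
    return pd.DataFrame(out)


def call_regions(
    windows: dict[str, pd.DataFrame],
    threshold: float = 0.5,
    flank: int = 200_000,
) -> pd.DataFrame:
    """Merge significant windows (across coefficients) into candidate regions.

    ``windows`` maps coefficient name -> window table.  Windows explaining
    at least ``threshold`` % of the coefficient's genetic variance are
    extended ``flank`` bp both ways and overlapping intervals on a
    chromosome are merged; each region records the leading window % per
    coefficient.
    """
    hits = []
    for coef, tab in windows.items():
        sig = tab[tab["pct_var"] >= threshold]
        for _, row in sig.iterrows():
            hits.append(
                {
                    "chr": row["chr"],
                    "start": max(1, int(row["window_start"]) - flank),
                    "end": int(row["window_end"]) + flank,
                    "coef": coef,
                    "pct_var": row["pct_var"],
                }
            )
    if not hits:
        return pd.DataFrame(
            columns=["region", "chr", "start", "end"] + [f"pct_{c}" for c in windows]
        )
    hits = pd.DataFrame(hits).sort_values(["chr", "start"])
    regions = []
    for c, grp in hits.groupby("chr", sort=True):
        cur = None
        for _, h in grp.iterrows():
            if cur is None or h["start"] > cur["end"]:
                if cur is not None:
                    regions.append(cur)
                cur = {"chr": c, "start": h["start"], "end": h["end"], "lead": {}}
            else:
                cur["end"] = max(cur["end"], h["end"])
            cur["lead"][h["coef"]] = max(cur["lead"].get(h["coef"], 0.0), h["pct_var"])
        regions.append(cur)
    rows = []
    for i, r in enumerate(sorted(regions, key=lambda r: (str(r["chr"]), r["start"])), 1):
        row = {"region": i, "chr": r["chr"], "start": int(r["start"]), "end": int(r["end"])}
        for coef in windows:
            row[f"pct_{coef}"] = round(r["lead"].get(coef, np.nan), 4)
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------- orchestrator
@dataclass
class WssgwasResult:
    spec: RNMSpec
    snp_effects: pd.DataFrame  # snp, chr, bp, one column per coefficient
    weights: pd.DataFrame
    windows: dict[str, pd.DataFrame] = field(default_factory=dict)
    regions: pd.DataFrame | None = None


def wssgwas(
    fit: RNMFit,
    records: pd.DataFrame,
    w_map: pd.Series,
    M: np.ndarray,
    snp_map: pd.DataFrame,
    genotyped_ids: np.ndarray,
    A22: np.ndarray | None = None,
    coefficients: tuple[str, ...] | None = None,
    n_iterations: int = 3,
    eps: float = 0.05,
    threshold: float = 0.5,
    flank: int = 200_000,
    window_size: int = 5,
) -> WssgwasResult:
    """Weighted single-step GWAS for the reported reaction-norm coefficients.

    Requires every phenotyped animal to be genotyped (the equivalent-model
    dense path); (co)variance components come from ``fit`` and are treated
    as known.  One weighted evaluation is run per target coefficient, with
    that coefficient's own back-solved effects driving the weights.
    """
    from .rnm import build_design

    spec = fit.spec
    order = pd.Index(genotyped_ids)
    rec = records.set_index("animal").loc[order].reset_index()
    w = rec["cg"].map(w_map).to_numpy(float)
    y = rec["pwg300"].to_numpy(float)
    X, _, W, Zr = build_design(spec, rec, w)
    p_frq = allele_frequencies(M)
    if np.any((p_frq <= 0) | (p_frq >= 1)):
        raise ValueError("monomorphic SNPs present; run qc_snps first")
    Z = np.asarray(M, float) - 2.0 * p_frq
    denom = 2.0 * np.sum(p_frq * (1.0 - p_frq))
    if A22 is None:
        A22 = np.eye(len(y))
    coefficients = coefficients or spec.reported_coefficients()
    eff = {}
    wts = {}
    windows = {}
    for coef in coefficients:
        c = coefficient_contrast(spec, coef)
        coef_var = float(c @ fit.K @ c)
        d = np.ones(Z.shape[1])
        u = np.zeros(Z.shape[1])
        for it in range(n_iterations):
            if it > 0:
                d = update_weights(u, p_frq)
            Gw = _syrk(Z * np.sqrt(d)) / denom
            Gb = blend_G(Gw, A22, eps)
            bhat, _ = solve_gblup_direct(y, X, W, Zr, Gb, fit.K, fit.eta)
            g_c = bhat @ c
            u = backsolve_snp_effects(g_c, Z, p_frq, d, Gb)
        eff[coef] = u
        wts[coef] = d
        if coef_var > 0:
            windows[coef] = window_variance(
                u, Z, snp_map, coef_var, size=window_size
            )
    snp_eff = snp_map.copy()
    for coef, u in eff.items():
        snp_eff[coef] = u
    wdf = snp_map[["snp"]].copy()
    for coef, d in wts.items():
        wdf[coef] = d
    regions = call_regions(windows, threshold=threshold, flank=flank)
    return WssgwasResult(
        spec=spec, snp_effects=snp_eff, weights=wdf, windows=windows, regions=regions
    )
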