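"""End-to-end orchestration: simulate/load -> gradient -> reaction norms ->
model comparison -> weighted single-step GWAS -> candidate regions -> genes.

Every stage logs its filter counts; outputs are plain TSV tables.  The
reaction-norm models are fitted as a warm-started ladder (homoscedastic
linear first, richer models started from the previous fit) so the
comparison table respects model nesting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import envgrad, genes as genes_mod, ssgwas
from .pedkin import Pedigree
from .rnm import (
    RNMFit,
    RNMSpec,
    embed_start,
    reml_fit,
    variance_at,
)
from .simdata import SimConfig, SimOutput, simulate

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run"]

_LADDER = {
    "homo-linear": None,
    "hete-linear": "homo-linear",
    "hete-quad": "hete-linear",
    "spline-ll": "hete-linear",
    "spline-qq": "spline-ll",
}


@dataclass
class PipelineConfig:
    sim: SimConfig | None = None  # simulate when set, else read input paths
    phenotypes: str | None = None
    pedigree: str | None = None
    genotypes: str | None = None
    snp_map: str | None = None
    annotation: str | None = None  # BED
    gene_sets: str | None = None  # TSV set_id, gene_id
    models: tuple[str, ...] = (
        "homo-linear", "hete-linear", "hete-quad", "spline-ll", "spline-qq",
    )
    gwas_models: tuple[str, ...] = ("hete-linear", "spline-ll")
    knot: float = 0.0
    min_cg_size: int = 20
    pwg_range: tuple[float, float] = (30.0, 250.0)
    eg_threshold: float = 3.0
    gwas_iterations: int = 3
    window_threshold: float = 0.5
    flank: int = 200_000
    blend_eps: float = 0.05
    seed: int = 0

    def digest(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return vars(o)
            return str(o)

        return hashlib.sha256(
            json.dumps(asdict(self), default=default, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    gradient: envgrad.EnvironmentalGradient
    fits: dict[str, RNMFit]
    comparison: pd.DataFrame
    gwas: dict[str, "ssgwas.WssgwasResult"] = field(default_factory=dict)
    regions: pd.DataFrame | None = None
    annotated: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None


def _load_inputs(cfg: PipelineConfig):
    if cfg.sim is not None:
        out: SimOutput = simulate(cfg.sim)
        geno_ids = out.genotype_ids[~out.pedigree.is_founder]
        M = out.genotypes[~out.pedigree.is_founder]
        return out.pedigree, out.phenotypes, M, out.snp_map, geno_ids
    if not (cfg.phenotypes and cfg.pedigree):
        raise ValueError("either sim config or phenotype+pedigree paths required")
    ped = Pedigree.from_csv(cfg.pedigree)
    phen = pd.read_csv(cfg.phenotypes)
    M = snp_map = geno_ids = None
    if cfg.genotypes and cfg.snp_map:
        gt = pd.read_csv(cfg.genotypes, sep="\t", index_col=0)
        M = gt.to_numpy(float)
        geno_ids = gt.index.to_numpy()
        snp_map = pd.read_csv(cfg.snp_map, sep="\t")
    return ped, phen, M, snp_map, geno_ids


def _comparison_table(fits: dict[str, RNMFit]) -> pd.DataFrame:
    rows = []
    base = fits.get("homo-linear")
    for name, fit in fits.items():
        rows.append(
            {
                "model": name,
                "np": fit.n_params,
                "logL": fit.logL,
                "AIC": fit.aic,
                "BIC": fit.bic,
                "dAIC": fit.aic - base.aic if base else np.nan,
                "dBIC": fit.bic - base.bic if base else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run(cfg: PipelineConfig, outdir) -> PipelineResult:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ped, phen_raw, M, snp_map, geno_ids = _load_inputs(cfg)
    if cfg.sim is not None:
        phen_raw.to_csv(out / "phenotypes_raw.csv", index=False)

    # ---- stage 1: QC + gradient ------------------------------------------
    rec = envgrad.qc_phenotypes(
        phen_raw, min_cg_size=cfg.min_cg_size, pwg_range=cfg.pwg_range
    )
    log.info("stage 1: %d records after QC", len(rec))
    eg_raw, _base_fit = envgrad.fit_baseline(rec, ped)
    eg = envgrad.standardize(eg_raw)
    rec, eg = envgrad.filter_extreme(rec, eg, threshold=cfg.eg_threshold)
    eg.to_tsv(out / "gradient.tsv")

    # ---- stage 2: reaction-norm ladder -----------------------------------
    fits: dict[str, RNMFit] = {}
    for name in cfg.models:
        spec = RNMSpec(name, knot=cfg.knot)
        start = None
        parent = _LADDER.get(name)
        if parent and parent in fits:
            pf = fits[parent]
            start = embed_start(pf.spec, spec, pf.K, pf.eta)
        fits[name] = reml_fit(spec, rec, eg, ped, start=start)
        log.info("fitted %s: logL=%.2f", name, fits[name].logL)
    comparison = _comparison_table(fits)
    comparison.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    for name, fit in fits.items():
        grid = np.linspace(-2.5, 3.0, 23)
        variance_at(fit, grid).to_csv(
            out / f"trajectory_{name}.tsv", sep="\t", index=False
        )
        if fit.solutions is not None:
            sols = fit.solutions.copy()
            if name == "spline-ll":
                sols["b1s2"] = sols["b1"] + sols["b1dev"]
            sols.to_csv(out / f"solutions_{name}.tsv", sep="\t")

    result = PipelineResult(gradient=eg, fits=fits, comparison=comparison)

    # ---- stage 3: GWAS ----------------------------------------------------
    if M is not None and len(rec):
        keep = np.isin(geno_ids, rec["animal"])
        M2, snp_map2, qc_rep = ssgwas.qc_snps(M[keep], snp_map)
        qc_rep.to_csv(out / "snp_qc.tsv", sep="\t", index=False)
        ids = np.asarray(geno_ids)[keep]
        rec_g = rec[rec["animal"].isin(ids)]
        if set(rec_g["animal"]) != set(ids):
            ids = rec_g["animal"].unique()
            keep2 = np.isin(np.asarray(geno_ids)[keep], ids)
            M2 = M2[keep2]
        A22 = ped.a_submatrix(ids)
        all_windows: dict[str, pd.DataFrame] = {}
        for name in cfg.gwas_models:
            if name not in fits:
                continue
            res = ssgwas.wssgwas(
                fits[name], rec_g, eg.table["w"], M2, snp_map2, ids,
                A22=A22, n_iterations=cfg.gwas_iterations, eps=cfg.blend_eps,
                threshold=cfg.window_threshold, flank=cfg.flank,
            )
            result.gwas[name] = res
            suffix = "s" if name.startswith("spline") else ""
            for coef, tab in res.windows.items():
                label = coef + suffix if coef == "b0" else coef
                all_windows[label] = tab
            res.snp_effects.to_csv(
                out / f"snp_effects_{name}.tsv", sep="\t", index=False
            )
        regions = ssgwas.call_regions(
            all_windows, threshold=cfg.window_threshold, flank=cfg.flank
        )
        regions.to_csv(out / "regions.tsv", sep="\t", index=False)
        result.regions = regions

        # ---- stage 4: genes ----------------------------------------------
        if cfg.annotation and len(regions):
            ann = genes_mod.read_bed(cfg.annotation)
            annotated = genes_mod.annotate_regions(regions, ann)
            annotated.to_csv(out / "regions_annotated.tsv", sep="\t", index=False)
            result.annotated = annotated
            if cfg.gene_sets:
                sets = pd.read_csv(cfg.gene_sets, sep="\t")
                query = sorted(
                    set(g for gs in annotated["genes"] for g in gs.split(",") if g)
                )
                enr = genes_mod.enrich(query, sets, set(ann["gene"]))
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                result.enrichment = enr
    return result
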