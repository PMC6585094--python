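"""Stage 1: phenotype QC and the contemporary-group environmental gradient.

The environmental descriptor is derived from the data itself: BLUEs of
contemporary-group (CG) effects from a baseline animal model (post-weaning
gain on age and CG fixed effects, additive animal and residual random
effects), standardised over CG levels to zero mean and unit sd.  Records
from CGs more than 3 sd above the mean are discarded before the
reaction-norm stage - only the upper tail, where few very favourable
management groups would otherwise dominate the regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "EnvironmentalGradient",
    "qc_phenotypes",
    "fit_baseline",
    "standardize",
    "filter_extreme",
    "gradient_to_adg",
]

UNKNOWN_CODES = {"0", "", "nan", "NA", "None", "<NA>", "0.0"}


@dataclass
class EnvironmentalGradient:
    """Per-CG BLUE (kg) and its standardised value w (sd units)."""

    table: pd.DataFrame  # index cg; columns blue, w
    mean_kg: float = float("nan")
    sd_kg: float = float("nan")

    @property
    def is_standardized(self) -> bool:
        return np.isfinite(self.mean_kg)

    def destandardize(self, w) -> np.ndarray:
        """Map gradient values (sd units) back to CG effects in kg."""
        if not self.is_standardized:
            raise ValueError("gradient has not been standardised yet")
        return self.mean_kg + np.asarray(w, float) * self.sd_kg

    def to_tsv(self, path) -> None:
        out = self.table.reset_index()
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EnvironmentalGradient":
        t = pd.read_csv(path, sep="\t").set_index("cg")
        blue = t["blue"]
        sd = float(blue.std(ddof=0))
        return cls(t, float(blue.mean()), sd)


# ---------------------------------------------------------------------------
def qc_phenotypes(
    raw: pd.DataFrame,
    min_cg_size: int = 20,
    pwg_range: tuple[float, float] = (30.0, 250.0),
    period_days: float = 300.0,
) -> pd.DataFrame:
    """Phenotype quality control.

    Keeps records with known sire and dam and an adjusted gain
    ``pwg300 = gain * 300 / days`` inside ``pwg_range``; afterwards drops
    contemporary groups below ``min_cg_size``, iterating until stable.
    Returns a copy with the ``pwg300`` column added.
    """
    required = {"animal", "cg", "days", "gain"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"phenotype table lacks column(s): {sorted(missing)}")
    rec = raw.copy()
    n0 = len(rec)
    if {"sire", "dam"} <= set(rec.columns):
        known = ~rec["sire"].astype(str).isin(UNKNOWN_CODES) & ~rec["dam"].astype(
            str
        ).isin(UNKNOWN_CODES)
        rec = rec[known]
    log.info("QC: %d/%d records with known parents", len(rec), n0)
    rec = rec[rec["days"] > 0]
    rec = rec.assign(pwg300=rec["gain"] * period_days / rec["days"].to_numpy(float))
    rec = rec[(rec["pwg300"] >= pwg_range[0]) & (rec["pwg300"] <= pwg_range[1])]
    log.info("QC: %d records inside PWG range %s", len(rec), pwg_range)
    while True:
        sizes = rec.groupby("cg")["animal"].transform("size")
        keep = sizes >= min_cg_size
        if keep.all():
            break
        rec = rec[keep]
    log.info("QC: %d records after CG-size filter (>= %d)", len(rec), min_cg_size)
    return rec.reset_index(drop=True)


def fit_baseline(
    records: pd.DataFrame, ped, options=None, variance_components=None
) -> tuple[EnvironmentalGradient, "object"]:
    """CG BLUEs from the baseline animal model.

    The model regresses pwg300 on CG (fixed, no global intercept so the
    solutions stay on the kg scale), linear+quadratic period terms, with an
    additive animal effect (pedigree covariance) and homoscedastic residual.
    Variance components are estimated by the same REML engine used for the
    reaction-norm stage unless supplied as ``(sigma2_a, sigma2_e)``.
    Returns the (unstandardised) gradient and the underlying fit.
    """
    fit = _baseline_reml(records, ped, options, variance_components)
    blues = fit.beta[fit.beta.index.str.startswith("cg:")]
    table = pd.DataFrame(
        {"blue": blues.to_numpy()},
        index=pd.Index([c.split(":", 1)[1] for c in blues.index], name="cg"),
    )
    table["w"] = np.nan
    return EnvironmentalGradient(table), fit


def _baseline_reml(records, ped, options, variance_components):
    """Single-coefficient animal model via the REML engine."""
    from . import reml as _reml
    from .pedkin import PedigreeError
    from .rnm import RNMFit, RNMSpec, _full_rank_columns

    y = records["pwg300"].to_numpy(float)
    cg = pd.Categorical(records["cg"])
    Xcg = pd.get_dummies(cg, dtype=float).to_numpy()
    d = (records["days"].to_numpy(float) - 300.0) / 100.0
    X = np.column_stack([Xcg, d, d * d])
    names = [f"cg:{c}" for c in cg.categories] + ["days_lin", "days_quad"]
    X, names = _full_rank_columns(X, names)
    n = len(y)
    W = np.ones((n, 1))
    Zr = np.ones((n, 1))
    animals = records["animal"].to_numpy()
    try:
        d0, F = ped.factored_submatrix(animals)
        core = _reml.FactoredCore(y, X, W, Zr, d0, F)
    except PedigreeError:
        core = _reml.DenseCore(y, X, W, Zr, ped.a_submatrix(animals))
    if variance_components is not None:
        s2a, s2e = variance_components
        K = np.array([[float(s2a)]])
        eta = np.array([np.log(float(s2e))])
        logL = core.set_params(K, eta)
        res = _reml.REMLResult(K=K, eta=eta, logL=logL, converged=True, n_iter=0,
                               beta=core.beta.copy(), Py=core.Py.copy())
    else:
        vy = float(records.groupby("cg")["pwg300"].var().mean())
        res = _reml.ai_reml(core, np.array([[0.35 * vy]]), np.array([np.log(0.65 * vy)]), options)
    spec = RNMSpec("homo-linear")
    fit = RNMFit(
        spec=spec,
        K=np.array([[res.K[0, 0], 0.0], [0.0, 0.0]]),
        eta=res.eta,
        logL=res.logL,
        n_records=n,
        beta=pd.Series(res.beta, index=names),
        converged=res.converged,
        n_iter=res.n_iter,
    )
    fit.residuals_orthogonality = float(
        np.abs(X.T @ core.vinv_apply(y - X @ res.beta)).max()
    )
    return fit


def standardize(eg: EnvironmentalGradient) -> EnvironmentalGradient:
    """Standardise BLUEs over CG levels (unweighted, population sd)."""
    if len(eg.table) < 2:
        raise ValueError("need at least two CGs to standardise")
    blue = eg.table["blue"].to_numpy(float)
    mean = float(blue.mean())
    sd = float(blue.std(ddof=0))
    if sd == 0:
        raise ValueError("zero spread among CG BLUEs; gradient undefined")
    table = eg.table.copy()
    table["w"] = (blue - mean) / sd
    return EnvironmentalGradient(table, mean, sd)


def filter_extreme(
    records: pd.DataFrame, eg: EnvironmentalGradient, threshold: float = 3.0
) -> tuple[pd.DataFrame, EnvironmentalGradient]:
    """Discard records from CGs with w above ``threshold`` sd.

    Only the upper tail is cut: very favourable environments are rare and
    exert outsized leverage on the regression slopes, while the harsh tail
    is part of the phenomenon under study.
    """
    if not eg.is_standardized:
        raise ValueError("standardise the gradient before filtering")
    bad_cg = eg.table.index[eg.table["w"] > threshold]
    kept = records[~records["cg"].isin(bad_cg)].reset_index(drop=True)
    log.info(
        "gradient filter: dropped %d CG(s) with w > %.1f sd holding %d record(s)",
        len(bad_cg), threshold, len(records) - len(kept),
    )
    eg2 = EnvironmentalGradient(
        eg.table.drop(index=bad_cg), eg.mean_kg, eg.sd_kg
    )
    return kept, eg2


def gradient_to_adg(effect_kg, days: float = 300.0) -> np.ndarray:
    """CG effect (kg over the period) -> average daily gain in g/day."""
    if days <= 0:
        raise ValueError("days must be positive")
    return np.asarray(effect_kg, float) * 1000.0 / days
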