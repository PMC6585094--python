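"""Reaction-norm model specifications, covariates and reporting.

Five model kinds are supported for the genetic regression on the
environmental gradient w (standardised contemporary-group effect):

============  =======================  =========================
kind          genetic basis z(w)       residual basis z_r(w)
============  =======================  =========================
homo-linear   (1, w)                   (1,)
hete-linear   (1, w)                   (1, w)
hete-quad     (1, w, w^2)              (1, w, w^2)
spline-ll     (1, w, w*)               (1, w, w*)
spline-qq     (1, w, w^2, w*, w^2*)    (1, w, w^2, w*, w^2*)
============  =======================  =========================

with w* = w if w >= k else 0 (one knot k, default at the average
environment k = 0) and w^2* defined analogously.  Residual variance is
log-linear in its basis: sigma^2_e(w) = exp(eta' z_r(w)); the homoscedastic
model is the special case of a constant basis.  The spline slope of the
second segment is the derived quantity b1seg2 = b1 + b1*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

__all__ = [
    "RNMSpec",
    "RNMFit",
    "MODEL_KINDS",
    "build_covariates",
    "n_dispersion_parameters",
    "information_criteria",
    "cov_to_corr",
    "variance_at",
    "ebv_at",
    "coefficient_contrast",
]

# term codes: "1", "w", "w2", "ws", "w2s"
_MODEL_TERMS = {
    "homo-linear": (("1", "w"), ("1",)),
    "hete-linear": (("1", "w"), ("1", "w")),
    "hete-quad": (("1", "w", "w2"), ("1", "w", "w2")),
    "spline-ll": (("1", "w", "ws"), ("1", "w", "ws")),
    "spline-qq": (("1", "w", "w2", "ws", "w2s"), ("1", "w", "w2", "ws", "w2s")),
}
MODEL_KINDS = tuple(_MODEL_TERMS)

_COEF_NAMES = {
    "homo-linear": ("b0", "b1"),
    "hete-linear": ("b0", "b1"),
    "hete-quad": ("b0", "b1", "b2"),
    "spline-ll": ("b0", "b1", "b1dev"),
    "spline-qq": ("b0", "b1", "b2", "b1dev", "b2dev"),
}


@dataclass(frozen=True)
class RNMSpec:
    """A reaction-norm model kind plus its knot position (gradient units)."""

    kind: str = "spline-ll"
    knot: float = 0.0

    def __post_init__(self):
        if self.kind not in _MODEL_TERMS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")

    @property
    def genetic_terms(self) -> tuple[str, ...]:
        return _MODEL_TERMS[self.kind][0]

    @property
    def residual_terms(self) -> tuple[str, ...]:
        return _MODEL_TERMS[self.kind][1]

    @property
    def coefficients(self) -> tuple[str, ...]:
        return _COEF_NAMES[self.kind]

    @property
    def n_coefficients(self) -> int:
        return len(self.genetic_terms)

    @property
    def is_spline(self) -> bool:
        return self.kind.startswith("spline")

    def reported_coefficients(self) -> tuple[str, ...]:
        """Coefficients reported downstream (GWAS, EBV tables): spline
        deviations are replaced by derived segment quantities."""
        if self.kind == "spline-ll":
            return ("b0", "b1s1", "b1s2")
        if self.kind == "spline-qq":
            return ("b0", "b1", "b2", "b1s2", "b2s2")
        return _COEF_NAMES[self.kind]


def _eval_terms(terms, w: np.ndarray, knot: float) -> np.ndarray:
    w = np.atleast_1d(np.asarray(w, float))
    above = (w >= knot).astype(float)
    cols = {
        "1": np.ones_like(w),
        "w": w,
        "w2": w * w,
        "ws": w * above,
        "w2s": w * w * above,
    }
    return np.column_stack([cols[t] for t in terms])


def build_covariates(spec: RNMSpec, w) -> dict[str, np.ndarray]:
    """Design rows at gradient values ``w``.

    Returns ``genetic`` (n x q), ``residual`` (n x c) and ``fixed_curve``
    (n x (q-1): the overall-curve regressors, i.e. the genetic basis without
    its intercept which is absorbed by the contemporary-group effects).
    """
    Z = _eval_terms(spec.genetic_terms, w, spec.knot)
    Zr = _eval_terms(spec.residual_terms, w, spec.knot)
    return {"genetic": Z, "residual": Zr, "fixed_curve": Z[:, 1:]}


def n_dispersion_parameters(spec: RNMSpec) -> int:
    q = spec.n_coefficients
    return q * (q + 1) // 2 + len(spec.residual_terms)


def information_criteria(logL: float, n_params: int, n: int) -> tuple[float, float]:
    """AIC = -2logL + 2 np; BIC = -2logL + np ln(n), n = records used."""
    aic = -2.0 * logL + 2.0 * n_params
    bic = -2.0 * logL + n_params * math.log(n)
    return aic, bic


def cov_to_corr(K: np.ndarray) -> np.ndarray:
    """Correlations among random-regression coefficients.

    Zero-variance coefficients yield NaN entries (flagged, not raised: a
    degenerate fit is still reportable).
    """
    K = np.asarray(K, float)
    s = np.sqrt(np.diag(K))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = K / np.outer(s, s)
    np.fill_diagonal(R, np.where(s > 0, 1.0, np.nan))
    return R


def coefficient_contrast(spec: RNMSpec, name: str) -> np.ndarray:
    """Contrast vector c such that the named (possibly derived) coefficient
    equals c' b.  Supports the spline segment quantities b1s1/b1s2 (and
    b2s1/b2s2 for the quadratic spline)."""
    coefs = list(spec.coefficients)
    c = np.zeros(len(coefs))
    if name in coefs:
        c[coefs.index(name)] = 1.0
        return c
    derived = {
        "b1s1": ("b1",),
        "b1s2": ("b1", "b1dev"),
        "b2s1": ("b2",),
        "b2s2": ("b2", "b2dev"),
    }
    if name not in derived:
        raise KeyError(f"unknown coefficient {name!r} for model {spec.kind}")
    for base in derived[name]:
        if base not in coefs:
            raise KeyError(f"coefficient {name!r} undefined for model {spec.kind}")
        c[coefs.index(base)] = 1.0
    return c


@dataclass
class RNMFit:
    """Converged REML fit of a reaction-norm model."""

    spec: RNMSpec
    K: np.ndarray  # (co)variances among coefficients, kg^2
    eta: np.ndarray  # log-residual coefficients, log kg^2
    logL: float
    n_records: int
    solutions: pd.DataFrame | None = None  # animal x coefficient estimates
    beta: pd.Series | None = None  # fixed-effect solutions
    converged: bool = True
    n_iter: int = 0
    history: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return n_dispersion_parameters(self.spec)

    @property
    def aic(self) -> float:
        return information_criteria(self.logL, self.n_params, self.n_records)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.logL, self.n_params, self.n_records)[1]

    def corr(self) -> np.ndarray:
        return cov_to_corr(self.K)

    def reported_K(self) -> pd.DataFrame:
        """K expressed on the reported-coefficient basis (spline deviations
        mapped to derived segment slopes), mirroring how variance-component
        tables are usually printed."""
        names = self.spec.reported_coefficients()
        C = np.column_stack([coefficient_contrast(self.spec, n) for n in names])
        return pd.DataFrame(C.T @ self.K @ C, index=names, columns=names)


def variance_at(fit: RNMFit, w) -> pd.DataFrame:
    """Genetic variance, residual variance and heritability along w."""
    w = np.atleast_1d(np.asarray(w, float))
    cov = build_covariates(fit.spec, w)
    Z, Zr = cov["genetic"], cov["residual"]
    var_a = np.einsum("ij,jk,ik->i", Z, fit.K, Z)
    var_e = np.exp(Zr @ fit.eta)
    h2 = var_a / (var_a + var_e)
    return pd.DataFrame({"w": w, "var_a": var_a, "var_e": var_e, "h2": h2})


def _full_rank_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are linear combinations of *earlier* ones (greedy
    left-to-right Gram-Schmidt).  With contemporary-group dummies present,
    the overall-curve regressors are exactly collinear (the gradient is
    constant within a group) and, being last, are the ones removed.  The
    deterministic earliest-first preference keeps the fixed-effect basis
    identical across model kinds, which keeps their restricted likelihoods
    comparable (log |X'V^-1 X| depends on the basis, not just the span)."""
    Q = np.zeros((X.shape[0], 0))
    keep: list[int] = []
    norms = np.linalg.norm(X, axis=0)
    tol = norms.max() * 1e-9
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        if keep:
            v = v - Q @ (Q.T @ v)
            v = v - Q @ (Q.T @ v)  # second pass for numerical safety
        nv = np.linalg.norm(v)
        if nv > tol:
            Q = np.column_stack([Q, v / nv])
            keep.append(j)
    return X[:, keep], [names[i] for i in keep]


def build_design(
    spec: RNMSpec, records: pd.DataFrame, w: np.ndarray
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Fixed-effect matrix plus genetic/residual covariate rows.

    Fixed effects: contemporary-group dummies (no global intercept: CG
    absorbs it, keeping solutions on the kg scale), linear and quadratic
    post-weaning-period terms (centred at 300 d), and the overall-curve
    regressors of the model (pruned when collinear with CG).
    """
    cov = build_covariates(spec, w)
    cg = pd.Categorical(records["cg"])
    Xcg = pd.get_dummies(cg, dtype=float).to_numpy()
    names = [f"cg:{c}" for c in cg.categories]
    d = (records["days"].to_numpy(float) - 300.0) / 100.0
    X = np.column_stack([Xcg, d, d * d, cov["fixed_curve"]])
    names += ["days_lin", "days_quad"] + [
        f"curve:{t}" for t in spec.genetic_terms[1:]
    ]
    X, names = _full_rank_columns(X, names)
    return X, names, cov["genetic"], cov["residual"]


def reml_fit(
    spec: RNMSpec,
    records: pd.DataFrame,
    gradient,
    ped,
    options=None,
    start: tuple[np.ndarray, np.ndarray] | None = None,
    solve_all_animals: bool = True,
    dense_limit: int = 8000,
) -> RNMFit:
    """REML estimation of (K, eta) for one reaction-norm model.

    ``records`` needs columns animal/cg/days/pwg300; ``gradient`` maps CG to
    its standardised environmental value (mapping, Series, or an
    EnvironmentalGradient); ``ped`` is the Pedigree providing relationships.
    The fast diagonal-plus-low-rank backend is used when the phenotyped
    animals form a half-sib design over founder parents, otherwise the dense
    relationship block is formed.
    """
    from .envgrad import EnvironmentalGradient  # local import, no cycle at module load
    from .pedkin import PedigreeError
    from . import reml as _reml

    if isinstance(gradient, EnvironmentalGradient):
        w_map = gradient.table["w"]
    elif isinstance(gradient, pd.DataFrame):
        w_map = gradient.set_index("cg")["w"]
    else:
        w_map = pd.Series(gradient)
    w = records["cg"].map(w_map).to_numpy(float)
    if np.isnan(w).any():
        missing = records.loc[np.isnan(w), "cg"].unique()
        raise ValueError(f"no gradient value for CG(s): {list(missing)[:5]} ...")
    y = records["pwg300"].to_numpy(float)
    X, xnames, W, Zr = build_design(spec, records, w)
    animals = records["animal"].to_numpy()
    try:
        d0, F = ped.factored_submatrix(animals)
        core = _reml.FactoredCore(y, X, W, Zr, d0, F)
    except PedigreeError:
        if len(records) > dense_limit:
            raise ValueError(
                f"{len(records)} records need the dense relationship block; "
                f"raise dense_limit to allow it"
            )
        core = _reml.DenseCore(y, X, W, Zr, ped.a_submatrix(animals))
    if start is None:
        vy = float(records.groupby("cg")["pwg300"].var().mean())
        q = spec.n_coefficients
        K0 = np.diag([0.3 * vy] + [0.03 * vy] * (q - 1))
        eta0 = np.zeros(len(spec.residual_terms))
        eta0[0] = np.log(0.6 * vy)
    else:
        K0, eta0 = start
    res = _reml.ai_reml(core, K0, eta0, options)

    # kriging of coefficient solutions through the pedigree: bhat = A[:, phen] diag(Py) W K
    phen_idx = ped.indices(animals)
    E = np.zeros((len(ped), spec.n_coefficients))
    E[phen_idx] = res.Py[:, None] * (W @ res.K)
    if solve_all_animals:
        sols = ped.a_matmat(E)
        sol_df = pd.DataFrame(sols, index=ped.ids, columns=spec.coefficients)
    else:
        sols = core.relationship_matvec(E[phen_idx])
        sol_df = pd.DataFrame(sols, index=animals, columns=spec.coefficients)
    sol_df.index.name = "animal"
    return RNMFit(
        spec=spec,
        K=res.K,
        eta=res.eta,
        logL=res.logL,
        n_records=len(records),
        solutions=sol_df,
        beta=pd.Series(res.beta, index=xnames),
        converged=res.converged,
        n_iter=res.n_iter,
        history=res.history,
    )


def embed_start(
    src_spec: RNMSpec, dst_spec: RNMSpec, K: np.ndarray, eta: np.ndarray,
    frac: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a fitted (K, eta) into starting values for a richer model.

    Shared coefficients keep their (co)variances; coefficients new to the
    destination start at ``frac`` of the mean non-intercept variance (or of
    the intercept variance when there is none).  Residual coefficients map
    by basis term; new terms start at zero.  Warm-starting the model ladder
    this way makes the nesting inequality logL(bigger) >= logL(smaller)
    hold by construction up to optimiser tolerance.
    """
    src_c, dst_c = src_spec.coefficients, dst_spec.coefficients
    q = len(dst_c)
    K0 = np.zeros((q, q))
    for i, ci in enumerate(dst_c):
        for j, cj in enumerate(dst_c):
            if ci in src_c and cj in src_c:
                K0[i, j] = K[src_c.index(ci), src_c.index(cj)]
    old_vars = [K0[i, i] for i, ci in enumerate(dst_c) if ci in src_c and ci != "b0"]
    fill = frac * (np.mean(old_vars) if old_vars and np.mean(old_vars) > 0 else K0[0, 0] * 0.05)
    fill = max(fill, 1e-4 * max(K0[0, 0], 1.0))
    for i, ci in enumerate(dst_c):
        if ci not in src_c:
            K0[i, i] = fill
    eta0 = np.zeros(len(dst_spec.residual_terms))
    for i, t in enumerate(dst_spec.residual_terms):
        if t in src_spec.residual_terms:
            eta0[i] = eta[src_spec.residual_terms.index(t)]
    return K0, eta0


def ebv_at(fit: RNMFit, animal, w) -> np.ndarray:
    """EBV trajectory z(w)' b_hat for one animal."""
    if fit.solutions is None:
        raise ValueError("fit carries no animal solutions")
    if animal not in fit.solutions.index:
        raise KeyError(f"unknown animal {animal!r}")
    b = fit.solutions.loc[animal].to_numpy(float)
    Z = build_covariates(fit.spec, w)["genetic"]
    return Z @ b
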