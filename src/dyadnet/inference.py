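"""Mixed-effects models on dyadic association indices.

Two families are supported, both with a logit link: a beta model for the
simple-ratio index itself (density parameterized by mean mu and precision
phi) and a Bernoulli model for the hurdle occurrence part. Every dyad row
carries two random intercepts — one for each member — integrated out by a
Laplace approximation; the member-A and member-B roles get their own
variance components by default ("crossed"), with a multi-membership
single-variance alternative available.

Fitting profiles the fixed effects into the inner mode-finding step for
speed and then, by default, polishes all parameters against the standard
Laplace objective. Likelihood-ratio comparisons, analytic chi-square
p-values, and emmeans-style per-dyad-sex group contrasts are provided on
top of the fits. ``marginal_loglik`` exposes the Laplace integral alongside
a dense Gauss-Hermite quadrature evaluation of the same integral so the
approximation can be validated on small instances.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import _glmm_core as core

logger = logging.getLogger("dyadnet")

__all__ = [
    "ModelSpec",
    "FitOptions",
    "GLMMFit",
    "LRTResult",
    "ContrastResult",
    "squeeze_unit_interval",
    "build_design",
    "fit_glmm",
    "fit_from_response",
    "fit_full_reduced",
    "likelihood_ratio",
    "group_contrasts",
    "marginal_loglik",
    "FULL_TERMS",
    "REDUCED_TERMS",
]

FULL_TERMS = ("intercept", "sex_type", "group", "sex_type:group", "kin", "age_diff")
REDUCED_TERMS = ("intercept", "sex_type", "group", "kin", "age_diff")

#: response name -> (SRI column, family, hurdle part)
RESPONSES = {
    "party_sri": ("sri_party", "beta_logit", "sri"),
    "occurrence": ("sri_direct", "binomial_logit", "occurrence"),
    "magnitude_sri": ("sri_direct", "beta_logit", "magnitude"),
    "grooming_occurrence": ("sri_groom", "binomial_logit", "occurrence"),
    "grooming_magnitude": ("sri_groom", "beta_logit", "magnitude"),
}


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed_terms: Tuple[str, ...] = FULL_TERMS
    family: str = "beta_logit"
    re_structure: str = "crossed"  # or "multi_membership"
    random_terms: Tuple[str, ...] = ("member_a_intercept", "member_b_intercept")

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if "sex_type:group" in self.fixed_terms and not (
            "sex_type" in self.fixed_terms and "group" in self.fixed_terms
        ):
            raise ValueError("interaction requires both main effects")
        expected_family = RESPONSES[self.response][1]
        if self.family != expected_family:
            raise ValueError(
                f"family {self.family!r} does not match response {self.response!r} (expected {expected_family})"
            )
        if self.re_structure not in ("crossed", "multi_membership"):
            raise ValueError(f"unknown random-effect structure {self.re_structure!r}")


@dataclass(frozen=True)
class FitOptions:
    polish: bool = True
    fix_sigma_zero: bool = False
    max_restarts: int = 5
    seed: int = 0
    inner_maxit: int = 60
    inner_tol: float = 1e-11
    nm_maxiter: int = 300
    nm_ftol: float = 1e-10
    nm_step: float = 0.4
    polish_maxfev: int = 3000


@dataclass
class GLMMFit:
    spec: ModelSpec
    terms: List[str]
    beta_hat: np.ndarray
    se: np.ndarray
    vcov_fixed: np.ndarray
    phi_hat: Optional[float]
    sigma2_a: float
    sigma2_b: float
    loglik: float
    n_obs: int
    converged: bool
    design_meta: Dict
    n_squeezed: int = 0

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def coef(self, name: str) -> float:
        return float(self.beta_hat[self.terms.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        z = self.beta_hat / self.se
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta_hat,
                "se": self.se,
                "statistic": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_analytic: float


@dataclass(frozen=True)
class ContrastResult:
    level: str
    estimate: float
    se: float
    statistic: float
    p: float


# ---------------------------------------------------------------------------
# Response preparation


def squeeze_unit_interval(values: np.ndarray, n: int) -> np.ndarray:
    """Compress proportions into the open unit interval: (y*(n-1)+0.5)/n.

    The standard boundary fix for beta-distributed responses observed at
    exactly 0 or 1; order-preserving, with 0.5 as fixed point.
    """
    if n < 2:
        raise ValueError("squeeze requires n >= 2")
    values = np.asarray(values, dtype=float)
    return (values * (n - 1) + 0.5) / n


def _prepare_response(table: pd.DataFrame, response: str) -> Tuple[pd.DataFrame, np.ndarray, str, int]:
    column, family, part = RESPONSES[response]
    y = table[column].to_numpy(dtype=float)
    if part == "occurrence":
        return table, (y > 0).astype(float), family, 0
    if part == "magnitude":
        mask = y > 0
        table = table.loc[mask].reset_index(drop=True)
        y = y[mask]
    n_squeezed = 0
    if len(y) and (np.any(y <= 0.0) or np.any(y >= 1.0)):
        n_squeezed = int(np.sum((y <= 0.0) | (y >= 1.0)))
        logger.info("squeezing %d boundary values of %s into (0,1) with n=%d", n_squeezed, column, len(y))
        y = squeeze_unit_interval(y, len(y))
    return table, y, family, n_squeezed


# ---------------------------------------------------------------------------
# Design construction


def build_design(table: pd.DataFrame, fixed_terms: Sequence[str]) -> Tuple[np.ndarray, List[str], Dict]:
    """Treatment-coded fixed-effects design matrix.

    Reference levels: FF for dyad sex type, the first (sorted) group id for
    group. Returns (X, column names, metadata for contrasts).
    """
    n = len(table)
    sex_levels = ["FF", "MF", "MM"]
    group_levels = sorted(table["group_id"].unique().tolist())
    cols: List[np.ndarray] = []
    names: List[str] = []
    sex = table["sex_type"].to_numpy()
    grp = table["group_id"].to_numpy()
    for term in fixed_terms:
        if term == "intercept":
            cols.append(np.ones(n))
            names.append("intercept")
        elif term == "sex_type":
            for lv in sex_levels[1:]:
                cols.append((sex == lv).astype(float))
                names.append(f"sex_type[{lv}]")
        elif term == "group":
            for gv in group_levels[1:]:
                cols.append((grp == gv).astype(float))
                names.append(f"group[{gv}]")
        elif term == "sex_type:group":
            for lv in sex_levels[1:]:
                for gv in group_levels[1:]:
                    cols.append(((sex == lv) & (grp == gv)).astype(float))
                    names.append(f"sex_type[{lv}]:group[{gv}]")
        elif term == "kin":
            cols.append(table["kin"].to_numpy(dtype=float))
            names.append("kin")
        elif term == "age_diff":
            cols.append(table["age_diff"].to_numpy(dtype=float))
            names.append("age_diff")
        else:
            raise ValueError(f"unknown fixed term {term!r}")
    X = np.column_stack(cols) if cols else np.zeros((n, 0))
    meta = {
        "sex_levels": sex_levels,
        "group_levels": group_levels,
        "age_mean": float(table["age_diff"].mean()) if "age_diff" in table else 0.0,
        "fixed_terms": tuple(fixed_terms),
    }
    return X, names, meta


def _random_design(table: pd.DataFrame, re_structure: str) -> Tuple[np.ndarray, np.ndarray, int, int, bool]:
    """Role index vectors for the latent intercepts.

    crossed: separate intercept vectors (and variances) for the member-A and
    member-B roles; multi_membership: one intercept per individual entering
    additively through both roles, single variance.
    """
    a = table["member_a"].to_numpy()
    b = table["member_b"].to_numpy()
    if re_structure == "multi_membership":
        ids = sorted(set(a) | set(b))
        idx = {v: k for k, v in enumerate(ids)}
        ia = np.array([idx[v] for v in a], dtype=np.int64)
        ib = np.array([idx[v] for v in b], dtype=np.int64)
        return ia, ib, len(ids), 0, True
    a_ids = sorted(set(a))
    b_ids = sorted(set(b))
    ia = np.array([a_ids.index(v) for v in a], dtype=np.int64)
    ib = np.array([b_ids.index(v) for v in b], dtype=np.int64)
    return ia, ib, len(a_ids), len(b_ids), False


def _assemble(X: np.ndarray, ia: np.ndarray, ib: np.ndarray, qa: int, qb: int, tie: bool) -> np.ndarray:
    n, p = X.shape
    if qa == 0:
        return np.ascontiguousarray(X)
    m = p + qa + qb
    A = np.zeros((n, m))
    A[:, :p] = X
    rows = np.arange(n)
    if tie and qb == 0:  # multi-membership: both roles hit the same block
        A[rows, p + ia] = 1.0
        A[rows, p + ib] += 1.0
    else:
        A[rows, p + ia] = 1.0
        A[rows, p + qa + ib] = 1.0
    return A


def _theta_layout(family: str, qa: int, qb: int, tie: bool) -> int:
    d = 1 if family == "beta_logit" else 0
    if qa > 0:
        d += 1
        if qb > 0 and not tie:
            d += 1
    return d


def _initial_theta(y: np.ndarray, family: str, qa: int, qb: int, tie: bool) -> np.ndarray:
    parts = []
    if family == "beta_logit":
        m, v = float(np.mean(y)), float(np.var(y))
        phi0 = m * (1 - m) / max(v, 1e-6) - 1.0
        parts.append(np.log(min(max(phi0, 1.0), 300.0)))
    if qa > 0:
        parts.append(np.log(0.4))
        if qb > 0 and not tie:
            parts.append(np.log(0.4))
    return np.array(parts, dtype=float)


# ---------------------------------------------------------------------------
# Fitting


def fit_from_response(
    table: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    options: FitOptions = FitOptions(),
    init: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    n_squeezed: int = 0,
) -> GLMMFit:
    """Fit a model given a prepared response vector (rows match *table*)."""
    y = np.ascontiguousarray(y, dtype=float)
    X, names, meta = build_design(table, spec.fixed_terms)
    p = X.shape[1]
    if options.fix_sigma_zero:
        ia = ib = np.zeros(0, dtype=np.int64)
        qa = qb = 0
        tie = False
    else:
        ia, ib, qa, qb, tie = _random_design(table, spec.re_structure)
    A = _assemble(X, ia, ib, qa, qb, tie)
    m = A.shape[1]
    fam = core.FAM_BETA if spec.family == "beta_logit" else core.FAM_BERNOULLI
    offset = np.zeros(len(y))

    theta0 = _initial_theta(y, spec.family, qa, qb, tie)
    z0 = np.zeros(m)
    if init is not None:
        init_theta, init_z = init
        if init_theta.shape == theta0.shape:
            theta0 = init_theta.copy()
        if init_z.shape == z0.shape:
            z0 = init_z.copy()

    rng = np.random.default_rng(options.seed)
    best = None
    theta_try = theta0
    z_try = z0
    for attempt in range(options.max_restarts + 1):
        theta, z, ll, gnorm, converged, spread = core.fit_core(
            y, offset, A, p, qa, qb, fam, tie, theta_try, z_try,
            options.inner_maxit, options.inner_tol, options.nm_maxiter, options.nm_ftol, options.nm_step,
        )
        if best is None or ll > best[2]:
            best = (theta, z, ll, gnorm, bool(converged))
        if converged:
            break
        theta_try = theta0 + rng.normal(0.0, 0.4, size=theta0.shape)
        z_try = np.zeros(m)
        logger.warning("GLMM fit restart %d (gradient norm %.2e)", attempt + 1, gnorm)
    theta, z, ll, gnorm, converged = best

    if options.polish and qa > 0 and theta0.shape[0] > 0:
        theta, z, ll = _polish(y, X, A, p, qa, qb, fam, tie, theta, z, ll, options)

    phi, prec = core._build_prec(theta, p, qa, qb, m, fam, tie)
    H = core.full_hessian(y, offset, A, prec, z, fam, phi)
    try:
        vcov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_all = np.linalg.pinv(H)
    vcov = vcov_all[:p, :p]
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))

    idx = 1 if spec.family == "beta_logit" else 0
    if qa == 0:
        s2a = s2b = 0.0
    elif tie:
        s2a = s2b = float(np.exp(2 * np.clip(theta[idx], -6, 3)))
    else:
        s2a = float(np.exp(2 * np.clip(theta[idx], -6, 3)))
        s2b = float(np.exp(2 * np.clip(theta[idx + 1], -6, 3))) if qb > 0 else 0.0

    if not converged:
        logger.warning("GLMM fit for %s did not converge (gradient norm %.2e)", spec.response, gnorm)

    meta["theta"] = theta.copy()
    meta["z"] = z.copy()
    return GLMMFit(
        spec=spec,
        terms=names,
        beta_hat=z[:p].copy(),
        se=se,
        vcov_fixed=0.5 * (vcov + vcov.T),
        phi_hat=float(phi) if spec.family == "beta_logit" else None,
        sigma2_a=s2a,
        sigma2_b=s2b,
        loglik=float(ll),
        n_obs=len(y),
        converged=bool(converged),
        design_meta=meta,
        n_squeezed=n_squeezed,
    )


def _polish(y, X, A, p, qa, qb, fam, tie, theta, z, ll, options: FitOptions):
    """Refine (beta, theta) against the standard Laplace objective.

    The core fit profiles beta into the joint mode; here beta is treated as
    an outer parameter (the textbook Laplace ML), which matters only in the
    third decimal but keeps the model ladder monotone.
    """
    Au = np.ascontiguousarray(A[:, p:])
    m = A.shape[1]
    u_state = z[p:].copy()

    def neg(params: np.ndarray) -> float:
        beta = params[:p]
        th = params[p:]
        phi, prec_full = core._build_prec(th, 0, qa, qb, m - p, fam, tie)
        offset = X @ beta
        lpen, gnorm, ok = core._inner(y, offset, Au, prec_full, u_state, fam, phi, options.inner_maxit, options.inner_tol)
        return -core._laplace_value(y, offset, Au, prec_full, u_state, fam, phi, 0)

    x0 = np.concatenate([z[:p], theta])
    res = optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"maxfev": options.polish_maxfev, "fatol": 1e-9, "xatol": 1e-6},
    )
    if -res.fun > ll:
        x = res.x
        theta = x[p:].copy()
        neg(x)  # leaves u_state at the mode for x
        z = np.concatenate([x[:p], u_state])
        ll = -res.fun
    return theta, z, float(ll)


def fit_glmm(table: pd.DataFrame, spec: ModelSpec, options: FitOptions = FitOptions()) -> GLMMFit:
    """Fit a dyadic GLMM on a dyad table (see ``association.dyad_table``)."""
    subtable, y, family, n_squeezed = _prepare_response(table, spec.response)
    if family == "beta_logit" and len(y) == 0:
        raise ValueError("magnitude model has no nonzero dyads to fit")
    if family == "beta_logit" and (np.any(y <= 0) or np.any(y >= 1)):
        raise ValueError("beta response outside the open unit interval")
    return fit_from_response(subtable, y, spec, options, n_squeezed=n_squeezed)


def fit_full_reduced(
    table: pd.DataFrame,
    spec_full: ModelSpec,
    spec_reduced: ModelSpec,
    options: FitOptions = FitOptions(),
) -> Tuple[GLMMFit, GLMMFit]:
    """Fit the nested pair, warm-starting the full model from the reduced one.

    Starting the full fit at the reduced optimum makes the likelihood-ratio
    statistic structurally non-negative up to optimizer tolerance.
    """
    subtable, y, family, n_squeezed = _prepare_response(table, spec_full.response)
    reduced = fit_from_response(subtable, y, spec_reduced, options, n_squeezed=n_squeezed)
    X_f, names_f, _ = build_design(subtable, spec_full.fixed_terms)
    p_f = X_f.shape[1]
    # map reduced coefficients onto the full design by term name
    beta0 = np.zeros(p_f)
    for j, name in enumerate(names_f):
        if name in reduced.terms:
            beta0[j] = reduced.beta_hat[reduced.terms.index(name)]
    z_tail = reduced.design_meta["z"][len(reduced.terms):]
    init = (reduced.design_meta["theta"], np.concatenate([beta0, z_tail]))
    full = fit_from_response(subtable, y, spec_full, options, init=init, n_squeezed=n_squeezed)
    return full, reduced


# ---------------------------------------------------------------------------
# Model comparison and contrasts


def likelihood_ratio(full: GLMMFit, reduced: GLMMFit) -> LRTResult:
    """Deviance-difference test of nested fits against the chi-square reference."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms are not nested in the full model")
    if full.spec.family != reduced.spec.family or full.n_obs != reduced.n_obs:
        raise ValueError("fits are not comparable (family or data differ)")
    chi2 = reduced.deviance - full.deviance
    if chi2 < -1e-6:
        raise ConvergenceError(f"negative LRT statistic ({chi2:.3g}): fits not at their optima")
    chi2 = max(chi2, 0.0)
    df = len(full.terms) - len(reduced.terms)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return LRTResult(chi2=float(chi2), df=df, p_analytic=p)


def group_contrasts(fit: GLMMFit) -> List[ContrastResult]:
    """Per-dyad-sex group difference on the link scale (first minus second group).

    Estimated-marginal-mean style: kinship held at 0 and age difference at
    its sample mean (both cancel in the between-group difference), standard
    errors from the fixed-effect covariance, two-sided normal p-values.
    """
    meta = fit.design_meta
    groups = meta["group_levels"]
    if len(groups) != 2:
        raise ValueError("group contrasts require exactly two groups")
    inter_cols = [t for t in fit.terms if ":" in t]
    if not any(":" in t for t in fit.terms) and "sex_type:group" not in meta["fixed_terms"]:
        raise ValueError("model has no sex_type:group interaction")
    g2 = groups[1]
    results = []
    for level in meta["sex_levels"]:
        c = np.zeros(len(fit.terms))
        gcol = f"group[{g2}]"
        if gcol in fit.terms:
            c[fit.terms.index(gcol)] = -1.0  # group1 - group2
        icol = f"sex_type[{level}]:group[{g2}]"
        if icol in fit.terms:
            c[fit.terms.index(icol)] = -1.0
        est = float(c @ fit.beta_hat)
        se = float(np.sqrt(max(c @ fit.vcov_fixed @ c, 0.0)))
        stat = est / se if se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(stat))) if se > 0 else np.nan
        results.append(ContrastResult(level=level, estimate=est, se=se, statistic=stat, p=p))
    return results


# ---------------------------------------------------------------------------
# Marginal likelihood evaluators (Laplace and quadrature oracle)


def _family_loglik_matrix(y: np.ndarray, eta: np.ndarray, family: str, phi: float) -> np.ndarray:
    """Row-wise conditional log-likelihood for a (k, n) matrix of linear predictors."""
    eta = np.clip(eta, -35, 35)
    mu = special.expit(eta)
    if family == "binomial_logit":
        return (y * eta - np.log1p(np.exp(eta))).sum(axis=-1)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    a = mu * phi
    b = (1 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1) * np.log(y)
        + (b - 1) * np.log(1 - y)
    ).sum(axis=-1)


def marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    qa: int,
    qb: int,
    family: str,
    phi: float = 1.0,
    sigma_a: float = 0.5,
    sigma_b: float = 0.5,
    multi_membership: bool = False,
    method: str = "laplace",
    gh_nodes: int = 21,
) -> float:
    """Log marginal likelihood at fixed parameters.

    ``method="laplace"`` uses the same machinery as the fitter (inner mode
    search plus curvature correction); ``method="gh"`` evaluates the
    integral over the latent intercepts by dense tensor-product
    Gauss-Hermite quadrature and is only feasible for a handful of latent
    dimensions — it is the accuracy oracle for the Laplace approximation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    offset = X @ beta if X.size else np.zeros(len(y))
    tie = multi_membership
    q = qa + qb
    fam = core.FAM_BETA if family == "beta_logit" else core.FAM_BERNOULLI

    if method == "laplace":
        A = _assemble(np.zeros((len(y), 0)), ia, ib, qa, qb, tie)
        prec = np.zeros(q)
        prec[:qa] = 1.0 / sigma_a**2
        if qb > 0:
            prec[qa:] = 1.0 / sigma_b**2
        u = np.zeros(q)
        core._inner(y, offset, A, prec, u, fam, phi, 200, 1e-12)
        return float(core._laplace_value(y, offset, A, prec, u, fam, phi, 0))

    if method != "gh":
        raise ValueError(f"unknown method {method!r}")
    if q > 6:
        raise ValueError("dense Gauss-Hermite quadrature limited to q <= 6 latent dimensions")
    nodes, weights = np.polynomial.hermite.hermgauss(gh_nodes)
    logw = np.log(weights)
    sig = np.concatenate([np.full(qa, sigma_a), np.full(qb, sigma_b)])
    total = gh_nodes**q
    chunk = max(1, 4_000_000 // max(len(y), 1))  # stream the tensor grid
    partial: List[float] = []
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        digits = np.empty((len(idx), q), dtype=np.int64)
        rem = idx.copy()
        for j in range(q - 1, -1, -1):
            digits[:, j] = rem % gh_nodes
            rem //= gh_nodes
        U = np.sqrt(2.0) * nodes[digits] * sig  # latent draws at the nodes
        LW = logw[digits].sum(axis=1)
        if multi_membership:
            eta = offset[None, :] + U[:, ia] + U[:, ib]
        else:
            eta = offset[None, :] + U[:, ia] + U[:, qa + ib]
        ll = _family_loglik_matrix(y[None, :], eta, family, phi)
        partial.append(float(special.logsumexp(ll + LW)))
    return float(special.logsumexp(np.array(partial)) - q * np.log(np.sqrt(np.pi)))
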