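"""Datastream (prenetwork) permutation test for the group x dyad-sex interaction.

The daily binarized association events are randomized: within each day, the
observed events are reassigned uniformly at random across the dyads that had
at least one member identified that day, keeping the per-day event count —
and hence every SRI denominator — fixed. Each permuted stream is condensed
into simple-ratio indices and analysed with the same full/reduced model pair
as the original data; the permutation p-value is the proportion of permuted
deviance differences at least as large as the observed one,

    P_rand = #(delta_obs <= delta_perm) / n_kept.

An alternative swap-based scheme that additionally preserves each
individual's daily association count is available behind ``scheme``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import _glmm_core as core
from .association import DailyStream, build_daily_stream, table_from_stream
from .data_model import FocalRecord, Individual
from .inference import (
    FULL_TERMS,
    REDUCED_TERMS,
    FitOptions,
    ModelSpec,
    RESPONSES,
    _assemble,
    _initial_theta,
    _random_design,
    build_design,
    fit_from_response,
    squeeze_unit_interval,
)

logger = logging.getLogger("dyadnet")

__all__ = ["PermutationResult", "permute_day", "run_permutation_test", "format_p_rand"]

#: negative deviance differences smaller than this are treated as optimizer
#: noise and clipped to zero; anything larger marks a failed permuted fit
NEGATIVE_DELTA_TOL = 0.05

MEASURE_PARTS = {
    "party_sri": ("party10m", "sri"),
    "occurrence": ("direct1m", "occurrence"),
    "magnitude_sri": ("direct1m", "magnitude"),
    "grooming_occurrence": ("grooming", "occurrence"),
    "grooming_magnitude": ("grooming", "magnitude"),
}


@dataclass
class PermutationResult:
    n_perm: int
    observed_delta: float
    null_deltas: np.ndarray
    p_rand: float
    n_failed: int
    seed: int
    warning: bool = False

    def __post_init__(self) -> None:
        assert len(self.null_deltas) + self.n_failed == self.n_perm


def format_p_rand(result: PermutationResult) -> str:
    """Report string; zero exceedance counts are shown as a bound, never as 0."""
    k = int(np.sum(result.observed_delta <= result.null_deltas))
    n = len(result.null_deltas)
    if k == 0:
        return f"< {1.0 / max(n, 1):.4g}"
    return f"{k / n:.4g}"


def permute_day(events: Set[Tuple[str, str]], eligible: Sequence[Tuple[str, str]], rng: np.random.Generator):
    """Uniform random reassignment of one day's events across eligible dyads.

    Returns a subset of *eligible* of the same size as *events*; identified
    sets (and hence SRI denominators) are untouched by construction.
    """
    eligible = sorted(set(eligible))
    k = len(events)
    if k > len(eligible):
        raise ValueError(f"{k} events but only {len(eligible)} eligible dyads: inconsistent data")
    if k == 0:
        return set()
    if k == len(eligible):
        return set(eligible)
    picked = rng.choice(len(eligible), size=k, replace=False)
    return {eligible[i] for i in picked}


def _permute_events_uniform(events: np.ndarray, eligible: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Array form of :func:`permute_day` over all days of a stream."""
    out = np.zeros_like(events)
    for t in range(events.shape[0]):
        k = int(events[t].sum())
        if k == 0:
            continue
        idx = np.flatnonzero(eligible[t])
        if k > len(idx):
            raise ValueError(f"day {t}: {k} events exceed {len(idx)} eligible dyads")
        out[t, rng.choice(idx, size=k, replace=False)] = True
    return out


def _permute_events_degree(
    events: np.ndarray,
    eligible: np.ndarray,
    dyad_a: np.ndarray,
    dyad_b: np.ndarray,
    pair_index: Dict[Tuple[int, int], int],
    rng: np.random.Generator,
    swaps_per_event: int = 10,
) -> np.ndarray:
    """Checkerboard-swap randomization preserving per-individual daily degree."""
    out = events.copy()
    for t in range(events.shape[0]):
        idx = np.flatnonzero(out[t])
        k = len(idx)
        if k < 2:
            continue
        idx = list(idx)
        for _ in range(swaps_per_event * k):
            e1, e2 = rng.choice(len(idx), size=2, replace=False)
            k1, k2 = idx[e1], idx[e2]
            a, b = int(dyad_a[k1]), int(dyad_b[k1])
            c, d = int(dyad_a[k2]), int(dyad_b[k2])
            if len({a, b, c, d}) < 4:
                continue
            if rng.random() < 0.5:
                p1, p2 = (min(a, d), max(a, d)), (min(c, b), max(c, b))
            else:
                p1, p2 = (min(a, c), max(a, c)), (min(b, d), max(b, d))
            j1 = pair_index.get(p1)
            j2 = pair_index.get(p2)
            if j1 is None or j2 is None or out[t, j1] or out[t, j2]:
                continue
            if not (eligible[t, j1] and eligible[t, j2]):
                continue
            out[t, k1] = out[t, k2] = False
            out[t, j1] = out[t, j2] = True
            idx[e1], idx[e2] = j1, j2
    return out


def _response_from_sri(table: pd.DataFrame, sri: np.ndarray, part: str):
    if part == "occurrence":
        return table, (sri > 0).astype(float)
    if part == "magnitude":
        mask = sri > 0
        sub = table.loc[mask].reset_index(drop=True)
        y = sri[mask]
    else:
        sub, y = table, sri
    if len(y) and (np.any(y <= 0) or np.any(y >= 1)):
        y = squeeze_unit_interval(y, len(y))
    return sub, np.asarray(y, dtype=float)


def run_permutation_test(
    records: Sequence[FocalRecord],
    roster: Sequence[Individual],
    response: str = "party_sri",
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "uniform-day",
    full_terms: Tuple[str, ...] = FULL_TERMS,
    reduced_terms: Tuple[str, ...] = REDUCED_TERMS,
    options: Optional[FitOptions] = None,
    stream: Optional[DailyStream] = None,
) -> PermutationResult:
    """Permutation p-value for dropping ``full_terms - reduced_terms``.

    The observed deviance difference is computed through the same code path
    as the permuted ones (fast, un-polished fits for both), so the observed
    statistic is exchangeable with the null draws. Non-convergent permuted
    fits are dropped and counted in ``n_failed`` (never retried, which would
    bias the null); a warning flag is raised if more than 10% fail.
    """
    if stream is None:
        stream = build_daily_stream(records, roster)
    if response not in MEASURE_PARTS:
        raise ValueError(f"unknown response {response!r}")
    measure, part = MEASURE_PARTS[response]
    family = RESPONSES[response][1]
    opts = options or FitOptions()
    opts = dc_replace(opts, polish=False)

    table = table_from_stream(stream)
    base_cols = table[["member_a", "member_b", "sex_type", "kin", "age_diff", "group_id"]]
    eligible = stream.eligible
    events = stream.events[measure]
    pair_index = {
        (int(stream.dyad_a[k]), int(stream.dyad_b[k])): k for k in range(len(stream.dyads))
    }

    spec_full = ModelSpec(response=response, fixed_terms=full_terms, family=family)
    spec_reduced = ModelSpec(response=response, fixed_terms=reduced_terms, family=family)

    # warm-start state: after the observed fit, permuted refits start their
    # outer search at the observed optimum (smaller initial simplex)
    warm: Dict[str, object] = {"theta": None}
    base_opts = dc_replace(opts, nm_ftol=max(opts.nm_ftol, 1e-8), nm_maxiter=min(opts.nm_maxiter, 150))
    warm_opts = dc_replace(base_opts, nm_step=0.15)

    if part == "magnitude":
        # the nonzero-dyad subset changes per permutation, so the design is
        # rebuilt each iteration through the general fitting path
        def delta_for_events(ev: np.ndarray) -> Tuple[float, bool]:
            sri = stream.sri(measure, ev)
            sub, y = _response_from_sri(base_cols, sri, part)
            if len(y) < len(full_terms) + 4:
                return np.nan, False
            if warm["theta"] is not None:
                o = warm_opts
                red_init = (warm["theta"], np.zeros(0))
            else:
                o = base_opts
                red_init = None
            reduced = fit_from_response(sub, y, spec_reduced, o, init=red_init)
            X_f, names_f, _ = build_design(sub, full_terms)
            beta0 = np.zeros(len(names_f))
            for j, name in enumerate(names_f):
                if name in reduced.terms:
                    beta0[j] = reduced.beta_hat[reduced.terms.index(name)]
            z_tail = reduced.design_meta["z"][len(reduced.terms):]
            init = (reduced.design_meta["theta"], np.concatenate([beta0, z_tail]))
            full = fit_from_response(sub, y, spec_full, o, init=init)
            delta = reduced.deviance - full.deviance
            ok = full.converged and reduced.converged and delta > -NEGATIVE_DELTA_TOL
            if warm["theta"] is None and ok:
                warm["theta"] = reduced.design_meta["theta"]
            return max(delta, 0.0), ok

    else:
        # occurrence / whole-index responses keep every dyad row: the designs
        # are permutation-invariant and built once, only y changes
        X_f, names_f, _ = build_design(base_cols, full_terms)
        X_r, names_r, _ = build_design(base_cols, reduced_terms)
        ia, ib, qa, qb, tie = _random_design(base_cols, spec_full.re_structure)
        A_f = _assemble(X_f, ia, ib, qa, qb, tie)
        A_r = _assemble(X_r, ia, ib, qa, qb, tie)
        p_f, p_r = X_f.shape[1], X_r.shape[1]
        col_map = np.array([names_f.index(nm) for nm in names_r])
        fam = core.FAM_BETA if family == "beta_logit" else core.FAM_BERNOULLI
        offset = np.zeros(len(base_cols))
        n_rows = len(base_cols)

        def _core_pair(y: np.ndarray, theta0: np.ndarray, step: float) -> Tuple[float, bool, np.ndarray]:
            # nuisance (phi, sigma) estimated once under the reduced model;
            # the full model's coefficients are then profiled at those values,
            # so each iteration costs one outer search plus one inner solve
            z0r = np.zeros(A_r.shape[1])
            theta_r, z_r, ll_r, _, conv_r, _ = core.fit_core(
                y, offset, A_r, p_r, qa, qb, fam, tie, theta0, z0r,
                opts.inner_maxit, opts.inner_tol, base_opts.nm_maxiter, base_opts.nm_ftol, step,
            )
            z0f = np.zeros(A_f.shape[1])
            z0f[col_map] = z_r[:p_r]
            z0f[p_f:] = z_r[p_r:]
            phi, prec = core._build_prec(theta_r, p_f, qa, qb, A_f.shape[1], fam, tie)
            _, _, conv_f = core._inner(y, offset, A_f, prec, z0f, fam, phi, opts.inner_maxit * 2, opts.inner_tol)
            ll_f = core._laplace_value(y, offset, A_f, prec, z0f, fam, phi, p_f)
            return 2.0 * (ll_f - ll_r), bool(conv_r and conv_f), theta_r

        def delta_for_events(ev: np.ndarray) -> Tuple[float, bool]:
            sri = stream.sri(measure, ev)
            if part == "occurrence":
                y = (sri > 0).astype(float)
            else:
                y = sri
                if np.any(y <= 0) or np.any(y >= 1):
                    y = squeeze_unit_interval(y, n_rows)
            y = np.ascontiguousarray(y)
            if warm["theta"] is not None:
                delta, ok, theta_r = _core_pair(y, warm["theta"], 0.15)
            else:
                delta, ok, theta_r = _core_pair(y, _initial_theta(y, family, qa, qb, tie), base_opts.nm_step)
            if not ok:  # one deterministic cold restart with a wider simplex
                delta2, ok2, theta_r2 = _core_pair(y, _initial_theta(y, family, qa, qb, tie), 0.6)
                if ok2:
                    delta, ok, theta_r = delta2, ok2, theta_r2
            ok = ok and delta > -NEGATIVE_DELTA_TOL
            if warm["theta"] is None and ok:
                warm["theta"] = theta_r
            return max(delta, 0.0), ok

    observed_delta, obs_ok = delta_for_events(events)
    if not obs_ok:
        logger.warning("observed-data fits flagged non-converged in permutation test for %s", response)

    rng = np.random.default_rng(seed)
    null_deltas: List[float] = []
    n_failed = 0
    for _ in range(n_perm):
        if scheme == "uniform-day":
            ev = _permute_events_uniform(events, eligible, rng)
        elif scheme == "degree-preserving":
            ev = _permute_events_degree(events, eligible, stream.dyad_a, stream.dyad_b, pair_index, rng)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        delta, ok = delta_for_events(ev)
        if ok:
            null_deltas.append(delta)
        else:
            n_failed += 1
    null_arr = np.array(null_deltas)
    p_rand = float(np.mean(observed_delta <= null_arr)) if len(null_arr) else np.nan
    warn = n_failed > 0.1 * n_perm
    if warn:
        logger.warning("permutation test for %s: %d/%d permuted fits failed", response, n_failed, n_perm)
    return PermutationResult(
        n_perm=n_perm,
        observed_delta=float(observed_delta),
        null_deltas=null_arr,
        p_rand=p_rand,
        n_failed=n_failed,
        seed=seed,
        warning=warn,
    )
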