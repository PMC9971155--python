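"""Compiled numerics for mixed beta/binomial regression with logit link.

The marginal likelihood integrates the random intercepts out with a Laplace
approximation: an inner penalized Fisher-scoring solve locates the joint mode
of the latent effects (and, during fitting, the fixed effects with them), and
the Gaussian curvature correction uses the exact observed Hessian of the
conditional log-likelihood. The outer dispersion/variance parameters are
optimized by Nelder-Mead. Everything here is numba-compiled because the
datastream permutation test refits both models thousands of times.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

FAM_BETA = 0
FAM_BERNOULLI = 1

# clamp bounds for outer parameters (log phi, log sigma)
_LOGPHI_LO, _LOGPHI_HI = -3.0, 9.0
_LOGSIG_LO, _LOGSIG_HI = -6.0, 3.0


@njit(cache=True)
def _digamma(x):
    r = 0.0
    while x < 6.0:
        r -= 1.0 / x
        x += 1.0
    f = 1.0 / (x * x)
    return r + math.log(x) - 0.5 / x - f * (
        1.0 / 12.0 - f * (1.0 / 120.0 - f * (1.0 / 252.0 - f / 240.0))
    )


@njit(cache=True)
def _trigamma(x):
    r = 0.0
    while x < 6.0:
        r += 1.0 / (x * x)
        x += 1.0
    f = 1.0 / (x * x)
    return r + 1.0 / x + 0.5 * f + (1.0 / x) * f * (
        1.0 / 6.0 - f * (1.0 / 30.0 - f * (1.0 / 42.0 - f / 30.0))
    )


@njit(cache=True)
def _derivs(fam, y, eta, phi, exact):
    """Conditional log-likelihood, d l/d eta, and w = -d2 l/d eta2.

    With ``exact`` False, w is the expected (Fisher) information, which is
    strictly positive and keeps the inner Newton steps stable; with True,
    the observed curvature (floored at a tiny positive value) used for the
    Laplace determinant.
    """
    n = y.shape[0]
    ll = 0.0
    dl = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        e = eta[i]
        if e > 35.0:
            e = 35.0
        elif e < -35.0:
            e = -35.0
        mu = 1.0 / (1.0 + math.exp(-e))
        if fam == FAM_BERNOULLI:
            ll += y[i] * e - math.log(1.0 + math.exp(e)) if e < 30.0 else y[i] * e - e
            dl[i] = y[i] - mu
            w[i] = mu * (1.0 - mu) + 1e-12
        else:
            if mu < 1e-12:
                mu = 1e-12
            elif mu > 1.0 - 1e-12:
                mu = 1.0 - 1e-12
            a = mu * phi
            b = (1.0 - mu) * phi
            yi = y[i]
            ll += (
                math.lgamma(phi)
                - math.lgamma(a)
                - math.lgamma(b)
                + (a - 1.0) * math.log(yi)
                + (b - 1.0) * math.log(1.0 - yi)
            )
            ystar = math.log(yi / (1.0 - yi))
            mustar = _digamma(a) - _digamma(b)
            dmu = mu * (1.0 - mu)
            dl[i] = phi * (ystar - mustar) * dmu
            we = phi * phi * (_trigamma(a) + _trigamma(b)) * dmu * dmu
            if exact:
                wi = we - phi * (ystar - mustar) * (1.0 - 2.0 * mu) * dmu
                if wi < 1e-10:
                    wi = 1e-10
                w[i] = wi
            else:
                w[i] = we + 1e-12
    return ll, dl, w


@njit(cache=True)
def _penalized(fam, y, offset, A, prec, z, phi, exact):
    eta = offset + A @ z
    ll, dl, w = _derivs(fam, y, eta, phi, exact)
    lpen = ll
    for k in range(z.shape[0]):
        lpen -= 0.5 * prec[k] * z[k] * z[k]
    return lpen, dl, w


@njit(cache=True)
def _inner(y, offset, A, prec, z, fam, phi, maxit, tol):
    """Penalized Newton solve for z (fixed + latent effects), in place.

    The first step uses the expected (Fisher) information for stability, then
    the exact observed Hessian (floored positive) for quadratic convergence.
    Returns (penalized loglik, max-abs gradient, converged flag).
    """
    n, m = A.shape
    lpen, dl, w = _penalized(fam, y, offset, A, prec, z, phi, False)
    gnorm = 1e30
    ok = False
    for it in range(maxit):
        g = A.T @ dl
        gnorm = 0.0
        for k in range(m):
            g[k] -= prec[k] * z[k]
            if abs(g[k]) > gnorm:
                gnorm = abs(g[k])
        if gnorm < 1e-6:
            ok = True
            break
        H = (A * w.reshape(n, 1)).T @ A
        for k in range(m):
            H[k, k] += prec[k] + 1e-10
        step = np.linalg.solve(H, g)
        t = 1.0
        accepted = False
        improve = 0.0
        for _ls in range(40):
            zn = z + t * step
            lpn, dln, wn = _penalized(fam, y, offset, A, prec, zn, phi, True)
            if lpn >= lpen - 1e-13:
                improve = lpn - lpen
                for k in range(m):
                    z[k] = zn[k]
                dl = dln
                w = wn
                lpen = lpn
                accepted = True
                break
            t *= 0.5
        if not accepted:
            ok = gnorm < 1e-3  # stuck at numerical precision
            break
        if improve < tol * (abs(lpen) + 1.0):
            g2 = A.T @ dl
            gnorm = 0.0
            for k in range(m):
                g2[k] -= prec[k] * z[k]
                if abs(g2[k]) > gnorm:
                    gnorm = abs(g2[k])
            ok = gnorm < 1e-4
            break
    return lpen, gnorm, ok


@njit(cache=True)
def _laplace_value(y, offset, A, prec, z, fam, phi, p):
    """Laplace log marginal likelihood, with z at the (joint) mode.

    The curvature correction is taken over the latent block only (columns
    ``p:``); with no latent columns this is the plain log-likelihood.
    """
    n, m = A.shape
    eta = offset + A @ z
    ll, dl, w = _derivs(fam, y, eta, phi, True)
    lpen = ll
    for k in range(m):
        lpen -= 0.5 * prec[k] * z[k] * z[k]
    q = m - p
    if q == 0:
        return lpen
    Au = np.ascontiguousarray(A[:, p:])
    Hu = (Au * w.reshape(n, 1)).T @ Au
    sumlog = 0.0
    for k in range(q):
        Hu[k, k] += prec[p + k]
        sumlog += math.log(prec[p + k])
    L = np.linalg.cholesky(Hu)
    logdet = 0.0
    for k in range(q):
        logdet += math.log(L[k, k])
    logdet *= 2.0
    return lpen + 0.5 * sumlog - 0.5 * logdet


@njit(cache=True)
def _build_prec(theta, p, qa, qb, m, fam, tie):
    """Map outer parameters onto (phi, prior precision vector)."""
    idx = 0
    phi = 1.0
    if fam == FAM_BETA:
        lp = theta[0]
        if lp > _LOGPHI_HI:
            lp = _LOGPHI_HI
        elif lp < _LOGPHI_LO:
            lp = _LOGPHI_LO
        phi = math.exp(lp)
        idx = 1
    prec = np.zeros(m)
    if qa > 0:
        sa = theta[idx]
        if sa > _LOGSIG_HI:
            sa = _LOGSIG_HI
        elif sa < _LOGSIG_LO:
            sa = _LOGSIG_LO
        pa = math.exp(-2.0 * sa)
        for k in range(p, p + qa):
            prec[k] = pa
        if qb > 0:
            if tie:
                sb = sa
            else:
                sb = theta[idx + 1]
                if sb > _LOGSIG_HI:
                    sb = _LOGSIG_HI
                elif sb < _LOGSIG_LO:
                    sb = _LOGSIG_LO
            pb = math.exp(-2.0 * sb)
            for k in range(p + qa, m):
                prec[k] = pb
    return phi, prec


@njit(cache=True)
def _objective(theta, y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol):
    """Negative Laplace log-likelihood at outer parameters theta; z warm in place."""
    phi, prec = _build_prec(theta, p, qa, qb, A.shape[1], fam, tie)
    lpen, gnorm, ok = _inner(y, offset, A, prec, z, fam, phi, inner_maxit, inner_tol)
    ll = _laplace_value(y, offset, A, prec, z, fam, phi, p)
    if not ok:
        ll -= 0.0  # non-convergence is reported by the caller via gradient check
    return -ll


@njit(cache=True)
def fit_core(y, offset, A, p, qa, qb, fam, tie, theta0, z0, inner_maxit, inner_tol, nm_maxiter, nm_ftol, nm_step):
    """Maximize the Laplace marginal likelihood; Nelder-Mead over theta.

    Returns (theta_hat, z_hat, loglik, inner gradient norm, converged flag,
    nm spread). The fixed effects live in the first ``p`` columns of ``A``
    and are profiled inside the inner solve.
    """
    m = A.shape[1]
    z = z0.copy()
    d = theta0.shape[0]
    if d == 0:
        phi, prec = _build_prec(theta0, p, qa, qb, m, fam, tie)
        lpen, gnorm, ok = _inner(y, offset, A, prec, z, fam, phi, inner_maxit, inner_tol)
        ll = _laplace_value(y, offset, A, prec, z, fam, phi, p)
        return theta0.copy(), z, ll, gnorm, ok, 0.0

    pts = np.empty((d + 1, d))
    fv = np.empty(d + 1)
    pts[0] = theta0
    fv[0] = _objective(theta0, y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol)
    for i in range(d):
        pt = theta0.copy()
        pt[i] += nm_step
        pts[i + 1] = pt
        fv[i + 1] = _objective(pt, y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol)

    spread = 1e30
    for _it in range(nm_maxiter):
        order = np.argsort(fv)
        pts = pts[order]
        fv = fv[order]
        spread = fv[d] - fv[0]
        if spread < nm_ftol * (abs(fv[0]) + 1e-8):
            break
        centroid = np.zeros(d)
        for i in range(d):
            centroid += pts[i]
        centroid /= d
        xr = centroid + (centroid - pts[d])
        fr = _objective(xr, y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol)
        if fr < fv[0]:
            xe = centroid + 2.0 * (centroid - pts[d])
            fe = _objective(xe, y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol)
            if fe < fr:
                pts[d] = xe
                fv[d] = fe
            else:
                pts[d] = xr
                fv[d] = fr
        elif fr < fv[d - 1]:
            pts[d] = xr
            fv[d] = fr
        else:
            xc = centroid + 0.5 * (pts[d] - centroid)
            fc = _objective(xc, y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol)
            if fc < fv[d]:
                pts[d] = xc
                fv[d] = fc
            else:
                for i in range(1, d + 1):
                    pts[i] = pts[0] + 0.5 * (pts[i] - pts[0])
                    fv[i] = _objective(pts[i], y, offset, A, p, qa, qb, fam, tie, z, inner_maxit, inner_tol)

    order = np.argsort(fv)
    pts = pts[order]
    fv = fv[order]
    theta = pts[0].copy()
    # final solve at the best point so z sits at its mode
    phi, prec = _build_prec(theta, p, qa, qb, m, fam, tie)
    lpen, gnorm, ok = _inner(y, offset, A, prec, z, fam, phi, inner_maxit * 2, inner_tol)
    ll = _laplace_value(y, offset, A, prec, z, fam, phi, p)
    converged = ok and (spread < 1e-6 * (abs(fv[0]) + 1e-8) or spread < 1e-6)
    return theta, z, ll, gnorm, converged, spread


@njit(cache=True)
def full_hessian(y, offset, A, prec, z, fam, phi):
    """Exact negative Hessian of the joint penalized log-likelihood at z."""
    n, m = A.shape
    eta = offset + A @ z
    ll, dl, w = _derivs(fam, y, eta, phi, True)
    H = (A * w.reshape(n, 1)).T @ A
    for k in range(m):
        H[k, k] += prec[k]
    return H
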