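"""Numba core for restricted pseudo-likelihood (REPL) fitting.

The random-intercept logistic GLMM is linearised at the current predictions
(Wolfinger-O'Connell subject-specific expansion): with cluster totals y_c
out of m_c and conditional mean mu_c = expit(eta_c),

    pseudo-response (cluster mean)  zbar_c = eta_c + (y_c/m_c - mu_c)/w_c
    working weight per individual   w_c    = mu_c (1 - mu_c)

and the linear mixed model  z_ik = beta0 + beta1 x_c + u_c + e_ik with
Var(e_ik) = phi / w_c, Var(u_c) = sigma_b2 is fitted by REML.  Because the
working weights are constant within a cluster, the REML criterion depends
on the data only through the cluster means zbar_c, the cluster information
W_c = m_c w_c and the pooled within-cluster weighted sum of squares
SSW = sum_c y_c (m_c - y_c) / (m_c w_c).  Writing gamma = sigma_b2/phi and
Wt_c = W_c / (1 + gamma W_c) (the precision of zbar_c on the phi scale),
the profiled criterion (constants dropped) is

    crit(gamma) = (N - 2) log Q(gamma) + sum_c log(1 + gamma W_c)
                  + log sum_{c in arm0} Wt_c + log sum_{c in arm1} Wt_c

with Q = SSW + sum_c Wt_c (zbar_c - x_c' betahat(gamma))^2 and betahat the
weighted arm means; phihat = Q/(N-2) and sigma_b2hat = gamma * phihat.
The 1-D minimisation uses a log-spaced grid (plus the gamma = 0 boundary)
refined by golden-section search; the linearisation is iterated to joint
convergence of (beta, sigma_b2).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLD = 0.6180339887498949


@njit(cache=True)
def _crit(gamma, W, zbar, n0, SSW, Nm2):
    """Profiled REML criterion; returns (crit, b0, b1, phi, sw0, sw1)."""
    n = W.shape[0]
    sw0 = 0.0
    sw1 = 0.0
    sz0 = 0.0
    sz1 = 0.0
    slog = 0.0
    for c in range(n):
        gw = gamma * W[c]
        wt = W[c] / (1.0 + gw)
        slog += np.log1p(gw)
        if c < n0:
            sw0 += wt
            sz0 += wt * zbar[c]
        else:
            sw1 += wt
            sz1 += wt * zbar[c]
    mu0 = sz0 / sw0
    mu1 = sz1 / sw1
    q = SSW
    for c in range(n):
        wt = W[c] / (1.0 + gamma * W[c])
        fit = mu0 if c < n0 else mu1
        d = zbar[c] - fit
        q += wt * d * d
    crit = Nm2 * np.log(q) + slog + np.log(sw0) + np.log(sw1)
    return crit, mu0, mu1 - mu0, q / Nm2, sw0, sw1


@njit(cache=True)
def _reml_profile(W, zbar, n0, SSW, Nm2, g_lo, g_hi, n_grid):
    """Minimise the profiled criterion over gamma in {0} U [g_lo, g_hi].

    Log-spaced grid scan followed by golden-section refinement between the
    best point's neighbours.
    """
    best_g = 0.0
    best_c, b0, b1, phi, sw0, sw1 = _crit(0.0, W, zbar, n0, SSW, Nm2)
    lt_lo = np.log(g_lo)
    lt_hi = np.log(g_hi)
    step = (lt_hi - lt_lo) / (n_grid - 1)
    best_i = -1  # -1 encodes the zero boundary
    for i in range(n_grid):
        g = np.exp(lt_lo + step * i)
        c, _, _, _, _, _ = _crit(g, W, zbar, n0, SSW, Nm2)
        if c < best_c:
            best_c = c
            best_i = i
            best_g = g
    if best_i >= 0:
        # golden-section on log gamma between the neighbouring grid points
        a = lt_lo + step * (best_i - 1) if best_i > 0 else np.log(g_lo) - step
        b = lt_lo + step * (best_i + 1) if best_i < n_grid - 1 else lt_hi + step
        x1 = b - _GOLD * (b - a)
        x2 = a + _GOLD * (b - a)
        f1, _, _, _, _, _ = _crit(np.exp(x1), W, zbar, n0, SSW, Nm2)
        f2, _, _, _, _, _ = _crit(np.exp(x2), W, zbar, n0, SSW, Nm2)
        for _ in range(30):
            if f1 < f2:
                b = x2
                x2 = x1
                f2 = f1
                x1 = b - _GOLD * (b - a)
                f1, _, _, _, _, _ = _crit(np.exp(x1), W, zbar, n0, SSW, Nm2)
            else:
                a = x1
                x1 = x2
                f1 = f2
                x2 = a + _GOLD * (b - a)
                f2, _, _, _, _, _ = _crit(np.exp(x2), W, zbar, n0, SSW, Nm2)
        g = np.exp(0.5 * (a + b))
        c, cb0, cb1, cphi, csw0, csw1 = _crit(g, W, zbar, n0, SSW, Nm2)
        if c < best_c:
            best_c, best_g = c, g
    c, b0, b1, phi, sw0, sw1 = _crit(best_g, W, zbar, n0, SSW, Nm2)
    return best_g, b0, b1, phi, sw0, sw1


@njit(cache=True)
def repl_batch(y, m, n0, max_iter, tol, var_floor,
               est0, est1, se1, sig2, phi_out, conv, n_iter, zbar_out, w_out):
    """Fit REPL to a batch of trials; one row of y/m per repetition.

    Writes per-repetition: intercept, log OR, its SE, sigma_b2 estimate,
    convergence flag, iteration count, and the converged pseudo-data
    (cluster-mean pseudo-response and working weight) for downstream
    degrees-of-freedom computations.
    """
    reps, n = y.shape
    for r in range(reps):
        yr = y[r]
        mr = m[r]
        n_tot = 0.0
        for c in range(n):
            n_tot += mr[c]
        nm2 = n_tot - 2.0

        eta = np.empty(n)
        mu = np.empty(n)
        for c in range(n):
            p = (yr[c] + 0.5) / (mr[c] + 1.0)
            mu[c] = p
            eta[c] = np.log(p / (1.0 - p))

        W = np.empty(n)
        zbar = np.empty(n)
        b0 = 0.0
        b1 = 0.0
        gamma = 0.0
        phi = 1.0
        sw0 = 1.0
        sw1 = 1.0
        sig = 0.0
        ok = False
        it = 0
        pb0 = np.inf
        pb1 = np.inf
        psig = np.inf
        for it in range(1, max_iter + 1):
            ssw = 0.0
            for c in range(n):
                mc = mu[c]
                if mc < 1e-10:
                    mc = 1e-10
                if mc > 1.0 - 1e-10:
                    mc = 1.0 - 1e-10
                w = mc * (1.0 - mc)
                W[c] = mr[c] * w
                zbar[c] = eta[c] + (yr[c] / mr[c] - mc) / w
                ssw += yr[c] * (mr[c] - yr[c]) / (mr[c] * w)
            if it == 1:
                g_lo, g_hi, ngrid = 1e-8, 1e3, 45
            else:
                g_ref = gamma if gamma > 1e-8 else 1e-6
                g_lo = g_ref / 100.0
                g_hi = g_ref * 100.0
                ngrid = 17
            gamma, b0, b1, phi, sw0, sw1 = _reml_profile(
                W, zbar, n0, ssw, nm2, g_lo, g_hi, ngrid
            )
            sig = gamma * phi
            if sig < var_floor:
                sig = 0.0
                gamma = 0.0
            # BLUP update of the linear predictor
            for c in range(n):
                wt = W[c] / (1.0 + gamma * W[c])
                fit = b0 if c < n0 else b0 + b1
                eta[c] = fit + gamma * wt * (zbar[c] - fit)
                if eta[c] > 35.0:
                    eta[c] = 35.0
                if eta[c] < -35.0:
                    eta[c] = -35.0
                mu[c] = 1.0 / (1.0 + np.exp(-eta[c]))
            d0 = abs(b0 - pb0) / (1.0 + abs(b0))
            d1 = abs(b1 - pb1) / (1.0 + abs(b1))
            d2 = abs(sig - psig) / (1.0 + abs(sig))
            if d0 < tol and d1 < tol and d2 < tol:
                ok = True
                break
            pb0, pb1, psig = b0, b1, sig
        if not (np.isfinite(b0) and np.isfinite(b1) and np.isfinite(sig)):
            ok = False
        est0[r] = b0
        est1[r] = b1
        var1 = phi * (1.0 / sw0 + 1.0 / sw1)
        se1[r] = np.sqrt(var1) if var1 > 0 else np.nan
        sig2[r] = sig
        phi_out[r] = phi
        conv[r] = ok
        n_iter[r] = it
        for c in range(n):
            zbar_out[r, c] = zbar[c]
            w_out[r, c] = W[c]


def fit_repl_arrays(y: np.ndarray, m: np.ndarray, n0: int,
                    max_iter: int = 100, tol: float = 1e-8,
                    var_floor: float = 1e-12):
    """Driver: fit REPL to (reps, n) arrays of events/sizes.

    Clusters must be ordered control-first (``n0`` control clusters).
    Returns a dict of per-repetition arrays.
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    m = np.ascontiguousarray(m, dtype=np.float64)
    reps, n = y.shape
    est0 = np.empty(reps)
    est1 = np.empty(reps)
    se1 = np.empty(reps)
    sig2 = np.empty(reps)
    phi = np.empty(reps)
    conv = np.zeros(reps, dtype=np.bool_)
    n_iter = np.zeros(reps, dtype=np.int64)
    zbar = np.empty((reps, n))
    w = np.empty((reps, n))
    repl_batch(y, m, n0, max_iter, tol, var_floor,
               est0, est1, se1, sig2, phi, conv, n_iter, zbar, w)
    return {
        "beta0": est0,
        "beta1": est1,
        "se": se1,
        "sigma_b2": sig2,
        "phi": phi,
        "converged": conv,
        "iterations": n_iter,
        "zbar": zbar,
        "W": w,
    }
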