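"""Vectorised batch analyzers for the Monte-Carlo engine.

Each analyzer maps a batch of simulated trials — ``arm`` (n,), ``sizes``
and ``events`` (reps, n), control clusters first — to per-repetition
arrays (estimate, se, df, p, converged).  The fast paths (cluster-level
tests, GEE with independence working correlation, REPL) are fully
vectorised or numba-compiled; the remaining methods fall back to the
single-fit APIs.  A test suite pins every batch analyzer to its
single-dataset counterpart.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import gee, glmm
from ._repl import fit_repl_arrays
from .errors import ConfigurationError
from .trial_data import TrialDataset

__all__ = ["METHODS", "analyse_batch"]


def _package(est, se, df, conv):
    est = np.asarray(est, dtype=np.float64)
    se = np.asarray(se, dtype=np.float64)
    conv = np.asarray(conv, dtype=bool) & np.isfinite(est) & np.isfinite(se) & (se > 0)
    p = np.full_like(est, np.nan)
    tcrit = stats.t.ppf(0.975, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(conv, est / np.where(se > 0, se, np.nan), np.nan)
    p[conv] = 2.0 * stats.t.sf(np.abs(tstat[conv]), df)
    return {
        "estimate": est,
        "se": se,
        "df": np.full_like(est, float(df)),
        "p": p,
        "ci_low": est - tcrit * se,
        "ci_high": est + tcrit * se,
        "converged": conv,
    }


def _cl_unweighted(arm, sizes, events):
    n0 = int(np.sum(arm == 0))
    n = arm.size
    s = np.log((events + 0.5) / (sizes - events + 0.5))
    s0, s1 = s[:, :n0], s[:, n0:]
    est = s1.mean(axis=1) - s0.mean(axis=1)
    ss = ((s0 - s0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (s1 - s1.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n - 2
    sp2 = ss / df
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / (n - n0)))
    return _package(est, se, df, sp2 > 0)


def _cl_weighted(arm, sizes, events):
    n0 = int(np.sum(arm == 0))
    n = arm.size
    m = sizes.astype(np.float64)
    y = events.astype(np.float64)
    s = np.log((y + 0.5) / (m - y + 0.5))
    s0, s1 = s[:, :n0], s[:, n0:]
    pooled_var = (
        ((s0 - s0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((s1 - s1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (n - 2)
    ptilde = (y + 0.5) / (m + 1.0)
    within = (1.0 / (m * ptilde * (1.0 - ptilde))).mean(axis=1)
    sig = np.maximum(0.0, pooled_var - within)
    pbar = (y + 0.5).sum(axis=1) / (m + 1.0).sum(axis=1)
    rho = sig / (sig + 1.0 / (pbar * (1.0 - pbar)))
    rho = np.clip(rho, 0.0, 1.0 - 1e-8)
    w = m / (1.0 + (m - 1.0) * rho[:, None])
    num = np.zeros(len(s))
    means = []
    sums = []
    for sl in (slice(0, n0), slice(n0, n)):
        wa, sa = w[:, sl], s[:, sl]
        sw = wa.sum(axis=1)
        mean = (wa * sa).sum(axis=1) / sw
        num += (wa * (sa - mean[:, None]) ** 2).sum(axis=1)
        means.append(mean)
        sums.append(sw)
    est = means[1] - means[0]
    sp2 = num / (n - 2)
    se = np.sqrt(sp2 * (1.0 / sums[0] + 1.0 / sums[1]))
    return _package(est, se, n - 2, sp2 > 0)


def _gee_independence(arm, sizes, events, corrections=("none", "KC", "FG"),
                      fg_bound=0.75):
    """Closed-form GEE with independence working correlation.

    With an arm-only covariate the estimating equations are those of
    pooled logistic regression, so beta1 is the pooled-counts log odds
    ratio; all sandwich variants reduce to per-cluster scalars.
    Repetitions with separation (an arm with zero or all events) produce
    non-finite intermediates and are flagged non-converged.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return _gee_independence_impl(arm, sizes, events, corrections, fg_bound)


def _gee_independence_impl(arm, sizes, events, corrections, fg_bound):
    n0 = int(np.sum(arm == 0))
    n = arm.size
    m = sizes.astype(np.float64)
    y = events.astype(np.float64)
    m0, m1 = m[:, :n0], m[:, n0:]
    y0, y1 = y[:, :n0], y[:, n0:]
    e0, M0 = y0.sum(axis=1), m0.sum(axis=1)
    e1, M1 = y1.sum(axis=1), m1.sum(axis=1)
    sep = (e0 == 0) | (e0 == M0) | (e1 == 0) | (e1 == M1)
    p0 = e0 / M0
    p1 = e1 / M1
    est = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
    # information sums per arm: SW_i = sum of m*p(1-p) over arm i
    sw0 = M0 * p0 * (1 - p0)
    sw1 = M1 * p1 * (1 - p1)
    vm00 = 1.0 / sw0
    vm01 = -1.0 / sw0
    vm11 = 1.0 / sw0 + 1.0 / sw1
    # residual totals and leverages per cluster
    r0 = y0 - m0 * p0[:, None]
    r1 = y1 - m1 * p1[:, None]
    lev0 = m0 * (p0 * (1 - p0))[:, None] / sw0[:, None]
    lev1 = m1 * (p1 * (1 - p1))[:, None] / sw1[:, None]
    # row of V_M for beta1 contracted with x_c: arm0 -> -1/SW0, arm1 -> 1/SW1
    v0 = -vm00
    out = {}
    for corr in corrections:
        if corr == "none":
            var1 = (r0**2).sum(axis=1) / sw0**2 + (r1**2).sum(axis=1) / sw1**2
            conv = ~sep
        elif corr == "KC":
            bad = (lev0 >= 1 - 1e-12).any(axis=1) | (lev1 >= 1 - 1e-12).any(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                var1 = (r0**2 / (1 - lev0)).sum(axis=1) / sw0**2 + (
                    r1**2 / (1 - lev1)
                ).sum(axis=1) / sw1**2
            conv = ~sep & ~bad
        elif corr == "FG":
            # parameter-space adjustment: diag(W_c u x x' V_M) per cluster
            q0_0 = lev0  # arm0: q_beta0 = W/SW0, q_beta1 = 0
            a0_0 = 1.0 / np.sqrt(1.0 - np.minimum(fg_bound, q0_0))
            # arm1: q_beta0 = 0, q_beta1 = W/SW1
            q1_1 = lev1
            a1_1 = 1.0 / np.sqrt(1.0 - np.minimum(fg_bound, q1_1))
            # contraction of adjusted score with V_M row of beta1
            c0 = v0[:, None] * a0_0 * r0
            c1 = (
                -vm00[:, None] + a1_1 * (vm00[:, None] + (1.0 / sw1)[:, None])
            ) * r1
            var1 = (c0**2).sum(axis=1) + (c1**2).sum(axis=1)
            conv = ~sep
        else:  # pragma: no cover
            raise ConfigurationError(f"unknown correction {corr!r}")
        se = np.sqrt(var1)
        out[corr] = _package(est, se, n - 2, conv)
    return out


def _repl(arm, sizes, events):
    n0 = int(np.sum(arm == 0))
    n = arm.size
    out = fit_repl_arrays(events, sizes, n0)
    return _package(out["beta1"], out["se"], n - 2, out["converged"])


def _loop_single(arm, sizes, events, fn):
    """Generic slow path: apply a single-dataset analysis per repetition."""
    reps = sizes.shape[0]
    est = np.empty(reps)
    se = np.empty(reps)
    df = np.empty(reps)
    p = np.empty(reps)
    lo = np.empty(reps)
    hi = np.empty(reps)
    conv = np.zeros(reps, dtype=bool)
    for r in range(reps):
        data = TrialDataset.from_arrays(arm, events[r], sizes[r])
        res = fn(data)
        est[r], se[r], df[r], p[r] = res.estimate, res.se, res.df, res.p
        lo[r], hi[r], conv[r] = res.ci_low, res.ci_high, res.converged
    return {
        "estimate": est, "se": se, "df": df, "p": p,
        "ci_low": lo, "ci_high": hi, "converged": conv,
    }


def _repl_dof(rule):
    def fn(data):
        fit = glmm.fit_repl(data)
        dof = glmm.degrees_of_freedom(fit, rule)
        return glmm.glmm_test(fit, dof)

    return fn


def _aq_cp(data):
    fit = glmm.fit_aq(data)
    dof = glmm.degrees_of_freedom(fit, "CP")
    return glmm.glmm_test(fit, dof)


def _gee_exchangeable(correction):
    def fn(data):
        return gee.gee_analysis(data, "exchangeable", correction)

    return fn


# label -> (family, key); methods in the same family share one computation
METHODS: dict[str, tuple[str, object]] = {
    "CL-UNW": ("cl_unw", None),
    "CL-W": ("cl_w", None),
    "REPL.DF_CP": ("repl", None),
    "REPL.DF_S": ("slow", _repl_dof("S")),
    "REPL.DF_KR": ("slow", _repl_dof("KR")),
    "AQ.DF_CP": ("slow", _aq_cp),
    "GEE.I.DF_CP": ("gee_i", "none"),
    "KC.I.DF_CP": ("gee_i", "KC"),
    "FG.I.DF_CP": ("gee_i", "FG"),
    "GEE.E.DF_CP": ("slow", _gee_exchangeable("none")),
    "KC.E.DF_CP": ("slow", _gee_exchangeable("KC")),
    "FG.E.DF_CP": ("slow", _gee_exchangeable("FG")),
}


def analyse_batch(arm, sizes, events, methods) -> dict[str, dict[str, np.ndarray]]:
    """Apply the requested methods to one batch of trials.

    Methods sharing a fit family (the three independence-GEE sandwiches)
    are computed from a single pass.  Returns {label: arrays}.
    """
    unknown = [mth for mth in methods if mth not in METHODS]
    if unknown:
        raise ConfigurationError(
            f"unknown method label(s) {unknown}; valid labels: {sorted(METHODS)}"
        )
    results: dict[str, dict[str, np.ndarray]] = {}
    gee_i = [mth for mth in methods if METHODS[mth][0] == "gee_i"]
    if gee_i:
        corr = tuple(METHODS[mth][1] for mth in gee_i)
        out = _gee_independence(arm, sizes, events, corrections=corr)
        for mth in gee_i:
            results[mth] = out[METHODS[mth][1]]
    for mth in methods:
        if mth in results:
            continue
        family, key = METHODS[mth]
        if family == "cl_unw":
            results[mth] = _cl_unweighted(arm, sizes, events)
        elif family == "cl_w":
            results[mth] = _cl_weighted(arm, sizes, events)
        elif family == "repl":
            results[mth] = _repl(arm, sizes, events)
        elif family == "slow":
            results[mth] = _loop_single(arm, sizes, events, key)
    return results
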