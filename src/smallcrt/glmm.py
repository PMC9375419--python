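"""Random-intercept logistic GLMM: restricted pseudo-likelihood (REPL) and
adaptive Gauss-Hermite quadrature (AQ), with three degrees-of-freedom rules.

The model is logit Pr(y_ik = 1 | u_c) = beta0 + beta1 * arm_c + u_c with
u_c ~ N(0, sigma_b2); beta1 is a cluster-specific (conditional) log odds
ratio.  REPL iterates a linearisation of this model and fits the resulting
linear mixed model by REML (see :mod:`smallcrt._repl`); AQ maximises the
exact marginal likelihood with per-cluster adaptive quadrature.

Inference uses a t distribution.  Degrees of freedom are either
clusters-minus-parameters (CP: n - 2), Satterthwaite (delta-method on the
REML variance parameters of the converged pseudo-model), or
Kenward-Roger (adjusted covariance; the df part equals the Satterthwaite
df for this one-random-effect model).  Satterthwaite and KR are defined
only for REPL, which carries the pseudo-model state they need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp

from ._repl import fit_repl_arrays
from .errors import ConfigurationError
from .results import FitResult, t_inference
from .trial_data import TrialDataset

__all__ = [
    "GlmmControl",
    "GlmmFit",
    "PseudoModel",
    "DofResult",
    "fit_repl",
    "fit_aq",
    "marginal_loglik_aq",
    "degrees_of_freedom",
    "glmm_test",
]


@dataclass(frozen=True)
class GlmmControl:
    """Fitting controls shared by REPL and AQ."""

    max_iter: int = 100
    tol: float = 1e-8
    var_floor: float = 1e-12
    quad_points: int = 11
    fix_sigma2: float | None = None  # AQ only: hold sigma_b2 fixed


@dataclass(frozen=True)
class PseudoModel:
    """Converged linearised (pseudo-data) state of a REPL fit.

    ``zbar`` are cluster-mean pseudo-responses, ``W`` the cluster
    information weights m_c * mu_c(1 - mu_c), ``ssw`` the pooled
    within-cluster weighted sum of squares; together with (phi, sigma_b2)
    these determine the REML criterion and Var(beta1) needed for the
    Satterthwaite and Kenward-Roger corrections.
    """

    zbar: np.ndarray
    W: np.ndarray
    ssw: float
    arm: np.ndarray
    n_total: float
    phi: float
    sigma_b2: float


@dataclass(frozen=True)
class GlmmFit:
    beta0: float
    beta1: float
    sigma_b2_hat: float
    cov_beta: np.ndarray
    method: Literal["REPL", "AQ"]
    converged: bool
    iterations: int
    n_clusters: int
    pseudo_model: PseudoModel | None = field(default=None, repr=False)


@dataclass(frozen=True)
class DofResult:
    rule: Literal["CP", "S", "KR"]
    df: float
    se_used: float


def _ordered_arrays(data: TrialDataset):
    """Control clusters first (the layout the REPL kernel expects)."""
    data.require_two_arms(min_per_arm=2)
    arm = data.arm
    order = np.argsort(arm, kind="stable")
    return (
        data.events.astype(np.float64)[order],
        data.size.astype(np.float64)[order],
        arm[order],
        int(np.sum(arm == 0)),
    )


def fit_repl(data: TrialDataset, control: GlmmControl = GlmmControl()) -> GlmmFit:
    """Restricted pseudo-likelihood fit of the random-intercept model."""
    y, m, arm, n0 = _ordered_arrays(data)
    out = fit_repl_arrays(
        y[None, :], m[None, :], n0,
        max_iter=control.max_iter, tol=control.tol, var_floor=control.var_floor,
    )
    zbar = out["zbar"][0]
    W = out["W"][0]
    ssw = float(np.sum(y * (m - y) / W))
    sigma_b2 = float(out["sigma_b2"][0])
    phi = float(out["phi"][0])
    gamma = sigma_b2 / phi
    wt = W / (1.0 + gamma * W)
    sw0 = wt[arm == 0].sum()
    sw1 = wt[arm == 1].sum()
    cov = phi * np.array(
        [[1.0 / sw0, -1.0 / sw0], [-1.0 / sw0, 1.0 / sw0 + 1.0 / sw1]]
    )
    pm = PseudoModel(
        zbar=zbar, W=W, ssw=ssw, arm=arm, n_total=float(m.sum()),
        phi=phi, sigma_b2=sigma_b2,
    )
    return GlmmFit(
        beta0=float(out["beta0"][0]),
        beta1=float(out["beta1"][0]),
        sigma_b2_hat=sigma_b2,
        cov_beta=cov,
        method="REPL",
        converged=bool(out["converged"][0]),
        iterations=int(out["iterations"][0]),
        n_clusters=data.n,
        pseudo_model=pm,
    )


def _reml_m2l(phi, sigma_b2, pm: PseudoModel) -> float:
    """-2 * restricted log pseudo-likelihood (additive constants dropped)."""
    gamma = sigma_b2 / phi
    wt = pm.W / (1.0 + gamma * pm.W)
    sw0 = wt[pm.arm == 0].sum()
    sw1 = wt[pm.arm == 1].sum()
    mu0 = np.sum((wt * pm.zbar)[pm.arm == 0]) / sw0
    mu1 = np.sum((wt * pm.zbar)[pm.arm == 1]) / sw1
    fitted = np.where(pm.arm == 0, mu0, mu1)
    q = pm.ssw + float(np.sum(wt * (pm.zbar - fitted) ** 2))
    nm2 = pm.n_total - 2.0
    return (
        nm2 * math.log(phi)
        + float(np.sum(np.log1p(gamma * pm.W)))
        + q / phi
        + math.log(sw0)
        + math.log(sw1)
    )


def _var_beta1(phi, sigma_b2, pm: PseudoModel) -> float:
    gamma = sigma_b2 / phi
    wt = pm.W / (1.0 + gamma * pm.W)
    sw0 = wt[pm.arm == 0].sum()
    sw1 = wt[pm.arm == 1].sum()
    return phi * (1.0 / sw0 + 1.0 / sw1)


def _reml_info(pm: PseudoModel):
    """REML information matrix of theta = (phi, sigma_b2) by central
    finite differences of the criterion; one-sided at the sigma_b2 = 0
    boundary."""
    theta = np.array([pm.phi, pm.sigma_b2])
    h = np.array([1e-4 * (theta[0] + 1e-8), 1e-4 * (theta[1] + 1e-8)])

    def f(t):
        return _reml_m2l(max(t[0], 1e-12), max(t[1], 0.0), pm)

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    # information of -2l is Hess/2; Var(theta) = 2 * Hess^{-1}
    return hess


def _theta_cov(pm: PseudoModel) -> np.ndarray:
    hess = _reml_info(pm)
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return cov


def degrees_of_freedom(fit: GlmmFit, rule: str) -> DofResult:
    """CP, Satterthwaite, or Kenward-Roger degrees of freedom.

    Satterthwaite: df = 2 Var(beta1)^2 / Var[Var(beta1)], with
    Var[Var(beta1)] from the delta method over the REML variance
    parameters.  KR additionally replaces the SE by the square root of
    the Kenward-Roger adjusted covariance; its df equals the
    Satterthwaite df for this single-random-effect model.
    """
    rule = {"CP": "CP", "S": "S", "SATTERTHWAITE": "S", "KR": "KR"}.get(
        rule.upper(), None
    )
    if rule is None:
        raise ConfigurationError("rule must be one of 'CP', 'S', 'KR'")
    se_model = math.sqrt(float(fit.cov_beta[1, 1]))
    if rule == "CP":
        return DofResult(rule="CP", df=float(fit.n_clusters - 2), se_used=se_model)
    if fit.method != "REPL" or fit.pseudo_model is None:
        raise ConfigurationError(
            f"DF_{rule} requires a REPL fit with pseudo-model state; "
            f"got method={fit.method}"
        )
    pm = fit.pseudo_model
    theta_cov = _theta_cov(pm)
    # delta-method gradient of Var(beta1) w.r.t. (phi, sigma_b2)
    h = np.array([1e-4 * (pm.phi + 1e-8), 1e-4 * (pm.sigma_b2 + 1e-8)])
    g = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        up = _var_beta1(pm.phi + e[0], pm.sigma_b2 + e[1], pm)
        lo_t = np.array([pm.phi, pm.sigma_b2]) - e
        lo_t[1] = max(lo_t[1], 0.0)
        lo = _var_beta1(max(lo_t[0], 1e-12), lo_t[1], pm)
        g[i] = (up - lo) / (h[i] + (np.array([pm.phi, pm.sigma_b2])[i] - lo_t[i]))
    var1 = _var_beta1(pm.phi, pm.sigma_b2, pm)
    var_var = float(g @ theta_cov @ g)
    if not np.isfinite(var_var) or var_var <= 0:
        df_s = float(fit.n_clusters - 2)
    else:
        df_s = 2.0 * var1**2 / var_var
    df_s = float(np.clip(df_s, 1.0, 1e7))
    if rule == "S":
        return DofResult(rule="S", df=df_s, se_used=se_model)
    # Kenward-Roger adjusted covariance on the mean-collapsed model
    se_kr = _kr_se(pm, theta_cov)
    if not np.isfinite(se_kr):
        se_kr = se_model
    return DofResult(rule="KR", df=df_s, se_used=se_kr)


def _kr_se(pm: PseudoModel, theta_cov: np.ndarray) -> float:
    """Kenward-Roger adjusted SE of beta1.

    Works on the cluster-mean collapsed model, whose diagonal covariance
    diag(phi/W_c + sigma_b2) yields the same fixed-effect contractions as
    the individual-level pseudo-model; the covariance matrix V is linear
    in theta so the second-derivative term vanishes.
    """
    arm = pm.arm.astype(np.float64)
    X = np.column_stack([np.ones_like(arm), arm])
    v = pm.phi / pm.W + pm.sigma_b2
    vinv = 1.0 / v
    phi_mat = np.linalg.inv((X * vinv[:, None]).T @ X)
    dV = [1.0 / pm.W, np.ones_like(pm.W)]  # dV/dphi, dV/dsigma_b2 (diagonals)
    P = []
    Q = {}
    for i in range(2):
        P.append((X * (vinv * dV[i] * vinv)[:, None]).T @ X)
    for i in range(2):
        for j in range(2):
            Q[(i, j)] = (X * (vinv * dV[i] * vinv * dV[j] * vinv)[:, None]).T @ X
    lam = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            lam += theta_cov[i, j] * (Q[(i, j)] - P[i] @ phi_mat @ P[j])
    phi_adj = phi_mat + 2.0 * phi_mat @ lam @ phi_mat
    var1 = float(phi_adj[1, 1])
    return math.sqrt(var1) if var1 > 0 else float("nan")


def glmm_test(fit: GlmmFit, dof: DofResult) -> FitResult:
    """t test of the arm effect using the chosen df rule."""
    label = f"{fit.method}.DF_{dof.rule}"
    return t_inference(label, fit.beta1, dof.se_used, dof.df, fit.converged)


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite quadrature


def marginal_loglik_aq(
    beta0: float,
    beta1: float,
    sigma_b2: float,
    data: TrialDataset,
    quad_points: int = 11,
) -> float:
    """Marginal log-likelihood by per-cluster adaptive Gauss-Hermite
    quadrature (nodes centred at each cluster's conditional mode and
    scaled by its curvature).  With one quadrature point this is the
    Laplace approximation."""
    y = data.events.astype(np.float64)
    m = data.size.astype(np.float64)
    x = data.arm.astype(np.float64)
    eta0 = beta0 + beta1 * x
    const = gammaln(m + 1) - gammaln(y + 1) - gammaln(m - y + 1)
    if sigma_b2 <= 1e-12:
        eta = np.clip(eta0, -35, 35)
        return float(
            np.sum(const + y * eta - m * np.log1p(np.exp(eta)))
        )
    nodes, weights = hermgauss(quad_points)
    sigma2 = sigma_b2

    # conditional mode per cluster by Newton on
    # g(u) = y(eta+u) - m log(1+e^(eta+u)) - u^2/(2 sigma2)
    u = np.zeros_like(y)
    for _ in range(50):
        mu = expit(eta0 + u)
        grad = y - m * mu - u / sigma2
        hess = -m * mu * (1 - mu) - 1.0 / sigma2
        step = grad / hess
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = expit(eta0 + u)
    tau = 1.0 / np.sqrt(m * mu * (1 - mu) + 1.0 / sigma2)

    # integrand at shifted/scaled nodes, log-sum-exp across nodes
    uk = u[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]
    etak = np.clip(eta0[:, None] + uk, -35, 35)
    logf = (
        y[:, None] * etak
        - m[:, None] * np.log1p(np.exp(etak))
        - 0.5 * uk**2 / sigma2
        - 0.5 * math.log(2 * math.pi * sigma2)
    )
    lse = logsumexp(logf + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1)
    ll = const + 0.5 * math.log(2.0) + np.log(tau) + lse
    return float(np.sum(ll))


def fit_aq(data: TrialDataset, control: GlmmControl = GlmmControl()) -> GlmmFit:
    """Maximise the AQ marginal likelihood over (beta0, beta1, log sigma_b2).

    The variance is optimised on the log scale with a floor; a boundary
    solution is returned (not errored) with sigma_b2_hat ~ 0.  The
    fixed-effect covariance is the corresponding block of the inverse
    observed information (numerical Hessian of the marginal
    log-likelihood).
    """
    data.require_two_arms(min_per_arm=2)
    y = data.events.astype(np.float64)
    m = data.size.astype(np.float64)
    arm = data.arm
    e0, m0 = y[arm == 0].sum(), m[arm == 0].sum()
    e1, m1 = y[arm == 1].sum(), m[arm == 1].sum()
    b0_init = math.log((e0 + 0.5) / (m0 - e0 + 0.5))
    b1_init = math.log((e1 + 0.5) / (m1 - e1 + 0.5)) - b0_init
    q = control.quad_points

    if control.fix_sigma2 is not None:
        sig_fixed = float(control.fix_sigma2)

        def nll_b(b):
            return -marginal_loglik_aq(b[0], b[1], sig_fixed, data, q)

        res = optimize.minimize(nll_b, [b0_init, b1_init], method="BFGS")
        cov = _num_hess_inv(nll_b, res.x)
        return GlmmFit(
            beta0=float(res.x[0]), beta1=float(res.x[1]),
            sigma_b2_hat=sig_fixed, cov_beta=cov, method="AQ",
            converged=bool(res.success), iterations=int(res.nit),
            n_clusters=data.n, pseudo_model=None,
        )

    t_lo, t_hi = math.log(control.var_floor), math.log(50.0)

    def nll(theta):
        return -marginal_loglik_aq(
            theta[0], theta[1], math.exp(theta[2]), data, q
        )

    x0 = np.array([b0_init, b1_init, math.log(max(0.05, control.var_floor * 10))])
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B",
        bounds=[(-30, 30), (-30, 30), (t_lo, t_hi)],
    )
    b0, b1, t = res.x
    sigma_b2 = math.exp(t)
    at_floor = t <= t_lo + 1e-6
    if at_floor:
        sigma_b2 = 0.0

        def nll_b(b):
            return -marginal_loglik_aq(b[0], b[1], 0.0, data, q)

        cov = _num_hess_inv(nll_b, np.array([b0, b1]))
    else:
        hess = _num_hess(nll, res.x)
        try:
            cov_full = np.linalg.inv(hess)
            cov = cov_full[:2, :2]
            if cov[0, 0] <= 0 or cov[1, 1] <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov = _num_hess_inv(lambda b: nll(np.array([b[0], b[1], t])), res.x[:2])
    return GlmmFit(
        beta0=float(b0), beta1=float(b1), sigma_b2_hat=float(sigma_b2),
        cov_beta=cov, method="AQ", converged=bool(res.success),
        iterations=int(res.nit), n_clusters=data.n, pseudo_model=None,
    )


def _num_hess(f, x, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    k = len(x)
    h = rel_step * (np.abs(x) + 1.0)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return hess


def _num_hess_inv(f, x) -> np.ndarray:
    hess = _num_hess(f, x)
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.full((len(x), len(x)), np.nan)
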