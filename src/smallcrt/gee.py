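"""Logistic GEE with independence/exchangeable working correlation and
small-sample sandwich corrections (Kauermann-Carroll, Fay-Graubard).

The marginal model is logit E[y | X] = beta0 + beta1 * arm.  Because the
only covariate is cluster-constant and the working covariance within a
cluster is compound-symmetric, every per-cluster matrix quantity in the
estimating equations and in the sandwich estimators collapses to a scalar
(rank-one structure): no m x m matrix is ever materialised, so clusters of
size 1000 cost the same as clusters of size 5.

Collapsed identities used throughout (per cluster of size m, working
correlation alpha, mu the fitted marginal probability, w = mu(1-mu),
W = m*w, u = 1/(1 + (m-1)*alpha), R = events - m*mu, x = (1, arm)'):

* quasi-score contribution      D'V_W^{-1}(y - mu)          = x u R
* information contribution      D'V_W^{-1}D                 = x x' W u
* KC cluster leverage           tr part of D V_M D' V_W^{-1} -> l = W u x'V_M x
* KC-adjusted score             D'V_W^{-1}A_KC(y - mu)      = x u R (1-l)^{-1/2}
* FG parameter-space adjustment diag of (D'V_W^{-1}D)V_M    = diag(W u x x' V_M)

The scale parameter is fixed at 1: it cancels identically in all sandwich
estimators and cluster leverages, so inference is unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError, NumericalError
from .results import FitResult, t_inference
from .trial_data import TrialDataset

__all__ = ["GeeFit", "SandwichSpec", "fit_gee", "sandwich", "gee_test", "gee_analysis"]

_WORKINGS = ("independence", "exchangeable")
_CORRECTIONS = ("none", "KC", "FG")


@dataclass(frozen=True)
class SandwichSpec:
    """Which sandwich correction to apply.

    ``fg_bound`` is the Fay-Graubard boundary parameter b in
    (1 - min(b, .))^(-1/2); the default 0.75 is the conventional choice.
    """

    correction: Literal["none", "KC", "FG"] = "none"
    fg_bound: float = 0.75

    def __post_init__(self) -> None:
        if self.correction not in _CORRECTIONS:
            raise ConfigurationError(
                f"correction must be one of {_CORRECTIONS}, got {self.correction!r}"
            )
        if not 0.0 < self.fg_bound <= 1.0:
            raise ConfigurationError(f"fg_bound must lie in (0, 1], got {self.fg_bound}")


@dataclass
class GeeFit:
    """Converged GEE state plus per-cluster components for any sandwich."""

    beta: np.ndarray  # (intercept, log OR), population-averaged
    v_model: np.ndarray  # 2x2 model-based covariance (scale 1)
    working: str
    alpha_hat: float
    n_clusters: int
    converged: bool
    iterations: int
    alpha_truncated: bool
    # per-cluster components (arrays of length n)
    arm: np.ndarray = field(repr=False, default=None)
    size: np.ndarray = field(repr=False, default=None)
    events: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)

    @property
    def beta1(self) -> float:
        return float(self.beta[1])


def _design(arm: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(arm, dtype=np.float64), arm.astype(np.float64)])


def fit_gee(
    data: TrialDataset,
    working: str = "independence",
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> GeeFit:
    """Solve the GEE for beta by Fisher scoring on the collapsed data.

    The exchangeable working correlation is re-estimated at each iteration
    by the moment estimator on standardised Pearson residuals (bias-naive
    divisor sum m(m-1) - p).  With an arm-only covariate the independence
    estimating equations coincide with pooled logistic regression, whose
    root is the pooled-counts log odds ratio.
    """
    if working not in _WORKINGS:
        raise ConfigurationError(
            f"working must be one of {_WORKINGS}, got {working!r}"
        )
    data.require_two_arms()
    arm = data.arm
    y = data.events.astype(np.float64)
    m = data.size.astype(np.float64)
    X = _design(arm)
    n = data.n

    # continuity-corrected pooled start keeps the first step finite
    e0, m0 = y[arm == 0].sum(), m[arm == 0].sum()
    e1, m1 = y[arm == 1].sum(), m[arm == 1].sum()
    b0 = math.log((e0 + 0.5) / (m0 - e0 + 0.5))
    b1 = math.log((e1 + 0.5) / (m1 - e1 + 0.5)) - b0
    beta = np.array([b0, b1])
    # separation: an arm with zero (or all) events has no finite root
    separated = e0 in (0, m0) or e1 in (0, m1)

    alpha = 0.0
    truncated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        W = m * w
        if working == "exchangeable":
            alpha, truncated = _alpha_moment(y, m, mu, w, n_params=2)
        u = 1.0 / (1.0 + (m - 1.0) * alpha)
        R = y - m * mu
        score = X.T @ (u * R)
        info = (X * (W * u)[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.linalg.norm(score) < tol:
            converged = True
            # one final consistency pass so stored mu matches beta
            eta = np.clip(X @ beta, -30.0, 30.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            break
    if separated:
        converged = False
    if not np.all(np.isfinite(beta)):
        converged = False
        beta = np.array([b0, b1])
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))

    w = mu * (1.0 - mu)
    u = 1.0 / (1.0 + (m - 1.0) * alpha)
    info = (X * (m * w * u)[:, None]).T @ X
    v_model = np.linalg.inv(info)
    return GeeFit(
        beta=beta,
        v_model=v_model,
        working=working,
        alpha_hat=float(alpha),
        n_clusters=n,
        converged=converged,
        iterations=it,
        alpha_truncated=truncated,
        arm=arm,
        size=data.size,
        events=data.events,
        mu=mu,
    )


def _alpha_moment(y, m, mu, w, n_params: int) -> tuple[float, bool]:
    """Exchangeable correlation from standardised Pearson residuals.

    Per cluster the sum of residuals is R/sqrt(w) and the sum of squares
    is [y(1-mu)^2 + (m-y)mu^2]/w; the cross-product sum over ordered pairs
    k != l is the squared sum minus the sum of squares.
    """
    R = y - m * mu
    sum_e = R / np.sqrt(w)
    sum_e2 = (y * (1.0 - mu) ** 2 + (m - y) * mu**2) / w
    n_tot = m.sum()
    phi = sum_e2.sum() / (n_tot - n_params)
    pair_sum = np.sum(sum_e**2 - sum_e2)
    denom = np.sum(m * (m - 1.0)) - n_params
    if denom <= 0 or phi <= 0:
        return 0.0, False
    alpha = pair_sum / (phi * denom)
    m_max = m.max()
    lo = -1.0 / (m_max - 1.0) + 1e-8 if m_max > 1 else 0.0
    hi = 1.0 - 1e-8
    clipped = float(np.clip(alpha, lo, hi))
    return clipped, clipped != alpha


def sandwich(fit: GeeFit, spec: SandwichSpec = SandwichSpec()) -> np.ndarray:
    """Assemble the requested sandwich covariance from cluster components.

    Raises :class:`NumericalError` when the KC inverse square root is
    undefined (a cluster leverage >= 1); callers treat that repetition as
    non-converged for the KC method.
    """
    arm = fit.arm
    m = fit.size.astype(np.float64)
    y = fit.events.astype(np.float64)
    mu = fit.mu
    w = mu * (1.0 - mu)
    W = m * w
    u = 1.0 / (1.0 + (m - 1.0) * fit.alpha_hat)
    R = y - m * mu
    X = _design(arm)
    vm = fit.v_model

    g = X * (u * R)[:, None]  # per-cluster quasi-score contributions (n x 2)
    if spec.correction == "none":
        meat = g.T @ g
    elif spec.correction == "KC":
        lev = W * u * np.einsum("ij,jk,ik->i", X, vm, X)
        if np.any(lev >= 1.0 - 1e-12):
            raise NumericalError(
                "KC correction undefined: a cluster leverage reached 1"
            )
        gk = g / np.sqrt(1.0 - lev)[:, None]
        meat = gk.T @ gk
    else:  # FG
        # diagonal of (D'V_W^-1 D) V_M = W u * (x x' V_M) per cluster
        xxvm_diag = X * (X @ vm)  # row c, col k: x_k * (x'V_M)_k
        q = (W * u)[:, None] * xxvm_diag
        a = 1.0 / np.sqrt(1.0 - np.minimum(spec.fg_bound, q))
        ga = g * a
        meat = ga.T @ ga
    return vm @ meat @ vm


def gee_test(fit: GeeFit, cov: np.ndarray, *, correction: str = "none") -> FitResult:
    """t test of the arm effect at df = clusters - 2.

    Method labels follow the fixed vocabulary ``{GEE|KC|FG}.{I|E}.DF_CP``.
    """
    tag = {"none": "GEE", "KC": "KC", "FG": "FG"}[correction]
    wc = "I" if fit.working == "independence" else "E"
    label = f"{tag}.{wc}.DF_CP"
    df = fit.n_clusters - 2
    var1 = float(cov[1, 1])
    se = math.sqrt(var1) if var1 > 0 else float("nan")
    return t_inference(label, fit.beta1, se, df, fit.converged and var1 > 0)


def gee_analysis(
    data: TrialDataset,
    working: str = "independence",
    correction: str = "FG",
    *,
    fg_bound: float = 0.75,
) -> FitResult:
    """Fit, sandwich, and test in one call."""
    fit = fit_gee(data, working)
    spec = SandwichSpec(correction=correction, fg_bound=fg_bound)
    try:
        cov = sandwich(fit, spec)
    except NumericalError:
        fit.converged = False
        cov = fit.v_model
    return gee_test(fit, cov, correction=correction)
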