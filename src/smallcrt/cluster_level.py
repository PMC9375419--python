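"""Cluster-level (two-stage) analysis.

Each cluster is summarised by its continuity-corrected log odds

    s_c = log[(events + 0.5) / (size - events + 0.5)]

(0.5 events and 0.5 non-events added, so the summary is always finite),
and the two arms are compared with a t-test on the summaries at
df = n - 2.  The unweighted test (CL-UNW) treats every cluster equally;
the inverse-variance weighted test (CL-W) weights cluster c by the
Kerry-Bland weight m_c / (1 + (m_c - 1) * rho), with rho estimated from
the data by the method of moments under the null hypothesis of a common
prevalence in both arms.

The weighted test deliberately treats the estimated weights as known
(classical weighted least squares); the resulting understatement of the
standard error with estimated weights is a documented property of the
method, not a defect of this implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .results import FitResult, t_inference
from .trial_data import TrialDataset

__all__ = [
    "ClusterSummary",
    "CLVarianceModel",
    "cluster_log_odds",
    "cl_unweighted_test",
    "kerry_bland_weights",
    "estimate_weight_icc",
    "cl_weighted_test",
]

CL_UNWEIGHTED = "CL-UNW"
CL_WEIGHTED = "CL-W"


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: str
    arm: int
    log_odds: float
    weight: float = 1.0


@dataclass(frozen=True)
class CLVarianceModel:
    """Moment estimates behind the inverse-variance weights.

    ``sigma_b2_hat`` is the between-cluster log-odds variance,
    ``rho_hat`` the proportion-scale ICC implied by it at the pooled
    continuity-corrected prevalence ``p_bar``.
    """

    sigma_b2_hat: float
    rho_hat: float
    p_bar: float


def cluster_log_odds(events, size):
    """Continuity-corrected cluster log odds (vectorised)."""
    events = np.asarray(events, dtype=np.float64)
    size = np.asarray(size, dtype=np.float64)
    return np.log((events + 0.5) / (size - events + 0.5))


def summarise_clusters(data: TrialDataset, weights=None) -> list[ClusterSummary]:
    s = cluster_log_odds(data.events, data.size)
    w = np.ones(data.n) if weights is None else np.asarray(weights, dtype=np.float64)
    return [
        ClusterSummary(cid, int(a), float(si), float(wi))
        for cid, a, si, wi in zip(data.cluster_ids, data.arm, s, w)
    ]


def _split_arms(data: TrialDataset):
    data.require_two_arms(min_per_arm=2)
    s = cluster_log_odds(data.events, data.size)
    arm = data.arm
    return s[arm == 0], s[arm == 1]


def cl_unweighted_test(data: TrialDataset) -> FitResult:
    """Equal-variance two-sample t-test on cluster log odds, df = n - 2.

    Flagged non-converged only when the summaries are constant within
    *both* arms (zero pooled variance, the t statistic is undefined).
    """
    s0, s1 = _split_arms(data)
    n0, n1 = len(s0), len(s1)
    est = float(s1.mean() - s0.mean())
    ss = float(np.sum((s0 - s0.mean()) ** 2) + np.sum((s1 - s1.mean()) ** 2))
    df = n0 + n1 - 2
    sp2 = ss / df
    se = math.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    converged = sp2 > 0.0
    return t_inference(CL_UNWEIGHTED, est, se, df, converged)


def kerry_bland_weights(sizes, rho: float) -> np.ndarray:
    """Inverse-variance cluster weights w = m / (1 + (m - 1) * rho)."""
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError(f"rho must lie in [0, 1), got {rho}")
    m = np.asarray(sizes, dtype=np.float64)
    return m / (1.0 + (m - 1.0) * rho)


def estimate_weight_icc(data: TrialDataset) -> CLVarianceModel:
    """Method-of-moments ICC for the Kerry-Bland weights.

    The total variance of the cluster log odds is approximated (Taylor
    expansion) by sigma_b2 + E[1 / (p(1-p) m)].  Under the null the two
    arms share one ICC, so: pool the within-arm sample variances of the
    summaries to estimate the total; estimate the within-cluster term by
    the mean of 1 / (m * ptilde * (1 - ptilde)) with ptilde the
    continuity-corrected cluster proportion; subtract (truncated at 0);
    convert to a proportion-scale ICC at the pooled corrected prevalence.
    """
    s0, s1 = _split_arms(data)
    n0, n1 = len(s0), len(s1)
    pooled_var = (
        float(np.sum((s0 - s0.mean()) ** 2) + np.sum((s1 - s1.mean()) ** 2))
        / (n0 + n1 - 2)
    )
    events = data.events.astype(np.float64)
    size = data.size.astype(np.float64)
    ptilde = (events + 0.5) / (size + 1.0)
    within = float(np.mean(1.0 / (size * ptilde * (1.0 - ptilde))))
    sigma_b2 = max(0.0, pooled_var - within)
    p_bar = float((events + 0.5).sum() / (size + 1.0).sum())
    rho = sigma_b2 / (sigma_b2 + 1.0 / (p_bar * (1.0 - p_bar)))
    rho = min(max(rho, 0.0), 1.0 - 1e-8)
    return CLVarianceModel(sigma_b2_hat=sigma_b2, rho_hat=rho, p_bar=p_bar)


def cl_weighted_test(data: TrialDataset, rho: float | None = None) -> FitResult:
    """Kerry-Bland inverse-variance weighted t-test, df = n - 2.

    ``rho`` defaults to the moment estimate from
    :func:`estimate_weight_icc`. Weights are treated as known: the pooled
    weighted variance sum_arm sum_c w(s - sbar_w)^2 / (n - 2) estimates
    the per-unit-weight variance of a summary (unbiasedly when
    Var(s_c) = C / w_c), and SE = sqrt(sp2 * (1/sum w_0 + 1/sum w_1)).
    This reduces exactly to the unweighted test whenever the weights are
    constant (equal sizes, or rho -> 1).
    """
    data.require_two_arms(min_per_arm=2)
    if rho is None:
        rho = estimate_weight_icc(data).rho_hat
    s = cluster_log_odds(data.events, data.size)
    w = kerry_bland_weights(data.size, rho)
    arm = data.arm
    num = 0.0
    means = {}
    sums = {}
    for a in (0, 1):
        sa, wa = s[arm == a], w[arm == a]
        sw = wa.sum()
        mean = float(np.sum(wa * sa) / sw)
        means[a], sums[a] = mean, sw
        num += float(np.sum(wa * (sa - mean) ** 2))
    est = means[1] - means[0]
    sp2 = num / (data.n - 2)
    se = math.sqrt(sp2 * (1.0 / sums[0] + 1.0 / sums[1]))
    df = data.n - 2
    converged = sp2 > 0.0
    return t_inference(CL_WEIGHTED, est, se, df, converged)
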