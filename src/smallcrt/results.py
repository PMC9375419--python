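"""Common result contract shared by every estimator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FitResult:
    """One method applied to one trial: log-OR estimate with t inference.

    ``estimate`` is a log odds ratio (cluster-specific for cluster-level
    and GLMM methods, population-averaged for GEE). ``converged`` is False
    when the fitting procedure failed; such results are excluded from
    Monte-Carlo performance summaries.
    """

    method: str
    estimate: float
    se: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "df": self.df,
            "p": self.p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "converged": self.converged,
        }


def t_inference(
    method: str, estimate: float, se: float, df: float, converged: bool = True
) -> FitResult:
    """Build a :class:`FitResult` from a t statistic ``estimate/se``
    referred to a t distribution with ``df`` degrees of freedom."""
    if converged and se > 0 and np.isfinite(estimate) and np.isfinite(se):
        tstat = estimate / se
        p = float(2.0 * stats.t.sf(abs(tstat), df))
        tcrit = float(stats.t.ppf(0.975, df))
        lo, hi = estimate - tcrit * se, estimate + tcrit * se
    else:
        converged = False
        p = lo = hi = float("nan")
    return FitResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        df=float(df),
        p=p,
        ci_low=float(lo),
        ci_high=float(hi),
        converged=bool(converged),
    )
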