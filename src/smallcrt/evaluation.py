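"""Monte-Carlo engine: run scenario grids, compute performance measures,
classify scenarios, and convert conditional to marginal effects.

For each scenario x repetition one dataset is generated and every
requested method is applied to it (a paired design: method comparisons
share datasets).  Per scenario x method the engine reports, over the
converged repetitions only:

* standardised bias: 100 * (mean estimate - truth) / SD(estimates)
* relative SE bias:  100 * (ModSE / SD(estimates) - 1), where ModSE is
  the root-mean-square of the model-based SEs (the standard summary of
  an estimated variance in simulation studies; the arithmetic mean of
  SEs would be biased low exactly where SEs are most variable)
* type-one error or power: 100 * share of repetitions with p < 0.05
* coverage: 100 * share of CIs containing the truth

The truth is the conditional log odds ratio for cluster-level and GLMM
methods and the converted marginal log odds ratio for GEE methods.  A
null-scenario rejection rate below 3.6% is classified conservative and
above 6.4% inflated — the bounds of the 95% Monte-Carlo band for a true
5% rate estimated with 1000 repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from ._batch import METHODS, analyse_batch
from .errors import ConfigurationError
from .results import FitResult
from .simulator import Scenario, generate_trial_arrays

__all__ = [
    "FitResult",
    "PerformanceSummary",
    "CONSERVATIVE_BOUND_PCT",
    "INFLATED_BOUND_PCT",
    "marginal_truth",
    "mc_rejection_band",
    "summarise",
    "run_grid",
]

CONSERVATIVE_BOUND_PCT = 3.6
INFLATED_BOUND_PCT = 6.4

#: squared constant of the logistic conditional-to-marginal attenuation,
#: (16 * sqrt(3) / (15 * pi))^2
_ATTENUATION_C2 = (16.0 * math.sqrt(3.0) / (15.0 * math.pi)) ** 2


def marginal_truth(beta_conditional: float, sigma_b2: float) -> float:
    """Population-averaged log OR implied by a conditional log OR.

    beta_m ~= beta_c * (c^2 * sigma_b2 + 1)^(-1/2) with
    c = 16*sqrt(3)/(15*pi); the marginal effect is attenuated toward zero
    as the between-cluster variance grows.
    """
    if sigma_b2 < 0:
        raise ConfigurationError(f"sigma_b2 must be >= 0, got {sigma_b2}")
    return beta_conditional / math.sqrt(_ATTENUATION_C2 * sigma_b2 + 1.0)


def mc_rejection_band(
    rate: float = 0.05, reps: int = 1000, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation Monte-Carlo band (in %) for an estimated
    rejection rate, e.g. (3.6, 6.4) for 5% at 1000 repetitions."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(rate * (1.0 - rate) / reps)
    return 100.0 * (rate - half), 100.0 * (rate + half)


@dataclass(frozen=True)
class PerformanceSummary:
    scenario_id: str
    method: str
    n_reps: int
    n_converged: int
    standardized_bias_pct: float
    relative_se_bias_pct: float
    rejection_pct: float  # type-one error (null) or power (effect)
    coverage_pct: float
    classification: str  # conservative / nominal / inflated ('' for effect)

    def as_row(self) -> dict:
        return self.__dict__.copy()


def _classify(rejection_pct: float) -> str:
    if rejection_pct < CONSERVATIVE_BOUND_PCT:
        return "conservative"
    if rejection_pct > INFLATED_BOUND_PCT:
        return "inflated"
    return "nominal"


def summarise(
    results: Sequence[FitResult] | dict,
    truth: float,
    *,
    scenario_id: str = "",
    method: str | None = None,
    null_scenario: bool | None = None,
    alpha: float = 0.05,
) -> PerformanceSummary:
    """Collapse per-repetition results into one performance summary.

    ``results`` is either a sequence of :class:`FitResult` (one per
    repetition) or a dict of arrays with keys estimate/se/p/ci_low/
    ci_high/converged.  Non-converged repetitions are excluded from every
    metric.
    """
    if isinstance(results, dict):
        arr = results
        if method is None:
            method = arr.get("method", "")
    else:
        if len(results) == 0:
            raise ConfigurationError("summarise needs at least one result")
        if method is None:
            method = results[0].method
        arr = {
            "estimate": np.array([r.estimate for r in results]),
            "se": np.array([r.se for r in results]),
            "p": np.array([r.p for r in results]),
            "ci_low": np.array([r.ci_low for r in results]),
            "ci_high": np.array([r.ci_high for r in results]),
            "converged": np.array([r.converged for r in results]),
        }
    conv = np.asarray(arr["converged"], dtype=bool)
    n_reps = conv.size
    n_conv = int(conv.sum())
    if null_scenario is None:
        null_scenario = truth == 0.0
    if n_conv < 2:
        return PerformanceSummary(
            scenario_id, method, n_reps, n_conv,
            float("nan"), float("nan"), float("nan"), float("nan"), "",
        )
    est = np.asarray(arr["estimate"], dtype=np.float64)[conv]
    se = np.asarray(arr["se"], dtype=np.float64)[conv]
    p = np.asarray(arr["p"], dtype=np.float64)[conv]
    lo = np.asarray(arr["ci_low"], dtype=np.float64)[conv]
    hi = np.asarray(arr["ci_high"], dtype=np.float64)[conv]
    sd = float(np.std(est, ddof=1))
    if sd > 0:
        bias = 100.0 * (float(est.mean()) - truth) / sd
        mod_se = math.sqrt(float(np.mean(se**2)))
        se_bias = 100.0 * (mod_se / sd - 1.0)
    else:
        bias = se_bias = float("nan")
    rejection = 100.0 * float(np.mean(p < alpha))
    coverage = 100.0 * float(np.mean((lo <= truth) & (truth <= hi)))
    return PerformanceSummary(
        scenario_id=scenario_id,
        method=method,
        n_reps=n_reps,
        n_converged=n_conv,
        standardized_bias_pct=bias,
        relative_se_bias_pct=se_bias,
        rejection_pct=rejection,
        coverage_pct=coverage,
        classification=_classify(rejection) if null_scenario else "",
    )


def _scenario_id(s: Scenario) -> str:
    eff = "null" if s.is_null else f"or{float(s.effect):.4g}"
    return (
        f"n{s.n_clusters}_m{s.mean_size:g}_cv{s.cv_size:g}"
        f"_p{s.control_prevalence:g}_icc{s.icc:g}_{s.effect_distribution}_{eff}"
    )


def _truth_for(method: str, scenario: Scenario) -> float:
    beta1 = scenario.beta1
    family = METHODS[method][0]
    if family in ("gee_i",) or method.endswith(("E.DF_CP",)) or method.startswith(
        ("GEE.", "KC.", "FG.")
    ):
        return marginal_truth(beta1, scenario.sigma_b2)
    return beta1


def _run_one(scenario: Scenario, idx: int, methods, reps: int, master_seed: int):
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(idx), int(scenario.seed or 0))
    )
    rng = np.random.Generator(np.random.PCG64(ss))
    arm, sizes, events = generate_trial_arrays(scenario, reps, rng)
    batch = analyse_batch(arm, sizes, events, methods)
    rows = []
    sid = _scenario_id(scenario)
    for mth in methods:
        summ = summarise(
            batch[mth],
            truth=_truth_for(mth, scenario),
            scenario_id=sid,
            method=mth,
            null_scenario=scenario.is_null,
        )
        row = summ.as_row()
        row.update(
            n_clusters=scenario.n_clusters,
            mean_size=scenario.mean_size,
            cv_size=scenario.cv_size,
            control_prevalence=scenario.control_prevalence,
            icc=scenario.icc,
            effect_distribution=scenario.effect_distribution,
            effect="null" if scenario.is_null else float(scenario.effect),
            true_log_or=scenario.beta1,
        )
        rows.append(row)
    return rows


def run_grid(
    scenarios: Iterable[Scenario],
    methods: Sequence[str],
    reps: int,
    master_seed: int = 0,
    workers: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario x method at ``reps`` repetitions.

    Deterministic given ``master_seed`` and the scenario list, regardless
    of ``workers``: each scenario owns an independent generator derived
    from (master_seed, position, scenario seed), and all methods within a
    repetition analyse the same dataset.
    """
    scenarios = list(scenarios)
    methods = list(methods)
    if reps < 1:
        raise ConfigurationError(f"reps must be >= 1, got {reps}")
    unknown = [mth for mth in methods if mth not in METHODS]
    if unknown:
        raise ConfigurationError(
            f"unknown method label(s) {unknown}; valid labels: {sorted(METHODS)}"
        )
    iterator = enumerate(scenarios)
    if progress:
        from tqdm import tqdm  # pragma: no cover

        iterator = tqdm(list(iterator), desc="scenarios")
    if workers == 1:
        all_rows = [
            row
            for idx, scen in iterator
            for row in _run_one(scen, idx, methods, reps, master_seed)
        ]
    else:
        chunks = Parallel(n_jobs=workers)(
            delayed(_run_one)(scen, idx, methods, reps, master_seed)
            for idx, scen in iterator
        )
        all_rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(all_rows)
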