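"""Data-generating mechanism and scenario grid for the simulation study.

A two-arm CRT with a binary outcome is generated as

    Y_c ~ Binomial(expit(beta0 + beta1 * arm_c + u_c), m_c)

per cluster, where ``u_c`` is a cluster effect with mean zero and variance
``sigma_b2`` drawn from a normal, (shifted, scaled) gamma, or uniform
distribution, and cluster sizes are either common or negative-binomial with
a target mean and coefficient of variation. The intracluster correlation
(ICC) is defined on the log-odds scale as sigma_b2 / (sigma_b2 + pi^2/3).

The full factorial grid spans 4 cluster counts x 3 mean sizes x 3 CVs x
2 control prevalences x 4 ICCs x 3 cluster-effect distributions, each with
and without an intervention effect (1728 scenarios, 864 null). Effect
sizes are conditional odds ratios solved so that a design-effect-adjusted
two-proportion power calculation gives 80% power at two-sided alpha 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import ConfigurationError, NumericalError
from .trial_data import TrialDataset

__all__ = [
    "Scenario",
    "N_CLUSTERS_GRID",
    "MEAN_SIZE_GRID",
    "CV_SIZE_GRID",
    "PREVALENCE_GRID",
    "ICC_GRID",
    "DISTRIBUTIONS",
    "icc_to_sigma2",
    "sigma2_to_icc",
    "draw_cluster_sizes",
    "draw_cluster_effects",
    "solve_effect_size",
    "generate_trial",
    "generate_trial_arrays",
    "enumerate_grid",
    "grid_to_frame",
]

N_CLUSTERS_GRID = (8, 12, 20, 30)
MEAN_SIZE_GRID = (10.0, 50.0, 1000.0)
CV_SIZE_GRID = (0.0, 0.5, 0.8)
PREVALENCE_GRID = (0.10, 0.30)
ICC_GRID = (0.001, 0.01, 0.05, 0.1)
DISTRIBUTIONS = ("normal", "gamma", "uniform")

_LOGISTIC_VAR = math.pi**2 / 3.0


def icc_to_sigma2(icc: float) -> float:
    """Between-cluster log-odds variance implied by a log-odds-scale ICC.

    The ICC is sigma_b2 / (sigma_b2 + pi^2/3), so
    sigma_b2 = icc * (pi^2/3) / (1 - icc).
    """
    if not 0.0 <= icc < 1.0:
        raise ConfigurationError(f"icc must lie in [0, 1), got {icc}")
    return icc * _LOGISTIC_VAR / (1.0 - icc)


def sigma2_to_icc(sigma_b2: float) -> float:
    """Inverse of :func:`icc_to_sigma2`."""
    if sigma_b2 < 0:
        raise ConfigurationError(f"sigma_b2 must be >= 0, got {sigma_b2}")
    return sigma_b2 / (sigma_b2 + _LOGISTIC_VAR)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid.

    ``effect`` is either the string ``"null"`` or a conditional
    (cluster-specific) odds ratio > 0 applied to the intervention arm.
    """

    n_clusters: int
    mean_size: float
    cv_size: float
    control_prevalence: float
    icc: float
    effect: float | Literal["null"]
    effect_distribution: str = "normal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 2 or self.n_clusters % 2:
            raise ConfigurationError(
                f"n_clusters must be a positive even integer (1:1 randomisation), "
                f"got {self.n_clusters}"
            )
        if self.mean_size <= 0:
            raise ConfigurationError(f"mean_size must be > 0, got {self.mean_size}")
        if self.cv_size < 0:
            raise ConfigurationError(f"cv_size must be >= 0, got {self.cv_size}")
        if not 0.0 < self.control_prevalence < 1.0:
            raise ConfigurationError(
                f"control_prevalence must lie in (0, 1), got {self.control_prevalence}"
            )
        if not 0.0 <= self.icc < 1.0:
            raise ConfigurationError(f"icc must lie in [0, 1), got {self.icc}")
        if self.effect_distribution not in DISTRIBUTIONS:
            raise ConfigurationError(
                f"unknown effect_distribution {self.effect_distribution!r}; "
                f"choose from {DISTRIBUTIONS}"
            )
        if self.effect != "null" and not (
            isinstance(self.effect, (int, float))
            and (self.effect > 0 or math.isnan(self.effect))
        ):
            # NaN is allowed as a to-be-solved placeholder; generation
            # refuses it (see _resolve_effect)
            raise ConfigurationError(
                f"effect must be 'null' or a positive odds ratio, got {self.effect!r}"
            )

    @property
    def sigma_b2(self) -> float:
        return icc_to_sigma2(self.icc)

    @property
    def is_null(self) -> bool:
        return self.effect == "null"

    @property
    def beta0(self) -> float:
        """True control-arm log-odds (conditional, median-cluster)."""
        return float(logit(self.control_prevalence))

    @property
    def beta1(self) -> float:
        """True conditional log odds ratio (0 under the null)."""
        return 0.0 if self.is_null else float(np.log(self.effect))

    def with_effect(self, effect: float | str) -> "Scenario":
        return replace(self, effect=effect)


def draw_cluster_sizes(
    n_clusters: int, mean_size: float, cv_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw cluster sizes: common (CV = 0) or 2 + negative binomial.

    With s = cv_size * mean_size, the negative-binomial count delta is
    parameterised with ``r = (mbar-2)^2 / (s^2 - (mbar-2))`` successes and
    success probability ``p = (mbar-2) / s^2`` (failures-before-rth-success
    convention), which gives E[delta] = mbar - 2 and Var[delta] = s^2
    exactly, hence sizes m = 2 + delta with mean mbar and CV cv_size.
    """
    if cv_size == 0.0:
        return np.full(n_clusters, int(round(mean_size)), dtype=np.int64)
    mbar = float(mean_size)
    s2 = (cv_size * mbar) ** 2
    if s2 <= mbar - 2.0:
        raise ConfigurationError(
            "negative-binomial size distribution requires "
            f"(cv*mean)^2 > mean - 2; got variance {s2} <= {mbar - 2.0}"
        )
    r = (mbar - 2.0) ** 2 / (s2 - (mbar - 2.0))
    p = (mbar - 2.0) / s2
    delta = rng.negative_binomial(r, p, size=n_clusters)
    return (2 + delta).astype(np.int64)


def draw_cluster_effects(
    n_clusters: int,
    distribution: str,
    sigma_b2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw cluster-level log-odds shifts with mean 0 and variance sigma_b2.

    ``normal``: N(0, sigma_b2); ``gamma``: sigma_b*(a-2)/sqrt(2) with
    a ~ Gamma(shape 2, scale 1), giving skewness sqrt(2); ``uniform``:
    U(-sqrt(3*sigma_b2), +sqrt(3*sigma_b2)).
    """
    if sigma_b2 < 0:
        raise ConfigurationError(f"sigma_b2 must be >= 0, got {sigma_b2}")
    sigma = math.sqrt(sigma_b2)
    if distribution == "normal":
        return rng.normal(0.0, sigma, size=n_clusters)
    if distribution == "gamma":
        a = rng.gamma(2.0, 1.0, size=n_clusters)
        return sigma * (a - 2.0) / math.sqrt(2.0)
    if distribution == "uniform":
        half = math.sqrt(3.0 * sigma_b2)
        return rng.uniform(-half, half, size=n_clusters)
    raise ConfigurationError(
        f"unknown cluster-effect distribution {distribution!r}; choose from {DISTRIBUTIONS}"
    )


def _power_two_proportions(p0: float, p1: float, n_per_arm: float, alpha: float) -> float:
    """Normal-approximation power of the two-sided two-proportion test.

    Pooled variance in the alpha term (chi-squared-style), unpooled in the
    beta term — the classical sample-size formula.
    """
    delta = abs(p1 - p0)
    if delta == 0.0:
        return alpha
    pbar = 0.5 * (p0 + p1)
    za = norm.ppf(1.0 - alpha / 2.0)
    sd0 = math.sqrt(2.0 * pbar * (1.0 - pbar))
    sd1 = math.sqrt(p0 * (1.0 - p0) + p1 * (1.0 - p1))
    z = (delta * math.sqrt(n_per_arm) - za * sd0) / sd1
    return float(norm.cdf(z))


def design_effect(mean_size: float, cv_size: float, icc: float) -> float:
    """Variance inflation for cluster randomisation with unequal sizes.

    The equal-size design effect 1 + (mbar - 1)*rho is divided by the
    van Breukelen-Candel-Berger relative efficiency
    RE = 1 - cv^2 * lam * (1 - lam) with lam = mbar*rho / (1 + (mbar-1)*rho).
    """
    de_eq = 1.0 + (mean_size - 1.0) * icc
    lam = mean_size * icc / de_eq
    re = 1.0 - cv_size**2 * lam * (1.0 - lam)
    return de_eq / re


def solve_effect_size(
    scenario: Scenario,
    *,
    target_power: float = 0.80,
    alpha: float = 0.05,
    or_max: float = 100.0,
    tol: float = 1e-8,
) -> float:
    """Conditional odds ratio giving ``target_power`` for a scenario.

    Bisection on the log odds ratio: the effective sample size per arm is
    (n_clusters/2 * mean_size) / DE with DE from :func:`design_effect`
    (the log-odds-scale ICC is used directly in the design effect), and
    power comes from the two-proportion normal approximation.
    """
    p0 = scenario.control_prevalence
    de = design_effect(scenario.mean_size, scenario.cv_size, scenario.icc)
    n_eff = (scenario.n_clusters / 2.0) * scenario.mean_size / de

    def power_at(log_or: float) -> float:
        p1 = float(expit(logit(p0) + log_or))
        return _power_two_proportions(p0, p1, n_eff, alpha)

    lo, hi = 0.0, math.log(or_max)
    if power_at(hi) < target_power:
        raise NumericalError(
            f"no odds ratio in (1, {or_max}] achieves {target_power:.0%} power "
            f"for scenario {scenario}"
        )
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if power_at(mid) < target_power:
            lo = mid
        else:
            hi = mid
        if abs(power_at(0.5 * (lo + hi)) - target_power) < tol:
            break
    return math.exp(0.5 * (lo + hi))


def _resolve_effect(scenario: Scenario) -> float:
    if scenario.is_null:
        return 0.0
    if math.isnan(scenario.effect):
        raise ConfigurationError(
            "scenario carries an unsolved effect placeholder; call "
            "solve_effect_size (or enumerate_grid with solve_powered=True) first"
        )
    return float(np.log(scenario.effect))


def generate_trial_arrays(
    scenario: Scenario, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``reps`` trials at once; returns (arm, sizes, events).

    ``arm`` has shape (n,) — the first n/2 clusters are control — while
    ``sizes`` and ``events`` have shape (reps, n). All repetitions share
    one vectorised stream, so a fixed generator state reproduces the whole
    batch bitwise.
    """
    n = scenario.n_clusters
    arm = np.repeat(np.array([0, 1], dtype=np.int64), n // 2)
    beta1 = _resolve_effect(scenario)
    if scenario.cv_size == 0.0:
        sizes = np.full((reps, n), int(round(scenario.mean_size)), dtype=np.int64)
    else:
        sizes = draw_cluster_sizes(
            reps * n, scenario.mean_size, scenario.cv_size, rng
        ).reshape(reps, n)
    u = draw_cluster_effects(
        reps * n, scenario.effect_distribution, scenario.sigma_b2, rng
    ).reshape(reps, n)
    eta = scenario.beta0 + beta1 * arm[None, :] + u
    events = rng.binomial(sizes, expit(eta))
    return arm, sizes, events.astype(np.int64)


def generate_trial(scenario: Scenario, rng: np.random.Generator) -> TrialDataset:
    """Generate a single trial dataset under the scenario's mechanism."""
    arm, sizes, events = generate_trial_arrays(scenario, 1, rng)
    return TrialDataset.from_arrays(arm, events[0], sizes[0])


def enumerate_grid(
    *,
    master_seed: int = 0,
    n_clusters: Sequence[int] | None = None,
    mean_size: Sequence[float] | None = None,
    cv_size: Sequence[float] | None = None,
    control_prevalence: Sequence[float] | None = None,
    icc: Sequence[float] | None = None,
    effect_distribution: Sequence[str] | None = None,
    effects: Sequence[str] = ("null", "powered"),
    solve_powered: bool = True,
) -> list[Scenario]:
    """Enumerate the factorial scenario grid in deterministic order.

    The full grid is 4 x 3 x 3 x 2 x 4 x 3 = 864 cells, each in a null and
    a powered-effect version (1728 scenarios). ``effects`` selects which
    versions to include; with ``solve_powered`` the powered cells carry the
    odds ratio from :func:`solve_effect_size`, otherwise a placeholder that
    callers must resolve. Per-scenario seeds are derived from
    ``master_seed`` by the scenario's position in the *full* grid so that
    filtered grids reuse the same streams.
    """
    n_clusters = tuple(n_clusters or N_CLUSTERS_GRID)
    mean_size = tuple(mean_size or MEAN_SIZE_GRID)
    cv_size = tuple(cv_size or CV_SIZE_GRID)
    control_prevalence = tuple(control_prevalence or PREVALENCE_GRID)
    icc = tuple(icc or ICC_GRID)
    effect_distribution = tuple(effect_distribution or DISTRIBUTIONS)
    for eff in effects:
        if eff not in ("null", "powered"):
            raise ConfigurationError(f"effects entries must be 'null' or 'powered', got {eff!r}")

    scenarios: list[Scenario] = []
    index = 0
    for status in ("null", "powered"):
        for nc in N_CLUSTERS_GRID:
            for ms in MEAN_SIZE_GRID:
                for cv in CV_SIZE_GRID:
                    for prev in PREVALENCE_GRID:
                        for rho in ICC_GRID:
                            for dist in DISTRIBUTIONS:
                                index += 1
                                if status not in effects:
                                    continue
                                if (
                                    nc not in n_clusters
                                    or ms not in mean_size
                                    or cv not in cv_size
                                    or prev not in control_prevalence
                                    or rho not in icc
                                    or dist not in effect_distribution
                                ):
                                    continue
                                scen = Scenario(
                                    n_clusters=nc,
                                    mean_size=ms,
                                    cv_size=cv,
                                    control_prevalence=prev,
                                    icc=rho,
                                    effect="null",
                                    effect_distribution=dist,
                                    seed=_scenario_seed(master_seed, index),
                                )
                                if status == "powered":
                                    if solve_powered:
                                        scen = scen.with_effect(solve_effect_size(scen))
                                    else:
                                        scen = scen.with_effect(float("nan"))
                                scenarios.append(scen)
    return scenarios


def _scenario_seed(master_seed: int, index: int) -> int:
    """Reproducible per-scenario seed from the master seed via SeedSequence."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, np.uint32)[0])


def grid_to_frame(scenarios: Iterable[Scenario]) -> pd.DataFrame:
    """Serialise a scenario list to one row per scenario."""
    rows = []
    for s in scenarios:
        rows.append(
            {
                "n_clusters": s.n_clusters,
                "mean_size": s.mean_size,
                "cv_size": s.cv_size,
                "control_prevalence": s.control_prevalence,
                "icc": s.icc,
                "effect_distribution": s.effect_distribution,
                "effect": s.effect,
                "odds_ratio": np.nan if s.is_null else float(s.effect),
                "sigma_b2": s.sigma_b2,
                "seed": s.seed,
            }
        )
    return pd.DataFrame(rows)
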