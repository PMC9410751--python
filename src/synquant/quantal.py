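"""Binomial release-model analysis.

Under a simple binomial model of transmission — N release sites with
uniform release probability p and quantal amplitude q — the mean unitary
response and the failure probability are

    E = N p q          F = (1 - p)^N

For low-p synapses the series expansion F ~ 1 - Np = 1 - E/q makes the
failure percentage an approximately linear function of the mean response,
with a slope inversely proportional to the quantal amplitude. Fitting that
line across a population of connections (excluding high-release-probability
synapses, F < 0.4, where the linearization breaks down) therefore estimates
q, and comparing per-genotype slopes with an interaction-term ANOVA tests
whether the postsynaptic response to uniquantal release differs between
genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ConnectionRecord", "FailureRegression", "binomial_moments",
    "release_pmf", "fit_failure_regression", "estimate_quantal_amplitude",
    "predict_failure_percent",
]


@dataclass(frozen=True)
class ConnectionRecord:
    """Per-connection summary used by the population regression."""

    connection_id: str
    genotype: str
    mean_amplitude: float          # E, mV or pA
    failure_fraction: float        # F in [0, 1]
    synapse: str = "PC-SOM"
    ppr: float | None = None
    n_sweeps: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.failure_fraction <= 1.0:
            raise ValueError("failure_fraction must lie in [0, 1]")
        if self.mean_amplitude < 0:
            raise ValueError("mean_amplitude must be >= 0")


@dataclass
class FailureRegression:
    """Failure(%)-vs-amplitude regression across connections."""

    slope: float                   # shared slope, % per mV (or per pA)
    intercept: float               # %
    genotype_slopes: dict[str, float]
    interaction_p: float
    shared: bool                   # interaction non-significant
    spearman_r: float
    spearman_p: float
    n_used: int
    n_excluded: int
    used_ids: list[str] = field(default_factory=list)


def binomial_moments(n_sites: int, p: float, q: float) -> tuple[float, float]:
    """Mean response E = Npq and failure probability F = (1-p)^N."""
    if not (n_sites >= 1 and float(n_sites).is_integer()):
        raise ValueError("n_sites must be an integer >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if q <= 0:
        raise ValueError("q must be positive")
    return n_sites * p * q, (1.0 - p) ** n_sites


def release_pmf(n_sites: int, p: float, q: float, quantal_cv: float = 0.0):
    """Exact outcome distribution of the binomial release model.

    Returns ``(amplitudes, probabilities, moments)``: the support ``k*q``
    for k = 0..N released quanta with binomial probabilities, and the
    (mean, variance) of the response amplitude. With ``quantal_cv > 0`` the
    support refers to quantal counts (each quantum's amplitude is lognormal)
    and the moments include the quantal variability:
    Var = N p (1-p) q^2 + N p (cv q)^2.
    """
    if quantal_cv < 0:
        raise ValueError("quantal_cv must be >= 0")
    _ = binomial_moments(n_sites, p, q)  # domain checks
    k = np.arange(n_sites + 1)
    pmf = stats.binom.pmf(k, n_sites, p)
    mean = n_sites * p * q
    var = n_sites * p * (1 - p) * q ** 2 + n_sites * p * (quantal_cv * q) ** 2
    return k * q, pmf, (mean, var)


def predict_failure_percent(mean_amplitude: float, slope: float,
                            intercept: float = 100.0) -> float:
    """Linearized binomial prediction F(%) = intercept + slope * E.

    The theoretical intercept is 100% (zero mean response implies failure on
    every trial); the slope is -100/q when F is expressed in percent.
    """
    return intercept + slope * mean_amplitude


def fit_failure_regression(records: list[ConnectionRecord],
                           min_failure: float = 0.4,
                           alpha: float = 0.05) -> FailureRegression:
    """OLS of failure % on mean amplitude with a genotype interaction test.

    Connections with F below ``min_failure`` (high release probability,
    where the linearization deviates) are excluded from the fit but kept in
    the Spearman correlation. The interaction term (amplitude x genotype)
    tests whether the per-genotype slopes differ; when it is non-significant
    the pooled shared-slope fit is reported.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame({
        "id": [r.connection_id for r in records],
        "genotype": [r.genotype for r in records],
        "E": [r.mean_amplitude for r in records],
        "Fpct": [100.0 * r.failure_fraction for r in records],
    })
    if df["E"].nunique() > 1 and df["Fpct"].nunique() > 1:
        rho, sp_p = stats.spearmanr(df["E"], df["Fpct"])
    else:
        rho, sp_p = float("nan"), float("nan")
    use = df[df["Fpct"] >= 100.0 * min_failure]
    if use.empty:
        raise ValueError("all records excluded by the failure-fraction rule")
    counts = use.groupby("genotype").size()
    if (counts < 3).any() or len(counts) < 1:
        raise ValueError("need at least 3 usable records per genotype")
    genotypes = sorted(counts.index)
    if len(genotypes) > 1:
        inter = smf.ols("Fpct ~ E * C(genotype)", data=use).fit()
        inter_term = [t for t in inter.pvalues.index
                      if t.startswith("E:C(genotype)")]
        interaction_p = float(inter.pvalues[inter_term].min())
        slopes = {}
        for g in genotypes:
            sub = use[use["genotype"] == g]
            slopes[g] = float(np.polyfit(sub["E"], sub["Fpct"], 1)[0])
    else:
        interaction_p = 1.0
        slopes = {}
    shared = interaction_p >= alpha
    pooled = smf.ols("Fpct ~ E", data=use).fit()
    slope = float(pooled.params["E"])
    intercept = float(pooled.params["Intercept"])
    if len(genotypes) == 1:
        slopes = {genotypes[0]: slope}
    return FailureRegression(slope=slope, intercept=intercept,
                             genotype_slopes=slopes,
                             interaction_p=interaction_p, shared=shared,
                             spearman_r=float(rho), spearman_p=float(sp_p),
                             n_used=len(use), n_excluded=len(df) - len(use),
                             used_ids=list(use["id"]))


def estimate_quantal_amplitude(slope: float) -> float:
    """Quantal amplitude from the failure-regression slope: q = -100/slope.

    Follows from F(%) ~ 100 - (100/q) E in the linearized model; a
    non-negative slope carries no quantal interpretation.
    """
    if not math.isfinite(slope) or slope >= 0:
        raise ValueError("slope must be negative for a quantal interpretation")
    return -100.0 / slope
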