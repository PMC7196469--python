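"""Causal-effect estimators for two-sample Mendelian randomization.

Given J harmonized instruments with exposure effects gamma_j (SE sigma_Xj)
and outcome effects Gamma_j (SE sigma_Yj), each SNP's Wald ratio
theta_j = Gamma_j / gamma_j estimates the causal effect of the exposure on
the outcome (log-odds per SD for a binary outcome). Three pooled estimators
with different validity assumptions are provided:

* **IVW** — inverse-variance weighted average of the Wald ratios; unbiased
  when every instrument satisfies the exclusion restriction. Offered with
  fixed-effect or multiplicative random-effect standard errors (the latter
  inflates the SE by sqrt(Q / (J-1)) when Cochran's Q exceeds its
  expectation, leaving the point estimate unchanged).
* **MR-Egger** — weighted regression of Gamma_j on gamma_j with a free
  intercept. The intercept estimates average directional pleiotropy; the
  slope remains a consistent causal estimate under the InSIDE assumption
  even when all instruments are pleiotropic.
* **Weighted median** — the weighted median of the Wald ratios; consistent
  when instruments carrying at least half the total weight are valid.
  Its SE comes from a parametric bootstrap.

Standard errors throughout use the first-order delta method for the Wald
ratio, se(theta_j) = sigma_Yj / |gamma_j|, which ignores exposure-side
sampling error — the standard choice when instruments are strong (F > 10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .summary_io import InstrumentSet, SummaryStatsError, ConfigurationError

logger = logging.getLogger(__name__)

Z_95 = 1.959964  # two-sided 95% standard-normal quantile

DEFAULT_N_BOOT = 1000
DEFAULT_BOOT_SEED = 20200224


class EstimationError(SummaryStatsError):
    """An estimator's preconditions are not met."""


@dataclass(frozen=True)
class RatioEstimate:
    """A single SNP's Wald-ratio causal estimate.

    ``weight`` is the inverse-variance weight 1/se_theta**2 used by IVW,
    Cochran's Q and the weighted median.
    """

    rsid: str
    theta: float
    se_theta: float

    @property
    def weight(self) -> float:
        return self.se_theta ** -2

    @property
    def pval(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.theta / self.se_theta)))


@dataclass(frozen=True)
class MrEstimate:
    """A pooled causal-effect estimate on the log-odds (per 1-SD exposure) scale.

    ``dispersion`` is the residual scale factor applied to the fixed-effect
    covariance (1 for fixed effects). The intercept triple is populated for
    MR-Egger only.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    dispersion: float = 1.0
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or_point": self.or_point,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "dispersion": self.dispersion,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
        }


def wald_ratios(s: InstrumentSet) -> list[RatioEstimate]:
    """Per-SNP Wald ratios theta_j = beta_out/beta_exp with delta-method SEs."""
    out = []
    for i in s:
        if i.beta_exp == 0:
            raise EstimationError(f"{i.rsid}: zero exposure effect, Wald ratio undefined")
        out.append(
            RatioEstimate(
                rsid=i.rsid,
                theta=i.beta_out / i.beta_exp,
                se_theta=i.se_out / abs(i.beta_exp),
            )
        )
    return out


def _ratio_arrays(s: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = wald_ratios(s)
    theta = np.array([x.theta for x in r])
    se = np.array([x.se_theta for x in r])
    return theta, se, se ** -2


def _normal_estimate(method: str, beta: float, se: float, n_snp: int, dispersion: float = 1.0,
                     **extra) -> MrEstimate:
    return MrEstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z_95 * se,
        ci_high=beta + Z_95 * se,
        pval=float(2.0 * stats.norm.sf(abs(beta / se))),
        n_snp=n_snp,
        dispersion=dispersion,
        **extra,
    )


def ivw(s: InstrumentSet, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance weighted meta-analysis of the Wald ratios.

    ``model`` selects the standard error: ``"fixed"`` uses (sum of weights)**-0.5;
    ``"multiplicative_random"`` multiplies it by max(1, sqrt(Q/(J-1))), the
    multiplicative random-effects dispersion, so heterogeneity beyond chance
    widens the interval without moving the point estimate. Inference uses the
    standard normal distribution.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown IVW model {model!r}")
    if len(s) == 0:
        raise EstimationError("IVW requires at least one instrument")
    theta, se, w = _ratio_arrays(s)
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    dispersion = 1.0
    if len(s) == 1:
        if model == "multiplicative_random":
            logger.warning("single instrument: multiplicative random effects "
                           "falls back to fixed-effect SE")
        method = "wald_single"
    elif model == "multiplicative_random":
        q = float(np.sum(w * (theta - beta) ** 2))
        dispersion = max(1.0, math.sqrt(q / (len(s) - 1)))
        method = "ivw_mre"
    else:
        method = "ivw_fixed"
    return _normal_estimate(method, beta, se_fixed * dispersion, len(s), dispersion)


def egger(s: InstrumentSet) -> MrEstimate:
    """MR-Egger regression: pleiotropy-robust slope and directional-pleiotropy intercept.

    Each instrument is first oriented so its exposure effect is positive
    (negating both betas where needed) — the convention under which the Egger
    intercept is defined. A weighted least-squares fit of beta_out on beta_exp
    with intercept and weights 1/se_out**2 follows; the residual scale is
    floored at 1 (an under-dispersed fit is not allowed to shrink the SEs
    below their fixed-effect value), and inference uses Student's t with
    J - 2 degrees of freedom.
    """
    if len(s) < 3:
        raise EstimationError("MR-Egger requires >= 3 instruments")
    bx = np.array([i.beta_exp for i in s])
    by = np.array([i.beta_out for i in s])
    so = np.array([i.se_out for i in s])
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign
    if np.ptp(x) == 0:
        raise EstimationError("MR-Egger design is singular: no spread in exposure effects")
    fit = sm.WLS(y, sm.add_constant(x), weights=so ** -2).fit()
    df = len(s) - 2
    scale = float(fit.scale)  # weighted residual MSE
    dispersion = max(1.0, math.sqrt(scale))
    # statsmodels' bse already carries sqrt(scale); re-floor it at the
    # fixed-effect covariance.
    bse = np.asarray(fit.bse) * dispersion / math.sqrt(scale)
    params = np.asarray(fit.params)
    tq = float(stats.t.ppf(0.975, df))
    intercept, slope = float(params[0]), float(params[1])
    se_int, se_slope = float(bse[0]), float(bse[1])
    return MrEstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=float(2.0 * stats.t.sf(abs(slope / se_slope), df)),
        n_snp=len(s),
        dispersion=dispersion,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=float(2.0 * stats.t.sf(abs(intercept / se_int), df)),
    )


def _weighted_median(theta: np.ndarray, weight: np.ndarray, rsid: Sequence[str]) -> float:
    """Weighted median of theta by cumulative-weight interpolation.

    With normalized weights p_j (sorted by theta, ties broken by rsid for
    determinism), the cumulative midpoints are S_j = sum_{i<=j} p_i - p_j/2;
    the estimate interpolates theta linearly in S at S = 0.5. If the
    midpoints never bracket 0.5 the boundary theta is returned.
    """
    order = np.lexsort((np.asarray(rsid, dtype=object), theta))
    t, p = theta[order], weight[order] / np.sum(weight)
    s_mid = np.cumsum(p) - p / 2
    if s_mid[0] >= 0.5:
        return float(t[0])
    if s_mid[-1] <= 0.5:
        return float(t[-1])
    return float(np.interp(0.5, s_mid, t))


def weighted_median(
    s: InstrumentSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> MrEstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    The point estimate is deterministic. Its SE is the standard deviation of
    the statistic over ``n_boot`` replicates drawing theta_j* from
    Normal(theta_j, se_theta_j) with the inverse-variance weights held fixed
    at their observed values; p-value and CI use the normal approximation.
    """
    if len(s) < 3:
        raise EstimationError("weighted median requires >= 3 instruments")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    theta, se, w = _ratio_arrays(s)
    rsid = list(s.rsids)
    beta = _weighted_median(theta, w, rsid)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=theta, scale=se, size=(n_boot, len(theta)))
    boot = np.array([_weighted_median(d, w, rsid) for d in draws])
    se_boot = float(np.std(boot, ddof=0))
    return _normal_estimate("weighted_median", beta, se_boot, len(s))


def estimate_all(
    s: InstrumentSet,
    ivw_model: str = "multiplicative_random",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_BOOT_SEED,
) -> list[MrEstimate]:
    """Run IVW, MR-Egger and the weighted median; skip methods whose
    preconditions fail (with a logged reason) rather than aborting the batch."""
    results: list[MrEstimate] = []
    for name, call in (
        ("ivw", lambda: ivw(s, model=ivw_model)),
        ("egger", lambda: egger(s)),
        ("weighted_median", lambda: weighted_median(s, n_boot=n_boot, seed=seed)),
    ):
        try:
            results.append(call())
        except EstimationError as exc:
            logger.warning("%s skipped: %s", name, exc)
    if not results:
        raise EstimationError("no estimator could run on this instrument set")
    return results
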