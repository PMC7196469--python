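"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator implements the data-generating model the estimators assume:
each instrument j has a true exposure effect gamma_j, a (possibly zero)
direct pleiotropic effect alpha_j on the outcome, and a true outcome effect
Gamma_j = beta * gamma_j + alpha_j, where beta is the causal slope. The two
studies observe these effects with independent Gaussian noise at their
respective standard errors — the defining feature of a two-sample design.
Binary-outcome log-odds are simulated directly as Gaussian summary
statistics; no individual-level data are generated, because summary-level MR
never sees any.

Pleiotropy modes:

* ``none`` — alpha_j = 0: every instrument is valid; IVW is unbiased.
* ``balanced`` — alpha_j ~ Normal(0, sd): pleiotropy averages out; IVW stays
  consistent but heterogeneity is inflated.
* ``directional`` — alpha_j ~ Normal(mean, sd) with nonzero mean: violates
  the zero-intercept assumption; IVW is biased while the MR-Egger intercept
  targets the mean pleiotropic effect.

The default scenario mirrors the bundled waist-circumference instrument set:
J = 46 instruments with per-allele effects of 0.018–0.072 SD, exposure SEs
of 0.003–0.010 and outcome SEs of 0.009–0.031, and a causal slope of 0.45
log-odds per SD (the scale of the headline analysis). Exposure-side noise is
generated even though the first-order Wald SE ignores it, so simulation
studies quantify — rather than hide — that approximation at realistic
instrument strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import MrEstimate, EstimationError, egger, ivw, weighted_median
from .summary_io import ConfigurationError, HarmonizedInstrument, InstrumentSet, SnpAssociation

PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of the generative model for one pair of synthetic GWAS.

    ``gamma_dist`` is ``("uniform", low, high)`` or ``("normal", mean, sd)``
    for the true instrument effects (positive by default, as instrument
    tables are conventionally oriented to the trait-increasing allele).
    SE ranges are uniform sampling intervals with positive lower bounds.
    """

    n_snp: int = 46
    causal_beta: float = 0.45
    gamma_dist: tuple = ("uniform", 0.018, 0.072)
    se_exp_range: tuple[float, float] = (0.003, 0.010)
    se_out_range: tuple[float, float] = (0.009, 0.031)
    pleiotropy: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ConfigurationError("n_snp must be >= 1")
        if self.pleiotropy not in PLEIOTROPY_MODES:
            raise ConfigurationError(f"pleiotropy must be one of {PLEIOTROPY_MODES}")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        for name, rng in (("se_exp_range", self.se_exp_range), ("se_out_range", self.se_out_range)):
            if rng[0] < 0 or rng[1] < rng[0]:
                raise ConfigurationError(f"{name} must satisfy 0 <= low <= high")
        if self.gamma_dist[0] not in ("uniform", "normal"):
            raise ConfigurationError("gamma_dist kind must be 'uniform' or 'normal'")
        if not (0 < self.eaf_range[0] <= self.eaf_range[1] < 1):
            raise ConfigurationError("eaf_range must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated instrument set together with its generating truth."""

    instruments: InstrumentSet
    truth: pd.DataFrame  # columns: rsid, gamma, alpha, big_gamma
    scenario: SimulationScenario


def _draw_gamma(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind, a, b = dist
    if kind == "uniform":
        return rng.uniform(a, b, size=n)
    return rng.normal(a, b, size=n)


def simulate_instrument_set(sc: SimulationScenario) -> SimulatedStudy:
    """Draw one pair of synthetic exposure/outcome GWAS summary tables.

    Fully reproducible from ``sc.seed``. Observed effects are
    beta_exp_j ~ Normal(gamma_j, se_exp_j) and
    beta_out_j ~ Normal(Gamma_j, se_out_j) with noise independent across the
    two samples; the per-SNP SEs are treated as known (reported) quantities.
    Degenerate SE ranges at zero yield noise-free observations.
    """
    rng = np.random.default_rng(sc.seed)
    j = sc.n_snp
    gamma = _draw_gamma(rng, sc.gamma_dist, j)
    if sc.pleiotropy == "none":
        alpha = np.zeros(j)
    else:
        mean = sc.pleiotropy_mean if sc.pleiotropy == "directional" else 0.0
        alpha = rng.normal(mean, sc.pleiotropy_sd, size=j)
    big_gamma = sc.causal_beta * gamma + alpha

    se_exp = rng.uniform(*sc.se_exp_range, size=j)
    se_out = rng.uniform(*sc.se_out_range, size=j)
    eaf = rng.uniform(*sc.eaf_range, size=j)
    beta_exp = gamma + np.where(se_exp > 0, rng.normal(0.0, 1.0, size=j) * se_exp, 0.0)
    beta_out = big_gamma + np.where(se_out > 0, rng.normal(0.0, 1.0, size=j) * se_out, 0.0)

    rsids = [f"snp{k + 1:04d}" for k in range(j)]
    # SE of exactly 0 is not representable in a summary table; floor at a
    # negligible positive value so the noise-free limit remains expressible.
    tiny = 1e-12
    instruments = tuple(
        HarmonizedInstrument(
            rsid=rsids[k],
            beta_exp=float(beta_exp[k]),
            se_exp=float(max(se_exp[k], tiny)),
            beta_out=float(beta_out[k]),
            se_out=float(max(se_out[k], tiny)),
            effect_allele="A",
            eaf=float(eaf[k]),
        )
        for k in range(j)
        if beta_exp[k] != 0
    )
    iset = InstrumentSet(
        exposure_name="sim_exposure",
        outcome_name="sim_outcome",
        instruments=instruments,
        provenance={"scenario": sc},
    )
    truth = pd.DataFrame({"rsid": rsids, "gamma": gamma, "alpha": alpha, "big_gamma": big_gamma})
    return SimulatedStudy(instruments=iset, truth=truth, scenario=sc)


def to_summary_tables(study: SimulatedStudy) -> tuple[list[SnpAssociation], list[SnpAssociation]]:
    """Export a simulated study as two raw summary-statistic tables.

    The exposure table carries effect allele A (other allele G), the outcome
    table the same orientation, so reading the pair back through
    ``harmonize`` reproduces the instrument set (round-trip tested).
    """
    exp, out = [], []
    for i in study.instruments:
        exp.append(
            SnpAssociation(
                rsid=i.rsid, effect_allele="A", other_allele="G",
                eaf=i.eaf, beta=i.beta_exp, se=i.se_exp,
            )
        )
        out.append(
            SnpAssociation(
                rsid=i.rsid, effect_allele="A", other_allele="G",
                eaf=i.eaf, beta=i.beta_out, se=i.se_out,
            )
        )
    return exp, out


_ESTIMATOR_CALLS = {
    "ivw": lambda s, seed: ivw(s, model="multiplicative_random"),
    "ivw_fixed": lambda s, seed: ivw(s, model="fixed"),
    "egger": lambda s, seed: egger(s),
    "weighted_median": lambda s, seed: weighted_median(s, seed=seed),
}


def replicate_study(
    sc: SimulationScenario,
    n_reps: int,
    estimators: Sequence[str] = ("ivw",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo evaluation of estimators under a scenario.

    Runs ``simulate_instrument_set`` with seeds ``sc.seed, sc.seed + 1, ...``
    and each requested estimator, returning (per_replicate, aggregate) frames.
    The aggregate reports, per estimator: mean bias against the true causal
    slope, the Monte-Carlo SE of that bias, empirical SD of the estimates,
    mean estimated SE, 95%-CI coverage of the true slope, and rejection rate
    of the null at 0.05. For MR-Egger, the same summaries of the intercept
    against the mean pleiotropic effect are included. A replicate on which an
    estimator's preconditions fail is recorded as failed, not fatal.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    unknown = set(estimators) - set(_ESTIMATOR_CALLS)
    if unknown:
        raise ConfigurationError(f"unknown estimators: {sorted(unknown)}")

    rows = []
    for rep in range(n_reps):
        study = simulate_instrument_set(replace(sc, seed=sc.seed + rep))
        for name in estimators:
            row = {"replicate": rep, "seed": sc.seed + rep, "estimator": name, "ok": True}
            try:
                est = _ESTIMATOR_CALLS[name](study.instruments, sc.seed + rep)
            except EstimationError as exc:
                row.update(ok=False, error=str(exc))
                rows.append(row)
                continue
            row.update(
                beta=est.beta, se=est.se, pval=est.pval,
                ci_low=est.ci_low, ci_high=est.ci_high,
                intercept=est.intercept, intercept_se=est.intercept_se,
                intercept_p=est.intercept_p,
            )
            rows.append(row)
    per_rep = pd.DataFrame(rows)

    true_beta = sc.causal_beta
    true_alpha = sc.pleiotropy_mean if sc.pleiotropy == "directional" else 0.0
    agg_rows = []
    for name in estimators:
        g = per_rep[(per_rep.estimator == name) & per_rep.ok]
        n = len(g)
        if n == 0:
            agg_rows.append({"estimator": name, "n_ok": 0})
            continue
        bias = g.beta - true_beta
        agg = {
            "estimator": name,
            "n_ok": n,
            "mean_beta": g.beta.mean(),
            "bias": bias.mean(),
            "mc_se_bias": g.beta.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "empirical_se": g.beta.std(ddof=1) if n > 1 else np.nan,
            "mean_est_se": g.se.mean(),
            "coverage": ((g.ci_low <= true_beta) & (true_beta <= g.ci_high)).mean(),
            "rejection_rate": (g.pval < 0.05).mean(),
        }
        if name == "egger" and g.intercept.notna().any():
            agg["mean_intercept"] = g.intercept.mean()
            agg["intercept_bias"] = (g.intercept - true_alpha).mean()
            agg["intercept_rejection_rate"] = (g.intercept_p < 0.05).mean()
        agg_rows.append(agg)
    return per_rep, pd.DataFrame(agg_rows)
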